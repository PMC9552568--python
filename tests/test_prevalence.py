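"""Prevalence reports, person-years, annual migration rule, evaluation."""
from datetime import date

import pytest

from scdcsurv.classification import CaseStatus
from scdcsurv.index import MasterIndex, MasterIndexEntry, ResolvedDemographics
from scdcsurv.linkage import IdentifierSet
from scdcsurv.prevalence import (annual_report, counted_in_year,
                                 cumulative_report, evaluate_against_truth,
                                 pairwise_linkage_metrics, pct_of_total,
                                 person_years, round_half_up,
                                 stratified_report)
from scdcsurv.synthetic import Genotype, Source, SourceRecord

IDS = IdentifierSet("ANNA", "SMITH", date(1990, 4, 12), "123456789", "F",
                    "30301")


def _record(rid, source, day, **kw):
    return SourceRecord(rid, source, IDS, day, **kw)


def _index(entries, records):
    return MasterIndex(entries=entries,
                       records={r.record_id: r for r in records})


def _entry(uid, refs, status, sex="F", birth=date(1990, 4, 12), geno=None,
           death=None):
    return MasterIndexEntry(
        uid, refs, case_status=status.value,
        resolved=ResolvedDemographics(sex=sex, birth_date=birth, genotype=geno),
        death_date=death)


# ---------------------------------------------------------------------------
# rounding and percentage cells
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("x,expected", [
    (16.445, 16.4), (16.45, 16.5), (27.736, 27.7), (0.05, 0.1), (99.95, 100.0),
])
def test_round_half_up(x, expected):
    assert round_half_up(x, 1) == expected


def test_pct_of_total_zero_denominator():
    assert pct_of_total(5, 0) == 0.0


# ---------------------------------------------------------------------------
# cumulative report
# ---------------------------------------------------------------------------


def test_overlap_not_double_counted():
    """One confirmed person in NBS + claims: each source row 1, dedup total 1."""
    records = [
        _record("NBS-1", Source.NBS, date(2010, 4, 15), lab_confirmed=True,
                genotype_result=Genotype.SS_SB0),
        _record("MEDICAID-1", Source.MEDICAID, date(2012, 1, 1),
                enrollment_months=12),
    ]
    entry = _entry("U1", {Source.NBS: ["NBS-1"], Source.MEDICAID: ["MEDICAID-1"]},
                   CaseStatus.CONFIRMED)
    rep = cumulative_report(_index([entry], records), (2004, 2018))
    assert rep.rows[Source.NBS].total == 1
    assert rep.rows[Source.MEDICAID].total == 1
    assert rep.dedup_total == 1
    assert rep.rows[Source.NBS].pct_of_dedup_total == 100.0


def test_possible_tier_excluded_from_reports():
    records = [_record("MEDICAID-1", Source.MEDICAID, date(2012, 1, 1),
                       enrollment_months=12)]
    entry = _entry("U1", {Source.MEDICAID: ["MEDICAID-1"]}, CaseStatus.POSSIBLE)
    rep = cumulative_report(_index([entry], records), (2004, 2018))
    assert rep.dedup_total == 0
    assert all(r.total == 0 for r in rep.rows.values())


def test_empty_index_report_of_zeros():
    rep = cumulative_report(_index([], []), (2004, 2018))
    assert rep.dedup_total == 0


def test_report_conservation_invariants(default_run):
    index = default_run.index
    period = default_run.dataset.config.period
    rep = cumulative_report(index, period)
    assert rep.dedup_confirmed + rep.dedup_probable == rep.dedup_total
    for row in rep.rows.values():
        assert row.confirmed + row.probable == row.total
        assert row.total <= rep.dedup_total
    # overlapping sources never inflate the dedup row
    assert rep.dedup_total <= sum(r.total for r in rep.rows.values())
    # annual never exceeds cumulative
    for year in range(period[0], period[1] + 1):
        annual = annual_report(index, year, period)
        assert annual.dedup_total <= rep.dedup_total


def test_noiseless_report_matches_truth(noiseless_run):
    """Full coverage, zero noise: every source row equals the truth count."""
    ds = noiseless_run.dataset
    rep = cumulative_report(noiseless_run.index, ds.config.period)
    cases = {p.true_id for p in ds.truth if p.has_scd}
    assert rep.dedup_total == len(
        {r.true_id for r in ds.all_records() if r.true_id in cases})
    for source in (Source.NBS, Source.CLINIC, Source.MEDICAID,
                   Source.HOSPITAL_ED):
        in_source = {r.true_id for r in ds.records[source]
                     if r.true_id in cases}
        assert rep.rows[source].total == len(in_source)


# ---------------------------------------------------------------------------
# person-years
# ---------------------------------------------------------------------------


def test_person_years_distinct_calendar_years():
    records = [
        _record("MEDICAID-1", Source.MEDICAID, date(2010, 2, 1),
                enrollment_months=12),
        _record("MEDICAID-2", Source.MEDICAID, date(2010, 11, 1),
                enrollment_months=12),
        _record("MEDICAID-3", Source.MEDICAID, date(2012, 6, 1),
                enrollment_months=6),
    ]
    entry = _entry("U1", {Source.MEDICAID: [r.record_id for r in records]},
                   CaseStatus.PROBABLE)
    index = _index([entry], records)
    assert person_years(index, Source.MEDICAID, (2004, 2018)) == 2
    assert person_years(index, Source.HOSPITAL_ED, (2004, 2018)) == 0


def test_person_years_recount_oracle(default_run):
    """Report person-years equal a direct recount from emitted records."""
    index = default_run.index
    ds = default_run.dataset
    period = ds.config.period
    rep = cumulative_report(index, period)
    counted_uids = set()
    rec_to_uid = index.record_to_uid()
    for e in index.entries:
        if e.case_status in ("CONFIRMED", "PROBABLE"):
            counted_uids.add(e.person_uid)
    for source in (Source.MEDICAID, Source.HOSPITAL_ED):
        recount: dict[str, set] = {}
        for r in ds.records[source]:
            uid = rec_to_uid.get(r.record_id)
            if uid in counted_uids:
                recount.setdefault(uid, set()).add(r.event_date.year)
        expected = sum(len(v) for v in recount.values())
        assert rep.rows[source].person_years == expected


# ---------------------------------------------------------------------------
# annual report and migration adjustment
# ---------------------------------------------------------------------------


def _annual_fixture(record_days, death=None):
    records = [
        _record(f"MEDICAID-{i}", Source.MEDICAID, d, enrollment_months=12)
        for i, d in enumerate(record_days)
    ]
    entry = _entry("U1", {Source.MEDICAID: [r.record_id for r in records]},
                   CaseStatus.PROBABLE, death=death)
    return _index([entry], records)


def test_bracketing_evidence_counts():
    """Records two years before and one year after Y still count the person."""
    index = _annual_fixture([date(2010, 5, 1), date(2013, 2, 1)])
    assert counted_in_year(index.entries[0], index, 2012)
    assert annual_report(index, 2012).dedup_total == 1
    # ... but a source row requires in-year evidence in that source
    assert annual_report(index, 2012).rows[Source.MEDICAID].total == 0


def test_only_prior_evidence_does_not_count():
    index = _annual_fixture([date(2010, 5, 1), date(2011, 2, 1)])
    assert not counted_in_year(index.entries[0], index, 2012)


def test_death_precedence_over_stray_claims():
    """A claim dated after death never revives the person in annual counts."""
    index = _annual_fixture([date(2010, 5, 1), date(2012, 3, 1)],
                            death=date(2011, 6, 1))
    assert not counted_in_year(index.entries[0], index, 2012)


def test_unadjusted_mode_requires_in_year_evidence():
    index = _annual_fixture([date(2010, 5, 1), date(2013, 2, 1)])
    assert annual_report(index, 2012, migration_adjusted=False).dedup_total == 0
    assert annual_report(index, 2013, migration_adjusted=False).dedup_total == 1


def test_annual_year_outside_period_rejected():
    index = _annual_fixture([date(2010, 5, 1)])
    with pytest.raises(ValueError):
        annual_report(index, 2030, period=(2004, 2018))


# ---------------------------------------------------------------------------
# stratified report
# ---------------------------------------------------------------------------


def test_stratified_genotype_percentages():
    genos = [Genotype.SS_SB0, Genotype.SS_SB0, Genotype.SC, Genotype.SB_PLUS]
    records, entries = [], []
    for i, g in enumerate(genos):
        r = _record(f"CLINIC-{i}", Source.CLINIC, date(2018, 3, 1),
                    lab_confirmed=True, genotype_result=g)
        records.append(r)
        entries.append(_entry(f"U{i}", {Source.CLINIC: [r.record_id]},
                              CaseStatus.CONFIRMED, geno=g,
                              birth=date(2000, 1, 1), sex="M" if i < 2 else "F"))
    rep = stratified_report(_index(entries, records), 2018)
    assert rep.dedup.genotype_pct[Genotype.SS_SB0] == 50.0
    assert rep.dedup.genotype_pct[Genotype.SC] == 25.0
    assert rep.dedup.genotype_pct[Genotype.SB_PLUS] == 25.0
    assert rep.dedup.genotype_pct[Genotype.OTHER_SCD] == 0.0
    assert rep.dedup.pct_male == 50.0 and rep.dedup.pct_female == 50.0
    assert rep.dedup.pct_pediatric == 100.0  # all aged 18 at mid-year 2018


def test_pediatric_stratum_inclusive_of_18():
    r = _record("CLINIC-0", Source.CLINIC, date(2018, 3, 1),
                lab_confirmed=True, genotype_result=Genotype.SS_SB0)
    e18 = _entry("U1", {Source.CLINIC: ["CLINIC-0"]}, CaseStatus.CONFIRMED,
                 geno=Genotype.SS_SB0, birth=date(2000, 7, 1))
    e19 = _entry("U2", {Source.CLINIC: ["CLINIC-0"]}, CaseStatus.CONFIRMED,
                 geno=Genotype.SS_SB0, birth=date(1999, 6, 30))
    rep = stratified_report(_index([e18, e19], [r]), 2018)
    assert rep.dedup.pct_pediatric == 50.0


def test_strata_match_generator_marginals(noiseless_run):
    """Noiseless strata reproduce the truth marginals of the annual cohort."""
    ds = noiseless_run.dataset
    year = ds.config.period[1]
    rep = stratified_report(noiseless_run.index, year)
    rec_truth = ds.record_truth_map()
    truth = ds.truth_by_id()
    counted = [e for e in noiseless_run.index.entries
               if e.case_status in ("CONFIRMED", "PROBABLE")
               and counted_in_year(e, noiseless_run.index, year)]
    persons = [truth[rec_truth[e.record_ids[0]]] for e in counted]
    n_male = sum(p.sex == "M" for p in persons)
    assert rep.dedup.n_total == len(persons)
    assert rep.dedup.pct_male == pct_of_total(n_male, len(persons))
    for g in (Genotype.SS_SB0, Genotype.SB_PLUS, Genotype.SC,
              Genotype.OTHER_SCD):
        expected = pct_of_total(sum(p.genotype is g for p in persons),
                                len(persons))
        assert rep.dedup.genotype_pct[g] == expected


# ---------------------------------------------------------------------------
# truth-based evaluation
# ---------------------------------------------------------------------------


def test_evaluation_hand_computed_contingency():
    """Metrics equal the hand-computed 2x2 on a small fixture."""
    from scdcsurv.prevalence import EvaluationResult
    res = EvaluationResult(tp=8, fp=2, fn=1, tn=9)
    assert res.sensitivity == pytest.approx(8 / 9)
    assert res.specificity == pytest.approx(9 / 11)
    assert res.ppv == pytest.approx(0.8)
    assert res.npv == pytest.approx(0.9)


def test_evaluate_against_truth_counts(default_run):
    ds = default_run.dataset
    truth_map = ds.record_truth_map()
    res = evaluate_against_truth(default_run.index, ds.truth, truth_map)
    observed = {truth_map[r.record_id] for r in ds.all_records()}
    assert res.tp + res.fp + res.fn + res.tn == len(observed)
    # a classifier that labels every indexed person PROBABLE maximises
    # sensitivity and zeroes specificity
    for e in default_run.index.entries:
        e.case_status = "PROBABLE"
    all_prob = evaluate_against_truth(default_run.index, ds.truth, truth_map)
    # restore statuses before other session-scoped tests read them
    from scdcsurv.classification import classify_index
    classify_index(default_run.index)
    indexed = {truth_map[rid] for e in default_run.index.entries
               for rid in e.record_ids}
    n_cases_indexed = sum(1 for p in ds.truth
                          if p.has_scd and p.true_id in indexed)
    n_cases_observed = sum(1 for p in ds.truth
                           if p.has_scd and p.true_id in observed)
    assert all_prob.sensitivity == pytest.approx(
        n_cases_indexed / n_cases_observed)
    # every indexed non-case becomes a false positive; only persons whose
    # records never entered the index (out of scope) remain true negatives
    n_noncases_indexed = sum(1 for p in ds.truth
                             if not p.has_scd and p.true_id in indexed)
    assert all_prob.fp == n_noncases_indexed


def test_pairwise_metrics_tiny_fixture():
    clusters = {"a": "c1", "b": "c1", "c": "c2", "d": "c2", "e": "c3"}
    truth = {"a": "p1", "b": "p1", "c": "p1", "d": "p2", "e": "p2"}
    # predicted pairs: (a,b),(c,d); truth pairs: (a,b),(a,c),(b,c)
    res = pairwise_linkage_metrics(clusters, truth)
    assert res.predicted_pairs == 2
    assert res.truth_pairs == 4  # {a,b,c} has 3 pairs + {d,e} has 1
    assert res.true_positive_pairs == 1
    assert res.precision == 0.5
    assert res.recall == 0.25
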