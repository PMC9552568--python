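"""Prevalence reports and truth-based evaluation.

Surveillance programs publish two views of the linked, classified index:

* a **cumulative** report over the whole surveillance period — confirmed and
  probable persons, broken down by contributing source (a person counts in a
  source row if at least one of their linked records from that source is
  dated in-period), with each source's share of the deduplicated total and
  person-years of longitudinal follow-up;
* an **annual** report for one index year with a migration adjustment: a
  person counts in year Y only with evidence of in-state health care use
  during Y, or both before and after Y, and only if not known dead before Y.

Possible-tier persons are excluded from both reports. A stratified view adds
genotype shares among confirmed cases, sex, and the pediatric (0-18 years,
inclusive) stratum, with ages taken at mid-year (July 1). All percentages are
rounded half-up to one decimal, the convention of published surveillance
tables; on synthetic data the pipeline output can additionally be scored
against the generator's ground truth with standard 2x2 validation metrics.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import pandas as pd

from .classification import CaseStatus
from .index import MasterIndex, MasterIndexEntry
from .synthetic import Genotype, PersonTruth, Source

LONGITUDINAL_SOURCES = (Source.MEDICAID, Source.HOSPITAL_ED)
REPORT_SOURCES = (Source.NBS, Source.CLINIC, Source.MEDICAID, Source.HOSPITAL_ED)
REPORTED_STATUSES = (CaseStatus.CONFIRMED.value, CaseStatus.PROBABLE.value)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (printed-table convention), not banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct_of_total(part: int, total: int) -> float:
    """A percentage cell: 100 * part / total, rounded half-up to 1 decimal."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * part / total, 1)


@dataclass
class SourceRow:
    confirmed: int
    probable: int
    pct_of_dedup_total: float
    person_years: Optional[int] = None  # longitudinal sources only

    @property
    def total(self) -> int:
        return self.confirmed + self.probable


@dataclass
class PrevalenceReport:
    period: tuple[int, int]
    rows: dict  # Source -> SourceRow
    dedup_confirmed: int
    dedup_probable: int

    @property
    def dedup_total(self) -> int:
        return self.dedup_confirmed + self.dedup_probable

    def to_frame(self) -> pd.DataFrame:
        data = []
        for source in REPORT_SOURCES:
            row = self.rows[source]
            data.append([source.value, row.confirmed, row.probable, row.total,
                         row.pct_of_dedup_total,
                         row.person_years if row.person_years is not None else ""])
        data.append(["DEDUPLICATED_TOTAL", self.dedup_confirmed,
                     self.dedup_probable, self.dedup_total,
                     pct_of_total(self.dedup_total, self.dedup_total), ""])
        return pd.DataFrame(data, columns=[
            "source", "confirmed", "probable", "total",
            "pct_of_dedup_total", "person_years"])


def _in_period(year: int, period: tuple[int, int]) -> bool:
    return period[0] <= year <= period[1]


def _source_years(entry: MasterIndexEntry, index: MasterIndex, source: Source,
                  period: tuple[int, int]) -> set[int]:
    return {index.records[rid].event_date.year
            for rid in entry.source_refs.get(source, [])
            if _in_period(index.records[rid].event_date.year, period)}


def _counted_entries(index: MasterIndex, period: tuple[int, int]
                     ) -> list[MasterIndexEntry]:
    return [e for e in index.entries
            if e.case_status in REPORTED_STATUSES
            and any(_source_years(e, index, s, period) for s in REPORT_SOURCES)]


def person_years(index: MasterIndex, source: Source,
                 period: tuple[int, int],
                 entries: Optional[Sequence[MasterIndexEntry]] = None) -> int:
    """Calendar years with evidence in one longitudinal source, summed over
    the report's counted persons.

    A year qualifies with at least one in-period record in the source; for
    Medicaid, a record with positive reported enrollment months also
    qualifies its year.
    """
    if entries is None:
        entries = _counted_entries(index, period)
    total = 0
    for e in entries:
        years = set()
        for rid in e.source_refs.get(source, []):
            r = index.records[rid]
            if not _in_period(r.event_date.year, period):
                continue
            # enrollment_months == 0 on a claim marks a reporting artifact
            # (no actual coverage that year) and does not qualify the year
            if source is Source.MEDICAID:
                if r.enrollment_months is None or r.enrollment_months > 0:
                    years.add(r.event_date.year)
            else:
                years.add(r.event_date.year)
        total += len(years)
    return total


def cumulative_report(index: MasterIndex,
                      period: tuple[int, int]) -> PrevalenceReport:
    """Cumulative confirmed + probable counts by source over a period."""
    counted = _counted_entries(index, period)
    dedup_c = sum(1 for e in counted if e.case_status == CaseStatus.CONFIRMED.value)
    dedup_p = len(counted) - dedup_c
    dedup_total = dedup_c + dedup_p
    rows = {}
    for source in REPORT_SOURCES:
        in_source = [e for e in counted if _source_years(e, index, source, period)]
        c = sum(1 for e in in_source if e.case_status == CaseStatus.CONFIRMED.value)
        p = len(in_source) - c
        rows[source] = SourceRow(
            confirmed=c, probable=p,
            pct_of_dedup_total=pct_of_total(c + p, dedup_total),
            person_years=(person_years(index, source, period, in_source)
                          if source in LONGITUDINAL_SOURCES else None),
        )
    return PrevalenceReport(period=period, rows=rows,
                            dedup_confirmed=dedup_c, dedup_probable=dedup_p)


def _health_care_years(entry: MasterIndexEntry, index: MasterIndex) -> list[int]:
    return sorted({index.records[rid].event_date.year
                   for s in REPORT_SOURCES
                   for rid in entry.source_refs.get(s, [])})


def counted_in_year(entry: MasterIndexEntry, index: MasterIndex, year: int,
                    migration_adjusted: bool = True) -> bool:
    """Annual inclusion rule.

    A person counts in year Y if not known dead before January 1 of Y, and
    either has a health-care record dated in Y, or (migration-adjusted mode)
    has records both before and after Y — bracketing evidence that the person
    remained in state through a quiet year.
    """
    if entry.death_date is not None and entry.death_date < date(year, 1, 1):
        return False
    years = _health_care_years(entry, index)
    if year in years:
        return True
    if migration_adjusted:
        return any(y < year for y in years) and any(y > year for y in years)
    return False


def annual_report(index: MasterIndex, year: int,
                  period: Optional[tuple[int, int]] = None,
                  migration_adjusted: bool = True) -> PrevalenceReport:
    """One-year prevalence with the migration adjustment.

    Source rows count persons with in-year evidence in that source; the
    deduplicated row additionally includes persons counted only through
    bracketing evidence.
    """
    if period is not None and not _in_period(year, period):
        raise ValueError(f"year {year} outside surveillance period {period}")
    counted = [e for e in index.entries
               if e.case_status in REPORTED_STATUSES
               and counted_in_year(e, index, year, migration_adjusted)]
    dedup_c = sum(1 for e in counted if e.case_status == CaseStatus.CONFIRMED.value)
    dedup_p = len(counted) - dedup_c
    dedup_total = dedup_c + dedup_p
    rows = {}
    yr = (year, year)
    for source in REPORT_SOURCES:
        in_source = [e for e in counted if _source_years(e, index, source, yr)]
        c = sum(1 for e in in_source if e.case_status == CaseStatus.CONFIRMED.value)
        p = len(in_source) - c
        rows[source] = SourceRow(
            confirmed=c, probable=p,
            pct_of_dedup_total=pct_of_total(c + p, dedup_total),
            person_years=None,
        )
    return PrevalenceReport(period=yr, rows=rows,
                            dedup_confirmed=dedup_c, dedup_probable=dedup_p)


# ---------------------------------------------------------------------------
# stratified (genotype / sex / age) report
# ---------------------------------------------------------------------------

_GENOTYPE_COLUMNS = (Genotype.SS_SB0, Genotype.SB_PLUS, Genotype.SC,
                     Genotype.OTHER_SCD)


@dataclass
class StratifiedRow:
    n_confirmed: int
    genotype_pct: dict  # Genotype -> % among confirmed with known genotype
    unknown_genotype: int  # probable + confirmed lacking a genotype result
    n_total: int
    pct_male: float
    pct_female: float
    pct_pediatric: float  # aged 0-18 inclusive at mid-year


@dataclass
class StratifiedReport:
    year: int
    rows: dict  # Source -> StratifiedRow
    dedup: StratifiedRow = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        data = []
        for label, row in [*[(s.value, self.rows[s]) for s in REPORT_SOURCES],
                           ("DEDUPLICATED_TOTAL", self.dedup)]:
            data.append([label, row.n_confirmed,
                         *[row.genotype_pct[g] for g in _GENOTYPE_COLUMNS],
                         row.unknown_genotype, row.n_total, row.pct_male,
                         row.pct_female, row.pct_pediatric])
        return pd.DataFrame(data, columns=[
            "source", "confirmed", "pct_ss_sb0", "pct_sb_plus", "pct_sc",
            "pct_other_scd", "unknown_genotype", "total", "pct_male",
            "pct_female", "pct_aged_0_18"])


def _stratified_row(entries: Sequence[MasterIndexEntry], year: int
                    ) -> StratifiedRow:
    confirmed = [e for e in entries
                 if e.case_status == CaseStatus.CONFIRMED.value]
    known = [e for e in confirmed if e.resolved.genotype is not None]
    geno_pct = {
        g: pct_of_total(sum(1 for e in known if e.resolved.genotype is g),
                        len(known))
        for g in _GENOTYPE_COLUMNS
    }
    unknown = len(entries) - len(known)
    midyear = date(year, 7, 1)
    n_sexed = sum(1 for e in entries if e.resolved.sex in ("M", "F"))
    n_male = sum(1 for e in entries if e.resolved.sex == "M")
    n_ped = 0
    n_aged = 0
    for e in entries:
        b = e.resolved.birth_date
        if b is None or b > midyear:
            continue
        n_aged += 1
        age = midyear.year - b.year - ((midyear.month, midyear.day) < (b.month, b.day))
        if age <= 18:
            n_ped += 1
    return StratifiedRow(
        n_confirmed=len(confirmed),
        genotype_pct=geno_pct,
        unknown_genotype=unknown,
        n_total=len(entries),
        pct_male=pct_of_total(n_male, n_sexed),
        pct_female=pct_of_total(n_sexed - n_male, n_sexed),
        pct_pediatric=pct_of_total(n_ped, n_aged),
    )


def stratified_report(index: MasterIndex, year: int,
                      migration_adjusted: bool = True) -> StratifiedReport:
    """Genotype, sex, and pediatric strata of the annual prevalent cohort."""
    counted = [e for e in index.entries
               if e.case_status in REPORTED_STATUSES
               and counted_in_year(e, index, year, migration_adjusted)]
    yr = (year, year)
    rows = {}
    for source in REPORT_SOURCES:
        in_source = [e for e in counted if _source_years(e, index, source, yr)]
        rows[source] = _stratified_row(in_source, year)
    return StratifiedReport(year=year, rows=rows,
                            dedup=_stratified_row(counted, year))


# ---------------------------------------------------------------------------
# truth-based evaluation (synthetic data only)
# ---------------------------------------------------------------------------


@dataclass
class EvaluationResult:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else float("nan")


def evaluate_against_truth(index: MasterIndex,
                           truth: Sequence[PersonTruth],
                           record_truth: dict[str, str]) -> EvaluationResult:
    """Score reported case status (confirmed or probable) against ground truth.

    The denominator is every true person with at least one record that
    entered the pipeline (persons invisible to every source cannot be found
    by any surveillance system). A true person is predicted positive when any
    of their records belongs to an index entry classified confirmed or
    probable.
    """
    observed: set[str] = {record_truth[rid] for rid in index.records
                          if rid in record_truth}
    positive_truth_ids: set[str] = set()
    for e in index.entries:
        if e.case_status in REPORTED_STATUSES:
            positive_truth_ids.update(
                record_truth[rid] for rid in e.record_ids if rid in record_truth)
    tp = fp = fn = tn = 0
    for p in truth:
        if p.true_id not in observed:
            continue
        predicted = p.true_id in positive_truth_ids
        if p.has_scd:
            tp += predicted
            fn += not predicted
        else:
            fp += predicted
            tn += not predicted
    return EvaluationResult(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass
class PairwiseLinkageResult:
    true_positive_pairs: int
    predicted_pairs: int
    truth_pairs: int

    @property
    def precision(self) -> float:
        return (self.true_positive_pairs / self.predicted_pairs
                if self.predicted_pairs else 1.0)

    @property
    def recall(self) -> float:
        return (self.true_positive_pairs / self.truth_pairs
                if self.truth_pairs else 1.0)

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def pairwise_linkage_metrics(clusters: dict[str, str],
                             record_truth: dict[str, str]
                             ) -> PairwiseLinkageResult:
    """Pairwise precision/recall of a clustering against true identities.

    ``clusters`` maps record_id -> cluster label; metrics are computed over
    the records present in that mapping. Pair counts use the standard
    same-cluster / same-person contingency computed from group sizes rather
    than explicit pair enumeration.
    """
    from collections import Counter

    records = list(clusters)
    truth_sizes = Counter(record_truth[r] for r in records)
    pred_sizes = Counter(clusters[r] for r in records)
    joint_sizes = Counter((clusters[r], record_truth[r]) for r in records)
    n2 = lambda n: n * (n - 1) // 2
    return PairwiseLinkageResult(
        true_positive_pairs=sum(n2(v) for v in joint_sizes.values()),
        predicted_pairs=sum(n2(v) for v in pred_sizes.values()),
        truth_pairs=sum(n2(v) for v in truth_sizes.values()),
    )
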