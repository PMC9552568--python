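"""Build the hub-and-spoke master index from the five source files.

The index is built in the fixed order used by state surveillance programs:

1. each source file is cleaned and deduplicated on its own;
2. the confirmed-case sources (newborn screening and clinic reports) are
   linked into a confirmed-person index;
3. administrative sources (Medicaid/CHIP claims, hospital/ED discharges) are
   filtered to persons with at least one SCD- or trait-coded encounter and
   linked into an administrative index;
4. the two indices are merged: confirmed persons absorb their administrative
   records, and administrative persons with no confirmed match pass to the
   case-definition algorithm on their own;
5. death certificates are linked last as supplementary data — a death record
   can attach a death date to an indexed person but never creates a person.

The result is a partition: every non-quarantined, in-scope record belongs to
exactly one person entry (the hub), and each entry keeps provenance links to
all of its source records (the spokes). Person uids are deterministic hashes
of the member record ids at first creation and are preserved across
incremental re-runs, so adding a new year of data never renames or splits an
existing person.
"""
from __future__ import annotations

import csv
import hashlib
from collections import Counter
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .codes import CodeCategory, classify_code
from .linkage import (IdentifierSet, LinkDecision, LinkageConfig, resolve)
from .synthetic import Source, SourceRecord, Genotype

DEFAULT_DEMOGRAPHIC_PRIORITY = (Source.NBS, Source.CLINIC, Source.MEDICAID,
                                Source.HOSPITAL_ED, Source.DEATH)


# ---------------------------------------------------------------------------
# entities: within-source deduplicated persons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Entity:
    """One deduplicated person within a source (or stratum), linkable again."""

    record_id: str  # entity id; named so the linkage engine can consume it
    sources: frozenset
    member_records: tuple[str, ...]
    ids: IdentifierSet


def representative_ids(idsets: Sequence[IdentifierSet]) -> IdentifierSet:
    """Per-field plurality vote over member records, ignoring missing values.

    Ties break deterministically toward the smallest value so reruns are
    stable.
    """
    out = {}
    for f in ("first_name", "last_name", "dob", "ssn", "sex", "zip"):
        values = [getattr(i, f) for i in idsets if getattr(i, f) is not None]
        if not values:
            out[f] = None
            continue
        counts = Counter(values)
        best = max(counts.items(), key=lambda kv: (kv[1], _neg_key(kv[0])))
        out[f] = best[0]
    return IdentifierSet(**out)


def _neg_key(v):
    # invert ordering so max() prefers the smallest value on count ties
    s = v.isoformat() if isinstance(v, date) else str(v)
    return tuple(-ord(c) for c in s)


def _malformed(r: SourceRecord) -> Optional[str]:
    i = r.ids
    if i.first_name is None and i.last_name is None and i.ssn is None and i.dob is None:
        return "all linking identifiers missing"
    return None


def dedupe_source(records: Sequence[SourceRecord], config: LinkageConfig,
                  period: Optional[tuple[int, int]] = None,
                  ) -> tuple[list[Entity], list[tuple[str, str]], list[LinkDecision]]:
    """Clean and deduplicate one source file.

    Returns (entities, quarantined, audit). Records with no usable linking
    identifiers, or dated outside the surveillance period when one is given,
    are quarantined with a reason — never silently dropped.
    """
    good, quarantined = [], []
    for r in records:
        reason = _malformed(r)
        if reason is None and period is not None:
            if not (period[0] <= r.event_date.year <= period[1]):
                reason = "event date outside surveillance period"
        if reason is None:
            good.append(r)
        else:
            quarantined.append((r.record_id, reason))
    clusters, audit = resolve(good, config)
    by_id = {r.record_id: r for r in good}
    entities = []
    source = records[0].source if records else None
    for members in clusters:
        idsets = [by_id[m].ids for m in members]
        entities.append(Entity(
            record_id=f"E-{members[0]}",
            sources=frozenset({source}) if source else frozenset(),
            member_records=tuple(members),
            ids=representative_ids(idsets),
        ))
    return entities, quarantined, audit


def _merge_entities(groups: Iterable[Sequence[Entity]]) -> list[Entity]:
    out = []
    for group in groups:
        members = tuple(sorted(m for e in group for m in e.member_records))
        sources = frozenset(s for e in group for s in e.sources)
        out.append(Entity(
            record_id=f"E-{members[0]}",
            sources=sources,
            member_records=members,
            ids=representative_ids([e.ids for e in group]),
        ))
    return out


def _link_entity_pool(entities: list[Entity], config: LinkageConfig
                      ) -> tuple[list[Entity], list[LinkDecision]]:
    """Link a pool of entities (within and across sources) and merge clusters."""
    if not entities:
        return [], []
    clusters, audit = resolve(entities, config)
    by_id = {e.record_id: e for e in entities}
    merged = _merge_entities([[by_id[m] for m in members] for members in clusters])
    return merged, audit


def build_confirmed_index(nbs_entities: list[Entity],
                          clinic_entities: list[Entity],
                          config: LinkageConfig,
                          ) -> tuple[list[Entity], list[LinkDecision]]:
    """Link the laboratory-bearing sources into the confirmed-person index."""
    return _link_entity_pool(list(nbs_entities) + list(clinic_entities), config)


def has_relevant_codes(records: Iterable[SourceRecord]) -> bool:
    """True if any encounter carries an SCD or trait diagnosis code."""
    for r in records:
        for dx in r.diagnosis_codes:
            if classify_code(dx.system, dx.code) is not CodeCategory.OTHER:
                return True
    return False


def build_admin_index(medicaid_entities: list[Entity],
                      hospital_entities: list[Entity],
                      records_by_id: dict[str, SourceRecord],
                      config: LinkageConfig,
                      ) -> tuple[list[Entity], list[Entity], list[LinkDecision]]:
    """Link administrative persons carrying at least one SCD/trait code.

    Entities with no relevant diagnosis code are out of surveillance scope
    and returned separately (second element) rather than indexed.
    """
    pool, out_of_scope = [], []
    for e in list(medicaid_entities) + list(hospital_entities):
        recs = [records_by_id[m] for m in e.member_records]
        (pool if has_relevant_codes(recs) else out_of_scope).append(e)
    linked, audit = _link_entity_pool(pool, config)
    return linked, out_of_scope, audit


# ---------------------------------------------------------------------------
# master index
# ---------------------------------------------------------------------------


@dataclass
class ResolvedDemographics:
    sex: Optional[str] = None
    sex_source: Optional[Source] = None
    birth_date: Optional[date] = None
    birth_date_source: Optional[Source] = None
    genotype: Optional[Genotype] = None
    genotype_source: Optional[Source] = None


@dataclass
class MasterIndexEntry:
    person_uid: str
    source_refs: dict  # Source -> sorted list of record ids
    case_status: str = "NONE"  # filled by the case-classification stage
    resolved: ResolvedDemographics = field(default_factory=ResolvedDemographics)
    death_date: Optional[date] = None

    @property
    def record_ids(self) -> list[str]:
        return [m for recs in self.source_refs.values() for m in recs]


def _uid_for(members: Sequence[str]) -> str:
    digest = hashlib.sha1(",".join(sorted(members)).encode()).hexdigest()
    return f"U{digest[:12]}"


@dataclass
class MasterIndex:
    entries: list[MasterIndexEntry]
    records: dict[str, SourceRecord]
    quarantined: list[tuple[str, str]] = field(default_factory=list)
    out_of_scope_records: list[str] = field(default_factory=list)
    unmatched_deaths: list[str] = field(default_factory=list)
    demographic_conflicts: list[tuple[str, str, str]] = field(default_factory=list)
    audit: list[LinkDecision] = field(default_factory=list)

    def by_uid(self) -> dict[str, MasterIndexEntry]:
        return {e.person_uid: e for e in self.entries}

    def record_to_uid(self) -> dict[str, str]:
        return {rid: e.person_uid for e in self.entries for rid in e.record_ids}

    # -- persistence: hub (persons) + spokes (crosswalk) ---------------------

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "persons.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["person_uid", "case_status", "sex", "sex_source",
                        "birth_date", "birth_date_source", "genotype",
                        "genotype_source", "death_date"])
            for e in sorted(self.entries, key=lambda e: e.person_uid):
                r = e.resolved
                w.writerow([
                    e.person_uid, e.case_status,
                    r.sex or "", r.sex_source.value if r.sex_source else "",
                    r.birth_date.isoformat() if r.birth_date else "",
                    r.birth_date_source.value if r.birth_date_source else "",
                    r.genotype.value if r.genotype else "",
                    r.genotype_source.value if r.genotype_source else "",
                    e.death_date.isoformat() if e.death_date else "",
                ])
        with open(outdir / "crosswalk.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["person_uid", "source", "record_id"])
            for e in sorted(self.entries, key=lambda e: e.person_uid):
                for source in Source:
                    for rid in e.source_refs.get(source, []):
                        w.writerow([e.person_uid, source.value, rid])
        with open(outdir / "exceptions.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["record_id", "reason"])
            for rid, reason in self.quarantined:
                w.writerow([rid, reason])
            for rid in self.unmatched_deaths:
                w.writerow([rid, "death record matched no indexed person"])
        with open(outdir / "linkage_audit.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["record_a", "record_b", "pattern", "weight", "status",
                        "rule"])
            for d in self.audit:
                pat = ";".join(f"{f}={v}" for f, v in d.pattern)
                w.writerow([d.record_a, d.record_b, pat, f"{d.weight:.6f}",
                            d.status.value, d.rule])

    @staticmethod
    def read_entries(indir: str | Path) -> list[MasterIndexEntry]:
        indir = Path(indir)
        entries: dict[str, MasterIndexEntry] = {}
        with open(indir / "persons.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                entries[row["person_uid"]] = MasterIndexEntry(
                    person_uid=row["person_uid"],
                    source_refs={},
                    case_status=row["case_status"],
                    resolved=ResolvedDemographics(
                        sex=row["sex"] or None,
                        sex_source=Source(row["sex_source"]) if row["sex_source"] else None,
                        birth_date=(date.fromisoformat(row["birth_date"])
                                    if row["birth_date"] else None),
                        birth_date_source=(Source(row["birth_date_source"])
                                           if row["birth_date_source"] else None),
                        genotype=(Genotype(row["genotype"])
                                  if row["genotype"] else None),
                        genotype_source=(Source(row["genotype_source"])
                                         if row["genotype_source"] else None),
                    ),
                    death_date=(date.fromisoformat(row["death_date"])
                                if row["death_date"] else None),
                )
        with open(indir / "crosswalk.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                refs = entries[row["person_uid"]].source_refs
                refs.setdefault(Source(row["source"]), []).append(row["record_id"])
        return list(entries.values())


# ---------------------------------------------------------------------------
# demographic resolution
# ---------------------------------------------------------------------------


def resolve_demographics(entry: MasterIndexEntry,
                         records_by_id: dict[str, SourceRecord],
                         priority: Sequence[Source] = DEFAULT_DEMOGRAPHIC_PRIORITY,
                         ) -> tuple[ResolvedDemographics, list[tuple[str, str, str]]]:
    """Take each demographic field from the most-reliable source holding it.

    Within a source, members vote by plurality. Genotype comes only from the
    laboratory-bearing sources; a genotype disagreement between sources is
    resolved by priority and reported as a conflict for review.
    """
    resolved = ResolvedDemographics()
    conflicts: list[tuple[str, str, str]] = []

    def pick(getter):
        for source in priority:
            vals = [getter(records_by_id[rid])
                    for rid in entry.source_refs.get(source, [])]
            vals = [v for v in vals if v is not None]
            if vals:
                counts = Counter(vals)
                best = max(counts.items(), key=lambda kv: (kv[1], _neg_key(kv[0])))
                return best[0], source
        return None, None

    resolved.sex, resolved.sex_source = pick(lambda r: r.ids.sex)
    resolved.birth_date, resolved.birth_date_source = pick(lambda r: r.ids.dob)
    resolved.genotype, resolved.genotype_source = pick(
        lambda r: r.genotype_result if r.source in (Source.NBS, Source.CLINIC) else None)

    if resolved.genotype is not None:
        seen = {r.genotype_result
                for rid in entry.record_ids
                for r in [records_by_id[rid]]
                if r.genotype_result is not None}
        if len(seen) > 1:
            conflicts.append((entry.person_uid, "genotype",
                              ",".join(sorted(g.value for g in seen))))
    return resolved, conflicts


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------


def build_master_index(records: dict[Source, list[SourceRecord]],
                       config: Optional[LinkageConfig] = None,
                       period: Optional[tuple[int, int]] = None,
                       prior: Optional[MasterIndex] = None,
                       priority: Sequence[Source] = DEFAULT_DEMOGRAPHIC_PRIORITY,
                       ) -> MasterIndex:
    """Run the dedup/link/merge/supplement pipeline and return the index."""
    config = config or LinkageConfig()
    audit: list[LinkDecision] = []
    quarantined: list[tuple[str, str]] = []
    records_by_id = {r.record_id: r for s in Source for r in records.get(s, [])}

    per_source_entities: dict[Source, list[Entity]] = {}
    for source in (Source.NBS, Source.CLINIC, Source.MEDICAID,
                   Source.HOSPITAL_ED, Source.DEATH):
        ents, quar, aud = dedupe_source(records.get(source, []), config, period)
        per_source_entities[source] = ents
        quarantined.extend(quar)
        audit.extend(aud)

    confirmed, aud = build_confirmed_index(
        per_source_entities[Source.NBS], per_source_entities[Source.CLINIC],
        config)
    audit.extend(aud)

    admin, out_of_scope, aud = build_admin_index(
        per_source_entities[Source.MEDICAID],
        per_source_entities[Source.HOSPITAL_ED], records_by_id, config)
    audit.extend(aud)

    merged_entities, aud = merge_indices(confirmed, admin, config)
    audit.extend(aud)

    # assemble entries with deterministic (and re-entrant) uids
    prior_uid_of: dict[str, str] = prior.record_to_uid() if prior else {}
    entries: list[MasterIndexEntry] = []
    for ent in merged_entities:
        prior_uids = sorted({prior_uid_of[m] for m in ent.member_records
                             if m in prior_uid_of})
        uid = prior_uids[0] if prior_uids else _uid_for(ent.member_records)
        refs: dict[Source, list[str]] = {}
        for rid in ent.member_records:
            refs.setdefault(records_by_id[rid].source, []).append(rid)
        refs = {s: sorted(v) for s, v in refs.items()}
        entries.append(MasterIndexEntry(person_uid=uid, source_refs=refs))

    index = MasterIndex(
        entries=entries,
        records=records_by_id,
        quarantined=quarantined,
        out_of_scope_records=[m for e in out_of_scope for m in e.member_records],
        audit=audit,
    )

    death_aud = attach_supplementary(index, per_source_entities[Source.DEATH],
                                     config)
    index.audit.extend(death_aud)

    for entry in index.entries:
        entry.resolved, conflicts = resolve_demographics(entry, records_by_id,
                                                         priority)
        index.demographic_conflicts.extend(conflicts)
    return index


def merge_indices(confirmed: list[Entity], admin: list[Entity],
                  config: LinkageConfig,
                  ) -> tuple[list[Entity], list[LinkDecision]]:
    """Link confirmed persons to administrative persons and merge matches.

    Unmatched administrative persons are retained as their own entries (the
    case-definition algorithm classifies them as probable/possible);
    unmatched confirmed persons are retained unchanged.
    """
    if not confirmed or not admin:
        return list(confirmed) + list(admin), []
    clusters, audit = resolve(confirmed, config, records_b=admin)
    by_id = {e.record_id: e for e in confirmed + admin}
    merged = _merge_entities([[by_id[m] for m in members] for members in clusters])
    return merged, audit


def attach_supplementary(index: MasterIndex, death_entities: list[Entity],
                         config: LinkageConfig) -> list[LinkDecision]:
    """Link death certificates to indexed persons; never create a person."""
    if not death_entities or not index.entries:
        index.unmatched_deaths.extend(
            m for e in death_entities for m in e.member_records)
        return []
    person_entities = [
        Entity(record_id=f"X-{e.person_uid}",
               sources=frozenset(e.source_refs),
               member_records=tuple(sorted(e.record_ids)),
               ids=representative_ids([index.records[r].ids
                                       for r in e.record_ids]))
        for e in index.entries
    ]
    clusters, audit = resolve(person_entities, config, records_b=death_entities)
    by_uid = index.by_uid()
    death_by_id = {e.record_id: e for e in death_entities}
    for members in clusters:
        persons = [m[2:] for m in members if m.startswith("X-")]
        deaths = [death_by_id[m] for m in members if not m.startswith("X-")]
        if not deaths:
            continue
        if not persons:
            index.unmatched_deaths.extend(
                m for e in deaths for m in e.member_records)
            continue
        # a death entity matching several persons attaches to each; in
        # practice clusters hold one person and one death entity
        for uid in persons:
            entry = by_uid[uid]
            rids = sorted(m for e in deaths for m in e.member_records)
            entry.source_refs.setdefault(Source.DEATH, []).extend(rids)
            entry.source_refs[Source.DEATH] = sorted(set(entry.source_refs[Source.DEATH]))
            dates = [index.records[r].event_date for r in rids]
            entry.death_date = min(dates)
    return audit
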