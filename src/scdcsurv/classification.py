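"""The three-tier surveillance case definition.

Each indexed person is classified into exactly one tier:

* **CONFIRMED** — laboratory evidence: a newborn-screening SCD result with
  confirmatory testing, or a physician diagnosis with documented confirmatory
  testing from a CLIA-certified laboratory.
* **PROBABLE** — an NBS result without confirmatory testing, a clinical
  diagnosis without documented laboratory confirmation, or an SCD diagnosis
  code (excluding sickle cell trait) on three or more separate health care
  encounters within a 5-year period.
* **POSSIBLE** — any SCD or trait diagnosis code on at least one encounter,
  short of the probable tier (typically one or two coded encounters); most
  such persons do not have SCD, so this tier is retained in the index
  (future data may upgrade it) but excluded from reports.
* **NONE** — no qualifying evidence.

"Separate encounters" means distinct service dates after pooling claims and
hospital records: the same calendar date billed to both sources counts once.
The 5-year window is a rolling 1826-day span (5 x 365.25, rounded down),
inclusive at the boundary. An encounter carrying both trait and non-trait SCD
codes counts as an SCD encounter.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from enum import Enum
from typing import Sequence

from .codes import CodeCategory, classify_code
from .index import MasterIndexEntry
from .synthetic import Source, SourceRecord

FIVE_YEAR_WINDOW_DAYS = 1826


class CaseStatus(str, Enum):
    CONFIRMED = "CONFIRMED"
    PROBABLE = "PROBABLE"
    POSSIBLE = "POSSIBLE"
    NONE = "NONE"


_RANK = {CaseStatus.NONE: 0, CaseStatus.POSSIBLE: 1,
         CaseStatus.PROBABLE: 2, CaseStatus.CONFIRMED: 3}


def status_rank(status: CaseStatus | str) -> int:
    return _RANK[CaseStatus(status)]


@dataclass(frozen=True)
class CaseEvidence:
    nbs_confirmed: bool = False
    nbs_unconfirmed: bool = False
    clinical_dx_with_lab: bool = False
    clinical_dx_without_lab: bool = False
    scd_encounter_dates: tuple[date, ...] = ()    # sorted, distinct
    trait_encounter_dates: tuple[date, ...] = ()  # sorted, distinct, trait-only

    def __post_init__(self):
        for dates in (self.scd_encounter_dates, self.trait_encounter_dates):
            if list(dates) != sorted(set(dates)):
                raise ValueError("encounter dates must be sorted and distinct")


def has_three_in_window(dates: Sequence[date],
                        window_days: int = FIVE_YEAR_WINDOW_DAYS) -> bool:
    """True iff three of the (sorted, distinct) dates fall within the window.

    Checks consecutive triples: any qualifying triple contains a consecutive
    one, so dates[i+2] - dates[i] <= window_days for some i is equivalent.
    """
    if list(dates) != sorted(set(dates)):
        raise ValueError("dates must be sorted ascending and pairwise distinct")
    return any((dates[i + 2] - dates[i]).days <= window_days
               for i in range(len(dates) - 2))


def classify_case(ev: CaseEvidence,
                  window_days: int = FIVE_YEAR_WINDOW_DAYS) -> CaseStatus:
    """Apply the tiered case definition with strict precedence.

    Persons with three or more SCD-coded encounters none of which form a
    qualifying 5-year triple do not meet the probable tier; they are kept as
    POSSIBLE so later encounters can upgrade them.
    """
    if ev.nbs_confirmed or ev.clinical_dx_with_lab:
        return CaseStatus.CONFIRMED
    if (ev.nbs_unconfirmed or ev.clinical_dx_without_lab
            or has_three_in_window(ev.scd_encounter_dates, window_days)):
        return CaseStatus.PROBABLE
    # any coded encounter short of the probable tier is possible: the
    # one-or-two-encounter clause, extended so that persons with three or
    # more coded dates that never satisfy the 5-year condition (for example
    # trait-only histories) are retained rather than dropped to NONE —
    # classification must only ever move upward as evidence accumulates
    n_any = len(set(ev.scd_encounter_dates) | set(ev.trait_encounter_dates))
    if n_any >= 1:
        return CaseStatus.POSSIBLE
    return CaseStatus.NONE


def assemble_evidence(entry: MasterIndexEntry,
                      records_by_id: dict[str, SourceRecord]) -> CaseEvidence:
    """Pool one person's linked records into case-definition evidence.

    Encounter dates are pooled across Medicaid and hospital/ED records and
    reduced to distinct calendar dates; a date with any non-trait SCD code is
    an SCD encounter even if trait codes also appear on that date.
    """
    nbs_confirmed = nbs_unconfirmed = False
    dx_with_lab = dx_without_lab = False
    scd_dates: set[date] = set()
    trait_dates: set[date] = set()
    for source in (Source.NBS, Source.CLINIC, Source.MEDICAID,
                   Source.HOSPITAL_ED):
        for rid in entry.source_refs.get(source, []):
            r = records_by_id[rid]
            if source is Source.NBS:
                if r.lab_confirmed:
                    nbs_confirmed = True
                else:
                    nbs_unconfirmed = True
            elif source is Source.CLINIC:
                if r.lab_confirmed:
                    dx_with_lab = True
                else:
                    dx_without_lab = True
            else:
                cats = {classify_code(dx.system, dx.code)
                        for dx in r.diagnosis_codes}
                if CodeCategory.SCD in cats:
                    scd_dates.add(r.event_date)
                elif CodeCategory.TRAIT in cats:
                    trait_dates.add(r.event_date)
    trait_dates -= scd_dates  # SCD takes precedence on a shared date
    return CaseEvidence(
        nbs_confirmed=nbs_confirmed,
        nbs_unconfirmed=nbs_unconfirmed,
        clinical_dx_with_lab=dx_with_lab,
        clinical_dx_without_lab=dx_without_lab,
        scd_encounter_dates=tuple(sorted(scd_dates)),
        trait_encounter_dates=tuple(sorted(trait_dates)),
    )


def classify_index(index, window_days: int = FIVE_YEAR_WINDOW_DAYS) -> None:
    """Classify every person in a master index in place."""
    for entry in index.entries:
        ev = assemble_evidence(entry, index.records)
        entry.case_status = classify_case(ev, window_days).value
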