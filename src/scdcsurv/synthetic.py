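"""Seeded synthetic multi-source surveillance data with known ground truth.

Real state surveillance links five administrative/clinical sources — newborn
screening (NBS), clinic case reports, Medicaid/CHIP claims, hospital and
emergency department discharges, and death certificates — none of which covers
the whole case population. Those data are protected health records, so this
module generates a population with known disease status and emits the five
source files with the structural features the pipeline must survive:

* overlapping partial coverage — each source captures a configurable slice of
  the true case population, so no single file is complete;
* identifier noise — typos, missing fields, day/month-transposed birth dates,
  surname substitutions — that stresses record linkage;
* diagnostic miscoding — non-cases accruing sickle cell trait (and, more
  rarely, SCD) codes on one or two encounters, which populates the lowest
  "possible" case tier with mostly false positives, as validation studies of
  claims-based case definitions observe;
* duplicate billing — one clinical event emitted to both Medicaid and the
  hospital file on the same service date, exercising the distinct-date rule;
* annual in/out migration — a person out of state in a year emits no records
  dated in that year, exercising the annual-prevalence migration adjustment.

Everything is driven by one integer seed; identical config + seed reproduce
byte-identical output files.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional

import csv

import numpy as np

from .codes import CodeSystem, DiagnosisCode
from .linkage import IdentifierSet

ICD10_START = date(2015, 10, 1)  # US ICD-9-CM to ICD-10-CM transition


class Source(str, Enum):
    NBS = "NBS"
    CLINIC = "CLINIC"
    MEDICAID = "MEDICAID"
    HOSPITAL_ED = "HOSPITAL_ED"
    DEATH = "DEATH"


class Genotype(str, Enum):
    SS_SB0 = "SS_Sb0"      # HbSS or HbS/beta0-thalassemia (sickle cell anemia)
    SB_PLUS = "Sb_plus"    # HbS/beta+-thalassemia
    SC = "SC"              # HbSC
    OTHER_SCD = "OTHER_SCD"
    NONE = "NONE"


ADMIN_SOURCES = (Source.MEDICAID, Source.HOSPITAL_ED)
CONFIRMED_SOURCES = (Source.NBS, Source.CLINIC)

# genotype-specific diagnosis code pools (ICD-9 before Oct 2015, ICD-10 after)
_SCD_CODE_POOL = {
    Genotype.SS_SB0: {
        CodeSystem.ICD9: ["282.61", "282.62", "282.6"],
        CodeSystem.ICD10: ["D57.00", "D57.01", "D57.1"],
    },
    Genotype.SB_PLUS: {
        CodeSystem.ICD9: ["282.41", "282.42"],
        CodeSystem.ICD10: ["D57.40", "D57.41"],
    },
    Genotype.SC: {
        CodeSystem.ICD9: ["282.63", "282.64"],
        CodeSystem.ICD10: ["D57.20", "D57.21"],
    },
    Genotype.OTHER_SCD: {
        CodeSystem.ICD9: ["282.68", "282.69"],
        CodeSystem.ICD10: ["D57.80", "D57.819"],
    },
}
_TRAIT_CODE = {CodeSystem.ICD9: "282.5", CodeSystem.ICD10: "D57.3"}
# innocuous chronic-condition codes used as background noise
_OTHER_CODE_POOL = {
    CodeSystem.ICD9: ["250.00", "401.9", "493.90"],
    CodeSystem.ICD10: ["E11.9", "I10", "J45.909"],
}

# per-field corruption actions; at most one action fires per field per draw
DEFAULT_CORRUPTION = {
    "first_name_typo": 0.05,
    "first_name_missing": 0.01,
    "last_name_typo": 0.03,
    "last_name_sub": 0.02,
    "dob_transpose": 0.02,
    "dob_typo": 0.01,
    "dob_missing": 0.01,
    "ssn_missing": 0.15,
    "ssn_typo": 0.02,
    "sex_missing": 0.02,
    "sex_flip": 0.005,
    "zip_typo": 0.05,
    "zip_missing": 0.05,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic surveillance run."""

    n_population: int = 5000
    scd_prevalence: float = 0.02
    # confirmed-case genotype mix: sickle cell anemia / S-beta+ / SC / other
    genotype_props: tuple[float, float, float, float] = (0.63, 0.08, 0.27, 0.02)
    period: tuple[int, int] = (2004, 2018)
    nbs_start_year: int = 2004
    source_coverage: dict = field(default_factory=lambda: {
        Source.NBS: 0.90,
        Source.CLINIC: 0.60,
        Source.MEDICAID: 0.70,
        Source.HOSPITAL_ED: 0.75,
        Source.DEATH: 1.0,
    })
    encounter_rate: dict = field(default_factory=lambda: {
        Source.MEDICAID: 2.0,
        Source.HOSPITAL_ED: 1.0,
    })
    corruption_rates: dict = field(default_factory=lambda: dict(DEFAULT_CORRUPTION))
    miscode_rate: float = 0.01
    background_code_rate: float = 0.01
    clinic_false_report_rate: float = 0.002
    nbs_confirm_rate: float = 0.95
    clinic_lab_rate: float = 0.90
    dup_billing_rate: float = 0.10
    migration_out_rate: float = 0.02
    migration_return_rate: float = 0.30
    start_in_state_prob: float = 0.95
    born_in_state_prob: float = 0.80
    annual_death_rate: float = 0.003
    max_age_at_start: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.n_population <= 0:
            raise ValueError("n_population must be positive")
        if abs(sum(self.genotype_props) - 1.0) > 1e-9:
            raise ValueError("genotype_props must sum to 1")
        probs = [self.scd_prevalence, self.miscode_rate,
                 self.background_code_rate, self.clinic_false_report_rate,
                 self.nbs_confirm_rate, self.clinic_lab_rate,
                 self.dup_billing_rate, self.migration_out_rate,
                 self.migration_return_rate, self.start_in_state_prob,
                 self.born_in_state_prob, self.annual_death_rate,
                 *self.source_coverage.values(), *self.corruption_rates.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.period[0] > self.period[1]:
            raise ValueError("period start must not exceed period end")

    def replace(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)

    @classmethod
    def noiseless(cls, **kw) -> "GeneratorConfig":
        """Full coverage, zero identifier noise, zero miscoding, no migration.

        The limit in which linkage and classification are exactly recoverable:
        every observable true case is captured by every eligible source with
        clean identical identifiers and laboratory confirmation.
        """
        base = dict(
            source_coverage={s: 1.0 for s in Source},
            corruption_rates={k: 0.0 for k in DEFAULT_CORRUPTION},
            miscode_rate=0.0,
            background_code_rate=0.0,
            clinic_false_report_rate=0.0,
            nbs_confirm_rate=1.0,
            clinic_lab_rate=1.0,
            migration_out_rate=0.0,
            start_in_state_prob=1.0,
        )
        base.update(kw)
        return cls(**base)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["source_coverage"] = {k.value if isinstance(k, Source) else k: v
                                for k, v in self.source_coverage.items()}
        d["encounter_rate"] = {k.value if isinstance(k, Source) else k: v
                               for k, v in self.encounter_rate.items()}
        return d


@dataclass(frozen=True)
class PersonTruth:
    true_id: str
    has_scd: bool
    genotype: Genotype
    sex: str
    birth_date: date
    death_date: Optional[date]
    residence_intervals: tuple[tuple[date, date], ...]
    born_in_state: bool
    ids: IdentifierSet  # clean (uncorrupted) identifiers

    def __post_init__(self):
        if (self.genotype is Genotype.NONE) == self.has_scd:
            raise ValueError("genotype must be NONE iff has_scd is false")
        if self.death_date is not None and self.death_date < self.birth_date:
            raise ValueError("death before birth")
        prev_end = None
        for start, end in self.residence_intervals:
            if start > end or (prev_end is not None and start <= prev_end):
                raise ValueError("residence intervals must be ordered, disjoint")
            prev_end = end

    def resident_on(self, d: date) -> bool:
        return any(s <= d <= e for s, e in self.residence_intervals)

    def alive_on(self, d: date) -> bool:
        return d >= self.birth_date and (self.death_date is None or d <= self.death_date)


@dataclass(frozen=True)
class SourceRecord:
    record_id: str
    source: Source
    ids: IdentifierSet
    event_date: date
    diagnosis_codes: tuple[DiagnosisCode, ...] = ()
    lab_confirmed: Optional[bool] = None
    genotype_result: Optional[Genotype] = None
    enrollment_months: Optional[int] = None
    true_id: Optional[str] = None  # ground truth; never written to source files

    def __post_init__(self):
        if self.diagnosis_codes and self.source not in ADMIN_SOURCES:
            raise ValueError(f"{self.source.value} records carry no diagnosis codes")
        if self.lab_confirmed is not None and self.source not in CONFIRMED_SOURCES:
            raise ValueError(f"{self.source.value} records carry no lab results")
        if self.genotype_result is not None and self.source not in CONFIRMED_SOURCES:
            raise ValueError(f"{self.source.value} records carry no genotype")
        if self.enrollment_months is not None and self.source is not Source.MEDICAID:
            raise ValueError("enrollment_months applies to MEDICAID only")
        if self.enrollment_months is not None and not (0 <= self.enrollment_months <= 12):
            raise ValueError("enrollment_months must lie in 0..12")


def _load_pool(name: str) -> list[str]:
    ref = resources.files("scdcsurv.data").joinpath(name)
    return [ln.strip() for ln in ref.read_text().splitlines() if ln.strip()]


_ALPHA = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


# ---------------------------------------------------------------------------
# truth generation
# ---------------------------------------------------------------------------


def _truth_rng(config: GeneratorConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 0])


def _emit_rng(config: GeneratorConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 1])


def generate_truth(config: GeneratorConfig) -> list[PersonTruth]:
    """Generate the ground-truth population for one seeded run.

    Disease status is Bernoulli(scd_prevalence) per person; genotypes among
    cases follow ``genotype_props``. Birth dates are uniform between
    ``max_age_at_start`` years before the period and the period end, residence
    follows an annual memoryless in/out migration chain, and deaths occur
    in-period at a small annual hazard (pre-period deaths are not simulated:
    a person dead before the surveillance window would emit no records and is
    out of scope).
    """
    rng = _truth_rng(config)
    first_pool = _load_pool("first_names.txt")
    last_pool = _load_pool("last_names.txt")
    y0, y1 = config.period
    period_start = date(y0, 1, 1)
    period_end = date(y1, 12, 31)
    genos = [Genotype.SS_SB0, Genotype.SB_PLUS, Genotype.SC, Genotype.OTHER_SCD]
    persons: list[PersonTruth] = []
    used_ssn: set[str] = set()
    for i in range(config.n_population):
        has_scd = bool(rng.random() < config.scd_prevalence)
        genotype = (genos[int(rng.choice(4, p=list(config.genotype_props)))]
                    if has_scd else Genotype.NONE)
        sex = "M" if rng.random() < 0.5 else "F"
        # birth uniform over [period_start - max_age, period_end]
        span_days = (period_end - (period_start - timedelta(days=365 * config.max_age_at_start))).days
        birth = (period_start - timedelta(days=365 * config.max_age_at_start)
                 + timedelta(days=int(rng.integers(0, span_days + 1))))
        born_in_period = birth >= period_start
        born_in_state = bool(rng.random() < config.born_in_state_prob)

        # annual residence chain over the surveillance period
        first_year = max(birth.year, y0)
        in_state: dict[int, bool] = {}
        if born_in_period and born_in_state:
            state = True
        else:
            state = bool(rng.random() < config.start_in_state_prob)
        for y in range(first_year, y1 + 1):
            in_state[y] = state
            if state:
                state = not (rng.random() < config.migration_out_rate)
            else:
                state = bool(rng.random() < config.migration_return_rate)

        # in-period death hazard, only while alive
        death: Optional[date] = None
        for y in range(first_year, y1 + 1):
            if rng.random() < config.annual_death_rate:
                lo = max(date(y, 1, 1), birth)
                hi = date(y, 12, 31)
                death = lo + timedelta(days=int(rng.integers(0, (hi - lo).days + 1)))
                break

        intervals: list[tuple[date, date]] = []
        for y in range(first_year, y1 + 1):
            if not in_state.get(y, False):
                continue
            s = max(date(y, 1, 1), birth)
            e = date(y, 12, 31)
            if death is not None:
                if s > death:
                    continue
                e = min(e, death)
            if intervals and intervals[-1][1] == date(y - 1, 12, 31):
                intervals[-1] = (intervals[-1][0], e)
            else:
                intervals.append((s, e))

        ssn = "".join(str(d) for d in rng.integers(0, 10, size=9))
        while ssn in used_ssn:  # collisions would fake a true link
            ssn = "".join(str(d) for d in rng.integers(0, 10, size=9))
        used_ssn.add(ssn)
        ids = IdentifierSet(
            first_name=first_pool[int(rng.integers(0, len(first_pool)))],
            last_name=last_pool[int(rng.integers(0, len(last_pool)))],
            dob=birth,
            ssn=ssn,
            sex=sex,
            zip=f"{30000 + int(rng.integers(0, 80)):05d}",
        )
        persons.append(PersonTruth(
            true_id=f"P{i:06d}",
            has_scd=has_scd,
            genotype=genotype,
            sex=sex,
            birth_date=birth,
            death_date=death,
            residence_intervals=tuple(intervals),
            born_in_state=born_in_state,
            ids=ids,
        ))
    return persons


# ---------------------------------------------------------------------------
# identifier corruption
# ---------------------------------------------------------------------------


def _typo(s: str, rng: np.random.Generator, alphabet: str) -> str:
    i = int(rng.integers(0, len(s)))
    old = s[i]
    new = old
    while new == old:
        new = alphabet[int(rng.integers(0, len(alphabet)))]
    return s[:i] + new + s[i + 1:]


def corrupt_identifiers(ids: IdentifierSet, rates: dict,
                        rng: np.random.Generator,
                        name_pool: Optional[list[str]] = None) -> IdentifierSet:
    """Apply per-field noise; untouched fields pass through unchanged.

    Each field's corruption actions fire independently with their configured
    probabilities; within a field the first triggered action wins, so at most
    one corruption applies per field per draw. The day/month transposition
    applies only when the result is a calendar-valid date (day <= 12),
    otherwise the birth date is left intact. Missingness is represented by
    None, never by a sentinel string.
    """
    if name_pool is None:
        name_pool = _load_pool("last_names.txt")
    r = {k: rates.get(k, 0.0) for k in DEFAULT_CORRUPTION}

    first = ids.first_name
    if first is not None:
        if rng.random() < r["first_name_typo"]:
            first = _typo(first, rng, _ALPHA)
        elif rng.random() < r["first_name_missing"]:
            first = None

    last = ids.last_name
    if last is not None:
        if rng.random() < r["last_name_typo"]:
            last = _typo(last, rng, _ALPHA)
        elif rng.random() < r["last_name_sub"]:
            sub = last
            while sub == last:
                sub = name_pool[int(rng.integers(0, len(name_pool)))]
            last = sub

    dob = ids.dob
    if dob is not None:
        if rng.random() < r["dob_transpose"]:
            if dob.day <= 12 and dob.day != dob.month:
                dob = date(dob.year, dob.day, dob.month)
        elif rng.random() < r["dob_typo"]:
            # shift the day by a few days within the month
            lo = max(1, dob.day - 3)
            hi = min(28, dob.day + 3)
            day = dob.day
            while day == dob.day:
                day = int(rng.integers(lo, hi + 1))
            dob = date(dob.year, dob.month, day)
        elif rng.random() < r["dob_missing"]:
            dob = None

    ssn = ids.ssn
    if ssn is not None:
        if rng.random() < r["ssn_missing"]:
            ssn = None
        elif rng.random() < r["ssn_typo"]:
            ssn = _typo(ssn, rng, "0123456789")

    sex = ids.sex
    if sex is not None:
        if rng.random() < r["sex_missing"]:
            sex = None
        elif rng.random() < r["sex_flip"]:
            sex = "F" if sex == "M" else "M"

    zp = ids.zip
    if zp is not None:
        if rng.random() < r["zip_typo"]:
            zp = _typo(zp, rng, "0123456789")
        elif rng.random() < r["zip_missing"]:
            zp = None

    return IdentifierSet(first_name=first, last_name=last, dob=dob,
                         ssn=ssn, sex=sex, zip=zp)


# ---------------------------------------------------------------------------
# record emission
# ---------------------------------------------------------------------------


def _rand_date(rng: np.random.Generator, lo: date, hi: date) -> date:
    return lo + timedelta(days=int(rng.integers(0, (hi - lo).days + 1)))


def _system_for(d: date) -> CodeSystem:
    return CodeSystem.ICD9 if d < ICD10_START else CodeSystem.ICD10


def _scd_codes(genotype: Genotype, d: date,
               rng: np.random.Generator) -> tuple[DiagnosisCode, ...]:
    sys_ = _system_for(d)
    pool = _SCD_CODE_POOL[genotype][sys_]
    n = 2 if rng.random() < 0.2 else 1
    picks = [pool[int(rng.integers(0, len(pool)))] for _ in range(n)]
    return tuple(DiagnosisCode.parse(sys_, c) for c in dict.fromkeys(picks))


def _observable_window(p: PersonTruth, y: int) -> Optional[tuple[date, date]]:
    """Days of year y in which the person is alive and in-state, if any."""
    lo = max(date(y, 1, 1), p.birth_date)
    hi = date(y, 12, 31)
    if p.death_date is not None:
        hi = min(hi, p.death_date)
    if lo > hi:
        return None
    for s, e in p.residence_intervals:
        a, b = max(s, lo), min(e, hi)
        if a <= b:
            return a, b
    return None


def observable_years(p: PersonTruth, period: tuple[int, int]) -> list[int]:
    return [y for y in range(period[0], period[1] + 1)
            if _observable_window(p, y) is not None]


def emit_source_records(truth: list[PersonTruth], config: GeneratorConfig
                        ) -> dict[Source, list[SourceRecord]]:
    """Emit the five source files from the ground-truth population.

    Coverage acts at the person level for NBS/clinic and at the
    person-source level for the longitudinal sources (a person is either
    enrolled/using the source for the whole period or absent from it), so
    the fraction of cases each source captures tracks ``source_coverage``.
    Every emitted identifier set passes through :func:`corrupt_identifiers`
    independently — the same person looks slightly different in each record.
    """
    rng = _emit_rng(config)
    name_pool = _load_pool("last_names.txt")
    y0, y1 = config.period
    cov = config.source_coverage
    records: dict[Source, list[SourceRecord]] = {s: [] for s in Source}
    counters = {s: 0 for s in Source}

    def emit(source: Source, person: PersonTruth, event_date: date, **kw):
        counters[source] += 1
        rid = f"{source.value}-{counters[source]:06d}"
        ids = corrupt_identifiers(person.ids, config.corruption_rates, rng,
                                  name_pool)
        records[source].append(SourceRecord(
            record_id=rid, source=source, ids=ids, event_date=event_date,
            true_id=person.true_id, **kw))

    for p in truth:
        years = observable_years(p, config.period)

        # --- newborn screening: in-state, in-period births of true cases
        if (p.has_scd and p.born_in_state
                and p.birth_date.year >= config.nbs_start_year
                and y0 <= p.birth_date.year <= y1
                and rng.random() < cov[Source.NBS]):
            ev = min(p.birth_date + timedelta(days=3), date(y1, 12, 31))
            confirmed = bool(rng.random() < config.nbs_confirm_rate)
            emit(Source.NBS, p, ev, lab_confirmed=confirmed,
                 genotype_result=p.genotype)

        # --- clinic case reports
        if p.has_scd and years and rng.random() < cov[Source.CLINIC]:
            y = years[int(rng.integers(0, len(years)))]
            lo, hi = _observable_window(p, y)
            lab = bool(rng.random() < config.clinic_lab_rate)
            emit(Source.CLINIC, p, _rand_date(rng, lo, hi),
                 lab_confirmed=lab,
                 genotype_result=p.genotype if lab else None)
        elif (not p.has_scd) and years and rng.random() < config.clinic_false_report_rate:
            y = years[int(rng.integers(0, len(years)))]
            lo, hi = _observable_window(p, y)
            emit(Source.CLINIC, p, _rand_date(rng, lo, hi),
                 lab_confirmed=False)

        # --- longitudinal administrative encounters (cases)
        if p.has_scd and years:
            enrolled = rng.random() < cov[Source.MEDICAID]
            uses_hosp = rng.random() < cov[Source.HOSPITAL_ED]
            for y in years:
                lo, hi = _observable_window(p, y)
                frac = ((hi - lo).days + 1) / 365.0
                months = max(1, min(12, round(12 * frac)))
                if enrolled:
                    n = int(rng.poisson(config.encounter_rate[Source.MEDICAID] * frac))
                    for _ in range(n):
                        d = _rand_date(rng, lo, hi)
                        emit(Source.MEDICAID, p, d,
                             diagnosis_codes=_scd_codes(p.genotype, d, rng),
                             enrollment_months=months)
                if uses_hosp:
                    n = int(rng.poisson(config.encounter_rate[Source.HOSPITAL_ED] * frac))
                    for _ in range(n):
                        d = _rand_date(rng, lo, hi)
                        emit(Source.HOSPITAL_ED, p, d,
                             diagnosis_codes=_scd_codes(p.genotype, d, rng))
                        # duplicate billing: same event also in claims
                        if enrolled and rng.random() < config.dup_billing_rate:
                            emit(Source.MEDICAID, p, d,
                                 diagnosis_codes=_scd_codes(p.genotype, d, rng),
                                 enrollment_months=months)

        # --- non-case miscoding and background encounters
        if (not p.has_scd) and years:
            if rng.random() < config.miscode_rate:
                k = 1 + int(rng.integers(0, 2))
                for _ in range(k):
                    y = years[int(rng.integers(0, len(years)))]
                    lo, hi = _observable_window(p, y)
                    d = _rand_date(rng, lo, hi)
                    sys_ = _system_for(d)
                    if rng.random() < 0.8:
                        dx = (DiagnosisCode.parse(sys_, _TRAIT_CODE[sys_]),)
                    else:
                        geno = Genotype.SS_SB0
                        dx = _scd_codes(geno, d, rng)
                    src = ADMIN_SOURCES[int(rng.integers(0, 2))]
                    kw = {"diagnosis_codes": dx}
                    if src is Source.MEDICAID:
                        kw["enrollment_months"] = 12
                    emit(src, p, d, **kw)
            if rng.random() < config.background_code_rate:
                k = 1 + int(rng.integers(0, 2))
                for _ in range(k):
                    y = years[int(rng.integers(0, len(years)))]
                    lo, hi = _observable_window(p, y)
                    d = _rand_date(rng, lo, hi)
                    sys_ = _system_for(d)
                    pool = _OTHER_CODE_POOL[sys_]
                    dx = (DiagnosisCode.parse(sys_, pool[int(rng.integers(0, len(pool)))]),)
                    src = ADMIN_SOURCES[int(rng.integers(0, 2))]
                    kw = {"diagnosis_codes": dx}
                    if src is Source.MEDICAID:
                        kw["enrollment_months"] = 12
                    emit(src, p, d, **kw)

        # --- death certificates for in-period deaths
        if (p.death_date is not None and y0 <= p.death_date.year <= y1
                and rng.random() < cov[Source.DEATH]):
            emit(Source.DEATH, p, p.death_date)

    return records


# ---------------------------------------------------------------------------
# dataset container and delimited-text I/O
# ---------------------------------------------------------------------------

_RECORD_COLUMNS = ["record_id", "first_name", "last_name", "dob", "ssn", "sex",
                   "zip", "event_date", "diagnosis_codes", "lab_confirmed",
                   "genotype_result", "enrollment_months"]


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    truth: list[PersonTruth]
    records: dict[Source, list[SourceRecord]]

    @classmethod
    def generate(cls, config: GeneratorConfig) -> "SyntheticDataset":
        truth = generate_truth(config)
        return cls(config, truth, emit_source_records(truth, config))

    def all_records(self) -> list[SourceRecord]:
        return [r for s in Source for r in self.records[s]]

    def truth_by_id(self) -> dict[str, PersonTruth]:
        return {p.true_id: p for p in self.truth}

    def record_truth_map(self) -> dict[str, str]:
        return {r.record_id: r.true_id for r in self.all_records()}

    # -- persistence --------------------------------------------------------

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for source in Source:
            with open(outdir / f"{source.value.lower()}.csv", "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(_RECORD_COLUMNS)
                for r in self.records[source]:
                    w.writerow(_record_row(r))
        with open(outdir / "truth_persons.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["true_id", "has_scd", "genotype", "sex", "birth_date",
                        "death_date", "residence_intervals", "born_in_state",
                        "first_name", "last_name", "ssn", "zip"])
            for p in self.truth:
                w.writerow([
                    p.true_id, int(p.has_scd), p.genotype.value, p.sex,
                    p.birth_date.isoformat(),
                    p.death_date.isoformat() if p.death_date else "",
                    ";".join(f"{s.isoformat()}..{e.isoformat()}"
                             for s, e in p.residence_intervals),
                    int(p.born_in_state),
                    p.ids.first_name, p.ids.last_name, p.ids.ssn, p.ids.zip,
                ])
        with open(outdir / "truth_records.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["record_id", "true_id"])
            for r in self.all_records():
                w.writerow([r.record_id, r.true_id])
        with open(outdir / "manifest.json", "w") as fh:
            json.dump({"seed": self.config.seed, "config": self.config.to_dict()},
                      fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")

    @classmethod
    def read(cls, indir: str | Path) -> "SyntheticDataset":
        indir = Path(indir)
        with open(indir / "manifest.json") as fh:
            manifest = json.load(fh)
        config = config_from_dict(manifest["config"])
        truth = []
        with open(indir / "truth_persons.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                intervals = tuple(
                    tuple(date.fromisoformat(x) for x in part.split(".."))
                    for part in row["residence_intervals"].split(";") if part
                )
                truth.append(PersonTruth(
                    true_id=row["true_id"],
                    has_scd=row["has_scd"] == "1",
                    genotype=Genotype(row["genotype"]),
                    sex=row["sex"],
                    birth_date=date.fromisoformat(row["birth_date"]),
                    death_date=(date.fromisoformat(row["death_date"])
                                if row["death_date"] else None),
                    residence_intervals=intervals,
                    born_in_state=row["born_in_state"] == "1",
                    ids=IdentifierSet(
                        first_name=row["first_name"] or None,
                        last_name=row["last_name"] or None,
                        dob=date.fromisoformat(row["birth_date"]),
                        ssn=row["ssn"] or None,
                        sex=row["sex"] or None,
                        zip=row["zip"] or None,
                    ),
                ))
        truth_map = {}
        with open(indir / "truth_records.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                truth_map[row["record_id"]] = row["true_id"]
        records = {s: read_source_file(indir / f"{s.value.lower()}.csv", s,
                                       truth_map)
                   for s in Source}
        return cls(config, truth, records)


def _record_row(r: SourceRecord) -> list:
    return [
        r.record_id,
        r.ids.first_name or "",
        r.ids.last_name or "",
        r.ids.dob.isoformat() if r.ids.dob else "",
        r.ids.ssn or "",
        r.ids.sex or "",
        r.ids.zip or "",
        r.event_date.isoformat(),
        ";".join(f"{c.system.value}:{c.code}" for c in r.diagnosis_codes),
        "" if r.lab_confirmed is None else str(int(r.lab_confirmed)),
        r.genotype_result.value if r.genotype_result else "",
        "" if r.enrollment_months is None else str(r.enrollment_months),
    ]


def read_source_file(path: str | Path, source: Source,
                     truth_map: Optional[dict[str, str]] = None
                     ) -> list[SourceRecord]:
    """Read one delimited source file back into records."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            dx = tuple(
                DiagnosisCode(CodeSystem(part.split(":")[0]), part.split(":")[1])
                for part in row["diagnosis_codes"].split(";") if part
            )
            out.append(SourceRecord(
                record_id=row["record_id"],
                source=source,
                ids=IdentifierSet(
                    first_name=row["first_name"] or None,
                    last_name=row["last_name"] or None,
                    dob=date.fromisoformat(row["dob"]) if row["dob"] else None,
                    ssn=row["ssn"] or None,
                    sex=row["sex"] or None,
                    zip=row["zip"] or None,
                ),
                event_date=date.fromisoformat(row["event_date"]),
                diagnosis_codes=dx,
                lab_confirmed=(None if row["lab_confirmed"] == ""
                               else row["lab_confirmed"] == "1"),
                genotype_result=(Genotype(row["genotype_result"])
                                 if row["genotype_result"] else None),
                enrollment_months=(None if row["enrollment_months"] == ""
                                   else int(row["enrollment_months"])),
                true_id=(truth_map or {}).get(row["record_id"]),
            ))
    return out


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    if "source_coverage" in d:
        d["source_coverage"] = {Source(k): float(v)
                                for k, v in d["source_coverage"].items()}
    if "encounter_rate" in d:
        d["encounter_rate"] = {Source(k): float(v)
                               for k, v in d["encounter_rate"].items()}
    for tup in ("genotype_props", "period"):
        if tup in d and isinstance(d[tup], list):
            d[tup] = tuple(d[tup])
    return GeneratorConfig(**d)
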