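"""ICD-9-CM / ICD-10-CM diagnosis-code sets for sickle cell disease case finding.

Administrative claims and hospital discharge data identify potential SCD cases
through a fixed list of diagnosis codes: the ICD-9-CM 282.4x/282.6x family and
the ICD-10-CM D57 family, with the carrier state (sickle cell trait,
282.5 / D57.3) tracked separately because trait codes feed only the lowest
("possible") case tier. Classification is a pure function of (coding system,
normalized code); the code sets ship as a plain-text table so surveillance
programs can extend them through configuration rather than code changes.
"""
from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from functools import lru_cache


class CodeSystem(str, Enum):
    ICD9 = "ICD9"
    ICD10 = "ICD10"


class CodeCategory(str, Enum):
    SCD = "SCD"          # sickle cell disease, excluding trait
    TRAIT = "TRAIT"      # sickle cell trait (carrier state)
    OTHER = "OTHER"


_ICD9_RE = re.compile(r"^\d{3}(\.\d{1,2})?$")
_ICD10_RE = re.compile(r"^[A-Z]\d{2}(\.[A-Z0-9]{1,4})?$")


class CodeValidationError(ValueError):
    """Raised for a code string that is malformed for its declared system."""


def normalize_code(system: CodeSystem, raw: str) -> str:
    """Normalize a raw diagnosis code: trim, uppercase, restore the decimal.

    Claims extracts commonly omit the decimal point ("2826", "D5701"); the
    point is re-inserted after 3 digits (ICD-9) or 3 characters (ICD-10).
    Raises :class:`CodeValidationError` if the result is not syntactically
    valid for the system.
    """
    system = CodeSystem(system)
    code = raw.strip().upper()
    if not code:
        raise CodeValidationError(f"empty {system.value} code")
    if "." not in code and len(code) > 3:
        code = code[:3] + "." + code[3:]
    pattern = _ICD9_RE if system is CodeSystem.ICD9 else _ICD10_RE
    if not pattern.match(code):
        raise CodeValidationError(f"malformed {system.value} code: {raw!r}")
    return code


@dataclass(frozen=True)
class DiagnosisCode:
    """A normalized diagnosis code under a declared coding system."""

    system: CodeSystem
    code: str

    @classmethod
    def parse(cls, system: CodeSystem | str, raw: str) -> "DiagnosisCode":
        system = CodeSystem(system)
        return cls(system, normalize_code(system, raw))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.system.value}:{self.code}"


@dataclass(frozen=True)
class _CodeRule:
    system: CodeSystem
    code: str
    category: CodeCategory
    wildcard: bool


class CodeTable:
    """A loaded code set: exact codes plus wildcard prefixes per system.

    Trait rules take precedence over SCD prefix rules, so D57.31 is TRAIT
    even though it extends the bare D57 family row.
    """

    def __init__(self, rules: list[_CodeRule]):
        self._exact: dict[tuple[CodeSystem, str], CodeCategory] = {}
        self._prefixes: dict[CodeSystem, list[tuple[str, CodeCategory]]] = {
            CodeSystem.ICD9: [],
            CodeSystem.ICD10: [],
        }
        for r in rules:
            if r.wildcard:
                self._prefixes[r.system].append((r.code, r.category))
            else:
                self._exact[(r.system, r.code)] = r.category
        # longest prefix first so D57.3 beats D57 if both were wildcards
        for sys_ in self._prefixes:
            self._prefixes[sys_].sort(key=lambda t: -len(t[0]))

    @classmethod
    def from_tsv(cls, path) -> "CodeTable":
        rules = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                rules.append(
                    _CodeRule(
                        CodeSystem(row["system"]),
                        row["code"].strip().upper(),
                        CodeCategory(row["category"]),
                        row["wildcard"].strip() == "1",
                    )
                )
        return cls(rules)

    @classmethod
    def default(cls) -> "CodeTable":
        return _default_table()

    def classify(self, system: CodeSystem | str, code: str) -> CodeCategory:
        """Classify a raw code into SCD / TRAIT / OTHER.

        The code is normalized first; malformed codes raise
        :class:`CodeValidationError`. Trait membership is checked before SCD
        prefix membership so that trait extensions never fall into the SCD
        family via a shorter SCD prefix.
        """
        system = CodeSystem(system)
        norm = normalize_code(system, code)
        exact = self._exact.get((system, norm))
        if exact is CodeCategory.TRAIT:
            return CodeCategory.TRAIT
        trait_prefix = [p for p, c in self._prefixes[system] if c is CodeCategory.TRAIT]
        for p in trait_prefix:
            if norm == p or norm.startswith(p):
                return CodeCategory.TRAIT
        if exact is not None:
            return exact
        for p, cat in self._prefixes[system]:
            if cat is CodeCategory.TRAIT:
                continue
            if norm == p or norm.startswith(p):
                return cat
        return CodeCategory.OTHER


@lru_cache(maxsize=1)
def _default_table() -> CodeTable:
    ref = resources.files("scdcsurv.data").joinpath("scd_code_sets.tsv")
    with resources.as_file(ref) as path:
        return CodeTable.from_tsv(path)


def classify_code(system: CodeSystem | str, code: str) -> CodeCategory:
    """Classify a diagnosis code with the default SCD code table."""
    return _default_table().classify(system, code)
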