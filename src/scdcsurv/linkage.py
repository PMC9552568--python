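"""Record linkage: deterministic rules plus Fellegi-Sunter probabilistic scoring.

Surveillance records carry partial, noisy personal identifiers (names, date of
birth, SSN, sex, ZIP). Deciding which records belong to the same person uses
the classic two-stage strategy of population-based registries:

1. **Blocking** restricts comparison to pairs sharing a cheap key
   (phonetic surname code + birth year, or SSN), so the quadratic all-pairs
   comparison is never run on a full file.
2. Each candidate pair is compared field by field to an agreement pattern
   (AGREE / DISAGREE / MISSING). Names agree under a Jaro-Winkler similarity
   cutoff; other fields agree on exact normalized equality.
3. A deterministic cascade (exact SSN+DOB, or exact name+DOB+sex) links
   unambiguous pairs outright. Remaining pairs are scored with
   Fellegi-Sunter log-likelihood-ratio weights,

       w = sum_f  log2(m_f / u_f)             if field f agrees
                  log2((1-m_f) / (1-u_f))     if field f disagrees
                  0                           if field f is missing,

   where ``m_f`` is the probability field f agrees among true matches and
   ``u_f`` among non-matches. Pairs at or above the upper threshold are
   matches, below the lower threshold non-matches, and in between fall to a
   review band resolved by a configurable automated policy (the production
   systems this emulates route that band to manual clerical review).
4. Match pairs are closed transitively (union-find) into person clusters.

The m/u probabilities are configuration with documented defaults; they are not
estimated from the data (EM estimation is out of scope), keeping the engine
deterministic and auditable.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from datetime import date
from enum import Enum
from typing import Iterable, Mapping, Optional, Protocol, Sequence


# ---------------------------------------------------------------------------
# string comparators
# ---------------------------------------------------------------------------

_SOUNDEX_MAP = {
    **dict.fromkeys("BFPV", "1"),
    **dict.fromkeys("CGJKQSXZ", "2"),
    **dict.fromkeys("DT", "3"),
    "L": "4",
    **dict.fromkeys("MN", "5"),
    "R": "6",
}


def soundex(name: str) -> str:
    """American Soundex code (letter + 3 digits) of a name; '' for no letters."""
    letters = [c for c in name.upper() if "A" <= c <= "Z"]
    if not letters:
        return ""
    first = letters[0]
    out = [first]
    prev = _SOUNDEX_MAP.get(first, "")
    for i, c in enumerate(letters[1:], start=1):
        code = _SOUNDEX_MAP.get(c, "")
        if code and code != prev:
            out.append(code)
            if len(out) == 4:
                break
        # H and W are transparent: a consonant pair separated by H/W collapses
        if c not in "HW":
            prev = code
    return "".join(out).ljust(4, "0")


def jaro(s1: str, s2: str) -> float:
    """Jaro similarity in [0, 1]."""
    if s1 == s2:
        return 1.0
    len1, len2 = len(s1), len(s2)
    if len1 == 0 or len2 == 0:
        return 0.0
    window = max(len1, len2) // 2 - 1
    match1 = [False] * len1
    match2 = [False] * len2
    matches = 0
    for i, c in enumerate(s1):
        lo = max(0, i - window)
        hi = min(len2, i + window + 1)
        for j in range(lo, hi):
            if not match2[j] and s2[j] == c:
                match1[i] = match2[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    # transpositions: matched characters out of order, counted pairwise
    t = 0
    k = 0
    for i in range(len1):
        if match1[i]:
            while not match2[k]:
                k += 1
            if s1[i] != s2[k]:
                t += 1
            k += 1
    t //= 2
    return (matches / len1 + matches / len2 + (matches - t) / matches) / 3.0


def jaro_winkler(s1: str, s2: str, prefix_scale: float = 0.1) -> float:
    """Jaro-Winkler similarity: Jaro boosted for a shared prefix (up to 4)."""
    j = jaro(s1, s2)
    prefix = 0
    for a, b in zip(s1[:4], s2[:4]):
        if a != b:
            break
        prefix += 1
    return j + prefix * prefix_scale * (1.0 - j)


# ---------------------------------------------------------------------------
# identifiers and agreement patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IdentifierSet:
    """Personal identifiers carried by one record; None marks a missing field."""

    first_name: Optional[str] = None
    last_name: Optional[str] = None
    dob: Optional[date] = None
    ssn: Optional[str] = None
    sex: Optional[str] = None
    zip: Optional[str] = None


COMPARISON_FIELDS = ("first_name", "last_name", "dob", "ssn", "sex", "zip")
_NAME_FIELDS = frozenset({"first_name", "last_name"})


class Agreement(str, Enum):
    AGREE = "AGREE"
    DISAGREE = "DISAGREE"
    MISSING = "MISSING"


AgreementPattern = Mapping[str, Agreement]


class LinkStatus(str, Enum):
    MATCH = "MATCH"
    REVIEW = "REVIEW"
    NONMATCH = "NONMATCH"


class ReviewPolicy(str, Enum):
    AS_NONMATCH = "AS_NONMATCH"
    AS_MATCH = "AS_MATCH"
    # apply a looser second deterministic rule to the review band only:
    # DOB agrees and at least one name agrees
    SECOND_RULE = "SECOND_RULE"


# defaults chosen for administrative health data: SSN is near-decisive when
# present, sex is nearly uninformative (u = 0.5), names tolerate typos.
_DEFAULT_M = {
    "first_name": 0.92,
    "last_name": 0.92,
    "dob": 0.95,
    "ssn": 0.97,
    "sex": 0.98,
    "zip": 0.90,
}
_DEFAULT_U = {
    "first_name": 0.01,
    "last_name": 0.005,
    "dob": 0.001,
    "ssn": 1e-5,
    "sex": 0.5,
    "zip": 0.01,
}


@dataclass(frozen=True)
class LinkageConfig:
    m_probs: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_M))
    u_probs: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_U))
    upper_threshold: float = 10.0
    lower_threshold: float = 4.0
    name_similarity_cutoff: float = 0.85
    review_policy: ReviewPolicy = ReviewPolicy.AS_NONMATCH
    blocking: bool = True
    # all-pairs guard: refuse unblocked comparison above this record count
    allpairs_limit: int = 2000

    def __post_init__(self):
        if self.upper_threshold < self.lower_threshold:
            raise ValueError("upper_threshold must be >= lower_threshold")
        for f in COMPARISON_FIELDS:
            m, u = self.m_probs[f], self.u_probs[f]
            if not (0.0 < m < 1.0 and 0.0 < u < 1.0):
                raise ValueError(f"m/u for {f} must lie in (0, 1)")
            if m <= u:
                raise ValueError(f"m must exceed u for field {f}")

    def replace(self, **kw) -> "LinkageConfig":
        return replace(self, **kw)


class HasIdentifiers(Protocol):
    record_id: str
    ids: IdentifierSet


# ---------------------------------------------------------------------------
# blocking
# ---------------------------------------------------------------------------


def _norm_name(s: Optional[str]) -> Optional[str]:
    if s is None:
        return None
    out = "".join(s.split()).upper()
    return out or None


def blocking_keys(ids: IdentifierSet) -> list[tuple]:
    """Default blocking keys for one record; missing fields emit no key."""
    keys: list[tuple] = []
    last = _norm_name(ids.last_name)
    if last and ids.dob is not None:
        keys.append(("SNDX_YOB", soundex(last), ids.dob.year))
    if ids.ssn:
        keys.append(("SSN", ids.ssn))
    return keys


def block(records: Sequence[HasIdentifiers],
          records_b: Optional[Sequence[HasIdentifiers]] = None,
          ) -> set[tuple[str, str]]:
    """Candidate pairs sharing at least one blocking key value.

    One-file mode (``records_b`` omitted) yields within-file pairs; two-file
    mode yields only cross-file pairs. Pair ids are ordered lexicographically.
    """
    if records_b is None:
        buckets: dict[tuple, list[str]] = {}
        for r in records:
            for k in blocking_keys(r.ids):
                buckets.setdefault(k, []).append(r.record_id)
        pairs: set[tuple[str, str]] = set()
        for members in buckets.values():
            for a, b in itertools.combinations(sorted(members), 2):
                pairs.add((a, b))
        return pairs
    buckets_a: dict[tuple, list[str]] = {}
    for r in records:
        for k in blocking_keys(r.ids):
            buckets_a.setdefault(k, []).append(r.record_id)
    pairs = set()
    for r in records_b:
        for k in blocking_keys(r.ids):
            for a in buckets_a.get(k, ()):
                pairs.add((min(a, r.record_id), max(a, r.record_id)))
    return pairs


def all_pairs(records: Sequence[HasIdentifiers],
              records_b: Optional[Sequence[HasIdentifiers]] = None,
              ) -> set[tuple[str, str]]:
    """Unblocked candidate set (test escape hatch; guarded in resolve())."""
    if records_b is None:
        ids = sorted(r.record_id for r in records)
        return set(itertools.combinations(ids, 2))
    return {
        (min(a.record_id, b.record_id), max(a.record_id, b.record_id))
        for a in records
        for b in records_b
    }


# ---------------------------------------------------------------------------
# comparison, weighting, decision
# ---------------------------------------------------------------------------


def compare_pair(a: IdentifierSet, b: IdentifierSet,
                 config: LinkageConfig) -> dict[str, Agreement]:
    """Field-by-field agreement pattern for one candidate pair."""
    pattern: dict[str, Agreement] = {}
    for f in COMPARISON_FIELDS:
        va, vb = getattr(a, f), getattr(b, f)
        if f in _NAME_FIELDS:
            va, vb = _norm_name(va), _norm_name(vb)
        if va is None or vb is None:
            pattern[f] = Agreement.MISSING
        elif f in _NAME_FIELDS:
            sim = jaro_winkler(va, vb)
            pattern[f] = (Agreement.AGREE if sim >= config.name_similarity_cutoff
                          else Agreement.DISAGREE)
        else:
            pattern[f] = Agreement.AGREE if va == vb else Agreement.DISAGREE
    return pattern


def match_weight(pattern: AgreementPattern, config: LinkageConfig) -> float:
    """Fellegi-Sunter composite weight in log2 units; missing fields add 0."""
    w = 0.0
    for f, a in pattern.items():
        m, u = config.m_probs[f], config.u_probs[f]
        if a is Agreement.AGREE or a == Agreement.AGREE:
            w += math.log2(m / u)
        elif a is Agreement.DISAGREE or a == Agreement.DISAGREE:
            w += math.log2((1.0 - m) / (1.0 - u))
    return w


def deterministic_rule(a: IdentifierSet, b: IdentifierSet) -> Optional[str]:
    """Label of the first exact-match rule the pair satisfies, else None."""
    if a.ssn and b.ssn and a.ssn == b.ssn and a.dob and b.dob and a.dob == b.dob:
        return "ssn+dob"
    if (_norm_name(a.first_name) and _norm_name(a.first_name) == _norm_name(b.first_name)
            and _norm_name(a.last_name) and _norm_name(a.last_name) == _norm_name(b.last_name)
            and a.dob and a.dob == b.dob
            and a.sex and a.sex == b.sex):
        return "name+dob+sex"
    return None


def decide(weight: float, rule: Optional[str], config: LinkageConfig,
           pattern: Optional[AgreementPattern] = None) -> LinkStatus:
    """Final status: deterministic rules first, then thresholded FS weight.

    The review band [lower, upper) stands in for manual clerical review and
    is resolved by ``config.review_policy`` (default: treat as non-match,
    favouring precision). Under SECOND_RULE the band matches only when DOB
    and at least one name agree (requires ``pattern``).
    """
    if rule is not None:
        return LinkStatus.MATCH
    if weight >= config.upper_threshold:
        return LinkStatus.MATCH
    if weight < config.lower_threshold:
        return LinkStatus.NONMATCH
    if config.review_policy is ReviewPolicy.AS_MATCH:
        return LinkStatus.MATCH
    if config.review_policy is ReviewPolicy.SECOND_RULE and pattern is not None:
        if pattern["dob"] is Agreement.AGREE and (
                pattern["first_name"] is Agreement.AGREE
                or pattern["last_name"] is Agreement.AGREE):
            return LinkStatus.MATCH
    return LinkStatus.NONMATCH


@dataclass(frozen=True)
class LinkDecision:
    record_a: str
    record_b: str
    pattern: tuple[tuple[str, str], ...]  # (field, agreement value) pairs
    weight: float
    status: LinkStatus
    rule: str  # deterministic rule label or "probabilistic"


def evaluate_pair(a: HasIdentifiers, b: HasIdentifiers,
                  config: LinkageConfig) -> LinkDecision:
    ra, rb = sorted([a, b], key=lambda r: r.record_id)
    pattern = compare_pair(ra.ids, rb.ids, config)
    w = match_weight(pattern, config)
    rule = deterministic_rule(ra.ids, rb.ids)
    status = decide(w, rule, config, pattern)
    return LinkDecision(
        record_a=ra.record_id,
        record_b=rb.record_id,
        pattern=tuple((f, pattern[f].value) for f in COMPARISON_FIELDS),
        weight=w,
        status=status,
        rule=rule or "probabilistic",
    )


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic representative: lexicographically smaller root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def cluster(match_pairs: Iterable[tuple[str, str]],
            all_ids: Iterable[str]) -> list[list[str]]:
    """Partition record ids into connected components of the match graph.

    Every id appears in exactly one cluster; singletons are kept. Output is
    deterministic: clusters sorted by their smallest member, members sorted.
    """
    uf = _UnionFind(all_ids)
    for a, b in match_pairs:
        uf.union(a, b)
    groups: dict[str, list[str]] = {}
    for x in uf.parent:
        groups.setdefault(uf.find(x), []).append(x)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


def resolve(records: Sequence[HasIdentifiers],
            config: LinkageConfig,
            records_b: Optional[Sequence[HasIdentifiers]] = None,
            ) -> tuple[list[list[str]], list[LinkDecision]]:
    """Block, compare, decide and cluster one file (or a cross-file link).

    Returns the cluster partition over all input record ids together with the
    full audit trail of pair decisions.
    """
    if config.blocking:
        pairs = block(records, records_b)
    else:
        n = len(records) + (len(records_b) if records_b else 0)
        if n > config.allpairs_limit:
            raise ValueError(
                f"all-pairs comparison refused for {n} records "
                f"(limit {config.allpairs_limit}); enable blocking"
            )
        pairs = all_pairs(records, records_b)
    by_id = {r.record_id: r for r in records}
    if records_b:
        by_id.update({r.record_id: r for r in records_b})
    decisions = [
        evaluate_pair(by_id[a], by_id[b], config) for a, b in sorted(pairs)
    ]
    matches = [(d.record_a, d.record_b) for d in decisions
               if d.status is LinkStatus.MATCH]
    clusters = cluster(matches, by_id.keys())
    return clusters, decisions
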