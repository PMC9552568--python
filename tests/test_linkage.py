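"""Linkage engine: comparators, Fellegi-Sunter weights, decisions, clustering."""
import math
from dataclasses import dataclass
from datetime import date

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scdcsurv.linkage import (Agreement, COMPARISON_FIELDS, IdentifierSet,
                              LinkStatus, LinkageConfig, ReviewPolicy,
                              all_pairs, block, cluster, compare_pair, decide,
                              deterministic_rule, evaluate_pair, jaro,
                              jaro_winkler, match_weight, resolve, soundex)
from scdcsurv.synthetic import GeneratorConfig, Source, SyntheticDataset


# ---------------------------------------------------------------------------
# string comparators against independent references
# ---------------------------------------------------------------------------


def _jaro_reference(s1: str, s2: str) -> float:
    """Straightforward per-definition Jaro similarity (independent oracle)."""
    if s1 == s2:
        return 1.0
    if not s1 or not s2:
        return 0.0
    window = max(len(s1), len(s2)) // 2 - 1
    used = set()
    m1, m2 = [], []
    for i, c in enumerate(s1):
        for j in range(max(0, i - window), min(len(s2), i + window + 1)):
            if j not in used and s2[j] == c:
                used.add(j)
                m1.append((i, c))
                break
    m2 = sorted(used)
    if not m1:
        return 0.0
    m = len(m1)
    # transpositions: half the out-of-order matches, floored (the convention
    # of the standard C implementations)
    t = sum(1 for (_, c), j in zip(m1, m2) if c != s2[j]) // 2
    return (m / len(s1) + m / len(s2) + (m - t) / m) / 3


@pytest.mark.parametrize("a,b,expected", [
    ("MARTHA", "MARHTA", 0.9611),
    ("DIXON", "DICKSONX", 0.8133),
    ("DWAYNE", "DUANE", 0.8400),
    ("SMITH", "SMYTH", 0.8933),
    ("SMITH", "SMITH", 1.0),
    ("ABC", "XYZ", 0.0),
])
def test_jaro_winkler_known_values(a, b, expected):
    assert jaro_winkler(a, b) == pytest.approx(expected, abs=5e-5)


@settings(max_examples=300, deadline=None)
@given(st.text(alphabet="ABCDE", max_size=8), st.text(alphabet="ABCDE", max_size=8))
def test_jaro_matches_reference(a, b):
    assert jaro(a, b) == pytest.approx(_jaro_reference(a, b), abs=1e-12)
    assert jaro(a, b) == jaro(b, a)


@pytest.mark.parametrize("name,code", [
    ("ROBERT", "R163"), ("RUPERT", "R163"), ("ASHCRAFT", "A261"),
    ("TYMCZAK", "T522"), ("PFISTER", "P236"), ("HONEYMAN", "H555"),
    ("JACKSON", "J250"), ("WASHINGTON", "W252"), ("LEE", "L000"),
])
def test_soundex_known_values(name, code):
    assert soundex(name) == code


def test_name_agreement_cutoff():
    """SMITH vs SMYTH agrees at cutoff 0.85 but not at 0.95."""
    a = IdentifierSet(last_name="SMITH")
    b = IdentifierSet(last_name="SMYTH")
    loose = compare_pair(a, b, LinkageConfig(name_similarity_cutoff=0.85))
    strict = compare_pair(a, b, LinkageConfig(name_similarity_cutoff=0.95))
    assert loose["last_name"] is Agreement.AGREE
    assert strict["last_name"] is Agreement.DISAGREE


# ---------------------------------------------------------------------------
# agreement patterns and weights
# ---------------------------------------------------------------------------

IDS_FULL = IdentifierSet("ANNA", "SMITH", date(1990, 4, 12), "123456789",
                         "F", "30301")


def test_identical_records_agree_everywhere():
    pattern = compare_pair(IDS_FULL, IDS_FULL, LinkageConfig())
    assert all(v is Agreement.AGREE for v in pattern.values())


def test_missing_field_propagates():
    other = IdentifierSet("ANNA", "SMITH", date(1990, 4, 12), None, "F", "30301")
    pattern = compare_pair(IDS_FULL, other, LinkageConfig())
    assert pattern["ssn"] is Agreement.MISSING


def test_all_missing_weight_zero():
    pattern = {f: Agreement.MISSING for f in COMPARISON_FIELDS}
    assert match_weight(pattern, LinkageConfig()) == 0.0


def test_single_field_weight_closed_form():
    cfg = LinkageConfig(
        m_probs={f: 0.9 for f in COMPARISON_FIELDS},
        u_probs={f: 0.1 for f in COMPARISON_FIELDS},
    )
    pattern = {f: Agreement.MISSING for f in COMPARISON_FIELDS}
    pattern["dob"] = Agreement.AGREE
    assert match_weight(pattern, cfg) == pytest.approx(math.log2(9), abs=1e-12)


def test_weight_equals_brute_force_sum_on_random_patterns():
    """Composite weight equals the term-by-term sum over 1000 random patterns."""
    rng = np.random.default_rng(42)
    cfg = LinkageConfig()
    states = [Agreement.AGREE, Agreement.DISAGREE, Agreement.MISSING]
    for _ in range(1000):
        pattern = {f: states[rng.integers(0, 3)] for f in COMPARISON_FIELDS}
        expected = 0.0
        for f, a in pattern.items():
            m, u = cfg.m_probs[f], cfg.u_probs[f]
            if a is Agreement.AGREE:
                expected += math.log2(m / u)
            elif a is Agreement.DISAGREE:
                expected += math.log2((1 - m) / (1 - u))
        assert abs(match_weight(pattern, cfg) - expected) < 1e-12


def test_invalid_m_u_rejected():
    with pytest.raises(ValueError):
        LinkageConfig(m_probs={**dict.fromkeys(COMPARISON_FIELDS, 0.9), "dob": 1.0})
    with pytest.raises(ValueError):
        LinkageConfig(m_probs={**dict.fromkeys(COMPARISON_FIELDS, 0.9), "sex": 0.4})


# ---------------------------------------------------------------------------
# decisions
# ---------------------------------------------------------------------------


def test_deterministic_rule_overrides_weight():
    """Exact SSN+DOB links even when a name typo drags the weight down."""
    a = IDS_FULL
    b = IdentifierSet("ANNA", "SMITHX", date(1990, 4, 12), "123456789", "F", None)
    assert deterministic_rule(a, b) == "ssn+dob"
    cfg = LinkageConfig(upper_threshold=1e9)  # weight alone could never match
    assert decide(match_weight(compare_pair(a, b, cfg), cfg),
                  deterministic_rule(a, b), cfg) is LinkStatus.MATCH


def test_threshold_boundary_and_review_policy():
    cfg = LinkageConfig(upper_threshold=5.0, lower_threshold=2.0)
    assert decide(5.0, None, cfg) is LinkStatus.MATCH       # inclusive upper
    assert decide(1.999, None, cfg) is LinkStatus.NONMATCH
    assert decide(3.0, None, cfg) is LinkStatus.NONMATCH    # AS_NONMATCH default
    as_match = cfg.replace(review_policy=ReviewPolicy.AS_MATCH)
    assert decide(3.0, None, as_match) is LinkStatus.MATCH


def test_second_rule_review_policy():
    cfg = LinkageConfig(upper_threshold=50.0, lower_threshold=-50.0,
                        review_policy=ReviewPolicy.SECOND_RULE)
    agree = {f: Agreement.MISSING for f in COMPARISON_FIELDS}
    agree.update(dob=Agreement.AGREE, last_name=Agreement.AGREE)
    disagree = {f: Agreement.MISSING for f in COMPARISON_FIELDS}
    disagree.update(dob=Agreement.DISAGREE, last_name=Agreement.AGREE)
    assert decide(0.0, None, cfg, agree) is LinkStatus.MATCH
    assert decide(0.0, None, cfg, disagree) is LinkStatus.NONMATCH


def test_pair_order_symmetry(default_run):
    """compare/weight/decide are invariant to the order of the pair."""
    records = default_run.dataset.records[Source.MEDICAID][:40]
    cfg = LinkageConfig()
    for a, b in zip(records[:-1], records[1:]):
        d1 = evaluate_pair(a, b, cfg)
        d2 = evaluate_pair(b, a, cfg)
        assert (d1.weight, d1.status, d1.rule) == (d2.weight, d2.status, d2.rule)
        assert (d1.record_a, d1.record_b) == (d2.record_a, d2.record_b)


def test_raising_upper_threshold_never_adds_matches(default_run):
    records = default_run.dataset.records[Source.HOSPITAL_ED][:150]
    counts = []
    for upper in (6.0, 10.0, 14.0, 20.0):
        cfg = LinkageConfig(upper_threshold=upper, lower_threshold=4.0)
        _, decisions = resolve(records, cfg)
        counts.append(sum(d.status is LinkStatus.MATCH for d in decisions))
    assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# blocking and clustering
# ---------------------------------------------------------------------------


@dataclass
class Rec:
    record_id: str
    ids: IdentifierSet


def test_shared_ssn_is_candidate():
    a = Rec("a", IdentifierSet(ssn="111223333"))
    b = Rec("b", IdentifierSet(ssn="111223333"))
    assert ("a", "b") in block([a, b])


def test_no_shared_key_no_candidate():
    a = Rec("a", IdentifierSet("JO", "SMITH", date(1990, 1, 1), "111223333"))
    b = Rec("b", IdentifierSet("JO", "JONES", date(1985, 2, 2), "999887777"))
    assert block([a, b]) == set()


def test_blocking_covers_true_pairs_noiseless():
    """With clean identifiers every true-match pair survives blocking."""
    ds = SyntheticDataset.generate(
        GeneratorConfig.noiseless(n_population=300, seed=5))
    records = ds.records[Source.MEDICAID][:200]
    candidates = block(records)
    by_id = {r.record_id: r for r in records}
    truth_pairs = {
        (a, b) for a, b in all_pairs(records)
        if by_id[a].true_id == by_id[b].true_id
    }
    assert truth_pairs <= candidates


def test_cluster_transitivity_and_singletons():
    got = cluster([("a", "b"), ("b", "c")], ["a", "b", "c", "d"])
    assert got == [["a", "b", "c"], ["d"]]
    assert cluster([], ["x", "y"]) == [["x"], ["y"]]


@settings(max_examples=50, deadline=None)
@given(st.lists(
    st.tuples(st.integers(0, 49), st.integers(0, 49)).filter(lambda t: t[0] != t[1]),
    max_size=60,
))
def test_cluster_matches_graph_components(edges):
    """Union-find clusters equal graph connected components on random graphs."""
    nodes = [f"n{i}" for i in range(50)]
    pairs = [(f"n{a}", f"n{b}") for a, b in edges]
    got = {frozenset(c) for c in cluster(pairs, nodes)}
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(pairs)
    expected = {frozenset(c) for c in nx.connected_components(g)}
    assert got == expected


def test_allpairs_guard():
    recs = [Rec(f"r{i}", IdentifierSet(ssn=f"{i:09d}")) for i in range(30)]
    cfg = LinkageConfig(blocking=False, allpairs_limit=10)
    with pytest.raises(ValueError, match="all-pairs"):
        resolve(recs, cfg)


def test_noiseless_clusters_equal_truth_partition(noiseless_run):
    """Zero corruption + unique identities: linkage is exact (P = R = 1)."""
    metrics = noiseless_run.linkage_metrics()
    assert metrics.precision == 1.0
    assert metrics.recall == 1.0
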