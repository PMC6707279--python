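"""Enrichment score, permutation GSEA, over-representation, upstream z."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from coexsurv.enrichment import (
    EnrichmentResult,
    RegulatorCall,
    es_running_sum,
    overrepresentation,
    preranked_gsea,
    upstream_activation_z,
)
from coexsurv.io import GeneSet, GeneSetCollection


def brute_force_es(ranked, members, p=1.0):
    """Direct O(N) running-sum evaluation, kept independent of the package path."""
    genes = [g for g, _ in ranked]
    scores = np.array([s for _, s in ranked], float)
    hit = np.array([g in members for g in genes])
    n, nh = len(genes), int(hit.sum())
    w = np.abs(scores) ** p
    tot = w[hit].sum()
    run, up, down = 0.0, 0.0, 0.0
    for i in range(n):
        run += (w[i] / tot) if hit[i] else (-1.0 / (n - nh))
        up = max(up, run)
        down = min(down, run)
    # equal-magnitude extremes resolve to the positive one
    return up if up >= -down else down


def assert_matches_brute(es, ranked, members, p=1.0, tol=1e-12):
    """ES equals the brute-force value; a mathematically tied pair of
    extremes (positive deviation == negative deviation to rounding) only
    pins down the magnitude, since summation order decides the sign."""
    brute = brute_force_es(ranked, members, p)
    if abs(abs(es) - abs(brute)) < 1e-9 and abs(es - brute) > tol:
        assert abs(es) == pytest.approx(abs(brute), abs=tol)
    else:
        assert es == pytest.approx(brute, abs=tol)


def ranked_list(scores):
    return [(f"G{i}", float(s)) for i, s in enumerate(scores)]


def test_es_is_one_when_members_occupy_top_ranks():
    for p in (0.0, 1.0, 2.0):
        ranked = ranked_list(np.linspace(5, -5, 30))
        es, running, leading = es_running_sum(ranked, {f"G{i}" for i in range(7)}, weight_p=p)
        assert es == 1.0
        assert set(leading) == {f"G{i}" for i in range(7)}


def test_es_whole_universe_set_is_one():
    ranked = ranked_list(np.linspace(3, -3, 10))
    es, _, _ = es_running_sum(ranked, {f"G{i}" for i in range(10)})
    assert es == 1.0


def test_es_bottom_set_matches_brute_force():
    ranked = ranked_list(np.linspace(5, -5, 30))
    members = {f"G{i}" for i in range(25, 30)}
    es, _, _ = es_running_sum(ranked, members)
    assert es < 0
    assert es == pytest.approx(brute_force_es(ranked, members), abs=1e-12)


def test_es_matches_brute_force_on_random_inputs(rng):
    for _ in range(100):
        n = int(rng.integers(8, 60))
        scores = np.sort(rng.standard_normal(n))[::-1]
        k = int(rng.integers(1, n))
        members = {f"G{i}" for i in rng.choice(n, size=k, replace=False)}
        ranked = ranked_list(scores)
        es, _, _ = es_running_sum(ranked, members)
        assert_matches_brute(es, ranked, members)


def test_es_matches_gseapy_reference():
    """Same statistic as the reference pre-ranked implementation (weight 1)."""
    import pandas as pd
    gseapy = pytest.importorskip("gseapy")

    rng = np.random.default_rng(8)
    scores = np.sort(rng.standard_normal(50))[::-1]
    genes = [f"G{i}" for i in range(50)]
    members = [f"G{i}" for i in rng.choice(50, size=12, replace=False)]
    res = gseapy.prerank(
        rnk=pd.DataFrame({0: genes, 1: scores}), gene_sets={"S": members},
        permutation_num=10, weight=1, seed=1, outdir=None, min_size=1, no_plot=True,
    )
    es_ref = float(res.res2d["ES"].iloc[0])
    es, _, _ = es_running_sum(list(zip(genes, scores)), members)
    assert es == pytest.approx(es_ref, abs=1e-9)


def test_es_invariant_to_positive_rescaling_of_scores(rng):
    scores = np.sort(rng.standard_normal(40))[::-1]
    members = {f"G{i}" for i in rng.choice(40, size=10, replace=False)}
    es1, _, _ = es_running_sum(ranked_list(scores), members)
    es2, _, _ = es_running_sum(ranked_list(scores * 13.7), members)
    assert es1 == pytest.approx(es2, abs=1e-12)


def test_reversing_ranked_list_negates_es_weight0(rng):
    scores = np.sort(rng.standard_normal(40))[::-1]
    members = {f"G{i}" for i in rng.choice(40, size=9, replace=False)}
    ranked = ranked_list(scores)
    es_fwd, _, _ = es_running_sum(ranked, members, weight_p=0.0)
    es_rev, _, _ = es_running_sum(ranked[::-1], members, weight_p=0.0)
    assert es_fwd == pytest.approx(-es_rev, abs=1e-12)


def test_no_member_present_raises():
    with pytest.raises(ValueError, match="no gene-set member"):
        es_running_sum(ranked_list([1.0, 0.5]), {"ABSENT"})


def test_preranked_gsea_deterministic_under_fixed_seed(rng):
    scores = np.sort(rng.standard_normal(60))[::-1]
    col = GeneSetCollection(sets=(
        GeneSet("TOP", "d", tuple(f"G{i}" for i in range(8))),
        GeneSet("RAND", "d", tuple(f"G{i}" for i in rng.choice(60, 10, replace=False))),
    ))
    a = preranked_gsea(ranked_list(scores), col, n_perm=200, rng_seed=9)
    b = preranked_gsea(ranked_list(scores), col, n_perm=200, rng_seed=9)
    assert [(r.set_name, r.es, r.p_perm, r.fdr) for r in a] == \
           [(r.set_name, r.es, r.p_perm, r.fdr) for r in b]


def test_preranked_gsea_extreme_set_gets_floor_p(rng):
    scores = np.sort(rng.standard_normal(100))[::-1]
    col = GeneSetCollection(sets=(GeneSet("TOP", "d", tuple(f"G{i}" for i in range(10))),))
    res = preranked_gsea(ranked_list(scores), col, n_perm=500, rng_seed=4)
    assert res[0].es == 1.0
    # no null draw can match ES = 1: p sits at the continuity floor
    assert res[0].p_perm <= 0.01


def test_preranked_gsea_requires_enough_permutations():
    with pytest.raises(ValueError):
        preranked_gsea(ranked_list([1.0, 0.5, 0.2]), GeneSetCollection(), n_perm=10)


def test_preranked_gsea_skips_absent_sets(rng, caplog):
    scores = np.sort(rng.standard_normal(20))[::-1]
    col = GeneSetCollection(sets=(GeneSet("ABSENT", "d", ("NOPE",)),))
    with caplog.at_level("WARNING"):
        res = preranked_gsea(ranked_list(scores), col, n_perm=100, rng_seed=0)
    assert res == []


def exhaustive_overrep_p(n_universe, set_size, query_size, k_min):
    """P[overlap >= k] by exhaustive enumeration of query draws (tiny N)."""
    universe = list(range(n_universe))
    inset = set(range(set_size))
    total = hits = 0
    for combo in itertools.combinations(universe, query_size):
        total += 1
        if len(inset & set(combo)) >= k_min:
            hits += 1
    return hits / total


def test_overrepresentation_matches_exhaustive_enumeration():
    n_uni, set_size, query_size = 12, 5, 4
    universe = [f"G{i}" for i in range(n_uni)]
    gs = GeneSet("S", "d", tuple(f"G{i}" for i in range(set_size)))
    query = [f"G{i}" for i in (0, 1, 2, 7)]  # overlap k = 3
    df = overrepresentation(query, GeneSetCollection(sets=(gs,)), universe)
    expected = exhaustive_overrep_p(n_uni, set_size, query_size, k_min=3)
    assert df.loc[0, "p"] == pytest.approx(expected, abs=1e-12)


def test_overrepresentation_zero_overlap_p_near_one():
    universe = [f"G{i}" for i in range(30)]
    gs = GeneSet("S", "d", tuple(f"G{i}" for i in range(20)))
    query = [f"G{i}" for i in range(25, 29)]
    df = overrepresentation(query, GeneSetCollection(sets=(gs,)), universe)
    assert df.loc[0, "k_overlap"] == 0
    assert df.loc[0, "p"] == pytest.approx(1.0)


def test_overrepresentation_degenerate_inputs():
    with pytest.raises(ValueError, match="universe is empty"):
        overrepresentation(["A"], GeneSetCollection(), [])
    with pytest.raises(ValueError, match="no genes in the universe"):
        overrepresentation(["A"], GeneSetCollection(), ["B", "C"])


@given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=30))
@settings(max_examples=50, deadline=None)
def test_bh_adjustment_monotone(pvals):
    """BH-adjusted p >= raw p, and adjustment preserves the p ordering."""
    from statsmodels.stats.multitest import multipletests

    adj = multipletests(pvals, method="fdr_bh")[1]
    assert all(a >= p - 1e-12 for a, p in zip(adj, pvals))
    order = np.argsort(pvals)
    assert all(adj[order[i]] <= adj[order[i + 1]] + 1e-12 for i in range(len(order) - 1))


# --- upstream regulator -----------------------------------------------------


def edges(reg, targets, signs):
    return [(reg, t, s) for t, s in zip(targets, signs)]


def test_upstream_z_all_consistent():
    net = edges("R", [f"T{i}" for i in range(10)], [1] * 10)
    obs = {f"T{i}": 1 for i in range(10)}
    (call,) = upstream_activation_z(net, obs)
    assert call.z_activation == pytest.approx(10 / np.sqrt(10))
    assert call.state == "activated"


def test_upstream_z_balanced_is_zero():
    net = edges("R", [f"T{i}" for i in range(10)], [1] * 5 + [-1] * 5)
    obs = {f"T{i}": 1 for i in range(10)}
    (call,) = upstream_activation_z(net, obs)
    assert call.z_activation == 0.0
    assert call.state == "not-significant"


def test_upstream_z_mostly_inconsistent_below_threshold():
    net = edges("R", [f"T{i}" for i in range(10)], [1] * 10)
    obs = {f"T{i}": (1 if i < 2 else -1) for i in range(10)}
    (call,) = upstream_activation_z(net, obs)
    assert call.z_activation == pytest.approx(-6 / np.sqrt(10))
    assert call.state == "not-significant"


def test_upstream_negating_observations_negates_z(rng):
    targets = [f"T{i}" for i in range(15)]
    signs = rng.choice([1, -1], size=15)
    net = edges("R", targets, signs)
    obs = {t: int(d) for t, d in zip(targets, rng.choice([1, -1], size=15))}
    neg = {t: -d for t, d in obs.items()}
    (a,) = upstream_activation_z(net, obs)
    (b,) = upstream_activation_z(net, neg)
    assert a.z_activation == pytest.approx(-b.z_activation, abs=1e-12)


def test_upstream_low_evidence_flag_and_only_observed_targets():
    net = edges("R", ["T1", "T2", "T3"], [1, 1, 1]) + [("Q", "T1", 1), ("Q", "U", -1)]
    obs = {"T1": 1, "T2": 1}
    calls = {c.regulator: c for c in upstream_activation_z(net, obs)}
    assert calls["R"].n_targets_observed == 2 and calls["R"].low_evidence
    assert calls["Q"].n_targets_observed == 1


def test_regulator_call_state_must_match_threshold():
    with pytest.raises(ValueError):
        RegulatorCall("R", 10, 3.0, "not-significant")
    with pytest.raises(ValueError):
        EnrichmentResult("S", 1.5, 1.0, 0.5, 0.5, 3, ())
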