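"""Differential expression, correlations, overrepresentation, GSEA."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plaqomics.downstream import (
    GeneSetCollection,
    bh_adjust,
    compare_groups,
    differential_expression,
    gsoa,
    hypergeom_overrep,
    pearson_with_p,
    preranked_gsea,
    srf_cofactor_test,
)
from plaqomics.simulate import SimulationConfig, generate_multiomics

from conftest import block_from_array


# -- differential expression ----------------------------------------------

def _de_case(pos_rows, neg_rows):
    arr = np.column_stack([np.asarray(neg_rows).T, np.asarray(pos_rows).T])
    block = block_from_array(arr)
    y = ["nonIPH"] * np.asarray(neg_rows).shape[0] + ["IPH"] * np.asarray(pos_rows).shape[0]
    return block, pd.Series(y, index=block.sample_ids)


def test_log2fc_sign_convention_positive_means_higher_in_iph():
    block, y = _de_case(pos_rows=[[4.0], [4.1], [3.9]], neg_rows=[[3.0], [3.1], [2.9]])
    de = differential_expression(block, y, "IPH")
    assert de["log2fc"].iloc[0] == pytest.approx(1.0)


def test_equal_means_zero_log2fc_and_identical_groups_p_one():
    block, y = _de_case(pos_rows=[[1.0], [2.0], [3.0]], neg_rows=[[1.0], [2.0], [3.0]])
    de = differential_expression(block, y, "IPH")
    assert de["log2fc"].iloc[0] == 0.0
    assert de["t"].iloc[0] == 0.0
    assert de["p"].iloc[0] == pytest.approx(1.0)


def test_paired_test_used_when_pairing_complete():
    rng = np.random.default_rng(0)
    n_pairs = 8
    neg = rng.standard_normal((n_pairs, 5))
    pos = neg + 0.5 + 0.1 * rng.standard_normal((n_pairs, 5))
    block, y = _de_case(pos, neg)
    pid = pd.Series(
        [f"P{i}" for i in range(n_pairs)] * 2, index=block.sample_ids
    )
    de = differential_expression(block, y, "IPH", paired_by=pid)
    t_ref, p_ref = stats.ttest_rel(pos, neg, axis=0)
    np.testing.assert_allclose(de["t"].to_numpy(), t_ref, atol=1e-10)
    np.testing.assert_allclose(de["p"].to_numpy(), p_ref, atol=1e-10)


def test_constant_feature_flagged_degenerate():
    pos = np.ones((3, 2))
    neg = np.ones((3, 2))
    neg[:, 1] = [0.0, 0.5, 1.0]
    pos[:, 1] = [0.2, 0.6, 1.1]
    block, y = _de_case(pos, neg)
    de = differential_expression(block, y, "IPH")
    assert bool(de["degenerate"].iloc[0])
    assert de["p"].iloc[0] == 1.0
    assert not bool(de["degenerate"].iloc[1])


def test_null_type_one_error_near_alpha():
    cfg = SimulationConfig(
        n_per_class=(16, 26),
        block_specs=[("gene", 2000, 0.0)],
        n_informative=0,
        effect_size=0.0,
        seed=17,
    )
    data, _ = generate_multiomics(cfg)
    de = differential_expression(data.block("gene"), data.y, "IPH")
    frac = float((de["p"] < 0.05).mean())
    assert 0.03 <= frac <= 0.07


# -- pearson ---------------------------------------------------------------

def test_pearson_exact_cases():
    x = np.arange(10.0)
    assert pearson_with_p(x, 2 * x + 1).r == pytest.approx(1.0)
    res = pearson_with_p([0.0, 1.0, 2.0], [0.0, 1.0, 0.0])
    assert res.r == pytest.approx(0.0, abs=1e-12)


def test_pearson_null_band_at_n42():
    rng = np.random.default_rng(1)
    hits = 0
    for _ in range(200):
        r = pearson_with_p(rng.standard_normal(42), rng.standard_normal(42)).r
        hits += abs(r) < 0.31
    assert hits >= 0.93 * 200


def test_pearson_rejects_degenerate_input():
    with pytest.raises(ValueError):
        pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        pearson_with_p([1.0, 2.0], [1.0, 2.0])


# -- hypergeometric --------------------------------------------------------

def test_hypergeom_printed_cases():
    assert hypergeom_overrep(5, 5, 5, 20) == pytest.approx(1 / 15504, rel=1e-9)
    assert hypergeom_overrep(0, 5, 5, 20) == 1.0
    assert hypergeom_overrep(3, 5, 5, 10) == pytest.approx(0.5, rel=1e-12)


def test_hypergeom_matches_exhaustive_enumeration():
    """Independent oracle: enumerate all draws of size n from a universe of
    N with K marked items and count overlaps >= k."""
    N = 9
    universe = list(range(N))
    for K in (2, 4):
        marked = set(universe[:K])
        for n in (3, 5):
            draws = list(combinations(universe, n))
            for k in range(0, min(K, n) + 1):
                exact = sum(1 for d in draws if len(marked & set(d)) >= k) / len(draws)
                assert hypergeom_overrep(k, K, n, N) == pytest.approx(exact, rel=1e-9)


def test_hypergeom_rejects_inconsistent_counts():
    with pytest.raises(ValueError):
        hypergeom_overrep(6, 5, 5, 20)


# -- BH --------------------------------------------------------------------

def test_bh_step_up_hand_case():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_preserves_p_order():
    rng = np.random.default_rng(2)
    p = rng.uniform(size=50)
    adj = bh_adjust(p)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)


# -- GSOA ------------------------------------------------------------------

def test_gsoa_full_set_ranks_first():
    universe = {f"g{i}" for i in range(40)}
    sets = {"hit": {f"g{i}" for i in range(10)}, "other": {f"g{i}" for i in range(20, 30)}}
    out = gsoa([f"g{i}" for i in range(10)], GeneSetCollection(sets, universe))
    assert out.iloc[0]["set"] == "hit"
    assert out.iloc[0]["p"] < out.iloc[1]["p"]


def test_gsoa_disjoint_query_all_p_one():
    universe = {f"g{i}" for i in range(40)}
    sets = {"a": {"g0", "g1"}, "b": {"g2", "g3"}}
    out = gsoa(["g30", "g31"], GeneSetCollection(sets, universe))
    assert (out["p"] == 1.0).all()


def test_gsoa_query_outside_universe_is_error():
    universe = {"g0", "g1", "g2"}
    coll = GeneSetCollection({"a": {"g0"}}, universe)
    with pytest.raises(ValueError):
        gsoa(["zzz"], coll)


# -- cofactor test ---------------------------------------------------------

def test_cofactor_full_overlap_small_p():
    universe = {f"g{i}" for i in range(100)}
    targets = {f"g{i}" for i in range(10)}
    out = srf_cofactor_test(targets, {"MKL": set(targets), "ELF4": {f"g{i}" for i in range(50, 60)}}, universe)
    mkl = out[out["cofactor_set"] == "MKL"].iloc[0]
    elf = out[out["cofactor_set"] == "ELF4"].iloc[0]
    assert mkl["p"] < 1e-3
    assert elf["p"] == 1.0


def test_cofactor_enriched_set_wins():
    """A cofactor set built to be 5x enriched in the signature gets the
    smaller p-value in nearly every replicate."""
    rng = np.random.default_rng(3)
    universe = [f"g{i}" for i in range(400)]
    wins = 0
    n_rep = 40
    for _ in range(n_rep):
        sig = set(rng.choice(universe, size=40, replace=False))
        inside = rng.choice(sorted(sig), size=20, replace=False)
        outside = rng.choice(sorted(set(universe) - sig), size=20, replace=False)
        enriched = set(inside[:15]) | set(outside[:5])  # 75% inside the signature
        flat = set(inside[15:18]) | set(outside[5:20])  # ~3/18 inside
        out = srf_cofactor_test(sig, {"enr": enriched, "flat": flat}, universe)
        p = out.set_index("cofactor_set")["p"]
        wins += p["enr"] < p["flat"]
    assert wins >= 0.95 * n_rep


# -- preranked GSEA --------------------------------------------------------

def _ranked(n=50, seed=0):
    rng = np.random.default_rng(seed)
    vals = np.sort(rng.standard_normal(n))[::-1]
    return [(f"g{i}", float(v)) for i, v in enumerate(vals)]


def test_gsea_all_hits_at_top_unit_es():
    ranked = _ranked()
    top = {f"g{i}" for i in range(5)}
    res = preranked_gsea(ranked, top, n_perm=50, weight_exponent=0.0, seed=0)
    assert res.es == pytest.approx(1.0)
    assert res.nes > 1.0


def test_gsea_all_hits_at_bottom_negative_es():
    ranked = _ranked()
    bottom = {f"g{i}" for i in range(45, 50)}
    res = preranked_gsea(ranked, bottom, n_perm=50, seed=0)
    assert res.es < 0


def test_gsea_es_bounded_for_unit_weight_exponent_zero():
    rng = np.random.default_rng(4)
    ranked = _ranked(80, seed=4)
    for _ in range(20):
        gene_set = set(rng.choice([g for g, _ in ranked], size=8, replace=False))
        res = preranked_gsea(ranked, gene_set, n_perm=10, weight_exponent=0.0, seed=1)
        assert -1.0 <= res.es <= 1.0


def test_gsea_null_p_uniform():
    """Random gene sets yield approximately uniform permutation p-values."""
    rng = np.random.default_rng(5)
    ranked = _ranked(100, seed=5)
    pvals = []
    for i in range(100):
        gene_set = set(rng.choice([g for g, _ in ranked], size=10, replace=False))
        pvals.append(preranked_gsea(ranked, gene_set, n_perm=200, seed=i).p)
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_gsea_input_validation():
    ranked = _ranked(20)
    with pytest.raises(ValueError):
        preranked_gsea(ranked, {"absent"}, n_perm=10)
    with pytest.raises(ValueError):
        preranked_gsea(ranked, {g for g, _ in ranked}, n_perm=10)
    with pytest.raises(ValueError):
        preranked_gsea(ranked + [ranked[0]], {"g0"}, n_perm=10)


# -- two-group comparison utility -----------------------------------------

def test_compare_groups_picks_t_for_normal_and_wilcoxon_for_skewed():
    rng = np.random.default_rng(6)
    a, b = rng.standard_normal(30), rng.standard_normal(30) + 1.0
    res = compare_groups(a, b)
    assert res["test"] == "t" and res["p"] < 0.01
    skew_a = np.exp(rng.standard_normal(30) * 2)
    skew_b = np.exp(rng.standard_normal(30) * 2 + 1.5)
    res2 = compare_groups(skew_a, skew_b)
    assert res2["test"] == "wilcoxon_rank_sum"
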