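"""Missingness filter, k-NN imputation, normalization, variance filter."""

import numpy as np
import pandas as pd
import pytest

from plaqomics.preprocess import (
    PreprocessParams,
    filter_missing,
    knn_impute,
    normalize_block,
    preprocess_dataset,
    top_variance_filter,
)
from plaqomics.simulate import SimulationConfig, generate_multiomics

from conftest import block_from_array


# -- filter_missing --------------------------------------------------------

def test_filter_half_missing_is_discarded():
    """A feature missing in exactly half the samples falls to the >= rule."""
    arr = np.array([[1.0, np.nan, 3.0, np.nan], [1.0, 2.0, 3.0, 4.0]])
    block = block_from_array(arr)
    kept, discarded = filter_missing(block, 0.5)
    assert discarded == ["f0"]
    assert kept.feature_ids.tolist() == ["f1"]


def test_filter_no_missing_unchanged():
    block = block_from_array(np.arange(12.0).reshape(3, 4))
    kept, discarded = filter_missing(block, 0.5)
    assert discarded == []
    pd.testing.assert_frame_equal(kept.values, block.values)


def test_filter_enumerated_fractions():
    """Missing counts 0..9 of 10 samples at threshold 0.5: counts 0-4 survive."""
    arr = np.ones((10, 10))
    for i in range(10):
        arr[i, :i] = np.nan
    kept, discarded = filter_missing(block_from_array(arr), 0.5)
    assert kept.feature_ids.tolist() == [f"f{i}" for i in range(5)]
    assert len(discarded) == 5


def test_filter_idempotent():
    arr = np.ones((6, 4))
    arr[0, :3] = np.nan
    arr[1, 0] = np.nan
    once, _ = filter_missing(block_from_array(arr), 0.5)
    twice, again = filter_missing(once, 0.5)
    assert again == []
    pd.testing.assert_frame_equal(once.values, twice.values)


def test_filter_all_discarded_is_error():
    arr = np.full((2, 4), np.nan)
    with pytest.raises(ValueError):
        filter_missing(block_from_array(arr), 0.5)


# -- knn_impute ------------------------------------------------------------

def test_knn_k1_copies_nearest_neighbour_value():
    # s1 misses f0; s1 is close to s2 (f1, f2) and far from s3
    arr = np.array(
        [[np.nan, 5.0, 9.0], [0.0, 0.1, 10.0], [0.0, 0.0, 10.0]]
    )  # features x samples
    out = knn_impute(block_from_array(arr), k=1)
    assert out.values.iloc[0, 0] == pytest.approx(5.0)


def test_knn_equidistant_neighbours_average():
    """Two equidistant neighbours with values 2 and 4 impute their mean 3."""
    arr = np.array(
        [[np.nan, 2.0, 4.0], [0.0, 1.0, -1.0], [0.0, 0.0, 0.0]]
    )
    out = knn_impute(block_from_array(arr), k=2)
    assert out.values.iloc[0, 0] == pytest.approx(3.0)


def test_knn_identical_neighbours_return_shared_value():
    arr = np.array([[np.nan, 7.0, 7.0, 7.0], [1.0, 1.0, 1.0, 1.0]])
    out = knn_impute(block_from_array(arr), k=3)
    assert out.values.iloc[0, 0] == pytest.approx(7.0)


def test_knn_observed_entries_untouched_and_deterministic():
    rng = np.random.default_rng(0)
    arr = rng.standard_normal((30, 12))
    mask = rng.random((30, 12)) < 0.25
    arr_missing = np.where(mask, np.nan, arr)
    block = block_from_array(arr_missing)
    out1 = knn_impute(block, k=4)
    out2 = knn_impute(block, k=4)
    pd.testing.assert_frame_equal(out1.values, out2.values)
    observed = ~np.isnan(arr_missing)
    assert np.array_equal(out1.values.to_numpy()[observed], arr_missing[observed])
    assert not out1.has_missing


def test_knn_beats_global_mean_on_correlated_samples():
    """With correlated samples the k=7 neighbour mean recovers held-out
    values better than the feature's global mean."""
    rng = np.random.default_rng(1)
    n_feat, n = 200, 30
    latent = rng.standard_normal(n)
    load = rng.standard_normal(n_feat)
    truth = np.outer(load, latent) * 2.0 + 0.5 * rng.standard_normal((n_feat, n))
    mask = rng.random((n_feat, n)) < 0.2
    observed = np.where(mask, np.nan, truth)
    out = knn_impute(block_from_array(observed), k=7).values.to_numpy()
    knn_err = np.abs(out[mask] - truth[mask]).mean()
    gmean = np.nanmean(observed, axis=1)
    mean_err = np.abs(np.broadcast_to(gmean[:, None], truth.shape)[mask] - truth[mask]).mean()
    assert knn_err < mean_err


def test_knn_k_must_be_below_sample_count():
    arr = np.ones((3, 4))
    arr[0, 0] = np.nan
    with pytest.raises(ValueError):
        knn_impute(block_from_array(arr), k=4)


# -- normalize_block -------------------------------------------------------

def test_reference_geomean_scale_invariance():
    rng = np.random.default_rng(2)
    raw = np.exp(rng.standard_normal((20, 5)))
    scaled = raw.copy()
    scaled[:, 2] *= 4.0  # multiply one sample by a constant factor
    a = normalize_block(block_from_array(raw), "reference_geomean").values
    b = normalize_block(block_from_array(scaled), "reference_geomean").values
    np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)


def test_log_median_centers_each_sample():
    rng = np.random.default_rng(3)
    raw = np.exp(rng.standard_normal((31, 6)) + 2.0)
    out = normalize_block(block_from_array(raw), "log_median").values
    np.testing.assert_allclose(out.median(axis=0).to_numpy(), 0.0, atol=1e-12)


def test_reference_geomean_hand_computed_divisors():
    """Complete-case geometric means 2 and 8 are the per-sample divisors."""
    raw = np.array([[1.0, 4.0], [4.0, 16.0], [6.0, np.nan]])  # f2 incomplete
    out = normalize_block(block_from_array(raw), "reference_geomean").values
    expected = np.log2(np.array([[1 / 2, 4 / 8], [4 / 2, 16 / 8], [6 / 2, np.nan]]))
    np.testing.assert_allclose(out.to_numpy(), expected, atol=1e-12)


def test_normalize_rejects_nonpositive_and_unknown_mode():
    bad = block_from_array(np.array([[1.0, -2.0]]))
    with pytest.raises(ValueError):
        normalize_block(bad, "log_median")
    with pytest.raises(ValueError):
        normalize_block(block_from_array(np.ones((2, 2))), "quantile")


def test_reference_geomean_requires_complete_features():
    arr = np.array([[1.0, np.nan], [np.nan, 2.0]])
    with pytest.raises(ValueError):
        normalize_block(block_from_array(arr), "reference_geomean")


# -- top_variance_filter ---------------------------------------------------

def test_top_variance_selects_most_variable():
    arr = np.array(
        [[0.0, 2.0, 0.0, 2.0], [0.0, 4.0, 0.0, 4.0], [0.0, 6.0, 0.0, 6.0]]
    )  # variances increase with row index
    out = top_variance_filter(block_from_array(arr), 2)
    assert out.feature_ids.tolist() == ["f1", "f2"]


def test_top_variance_n_equal_all_is_identity():
    block = block_from_array(np.random.default_rng(4).standard_normal((5, 6)))
    out = top_variance_filter(block, 5)
    pd.testing.assert_frame_equal(out.values, block.values)


def test_top_variance_drops_constant_feature():
    rng = np.random.default_rng(5)
    arr = rng.standard_normal((10, 8))
    arr[3] = 1.0  # constant
    out = top_variance_filter(block_from_array(arr), 9)
    assert "f3" not in out.feature_ids


def test_top_variance_errors():
    block = block_from_array(np.ones((2, 3)))
    with pytest.raises(ValueError):
        top_variance_filter(block, 0)
    arr = np.ones((2, 3))
    arr[0, 0] = np.nan
    with pytest.raises(ValueError):
        top_variance_filter(block_from_array(arr), 1)


# -- orchestration ---------------------------------------------------------

def test_preprocess_dataset_pipeline_and_report():
    cfg = SimulationConfig(
        block_specs=[("gene", 150, 0.0), ("protein", 60, 0.3)], seed=8
    )
    data, _ = generate_multiomics(cfg)
    out, report = preprocess_dataset(data, PreprocessParams(top_n_variance=100))
    assert out.block("gene").n_features == 100  # variance filter applied
    assert not out.has_missing()
    prot = report["blocks"]["protein"]
    assert prot["n_features_out"] == prot["n_features_in"] - prot["n_discarded_missing"]
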