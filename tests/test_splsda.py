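"""Sparse PLS-DA core: soft thresholding, fitting, multiblock coupling,
prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaqomics.blocks import MultiOmicsDataset, OmicsBlock
from plaqomics.splsda import (
    ConvergenceError,
    DesignMatrix,
    MultiblockSPLSDA,
    SparsePLSDA,
    make_design,
    soft_select,
)
from plaqomics.splsda import _indicator, _scale_columns

from conftest import dataset_from_arrays


# -- soft_select -----------------------------------------------------------

def test_soft_select_hand_computed_threshold():
    """v = (3, -2, 1), keep 2: threshold 1, pre-normalization (2, -1, 0)."""
    out = soft_select(np.array([3.0, -2.0, 1.0]), 2)
    np.testing.assert_allclose(out, np.array([2.0, -1.0, 0.0]) / np.sqrt(5))


def test_soft_select_keep_all_preserves_direction():
    v = np.array([1.0, -4.0, 2.5])
    out = soft_select(v, 10)
    np.testing.assert_allclose(out, v / np.linalg.norm(v))


def test_soft_select_single_survivor_is_unit():
    np.testing.assert_allclose(soft_select(np.array([5.0, 0.0, 0.0]), 1), [1.0, 0.0, 0.0])


def test_soft_select_all_zero_rejected():
    with pytest.raises(ValueError):
        soft_select(np.zeros(4), 1)


def test_soft_select_tie_falls_back_to_lower_index():
    out = soft_select(np.array([2.0, 2.0, 1.0]), 1)
    np.testing.assert_allclose(out, [1.0, 0.0, 0.0])


@settings(max_examples=100, deadline=None)
@given(
    st.lists(
        st.floats(min_value=-100, max_value=100).filter(lambda x: abs(x) > 1e-6),
        min_size=2,
        max_size=30,
        unique_by=abs,
    ),
    st.data(),
)
def test_soft_select_exact_sparsity_and_unit_norm(values, data):
    """Distinct magnitudes: exactly `keep` nonzeros, unit norm, signs kept."""
    v = np.array(values)
    keep = data.draw(st.integers(min_value=1, max_value=len(values) - 1))
    out = soft_select(v, keep)
    assert np.count_nonzero(out) == keep
    assert np.linalg.norm(out) == pytest.approx(1.0)
    nz = out != 0
    assert np.all(np.sign(out[nz]) == np.sign(v[nz]))


# -- single-block fit ------------------------------------------------------

def _random_case(seed, n=8, p=6):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
    return X, y


def test_dense_fit_matches_cross_covariance_svd():
    """keep = all, one component: the loading is the dominant right singular
    vector of the outcome-block cross-covariance (independent SVD oracle)."""
    for seed in range(10):
        X, y = _random_case(seed)
        res = SparsePLSDA(pd.DataFrame(X), y, ncomp=1).fit()
        Xs, _, _ = _scale_columns(X)
        Yc, _ = _indicator(y, ["A", "B"])
        U = np.linalg.svd(Xs.T @ Yc, full_matrices=False)[0]
        cos = abs(res.loadings.to_numpy()[:, 0] @ U[:, 0])
        assert cos > 1 - 1e-6


def test_single_discriminative_feature_is_selected():
    """One feature separates the classes; keepX = 1 must pick it."""
    for seed in range(30):
        rng = np.random.default_rng(seed)
        n = 20
        X = rng.standard_normal((n, 15))
        y = np.array(["A"] * 10 + ["B"] * 10)
        X[:, 7] = np.where(y == "B", 5.0, -5.0) + 0.1 * rng.standard_normal(n)
        res = SparsePLSDA(pd.DataFrame(X), y, ncomp=1, keep_x=1).fit()
        assert res.selected_features(1) == ["7"]


def test_duplicated_samples_leave_loadings_unchanged():
    X, y = _random_case(1, n=10, p=8)
    base = SparsePLSDA(pd.DataFrame(X), y, ncomp=2, keep_x=4).fit()
    X2 = np.vstack([X, X])
    y2 = np.concatenate([y, y])
    dup = SparsePLSDA(pd.DataFrame(X2), y2, ncomp=2, keep_x=4).fit()
    np.testing.assert_allclose(
        base.loadings.to_numpy(), dup.loadings.to_numpy(), atol=1e-8
    )


def test_sign_convention_largest_loading_positive():
    for seed in range(10):
        X, y = _random_case(seed, n=12, p=9)
        res = SparsePLSDA(pd.DataFrame(X), y, ncomp=2, keep_x=5).fit()
        for h in range(2):
            w = res.loadings.to_numpy()[:, h]
            assert w[np.argmax(np.abs(w))] > 0


def test_deflation_orthogonality_and_exact_sparsity():
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((16, 25))
        y = np.array(["A"] * 8 + ["B"] * 8)
        res = SparsePLSDA(pd.DataFrame(X), y, ncomp=3, keep_x=[5, 7, 9]).fit()
        T = res.scores.to_numpy()
        G = T.T @ T
        assert np.max(np.abs(G - np.diag(np.diag(G)))) < 1e-8
        for h, k in enumerate([5, 7, 9]):
            assert np.count_nonzero(res.loadings.to_numpy()[:, h]) == k


def test_nonconvergence_raises_with_last_iterate():
    X, y = _random_case(2, n=10, p=40)
    with pytest.raises(ConvergenceError) as err:
        SparsePLSDA(pd.DataFrame(X), y, ncomp=1, keep_x=5, max_iter=1, tol=1e-30).fit()
    assert err.value.last_loadings is not None


def test_rejects_missing_values_and_bad_classes():
    X = np.ones((4, 3))
    X[0, 0] = np.nan
    with pytest.raises(ValueError):
        SparsePLSDA(pd.DataFrame(X), ["A", "A", "B", "B"])
    with pytest.raises(ValueError):
        SparsePLSDA(pd.DataFrame(np.ones((3, 2))), ["A", "A", "A"])


# -- design matrix ---------------------------------------------------------

def test_make_design_standard_values():
    d = make_design(["gene", "protein", "peptide"])
    assert d.matrix.shape == (4, 4)
    off = [d.weight(a, b) for a, b in [("gene", "protein"), ("gene", "peptide"), ("protein", "peptide")]]
    assert off == [0.1, 0.1, 0.1]
    assert all(d.weight(b, "outcome") == 1.0 for b in ["gene", "protein", "peptide"])
    assert np.all(np.diag(d.matrix) == 0)


def test_make_design_single_block_and_overrides():
    d = make_design(["gene"])
    assert d.matrix.shape == (2, 2)
    assert d.weight("gene", "outcome") == 1.0
    d2 = make_design(["a", "b"], omics_omics_weight=0.5, omics_outcome_weight=0.9)
    assert d2.weight("a", "b") == 0.5
    assert d2.weight("a", "outcome") == 0.9
    with pytest.raises(ValueError):
        make_design(["a"], omics_omics_weight=-0.1)


def test_design_invariants_enforced():
    with pytest.raises(ValueError):  # asymmetric
        DesignMatrix(["a", "outcome"], np.array([[0.0, 1.0], [0.5, 0.0]]))
    with pytest.raises(ValueError):  # disconnected outcome
        DesignMatrix(["a", "outcome"], np.zeros((2, 2)))


# -- multiblock fit --------------------------------------------------------

def test_identical_blocks_fully_coupled_scores_agree():
    rng = np.random.default_rng(6)
    X = rng.standard_normal((30, 20)).T  # features x samples
    labels = ["A"] * 15 + ["B"] * 15
    data = dataset_from_arrays({"b1": X, "b2": X.copy()}, labels)
    design = make_design(["b1", "b2"], omics_omics_weight=1.0)
    res = MultiblockSPLSDA(data, design, ncomp=1, keep_x=8).fit()
    r = np.corrcoef(res.scores("b1").iloc[:, 0], res.scores("b2").iloc[:, 0])[0, 1]
    assert abs(r) > 0.99


def test_zero_coupling_reduces_to_single_block(complete_two_block):
    """Design 0 between omics blocks: each block's loadings equal the
    single-block sPLS-DA fit (independent implementation path)."""
    data, _ = complete_two_block
    design = make_design(data.block_names, omics_omics_weight=0.0)
    mb = MultiblockSPLSDA(data, design, ncomp=2, keep_x=5).fit()
    for bn in data.block_names:
        single = SparsePLSDA.from_block(
            data.block(bn), data.y, ncomp=2, keep_x=5
        ).fit()
        np.testing.assert_allclose(
            mb.loadings(bn).to_numpy(), single.loadings.to_numpy(), atol=1e-6
        )


def test_multiblock_exact_keepx_per_block(cohort):
    data, _ = cohort
    res = MultiblockSPLSDA(data, ncomp=1, keep_x=10).fit()
    for bn in data.block_names:
        assert len(res.selected_features(bn, 1)) == 10


def test_multiblock_orthogonal_scores(cohort):
    data, _ = cohort
    res = MultiblockSPLSDA(data, ncomp=3, keep_x=12).fit()
    for bn in data.block_names:
        T = res.scores(bn).to_numpy()
        G = T.T @ T
        assert np.max(np.abs(G - np.diag(np.diag(G)))) < 1e-8


def test_multiblock_rejects_missing(cohort):
    data, _ = cohort
    vals = data.blocks[0].values.copy()
    vals.iloc[0, 0] = np.nan
    broken = data.with_blocks(
        [OmicsBlock(data.blocks[0].name, vals)] + data.blocks[1:]
    )
    with pytest.raises(ValueError):
        MultiblockSPLSDA(broken)


# -- prediction ------------------------------------------------------------

def _separable_toy(seed=0):
    rng = np.random.default_rng(seed)
    n = 24
    labels = ["A"] * 12 + ["B"] * 12
    shift = np.where(np.array(labels) == "B", 6.0, -6.0)
    arrays = {}
    for bn in ("b1", "b2"):
        X = rng.standard_normal((15, n))
        X[0] = shift + 0.2 * rng.standard_normal(n)
        arrays[bn] = X
    return dataset_from_arrays(arrays, labels, positive_label="B")


def test_training_predictions_separable():
    data = _separable_toy()
    res = MultiblockSPLSDA(data, ncomp=1, keep_x=3).fit()
    pred = res.predict(data)
    assert (pred.labels == data.y).mean() == 1.0


def test_new_sample_identical_to_training_sample(cohort):
    data, _ = cohort
    res = MultiblockSPLSDA(data, ncomp=2, keep_x=10).fit()
    fitted = res.predict(data)
    one_sample = {
        b.name: pd.DataFrame(b.values.iloc[:, [0]].T) for b in data.blocks
    }
    one = res.predict(one_sample)
    assert one.labels.iloc[0] == fitted.labels.iloc[0]
    np.testing.assert_allclose(
        one.aggregated.to_numpy()[0], fitted.aggregated.to_numpy()[0], atol=1e-12
    )


def test_single_block_aggregated_equals_block_score():
    rng = np.random.default_rng(8)
    X = rng.standard_normal((18, 12)).T
    data = dataset_from_arrays({"gene": X}, ["A"] * 9 + ["B"] * 9)
    res = MultiblockSPLSDA(data, ncomp=1, keep_x=5).fit()
    pred = res.predict(data)
    pd.testing.assert_frame_equal(pred.aggregated, pred.block_indicator["gene"])


def test_predict_missing_features_rejected(cohort):
    data, _ = cohort
    res = MultiblockSPLSDA(data, ncomp=1, keep_x=5).fit()
    truncated = {
        b.name: pd.DataFrame(b.values.iloc[:-5].T) for b in data.blocks
    }
    with pytest.raises(ValueError):
        res.predict(truncated)


def test_model_json_serialization(tmp_path, cohort):
    data, _ = cohort
    res = MultiblockSPLSDA(data, ncomp=1, keep_x=5).fit()
    path = tmp_path / "model.json"
    res.to_json(path)
    import json

    payload = json.loads(path.read_text())
    assert payload["keep_x"]["gene"] == [5]
    assert len(payload["blocks"]["gene"]["loadings_sparse"][0]) == 5


def test_summary_mentions_blocks_and_keepx(cohort):
    data, _ = cohort
    res = MultiblockSPLSDA(data, ncomp=1, keep_x=10).fit()
    text = res.summary()
    assert "gene" in text and "keepX" in text


def test_plot_scores_returns_axes(cohort):
    import matplotlib

    matplotlib.use("Agg")
    data, _ = cohort
    res = MultiblockSPLSDA(data, ncomp=2, keep_x=10).fit()
    ax = res.plot_scores()
    assert ax.get_xlabel() == "component 1"
    ax2 = res.plot_scores(block="gene")
    assert ax2.get_title() == "gene"
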