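"""Preprocessing: missingness filter, k-NN imputation, normalization,
top-variance feature selection.

The MS-based layers (proteins, peptides) arrive with substantial missingness;
features missing in at least half the samples are discarded and the remainder
imputed by unsupervised sample-wise k-nearest-neighbour averaging (k = 7 by
default).  The transcriptomics layer is reduced to its most variable features.

The platform-specific normalizations of the original pipelines (variance
stabilization + robust spline normalization for Illumina arrays, a
reference-gene procedure for MS ratios) require raw platform data; this module
provides two stand-ins that preserve their intent: ``log_median`` (log2 then
per-sample median centering, a variance-stabilizing location adjustment) and
``reference_geomean`` (per-sample scaling by the geometric mean of the
complete-case features, a housekeeping-style reference normalization).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocks import MultiOmicsDataset, OmicsBlock

__all__ = [
    "PreprocessParams",
    "filter_missing",
    "knn_impute",
    "normalize_block",
    "top_variance_filter",
    "preprocess_dataset",
]

logger = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    """Knobs of the preprocessing stage.

    max_missing_frac : features with missing fraction >= this are discarded
        (the default 0.5 discards a feature missing in exactly half the
        samples).
    knn_k : neighbour count for imputation; must be < number of samples.
    top_n_variance : if set, keep only this many most-variable features
        (applied to the complete transcriptomics block; 10,000 in the study).
    """

    max_missing_frac: float = 0.5
    knn_k: int = 7
    top_n_variance: int | None = 10_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_frac <= 1.0:
            raise ValueError("max_missing_frac must be in [0, 1]")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


def filter_missing(
    block: OmicsBlock, max_missing_frac: float = 0.5
) -> tuple[OmicsBlock, list[str]]:
    """Drop features whose missing fraction is >= ``max_missing_frac``.

    Returns the filtered block (feature order preserved) and the list of
    discarded feature ids.  An empty result signals degenerate input and
    raises.
    """
    frac = block.missing_fraction()
    keep = frac < max_missing_frac
    discarded = block.feature_ids[~keep].tolist()
    if not keep.any():
        raise ValueError(
            f"block {block.name!r}: no feature has missing fraction < {max_missing_frac}"
        )
    return block.with_values(block.values.loc[keep]), discarded


def knn_impute(block: OmicsBlock, k: int = 7) -> OmicsBlock:
    """Sample-wise k-nearest-neighbour imputation (unsupervised).

    For a sample with a missing feature, distances to every other sample are
    Euclidean over the mutually observed features, scaled by the number of
    such features (so distances remain comparable under 26-39% missingness).
    The missing value becomes the unweighted mean of the feature's observed
    values among the k nearest neighbours.  If none of the k neighbours
    observed the feature, the feature's overall observed mean is used and a
    warning is emitted.  Observed entries are never modified; phenotype
    labels are never consulted.
    """
    X = block.to_samples_by_features()  # n_samples x n_features
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"knn_k={k} must be smaller than the sample count {n}")
    if not np.isnan(X).any():
        return block
    from sklearn.metrics.pairwise import nan_euclidean_distances

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        D = nan_euclidean_distances(X)  # scaled by sqrt(n_total / n_observed)
    np.fill_diagonal(D, np.inf)
    feat_mean = np.nanmean(X, axis=0)
    out = X.copy()
    n_fallback = 0
    for i in np.where(np.isnan(X).any(axis=1))[0]:
        order = np.argsort(D[i], kind="stable")
        neighbours = order[:k]
        for j in np.where(np.isnan(X[i]))[0]:
            vals = X[neighbours, j]
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                out[i, j] = feat_mean[j]
                n_fallback += 1
            else:
                out[i, j] = vals.mean()
    if n_fallback:
        logger.warning(
            "block %r: %d entries imputed by overall feature mean "
            "(feature unobserved in all k neighbours)",
            block.name,
            n_fallback,
        )
    return block.with_values(
        pd.DataFrame(out.T, index=block.feature_ids, columns=block.sample_ids)
    )


def normalize_block(block: OmicsBlock, mode: str = "log_median") -> OmicsBlock:
    """Normalize raw (positive) abundances onto a comparable log2 scale.

    mode "log_median": log2 then subtract each sample's median.
    mode "reference_geomean": divide each sample by the geometric mean of its
    complete-case features (those observed in every sample), then log2 —
    invariant to per-sample scale factors.  Missing entries stay missing.
    """
    vals = block.values
    obs = vals.to_numpy()
    if np.nanmin(obs) <= 0:
        raise ValueError(f"block {block.name!r}: normalization requires positive values")
    if mode == "log_median":
        logged = np.log2(vals)
        centered = logged.sub(logged.median(axis=0, skipna=True), axis=1)
        return block.with_values(centered)
    if mode == "reference_geomean":
        complete = vals.dropna(axis=0)
        if complete.empty:
            raise ValueError(
                f"block {block.name!r}: no complete-case features for reference scaling"
            )
        geomean = np.exp(np.log(complete).mean(axis=0))  # per-sample divisor
        return block.with_values(np.log2(vals.div(geomean, axis=1)))
    raise ValueError(f"unknown normalization mode {mode!r}")


def top_variance_filter(block: OmicsBlock, n: int) -> OmicsBlock:
    """Keep the ``n`` features with largest sample variance.

    Requires a fully observed block.  Ties are broken by lexicographic
    feature id so the output is deterministic; the original feature order is
    preserved among the retained features.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if block.has_missing:
        raise ValueError(f"block {block.name!r}: impute before variance filtering")
    if n >= block.n_features:
        return block
    var = block.values.var(axis=1, ddof=1)
    ranked = var.to_frame("var").assign(fid=var.index)
    ranked = ranked.sort_values(["var", "fid"], ascending=[False, True])
    keep = set(ranked.index[:n])
    return block.with_values(block.values.loc[[f in keep for f in block.feature_ids]])


def preprocess_dataset(
    data: MultiOmicsDataset,
    params: PreprocessParams | None = None,
    variance_filter_blocks: tuple[str, ...] = ("gene",),
) -> tuple[MultiOmicsDataset, dict]:
    """Run the standard per-block pipeline and return (dataset, report).

    Blocks with missing values go through filter -> k-NN imputation; complete
    blocks named in ``variance_filter_blocks`` are reduced to the top
    ``params.top_n_variance`` most variable features.  Input blocks are
    assumed to be on a normalized log scale already (apply
    :func:`normalize_block` first when starting from raw abundances).
    """
    params = params or PreprocessParams()
    report: dict = {"blocks": {}}
    out_blocks: list[OmicsBlock] = []
    for b in data.blocks:
        entry: dict = {"n_features_in": b.n_features}
        if b.has_missing:
            filtered, discarded = filter_missing(b, params.max_missing_frac)
            entry["n_discarded_missing"] = len(discarded)
            entry["discarded_ids"] = discarded
            b = knn_impute(filtered, params.knn_k)
        elif params.top_n_variance is not None and b.name in variance_filter_blocks:
            b = top_variance_filter(b, min(params.top_n_variance, b.n_features))
        entry["n_features_out"] = b.n_features
        report["blocks"][b.name] = entry
        out_blocks.append(b)
    return data.with_blocks(out_blocks), report
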