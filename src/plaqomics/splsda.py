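"""Sparse PLS discriminant analysis, single-block and multiblock.

Single-block sPLS-DA projects a scaled feature matrix onto a small number of
latent components that covary maximally with the (centered, indicator-coded)
class membership, while an L1-style soft-thresholding step — ``soft_select`` —
caps the number of nonzero loading weights per component at a budget
``keepX``.  The multiblock variant couples several omics blocks through a
design matrix ``C``: each block's loading update pools the cross-covariance
with every connected block's latent score plus the outcome score, weighted by
the corresponding design entry, so the fitted components of different blocks
are driven to covary and span a common discriminative space.

Both models follow the statsmodels convention: a model object is built from
data, ``fit()`` returns a results object carrying loadings, scores, scaling
parameters, and ``predict``/``summary`` methods.

Numerical contract (documented, deterministic):

* loading vectors have unit Euclidean norm and exactly ``min(keepX, p)``
  nonzeros for generic inputs; ties at the selection threshold are broken
  toward the lower feature index;
* initialization is the dominant singular vector of the block-vs-outcome
  cross-covariance (no random start);
* convergence when the largest loading-weight change drops below ``tol``
  (default 1e-6), at most ``max_iter`` (default 100) sweeps;
* each X block is deflated by regression on its own score, which makes
  within-block scores of different components exactly orthogonal; the
  outcome block is kept fixed (a binary outcome's centered indicator matrix
  has rank one, so deflating it would leave nothing for later components);
* the largest-magnitude loading entry of every component is made positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .blocks import MultiOmicsDataset, OmicsBlock
from . import io as pio

__all__ = [
    "soft_select",
    "DesignMatrix",
    "make_design",
    "SparsePLSDA",
    "SparsePLSDAResults",
    "MultiblockSPLSDA",
    "MultiblockSPLSDAResults",
    "Prediction",
    "ConvergenceError",
]

OUTCOME = "outcome"


class ConvergenceError(RuntimeError):
    """Raised when the alternating updates fail to converge; carries the
    last iterate in ``last_loadings``."""

    def __init__(self, msg: str, last_loadings=None):
        super().__init__(msg)
        self.last_loadings = last_loadings


# ---------------------------------------------------------------------------
# soft-thresholded selection
# ---------------------------------------------------------------------------

def soft_select(v: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold ``v`` so that ``keep`` entries survive, then rescale to
    unit norm.

    The threshold is the ``(keep+1)``-th largest absolute value (zero when
    ``keep`` covers the whole vector); surviving entries are shrunk toward
    zero by the threshold, preserving sign.  With distinct magnitudes the
    result has exactly ``keep`` nonzeros.  When ties at the threshold would
    annihilate every survivor, the top-``keep`` entries (ties broken toward
    the lower index) are kept at their raw values instead.
    """
    v = np.asarray(v, dtype=float)
    if keep < 1:
        raise ValueError("keep must be >= 1")
    if not np.any(v != 0.0):
        raise ValueError("cannot select from an all-zero vector")
    absv = np.abs(v)
    if keep >= v.size:
        return v / np.linalg.norm(v)
    # stable ranking: magnitude descending, index ascending on ties
    order = np.lexsort((np.arange(v.size), -absv))
    lam = absv[order[keep]]
    out = np.sign(v) * np.maximum(absv - lam, 0.0)
    nrm = np.linalg.norm(out)
    if nrm == 0.0:  # all survivors tied with the threshold
        out = np.zeros_like(v)
        sel = order[:keep]
        out[sel] = v[sel]
        nrm = np.linalg.norm(out)
    return out / nrm


def _fix_sign(a: np.ndarray) -> float:
    """Return +-1 so that the largest-magnitude entry of ``sign * a`` is
    positive (lowest index wins ties)."""
    i = np.lexsort((np.arange(a.size), -np.abs(a)))[0]
    return 1.0 if a[i] >= 0 else -1.0


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Symmetric coupling weights between omics blocks and the outcome.

    ``names`` lists the blocks followed by ``"outcome"``; ``matrix`` holds
    entries in [0, 1] with a zero diagonal.  Every block must be connected
    to the outcome (strictly positive weight).
    """

    names: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.names)
        if self.matrix.shape != (k, k):
            raise ValueError("design matrix shape does not match names")
        if OUTCOME not in self.names:
            raise ValueError("design must include the outcome block")
        if np.any(self.matrix < 0) or np.any(self.matrix > 1):
            raise ValueError("design entries must lie in [0, 1]")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("design matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("design diagonal must be zero")
        out = self.names.index(OUTCOME)
        others = [i for i in range(k) if i != out]
        if np.any(self.matrix[out, others] <= 0):
            raise ValueError("every block must have positive weight to the outcome")

    def weight(self, a: str, b: str) -> float:
        return float(self.matrix[self.names.index(a), self.names.index(b)])


def make_design(
    block_names: Sequence[str],
    omics_omics_weight: float = 0.1,
    omics_outcome_weight: float = 1.0,
) -> DesignMatrix:
    """Standard design: a small coupling between omics blocks and full
    coupling of every block to the outcome (defaults 0.1 and 1.0)."""
    if omics_omics_weight < 0 or omics_outcome_weight < 0:
        raise ValueError("design weights must be nonnegative")
    names = list(block_names) + [OUTCOME]
    k = len(names)
    C = np.full((k, k), omics_omics_weight)
    C[-1, :] = C[:, -1] = omics_outcome_weight
    np.fill_diagonal(C, 0.0)
    return DesignMatrix(names, C)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _scale_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X - mean) / sd, mean, sd


def _indicator(y: np.ndarray, classes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Centered one-column-per-class indicator matrix and its column means."""
    Y = np.column_stack([(y == c).astype(float) for c in classes])
    mean = Y.mean(axis=0)
    return Y - mean, mean


def _init_loading(X: np.ndarray, Yc: np.ndarray) -> np.ndarray:
    """Dominant left singular vector of the block-outcome cross-covariance."""
    M = X.T @ Yc
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    a = U[:, 0]
    return a * _fix_sign(a)


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v if n == 0 else v / n


def _as_keepx_list(keep_x, ncomp: int, p: int) -> list[int]:
    if keep_x is None:
        return [p] * ncomp
    if np.isscalar(keep_x):
        return [int(keep_x)] * ncomp
    keep_x = [int(k) for k in keep_x]
    if len(keep_x) < ncomp:
        keep_x = keep_x + [keep_x[-1]] * (ncomp - len(keep_x))
    return keep_x[:ncomp]


# ---------------------------------------------------------------------------
# prediction container
# ---------------------------------------------------------------------------

@dataclass
class Prediction:
    """Projection of new samples through a fitted model.

    ``block_indicator`` holds each block's predicted class-indicator values;
    ``aggregated`` is their design-weighted average; ``labels`` applies the
    max.dist rule (argmax of the aggregated indicator); ``score`` is the
    aggregated indicator value of the positive class, the continuous score
    used for AUC.
    """

    classes: list[str]
    positive_label: str
    block_scores: dict[str, pd.DataFrame]
    block_indicator: dict[str, pd.DataFrame]
    aggregated: pd.DataFrame

    @property
    def labels(self) -> pd.Series:
        idx = self.aggregated.to_numpy().argmax(axis=1)
        return pd.Series(
            [self.classes[i] for i in idx], index=self.aggregated.index, name="label"
        )

    @property
    def score(self) -> pd.Series:
        return self.aggregated[self.positive_label].rename("score")

    def block_labels(self, block: str) -> pd.Series:
        ind = self.block_indicator[block]
        idx = ind.to_numpy().argmax(axis=1)
        return pd.Series([self.classes[i] for i in idx], index=ind.index)


def _project_block(
    Xs: np.ndarray, loadings: np.ndarray, p_reg: np.ndarray
) -> np.ndarray:
    """Sequentially project scaled data through the per-component loadings,
    deflating with the stored regression loadings ``p_reg``."""
    ncomp = loadings.shape[1]
    T = np.empty((Xs.shape[0], ncomp))
    Xd = Xs.copy()
    for h in range(ncomp):
        t = Xd @ loadings[:, h]
        T[:, h] = t
        Xd -= np.outer(t, p_reg[:, h])
    return T


# ---------------------------------------------------------------------------
# single-block model
# ---------------------------------------------------------------------------

class SparsePLSDA:
    """Single-block sparse PLS discriminant analysis.

    Parameters
    ----------
    X : pandas.DataFrame or ndarray, samples x features
    y : array-like of two class labels, aligned with the rows of X
    ncomp : number of latent components
    keep_x : per-component nonzero-loading budgets (scalar, list, or None
        for no sparsity)
    """

    def __init__(
        self,
        X,
        y,
        ncomp: int = 2,
        keep_x=None,
        *,
        tol: float = 1e-6,
        max_iter: int = 100,
        positive_label: str | None = None,
    ):
        X = pd.DataFrame(X)
        self.feature_ids = X.columns.astype(str)
        self.sample_ids = X.index.astype(str)
        self.X = X.to_numpy(dtype=float)
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values; impute first")
        self.y = np.asarray(pd.Series(y).astype(str))
        self.classes = sorted(set(self.y))
        if len(self.classes) != 2:
            raise ValueError("exactly two classes required")
        if ncomp < 1:
            raise ValueError("ncomp must be >= 1")
        self.ncomp = int(ncomp)
        self.keep_x = _as_keepx_list(keep_x, self.ncomp, self.X.shape[1])
        self.tol = tol
        self.max_iter = max_iter
        self.positive_label = positive_label or self.classes[-1]

    @classmethod
    def from_block(cls, block: OmicsBlock, y, **kwargs) -> "SparsePLSDA":
        return cls(pd.DataFrame(block.values.T), y, **kwargs)

    def fit(self) -> "SparsePLSDAResults":
        Xs, x_mean, x_sd = _scale_columns(self.X)
        Yc, y_mean = _indicator(self.y, self.classes)
        n, p = Xs.shape
        A = np.zeros((p, self.ncomp))
        P = np.zeros((p, self.ncomp))
        Cw = np.zeros((len(self.classes), self.ncomp))
        T = np.zeros((n, self.ncomp))
        Xd = Xs.copy()
        for h in range(self.ncomp):
            keep = min(self.keep_x[h], p)
            a = _init_loading(Xd, Yc)
            for _ in range(self.max_iter):
                t = Xd @ a
                b = _normalize(Yc.T @ t)
                u = Yc @ b
                a_new = soft_select(Xd.T @ u, keep)
                delta = np.max(np.abs(a_new - a))
                a = a_new
                if delta < self.tol:
                    break
            else:
                raise ConvergenceError(
                    f"component {h + 1} did not converge in {self.max_iter} iterations",
                    last_loadings=a,
                )
            s = _fix_sign(a)
            a = s * a
            t = Xd @ a
            tt = float(t @ t)
            P[:, h] = Xd.T @ t / tt
            Cw[:, h] = Yc.T @ t / tt
            A[:, h] = a
            T[:, h] = t
            Xd = Xd - np.outer(t, P[:, h])
        return SparsePLSDAResults(self, A, P, Cw, T, x_mean, x_sd, y_mean)


@dataclass
class SparsePLSDAResults:
    """Fitted single-block sPLS-DA: sparse loadings, scores and everything
    needed to project new samples."""

    model: SparsePLSDA
    _loadings: np.ndarray
    _p_reg: np.ndarray
    _y_weights: np.ndarray
    _scores: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray

    @property
    def classes(self) -> list[str]:
        return self.model.classes

    @property
    def loadings(self) -> pd.DataFrame:
        return pd.DataFrame(
            self._loadings,
            index=self.model.feature_ids,
            columns=[f"comp{h + 1}" for h in range(self.model.ncomp)],
        )

    @property
    def scores(self) -> pd.DataFrame:
        return pd.DataFrame(
            self._scores,
            index=self.model.sample_ids,
            columns=[f"comp{h + 1}" for h in range(self.model.ncomp)],
        )

    def centroids(self) -> pd.DataFrame:
        """Class centroids in score space."""
        sc = self.scores
        return sc.groupby(pd.Series(self.model.y, index=sc.index)).mean()

    def selected_features(self, comp: int = 1) -> list[str]:
        w = self._loadings[:, comp - 1]
        return [f for f, v in zip(self.model.feature_ids, w) if v != 0.0]

    def predict(self, X_new) -> Prediction:
        X_new = pd.DataFrame(X_new)
        missing = [f for f in self.model.feature_ids if f not in X_new.columns]
        if missing:
            raise ValueError(f"new data lacks {len(missing)} model features, e.g. {missing[:3]}")
        Xs = (X_new[self.model.feature_ids].to_numpy(dtype=float) - self.x_mean) / self.x_sd
        T = _project_block(Xs, self._loadings, self._p_reg)
        Yhat = T @ self._y_weights.T + self.y_mean
        idx = X_new.index.astype(str)
        cols = [f"comp{h + 1}" for h in range(self.model.ncomp)]
        sc = pd.DataFrame(T, index=idx, columns=cols)
        ind = pd.DataFrame(Yhat, index=idx, columns=self.classes)
        return Prediction(
            self.classes, self.model.positive_label, {"X": sc}, {"X": ind}, ind
        )

    def summary(self) -> str:
        lines = [
            "Sparse PLS-DA results",
            "=" * 48,
            f"samples: {len(self.model.sample_ids)}   features: {len(self.model.feature_ids)}",
            f"classes: {self.classes} (positive: {self.model.positive_label})",
            f"components: {self.model.ncomp}   keepX: {self.model.keep_x}",
        ]
        for h in range(self.model.ncomp):
            sel = self.selected_features(h + 1)
            top = self.loadings.iloc[:, h].abs().sort_values(ascending=False).head(5)
            lines.append(
                f"comp{h + 1}: {len(sel)} nonzero loadings; top |weight|: "
                + ", ".join(f"{f}={v:.3f}" for f, v in top.items() if v > 0)
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# multiblock model
# ---------------------------------------------------------------------------

class MultiblockSPLSDA:
    """Multiblock sparse PLS-DA coupling several omics blocks through a
    design matrix (DIABLO-style integration).

    Parameters
    ----------
    data : MultiOmicsDataset
        Aligned, fully observed blocks with a binary phenotype.
    design : DesignMatrix or None
        Coupling weights; defaults to 0.1 between omics blocks and 1.0 to
        the outcome.
    ncomp : number of components.
    keep_x : mapping block name -> per-component budgets (or scalar/list
        applied to every block; None keeps all features).
    """

    def __init__(
        self,
        data: MultiOmicsDataset,
        design: DesignMatrix | None = None,
        ncomp: int = 2,
        keep_x: Mapping[str, Sequence[int]] | Sequence[int] | int | None = None,
        *,
        tol: float = 1e-6,
        max_iter: int = 100,
    ):
        if data.has_missing():
            raise ValueError("blocks contain missing values; impute first")
        self.data = data
        self.block_names = data.block_names
        self.design = design or make_design(self.block_names)
        missing = [b for b in self.block_names if b not in self.design.names]
        if missing:
            raise ValueError(f"design lacks blocks {missing}")
        if ncomp < 1:
            raise ValueError("ncomp must be >= 1")
        self.ncomp = int(ncomp)
        self.classes = data.classes
        self.positive_label = data.positive_label
        self.keep_x: dict[str, list[int]] = {}
        for b in data.blocks:
            if keep_x is None or isinstance(keep_x, (int, np.integer, list, tuple)):
                kx = keep_x
            else:
                kx = keep_x.get(b.name)
            self.keep_x[b.name] = _as_keepx_list(kx, self.ncomp, b.n_features)
        self.tol = tol
        self.max_iter = max_iter

    def fit(self) -> "MultiblockSPLSDAResults":
        data = self.data
        y = np.asarray(data.y.astype(str))
        Yc, y_mean = _indicator(y, self.classes)
        n = data.n_samples
        Xs: dict[str, np.ndarray] = {}
        x_mean: dict[str, np.ndarray] = {}
        x_sd: dict[str, np.ndarray] = {}
        for b in data.blocks:
            Xs[b.name], x_mean[b.name], x_sd[b.name] = _scale_columns(
                b.to_samples_by_features()
            )
        names = self.block_names
        w_out = {bn: self.design.weight(bn, OUTCOME) for bn in names}
        w_bb = {
            (a, c): self.design.weight(a, c) for a in names for c in names if a != c
        }

        A = {bn: np.zeros((Xs[bn].shape[1], self.ncomp)) for bn in names}
        P = {bn: np.zeros((Xs[bn].shape[1], self.ncomp)) for bn in names}
        Cw = {bn: np.zeros((len(self.classes), self.ncomp)) for bn in names}
        T = {bn: np.zeros((n, self.ncomp)) for bn in names}
        Xd = {bn: Xs[bn].copy() for bn in names}

        for h in range(self.ncomp):
            a = {bn: _init_loading(Xd[bn], Yc) for bn in names}
            t = {bn: Xd[bn] @ a[bn] for bn in names}
            u = self._outcome_score(Yc, t, w_out)
            for _ in range(self.max_iter):
                delta = 0.0
                for bn in names:
                    direction = w_out[bn] * (Xd[bn].T @ u)
                    for other in names:
                        if other != bn and w_bb[(bn, other)] > 0:
                            direction = direction + w_bb[(bn, other)] * (
                                Xd[bn].T @ t[other]
                            )
                    keep = min(self.keep_x[bn][h], Xd[bn].shape[1])
                    a_new = soft_select(direction, keep)
                    delta = max(delta, float(np.max(np.abs(a_new - a[bn]))))
                    a[bn] = a_new
                    t[bn] = Xd[bn] @ a_new
                u = self._outcome_score(Yc, t, w_out)
                if delta < self.tol:
                    break
            else:
                raise ConvergenceError(
                    f"component {h + 1} did not converge in {self.max_iter} sweeps",
                    last_loadings=a,
                )
            for bn in names:
                s = _fix_sign(a[bn])
                a[bn] = s * a[bn]
                t[bn] = Xd[bn] @ a[bn]
                tt = float(t[bn] @ t[bn])
                P[bn][:, h] = Xd[bn].T @ t[bn] / tt
                Cw[bn][:, h] = Yc.T @ t[bn] / tt
                A[bn][:, h] = a[bn]
                T[bn][:, h] = t[bn]
                Xd[bn] = Xd[bn] - np.outer(t[bn], P[bn][:, h])
        return MultiblockSPLSDAResults(self, A, P, Cw, T, x_mean, x_sd, y_mean)

    @staticmethod
    def _outcome_score(
        Yc: np.ndarray, t: Mapping[str, np.ndarray], w_out: Mapping[str, float]
    ) -> np.ndarray:
        b = np.zeros(Yc.shape[1])
        for bn, tv in t.items():
            b += w_out[bn] * (Yc.T @ tv)
        return Yc @ _normalize(b)


@dataclass
class MultiblockSPLSDAResults:
    """Fitted multiblock sPLS-DA model."""

    model: MultiblockSPLSDA
    _loadings: dict[str, np.ndarray]
    _p_reg: dict[str, np.ndarray]
    _y_weights: dict[str, np.ndarray]
    _scores: dict[str, np.ndarray]
    x_mean: dict[str, np.ndarray]
    x_sd: dict[str, np.ndarray]
    y_mean: np.ndarray

    @property
    def classes(self) -> list[str]:
        return self.model.classes

    @property
    def block_names(self) -> list[str]:
        return self.model.block_names

    def _comp_cols(self) -> list[str]:
        return [f"comp{h + 1}" for h in range(self.model.ncomp)]

    def loadings(self, block: str) -> pd.DataFrame:
        return pd.DataFrame(
            self._loadings[block],
            index=self.model.data.block(block).feature_ids,
            columns=self._comp_cols(),
        )

    def scores(self, block: str) -> pd.DataFrame:
        return pd.DataFrame(
            self._scores[block],
            index=self.model.data.sample_ids,
            columns=self._comp_cols(),
        )

    def centroids(self, block: str) -> pd.DataFrame:
        sc = self.scores(block)
        return sc.groupby(self.model.data.y).mean()

    def selected_features(self, block: str, comp: int = 1) -> list[str]:
        load = self.loadings(block)
        w = load.iloc[:, comp - 1]
        return w.index[w != 0.0].tolist()

    def average_scores(self) -> pd.DataFrame:
        """Design-weighted average of the per-block score matrices — the
        consensus coordinates used for component-trait correlations."""
        w = np.array(
            [self.model.design.weight(bn, OUTCOME) for bn in self.block_names]
        )
        w = w / w.sum()
        agg = sum(
            wi * self._scores[bn] for wi, bn in zip(w, self.block_names)
        )
        return pd.DataFrame(
            agg, index=self.model.data.sample_ids, columns=self._comp_cols()
        )

    def predict(self, new_data: MultiOmicsDataset | Mapping[str, pd.DataFrame]) -> Prediction:
        """Project new samples and classify by the max.dist rule on the
        design-weighted average of per-block predicted indicator values."""
        if isinstance(new_data, MultiOmicsDataset):
            frames = {b.name: pd.DataFrame(b.values.T) for b in new_data.blocks}
        else:
            frames = {k: pd.DataFrame(v) for k, v in new_data.items()}
        block_scores: dict[str, pd.DataFrame] = {}
        block_ind: dict[str, pd.DataFrame] = {}
        weights = []
        idx = None
        for bn in self.block_names:
            if bn not in frames:
                raise ValueError(f"new data lacks block {bn!r}")
            feats = self.model.data.block(bn).feature_ids
            Xn = frames[bn]
            missing = [f for f in feats if f not in Xn.columns]
            if missing:
                raise ValueError(
                    f"block {bn!r}: new data lacks {len(missing)} model features, "
                    f"e.g. {missing[:3]}"
                )
            Xsn = (Xn[feats].to_numpy(dtype=float) - self.x_mean[bn]) / self.x_sd[bn]
            T = _project_block(Xsn, self._loadings[bn], self._p_reg[bn])
            Yhat = T @ self._y_weights[bn].T + self.y_mean
            idx = Xn.index.astype(str)
            block_scores[bn] = pd.DataFrame(T, index=idx, columns=self._comp_cols())
            block_ind[bn] = pd.DataFrame(Yhat, index=idx, columns=self.classes)
            weights.append(self.model.design.weight(bn, OUTCOME))
        w = np.asarray(weights)
        w = w / w.sum()
        agg = sum(wi * block_ind[bn] for wi, bn in zip(w, self.block_names))
        return Prediction(
            self.classes, self.model.positive_label, block_scores, block_ind, agg
        )

    # -- serialization ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": self.classes,
            "positive_label": self.model.positive_label,
            "ncomp": self.model.ncomp,
            "keep_x": self.model.keep_x,
            "design": {
                "names": self.model.design.names,
                "matrix": self.model.design.matrix.tolist(),
            },
            "y_mean": self.y_mean.tolist(),
            "blocks": {},
        }
        for bn in self.block_names:
            feats = self.model.data.block(bn).feature_ids
            sparse = []
            for h in range(self.model.ncomp):
                w = self._loadings[bn][:, h]
                sparse.append({str(f): float(v) for f, v in zip(feats, w) if v != 0.0})
            payload["blocks"][bn] = {
                "feature_ids": [str(f) for f in feats],
                "loadings_sparse": sparse,
                "p_reg": self._p_reg[bn].tolist(),
                "y_weights": self._y_weights[bn].tolist(),
                "x_mean": self.x_mean[bn].tolist(),
                "x_sd": self.x_sd[bn].tolist(),
            }
        pio.dump_json(payload, path)

    def plot_scores(self, block: str | None = None, comps: tuple[int, int] = (1, 2), ax=None):
        """Scatter of samples in component space, colored by phenotype.

        ``block=None`` plots the design-weighted consensus scores.  With a
        one-component model the second axis is jittered at zero.
        """
        import matplotlib.pyplot as plt

        sc = self.average_scores() if block is None else self.scores(block)
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        x = sc.iloc[:, comps[0] - 1]
        y_ax = (
            sc.iloc[:, comps[1] - 1]
            if sc.shape[1] >= comps[1]
            else pd.Series(0.0, index=sc.index)
        )
        for cls, marker in zip(self.classes, ("o", "s")):
            m = (self.model.data.y == cls).to_numpy()
            ax.scatter(x[m], y_ax[m], label=cls, marker=marker, alpha=0.8)
        ax.set_xlabel(f"component {comps[0]}")
        ax.set_ylabel(f"component {comps[1]}")
        ax.set_title(block or "consensus")
        ax.legend()
        return ax

    def summary(self) -> str:
        m = self.model
        lines = [
            "Multiblock sparse PLS-DA results",
            "=" * 48,
            f"samples: {m.data.n_samples}   blocks: "
            + ", ".join(f"{b.name}({b.n_features})" for b in m.data.blocks),
            f"classes: {self.classes} (positive: {m.positive_label})",
            f"components: {m.ncomp}",
        ]
        for bn in self.block_names:
            kx = m.keep_x[bn]
            nsel = [len(self.selected_features(bn, h + 1)) for h in range(m.ncomp)]
            lines.append(f"  {bn}: keepX={kx} selected={nsel}")
        agg = self.average_scores()
        cors = agg.corrwith(
            pd.Series(
                (m.data.y == m.positive_label).astype(float), index=agg.index
            )
        )
        lines.append(
            "component-phenotype correlation: "
            + ", ".join(f"{c}={v:.3f}" for c, v in cors.items())
        )
        return "\n".join(lines)
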