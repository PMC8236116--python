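"""Parameter tuning and cross-validated performance estimation.

The number of components and the per-block feature budgets (keepX) are tuned
by stratified repeated k-fold cross-validation scored with the balanced error
rate (BER) — the mean of the per-class error rates, which does not reward
majority-class guessing in an unbalanced cohort such as 16 vs 26.  The keepX
search runs sequentially per component: earlier components' budgets are
frozen while the candidate grid is scanned for the current one, which keeps
the published candidate grids tractable.

Grids are specified as inclusive piecewise ranges.  The canonical single-omics
grid (3-30 by 3, 30-60 by 6, 60-150 by 15, 150-300 by 30) enumerates to 26
distinct candidates; the integrative grid (10-50 by 5, 50-100 by 10) to 14.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .blocks import MultiOmicsDataset
from .splsda import DesignMatrix, MultiblockSPLSDA, SparsePLSDA, make_design

__all__ = [
    "SINGLE_KEEPX_RANGES",
    "INTEGRATIVE_KEEPX_RANGES",
    "enumerate_grid",
    "TuningGrid",
    "ModelSpec",
    "CVResult",
    "PerformanceSummary",
    "balanced_error_rate",
    "auc_score",
    "stratified_kfold_cv",
    "tune",
    "TuneResult",
]

#: canonical keepX candidate ranges, as (start, stop, step) inclusive pieces
SINGLE_KEEPX_RANGES: list[tuple[int, int, int]] = [
    (3, 30, 3),
    (30, 60, 6),
    (60, 150, 15),
    (150, 300, 30),
]
INTEGRATIVE_KEEPX_RANGES: list[tuple[int, int, int]] = [(10, 50, 5), (50, 100, 10)]


def enumerate_grid(ranges: Sequence[tuple[int, int, int]]) -> list[int]:
    """Expand inclusive (start, stop, step) pieces into sorted distinct values."""
    if not ranges:
        raise ValueError("empty grid specification")
    values: set[int] = set()
    for start, stop, step in ranges:
        if step <= 0 or stop < start:
            raise ValueError(f"invalid range piece ({start}, {stop}, {step})")
        values.update(range(start, stop + 1, step))
    return sorted(values)


@dataclass
class TuningGrid:
    """Candidate sets for the sequential tuning search.

    ``keepx_candidates`` maps block name -> strictly increasing candidate
    budgets (a plain list for single-block tuning).  ``ncomp_candidates``
    defaults to 1..6.
    """

    keepx_candidates: dict[str, list[int]] | list[int]
    ncomp_candidates: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5, 6])
    mode: str = "integrative"

    def __post_init__(self) -> None:
        cand = (
            self.keepx_candidates.values()
            if isinstance(self.keepx_candidates, dict)
            else [self.keepx_candidates]
        )
        for c in cand:
            if not c or any(b <= a for a, b in zip(c, c[1:])) or min(c) < 1:
                raise ValueError("keepX candidates must be strictly increasing positive")
        if not self.ncomp_candidates:
            raise ValueError("ncomp_candidates must be nonempty")


@dataclass
class ModelSpec:
    """What to fit inside each CV fold."""

    kind: str  # "single" | "multiblock"
    ncomp: int
    keep_x: dict[str, list[int]] | list[int] | int | None = None
    design: DesignMatrix | None = None
    block: str | None = None  # required for kind="single"

    def fit(self, data: MultiOmicsDataset):
        if self.kind == "single":
            if self.block is None:
                raise ValueError("single-block spec needs a block name")
            blk = data.block(self.block)
            kx = self.keep_x
            if isinstance(kx, dict):
                kx = kx[self.block]
            return SparsePLSDA.from_block(
                blk, data.y, ncomp=self.ncomp, keep_x=kx,
                positive_label=data.positive_label,
            ).fit()
        if self.kind == "multiblock":
            return MultiblockSPLSDA(
                data, self.design, ncomp=self.ncomp, keep_x=self.keep_x
            ).fit()
        raise ValueError(f"unknown model kind {self.kind!r}")

    def predict(self, results, data: MultiOmicsDataset):
        if self.kind == "single":
            blk = data.block(self.block)
            return results.predict(pd.DataFrame(blk.values.T))
        return results.predict(data)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def balanced_error_rate(y_true, y_pred) -> float:
    """Mean of per-class misclassification rates."""
    y_true = np.asarray(pd.Series(y_true).astype(str))
    y_pred = np.asarray(pd.Series(y_pred).astype(str))
    classes = np.unique(y_true)
    if len(classes) < 2:
        raise ValueError("both classes must be present in y_true")
    errs = [np.mean(y_pred[y_true == c] != c) for c in classes]
    return float(np.mean(errs))


def auc_score(y_true, scores, positive_label: str | None = None) -> float:
    """Exact rank-statistic AUC: P(score_pos > score_neg) + 0.5 P(tie).

    Computed from the rank sum of the positive class, which counts every
    discordant/concordant pair exactly and gives ties half weight.
    """
    y = pd.Series(y_true)
    scores = np.asarray(scores, dtype=float)
    if y.dtype == bool:
        pos = y.to_numpy()
    else:
        y = y.astype(str)
        labels = sorted(y.unique())
        if len(labels) != 2:
            raise ValueError("y_true must contain exactly two classes")
        positive_label = positive_label or labels[-1]
        pos = (y == positive_label).to_numpy()
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-fold metrics of one repeated stratified CV run."""

    ber: np.ndarray  # (n_repeats * n_folds,)
    accuracy: np.ndarray
    auc: np.ndarray
    n_folds: int
    n_repeats: int
    seed: int

    @property
    def mean_ber(self) -> float:
        return float(self.ber.mean())

    @property
    def sd_ber(self) -> float:
        return float(self.ber.std(ddof=1)) if self.ber.size > 1 else 0.0

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracy.mean())

    @property
    def mean_auc(self) -> float:
        return float(self.auc.mean())

    def summary(self) -> "PerformanceSummary":
        return PerformanceSummary(
            accuracy_mean=self.mean_accuracy,
            accuracy_sd=float(self.accuracy.std(ddof=1)) if self.accuracy.size > 1 else 0.0,
            auc_mean=self.mean_auc,
            auc_sd=float(self.auc.std(ddof=1)) if self.auc.size > 1 else 0.0,
            n_repeats=self.n_repeats,
            n_folds=self.n_folds,
        )


@dataclass
class PerformanceSummary:
    """Mean +- SD of accuracy and AUC over folds x repeats."""

    accuracy_mean: float
    accuracy_sd: float
    auc_mean: float
    auc_sd: float
    n_repeats: int
    n_folds: int

    def __str__(self) -> str:
        return (
            f"accuracy {self.accuracy_mean:.3f} +- {self.accuracy_sd:.3f}, "
            f"AUC {self.auc_mean:.3f} +- {self.auc_sd:.3f} "
            f"({self.n_folds}-fold CV, {self.n_repeats} repeats)"
        )


def stratified_folds(
    y: np.ndarray, n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled stratified fold index pairs; per-class fold sizes differ by <= 1."""
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class ({counts.min()}) has fewer members than n_folds={n_folds}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**32 - 1))
    return list(skf.split(np.zeros(len(y)), y))


def stratified_kfold_cv(
    data: MultiOmicsDataset,
    spec: ModelSpec,
    n_folds: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold CV of a model spec.

    Each repeat uses the derived seed ``seed + repeat``.  Per fold the model
    is fitted on the training portion only (feature scaling included, so no
    statistics leak from held-out samples) and scored on the held-out
    samples with BER, accuracy, and the rank AUC of the positive-class
    score.
    """
    y = np.asarray(data.y.astype(str))
    bers, accs, aucs = [], [], []
    for rep in range(n_repeats):
        for train, test in stratified_folds(y, n_folds, seed + rep):
            fitted = spec.fit(data.subset(train))
            pred = spec.predict(fitted, data.subset(test))
            y_test = y[test]
            labels = pred.labels.to_numpy()
            bers.append(balanced_error_rate(y_test, labels))
            accs.append(float(np.mean(labels == y_test)))
            aucs.append(
                auc_score(y_test, pred.score.to_numpy(), data.positive_label)
            )
    return CVResult(
        np.array(bers), np.array(accs), np.array(aucs), n_folds, n_repeats, seed
    )


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------

@dataclass
class TuneResult:
    ncomp: int
    keep_x: dict[str, list[int]]
    best_ber: float
    surface: pd.DataFrame  # component, candidate setting, mean/sd BER, acc, AUC

    def as_model_spec(self, kind: str, design=None, block: str | None = None) -> ModelSpec:
        kx = self.keep_x if kind == "multiblock" else self.keep_x[block]
        return ModelSpec(kind=kind, ncomp=self.ncomp, keep_x=kx, design=design, block=block)


def tune(
    data: MultiOmicsDataset,
    grid: TuningGrid,
    design: DesignMatrix | None = None,
    block: str | None = None,
    n_folds: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
) -> TuneResult:
    """Sequential (greedy per-component) keepX and ncomp selection by BER.

    For component h the budgets of components < h are frozen at their
    selected values and every candidate combination for component h is
    scored by repeated stratified CV.  Ties are broken toward the smaller
    total keepX, then the lexicographically smaller combination.  The
    component count is then the smallest ncomp achieving the minimal BER.
    """
    single = grid.mode == "single"
    if single:
        if block is None:
            raise ValueError("single-block tuning needs a block name")
        cand_map = {block: list(grid.keepx_candidates)}
        block_names = [block]
    else:
        if isinstance(grid.keepx_candidates, dict):
            cand_map = {b: list(c) for b, c in grid.keepx_candidates.items()}
        else:
            cand_map = {b: list(grid.keepx_candidates) for b in data.block_names}
        block_names = data.block_names
        design = design or make_design(block_names)

    max_ncomp = max(grid.ncomp_candidates)
    chosen: dict[str, list[int]] = {b: [] for b in block_names}
    rows = []
    ber_per_ncomp: dict[int, float] = {}
    for h in range(max_ncomp):
        best = None
        for combo in itertools.product(*(cand_map[b] for b in block_names)):
            kx = {b: chosen[b] + [c] for b, c in zip(block_names, combo)}
            spec = ModelSpec(
                kind="single" if single else "multiblock",
                ncomp=h + 1,
                keep_x=kx[block] if single else kx,
                design=design,
                block=block,
            )
            cv = stratified_kfold_cv(data, spec, n_folds, n_repeats, seed)
            rows.append(
                {
                    "component": h + 1,
                    **{f"keepx_{b}": c for b, c in zip(block_names, combo)},
                    "mean_ber": cv.mean_ber,
                    "sd_ber": cv.sd_ber,
                    "mean_accuracy": cv.mean_accuracy,
                    "mean_auc": cv.mean_auc,
                }
            )
            key = (cv.mean_ber, sum(combo), combo)
            if best is None or key < best[0]:
                best = (key, combo)
        combo = best[1]
        for b, c in zip(block_names, combo):
            chosen[b].append(c)
        if h + 1 in grid.ncomp_candidates:
            ber_per_ncomp[h + 1] = best[0][0]
    # smallest ncomp achieving the minimal BER (ties favour fewer components)
    best_ber = min(ber_per_ncomp.values())
    ncomp = min(h for h, b in ber_per_ncomp.items() if b == best_ber)
    keep_x = {b: chosen[b][:ncomp] for b in block_names}
    return TuneResult(ncomp, keep_x, best_ber, pd.DataFrame(rows))
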