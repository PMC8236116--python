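"""Stability-based feature selection and signature assembly.

A single fitted model on 42 samples is fragile, so the final signature is
built from many stratified resamples: each "copy" draws, per phenotype class,
80% of that class's samples with replacement (keeping the phenotype
distribution of the cohort), the model is refitted on every copy with the
tuned parameters, and each feature accumulates the absolute value of its
loading weight across copies.  Features that matter to the classification
keep being selected and accumulate importance; unstable ones wash out.

The final signature takes the top-keepX features per block and component by
aggregate importance, maps every gene/protein/peptide identifier to its gene
symbol, and deduplicates symbols keeping the maximum importance (a symbol's
component assignment follows its maximum-importance occurrence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import MultiOmicsDataset
from .model_selection import ModelSpec

__all__ = [
    "ResamplePlan",
    "stratified_resample",
    "stability_select",
    "FeatureImportanceTable",
    "Signature",
    "finalize_signature",
]

logger = logging.getLogger(__name__)


@dataclass
class ResamplePlan:
    """How to draw the incomplete copies.

    ``n_copies`` defaults to a desk-scale 200 (the study used 10,000);
    ``coverage_frac`` is the per-class fraction of samples drawn (with
    replacement), 0.8 by default.
    """

    n_copies: int = 200
    coverage_frac: float = 0.8
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.coverage_frac <= 1.0:
            raise ValueError("coverage_frac must be in (0, 1]")
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_resample(y, coverage_frac: float, seed: int) -> np.ndarray:
    """Draw round(coverage_frac * n_c) indices per class c, with replacement.

    Rounding is half-up (e.g. 16 and 26 samples at 0.8 give 13 + 21 draws),
    so the phenotype distribution of every copy matches the cohort's.
    Deterministic per seed.
    """
    y = np.asarray(pd.Series(y).astype(str))
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    out = []
    for c in classes:
        idx = np.where(y == c)[0]
        n_draw = _round_half_up(coverage_frac * len(idx))
        out.append(rng.choice(idx, size=n_draw, replace=True))
    return np.concatenate(out)


@dataclass
class FeatureImportanceTable:
    """Aggregated |loading weight| per (block, component, feature).

    ``table`` columns: block, component, feature_id, importance (sum of
    absolute loading weights over copies), frequency (fraction of copies in
    which the feature had a nonzero loading); sorted descending by
    importance within (block, component).
    """

    table: pd.DataFrame
    n_copies: int
    n_failed: int = 0

    def top_features(self, block: str, component: int, n: int) -> pd.DataFrame:
        sub = self.table[
            (self.table["block"] == block) & (self.table["component"] == component)
        ]
        return sub.head(n)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def stability_select(
    data: MultiOmicsDataset, spec: ModelSpec, plan: ResamplePlan
) -> FeatureImportanceTable:
    """Refit ``spec`` on every resampled copy and aggregate loading weights.

    Copies that fail to fit (e.g. a degenerate resample) are skipped and
    counted; more than 10% failures aborts.  Copy ``i`` uses the derived
    seed ``base_seed + i``, so the table is reproducible.
    """
    y = data.y
    importance: dict[tuple[str, int, str], float] = {}
    frequency: dict[tuple[str, int, str], int] = {}
    n_failed = 0
    for i in range(plan.n_copies):
        idx = stratified_resample(y, plan.coverage_frac, plan.base_seed + i)
        try:
            fitted = spec.fit(data.subset(idx))
        except Exception as exc:  # degenerate copy: count and move on
            n_failed += 1
            logger.warning("copy %d failed to fit: %s", i, exc)
            continue
        if spec.kind == "single":
            block_loadings = {spec.block: fitted.loadings}
        else:
            block_loadings = {bn: fitted.loadings(bn) for bn in fitted.block_names}
        for bn, load in block_loadings.items():
            arr = load.to_numpy()
            feats = load.index
            for h in range(arr.shape[1]):
                nz = np.nonzero(arr[:, h])[0]
                for j in nz:
                    key = (bn, h + 1, str(feats[j]))
                    importance[key] = importance.get(key, 0.0) + abs(float(arr[j, h]))
                    frequency[key] = frequency.get(key, 0) + 1
    if n_failed > 0.1 * plan.n_copies:
        raise RuntimeError(
            f"{n_failed}/{plan.n_copies} resample copies failed to fit"
        )
    n_ok = plan.n_copies - n_failed
    rows = [
        {
            "block": k[0],
            "component": k[1],
            "feature_id": k[2],
            "importance": v,
            "frequency": frequency[k] / max(n_ok, 1),
        }
        for k, v in importance.items()
    ]
    table = pd.DataFrame(
        rows, columns=["block", "component", "feature_id", "importance", "frequency"]
    )
    table = table.sort_values(
        ["block", "component", "importance", "feature_id"],
        ascending=[True, True, False, True],
    ).reset_index(drop=True)
    return FeatureImportanceTable(table, plan.n_copies, n_failed)


@dataclass
class Signature:
    """Ordered gene-symbol signature with provenance.

    ``table`` columns: symbol, importance, blocks (comma-joined), component
    (the symbol's maximum-importance component); rows sorted by descending
    importance.
    """

    name: str
    table: pd.DataFrame

    @property
    def symbols(self) -> list[str]:
        return self.table["symbol"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def restrict_components(self, components: set[int], name: str | None = None) -> "Signature":
        sub = self.table[self.table["component"].isin(components)].reset_index(drop=True)
        return Signature(name or self.name, sub)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def write_symbol_list(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.symbols) + "\n")

    @classmethod
    def from_symbol_list(cls, path: str | Path, name: str = "signature") -> "Signature":
        symbols = [s.strip() for s in Path(path).read_text().splitlines() if s.strip()]
        table = pd.DataFrame(
            {
                "symbol": symbols,
                "importance": np.nan,
                "blocks": "",
                "component": 0,
            }
        )
        return cls(name, table)


def finalize_signature(
    importance: FeatureImportanceTable,
    keep_x: dict[str, list[int]],
    symbol_map: dict[str, str],
    name: str = "MULTI",
    components: set[int] | None = None,
) -> Signature:
    """Assemble the deduplicated gene-symbol signature.

    Takes the top ``keep_x[block][component-1]`` features per (block,
    component) by aggregate importance, maps each feature id to its gene
    symbol via ``symbol_map`` (an unmapped id is an error), and keeps one
    row per symbol — the maximum-importance occurrence, which also fixes
    the symbol's component and block provenance.
    """
    picked = []
    for block, budgets in keep_x.items():
        for h, budget in enumerate(budgets, start=1):
            if components is not None and h not in components:
                continue
            top = importance.top_features(block, h, budget)
            picked.append(top)
    if not picked:
        raise ValueError("no (block, component) cells selected")
    sel = pd.concat(picked, ignore_index=True)
    unmapped = [f for f in sel["feature_id"] if f not in symbol_map]
    if unmapped:
        raise KeyError(f"{len(unmapped)} selected feature ids lack a symbol, e.g. {unmapped[:3]}")
    sel = sel.assign(symbol=[symbol_map[f] for f in sel["feature_id"]])
    # best row per symbol; provenance lists every contributing block
    blocks_per_symbol = sel.groupby("symbol")["block"].agg(
        lambda s: ",".join(sorted(set(s)))
    )
    best = (
        sel.sort_values(["importance", "feature_id"], ascending=[False, True])
        .drop_duplicates("symbol", keep="first")
        .reset_index(drop=True)
    )
    table = pd.DataFrame(
        {
            "symbol": best["symbol"],
            "importance": best["importance"],
            "blocks": best["symbol"].map(blocks_per_symbol),
            "component": best["component"],
        }
    ).sort_values(["importance", "symbol"], ascending=[False, True]).reset_index(drop=True)
    return Signature(name, table)
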