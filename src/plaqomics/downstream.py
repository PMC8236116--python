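"""Downstream statistics: differential expression, correlations,
overrepresentation, and preranked gene-set enrichment.

Differential expression uses an ordinary linear-model t-test per feature
(paired when the patient pairing covers every sample, Welch otherwise) with
Benjamini-Hochberg adjustment; the sign convention is fixed so a positive
log2 fold change means higher expression in the hemorrhaged (IPH) group.
Overrepresentation is the upper-tail hypergeometric test of a query gene list
against a curated set within an explicit background universe.  Preranked GSEA
walks the running sum down a log2FC-ranked list and normalizes the enrichment
score against gene-label permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .blocks import OmicsBlock

__all__ = [
    "differential_expression",
    "pearson_with_p",
    "CorrelationResult",
    "component_trait_correlations",
    "hypergeom_overrep",
    "bh_adjust",
    "GeneSetCollection",
    "gsoa",
    "preranked_gsea",
    "GseaResult",
    "srf_cofactor_test",
    "compare_groups",
]


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def differential_expression(
    block: OmicsBlock,
    y,
    positive_label: str,
    paired_by=None,
) -> pd.DataFrame:
    """Per-feature log2 fold change and t-test between the two groups.

    log2FC = mean(positive group) - mean(other group) on log2-scale data,
    so positive values mean higher expression in the positive (IPH) group.
    A paired t-test is used when ``paired_by`` assigns every sample to a
    patient with exactly one sample in each group; otherwise Welch's
    unequal-variance t-test.  P-values are BH-adjusted across features; a
    feature with zero within-test variance gets p = 1 and ``degenerate`` set.

    Returns a DataFrame indexed by feature id with columns log2fc, t, p,
    p_adj, degenerate.
    """
    if block.has_missing:
        raise ValueError("impute before differential expression")
    y = pd.Series(y).astype(str)
    X = block.values  # features x samples
    groups = sorted(y.unique())
    if len(groups) != 2 or positive_label not in groups:
        raise ValueError("need two groups including the positive label")
    neg_label = [g for g in groups if g != positive_label][0]
    pos = X.loc[:, (y == positive_label).to_numpy()]
    neg = X.loc[:, (y == neg_label).to_numpy()]
    if pos.shape[1] < 2 or neg.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    log2fc = pos.mean(axis=1) - neg.mean(axis=1)

    paired = False
    if paired_by is not None:
        pid = pd.Series(paired_by).astype(str)
        tab = pd.crosstab(pid, y)
        paired = bool((tab == 1).all().all())
    if paired:
        pid = pd.Series(paired_by).astype(str)
        order = pid[(y == positive_label).to_numpy()].to_numpy()
        pos_m = pos.to_numpy()
        neg_df = neg.copy()
        neg_df.columns = pid[(y == neg_label).to_numpy()].to_numpy()
        neg_m = neg_df[order].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_rel(pos_m, neg_m, axis=1)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(
                pos.to_numpy(), neg.to_numpy(), axis=1, equal_var=False
            )
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(degenerate, 1.0, p)
    out = pd.DataFrame(
        {
            "log2fc": log2fc.to_numpy(),
            "t": t,
            "p": p,
            "p_adj": bh_adjust(p),
            "degenerate": degenerate,
        },
        index=X.index,
    )
    return out


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    label: tuple[str, str]
    r: float
    p: float
    n: int


def pearson_with_p(x, y, label: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Product-moment correlation with the two-sided t-transform p-value
    (t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(label, float(r), float(p), int(x.size))


def component_trait_correlations(
    scores: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """All (component, trait) Pearson correlations with p-values."""
    rows = []
    for comp in scores.columns:
        for trait in traits.columns:
            res = pearson_with_p(
                scores[comp].to_numpy(), traits[trait].to_numpy(), (comp, trait)
            )
            rows.append(
                {"component": comp, "trait": trait, "r": res.r, "p": res.p, "n": res.n}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# overrepresentation
# ---------------------------------------------------------------------------

def hypergeom_overrep(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    ``k`` observed overlap, ``K`` set size, ``n`` query size, ``N`` universe
    size: the chance of drawing at least ``k`` set members when drawing
    ``n`` items without replacement from a universe containing ``K``.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GeneSetCollection:
    """Named gene-symbol sets with an explicit background universe.

    Sets are restricted to the universe on construction; empty sets (after
    restriction) are dropped.
    """

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("empty background universe")
        restricted = {
            name: members & self.universe for name, members in self.sets.items()
        }
        self.sets = {name: m for name, m in restricted.items() if m}
        if not self.sets:
            raise ValueError("no gene set overlaps the universe")


def gsoa(query_symbols, collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric overrepresentation of a query list against every set.

    The query is restricted to the universe first.  Returns one row per set
    (set, k, K, n, N, p, p_adj) sorted by adjusted then raw p.
    """
    query = set(query_symbols) & collection.universe
    if not query:
        raise ValueError("query does not intersect the background universe")
    N = len(collection.universe)
    n = len(query)
    rows = []
    for name, members in collection.sets.items():
        k = len(query & members)
        rows.append(
            {
                "set": name,
                "k": k,
                "K": len(members),
                "n": n,
                "N": N,
                "p": hypergeom_overrep(k, len(members), n, N),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["p_adj", "p", "set"]).reset_index(drop=True)


def srf_cofactor_test(
    signature_targets, cofactor_sets: dict[str, set[str]], universe
) -> pd.DataFrame:
    """Which cofactor-regulated target set is the signature enriched in?

    One upper-tail hypergeometric test per cofactor set (e.g. MKL1/2- vs
    ELF4-dependent SRF targets) against the stated universe, reported side
    by side.  The choice of universe materially moves these p-values; it is
    therefore an explicit argument.
    """
    if not cofactor_sets:
        raise ValueError("no cofactor reference sets supplied")
    universe = set(universe)
    query = set(signature_targets) & universe
    if not query:
        raise ValueError("signature does not intersect the universe")
    rows = []
    for name, members in cofactor_sets.items():
        members = set(members) & universe
        k = len(query & members)
        rows.append(
            {
                "cofactor_set": name,
                "k": k,
                "K": len(members),
                "n": len(query),
                "N": len(universe),
                "p": hypergeom_overrep(k, len(members), len(query), len(universe)),
            }
        )
    return pd.DataFrame(rows).sort_values("p").reset_index(drop=True)


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p: float
    n_perm: int
    n_hits: int


def _running_es(
    in_set: np.ndarray, weights: np.ndarray, weight_exponent: float
) -> float:
    """Signed extremum of the running enrichment sum for one ordering."""
    N = in_set.size
    s = int(in_set.sum())
    w = np.abs(weights) ** weight_exponent
    hit_total = w[in_set].sum()
    if hit_total == 0:  # all in-set stats zero: fall back to equal steps
        hit = in_set / s
    else:
        hit = np.where(in_set, w / hit_total, 0.0)
    miss = np.where(~in_set, 1.0 / (N - s), 0.0)
    running = np.cumsum(hit - miss)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def preranked_gsea(
    ranked: list[tuple[str, float]] | pd.Series,
    gene_set,
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    seed: int = 0,
) -> GseaResult:
    """Preranked gene-set enrichment along a log2FC-ranked list.

    The list is sorted by decreasing statistic; hits advance the running sum
    by |stat|^weight_exponent (normalized over the in-set total), misses
    retreat by 1/(N - s).  ES is the signed extremum of the running sum.
    NES divides ES by the mean |ES| of same-sign gene-label permutations,
    and the permutation p-value is the fraction of same-sign permuted ES at
    least as extreme (with the +1 continuity correction).
    """
    if isinstance(ranked, pd.Series):
        ranked = list(ranked.items())
    symbols = [s for s, _ in ranked]
    if len(set(symbols)) != len(symbols):
        raise ValueError("ranked list contains duplicate symbols")
    stats_ = np.array([v for _, v in ranked], dtype=float)
    order = np.argsort(-stats_, kind="stable")
    symbols = [symbols[i] for i in order]
    stats_ = stats_[order]
    gene_set = set(gene_set)
    in_set = np.array([s in gene_set for s in symbols])
    s = int(in_set.sum())
    if s == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if s == len(symbols):
        raise ValueError("gene set covers the entire ranked list")
    es = _running_es(in_set, stats_, weight_exponent)

    rng = np.random.default_rng(seed)
    perm_es = np.empty(n_perm)
    for i in range(n_perm):
        perm = np.zeros(len(symbols), dtype=bool)
        perm[rng.choice(len(symbols), size=s, replace=False)] = True
        perm_es[i] = _running_es(perm, stats_, weight_exponent)
    same_sign = perm_es * np.sign(es) > 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        nes = np.inf if es > 0 else -np.inf
        p = 1.0 / (n_perm + 1)
    else:
        nes = es / np.abs(perm_es[same_sign]).mean()
        p = (1 + int((np.abs(perm_es[same_sign]) >= abs(es)).sum())) / (n_same + 1)
    return GseaResult(
        set_name="gene_set", es=es, nes=float(nes), p=float(p), n_perm=n_perm, n_hits=s
    )


# ---------------------------------------------------------------------------
# two-group trait comparisons
# ---------------------------------------------------------------------------

def compare_groups(
    x, y, paired: bool = False, normality_alpha: float = 0.05
) -> dict:
    """Shapiro-Wilk-guided two-group comparison.

    Both samples normal (Shapiro-Wilk p > alpha in each): Student's t-test
    (paired when requested).  Otherwise the two-sided Wilcoxon test
    (signed-rank when paired, rank-sum otherwise); the exact null
    distribution is used up to n = 25 per group, the normal approximation
    beyond.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    normal = (
        stats.shapiro(x).pvalue > normality_alpha
        and stats.shapiro(y).pvalue > normality_alpha
    )
    if normal:
        if paired:
            stat, p = stats.ttest_rel(x, y)
        else:
            stat, p = stats.ttest_ind(x, y)
        test = "t_paired" if paired else "t"
    else:
        method = "exact" if max(len(x), len(y)) <= 25 else "asymptotic"
        if paired:
            res = stats.wilcoxon(x, y, mode="approx" if method == "asymptotic" else "exact")
            stat, p = res.statistic, res.pvalue
            test = "wilcoxon_signed_rank"
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            stat, p = res.statistic, res.pvalue
            test = "wilcoxon_rank_sum"
    return {"test": test, "statistic": float(stat), "p": float(p), "normal": bool(normal)}
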