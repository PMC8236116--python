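"""Signature validation on an independent expression cohort.

A signature (gene-symbol list) is evaluated by subsetting the cohort's
expression matrix to the signature genes and scoring three standard
classifiers — logistic regression (lbfgs), an RBF-kernel SVM (gamma =
1/n_features) and a decision tree with default settings — under stratified
five-fold cross-validation with random repeats.  Features are standardized on
the training fold only; performance is reported as mean +- SD of accuracy and
AUC over folds x repeats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .blocks import OmicsBlock
from .model_selection import PerformanceSummary, auc_score, stratified_folds
from .signature import Signature

__all__ = [
    "CLASSIFIERS",
    "ValidationSpec",
    "subset_to_signature",
    "evaluate_signature",
    "compare_signatures",
]

logger = logging.getLogger(__name__)

CLASSIFIERS = ("logistic", "svm_rbf", "decision_tree")


def _make_classifier(name: str, seed: int):
    if name == "logistic":
        return LogisticRegression(solver="lbfgs", max_iter=1000, random_state=seed)
    if name == "svm_rbf":
        # gamma="auto" semantics: 1 / n_features
        return SVC(kernel="rbf", gamma="auto", random_state=seed)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


@dataclass
class ValidationSpec:
    """One validation run: cohort, signature, classifier, CV settings."""

    cohort: OmicsBlock
    y: pd.Series
    signature: Signature
    classifier: str = "logistic"
    symbol_map: dict[str, str] | None = None  # cohort feature id -> symbol
    n_folds: int = 5
    n_repeats: int = 50
    seed: int = 0
    positive_label: str | None = None

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")
        self.y = pd.Series(self.y).astype(str)
        levels = sorted(self.y.unique())
        if len(levels) != 2:
            raise ValueError("cohort phenotype must have exactly two levels")
        if self.positive_label is None:
            self.positive_label = levels[-1]


def subset_to_signature(
    cohort: OmicsBlock,
    signature: Signature,
    symbol_map: dict[str, str] | None = None,
) -> tuple[OmicsBlock, float]:
    """Keep cohort features whose gene symbol is in the signature.

    ``symbol_map`` translates cohort feature ids to symbols (identity when
    omitted, i.e. features already named by symbol).  Duplicate symbols keep
    all matching features.  Returns the subset block and the coverage
    fraction = covered signature symbols / signature size.
    """
    if len(signature) == 0:
        raise ValueError("empty signature")
    wanted = set(signature.symbols)
    ids = cohort.feature_ids
    symbols = [symbol_map.get(str(f), str(f)) if symbol_map else str(f) for f in ids]
    keep = [f for f, s in zip(ids, symbols) if s in wanted]
    if not keep:
        raise ValueError("signature has zero overlap with cohort features")
    covered = {s for s in symbols if s in wanted}
    return cohort.select_features(keep), len(covered) / len(signature)


def _decision_scores(clf, X: np.ndarray, classes: np.ndarray, positive) -> np.ndarray:
    pos_idx = int(np.where(classes == positive)[0][0])
    if hasattr(clf, "decision_function"):
        d = clf.decision_function(X)
        return d if classes[1] == positive else -d
    proba = clf.predict_proba(X)
    return proba[:, pos_idx]


def evaluate_signature(spec: ValidationSpec) -> PerformanceSummary:
    """Stratified repeated CV of one signature/classifier combination.

    Per fold: standardize on the training samples, fit, score the held-out
    samples (accuracy and rank AUC of the classifier's continuous decision
    score).  Degenerate folds that fail to fit are skipped with a warning.
    """
    block, coverage = subset_to_signature(spec.cohort, spec.signature, spec.symbol_map)
    if coverage < 1.0:
        logger.info(
            "signature %s: cohort covers %.0f%% of symbols",
            spec.signature.name,
            100 * coverage,
        )
    X_all = block.to_samples_by_features()
    y = spec.y.to_numpy()
    accs, aucs = [], []
    for rep in range(spec.n_repeats):
        for train, test in stratified_folds(y, spec.n_folds, spec.seed + rep):
            scaler = StandardScaler().fit(X_all[train])
            Xtr, Xte = scaler.transform(X_all[train]), scaler.transform(X_all[test])
            clf = _make_classifier(spec.classifier, spec.seed)
            try:
                clf.fit(Xtr, y[train])
            except Exception as exc:
                logger.warning("fold skipped: %s", exc)
                continue
            pred = clf.predict(Xte)
            accs.append(float(np.mean(pred == y[test])))
            score = _decision_scores(clf, Xte, clf.classes_, spec.positive_label)
            aucs.append(auc_score(y[test], score, spec.positive_label))
    accs, aucs = np.array(accs), np.array(aucs)
    return PerformanceSummary(
        accuracy_mean=float(accs.mean()),
        accuracy_sd=float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
        auc_mean=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)) if aucs.size > 1 else 0.0,
        n_repeats=spec.n_repeats,
        n_folds=spec.n_folds,
    )


def _per_run_aucs(spec: ValidationSpec) -> np.ndarray:
    """AUC per (repeat, fold) run — the unit for significance testing."""
    block, _ = subset_to_signature(spec.cohort, spec.signature, spec.symbol_map)
    X_all = block.to_samples_by_features()
    y = spec.y.to_numpy()
    aucs = []
    for rep in range(spec.n_repeats):
        for train, test in stratified_folds(y, spec.n_folds, spec.seed + rep):
            scaler = StandardScaler().fit(X_all[train])
            clf = _make_classifier(spec.classifier, spec.seed)
            clf.fit(scaler.transform(X_all[train]), y[train])
            score = _decision_scores(
                clf, scaler.transform(X_all[test]), clf.classes_, spec.positive_label
            )
            aucs.append(auc_score(y[test], score, spec.positive_label))
    return np.array(aucs)


def compare_signatures(
    cohort: OmicsBlock,
    y,
    signatures: list[Signature],
    classifiers: tuple[str, ...] = ("logistic",),
    symbol_map: dict[str, str] | None = None,
    include_full_baseline: bool = True,
    n_folds: int = 5,
    n_repeats: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Head-to-head comparison of signatures (plus a FULL baseline).

    One row per (signature, classifier) with mean +- SD accuracy/AUC and,
    against the first signature under the same classifier and seeds, the
    two-sided t-test p-value on per-run AUCs.
    """
    if len(signatures) < 1:
        raise ValueError("need at least one signature")
    entries = [(s.name, s) for s in signatures]
    if include_full_baseline:
        full = Signature(
            "FULL",
            pd.DataFrame(
                {
                    "symbol": [
                        symbol_map.get(str(f), str(f)) if symbol_map else str(f)
                        for f in cohort.feature_ids
                    ],
                    "importance": np.nan,
                    "blocks": "",
                    "component": 0,
                }
            ).drop_duplicates("symbol"),
        )
        entries.append(("FULL", full))
    rows = []
    for clf_name in classifiers:
        baseline_aucs = None
        for name, sig in entries:
            spec = ValidationSpec(
                cohort=cohort,
                y=pd.Series(y),
                signature=sig,
                classifier=clf_name,
                symbol_map=symbol_map,
                n_folds=n_folds,
                n_repeats=n_repeats,
                seed=seed,
            )
            aucs = _per_run_aucs(spec)
            if baseline_aucs is None:
                baseline_aucs = aucs
                p_vs_first = np.nan
            elif np.allclose(aucs, baseline_aucs):
                p_vs_first = 1.0
            else:
                p_vs_first = float(stats.ttest_ind(aucs, baseline_aucs).pvalue)
            summ = evaluate_signature(spec)
            rows.append(
                {
                    "signature": name,
                    "classifier": clf_name,
                    "n_symbols": len(sig),
                    "accuracy_mean": summ.accuracy_mean,
                    "accuracy_sd": summ.accuracy_sd,
                    "auc_mean": summ.auc_mean,
                    "auc_sd": summ.auc_sd,
                    "p_vs_first": p_vs_first,
                }
            )
    return pd.DataFrame(rows)
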