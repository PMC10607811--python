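"""Marker discovery: per-feature AUC ranking and top-k classifier panels.

Every feature is scored individually with a battery of classifiers under
10-fold cross-validation; the out-of-fold decision scores are pooled into a
single ROC AUC per (feature, classifier) and features are ranked by their
best AUC.  Panels of the top k features (k in {1, 2, 5, 10, 20, 40, 80})
are then trained with each classifier and evaluated by the same pooled
10-fold protocol; a panel is retained as a candidate marker set when its
cross-validated AUC reaches 0.7.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .core import FeatureTable

__all__ = [
    "ClassPair",
    "PAIRS",
    "RankedFeature",
    "ModelResult",
    "DEFAULT_K_GRID",
    "RANKING_CLASSIFIERS",
    "EXTENDED_CLASSIFIERS",
    "auc_mann_whitney",
    "passes_gate",
    "stratified_kfold",
    "per_feature_auc",
    "build_topk_models",
    "top_models_report",
]

#: Panel sizes evaluated for every classifier.
DEFAULT_K_GRID = (1, 2, 5, 10, 20, 40, 80)

#: Minimum cross-validated AUC for a panel to count as a candidate marker set.
DEFAULT_GATE = 0.7


def passes_gate(cv_auc: float, gate: float = DEFAULT_GATE) -> bool:
    """A panel qualifies when its cross-validated AUC reaches the gate."""
    return cv_auc >= gate


@dataclass(frozen=True)
class ClassPair:
    """A two-group comparison; the more severe group is the positive class."""

    negative: str
    positive: str

    def __post_init__(self) -> None:
        if self.negative == self.positive:
            raise ValueError("class pair must contain two distinct groups")

    @property
    def name(self) -> str:
        return f"{self.negative}_vs_{self.positive}"


PAIRS: dict[str, ClassPair] = {
    "low_vs_high": ClassPair("low", "high"),
    "moderate_vs_high": ClassPair("moderate", "high"),
    "low_vs_moderate": ClassPair("low", "moderate"),
}


@dataclass
class RankedFeature:
    feature_id: str
    auc_by_classifier: dict[str, float]
    best_auc: float
    rank: int


@dataclass
class ModelResult:
    classifier: str
    pair: ClassPair
    k: int
    feature_ids: list[str]
    cv_auc: float
    roc: list[tuple[float, float]]
    passed_gate: bool


def auc_mann_whitney(scores, labels) -> float:
    """ROC AUC via the Mann-Whitney rank statistic.

    (concordant pairs + half the tied pairs) / (n_pos * n_neg), computed
    with average ranks; identical to trapezoidal integration of the
    empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def stratified_kfold(labels, n_folds: int = 10, seed: int = 0) -> np.ndarray:
    """Fold id per sample, class proportions balanced across folds."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than {n_folds} folds; "
            "use fewer folds"
        )
    folds = np.empty(labels.size, dtype=int)
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for i, (_, test) in enumerate(splitter.split(np.zeros(labels.size), labels)):
        folds[test] = i
    return folds


# -- classifier registry ----------------------------------------------------

def make_classifier(name: str, seed: int = 0, rf_trees: int = 200, boost_rounds: int = 100):
    """Fresh estimator by registry name.

    Hyperparameters are fixed: linear-kernel SVM scored by its margin,
    effectively unregularized plain logistic regression next to explicit
    L1/L2 variants, ``rf_trees``-tree random forest, ``boost_rounds``
    boosting rounds, unpruned CART for the decision tree.
    """
    registry = {
        "LDA": lambda: LinearDiscriminantAnalysis(),
        "NaiveBayes": lambda: GaussianNB(),
        # iteration cap guards against libsvm stalling on unscaled inputs
        "SVM": lambda: SVC(kernel="linear", random_state=seed, max_iter=200_000),
        "LogReg": lambda: LogisticRegression(C=1e6, max_iter=2000),
        "LogRegL1": lambda: LogisticRegression(
            penalty="l1", solver="liblinear", max_iter=2000, random_state=seed
        ),
        "LogRegL2": lambda: LogisticRegression(C=1.0, max_iter=2000),
        "RandomForest": lambda: RandomForestClassifier(
            n_estimators=rf_trees, random_state=seed, n_jobs=1
        ),
        "AdaBoost": lambda: AdaBoostClassifier(n_estimators=boost_rounds, random_state=seed),
        "LogitBoost": lambda: GradientBoostingClassifier(
            n_estimators=boost_rounds, random_state=seed
        ),
        "DecisionTree": lambda: DecisionTreeClassifier(random_state=seed),
    }
    try:
        return registry[name]()
    except KeyError:
        raise ValueError(f"unknown classifier {name!r}; registry: {sorted(registry)}") from None


#: The five-classifier battery used for per-feature ranking.
RANKING_CLASSIFIERS = ("LDA", "NaiveBayes", "SVM", "LogReg", "RandomForest")

#: Additional algorithms offered for panel building.
EXTENDED_CLASSIFIERS = RANKING_CLASSIFIERS + (
    "LogRegL1",
    "LogRegL2",
    "AdaBoost",
    "LogitBoost",
    "DecisionTree",
)


def _decision_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous score for the positive class (margin or probability)."""
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


def _pair_data(table: FeatureTable, pair: ClassPair) -> tuple[np.ndarray, np.ndarray, list[str]]:
    man = table.manifest
    mask = (man["sample_type"] == "study") & man["group"].isin([pair.negative, pair.positive])
    sample_ids = list(man.index[mask])
    if not sample_ids:
        raise ValueError(f"no study samples for pair {pair.name}")
    y = (man.loc[sample_ids, "group"] == pair.positive).to_numpy()
    X = table.intensities[sample_ids].to_numpy(dtype=float).T  # samples x features
    return X, y, sample_ids


def _oof_scores(X: np.ndarray, y: np.ndarray, folds: np.ndarray, factory) -> np.ndarray:
    """Pooled out-of-fold decision scores for one design matrix."""
    scores = np.zeros(y.size)
    for fold in np.unique(folds):
        test = folds == fold
        train = ~test
        Xtr = X[train]
        if np.unique(y[train]).size < 2 or np.all(Xtr == Xtr[0]):
            continue  # degenerate training fold: scores stay 0 (uninformative)
        model = factory()
        model.fit(Xtr, y[train])
        scores[test] = _decision_scores(model, X[test])
    return scores


def per_feature_auc(
    table: FeatureTable,
    pair: ClassPair,
    classifiers=RANKING_CLASSIFIERS,
    folds: np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
    rf_trees: int = 200,
) -> list[RankedFeature]:
    """Cross-validated single-feature AUC under each classifier, ranked.

    Each feature is fitted alone: out-of-fold scores from the shared fold
    assignment are pooled into one AUC per classifier; the feature's best
    AUC over the battery determines its rank (descending; ties keep table
    order).  Features constant across the pair's samples are recorded at
    AUC 0.5 for every classifier.
    """
    X, y, _ = _pair_data(table, pair)
    if folds is None:
        folds = stratified_kfold(y, n_folds=n_folds, seed=seed)
    feature_ids = list(table.features.index)

    auc_matrix = np.full((len(feature_ids), len(classifiers)), 0.5)
    for j, name in enumerate(classifiers):
        factory = lambda: make_classifier(name, seed=seed, rf_trees=rf_trees)  # noqa: E731
        for i in range(len(feature_ids)):
            x = X[:, i : i + 1]
            if np.all(x == x[0]):
                continue  # degenerate feature -> 0.5
            scores = _oof_scores(x, y, folds, factory)
            auc_matrix[i, j] = auc_mann_whitney(scores, y)

    best = auc_matrix.max(axis=1)
    order = np.argsort(-best, kind="mergesort")
    ranked = []
    for rank, i in enumerate(order, start=1):
        ranked.append(
            RankedFeature(
                feature_id=feature_ids[i],
                auc_by_classifier={c: float(auc_matrix[i, j]) for j, c in enumerate(classifiers)},
                best_auc=float(best[i]),
                rank=rank,
            )
        )
    return ranked


def _rank_on_training(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Feature order by orientation-free rank-sum AUC on training data only.

    Used by the nested (leakage-free) panel protocol; vectorized substitute
    for re-running the classifier battery inside every fold.
    """
    ranks = rankdata(X, axis=0)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    auc = (ranks[y].sum(axis=0) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return np.argsort(-np.maximum(auc, 1.0 - auc), kind="mergesort")


def build_topk_models(
    table: FeatureTable,
    pair: ClassPair,
    ranked: list[RankedFeature],
    k_grid=DEFAULT_K_GRID,
    classifiers=RANKING_CLASSIFIERS,
    folds: np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
    gate: float = DEFAULT_GATE,
    rf_trees: int = 200,
    nested: bool = False,
) -> list[ModelResult]:
    """Train top-k feature panels and evaluate them by pooled 10-fold CV.

    The default protocol ranks once on the full pair dataset (matching the
    marker-discovery procedure being reproduced); ``nested=True`` instead
    re-ranks features inside each training fold, removing selection leakage
    at the cost of diverging from that procedure.  k values exceeding the
    number of ranked features are skipped with a warning.
    """
    X, y, _ = _pair_data(table, pair)
    if folds is None:
        folds = stratified_kfold(y, n_folds=n_folds, seed=seed)
    ordered = [r.feature_id for r in sorted(ranked, key=lambda r: r.rank)]
    col_of = {fid: i for i, fid in enumerate(table.features.index)}
    ordered_cols = np.array([col_of[fid] for fid in ordered])

    results = []
    for name in classifiers:
        factory = lambda: make_classifier(name, seed=seed, rf_trees=rf_trees)  # noqa: E731
        for k in k_grid:
            if k > len(ordered):
                warnings.warn(
                    f"k={k} exceeds the {len(ordered)} ranked features; skipped",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            if nested:
                scores = np.zeros(y.size)
                for fold in np.unique(folds):
                    test = folds == fold
                    train = ~test
                    top = _rank_on_training(X[train], y[train])[:k]
                    model = factory()
                    model.fit(X[np.ix_(train, top)], y[train])
                    scores[test] = _decision_scores(model, X[np.ix_(test, top)])
                feature_ids = ordered[:k]  # full-data ranking reported for reference
            else:
                cols = ordered_cols[:k]
                scores = _oof_scores(X[:, cols], y, folds, factory)
                feature_ids = ordered[:k]
            cv_auc = auc_mann_whitney(scores, y)
            fpr, tpr, _ = roc_curve(y, scores)
            results.append(
                ModelResult(
                    classifier=name,
                    pair=pair,
                    k=k,
                    feature_ids=list(feature_ids),
                    cv_auc=float(cv_auc),
                    roc=list(zip(fpr.tolist(), tpr.tolist())),
                    passed_gate=passes_gate(cv_auc, gate),
                )
            )
    return results


def top_models_report(results: list[ModelResult], n: int = 10) -> list[ModelResult]:
    """Best ``n`` panels by CV AUC; ties prefer smaller k, then name order."""
    if not results:
        raise ValueError("no model results to report")
    ordered = sorted(results, key=lambda r: (-r.cv_auc, r.k, r.classifier))
    return ordered[:n]


def ranking_to_frame(ranked: list[RankedFeature]) -> pd.DataFrame:
    """Tabular view of a ranking (one row per feature, AUC per classifier)."""
    rows = []
    for r in sorted(ranked, key=lambda r: r.rank):
        row = {"feature_id": r.feature_id, "rank": r.rank, "best_auc": r.best_auc}
        row.update({f"auc_{k}": v for k, v in r.auc_by_classifier.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature_id")
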