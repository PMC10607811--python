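"""QC/blank-based feature filtering and drift normalization.

The conditioning chain applied to each polarity's feature table, in fixed
order:

1. ``blank_filter`` — drop features whose pooled-QC to solvent-blank or
   pooled-QC to fiber-blank mean intensity ratio falls below 5 (background
   contamination).
2. ``serrf_normalize`` — QC-anchored systematic-error removal: per feature,
   a random-forest regressor fitted on the pooled-QC injections predicts the
   drift component from injection order plus the most QC-correlated other
   features; every injection is divided by its predicted drift and re-scaled
   to the feature's QC median.
3. ``glog_transform`` — generalized log transform, variance stabilization.
4. ``pareto_scale`` — centre each feature and divide by the square root of
   its standard deviation.

Each step records itself on the table so the chain cannot be re-entered out
of order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .core import FeatureTable

__all__ = [
    "FilterReport",
    "NormalizationReport",
    "blank_filter",
    "serrf_normalize",
    "glog_transform",
    "pareto_scale",
    "qc_rsd",
]


@dataclass
class FilterReport:
    kept: set[str]
    removed: set[str]
    ratios: pd.DataFrame  # columns qc_over_solvent_blank, qc_over_fiber_blank


@dataclass
class NormalizationReport:
    """QC repeatability before/after correction, plus an honest error estimate.

    ``qc_rsd_before``/``qc_rsd_after`` are per-feature pooled-QC relative
    standard deviations (%).  ``cv_error`` is the median relative
    root-mean-square error of QC-fold cross-validated drift predictions on a
    subsample of features: unlike the in-sample RSD it does not reward
    memorizing QC noise.
    """

    qc_rsd_before: pd.Series
    qc_rsd_after: pd.Series
    cv_error: float


def _require_absent(table: FeatureTable, step: str, forbidden: set[str]) -> None:
    clash = forbidden & set(table.processing)
    if clash:
        raise ValueError(
            f"cannot apply {step!r} after {sorted(clash)}; the conditioning chain "
            "is blank_filter -> serrf -> glog -> pareto and is not re-entrant"
        )


def blank_filter(
    table: FeatureTable, threshold: float = 5.0
) -> tuple[FeatureTable, FilterReport]:
    """Remove features not sufficiently above the blank background.

    For each feature the mean pooled-QC intensity is divided by the mean
    solvent-blank and mean fiber-blank intensity; the feature is removed if
    either ratio is below ``threshold``.  A blank type with no injections,
    or a zero blank mean, yields an infinite ratio and cannot trigger
    removal.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    _require_absent(table, "blank_filter", {"glog", "pareto"})
    qc = table.qc_samples
    if not qc:
        raise ValueError("blank_filter requires at least one pooled-QC injection")

    qc_mean = table.intensities[qc].mean(axis=1)

    def ratio_to(blank_type: str) -> pd.Series:
        cols = table.samples_of_type(blank_type)
        if not cols:
            return pd.Series(np.inf, index=table.features.index)
        blank_mean = table.intensities[cols].mean(axis=1)
        with np.errstate(divide="ignore"):
            r = qc_mean.to_numpy() / blank_mean.to_numpy()
        r[blank_mean.to_numpy() == 0] = np.inf
        return pd.Series(r, index=table.features.index)

    ratios = pd.DataFrame(
        {
            "qc_over_solvent_blank": ratio_to("solvent_blank"),
            "qc_over_fiber_blank": ratio_to("fiber_blank"),
        }
    )
    removed_mask = (ratios < threshold).any(axis=1)
    kept_ids = list(table.features.index[~removed_mask])
    filtered = table.subset(feature_ids=kept_ids)
    filtered.processing.append("blank_filter")
    report = FilterReport(
        kept=set(kept_ids),
        removed=set(table.features.index[removed_mask]),
        ratios=ratios,
    )
    return filtered, report


def qc_rsd(table: FeatureTable) -> pd.Series:
    """Per-feature relative standard deviation (%) over pooled-QC injections.

    Sample (n-1) standard deviation; a zero QC mean leaves the RSD undefined
    (NaN).
    """
    qc = table.qc_samples
    if len(qc) < 2:
        raise ValueError("qc_rsd requires at least two pooled-QC injections")
    sub = table.intensities[qc]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = 100.0 * sd.to_numpy() / mean.to_numpy()
    rsd[mean.to_numpy() == 0] = np.nan
    return pd.Series(rsd, index=table.features.index, name="qc_rsd")


def serrf_normalize(
    table: FeatureTable,
    n_correlated: int = 10,
    trees: int = 500,
    seed: int = 0,
    min_qc: int = 5,
    cv_error_features: int = 25,
) -> tuple[FeatureTable, NormalizationReport]:
    """Systematic-error removal using random forests, anchored on pooled QCs.

    Per feature, a forest is fitted on the pooled-QC injections to predict
    that feature's QC intensity from injection order plus its
    ``n_correlated`` most QC-correlated other features (each scaled by its
    own QC median).  The fitted forest predicts a drift level for every
    injection and the corrected intensity is ``raw * qc_median / predicted``,
    which removes the shared injection-order trend while leaving the
    feature's QC median unchanged.

    The forest grows unpruned trees without bootstrap resampling (diversity
    comes from per-split predictor subsampling), so it interpolates the QC
    points exactly: a noise-free monotone drift is learned exactly, and the
    correction never relocates the QC median.  The honest generalization
    error is reported via ``cv_error`` (QC-fold cross-validation).
    """
    _require_absent(table, "serrf", {"serrf", "glog", "pareto"})
    qc = table.qc_samples
    if len(qc) < min_qc:
        raise ValueError(
            f"serrf_normalize requires >= {min_qc} pooled-QC injections, found {len(qc)}"
        )
    X = table.intensities.to_numpy(dtype=float)
    qc_idx = np.array([table.intensities.columns.get_loc(c) for c in qc])
    qc_block = X[:, qc_idx]
    nonpos = np.where((qc_block <= 0).any(axis=1))[0]
    if nonpos.size:
        fid = table.features.index[nonpos[0]]
        raise ValueError(f"non-positive pooled-QC intensity for feature {fid!r}")

    n_feat = X.shape[0]
    orders = table.manifest["injection_order"].to_numpy(dtype=float)
    qc_median = np.median(qc_block, axis=1)
    scaled = X / qc_median[:, None]  # predictor features on a common scale

    # rank candidate predictors by |correlation| across QC injections
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(qc_block)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)

    rsd_before = qc_rsd(table)
    rng = np.random.default_rng(seed)
    corrected = np.empty_like(X)
    eps = 1e-12

    def fit_predict(f: int, train_cols: np.ndarray, predict_cols: np.ndarray) -> np.ndarray:
        k = min(n_correlated, n_feat - 1)
        top = np.argsort(-np.abs(corr[f]))[:k] if k > 0 else np.array([], dtype=int)
        design = np.column_stack([orders[:, None], scaled[top].T]) if k else orders[:, None]
        model = RandomForestRegressor(
            n_estimators=trees,
            bootstrap=False,
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        model.fit(design[train_cols], X[f, train_cols])
        return model.predict(design[predict_cols])

    all_cols = np.arange(X.shape[1])
    for f in range(n_feat):
        pred = fit_predict(f, qc_idx, all_cols)
        pred = np.maximum(pred, eps * qc_median[f])
        corrected[f] = X[f] * qc_median[f] / pred

    # honest QC cross-validation error on a feature subsample
    n_eval = min(cv_error_features, n_feat)
    eval_features = rng.choice(n_feat, size=n_eval, replace=False)
    rel_errors = []
    splitter = KFold(n_splits=min(5, len(qc)), shuffle=True, random_state=seed)
    for f in eval_features:
        sq_rel = []
        for train, test in splitter.split(qc_idx):
            pred = fit_predict(f, qc_idx[train], qc_idx[test])
            pred = np.maximum(pred, eps * qc_median[f])
            sq_rel.extend(((X[f, qc_idx[test]] - pred) / qc_median[f]) ** 2)
        rel_errors.append(np.sqrt(np.mean(sq_rel)))
    cv_error = float(np.median(rel_errors))

    out = table.with_intensities(
        pd.DataFrame(corrected, index=table.intensities.index, columns=table.intensities.columns),
        step="serrf",
    )
    report = NormalizationReport(
        qc_rsd_before=rsd_before, qc_rsd_after=qc_rsd(out), cv_error=cv_error
    )
    return out, report


def glog_transform(table: FeatureTable, lam: float = 1.0) -> FeatureTable:
    """Generalized log transform: x -> log2((x + sqrt(x^2 + lam^2)) / 2).

    Behaves like log2(x) for x >> lam but stays finite (and monotone) down
    to zero, stabilizing the variance of low-intensity features.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    _require_absent(table, "glog", {"glog", "pareto"})
    x = table.intensities.to_numpy(dtype=float)
    values = np.log2((x + np.sqrt(x**2 + lam**2)) / 2.0)
    return table.with_intensities(
        pd.DataFrame(values, index=table.intensities.index, columns=table.intensities.columns),
        step="glog",
    )


def pareto_scale(table: FeatureTable) -> FeatureTable:
    """Centre each feature and divide by sqrt(sample standard deviation).

    Pareto scaling down-weights intense features less aggressively than
    autoscaling.  Constant features carry no information to scale and are
    set to zero with a warning.
    """
    _require_absent(table, "pareto", {"pareto"})
    x = table.intensities.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) set to zero by pareto scaling",
            UserWarning,
            stacklevel=2,
        )
    denom = np.sqrt(np.where(sd == 0, 1.0, sd))
    values = (x - mean) / denom
    values[constant] = 0.0
    return table.with_intensities(
        pd.DataFrame(values, index=table.intensities.index, columns=table.intensities.columns),
        step="pareto",
    )
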