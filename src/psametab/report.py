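"""Cross-comparison overlap, PCA diagnostics, and pipeline orchestration.

Features selected by gate-passing panels of different class-pair
comparisons are intersected to find markers that track disease severity
across more than one contrast; PCA score plots with the pooled QCs overlaid
diagnose instrumental stability (tight QC clustering) after drift
correction; and :func:`run_pipeline` wires simulation, conditioning,
ranking, panel building, annotation and overlap into one reproducible run
directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .annotate import annotate_features
from .core import FeatureTable
from .preprocess import blank_filter, glog_transform, pareto_scale, serrf_normalize
from .select import (
    DEFAULT_GATE,
    DEFAULT_K_GRID,
    PAIRS,
    RANKING_CLASSIFIERS,
    ModelResult,
    build_topk_models,
    per_feature_auc,
    ranking_to_frame,
    top_models_report,
)

__all__ = ["OverlapReport", "overlap_features", "pca_scores", "run_pipeline"]

log = logging.getLogger("psametab")

_PAIR_NAMES = tuple(PAIRS)  # low_vs_high, moderate_vs_high, low_vs_moderate


@dataclass
class OverlapReport:
    """Membership of each feature in the three per-comparison marker sets."""

    membership: pd.DataFrame  # one bool column per class pair
    pairwise: dict[tuple[str, str], set[str]]
    triple: set[str]
    annotations: pd.DataFrame | None = None

    def counts(self) -> dict[str, int]:
        out = {f"{a}&{b}": len(s) for (a, b), s in self.pairwise.items()}
        out["all_three"] = len(self.triple)
        return out


def overlap_features(
    features_by_pair: dict[str, set[str]],
    annotations: pd.DataFrame | None = None,
) -> OverlapReport:
    """Pairwise and triple intersections of per-comparison feature sets.

    ``features_by_pair`` must carry all three canonical comparisons (empty
    sets allowed).  When an annotation table is supplied, overlapping
    features are tagged with their tentative identification.
    """
    missing = set(_PAIR_NAMES) - set(features_by_pair)
    if missing:
        raise ValueError(f"missing class pairs: {sorted(missing)}")
    universe = sorted(set().union(*(features_by_pair[p] for p in _PAIR_NAMES)))
    membership = pd.DataFrame(
        {p: [f in features_by_pair[p] for f in universe] for p in _PAIR_NAMES},
        index=pd.Index(universe, name="feature_id"),
    )
    pairwise = {}
    for i, a in enumerate(_PAIR_NAMES):
        for b in _PAIR_NAMES[i + 1 :]:
            pairwise[(a, b)] = features_by_pair[a] & features_by_pair[b]
    triple = features_by_pair[_PAIR_NAMES[0]].copy()
    for p in _PAIR_NAMES[1:]:
        triple &= features_by_pair[p]
    ann = None
    if annotations is not None and universe:
        present = [f for f in universe if f in annotations.index]
        ann = annotations.loc[present]
    return OverlapReport(membership=membership, pairwise=pairwise, triple=triple, annotations=ann)


def pca_scores(
    table: FeatureTable | pd.DataFrame, n_components: int = 3
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample principal-component scores and explained-variance fractions.

    Computed by SVD of the column-centred samples x features matrix.  Sign
    convention: each component is oriented so its largest-magnitude feature
    loading is positive, making scores reproducible across runs.
    """
    if isinstance(table, FeatureTable):
        data = table.intensities.T  # samples x features
    else:
        data = table
    if data.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    n_components = int(n_components)
    if not 1 <= n_components <= min(data.shape):
        raise ValueError(f"n_components must be in [1, {min(data.shape)}]")
    X = data.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    for j in range(n_components):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U[:, :n_components] * S[:n_components]
    total_var = (S**2).sum()
    evr = (S[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    frame = pd.DataFrame(
        scores, index=data.index, columns=[f"PC{j + 1}" for j in range(n_components)]
    )
    return frame, evr


# -- end-to-end orchestration ----------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "polarities": ["positive"],
    "cohort": {"n_low": 56, "n_mod": 54, "n_high": 40, "qc_every": 10,
               "n_solvent_blank": 2, "n_fiber_blank": 2},
    "library_size": 300,
    "generator": {"n_features": 500, "n_informative": 20, "effect_size": 2.0,
                  "drift_strength": 0.3, "noise_cv": 0.5},
    "blank_threshold": 5.0,
    "serrf": {"n_correlated": 10, "trees": 500},
    "glog_lambda": 1.0,
    "classifiers": list(RANKING_CLASSIFIERS),
    "k_grid": list(DEFAULT_K_GRID),
    "n_folds": 10,
    "gate": DEFAULT_GATE,
    "rf_trees": 200,
    "tol_ppm": 5.0,
    "n_top_models": 10,
    "plots": False,
}


def _merged_config(config: dict | str | Path | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if config is None:
        return cfg
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    for key, value in config.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _model_record(m: ModelResult) -> dict:
    return {
        "classifier": m.classifier,
        "pair": m.pair.name,
        "k": m.k,
        "cv_auc": round(m.cv_auc, 6),
        "passed_gate": m.passed_gate,
        "feature_ids": m.feature_ids,
    }


def run_pipeline(config: dict | str | Path | None = None, out_dir=None) -> Path:
    """Run simulate -> preprocess -> rank -> model -> annotate -> overlap.

    Each polarity listed in the configuration is simulated and analysed
    independently.  All intermediate artifacts (CSV/JSON), a log file and a
    machine-readable ``summary.json`` are written under ``out_dir``; the
    summary is byte-identical across re-runs with the same configuration.
    """
    from .simulate import generate_compound_library, generate_feature_table, generate_manifest

    cfg = _merged_config(config)
    out = pio.ensure_dir(out_dir if out_dir is not None else cfg.get("out_dir", "psametab_run"))
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    (out / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True))

    summary: dict = {"config_seed": cfg["seed"], "polarities": {}}
    try:
        for pol_index, polarity in enumerate(cfg["polarities"]):
            summary["polarities"][polarity] = _run_polarity(
                cfg, polarity, cfg["seed"] + 1000 * pol_index, out
            )
    finally:
        log.removeHandler(handler)
        handler.close()

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return out


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # annotate failures with the stage name
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    return wrap


def _render_plots(pdir: Path, top: list[ModelResult], pca: pd.DataFrame, manifest) -> None:
    """ROC curves of the top panels and a PCA score plot with QCs overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for m in top:
        roc = np.array(m.roc)
        ax.plot(roc[:, 0], roc[:, 1], label=f"{m.classifier} k={m.k} AUC={m.cv_auc:.2f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=6)
    fig.savefig(pdir / "roc_top_models.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    roles = manifest.loc[pca.index]
    for label, mask in [
        ("low", roles["group"] == "low"),
        ("moderate", roles["group"] == "moderate"),
        ("high", roles["group"] == "high"),
        ("pooled QC", roles["sample_type"] == "pooled_qc"),
    ]:
        sub = pca[mask.to_numpy()]
        if len(sub):
            ax.scatter(sub["PC1"], sub["PC2"], s=12, label=label)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=7)
    fig.savefig(pdir / "pca_scores.png", dpi=120, bbox_inches="tight")
    plt.close(fig)


def _run_polarity(cfg: dict, polarity: str, seed: int, out: Path) -> dict:
    from .simulate import generate_compound_library, generate_feature_table, generate_manifest

    pdir = pio.ensure_dir(out / polarity)
    log.info("polarity=%s seed=%d", polarity, seed)

    manifest = _stage("simulate")(
        generate_manifest, seed=seed, **cfg["cohort"]
    )
    library = _stage("simulate")(generate_compound_library, cfg["library_size"], seed=seed + 1)
    table, truth = _stage("simulate")(
        generate_feature_table,
        manifest,
        library,
        seed=seed + 2,
        polarity=polarity,
        **cfg["generator"],
    )
    pio.write_feature_table(table, pdir / "features_raw.csv", pdir / "manifest.csv")
    library.to_tsv(pdir / "library.tsv")

    filtered, filter_report = _stage("preprocess")(blank_filter, table, cfg["blank_threshold"])
    log.info("blank_filter kept %d of %d features", len(filter_report.kept), table.n_features)
    normalized, norm_report = _stage("preprocess")(
        serrf_normalize, filtered, seed=seed + 3, **cfg["serrf"]
    )
    scaled = _stage("preprocess")(
        pareto_scale, glog_transform(normalized, lam=cfg["glog_lambda"])
    )
    pio.write_feature_table(normalized, pdir / "features_normalized.csv")

    rsd_before = float(norm_report.qc_rsd_before.median())
    rsd_after = float(norm_report.qc_rsd_after.median())
    log.info("median QC RSD %.2f%% -> %.2f%%", rsd_before, rsd_after)

    nonblank = scaled.study_samples + scaled.qc_samples
    pca, evr = _stage("report")(pca_scores, scaled.subset(sample_ids=nonblank), 3)
    pca.to_csv(pdir / "pca_scores.csv")

    all_models: list[ModelResult] = []
    features_by_pair: dict[str, set[str]] = {}
    for pair_name, pair in PAIRS.items():
        ranked = _stage("rank")(
            per_feature_auc,
            scaled,
            pair,
            classifiers=cfg["classifiers"],
            n_folds=cfg["n_folds"],
            seed=seed + 4,
            rf_trees=cfg["rf_trees"],
        )
        ranking_to_frame(ranked).to_csv(pdir / f"ranking_{pair_name}.csv")
        models = _stage("model")(
            build_topk_models,
            scaled,
            pair,
            ranked,
            k_grid=cfg["k_grid"],
            classifiers=cfg["classifiers"],
            n_folds=cfg["n_folds"],
            seed=seed + 4,
            gate=cfg["gate"],
            rf_trees=cfg["rf_trees"],
        )
        all_models.extend(models)
        passing = [m for m in models if m.passed_gate]
        features_by_pair[pair_name] = set().union(*(m.feature_ids for m in passing)) if passing else set()
        log.info("%s: %d/%d models passed the %.2f gate", pair_name, len(passing), len(models), cfg["gate"])

    selected = sorted(set().union(*features_by_pair.values()))
    annotations = _stage("annotate")(
        annotate_features,
        table.features.loc[selected] if selected else table.features.iloc[:0],
        library,
        polarity,
        cfg["tol_ppm"],
    )
    annotations.to_csv(pdir / "annotations.csv")

    overlap = _stage("overlap")(overlap_features, features_by_pair, annotations)
    overlap.membership.to_csv(pdir / "overlap.csv")

    top = top_models_report(all_models, n=cfg["n_top_models"]) if all_models else []
    (pdir / "models.json").write_text(
        json.dumps([_model_record(m) for m in all_models], indent=2, sort_keys=True)
    )
    roc_rows = [
        {"pair": m.pair.name, "classifier": m.classifier, "k": m.k,
         "fpr": fpr, "tpr": tpr}
        for m in top for fpr, tpr in m.roc
    ]
    pd.DataFrame(roc_rows).to_csv(pdir / "roc_top_models.csv", index=False)
    if cfg.get("plots"):
        _render_plots(pdir, top, pca, scaled.manifest)

    recovered = sorted(set(selected) & truth.informative_features)
    return {
        "n_features": table.n_features,
        "n_kept_after_blank_filter": len(filter_report.kept),
        "median_qc_rsd_before": round(rsd_before, 4),
        "median_qc_rsd_after": round(rsd_after, 4),
        "pca_explained_variance": [round(float(v), 4) for v in evr],
        "n_models": len(all_models),
        "n_models_passing_gate": sum(m.passed_gate for m in all_models),
        "top_models": [_model_record(m) for m in top],
        "overlap_counts": overlap.counts(),
        "n_selected_features": len(selected),
        "n_planted_recovered": len(recovered),
        "n_annotated": int(annotations["tentative_id"].notna().sum()) if len(annotations) else 0,
    }
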