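"""Synthetic cohort and LC-MS feature-table generator with known ground truth.

Emulates the acquisition design of a 150-patient psoriatic-arthritis serum
study: patients binned by PASI into low/moderate/high skin-disease activity
(n = 56/54/40), solvent and fiber blanks at the start of the run, a pooled
QC injected before and then after every 10 study injections, log-normal
feature intensities with multiplicative group effects on a planted subset
of features, and a monotone injection-order intensity drift shared by study
samples and pooled QCs.  Every feature's m/z is an exact library mass plus
one adduct offset, so annotation is an exact inverse of the generator.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .annotate import adducts_for
from .core import MZ_RANGE, CompoundLibrary, FeatureTable, GroundTruth

__all__ = [
    "classify_pasi",
    "generate_manifest",
    "generate_compound_library",
    "generate_feature_table",
]

# Observed PASI ranges per severity group in the emulated cohort; draws are
# uniform within these, keeping simulated scores consistent with the bins.
PASI_RANGES = {"low": (0.1, 4.8), "moderate": (5.0, 9.8), "high": (10.1, 54.6)}


def classify_pasi(pasi: float) -> str:
    """Severity group for a PASI score: low <5, moderate 5-10, high >10.

    Both bin edges belong to the moderate group (the clinical rule writes
    the moderate range as 5-10 inclusive).
    """
    if pasi < 0:
        raise ValueError(f"PASI must be nonnegative, got {pasi}")
    if pasi < 5:
        return "low"
    if pasi <= 10:
        return "moderate"
    return "high"


def generate_manifest(
    n_low: int = 56,
    n_mod: int = 54,
    n_high: int = 40,
    qc_every: int = 10,
    n_solvent_blank: int = 2,
    n_fiber_blank: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Injection manifest for one acquisition batch.

    Blanks open the run; a pooled QC precedes the first study injection and
    recurs after every ``qc_every`` study injections (150 study samples at
    the default spacing give 16 QCs).  Study samples are block-randomized
    over the injection sequence and split over two plates.  PASI scores are
    drawn uniformly inside each group's observed range.
    """
    if min(n_low, n_mod, n_high, n_solvent_blank, n_fiber_blank) < 0:
        raise ValueError("counts must be nonnegative")
    if qc_every < 1:
        raise ValueError("qc_every must be >= 1")
    n_study = n_low + n_mod + n_high
    if n_study == 0:
        raise ValueError("empty design: no study samples requested")

    rng = np.random.default_rng(seed)
    groups = ["low"] * n_low + ["moderate"] * n_mod + ["high"] * n_high
    order = rng.permutation(n_study)

    records = []
    for i in range(n_solvent_blank):
        records.append((f"SB{i + 1:02d}", "solvent_blank", None, np.nan))
    for i in range(n_fiber_blank):
        records.append((f"FB{i + 1:02d}", "fiber_blank", None, np.nan))

    n_qc = 0

    def add_qc():
        nonlocal n_qc
        n_qc += 1
        records.append((f"QC{n_qc:02d}", "pooled_qc", None, np.nan))

    add_qc()
    for pos, idx in enumerate(order, start=1):
        group = groups[idx]
        lo, hi = PASI_RANGES[group]
        pasi = round(float(rng.uniform(lo, hi)), 1)
        records.append((f"S{idx + 1:03d}", "study", group, pasi))
        if pos % qc_every == 0:
            add_qc()
    if len(order) % qc_every != 0:  # close the run with a QC bracket
        add_qc()

    manifest = pd.DataFrame(records, columns=["sample_id", "sample_type", "group", "pasi"])
    manifest["injection_order"] = np.arange(1, len(manifest) + 1)
    manifest["plate"] = np.where(manifest["injection_order"] <= len(manifest) / 2, 1, 2)
    for _, row in manifest[manifest["sample_type"] == "study"].iterrows():
        assert classify_pasi(row["pasi"]) == row["group"]
    return manifest.set_index("sample_id")


def generate_compound_library(
    n: int, mass_range: tuple[float, float] = (75.0, 950.0), seed: int = 0
) -> CompoundLibrary:
    """Uniformly spread neutral-mass library with unique synthetic names."""
    lo, hi = mass_range
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 < lo <= hi):
        raise ValueError(f"invalid mass range {mass_range}")
    rng = np.random.default_rng(seed)
    masses = np.sort(rng.uniform(lo, hi, size=n))
    entries = pd.DataFrame(
        {"name": [f"compound_{i + 1:04d}" for i in range(n)], "monoisotopic_mass": masses}
    )
    return CompoundLibrary(entries)


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise with the requested coefficient of variation."""
    if cv <= 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(0.0, sigma, size=shape))


def generate_feature_table(
    manifest: pd.DataFrame,
    library: CompoundLibrary,
    n_features: int = 500,
    n_informative: int = 20,
    effect_size: float = 2.0,
    drift_strength: float = 0.3,
    noise_cv: float = 0.5,
    seed: int = 0,
    polarity: str = "positive",
    blank_only_fraction: float = 0.05,
    blank_leakage: float = 0.02,
    qc_noise_cv: float | None = None,
) -> tuple[FeatureTable, GroundTruth]:
    """Intensity matrix over the manifest's injections, with ground truth.

    The intensity model is multiplicative: a log-normal per-feature baseline
    times a per-group effect (informative features only; low < moderate <
    high, spanning ``effect_size`` from low to high), times a linear
    injection-order drift factor (coefficient up to ``drift_strength`` over
    the run, identical for study samples and pooled QCs), times log-normal
    noise of coefficient of variation ``noise_cv`` (biological + technical
    for study samples; pooled QCs, being replicate injections of one pool,
    get ``qc_noise_cv``, default one tenth of ``noise_cv``).  A
    ``blank_only_fraction`` of features model background contamination:
    intense in blanks, near-absent elsewhere, which the blank-ratio filter
    must remove; genuine features leak into blanks at ``blank_leakage`` of
    baseline.  Each feature's m/z is one library mass plus one randomly
    chosen polarity-compatible adduct offset.
    """
    if n_informative > n_features:
        raise ValueError("n_informative cannot exceed n_features")
    if effect_size <= 0:
        raise ValueError("effect_size must be positive")
    if qc_noise_cv is None:
        qc_noise_cv = 0.1 * noise_cv

    rng = np.random.default_rng(seed)
    specs = adducts_for(polarity)
    n_qc = int((manifest["sample_type"] == "pooled_qc").sum())
    if drift_strength > 0 and n_qc == 0:
        warnings.warn(
            "drift_strength > 0 but the manifest has no pooled QCs; "
            "the drift will not be correctable downstream",
            UserWarning,
            stacklevel=2,
        )

    feature_ids = [f"F{i + 1:04d}" for i in range(n_features)]
    n_blank_only = int(round(blank_only_fraction * n_features))
    shuffled = list(rng.permutation(feature_ids))
    blank_only = set(shuffled[:n_blank_only])
    informative = set(shuffled[n_blank_only : n_blank_only + n_informative])
    if len(informative) < n_informative:
        raise ValueError("not enough non-background features to plant effects in")

    # m/z = library mass + adduct offset, resampled until inside the range
    mzs, compounds, adduct_labels = [], [], []
    for fid in feature_ids:
        for _ in range(1000):
            ci = int(rng.integers(len(library)))
            spec = specs[int(rng.integers(len(specs)))]
            mz = library.masses[ci] + spec.delta
            if MZ_RANGE[0] <= mz <= MZ_RANGE[1]:
                break
        else:
            raise ValueError("could not place a feature m/z inside the acquired range")
        mzs.append(mz)
        compounds.append(library.names[ci])
        adduct_labels.append(spec.label)

    features = pd.DataFrame(
        {
            "mz": mzs,
            "rt": rng.uniform(0.5, 25.0, size=n_features),
            "polarity": polarity,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )

    # baselines and per-group effects
    baseline = np.exp(rng.normal(np.log(1e6), 1.0, size=n_features))
    exponent = {"low": 0.0, "moderate": 0.5, "high": 1.0}
    effect: dict[str, dict[str, float]] = {}
    group_factor = np.ones((n_features, 3))  # columns: low, moderate, high
    for r, fid in enumerate(feature_ids):
        if fid in informative:
            factors = {g: effect_size ** exponent[g] for g in exponent}
            effect[fid] = factors
            group_factor[r] = [factors["low"], factors["moderate"], factors["high"]]

    # pooled QC mixes every study extract: group effects enter at cohort weights
    study = manifest[manifest["sample_type"] == "study"]
    weights = np.array(
        [(study["group"] == g).sum() for g in ("low", "moderate", "high")], dtype=float
    )
    weights = weights / weights.sum() if weights.sum() else np.ones(3) / 3
    qc_factor = group_factor @ weights

    drift_coef = (
        drift_strength * rng.uniform(0.5, 1.0, size=n_features)
        if drift_strength > 0
        else np.zeros(n_features)
    )
    orders = manifest["injection_order"].to_numpy(dtype=float)
    span = max(orders.max() - 1.0, 1.0)
    drift_factor = 1.0 + np.outer(drift_coef, (orders - 1.0) / span)

    group_col = {"low": 0, "moderate": 1, "high": 2}
    matrix = np.empty((n_features, len(manifest)))
    blank_mask = np.array([fid in blank_only for fid in feature_ids])
    for c, (sid, row) in enumerate(manifest.iterrows()):
        stype = row["sample_type"]
        if stype == "study":
            col = baseline * group_factor[:, group_col[row["group"]]]
            col = col * drift_factor[:, c] * _lognormal_noise(rng, noise_cv, n_features)
            col[blank_mask] = baseline[blank_mask] * 1e-4
        elif stype == "pooled_qc":
            col = baseline * qc_factor * drift_factor[:, c]
            col = col * _lognormal_noise(rng, qc_noise_cv, n_features)
            col[blank_mask] = baseline[blank_mask] * 1e-4
        else:  # blanks: background features intense, real features leak in
            col = baseline * blank_leakage * _lognormal_noise(rng, qc_noise_cv, n_features)
            col[blank_mask] = (
                baseline[blank_mask]
                * _lognormal_noise(rng, qc_noise_cv, int(blank_mask.sum()))
            )
        matrix[:, c] = col

    intensities = pd.DataFrame(matrix, index=features.index, columns=manifest.index)
    table = FeatureTable(features=features, intensities=intensities, manifest=manifest.copy())
    truth = GroundTruth(
        informative_features=informative,
        effect=effect,
        drift=dict(zip(feature_ids, drift_coef.tolist())),
        blank_only_features=blank_only,
        compound=dict(zip(feature_ids, compounds)),
        adduct=dict(zip(feature_ids, adduct_labels)),
    )
    return table, truth
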