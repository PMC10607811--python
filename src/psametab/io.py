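"""Plain-text persistence for manifests, feature tables and libraries.

Formats:

- manifest CSV: ``sample_id, sample_type, group, pasi, injection_order, plate``
- feature table CSV: ``feature_id, mz, rt, polarity`` followed by one
  intensity column per sample id
- compound library TSV: ``name, monoisotopic_mass``
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .core import FEATURE_COLUMNS, MANIFEST_COLUMNS, FeatureTable


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.reset_index()[["sample_id", *MANIFEST_COLUMNS]].to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    man = pd.read_csv(path, dtype={"group": "string"})
    man["group"] = man["group"].astype(object).where(man["group"].notna(), None)
    return man.set_index("sample_id")


def write_feature_table(table: FeatureTable, features_path, manifest_path=None) -> None:
    wide = table.features[FEATURE_COLUMNS].join(table.intensities)
    wide.reset_index().to_csv(features_path, index=False)
    if manifest_path is not None:
        write_manifest(table.manifest, manifest_path)


def read_feature_table(features_path, manifest_path, processing=None) -> FeatureTable:
    """Load a feature table; ``processing`` restores the conditioning state.

    The CSV does not carry provenance, so a table holding negative values
    (possible only after the glog/pareto steps) is marked "transformed"
    unless the caller states the steps applied; raw-table invariants are
    then not enforced.
    """
    wide = pd.read_csv(features_path).set_index("feature_id")
    manifest = read_manifest(manifest_path)
    features = wide[FEATURE_COLUMNS]
    intensities = wide.drop(columns=FEATURE_COLUMNS)
    intensities = intensities[list(manifest.index)]  # enforce manifest order
    intensities.columns.name = "sample_id"
    if processing is None:
        processing = ["transformed"] if (intensities.to_numpy() < 0).any() else []
    return FeatureTable(
        features=features, intensities=intensities, manifest=manifest,
        processing=list(processing),
    )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
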