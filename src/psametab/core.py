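"""Core containers for untargeted LC-MS feature-table analysis.

A :class:`FeatureTable` bundles the three pieces every stage of the pipeline
needs: per-feature metadata (m/z, retention time, polarity), the nonnegative
intensity matrix (features x injections), and the injection manifest
describing each injection's role in the acquisition (study sample, pooled QC,
solvent blank, fiber blank), its PASI-derived severity group and its position
in the injection sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("low", "moderate", "high")
SAMPLE_TYPES = ("study", "pooled_qc", "solvent_blank", "fiber_blank")

#: Acquired mass range of the instrument method, Th.
MZ_RANGE = (75.0, 1000.0)

MANIFEST_COLUMNS = ["sample_type", "group", "pasi", "injection_order", "plate"]
FEATURE_COLUMNS = ["mz", "rt", "polarity"]


@dataclass
class FeatureTable:
    """Feature intensity matrix plus feature metadata and injection manifest.

    Parameters
    ----------
    features
        Indexed by ``feature_id``; columns ``mz`` (Th), ``rt`` (minutes) and
        ``polarity`` ("positive"/"negative").
    intensities
        Indexed by ``feature_id``, one column per ``sample_id``. Raw tables
        are nonnegative; transformed tables (after the generalized log /
        pareto steps) may hold negative values and record the applied steps
        in :attr:`processing`.
    manifest
        Indexed by ``sample_id``; columns ``sample_type``, ``group``,
        ``pasi``, ``injection_order``, ``plate``.
    processing
        Ordered names of the conditioning steps already applied
        ("blank_filter", "serrf", "glog", "pareto"); used to enforce the
        fixed pipeline order.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    manifest: pd.DataFrame
    processing: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- consistency ---------------------------------------------------
    def validate(self) -> None:
        if not self.features.index.equals(self.intensities.index):
            raise ValueError("feature metadata and intensity rows disagree")
        if list(self.intensities.columns) != list(self.manifest.index):
            raise ValueError("intensity columns and manifest rows disagree")
        bad = ~self.manifest["sample_type"].isin(SAMPLE_TYPES)
        if bad.any():
            raise ValueError(
                f"unknown sample_type: {sorted(self.manifest['sample_type'][bad].unique())}"
            )
        order = self.manifest["injection_order"].to_numpy()
        # uniqueness only: sample subsets legitimately break contiguity
        if len(np.unique(order)) != len(order) or (order < 1).any():
            raise ValueError("injection_order values must be unique positive integers")
        if not self.processing:  # raw intensities only
            if (self.intensities.to_numpy() < 0).any():
                raise ValueError("negative intensities in a raw feature table")
            mz = self.features["mz"].to_numpy()
            if ((mz < MZ_RANGE[0]) | (mz > MZ_RANGE[1])).any():
                raise ValueError(f"feature m/z outside acquired range {MZ_RANGE}")

    # -- selections ----------------------------------------------------
    def samples_of_type(self, sample_type: str) -> list[str]:
        mask = self.manifest["sample_type"] == sample_type
        return list(self.manifest.index[mask])

    @property
    def qc_samples(self) -> list[str]:
        return self.samples_of_type("pooled_qc")

    @property
    def study_samples(self) -> list[str]:
        return self.samples_of_type("study")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.manifest)

    def subset(self, feature_ids=None, sample_ids=None) -> "FeatureTable":
        """Return a new table restricted to the given features/samples."""
        feats = self.features if feature_ids is None else self.features.loc[list(feature_ids)]
        cols = list(self.manifest.index) if sample_ids is None else list(sample_ids)
        return FeatureTable(
            features=feats.copy(),
            intensities=self.intensities.loc[feats.index, cols].copy(),
            manifest=self.manifest.loc[cols].copy(),
            processing=list(self.processing),
        )

    def with_intensities(self, values: pd.DataFrame, step: str | None = None) -> "FeatureTable":
        """Copy of this table with a replaced intensity matrix."""
        steps = list(self.processing) + ([step] if step else [])
        return FeatureTable(
            features=self.features.copy(),
            intensities=values,
            manifest=self.manifest.copy(),
            processing=steps,
        )


@dataclass
class GroundTruth:
    """What the synthetic generator planted, for downstream validation.

    ``effect`` maps each informative feature to its per-group multiplicative
    intensity shift; ``drift`` maps every feature to its injection-order
    drift coefficient (fractional intensity change over the full run);
    ``compound`` and ``adduct`` record the library compound and ion form each
    feature's m/z was built from, so annotation can be checked as an exact
    inverse.
    """

    informative_features: set[str]
    effect: dict[str, dict[str, float]]
    drift: dict[str, float]
    blank_only_features: set[str]
    compound: dict[str, str]
    adduct: dict[str, str]

    def __post_init__(self) -> None:
        if self.informative_features & self.blank_only_features:
            raise ValueError("informative and blank-only feature sets overlap")
        unknown = set(self.effect) - set(self.compound)
        if unknown:
            raise ValueError(f"effect keys are not feature ids: {sorted(unknown)[:5]}")


@dataclass
class CompoundLibrary:
    """Neutral monoisotopic mass library used for tentative identification.

    ``entries`` has columns ``name`` and ``monoisotopic_mass`` (Da) and is
    kept sorted by mass so window queries can bisect.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        ent = self.entries
        if list(ent.columns) != ["name", "monoisotopic_mass"]:
            ent = ent[["name", "monoisotopic_mass"]]
        if (ent["monoisotopic_mass"] <= 0).any():
            raise ValueError("library masses must be strictly positive")
        if ent["name"].duplicated().any():
            dupes = ent["name"][ent["name"].duplicated()].tolist()
            raise ValueError(f"duplicate compound names: {dupes[:5]}")
        self.entries = ent.sort_values("monoisotopic_mass", kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def masses(self) -> np.ndarray:
        return self.entries["monoisotopic_mass"].to_numpy()

    @property
    def names(self) -> np.ndarray:
        return self.entries["name"].to_numpy()

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CompoundLibrary":
        return cls(pd.read_csv(path, sep="\t"))
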