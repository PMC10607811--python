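import numpy as np
import pandas as pd
import pytest

import psametab as pm
from psametab.core import FeatureTable


@pytest.fixture(scope="session")
def small_manifest():
    # 36 study samples, QC bracket every 6 injections, 2+2 blanks
    return pm.generate_manifest(12, 12, 12, qc_every=6, seed=7)


@pytest.fixture(scope="session")
def library():
    return pm.generate_compound_library(120, (80.0, 900.0), seed=11)


@pytest.fixture(scope="session")
def drifted_table(small_manifest, library):
    table, truth = pm.generate_feature_table(
        small_manifest,
        library,
        n_features=40,
        n_informative=5,
        effect_size=3.0,
        drift_strength=0.4,
        noise_cv=0.2,
        seed=13,
    )
    return table, truth


@pytest.fixture(scope="session")
def clean_table(small_manifest, library):
    """No drift, no noise: every feature constant across non-blank injections."""
    table, truth = pm.generate_feature_table(
        small_manifest,
        library,
        n_features=25,
        n_informative=0,
        effect_size=2.0,
        drift_strength=0.0,
        noise_cv=0.0,
        seed=17,
    )
    return table, truth


def toy_table(values, sample_types, groups=None, mz=None):
    """Hand-built FeatureTable from a dense array and per-sample roles."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    fids = [f"F{i + 1:04d}" for i in range(n_feat)]
    sids = [f"X{j + 1:02d}" for j in range(n_samp)]
    features = pd.DataFrame(
        {
            "mz": mz if mz is not None else np.linspace(100, 900, n_feat),
            "rt": np.linspace(1, 20, n_feat),
            "polarity": "positive",
        },
        index=pd.Index(fids, name="feature_id"),
    )
    manifest = pd.DataFrame(
        {
            "sample_type": sample_types,
            "group": groups if groups is not None else [None] * n_samp,
            "pasi": np.nan,
            "injection_order": np.arange(1, n_samp + 1),
            "plate": 1,
        },
        index=pd.Index(sids, name="sample_id"),
    )
    intensities = pd.DataFrame(values, index=features.index, columns=manifest.index)
    return FeatureTable(features=features, intensities=intensities, manifest=manifest)
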