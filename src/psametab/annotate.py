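"""Adduct arithmetic and tentative metabolite identification.

An electrospray source observes a neutral molecule M as an ion such as
[M+H]+ or [M+Cl]-.  The measured m/z of a singly charged ion is the neutral
monoisotopic mass plus the adduct's mass offset (charge carrier including
the electron adjustment), so the neutral mass is recovered by subtracting
that offset and can then be matched against a compound library inside a
ppm window.  Only singly charged species are modelled, one adduct
hypothesis per feature, which mirrors how untargeted serum studies report
tentative identifications.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import CompoundLibrary

__all__ = [
    "AdductSpec",
    "ADDUCTS",
    "adducts_for",
    "neutral_mass",
    "match_compounds",
    "annotate_features",
    "format_identification",
    "load_reference_library",
    "load_published_markers",
]


@dataclass(frozen=True)
class AdductSpec:
    """A named ion form: observed m/z = neutral mass + ``delta`` (Da).

    ``delta`` carries the electron adjustment (proton = 1.007276 Da, not the
    hydrogen atom mass), which is required to invert printed reference
    masses at sub-ppm accuracy.
    """

    label: str
    polarity: str
    delta: float


# Singly charged adducts seen in the positive/negative serum methods.
ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", "positive", 1.007276),
    "[M+Na]+": AdductSpec("[M+Na]+", "positive", 22.989218),
    "[M+NH4]+": AdductSpec("[M+NH4]+", "positive", 18.033823),
    "[M-H]-": AdductSpec("[M-H]-", "negative", -1.007276),
    "[M+Cl]-": AdductSpec("[M+Cl]-", "negative", 34.969402),
}


def adducts_for(polarity: str) -> list[AdductSpec]:
    """Registry entries compatible with one ionization polarity."""
    specs = [a for a in ADDUCTS.values() if a.polarity == polarity]
    if not specs:
        raise ValueError(f"unknown polarity {polarity!r}; use 'positive' or 'negative'")
    return specs


def _resolve(adduct: str | AdductSpec) -> AdductSpec:
    if isinstance(adduct, AdductSpec):
        return adduct
    try:
        return ADDUCTS[adduct]
    except KeyError:
        raise ValueError(
            f"unknown adduct {adduct!r}; registry: {sorted(ADDUCTS)}"
        ) from None


def neutral_mass(mz: float, adduct: str | AdductSpec) -> float:
    """Neutral monoisotopic mass implied by an observed m/z and adduct."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    spec = _resolve(adduct)
    mass = mz - spec.delta
    if mass < 0:
        raise ValueError(f"adduct {spec.label} yields a negative neutral mass for m/z {mz}")
    return mass


def ppm_error(observed: float, reference: float) -> float:
    """Relative mass deviation in parts per million, signed."""
    return 1e6 * (observed - reference) / reference


def match_compounds(
    mass: float, library: CompoundLibrary, tol_ppm: float = 5.0
) -> pd.DataFrame:
    """All library entries within ``tol_ppm`` of ``mass``.

    ppm error is signed as (library - query)/query; results are sorted by
    absolute ppm error, ties alphabetically. An empty frame is a valid
    "no tentative identification" outcome.
    """
    if mass <= 0:
        raise ValueError("query mass must be positive")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    masses = library.masses
    half = mass * tol_ppm * 1e-6
    lo = np.searchsorted(masses, mass - half, side="left")
    hi = np.searchsorted(masses, mass + half, side="right")
    hits = library.entries.iloc[lo:hi].copy()
    hits["ppm_error"] = 1e6 * (hits["monoisotopic_mass"] - mass) / mass
    hits = hits[hits["ppm_error"].abs() <= tol_ppm]
    hits["_abs"] = hits["ppm_error"].abs()
    hits = hits.sort_values(["_abs", "name"], kind="mergesort").drop(columns="_abs")
    return hits.reset_index(drop=True)


def format_identification(name: str | None, n_other_hits: int = 0) -> str:
    """Render a tentative identification the way marker tables print it."""
    if name is None:
        return "N/A"
    if n_other_hits > 0:
        plural = "hit" if n_other_hits == 1 else "hits"
        return f"{name}; {n_other_hits} other {plural}"
    return name


def annotate_features(
    features: pd.DataFrame,
    library: CompoundLibrary,
    polarity: str | None = None,
    tol_ppm: float = 5.0,
) -> pd.DataFrame:
    """Tentatively identify each feature by trying every compatible adduct.

    For every feature the polarity-appropriate adducts are applied to its
    m/z; among all (adduct, library hit) combinations the one with the
    smallest absolute ppm error is reported, with ``n_other_hits`` counting
    the remaining matches for that same adduct. Features with no match
    inside the window are emitted with a null identification.

    Parameters
    ----------
    features
        Indexed by feature id with at least an ``mz`` column; ``rt`` and
        ``polarity`` columns are carried through when present.
    polarity
        Overrides the per-feature polarity column when given.
    """
    rows = []
    for fid, row in features.iterrows():
        pol = polarity or row.get("polarity")
        if pol is None:
            raise ValueError(f"feature {fid} has no polarity and none was given")
        best = None  # (abs_ppm, adduct_label, hit_row, n_matches)
        for spec in adducts_for(pol):
            mass = row["mz"] - spec.delta
            if mass <= 0:
                continue
            hits = match_compounds(mass, library, tol_ppm=tol_ppm)
            if hits.empty:
                continue
            top = hits.iloc[0]
            key = (abs(top["ppm_error"]), spec.label)
            if best is None or key < (best[0], best[1]):
                best = (abs(top["ppm_error"]), spec.label, mass, top, len(hits))
        out = {
            "feature_id": fid,
            "mz": row["mz"],
            "rt": row.get("rt", np.nan),
            "adduct": None,
            "neutral_mass": np.nan,
            "tentative_id": None,
            "library_mass": np.nan,
            "ppm_error": np.nan,
            "n_other_hits": 0,
        }
        if best is not None:
            _, label, mass, top, n_matches = best
            out.update(
                adduct=label,
                neutral_mass=mass,
                tentative_id=top["name"],
                library_mass=top["monoisotopic_mass"],
                ppm_error=top["ppm_error"],
                n_other_hits=n_matches - 1,
            )
        out["identification"] = format_identification(out["tentative_id"], out["n_other_hits"])
        rows.append(out)
    columns = ["feature_id", "mz", "rt", "adduct", "neutral_mass", "tentative_id",
               "library_mass", "ppm_error", "n_other_hits", "identification"]
    return pd.DataFrame(rows, columns=columns).set_index("feature_id")


# -- packaged reference data ------------------------------------------------

def _data_path(name: str):
    return resources.files("psametab.data").joinpath(name)


def load_reference_library() -> CompoundLibrary:
    """Bundled neutral-mass library of literature serum metabolites.

    A small stand-in for a full compound database (HMDB-scale resources are
    queried online in practice): the compounds tentatively identified in
    published PsA serum marker tables, with their printed monoisotopic
    masses.
    """
    with resources.as_file(_data_path("reference_compounds.tsv")) as p:
        return CompoundLibrary.from_tsv(p)


def load_published_markers() -> pd.DataFrame:
    """Published marker-table rows: m/z, adduct, printed neutral mass, id.

    Used as a golden fixture for the adduct arithmetic and as a realistic
    annotation workload.
    """
    with resources.as_file(_data_path("published_marker_rows.tsv")) as p:
        return pd.read_csv(p, sep="\t")
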