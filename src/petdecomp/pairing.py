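"""Cross-modal pairing of PET observations with IHC mice.

PET and IHC are acquired on different animals (to exclude within-modality
batch effects), so the regression design is built by enumerating *all*
combinations of a PET observation and an IHC mouse that share genotype and
age — the full cross product within each (genotype, age) stratum.  Every
PET observation contributes its z-score and its heterogeneity (deviation
from the stratum mean z, a property of the mouse, computed once before
pairing); every IHC mouse contributes its fibrillar and nonfibrillar
coverage.

``ihc_aggregate="mean"`` collapses the IHC side to stratum means instead,
giving one row per PET observation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import EmptyDesignError, ValidationError

PAIR_COLUMNS = ["pet_mouse_id", "ihc_mouse_id", "genotype", "age_months",
                "z", "fibrillar_area_pct", "nonfibrillar_area_pct", "heterogeneity"]

STRATUM = ["genotype", "age_months"]


def compute_heterogeneity(pet_z: pd.DataFrame) -> pd.DataFrame:
    """Attach ``heterogeneity`` = z minus the (genotype, age) group mean z.

    Within every stratum the values sum to zero; a singleton stratum gets
    h = 0 with a warning (its deviation is unidentifiable).
    """
    if "z" not in pet_z.columns:
        raise ValidationError("PET table must carry a 'z' column; run z_score_cohort first")
    out = pet_z.copy()
    grouped = out.groupby(STRATUM)["z"]
    out["heterogeneity"] = out["z"] - grouped.transform("mean")
    singleton = grouped.transform("count") == 1
    if singleton.any():
        warnings.warn("singleton (genotype, age) strata: heterogeneity set to 0", stacklevel=2)
        out.loc[singleton, "heterogeneity"] = 0.0
    return out


def build_pairs(pet_z: pd.DataFrame, ihc: pd.DataFrame,
                ihc_aggregate: str = "mice") -> pd.DataFrame:
    """All age- and genotype-matched PET x IHC combinations.

    Parameters
    ----------
    pet_z
        PET observations with a ``z`` column (wild-type excluded).  A
        ``heterogeneity`` column is used if present, otherwise computed.
    ihc
        Validated IHC table with derived ``nonfibrillar_area_pct``.
    ihc_aggregate
        ``"mice"`` (default) pairs each PET observation with every IHC
        mouse of its stratum; ``"mean"`` pairs it with the stratum mean
        coverages instead.

    Returns the paired table (sorted canonically, so row order of the inputs
    is irrelevant) with per-stratum pair counts in ``.attrs["stratum_counts"]``.
    """
    if ihc_aggregate not in ("mice", "mean"):
        raise ValidationError("ihc_aggregate must be 'mice' or 'mean'")
    if pet_z.empty or ihc.empty:
        raise EmptyDesignError("both a PET and an IHC cohort are required")
    if "heterogeneity" not in pet_z.columns:
        pet_z = compute_heterogeneity(pet_z)

    left = pet_z.loc[:, STRATUM + ["mouse_id", "z", "heterogeneity"]].rename(
        columns={"mouse_id": "pet_mouse_id"})
    if ihc_aggregate == "mean":
        right = (ihc.groupby(STRATUM, as_index=False)
                 [["fibrillar_area_pct", "nonfibrillar_area_pct"]].mean())
        right["ihc_mouse_id"] = "stratum-mean"
    else:
        right = ihc.loc[:, STRATUM + ["mouse_id", "fibrillar_area_pct",
                                      "nonfibrillar_area_pct"]].rename(
            columns={"mouse_id": "ihc_mouse_id"})

    pairs = left.merge(right, on=STRATUM)
    if pairs.empty:
        raise EmptyDesignError("no (genotype, age) stratum is present in both modalities")
    pairs = (pairs.loc[:, PAIR_COLUMNS]
             .sort_values(PAIR_COLUMNS[:4], kind="mergesort")
             .reset_index(drop=True))
    counts = (pairs.groupby(STRATUM).size().rename("n_pairs").reset_index())
    pairs.attrs["stratum_counts"] = counts
    return pairs


def stratum_pair_counts(pet_z: pd.DataFrame, ihc: pd.DataFrame) -> pd.DataFrame:
    """Expected pair count per stratum: n_pet(stratum) x n_ihc(stratum)."""
    n_pet = pet_z.groupby(STRATUM).size().rename("n_pet")
    n_ihc = ihc.groupby(STRATUM).size().rename("n_ihc")
    joint = pd.concat([n_pet, n_ihc], axis=1, join="inner")
    joint["n_pairs"] = joint["n_pet"] * joint["n_ihc"]
    return joint.reset_index()
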