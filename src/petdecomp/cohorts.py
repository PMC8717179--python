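"""Cohort tables, z-scoring and elementary group statistics.

Two tabular schemas are used throughout the package:

``pet``
    One row per PET measurement of one mouse at one age:
    ``mouse_id, genotype, age_months, suvr, reference_region``.
    ``suvr`` is the target-to-reference standardized-uptake-value ratio.

``ihc``
    One row per immunohistochemistry mouse at one age:
    ``mouse_id, genotype, age_months, total_area_pct, fibrillar_area_pct``.
    Coverage is carried in percent of field area (0-100).  The nonfibrillar
    coverage is always derived as ``total - fibrillar`` and never read from
    disk.

PET signal is standardized as a z-score against wild-type controls measured
with the same reference region:  z = (SUVR - mean_WT) / sd_WT, with the
sample (n-1) standard deviation.  Controls are pooled across ages by
default; ``age_matched=True`` restricts them to the same integer age.
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateControlsError,
    InsufficientControlsError,
    MissingStratumError,
    SchemaError,
    ValidationError,
)

PET_COLUMNS = ["mouse_id", "genotype", "age_months", "suvr", "reference_region"]
IHC_COLUMNS = ["mouse_id", "genotype", "age_months", "total_area_pct", "fibrillar_area_pct"]

_SCHEMAS: Mapping[str, list[str]] = {"pet": PET_COLUMNS, "ihc": IHC_COLUMNS}

WILD_TYPE = "wild_type"


def derive_nonfibrillar(total_area_pct, fibrillar_area_pct):
    """Nonfibrillar coverage = total coverage - fibrillar coverage.

    Exact subtraction in percent of field area; inputs where fibrillar
    exceeds total raise :class:`ValidationError` rather than being clipped.
    Accepts scalars or array-likes.
    """
    total = np.asarray(total_area_pct, dtype=float)
    fib = np.asarray(fibrillar_area_pct, dtype=float)
    if np.any(total < 0) or np.any(total > 100) or np.any(fib < 0) or np.any(fib > 100):
        raise ValidationError("area coverages must lie in [0, 100] percent")
    if np.any(fib > total):
        raise ValidationError("fibrillar coverage exceeds total coverage")
    out = total - fib
    return out if out.ndim else float(out)


def _require_columns(df: pd.DataFrame, schema: str) -> list[str]:
    try:
        cols = _SCHEMAS[schema]
    except KeyError:
        raise SchemaError(f"unknown schema {schema!r}; expected 'pet' or 'ihc'") from None
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema} table is missing columns: {missing}")
    return cols


def validate_cohort(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    """Validate a cohort table and (for IHC) derive nonfibrillar coverage.

    Offending rows are reported with their positional row number and
    mouse id.  Returns a copy restricted to the schema's columns plus,
    for IHC, ``nonfibrillar_area_pct``.
    """
    cols = _require_columns(df, schema)
    out = df.loc[:, cols].copy()
    out["age_months"] = pd.to_numeric(out["age_months"]).astype(float)
    bad: list[str] = []

    def flag(mask: pd.Series, why: str) -> None:
        for pos in np.flatnonzero(mask.to_numpy()):
            bad.append(f"row {pos} (mouse {out['mouse_id'].iloc[pos]}): {why}")

    flag(out["age_months"] <= 0, "age_months must be positive")
    if schema == "pet":
        out["suvr"] = pd.to_numeric(out["suvr"])
        flag(out["suvr"] <= 0, "suvr must be positive")
        dup = out.duplicated(subset=["mouse_id", "age_months", "reference_region"], keep=False)
        flag(dup & ~dup.duplicated(), "duplicate (mouse_id, age_months) observation")
    else:
        for c in ("total_area_pct", "fibrillar_area_pct"):
            out[c] = pd.to_numeric(out[c])
            flag((out[c] < 0) | (out[c] > 100), f"{c} outside [0, 100]")
        flag(out["fibrillar_area_pct"] > out["total_area_pct"],
             "fibrillar coverage exceeds total coverage")
    if bad:
        raise ValidationError("invalid rows:\n  " + "\n  ".join(bad))
    if schema == "ihc":
        out["nonfibrillar_area_pct"] = out["total_area_pct"] - out["fibrillar_area_pct"]
    return out


def read_cohort(path, schema: str) -> pd.DataFrame:
    """Read and validate a comma-delimited cohort table.

    Lines starting with ``#`` (provenance headers written by
    :func:`write_cohort`) are ignored.
    """
    df = pd.read_csv(path, comment="#")
    return validate_cohort(df, schema)


def write_cohort(df: pd.DataFrame, path, schema: str, provenance: str | None = None) -> None:
    """Write a cohort table with an optional ``#``-prefixed provenance line.

    The derived ``nonfibrillar_area_pct`` column is never written; it is
    re-derived on read.
    """
    cols = _require_columns(df, schema)
    buf = io.StringIO()
    if provenance:
        buf.write(f"# {provenance}\n")
    df.loc[:, cols].to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def compute_z(suvr: float, wt_suvrs: Sequence[float]) -> dict:
    """Standardize one SUVR against wild-type control SUVRs.

    Returns ``{"value", "wt_mean", "wt_sd"}`` where
    ``value = (suvr - wt_mean) / wt_sd`` and ``wt_sd`` uses the n-1
    denominator.
    """
    wt = np.asarray(list(wt_suvrs), dtype=float)
    if wt.size < 2:
        raise InsufficientControlsError(f"need >=2 wild-type controls, got {wt.size}")
    wt_mean = float(wt.mean())
    wt_sd = float(wt.std(ddof=1))
    if wt_sd == 0.0:
        raise DegenerateControlsError("wild-type controls have zero standard deviation")
    return {"value": (float(suvr) - wt_mean) / wt_sd, "wt_mean": wt_mean, "wt_sd": wt_sd}


def z_score_cohort(pet: pd.DataFrame, wt: pd.DataFrame, age_matched: bool = False) -> pd.DataFrame:
    """Attach a ``z`` column to a PET cohort table.

    Each observation is standardized against the wild-type observations that
    share its ``reference_region`` (and, when ``age_matched``, its integer
    age).  Wild-type rows present in ``pet`` itself are ignored.
    """
    pet = validate_cohort(pet, "pet")
    wt = validate_cohort(wt, "pet")
    pet = pet[pet["genotype"] != WILD_TYPE].copy()
    z = np.empty(len(pet))
    for i, (_, row) in enumerate(pet.iterrows()):
        sel = wt["reference_region"] == row["reference_region"]
        if age_matched:
            sel &= wt["age_months"].round() == round(row["age_months"])
        controls = wt.loc[sel, "suvr"]
        if controls.size < 2:
            raise InsufficientControlsError(
                f"<2 wild-type controls for reference region {row['reference_region']!r}"
                + (f" at {row['age_months']} mo" if age_matched else "")
            )
        z[i] = compute_z(row["suvr"], controls)["value"]
    pet["z"] = z
    return pet


def group_summary(
    df: pd.DataFrame,
    value_cols: Iterable[str],
    by: Sequence[str] = ("genotype", "age_months"),
) -> pd.DataFrame:
    """Per-stratum mean, sample sd (n-1) and n for each value column.

    Strata with a single observation carry ``sd = NaN`` and are flagged in
    the ``sd_undefined`` column.
    """
    value_cols = list(value_cols)
    if df.empty:
        raise MissingStratumError("no observations to summarize")
    g = df.groupby(list(by), sort=True)
    out = g[value_cols].agg(["mean", lambda s: s.std(ddof=1), "count"])
    out.columns = [f"{v}_{stat}" for v, stat in
                   ((v, s) for v in value_cols for s in ("mean", "sd", "n"))]
    out = out.reset_index()
    out["sd_undefined"] = out[f"{value_cols[0]}_n"] == 1
    return out


def unpaired_t_test(a: Sequence[float], b: Sequence[float]) -> dict:
    """Classical pooled-variance (Student) two-sample t test, two-sided.

    Returns ``{"t", "df", "p"}``.  Both groups must have n >= 2.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("both groups need n >= 2 for a t test")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return {"t": float(t), "df": int(a.size + b.size - 2), "p": float(p)}
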