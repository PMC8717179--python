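"""Signal attribution, prediction for independent cohorts, and group-line gap.

Under the fitted linear model the plaque-derived part of a PET z-score is
``b_fib * F + b_nonfib * N`` (intercept and age terms are not plaque signal),
so the nonfibrillar share of the signal is

    nonfibrillar_share = b_nonfib * N / (b_fib * F + b_nonfib * N)

and the fibrillar share its complement.  Shares are computed per IHC mouse
and summarized per genotype (the +/- dispersion is the sd over mice, pooled
across ages by default).

``predict_z`` applies fitted coefficients to independent coverage data,
either with both plaque components ("full") or with the nonfibrillar term
dropped ("fibrillar_only"); ``validation_bias`` compares both predictions
with the measured z of an independent PET cohort, stratum by stratum.

``group_line_gap`` reproduces the group-level analysis: one regression line
per genotype through its per-age (predictor mean, z mean) points; the signed
mean vertical gap between the two lines over a shared predictor range indexes
how strongly PET over- or under-states pathology in one model relative to
the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingStratumError, ValidationError
from .regression import CoefficientSummary, LinearZModel

STRATUM = ["genotype", "age_months"]


def _coefficients(source) -> dict:
    """Extract {fibrillar, nonfibrillar, intercept, age?} from any source."""
    if isinstance(source, CoefficientSummary):
        return {"fibrillar": source.b_fib_mean, "nonfibrillar": source.b_nonfib_mean,
                "intercept": 0.0}
    if isinstance(source, LinearZModel):
        return {**source.coefficients_, "intercept": source.intercept_}
    out = dict(source)
    out.setdefault("intercept", 0.0)
    return out


def contribution_shares(fibrillar_area_pct, nonfibrillar_area_pct, coefficients):
    """Fibrillar and nonfibrillar fractional shares of the plaque signal.

    Accepts scalars or arrays; ``coefficients`` may be a
    :class:`CoefficientSummary`, a fitted model, or a mapping.  Where both
    signal components are zero the shares are NaN (undefined, flagged by the
    caller).  Returns ``(fibrillar_share, nonfibrillar_share)``.
    """
    c = _coefficients(coefficients)
    F = np.asarray(fibrillar_area_pct, dtype=float)
    N = np.asarray(nonfibrillar_area_pct, dtype=float)
    if np.any(F < 0) or np.any(N < 0):
        raise ValidationError("coverages must be nonnegative")
    fib_sig = c["fibrillar"] * F
    nonfib_sig = c["nonfibrillar"] * N
    total = fib_sig + nonfib_sig
    with np.errstate(invalid="ignore", divide="ignore"):
        nonfib_share = np.where(total > 0, nonfib_sig / np.where(total > 0, total, 1.0), np.nan)
    fib_share = 1.0 - nonfib_share
    if fib_share.ndim:
        return fib_share, nonfib_share
    return float(fib_share), float(nonfib_share)


@dataclass
class ContributionEstimate:
    """Mean fractional shares for one genotype (optionally one age)."""

    genotype: str
    age_months: float  # NaN when pooled across ages
    fibrillar_share: float
    nonfibrillar_share: float
    dispersion: float  # sd of per-mouse nonfibrillar shares
    n_mice: int


def contribution_table(ihc: pd.DataFrame, coefficients, per_age: bool = False
                       ) -> pd.DataFrame:
    """Per-genotype (or per genotype x age) contribution shares over IHC mice.

    ``dispersion`` is the sample sd of the per-mouse nonfibrillar share —
    pooled across ages by default, per age with ``per_age=True``.
    """
    fib_share, nonfib_share = contribution_shares(
        ihc["fibrillar_area_pct"], ihc["nonfibrillar_area_pct"], coefficients)
    work = ihc.loc[:, STRATUM].copy()
    work["fibrillar_share"] = fib_share
    work["nonfibrillar_share"] = nonfib_share
    keys = STRATUM if per_age else ["genotype"]
    rows = []
    for key, grp in work.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        rows.append(ContributionEstimate(
            genotype=key[0],
            age_months=float(key[1]) if per_age else float("nan"),
            fibrillar_share=float(grp["fibrillar_share"].mean()),
            nonfibrillar_share=float(grp["nonfibrillar_share"].mean()),
            dispersion=float(grp["nonfibrillar_share"].std(ddof=1)) if len(grp) > 1 else np.nan,
            n_mice=len(grp),
        ))
    return pd.DataFrame([vars(r) for r in rows])


def predict_z(fibrillar_area_pct, nonfibrillar_area_pct, age_months=None,
              coefficients=None, mode: str = "full"):
    """Predicted PET z-score from coverage (and optionally age).

    ``mode="full"`` uses intercept + b_fib*F + b_nonfib*N (+ age term when the
    source carries one and ``age_months`` is given); ``mode="fibrillar_only"``
    drops the nonfibrillar term with everything else unchanged.
    """
    if mode not in ("full", "fibrillar_only"):
        raise ValidationError("mode must be 'full' or 'fibrillar_only'")
    c = _coefficients(coefficients)
    for needed in ("fibrillar",) + (("nonfibrillar",) if mode == "full" else ()):
        if needed not in c:
            raise ValidationError(f"missing coefficient {needed!r}")
    F = np.asarray(fibrillar_area_pct, dtype=float)
    N = np.asarray(nonfibrillar_area_pct, dtype=float)
    z = c["intercept"] + c["fibrillar"] * F
    if mode == "full":
        z = z + c["nonfibrillar"] * N
    if "age" in c:
        if age_months is None:
            raise ValidationError("model includes an age term; pass age_months")
        z = z + c["age"] * np.asarray(age_months, dtype=float)
    return z if np.ndim(z) else float(z)


@dataclass
class BiasReport:
    """Prediction bias for one (genotype, age) validation stratum."""

    genotype: str
    age_months: float
    actual_z: float
    predicted_z_full: float
    predicted_z_fibrillar_only: float
    deviation_full: float
    deviation_fibrillar_only: float


def validation_bias(validation_pet_z: pd.DataFrame, validation_ihc: pd.DataFrame,
                    coefficients) -> pd.DataFrame:
    """Compare predicted and measured z on an independent cohort, per stratum.

    Predictions use stratum-mean coverages (PET and IHC mice are different
    animals); the measured value is the stratum-mean z.  Raises
    :class:`MissingStratumError` listing strata present in only one table.
    """
    if validation_ihc.empty or validation_pet_z.empty:
        raise MissingStratumError("validation PET and IHC tables must be non-empty")
    pet_means = validation_pet_z.groupby(STRATUM)["z"].mean()
    ihc_means = validation_ihc.groupby(STRATUM)[
        ["fibrillar_area_pct", "nonfibrillar_area_pct"]].mean()
    missing = sorted(set(pet_means.index) ^ set(ihc_means.index))
    if missing:
        raise MissingStratumError(f"strata present in only one modality: {missing}")
    rows = []
    for (genotype, age), z_actual in pet_means.items():
        cov = ihc_means.loc[(genotype, age)]
        args = (cov["fibrillar_area_pct"], cov["nonfibrillar_area_pct"], age, coefficients)
        z_full = predict_z(*args, mode="full")
        z_fib = predict_z(*args, mode="fibrillar_only")
        rows.append(BiasReport(
            genotype=genotype, age_months=float(age), actual_z=float(z_actual),
            predicted_z_full=float(z_full), predicted_z_fibrillar_only=float(z_fib),
            deviation_full=float(z_full - z_actual),
            deviation_fibrillar_only=float(z_fib - z_actual),
        ))
    return pd.DataFrame([vars(r) for r in rows])


@dataclass
class GroupLineGap:
    """Signed mean vertical gap between two per-genotype regression lines."""

    slope_a: float
    intercept_a: float
    slope_b: float
    intercept_b: float
    x_range: tuple[float, float]
    gap_index: float  # mean signed gap (line_a - line_b) over x_range, z units
    raw_area: float   # gap_index * range width (signed area between lines)


def group_line_gap(groups_a: pd.DataFrame, groups_b: pd.DataFrame,
                   x_col: str, y_col: str = "z",
                   x_range: str = "intersection") -> GroupLineGap:
    """Fit one line per genotype through its per-age group means; integrate.

    ``groups_a``/``groups_b`` hold one row per age with columns ``x_col``
    (predictor group mean) and ``y_col`` (z group mean).  The signed mean gap
    is (1/W) * integral of (line_a - line_b) over the chosen x range — the
    ``"intersection"`` (default) or ``"union"`` of the two observed ranges.
    Crossing lines may cancel to a gap of 0 by design.
    """
    for name, g in (("a", groups_a), ("b", groups_b)):
        if len(g) < 2:
            raise ValidationError(f"group {name} needs means at >=2 ages")
    slope_a, int_a = np.polyfit(groups_a[x_col], groups_a[y_col], 1)
    slope_b, int_b = np.polyfit(groups_b[x_col], groups_b[y_col], 1)
    ra = (groups_a[x_col].min(), groups_a[x_col].max())
    rb = (groups_b[x_col].min(), groups_b[x_col].max())
    if x_range == "intersection":
        lo, hi = max(ra[0], rb[0]), min(ra[1], rb[1])
    elif x_range == "union":
        lo, hi = min(ra[0], rb[0]), max(ra[1], rb[1])
    else:
        raise ValidationError("x_range must be 'intersection' or 'union'")
    width = hi - lo
    if width <= 0:
        raise ValidationError("degenerate predictor range: the group ranges do not overlap")
    mid = (lo + hi) / 2.0
    gap = (slope_a - slope_b) * mid + (int_a - int_b)  # mean of a linear gap
    return GroupLineGap(
        slope_a=float(slope_a), intercept_a=float(int_a),
        slope_b=float(slope_b), intercept_b=float(int_b),
        x_range=(float(lo), float(hi)),
        gap_index=float(gap), raw_area=float(gap * width),
    )
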