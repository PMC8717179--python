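"""Nested linear models of the PET z-score and their bootstrap CIs.

The central object is :class:`LinearZModel`, a scikit-learn style estimator
that regresses the PET z-score of a paired table on a chosen subset of

* ``fibrillar``       — percent area covered by fibrillar plaque,
* ``nonfibrillar``    — percent area covered by nonfibrillar plaque,
* ``heterogeneity``   — the mouse's deviation from its group-mean z,
* ``age``             — age at scanning in months,

always with an intercept.  :func:`fit_ladder` fits the canonical ladder of
five nested specifications (fibrillar alone, nonfibrillar alone, both, both
plus heterogeneity, both plus heterogeneity and age).  Coefficients are in
z-score units per predictor unit, so ``b_fibrillar`` reads "z units per 1%
fibrillar area covered".

Confidence intervals are percentile bootstrap intervals (default 1000
resamples).  Because each paired row duplicates one PET observation across
several IHC mice and vice versa, plain row resampling understates the
uncertainty; the resampling unit is therefore selectable:

* ``"row"``        — iid rows (the simplest reading; default),
* ``"pet-mouse"``  — clusters of rows sharing a PET mouse,
* ``"ihc-mouse"``  — clusters sharing an IHC mouse,
* ``"crossed"``    — two-way (pigeonhole) resampling of PET mice and IHC
  mice jointly, the appropriate scheme for this crossed design.

The heterogeneity covariate is data-derived, so by default it is recomputed
inside every resample from the resampled z values.

The headline quantity of the analysis is the *model-averaged* pair of
coefficients across the two most complete models, summarized by
:func:`summarize_coefficients` into a fold ratio with an opposite-CI-edge
range; :func:`bootstrap_model_average` gives the averaged coefficients a
coherent bootstrap CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import SingularDesignError, ValidationError

PREDICTOR_COLUMNS = {
    "fibrillar": "fibrillar_area_pct",
    "nonfibrillar": "nonfibrillar_area_pct",
    "heterogeneity": "heterogeneity",
    "age": "age_months",
}

#: The five nested model specifications, in report order.
LADDER: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("fibrillar", ("fibrillar",)),
    ("nonfibrillar", ("nonfibrillar",)),
    ("fibrillar × nonfibrillar", ("fibrillar", "nonfibrillar")),
    ("fibrillar × nonfibrillar × heterogeneity",
     ("fibrillar", "nonfibrillar", "heterogeneity")),
    ("fibrillar × nonfibrillar × heterogeneity × age",
     ("fibrillar", "nonfibrillar", "heterogeneity", "age")),
)

_FULL_SPECS = (LADDER[3][1], LADDER[4][1])  # the two most complete models


def _design(X: pd.DataFrame, predictors: tuple[str, ...]) -> np.ndarray:
    cols = []
    for p in predictors:
        col = PREDICTOR_COLUMNS.get(p, p)
        if col not in X.columns:
            raise ValidationError(f"paired table lacks column {col!r} for predictor {p!r}")
        cols.append(X[col].to_numpy(dtype=float))
    return np.column_stack([np.ones(len(X))] + cols)


def _check_rank(M: np.ndarray, predictors: tuple[str, ...], cond_threshold: float) -> None:
    if np.linalg.matrix_rank(M) < M.shape[1] or np.linalg.cond(M) > cond_threshold:
        # name the offending predictors: those whose removal restores conditioning
        guilty = []
        for i, p in enumerate(predictors):
            sub = np.delete(M, i + 1, axis=1)
            if np.linalg.matrix_rank(sub) == sub.shape[1] and np.linalg.cond(sub) <= cond_threshold:
                guilty.append(p)
        raise SingularDesignError(
            "design matrix is rank deficient or ill conditioned"
            + (f"; collinear predictors: {guilty}" if guilty else ""))


class LinearZModel(RegressorMixin, BaseEstimator):
    """OLS of PET z-score on plaque coverage and covariates.

    Parameters
    ----------
    predictors
        Ordered subset of ``{"fibrillar", "nonfibrillar", "heterogeneity",
        "age"}``.  An intercept is always included.
    cond_threshold
        Relative condition-number limit above which the design is declared
        singular.

    Attributes (after ``fit``)
    --------------------------
    coef_ : ndarray, coefficients in ``predictors`` order.
    intercept_ : float.
    coefficients_ : dict mapping predictor name to coefficient.
    r2_, adjusted_r2_ : coefficient of determination and its small-sample
        correction.
    pvalues_ : dict of per-coefficient two-sided t-test p-values.
    f_pvalue_ : p-value of the overall model F test.
    n_rows_ : number of rows used.
    residuals_ : ndarray of fit residuals.
    """

    def __init__(self, predictors: tuple[str, ...] = ("fibrillar", "nonfibrillar"),
                 cond_threshold: float = 1e10):
        self.predictors = predictors
        self.cond_threshold = cond_threshold

    def fit(self, X: pd.DataFrame, y=None) -> "LinearZModel":
        predictors = tuple(self.predictors)
        if not predictors:
            raise ValidationError("at least one predictor is required")
        if y is None:
            if "z" not in X.columns:
                raise ValidationError("y omitted and paired table lacks a 'z' column")
            y = X["z"]
        y = np.asarray(y, dtype=float)
        M = _design(X, predictors)
        if len(y) <= M.shape[1]:
            raise ValidationError(
                f"need more rows ({len(y)}) than parameters ({M.shape[1]})")
        # An identically-zero covariate (e.g. heterogeneity in the noiseless
        # limit, where every mouse sits on its group mean) carries no
        # information: it is excluded from estimation and its coefficient
        # pinned to 0.  Constant *nonzero* columns remain collinear with the
        # intercept and raise SingularDesignError below.
        keep = [0] + [i for i in range(1, M.shape[1])
                      if np.max(np.abs(M[:, i])) > 1e-9]
        kept_names = tuple(predictors[i - 1] for i in keep[1:])
        Mk = M[:, keep]
        _check_rank(Mk, kept_names, self.cond_threshold)
        res = sm.OLS(y, Mk).fit()
        params = np.zeros(M.shape[1])
        params[keep] = res.params
        pvals = np.full(M.shape[1], np.nan)
        pvals[keep] = res.pvalues
        self.result_ = res
        self.intercept_ = float(params[0])
        self.coef_ = params[1:]
        self.coefficients_ = dict(zip(predictors, self.coef_))
        self.r2_ = float(res.rsquared)
        self.adjusted_r2_ = float(res.rsquared_adj)
        self.pvalues_ = dict(zip(predictors, pvals[1:]))
        self.f_pvalue_ = float(res.f_pvalue)
        self.n_rows_ = int(res.nobs)
        self.residuals_ = np.asarray(res.resid, dtype=float)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return _design(X, tuple(self.predictors)) @ np.concatenate(
            [[self.intercept_], self.coef_])


def fit_ols(pairs: pd.DataFrame, predictors: tuple[str, ...]) -> LinearZModel:
    """Fit one OLS specification on a paired table (thin estimator wrapper)."""
    return LinearZModel(predictors=tuple(predictors)).fit(pairs)


def fit_ladder(pairs: pd.DataFrame) -> list[tuple[str, LinearZModel]]:
    """Fit the five nested specifications in canonical report order."""
    return [(name, fit_ols(pairs, spec)) for name, spec in LADDER]


@dataclass
class BootstrapCI:
    """Percentile bootstrap confidence intervals for one model."""

    ci: dict[str, tuple[float, float]]
    n_boot: int
    seed: int
    unit: str
    level: float = 0.95
    n_redrawn: int = 0


def _unit_codes(pairs: pd.DataFrame, unit: str) -> tuple[np.ndarray, ...]:
    if unit == "row":
        return (np.arange(len(pairs)),)
    if unit == "pet-mouse":
        return (pd.factorize(
            pairs["pet_mouse_id"].astype(str) + "/" + pairs["genotype"].astype(str))[0],)
    if unit == "ihc-mouse":
        return (pd.factorize(
            pairs["ihc_mouse_id"].astype(str) + "/" + pairs["genotype"].astype(str))[0],)
    if unit == "crossed":
        return (_unit_codes(pairs, "pet-mouse")[0], _unit_codes(pairs, "ihc-mouse")[0])
    raise ValidationError(
        "bootstrap unit must be one of 'row', 'pet-mouse', 'ihc-mouse', 'crossed'")


def _resample_weights(rng: np.random.Generator, codes: tuple[np.ndarray, ...]) -> np.ndarray:
    w = np.ones(len(codes[0]))
    for c in codes:
        k = c.max() + 1
        counts = np.bincount(rng.integers(0, k, k), minlength=k)
        w = w * counts[c]
    return w


def _weighted_coefs(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                    het_col: int | None, z: np.ndarray | None,
                    strat: np.ndarray | None) -> np.ndarray | None:
    """Weighted OLS coefficients for one resample; None if degenerate.

    When ``het_col`` is given, the heterogeneity column is recomputed as the
    resample-weighted within-stratum centering of z before fitting.
    """
    if het_col is not None:
        nstrat = strat.max() + 1
        den = np.bincount(strat, weights=w, minlength=nstrat)
        den[den == 0] = 1.0  # strata with zero resample weight carry no rows
        num = np.bincount(strat, weights=w * z, minlength=nstrat)
        X = X.copy()
        X[:, het_col] = z - (num / den)[strat]
    active = w > 0
    keep = [0] + [j for j in range(1, X.shape[1])
                  if np.max(np.abs(X[active, j]), initial=0.0) > 1e-9]
    Xk = X[:, keep]
    Xw = Xk * w[:, None]
    G = Xw.T @ Xk
    if np.linalg.cond(G) > 1e12:
        return None
    b = np.zeros(X.shape[1])
    b[keep] = np.linalg.solve(G, Xw.T @ y)
    return b


def _bootstrap(pairs: pd.DataFrame, specs: list[tuple[str, ...]], n_boot: int,
               seed: int, unit: str, recompute_heterogeneity: bool,
               combine) -> tuple[np.ndarray, int]:
    """Shared bootstrap loop.

    ``combine(list_of_coef_arrays) -> 1d array`` maps the per-spec coefficient
    vectors (without intercept) of one resample to the statistic of interest.
    Returns the (n_boot, dim) matrix of statistics and the redraw count.
    """
    rng = np.random.default_rng(seed)
    y = pairs["z"].to_numpy(dtype=float)
    strat = pd.factorize(
        pairs["genotype"].astype(str) + "/" + pairs["age_months"].astype(str))[0]
    designs = []
    for spec in specs:
        X = _design(pairs, spec)
        het = (spec.index("heterogeneity") + 1
               if recompute_heterogeneity and "heterogeneity" in spec else None)
        designs.append((X, het))
    codes = _unit_codes(pairs, unit)
    out = []
    n_redrawn = 0
    attempts = 0
    while len(out) < n_boot:
        attempts += 1
        if attempts > 20 * n_boot:
            raise SingularDesignError("too many rank-deficient bootstrap resamples")
        w = _resample_weights(rng, codes)
        coefs = []
        for X, het in designs:
            b = _weighted_coefs(X, y, w, het, y if het is not None else None, strat)
            if b is None:
                coefs = None
                break
            coefs.append(b[1:])
        if coefs is None:
            n_redrawn += 1
            continue
        out.append(combine(coefs))
    if n_redrawn > 0.1 * n_boot:
        warnings.warn(f"{n_redrawn} of {n_boot} bootstrap resamples were rank "
                      "deficient and redrawn", stacklevel=3)
    return np.asarray(out), n_redrawn


def bootstrap_ci(pairs: pd.DataFrame, predictors: tuple[str, ...],
                 n_boot: int = 1000, seed: int = 0, unit: str = "row",
                 level: float = 0.95,
                 recompute_heterogeneity: bool = True) -> BootstrapCI:
    """Percentile bootstrap CI for every coefficient of one specification."""
    predictors = tuple(predictors)
    stats, n_redrawn = _bootstrap(pairs, [predictors], n_boot, seed, unit,
                                  recompute_heterogeneity, lambda cs: cs[0])
    alpha = 100 * (1 - level) / 2
    lo, hi = np.percentile(stats, [alpha, 100 - alpha], axis=0)
    return BootstrapCI(
        ci={p: (float(lo[i]), float(hi[i])) for i, p in enumerate(predictors)},
        n_boot=n_boot, seed=seed, unit=unit, level=level, n_redrawn=n_redrawn)


def bootstrap_model_average(pairs: pd.DataFrame,
                            specs: tuple[tuple[str, ...], ...] = _FULL_SPECS,
                            n_boot: int = 1000, seed: int = 0,
                            unit: str = "crossed", level: float = 0.95,
                            recompute_heterogeneity: bool = True) -> BootstrapCI:
    """CI for the model-averaged fibrillar/nonfibrillar coefficients.

    Within each resample every spec in ``specs`` is refit and the fibrillar
    and nonfibrillar coefficients are averaged across specs; the percentile
    interval of those averages is returned.
    """
    idx = [(spec.index("fibrillar"), spec.index("nonfibrillar")) for spec in specs]

    def combine(coefs):
        return np.array([
            np.mean([c[i_f] for c, (i_f, _) in zip(coefs, idx)]),
            np.mean([c[i_n] for c, (_, i_n) in zip(coefs, idx)]),
        ])

    stats, n_redrawn = _bootstrap(pairs, list(specs), n_boot, seed, unit,
                                  recompute_heterogeneity, combine)
    alpha = 100 * (1 - level) / 2
    lo, hi = np.percentile(stats, [alpha, 100 - alpha], axis=0)
    return BootstrapCI(
        ci={"fibrillar": (float(lo[0]), float(hi[0])),
            "nonfibrillar": (float(lo[1]), float(hi[1]))},
        n_boot=n_boot, seed=seed, unit=unit, level=level, n_redrawn=n_redrawn)


@dataclass
class CoefficientSummary:
    """Model-averaged coefficients and the fold ratio of their contributions.

    ``fold_range`` is the (low, high) range obtained from the opposite edges
    of the per-model 95% CIs: low averages B_fib_lower / B_nonfib_upper over
    the models, high averages B_fib_upper / B_nonfib_lower.
    """

    b_fib_mean: float
    b_nonfib_mean: float
    fold_ratio: float = field(init=False)
    fold_range: tuple[float, float] = (np.nan, np.nan)

    def __post_init__(self) -> None:
        if self.b_nonfib_mean == 0:
            raise ValidationError("fold ratio undefined: nonfibrillar coefficient is 0")
        self.fold_ratio = self.b_fib_mean / self.b_nonfib_mean

    def rounded(self) -> dict:
        """Presentation rounding: B to 2 decimals, folds to whole numbers."""
        return {
            "b_fib_mean": round(self.b_fib_mean, 2),
            "b_nonfib_mean": round(self.b_nonfib_mean, 2),
            "fold_ratio": round(self.fold_ratio),
            "fold_low": round(self.fold_range[0]),
            "fold_high": round(self.fold_range[1]),
        }

    def to_dict(self) -> dict:
        return {"b_fib_mean": self.b_fib_mean, "b_nonfib_mean": self.b_nonfib_mean,
                "fold_ratio": self.fold_ratio, "fold_range": list(self.fold_range)}


def _coef_of(model, name: str) -> float:
    coeffs = model.coefficients_ if hasattr(model, "coefficients_") else model
    try:
        return float(coeffs[name])
    except KeyError:
        raise ValidationError(f"model lacks a {name!r} coefficient") from None


def _ci_of(ci, name: str) -> tuple[float, float]:
    mapping = ci.ci if isinstance(ci, BootstrapCI) else ci
    try:
        lo, hi = mapping[name]
    except KeyError:
        raise ValidationError(f"confidence intervals lack {name!r}") from None
    return float(lo), float(hi)


def summarize_coefficients(models, cis) -> CoefficientSummary:
    """Average fibrillar/nonfibrillar coefficients across models.

    Parameters
    ----------
    models
        Sequence of fitted :class:`LinearZModel` (or plain mappings
        predictor -> coefficient), normally the two most complete models.
    cis
        Matching sequence of :class:`BootstrapCI` (or mappings
        predictor -> (lower, upper)).

    The fold range averages, over models, the quotients of opposite CI
    edges: lower = B_fib_lo / B_nonfib_hi, upper = B_fib_hi / B_nonfib_lo.
    """
    models = list(models)
    cis = list(cis)
    if len(models) != len(cis) or not models:
        raise ValidationError("need one CI set per model")
    b_fib = [_coef_of(m, "fibrillar") for m in models]
    b_nonfib = [_coef_of(m, "nonfibrillar") for m in models]
    lows, highs = [], []
    for c in cis:
        f_lo, f_hi = _ci_of(c, "fibrillar")
        n_lo, n_hi = _ci_of(c, "nonfibrillar")
        if n_lo <= 0 or n_hi <= 0:
            raise ValidationError("nonfibrillar CI touches zero: fold range undefined")
        lows.append(f_lo / n_hi)
        highs.append(f_hi / n_lo)
    summary = CoefficientSummary(
        b_fib_mean=float(np.mean(b_fib)),
        b_nonfib_mean=float(np.mean(b_nonfib)),
        fold_range=(float(np.mean(lows)), float(np.mean(highs))),
    )
    return summary
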