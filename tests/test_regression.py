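import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import petdecomp as pdc
from petdecomp.errors import SingularDesignError, ValidationError
from petdecomp.regression import LADDER


def _pairs_from_arrays(F, N, z, het=None, age=None):
    n = len(z)
    return pd.DataFrame({
        "pet_mouse_id": [f"p{i}" for i in range(n)],
        "ihc_mouse_id": [f"i{i}" for i in range(n)],
        "genotype": ["g"] * n,
        "age_months": age if age is not None else [3.0] * n,
        "z": z,
        "fibrillar_area_pct": F,
        "nonfibrillar_area_pct": N,
        "heterogeneity": het if het is not None else np.zeros(n),
    })


def test_noiseless_interpolation_recovers_exact_coefficients():
    rng = np.random.default_rng(0)
    F, N = rng.uniform(0, 5, 30), rng.uniform(0, 15, 30)
    pairs = _pairs_from_arrays(F, N, 2.0 * F + 0.5 * N)
    m = pdc.fit_ols(pairs, ("fibrillar", "nonfibrillar"))
    assert m.coefficients_["fibrillar"] == pytest.approx(2.0, abs=1e-10)
    assert m.coefficients_["nonfibrillar"] == pytest.approx(0.5, abs=1e-10)
    assert m.intercept_ == pytest.approx(0.0, abs=1e-10)
    assert m.r2_ == pytest.approx(1.0, abs=1e-12)


def test_ols_matches_pseudoinverse_oracle_on_random_designs():
    """Coefficients agree with a normal-equations pseudoinverse solution."""
    rng = np.random.default_rng(42)
    for _ in range(25):
        n = rng.integers(8, 50)
        F, N = rng.uniform(0, 5, n), rng.uniform(0, 12, n)
        het, age = rng.normal(0, 1, n), rng.choice([3.0, 6.0, 12.0], n)
        z = rng.normal(0, 2, n) + 3 * F + 0.2 * N
        pairs = _pairs_from_arrays(F, N, z, het, age)
        preds = ("fibrillar", "nonfibrillar", "heterogeneity", "age")
        k = rng.integers(1, 5)
        spec = preds[:k]
        m = pdc.fit_ols(pairs, spec)
        X = np.column_stack([np.ones(n)] + [pairs[pdc.regression.PREDICTOR_COLUMNS[p]]
                                            for p in spec])
        beta = np.linalg.pinv(X) @ z
        assert m.intercept_ == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(m.coef_, beta[1:], atol=1e-8)


def test_constant_predictor_raises_singular_design_error():
    pairs = _pairs_from_arrays(np.full(10, 2.0), np.arange(10.0), np.arange(10.0))
    with pytest.raises(SingularDesignError, match="fibrillar"):
        pdc.fit_ols(pairs, ("fibrillar",))


def test_all_zero_heterogeneity_is_pinned_not_singular():
    """In the noiseless limit heterogeneity is identically 0; the ladder's
    larger models must still fit, with that coefficient reported as 0."""
    rng = np.random.default_rng(1)
    F, N = rng.uniform(0, 5, 20), rng.uniform(0, 12, 20)
    pairs = _pairs_from_arrays(F, N, 3.0 * F + 0.25 * N)
    m = pdc.fit_ols(pairs, ("fibrillar", "nonfibrillar", "heterogeneity"))
    assert m.coefficients_["heterogeneity"] == 0.0
    assert m.r2_ == pytest.approx(1.0, abs=1e-12)


def test_ladder_labels_and_nested_r2_monotonicity(default_study):
    fits = pdc.fit_ladder(default_study["pairs"])
    assert [name for name, _ in fits] == [name for name, _ in LADDER]
    r2 = [m.r2_ for _, m in fits]
    assert r2[2] <= r2[3] + 1e-12 and r2[3] <= r2[4] + 1e-12
    assert r2[3] > r2[2]  # heterogeneity_sd > 0 in the default study
    adj = [m.adjusted_r2_ for _, m in fits]
    assert all(a <= r + 1e-12 for a, r in zip(adj, r2))
    assert all(abs(m.residuals_.sum()) < 1e-8 for _, m in fits)


def test_estimator_is_sklearn_compatible(default_study):
    m = pdc.LinearZModel(predictors=("fibrillar", "nonfibrillar"))
    assert clone(m).get_params()["predictors"] == ("fibrillar", "nonfibrillar")
    pairs = default_study["pairs"]
    m.fit(pairs, pairs["z"])
    score = m.score(pairs, pairs["z"])  # RegressorMixin R^2
    assert score == pytest.approx(m.r2_)
    assert len(m.predict(pairs)) == len(pairs)


@pytest.mark.parametrize("unit", ["row", "pet-mouse", "ihc-mouse", "crossed"])
def test_bootstrap_is_deterministic_per_seed(default_study, unit):
    pairs = default_study["pairs"]
    a = pdc.bootstrap_ci(pairs, ("fibrillar", "nonfibrillar"), n_boot=50,
                         seed=3, unit=unit)
    b = pdc.bootstrap_ci(pairs, ("fibrillar", "nonfibrillar"), n_boot=50,
                         seed=3, unit=unit)
    assert a.ci == b.ci
    c = pdc.bootstrap_ci(pairs, ("fibrillar", "nonfibrillar"), n_boot=50,
                         seed=4, unit=unit)
    assert a.ci != c.ci


def test_bootstrap_ci_width_zero_on_noiseless_data(noiseless_study):
    pairs = noiseless_study["pairs"]
    ci = pdc.bootstrap_ci(pairs, ("fibrillar", "nonfibrillar", "heterogeneity"),
                          n_boot=50, seed=0, unit="crossed")
    for lo, hi in ci.ci.values():
        assert hi - lo == pytest.approx(0.0, abs=1e-9)


def test_bootstrap_ci_brackets_point_estimate(default_study):
    pairs = default_study["pairs"]
    spec = ("fibrillar", "nonfibrillar", "heterogeneity", "age")
    m = pdc.fit_ols(pairs, spec)
    ci = pdc.bootstrap_ci(pairs, spec, n_boot=200, seed=0, unit="crossed")
    for p in spec:
        lo, hi = ci.ci[p]
        assert lo <= m.coefficients_[p] <= hi


def test_bootstrap_ci_shrinks_with_sample_size():
    """Quadrupling both cohorts narrows the percentile CI (same truth/noise)."""
    import dataclasses

    def width(scale, seed):
        cfg = pdc.default_config(seed)
        cfg.profiles = [dataclasses.replace(
            p, n_pet_mice=p.n_pet_mice * scale,
            n_ihc_per_age=tuple(n * scale for n in p.n_ihc_per_age))
            for p in cfg.profiles]
        ihc = pdc.generate_ihc(cfg)
        pet, wt = pdc.generate_pet(cfg)
        pairs = pdc.build_pairs(
            pdc.compute_heterogeneity(pdc.z_score_cohort(pet, wt)), ihc)
        ci = pdc.bootstrap_ci(pairs, ("fibrillar", "nonfibrillar"),
                              n_boot=300, seed=0, unit="crossed")
        return {p: hi - lo for p, (lo, hi) in ci.ci.items()}, len(pairs)

    w1, n1 = width(1, 21)
    w4, n4 = width(4, 22)
    assert n4 > 10 * n1  # ~16x rows (enrollment rounding keeps it inexact)
    assert w4["fibrillar"] < w1["fibrillar"]
    assert w4["nonfibrillar"] < w1["nonfibrillar"]


def test_summary_from_published_coefficients():
    s = pdc.published_summary()
    assert s.rounded() == {"b_fib_mean": 3.17, "b_nonfib_mean": 0.20,
                           "fold_ratio": 16, "fold_low": 11, "fold_high": 26}
    assert s.fold_ratio == pytest.approx(s.b_fib_mean / s.b_nonfib_mean)
    assert s.fold_range[0] <= s.fold_ratio <= s.fold_range[1]


def test_summary_rejects_zero_nonfibrillar_coefficient():
    with pytest.raises(ValidationError):
        pdc.CoefficientSummary(b_fib_mean=3.0, b_nonfib_mean=0.0)
    with pytest.raises(ValidationError):
        pdc.summarize_coefficients(
            [{"fibrillar": 3.0, "nonfibrillar": 0.2}],
            [{"fibrillar": (2.0, 4.0), "nonfibrillar": (-0.1, 0.3)}])
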