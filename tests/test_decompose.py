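import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import petdecomp as pdc
from petdecomp.errors import MissingStratumError, ValidationError

from conftest import noiseless_config

COEFS = {"fibrillar": 3.17, "nonfibrillar": 0.20}


def test_share_limits_and_hand_value():
    fib, nonfib = pdc.contribution_shares(0.0, 2.0, COEFS)
    assert (fib, nonfib) == (0.0, 1.0)
    fib, nonfib = pdc.contribution_shares(1.0, 4.0, COEFS)
    assert nonfib == pytest.approx(0.8 / 3.97, abs=1e-4)
    assert fib + nonfib == pytest.approx(1.0)
    # equal shares exactly when b_fib*F == b_nonfib*N
    fib, nonfib = pdc.contribution_shares(1.0, 3.17 / 0.20, COEFS)
    assert fib == pytest.approx(0.5) and nonfib == pytest.approx(0.5)


def test_share_undefined_when_both_components_zero():
    fib, nonfib = pdc.contribution_shares(0.0, 0.0, COEFS)
    assert np.isnan(fib) and np.isnan(nonfib)


@given(c=st.floats(0.01, 100))
def test_shares_are_scale_invariant_in_the_coefficients(c):
    base = pdc.contribution_shares(2.0, 7.0, COEFS)
    scaled = pdc.contribution_shares(
        2.0, 7.0, {k: c * v for k, v in COEFS.items()})
    assert scaled[0] == pytest.approx(base[0], rel=1e-9)
    assert scaled[1] == pytest.approx(base[1], rel=1e-9)


def test_predict_z_identities():
    full = pdc.predict_z(2.0, 5.0, coefficients=COEFS, mode="full")
    fib_only = pdc.predict_z(2.0, 5.0, coefficients=COEFS, mode="fibrillar_only")
    assert full - fib_only == pytest.approx(0.20 * 5.0)
    assert pdc.predict_z(0.0, 0.0, coefficients=COEFS) == pytest.approx(0.0)
    with pytest.raises(ValidationError):
        pdc.predict_z(1.0, 1.0, coefficients={"nonfibrillar": 0.2})
    with pytest.raises(ValidationError):
        pdc.predict_z(1.0, 1.0, coefficients=COEFS, mode="both")


def test_noiseless_pipeline_closure():
    """simulate -> z-score -> pair -> fit -> predict reproduces z exactly."""
    cfg = noiseless_config(5)
    ihc = pdc.generate_ihc(cfg)
    pet, wt = pdc.generate_pet(cfg)
    pet_z = pdc.compute_heterogeneity(pdc.z_score_cohort(pet, wt))
    pairs = pdc.build_pairs(pet_z, ihc)
    m = pdc.fit_ols(pairs, ("fibrillar", "nonfibrillar"))
    assert m.coefficients_["fibrillar"] == pytest.approx(3.17, abs=1e-8)
    assert m.coefficients_["nonfibrillar"] == pytest.approx(0.20, abs=1e-8)
    pred = m.predict(pairs)
    np.testing.assert_allclose(pred, pairs["z"], atol=1e-8)


def test_validation_bias_prefers_full_model(default_study):
    """Coefficients fit on one cohort, applied to an independently generated
    cohort with the same truth: the fibrillar-only prediction under-predicts
    by exactly the nonfibrillar signal, the full prediction does not."""
    pairs = default_study["pairs"]
    fits = pdc.fit_ladder(pairs)
    cis = [pdc.bootstrap_ci(pairs, spec, n_boot=50, seed=0) for _, spec in
           (pdc.LADDER[3], pdc.LADDER[4])]
    summary = pdc.summarize_coefficients([fits[3][1], fits[4][1]], cis)

    cfg_b = pdc.default_config(1234)
    ihc_b = pdc.generate_ihc(cfg_b)
    pet_b, wt_b = pdc.generate_pet(cfg_b)
    pet_bz = pdc.z_score_cohort(pet_b, wt_b)
    bias = pdc.validation_bias(pet_bz, ihc_b, summary)
    assert len(bias) == 6
    assert (bias["deviation_full"].abs().mean()
            < bias["deviation_fibrillar_only"].abs().mean())
    # fibrillar-only systematically under-predicts by the nonfibrillar signal
    assert (bias["predicted_z_fibrillar_only"] < bias["predicted_z_full"]).all()


def test_validation_bias_errors():
    pet_z = pd.DataFrame({"genotype": ["a"], "age_months": [3.0], "z": [1.0]})
    with pytest.raises(MissingStratumError):
        pdc.validation_bias(pet_z, pd.DataFrame(
            columns=["genotype", "age_months", "fibrillar_area_pct",
                     "nonfibrillar_area_pct"]), COEFS)
    ihc = pd.DataFrame({"genotype": ["a", "b"], "age_months": [3.0, 3.0],
                        "fibrillar_area_pct": [1.0, 1.0],
                        "nonfibrillar_area_pct": [2.0, 2.0]})
    with pytest.raises(MissingStratumError, match="b"):
        pdc.validation_bias(pet_z, ihc, COEFS)


def test_trem2_scenario_raises_nonfibrillar_share_at_every_age():
    cfg = noiseless_config()
    base = cfg.profiles[0]
    ko = pdc.trem2_scenario(base, 0.5)
    cfg_ko = dataclasses.replace(cfg, profiles=[base, ko])
    ihc = pdc.generate_ihc(cfg_ko)
    shares = pdc.contribution_table(ihc, COEFS, per_age=True)
    wide = shares.pivot(index="age_months", columns="genotype",
                        values="nonfibrillar_share")
    assert (wide[ko.label] > wide[base.label]).all()


def test_fibrillar_only_bias_grows_with_nonfibrillar_burden():
    grid = np.linspace(0.0, 10.0, 6)
    dev = [pdc.predict_z(2.0, n, coefficients=COEFS, mode="fibrillar_only")
           - pdc.predict_z(2.0, n, coefficients=COEFS, mode="full") for n in grid]
    assert all(b - a < -1e-12 for a, b in zip(dev, dev[1:]))  # monotone down


def _groups(slope, intercept, xs):
    return pd.DataFrame({"x": xs, "z": [slope * x + intercept for x in xs]})


def test_group_line_gap_closed_forms():
    same = pdc.group_line_gap(_groups(1, 0, [0, 1, 2]), _groups(1, 0, [0, 2]), "x")
    assert same.gap_index == pytest.approx(0.0, abs=1e-12)
    offset = pdc.group_line_gap(_groups(1, 1, [0, 1, 2]), _groups(1, 0, [0, 2]), "x")
    assert offset.gap_index == pytest.approx(1.0)
    assert offset.raw_area == pytest.approx(2.0)
    crossing = pdc.group_line_gap(_groups(1, 0, [-1, 0, 1]), _groups(-1, 0, [-1, 1]), "x")
    assert crossing.gap_index == pytest.approx(0.0, abs=1e-12)
    assert crossing.x_range == (-1.0, 1.0)


def test_group_line_gap_range_handling():
    a, b = _groups(1, 0, [0, 1, 2]), _groups(1, 0.5, [1.5, 3])
    inter = pdc.group_line_gap(a, b, "x", x_range="intersection")
    union = pdc.group_line_gap(a, b, "x", x_range="union")
    assert inter.x_range == (1.5, 2.0)
    assert union.x_range == (0.0, 3.0)
    with pytest.raises(ValidationError):
        pdc.group_line_gap(a, _groups(1, 0, [5, 6]), "x")  # disjoint ranges
    with pytest.raises(ValidationError):
        pdc.group_line_gap(a.iloc[:1], b, "x")  # one age only
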