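"""Simulation studies of the pipeline's statistical behaviour.

These are the package's built-in method-validation experiments: they run the
full analysis on freshly generated synthetic cohorts with known ground truth
and measure how well it recovers that truth.

* :func:`noiseless_closure` — with every noise source at zero the pipeline
  must return the generative coefficients exactly (machine precision) and
  predict an independent noiseless cohort with zero bias.
* :func:`recovery_experiment` — at study scale (two genotypes, ~300 paired
  rows) it measures the median relative error of the model-averaged
  fibrillar/nonfibrillar coefficients over replicate simulations, and the
  frequentist coverage of their 95% percentile bootstrap CIs (crossed
  PET-mouse x IHC-mouse resampling).
* :func:`trem2_experiment` — fits coefficients on the default study, then
  applies them to an independent base + microglial-dysfunction (halved
  fibrillar fraction) validation study, returning per-age nonfibrillar
  shares and the prediction-bias comparison.

All randomness is derived from a single base seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cohorts import z_score_cohort
from .decompose import contribution_table, validation_bias
from .pairing import build_pairs, compute_heterogeneity
from .regression import (LADDER, bootstrap_ci, bootstrap_model_average, fit_ladder,
                         fit_ols, summarize_coefficients)
from .simulate import SimConfig, default_config, generate_ihc, generate_pet, trem2_scenario

__all__ = ["noiseless_closure", "recovery_experiment", "trem2_experiment",
           "simulate_pairs"]


def _derived_seeds(base_seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(base_seed).generate_state(n) % (2**31)


def simulate_pairs(config: SimConfig):
    """Generate one study and build its paired design; returns (pairs, ihc)."""
    ihc = generate_ihc(config)
    pet, wt = generate_pet(config)
    pet_z = compute_heterogeneity(z_score_cohort(pet, wt))
    return build_pairs(pet_z, ihc), ihc


def noiseless_closure(seed: int = 0) -> dict:
    """Zero-noise pipeline round trip.

    Returns the max absolute coefficient error of the two-predictor fit
    against the generative truth, the full-model R², and the max absolute
    full-model prediction deviation on an independent noiseless cohort.
    """
    def noiseless(s):
        cfg = default_config(int(s))
        cfg.truth = dataclasses.replace(cfg.truth, heterogeneity_sd=0.0, residual_sd=0.0)
        cfg.profiles = [dataclasses.replace(
            p, total_sd=(0.0,) * len(p.ages),
            fibrillar_fraction_sd=(0.0,) * len(p.ages)) for p in cfg.profiles]
        return cfg

    cfg = noiseless(seed)
    truth = cfg.truth
    pairs, _ = simulate_pairs(cfg)
    model = fit_ols(pairs, ("fibrillar", "nonfibrillar"))
    full = fit_ols(pairs, ("fibrillar", "nonfibrillar", "heterogeneity", "age"))
    coef_err = max(abs(model.coefficients_["fibrillar"] - truth.b_fibrillar),
                   abs(model.coefficients_["nonfibrillar"] - truth.b_nonfibrillar))

    val_cfg = noiseless(seed + 1)
    val_ihc = generate_ihc(val_cfg)
    val_pet, val_wt = generate_pet(val_cfg)
    bias = validation_bias(z_score_cohort(val_pet, val_wt), val_ihc, model)
    return {
        "max_coefficient_error": float(coef_err),
        "full_model_r2": float(full.r2_),
        "max_validation_deviation": float(bias["deviation_full"].abs().max()),
    }


def recovery_experiment(n_replicates: int = 100, n_boot: int = 1000,
                        base_seed: int = 0) -> dict:
    """Replicate-simulation study of coefficient recovery and CI coverage.

    Each replicate regenerates the default study with a derived seed, fits
    the two most complete nested models, model-averages their fibrillar and
    nonfibrillar coefficients, and bootstraps that average (percentile, 95%,
    crossed resampling of PET and IHC mice with the heterogeneity covariate
    recomputed per resample).
    """
    truth = default_config().truth
    seeds = _derived_seeds(base_seed, 2 * n_replicates)
    est = np.empty((n_replicates, 2))
    cover = np.zeros(2)
    r2 = np.empty(n_replicates)
    n_rows = 0
    for i in range(n_replicates):
        cfg = default_config(int(seeds[i]))
        pairs, _ = simulate_pairs(cfg)
        n_rows = len(pairs)
        fits = [fit_ols(pairs, spec) for _, spec in (LADDER[3], LADDER[4])]
        est[i] = [np.mean([m.coefficients_["fibrillar"] for m in fits]),
                  np.mean([m.coefficients_["nonfibrillar"] for m in fits])]
        r2[i] = fits[1].r2_
        ci = bootstrap_model_average(pairs, n_boot=n_boot,
                                     seed=int(seeds[n_replicates + i]), unit="crossed")
        for j, name in enumerate(("fibrillar", "nonfibrillar")):
            lo, hi = ci.ci[name]
            cover[j] += lo <= (truth.b_fibrillar, truth.b_nonfibrillar)[j] <= hi
    rel_err = np.abs(est - [truth.b_fibrillar, truth.b_nonfibrillar]) / [
        truth.b_fibrillar, truth.b_nonfibrillar]
    return {
        "n_replicates": n_replicates,
        "n_paired_rows": n_rows,
        "median_rel_err_fibrillar": float(np.median(rel_err[:, 0])),
        "median_rel_err_nonfibrillar": float(np.median(rel_err[:, 1])),
        "coverage_fibrillar": float(cover[0] / n_replicates),
        "coverage_nonfibrillar": float(cover[1] / n_replicates),
        "mean_full_model_r2": float(r2.mean()),
    }


def trem2_experiment(seed: int = 0, n_boot: int = 200) -> dict:
    """Fit on the default study; validate on a base vs Trem2-knockout study.

    Returns per-age nonfibrillar contribution shares for the base and
    knockout genotypes and the mean absolute prediction deviations of the
    full versus fibrillar-only models on the validation cohorts.
    """
    cfg = default_config(seed)
    pairs, _ = simulate_pairs(cfg)
    fits = fit_ladder(pairs)
    cis = [bootstrap_ci(pairs, spec, n_boot=n_boot, seed=seed + k, unit="crossed")
           for k, (_, spec) in enumerate((LADDER[3], LADDER[4]))]
    summary = summarize_coefficients([fits[3][1], fits[4][1]], cis)

    base = max(cfg.profiles,
               key=lambda p: sum(p.fibrillar_fraction_mean) / len(p.fibrillar_fraction_mean))
    ko = trem2_scenario(base, 0.5)
    val_cfg = dataclasses.replace(cfg, profiles=[base, ko],
                                  rng_seed=(cfg.rng_seed + 1000003) % (2**31))
    val_ihc = generate_ihc(val_cfg)
    val_pet, val_wt = generate_pet(val_cfg)
    shares = contribution_table(val_ihc, summary, per_age=True)
    wide = shares.pivot(index="age_months", columns="genotype",
                        values="nonfibrillar_share")
    bias = validation_bias(z_score_cohort(val_pet, val_wt), val_ihc, summary)
    return {
        "summary": summary,
        "shares_base": wide[base.label].to_dict(),
        "shares_knockout": wide[ko.label].to_dict(),
        "mean_abs_deviation_full": float(bias["deviation_full"].abs().mean()),
        "mean_abs_deviation_fibrillar_only":
            float(bias["deviation_fibrillar_only"].abs().mean()),
    }
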