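# petdecomp

Decomposition of the in vivo amyloid-PET signal into **fibrillar** and
**nonfibrillar** β-amyloid plaque source components.

## The problem

Amyloid-PET tracers (florbetaben and other thioflavin-T derivatives) bind
β-sheet–rich *fibrillar* plaque cores with high affinity, yet mouse models
whose plaques are almost entirely *nonfibrillar* (diffuse) still show a clear
PET signal. For anyone using amyloid PET as a pathology readout — e.g. when a
treatment or a microglial gene such as *Trem2* changes plaque compaction
without changing plaque load — it matters how much of the signal each plaque
component produces.

Because PET (in vivo, longitudinal) and immunohistochemistry (terminal,
cross-sectional) cannot be acquired on the same animals without batch
confounds, the two modalities are measured on separate cohorts and linked
statistically. `petdecomp` implements that cross-modal analysis end to end:

1. **z-scoring** — PET SUVR (target-to-reference uptake ratio) is
   standardized against wild-type controls measured with the same reference
   region: `z = (SUVR − mean_WT) / sd_WT`.
2. **Pairing** — every PET observation is combined with every IHC mouse of
   the same genotype and age (the full cross product per stratum), carrying
   the PET side's *heterogeneity* covariate `h_i = z_i − mean(z | genotype, age)`
   and the IHC side's percent-area coverages, with
   `nonfibrillar = total − fibrillar`.
3. **Nested regression ladder** — OLS of z on
   fibrillar (F), nonfibrillar (N), heterogeneity and age:

       z = β₀ + B_fib·F + B_nonfib·N + B_het·h + B_age·age + ε

   fit as five nested models (F alone, N alone, F+N, +h, +age), with
   percentile-bootstrap 95% CIs (1000 resamples).
4. **Coefficient synthesis** — B_fib and B_nonfib are averaged over the two
   most complete models; their quotient is the *fold ratio* of intrinsic
   per-percent signal contributions, with an opposite-CI-edge fold range.
5. **Decomposition & validation** — the linear model attributes a share
   `B_nonfib·N / (B_fib·F + B_nonfib·N)` of the plaque signal to the
   nonfibrillar component, and predicted z-scores are compared against
   measured z in independent cohorts (including a Trem2-knockout scenario
   with halved fibrillar fraction at equal total coverage).

A seeded synthetic-cohort generator emulates the two-genotype study design
(APPPS1-like: compact, high-fibrillar plaques; App^NL-G-F-like: diffuse,
nonfibrillar-dominant plaques; longitudinal PET at 3/6/12 months with partial
enrollment; small cross-sectional IHC groups), so the entire pipeline is
testable against known ground truth.

## Worked example

```sh
petdecomp run-all --seed 7 --out-dir demo --boot 1000
```

generates a synthetic study, pairs it (296 rows: per stratum
n_PET × n_IHC, e.g. 10×4 + 18×3 + 18×4 = 166 for the NL-G-F-like genotype),
fits the ladder and writes `table1.csv`:

```
                                         model       r2  adjusted_r2
                                     fibrillar 0.897628     0.897280
                                  nonfibrillar 0.165879     0.163042
                      fibrillar × nonfibrillar 0.963786     0.963539
      fibrillar × nonfibrillar × heterogeneity 0.991010     0.990917
fibrillar × nonfibrillar × heterogeneity × age 0.991107     0.990985
```

Neither component alone explains the PET signal across both genotypes; the
combined model does, and the heterogeneity covariate absorbs the remaining
mouse-level variance. `summary.json` holds the model-averaged coefficients
(this run: `B_fib = 3.12`, `B_nonfib = 0.22` z per % area — a 14-fold
intrinsic ratio, CI-edge range 13–17; the generative truth was 3.17 / 0.20).
`shares.csv` translates them into net signal shares per genotype:

```
genotype  fibrillar_share  nonfibrillar_share  dispersion  n_mice
 model_A            0.907               0.093       0.096      11
 model_B            0.197               0.803       0.114      11
```

Although one percent of fibrillar plaque produces ~14× more signal than one
percent of nonfibrillar plaque, the diffuse-plaque genotype (`model_B`)
derives ~80% ± 11% of its net PET signal from nonfibrillar amyloid, because
nonfibrillar coverage dominates its plaque load. `bias.csv` shows the
practical consequence on an independent validation study: at 12 months the
full model predicts the measured z of 15.7 as 15.8, while a fibrillar-only
reading predicts 12.4 — and the bias is largest exactly in the
Trem2-knockout cohort whose plaques are less compacted.

As a pure printed-number exercise, averaging the published per-model
coefficients (3.521/2.810 fibrillar, 0.259/0.146 nonfibrillar) gives the
headline values this package's summary operation reproduces:

```python
>>> import petdecomp as pdc
>>> pdc.published_summary().rounded()
{'b_fib_mean': 3.17, 'b_nonfib_mean': 0.2, 'fold_ratio': 16,
 'fold_low': 11, 'fold_high': 26}
```

## Library use

All CLI stages are thin wrappers over importable functions and one
scikit-learn-compatible estimator:

```python
import petdecomp as pdc

cfg = pdc.default_config(seed=7)
ihc = pdc.generate_ihc(cfg)
pet, wt = pdc.generate_pet(cfg)
pairs = pdc.build_pairs(
    pdc.compute_heterogeneity(pdc.z_score_cohort(pet, wt)), ihc)

model = pdc.LinearZModel(
    predictors=("fibrillar", "nonfibrillar", "heterogeneity", "age")).fit(pairs)
ci = pdc.bootstrap_ci(pairs, model.predictors, n_boot=1000, unit="crossed")
```

`LinearZModel` follows the fit/predict/get_params protocol and composes with
sklearn tooling; fitted attributes are `coef_`, `intercept_`,
`coefficients_`, `r2_`, `adjusted_r2_`, `pvalues_`, `f_pvalue_`.

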