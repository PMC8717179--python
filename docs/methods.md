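# Methods

## The statistical model

The unit of analysis is the *paired record*: one PET observation (mouse `i`,
genotype `g`, age `a`, z-score `z`) crossed with one IHC mouse of the same
`(g, a)` stratum (fibrillar coverage `F`, nonfibrillar coverage `N`, both in
percent of field area, with `N = total − F` by definition and never read from
disk). PET and IHC animals are disjoint cohorts, so the cross product within
each stratum is the complete set of defensible pairings; it is enumerated
exhaustively rather than sampled.

On the paired table the package fits, by ordinary least squares with an
intercept, the nested ladder

| model | predictors |
|---|---|
| 1 | F |
| 2 | N |
| 3 | F, N |
| 4 | F, N, h |
| 5 | F, N, h, age |

where `h` is the heterogeneity covariate, `h_i = z_i − mean(z | g, a)`,
computed once per PET observation *before* pairing (it is a property of the
mouse, not of the pair, so duplicating a PET observation across IHC partners
must not re-center it). Coefficients are reported in z units per percent
area; the headline estimate is the average of `B_fib` and of `B_nonfib`
across models 4 and 5, mirroring how the source analysis reports its
regression factors. The fold ratio is their quotient; its range averages the
opposite CI edges across the two models (`B_fib,lo/B_nonfib,hi` and
`B_fib,hi/B_nonfib,lo`).

Signal attribution assumes the fitted linear model: the plaque-derived part
of a z-score is `B_fib·F + B_nonfib·N`, so the nonfibrillar share is
`B_nonfib·N / (B_fib·F + B_nonfib·N)`. The intercept and age terms are not
plaque signal and are excluded from the attribution. The ± dispersion quoted
with a share is the sample SD of per-mouse shares within genotype, pooled
across ages by default (a per-age option exists); with both components zero
the share is undefined and flagged rather than forced.

The group-level gap index fits one line per genotype through its per-age
`(predictor mean, z mean)` points and reports the signed mean vertical gap
over a shared predictor range (intersection of the observed ranges by
default; the raw signed area is also emitted). Crossing lines can cancel to
zero — the index is deliberately signed.

## z-scoring

`z = (SUVR − mean_WT)/sd_WT` with the n−1 SD, against wild-type controls
measured with the same reference region. Controls are pooled across ages by
default; an `age_matched` flag restricts them to the same integer age.
Ages are matched by numeric equality after rounding to integer months. Both
choices are configurable because neither is forced by the design; pooling is
the default since the wild-type signal has no age trend in the generator.

## Bootstrap

CIs are percentile intervals from 1000 case resamples. The resampling unit
matters on this design: each row duplicates one PET observation across ~3–4
IHC mice and each IHC mouse across ~10–18 PET observations, so iid row
resampling treats ~300 rows as independent when the information content is
closer to 22 IHC mice × 46 PET mice, and its intervals are several-fold too
narrow (measured frequentist coverage ≈ 20–35% at nominal 95% on synthetic
data). Four units are exposed: `row` (the simplest reading, and the default
for the ladder report), `pet-mouse`, `ihc-mouse`, and `crossed` — a two-way
("pigeonhole") bootstrap that independently resamples PET mice and IHC mice
and weights each row by the product of its cluster multiplicities. Because
the heterogeneity covariate is data-derived, it is recomputed inside every
resample from the resampled z values (resample-weighted within-stratum
centering); without this the between-stratum component of uncertainty is
invisible to the bootstrap. With crossed resampling plus recomputation the
95% intervals of the model-averaged coefficients achieve ≈93–95% measured
coverage in the recovery experiment below; this is the unit the package's
validation studies use. Resamples whose design collapses (condition number
above 1e12) are redrawn and counted; more than 10% redraws triggers a
warning.

Rank handling elsewhere: a design is declared singular above a relative
condition number of 1e10, and the error names the collinear predictors. A
covariate that is *identically zero* (heterogeneity in the noiseless limit)
is excluded from estimation with its coefficient pinned to 0 — it carries no
information, and treating it as singular would make the ladder undefined
exactly in the limit used to verify the pipeline.

## The synthetic-cohort generator

The generator emulates the study design the analysis was built for: two
amyloidosis genotypes at 3/6/12 months; longitudinal PET (14 and 18 mice,
56% enrolled at 3 months, the rest from 6 months) giving 82 PET
observations; cross-sectional IHC with 4/3/4 mice per genotype×age; 8
wild-type controls measured with both reference regions. PET z is generated
from the *latent per-stratum coverage means* — not the simulated IHC mice,
which are a separate draw, exactly as in the real design:

    z = β₀ + B_fib·F̄(g,a) + B_nonfib·N̄(g,a) + B_age·a + h_i + ε

with persistent per-mouse `h_i ~ N(0, σ_h)` and per-observation
`ε ~ N(0, σ_ε)`; SUVR = wt_mean + z·wt_sd. IHC coverage is truncated-normal:
total ≥ 0, fibrillar fraction in [0, 1], fibrillar = total × fraction.

Defaults (all configurable through one YAML file):

| parameter | value | why |
|---|---|---|
| B_fib, B_nonfib | 3.17, 0.20 z/% | the published model-averaged coefficients, used as ground truth so recovery is checked at realistic effect sizes |
| β₀, B_age | 0 | aging acts through the age-dependent coverage profiles; a direct age effect would bias model 4 (which lacks the age term) by construction and is left to explicit configuration |
| σ_h, σ_ε | 0.7, 0.25 z | mouse-level heterogeneity dominates test–retest noise; the split is not identifiable from published data and is a simulation choice |
| coverage CV | 4% (total), 3% (fibrillar fraction) | see calibration note below |
| fibrillar coverage, model A | 0.5 / 2 / 4 % | compact-plaque genotype, high at all ages |
| nonfibrillar, model A | 0.2 / 0.5 / 15.5 % | late diffuse halo growth |
| fibrillar, model B | 0.05 / 0.2 / 0.5 % | diffuse-plaque genotype |
| nonfibrillar, model B | 8 / 14 / 14.5 % | early-dominant, plateauing |
| wt SUVR mean, sd | 1.0, 0.05 | unit-scale reference ratio |

The coverage profiles satisfy the qualitative orderings that define the two
genotypes (model B nonfibrillar exceeds model A at 3 and 6 months and is
overtaken at 12; model A fibrillar exceeds model B at every age; coverage
never shrinks with age) *and* keep the nonfibrillar coefficient identifiable:
with only six strata, a nonfibrillar trajectory proportional to age is nearly
collinear with the age covariate and no analysis could separate them, so the
defaults encode a strong genotype-by-age interaction in N̄.

The wild-type sample is affine-standardized so its sample mean and SD equal
the configured values exactly. This is a deliberate design choice: with only
8 controls, raw sampling noise in the control SD would rescale every z-score
by ~25%, contaminating every downstream quantity with noise about the
instrument rather than the biology, and making exact noiseless closure
through the z-scoring path impossible.

### Calibration note (and a structural identity)

In this design the heterogeneity covariate reproduces, row for row, the
entire PET-side deviation of z from its stratum mean. Consequently the full
model's unexplained variance is *exactly* the errors-in-variables share
contributed by IHC within-stratum coverage noise: `1 − R² ≈ Var_EIV / Var(z)`.
That identity couples the achievable R² to coefficient bias — pushing the
full-model R² down to ≈0.93 requires within-stratum coverage CVs near 25%,
which attenuates the nonfibrillar coefficient (16× smaller than the
fibrillar one, so any redistributed bias is 16× amplified in relative terms)
by ≳30%. The defaults therefore sit in the recoverable regime: coverage CVs
of a few percent, full-model R² ≈ 0.99, median relative recovery error ≈ 2%
(fibrillar) and ≈ 6% (nonfibrillar) with 93–95% CI coverage over replicate
studies. Real IHC area-fraction data scatter considerably more than 4%
between mice; on such data the nonfibrillar coefficient of this design is
correspondingly less reliable, and passing recovery tests here demonstrate
correctness of the machinery at the configured noise, not robustness of the
design to arbitrary biological scatter.

### What the generator does not emulate

No images, plaque geometry or tracer kinetics — only the scalar endpoints.
No attrition, no litter/batch structure, no within-mouse longitudinal PET
correlation beyond the persistent random intercept, no age trend in
wild-type uptake, and no model mis-specification: z is generated by the same
linear form the analysis fits, so passing tests certify the estimation
machinery, not the linearity assumption itself.

## Validation experiments (what the built-in studies compute)

* **Noiseless closure** — every noise source at zero: the pipeline must
  return the generative coefficients to machine precision, R² = 1, and zero
  prediction deviation on an independent noiseless study.
* **Recovery/coverage** — 100 replicate default studies (296 paired rows
  each): median relative error of the model-averaged coefficients and
  frequentist coverage of their crossed-bootstrap 95% CIs.
* **Trem2 scenario** — coefficients fit on the default study are applied to
  an independent base + knockout study (fibrillar fraction halved at equal
  total coverage): the knockout's nonfibrillar share must be strictly larger
  at every age, and fibrillar-only prediction strictly more biased than the
  full model.
* **Determinism** — a rerun with the same config and seed must reproduce
  every artifact byte for byte (no artifact embeds a timestamp).

Problem sizes (296 rows, 100 replicates, 1000 resamples) are the package's
standard validation settings; all are arguments.

## Known limitations

* With six strata and four between-stratum parameters, the nonfibrillar
  coefficient is intrinsically weakly identified; its CI is honest about
  this only under the crossed bootstrap.
* Row-unit bootstrap CIs are kept (default for the ladder report, matching
  the source analysis's presentation) but are anti-conservative on this
  design; treat them as descriptive.
* The share attribution inherits the linear-model assumption; saturation of
  tracer binding at high plaque load would bias shares in a way no linear
  reweighting can detect.
* OLS p-values ignore the duplication structure of the paired table
  entirely; they are reported for completeness of the ladder table, not for
  inference.
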