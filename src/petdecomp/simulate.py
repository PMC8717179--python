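"""Synthetic PET and IHC cohorts with known generative ground truth.

The generator emulates a two-cohort preclinical amyloid study:

* two amyloidosis genotypes with opposite plaque-fibrillarity profiles —
  an APPPS1-like model (high fibrillar coverage at every age) and an
  App^NL-G-F-like model (very low fibrillar coverage, nonfibrillar-dominant
  already at young ages);
* longitudinal PET at 3/6/12 months with partial enrollment (a fraction of
  mice has its baseline scan at the first age, the remainder enters at the
  second), wild-type controls measured with both reference regions;
* cross-sectional IHC on separate, smaller groups per genotype and age.

The PET z-score of mouse *i* at age *a* is generated from the latent
per-stratum coverage means (F̄, N̄):

    z = intercept + b_fib * F̄ + b_nonfib * N̄ + age_slope * a + h_i + eps

with a persistent per-mouse heterogeneity intercept h_i ~ N(0, sd_h) applied
at all of that mouse's ages and per-observation noise eps ~ N(0, sd_e).
SUVR is then mapped back as ``wt_mean + z * wt_sd``.

The wild-type SUVR sample is affine-standardized so that its sample mean and
sample sd equal the configured values exactly; downstream z-scoring against
these controls therefore recovers the generated z without a finite-control-
sample rescaling (with only 8 controls, raw sampling noise of the control sd
would rescale every z by ~25%, which is noise about the instrument, not about
the biology under study).

IHC coverage per mouse is drawn as  total ~ TruncNormal(mean, sd, >=0)  and
fibrillar = total * TruncNormal(frac_mean, frac_sd, [0, 1]); nonfibrillar is
derived by subtraction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohorts import WILD_TYPE
from .errors import ConfigError, MissingStratumError

__all__ = [
    "GroundTruth",
    "GenotypeProfile",
    "SimConfig",
    "default_config",
    "latent_coverage_means",
    "generate_ihc",
    "generate_pet",
    "trem2_scenario",
    "config_to_yaml",
    "config_from_yaml",
]


@dataclass
class GroundTruth:
    """Generative coefficients of the PET-signal model, in z-score units.

    ``b_fibrillar`` / ``b_nonfibrillar`` are z units per percent area
    covered; ``age_slope`` is z units per month of a direct age effect
    (0 by default: aging acts through the coverage profiles themselves);
    ``heterogeneity_sd`` is the sd of the persistent per-mouse intercept and
    ``residual_sd`` the per-observation noise sd.
    """

    b_fibrillar: float = 3.17
    b_nonfibrillar: float = 0.20
    intercept: float = 0.0
    age_slope: float = 0.0
    heterogeneity_sd: float = 0.7
    residual_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.b_fibrillar <= 0:
            raise ConfigError("b_fibrillar must be positive")
        if self.b_nonfibrillar < 0:
            raise ConfigError("b_nonfibrillar must be nonnegative")
        if self.heterogeneity_sd < 0 or self.residual_sd < 0:
            raise ConfigError("noise sds must be nonnegative")


@dataclass
class GenotypeProfile:
    """Per-age coverage profile and cohort sizes for one genotype.

    ``total_mean``/``total_sd`` give the percent-area total Aβ coverage per
    age; ``fibrillar_fraction_mean``/``_sd`` give the fibrillar share of the
    total in [0, 1].  ``longitudinal_enrollment`` is the fraction of PET mice
    whose baseline scan is at the first age; the remainder enters at the
    second age.
    """

    label: str
    ages: tuple[float, ...]
    total_mean: tuple[float, ...]
    total_sd: tuple[float, ...]
    fibrillar_fraction_mean: tuple[float, ...]
    fibrillar_fraction_sd: tuple[float, ...]
    n_pet_mice: int = 16
    n_ihc_per_age: tuple[int, ...] = (4, 3, 4)
    longitudinal_enrollment: float = 0.56
    reference_region: str = "white-matter"

    def __post_init__(self) -> None:
        n = len(self.ages)
        for name in ("total_mean", "total_sd", "fibrillar_fraction_mean",
                     "fibrillar_fraction_sd", "n_ihc_per_age"):
            if len(getattr(self, name)) != n:
                raise ConfigError(f"{self.label}: {name} must have one entry per age")
        if any(m < 0 for m in self.total_mean) or any(s < 0 for s in self.total_sd):
            raise ConfigError(f"{self.label}: coverage means/sds must be nonnegative")
        if any(not 0 <= f <= 1 for f in self.fibrillar_fraction_mean):
            raise ConfigError(f"{self.label}: fibrillar fractions must lie in [0, 1]")
        if any(s < 0 for s in self.fibrillar_fraction_sd):
            raise ConfigError(f"{self.label}: fraction sds must be nonnegative")
        if list(self.total_mean) != sorted(self.total_mean):
            raise ConfigError(f"{self.label}: total coverage must be nondecreasing in age")
        if not 0 <= self.longitudinal_enrollment <= 1:
            raise ConfigError(f"{self.label}: enrollment fraction must lie in [0, 1]")


@dataclass
class SimConfig:
    """Everything needed to regenerate a study bit-identically."""

    profiles: list[GenotypeProfile] = field(default_factory=list)
    truth: GroundTruth = field(default_factory=GroundTruth)
    wt_suvr_mean: float = 1.0
    wt_suvr_sd: float = 0.05
    n_wt: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.wt_suvr_sd <= 0:
            raise ConfigError("wt_suvr_sd must be positive")
        if self.n_wt < 2:
            raise ConfigError("need at least 2 wild-type mice")


def default_config(seed: int = 0) -> SimConfig:
    """The default two-genotype study configuration.

    Coverage numbers satisfy the qualitative orderings of the two mouse
    models (the NL-G-F-like model has more nonfibrillar coverage at 3 and
    6 months, reversed at 12 months; the APPPS1-like model has more
    fibrillar coverage at every age) while keeping the nonfibrillar
    coverage pattern identifiable against age in the paired regression
    (a strong genotype-by-age interaction).
    """
    ages = (3.0, 6.0, 12.0)

    def prof(label, fib, nonfib, n_pet, region):
        total = tuple(f + n for f, n in zip(fib, nonfib))
        frac = tuple(f / t for f, t in zip(fib, total))
        return GenotypeProfile(
            label=label,
            ages=ages,
            total_mean=total,
            total_sd=tuple(0.04 * t for t in total),
            fibrillar_fraction_mean=frac,
            fibrillar_fraction_sd=tuple(0.03 * f for f in frac),
            n_pet_mice=n_pet,
            reference_region=region,
        )

    return SimConfig(
        profiles=[
            prof("model_A", (0.5, 2.0, 4.0), (0.2, 0.5, 15.5), 14, "white-matter"),
            prof("model_B", (0.05, 0.2, 0.5), (8.0, 14.0, 14.5), 18, "periaqueductal-gray"),
        ],
        rng_seed=seed,
    )


def latent_coverage_means(profile: GenotypeProfile) -> pd.DataFrame:
    """Latent per-stratum fibrillar/nonfibrillar coverage means (percent)."""
    rows = []
    for age, t, f in zip(profile.ages, profile.total_mean, profile.fibrillar_fraction_mean):
        rows.append({"genotype": profile.label, "age_months": age,
                     "fibrillar_area_pct": t * f, "nonfibrillar_area_pct": t * (1 - f)})
    return pd.DataFrame(rows)


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    """Truncated normal draw by rejection; degenerates to the mean at sd=0."""
    mean = float(mean)
    sd = float(sd)
    if sd == 0.0:
        return np.full(size, np.clip(mean, lo, hi))
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.clip(out, lo, hi)  # pathological mean/sd: fall back to clipping


def _sub_rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(3)[stream])


def generate_ihc(config: SimConfig) -> pd.DataFrame:
    """Cross-sectional IHC cohort: independent mice per (genotype, age)."""
    rng = _sub_rng(config, 0)
    rows = []
    for prof in config.profiles:
        for k, age in enumerate(prof.ages):
            n = prof.n_ihc_per_age[k]
            total = _truncnorm(rng, prof.total_mean[k], prof.total_sd[k], 0.0, 100.0, n)
            frac = _truncnorm(rng, prof.fibrillar_fraction_mean[k],
                              prof.fibrillar_fraction_sd[k], 0.0, 1.0, n)
            for j in range(n):
                rows.append({
                    "mouse_id": f"{prof.label}-ihc-{int(age)}m-{j + 1}",
                    "genotype": prof.label,
                    "age_months": age,
                    "total_area_pct": total[j],
                    "fibrillar_area_pct": total[j] * frac[j],
                })
    df = pd.DataFrame(rows, columns=["mouse_id", "genotype", "age_months",
                                     "total_area_pct", "fibrillar_area_pct"])
    df["nonfibrillar_area_pct"] = df["total_area_pct"] - df["fibrillar_area_pct"]
    return df


def generate_pet(config: SimConfig, ihc_truth_means: pd.DataFrame | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Longitudinal PET cohort plus a wild-type control table.

    ``ihc_truth_means`` defaults to the latent per-stratum coverage means of
    the configured profiles; supplying a table with columns
    ``genotype, age_months, fibrillar_area_pct, nonfibrillar_area_pct``
    decouples the PET generator from the profiles.

    Returns ``(pet, wt)``.  Each PET mouse carries one persistent
    heterogeneity draw applied at all of its ages; enrollment follows
    ``longitudinal_enrollment``.  The wild-type sample is affine-standardized
    per reference region so its sample mean/sd equal the configured values.
    """
    if ihc_truth_means is None:
        ihc_truth_means = pd.concat(
            [latent_coverage_means(p) for p in config.profiles], ignore_index=True)
    latent = ihc_truth_means.set_index(["genotype", "age_months"])

    truth = config.truth
    rng = _sub_rng(config, 1)
    rows = []
    for prof in config.profiles:
        n_first = round(prof.longitudinal_enrollment * prof.n_pet_mice)
        for i in range(prof.n_pet_mice):
            h = rng.normal(0.0, truth.heterogeneity_sd)
            ages = prof.ages if i < n_first else prof.ages[1:]
            for age in ages:
                try:
                    lat = latent.loc[(prof.label, age)]
                except KeyError:
                    raise MissingStratumError(
                        f"no latent coverage means for ({prof.label}, {age} mo)") from None
                z = (truth.intercept
                     + truth.b_fibrillar * lat["fibrillar_area_pct"]
                     + truth.b_nonfibrillar * lat["nonfibrillar_area_pct"]
                     + truth.age_slope * age
                     + h + rng.normal(0.0, truth.residual_sd))
                rows.append({
                    "mouse_id": f"{prof.label}-pet-{i + 1}",
                    "genotype": prof.label,
                    "age_months": age,
                    "suvr": config.wt_suvr_mean + z * config.wt_suvr_sd,
                    "reference_region": prof.reference_region,
                })
    pet = pd.DataFrame(rows)

    wt_rng = _sub_rng(config, 2)
    raw = wt_rng.normal(0.0, 1.0, config.n_wt)
    sd = raw.std(ddof=1)
    raw = (raw - raw.mean()) / (sd if sd > 0 else 1.0)  # exact sample mean 0, sd 1
    suvr = config.wt_suvr_mean + raw * config.wt_suvr_sd
    regions = sorted({p.reference_region for p in config.profiles})
    wt = pd.DataFrame([
        {"mouse_id": f"wt-{i + 1}", "genotype": WILD_TYPE, "age_months": 6.0,
         "suvr": suvr[i], "reference_region": region}
        for region in regions for i in range(config.n_wt)
    ])
    return pet, wt


def trem2_scenario(base_profile: GenotypeProfile, fibrillar_shift: float) -> GenotypeProfile:
    """Microglial-dysfunction variant: same total coverage, less compaction.

    Scales the fibrillar fraction down by ``fibrillar_shift`` (strictly
    between 0 and 1) at every age, leaving total coverage unchanged —
    emulating Trem2 loss of function, which reduces plaque compaction.
    """
    if not 0.0 < fibrillar_shift < 1.0:
        raise ConfigError("fibrillar_shift must lie strictly between 0 and 1")
    return dataclasses.replace(
        base_profile,
        label=f"{base_profile.label}-trem2ko",
        fibrillar_fraction_mean=tuple(
            f * fibrillar_shift for f in base_profile.fibrillar_fraction_mean),
        fibrillar_fraction_sd=tuple(
            s * fibrillar_shift for s in base_profile.fibrillar_fraction_sd),
    )


def provenance_line(config: SimConfig) -> str:
    truth = config.truth
    return (f"petdecomp simulate seed={config.rng_seed} "
            f"b_fib={truth.b_fibrillar} b_nonfib={truth.b_nonfibrillar} "
            f"het_sd={truth.heterogeneity_sd} resid_sd={truth.residual_sd}")


def config_to_yaml(config: SimConfig, path=None) -> str:
    """Serialize a SimConfig to YAML (returned; also written when path given)."""
    doc = dataclasses.asdict(config)
    doc["profiles"] = [dataclasses.asdict(p) for p in config.profiles]
    text = yaml.safe_dump(json.loads(json.dumps(doc)), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def config_from_yaml(src) -> SimConfig:
    """Load a SimConfig from a YAML file path or string."""
    if hasattr(src, "read"):
        doc = yaml.safe_load(src)
    else:
        try:
            with open(src) as fh:
                doc = yaml.safe_load(fh)
        except (OSError, ValueError):
            doc = yaml.safe_load(src)
    try:
        profiles = [GenotypeProfile(**{**p, "ages": tuple(p["ages"]),
                                       "total_mean": tuple(p["total_mean"]),
                                       "total_sd": tuple(p["total_sd"]),
                                       "fibrillar_fraction_mean": tuple(p["fibrillar_fraction_mean"]),
                                       "fibrillar_fraction_sd": tuple(p["fibrillar_fraction_sd"]),
                                       "n_ihc_per_age": tuple(p["n_ihc_per_age"])})
                    for p in doc.pop("profiles")]
        truth = GroundTruth(**doc.pop("truth"))
        return SimConfig(profiles=profiles, truth=truth, **doc)
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"invalid simulation config: {exc}") from exc
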