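import dataclasses

import pytest
from hypothesis import HealthCheck, settings

import petdecomp as pdc

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def noiseless_config(seed: int = 0) -> pdc.SimConfig:
    """Default study with every noise source switched off."""
    cfg = pdc.default_config(seed)
    cfg.truth = pdc.GroundTruth(heterogeneity_sd=0.0, residual_sd=0.0)
    cfg.profiles = [
        dataclasses.replace(p,
                            total_sd=(0.0,) * len(p.ages),
                            fibrillar_fraction_sd=(0.0,) * len(p.ages))
        for p in cfg.profiles
    ]
    return cfg


@pytest.fixture(scope="session")
def default_study():
    """One generated default study: cohorts, z-scored PET, pairs."""
    cfg = pdc.default_config(7)
    ihc = pdc.generate_ihc(cfg)
    pet, wt = pdc.generate_pet(cfg)
    pet_z = pdc.compute_heterogeneity(pdc.z_score_cohort(pet, wt))
    pairs = pdc.build_pairs(pet_z, ihc)
    return {"config": cfg, "ihc": ihc, "pet": pet, "wt": wt,
            "pet_z": pet_z, "pairs": pairs}


@pytest.fixture(scope="session")
def noiseless_study():
    cfg = noiseless_config(3)
    ihc = pdc.generate_ihc(cfg)
    pet, wt = pdc.generate_pet(cfg)
    pet_z = pdc.compute_heterogeneity(pdc.z_score_cohort(pet, wt))
    pairs = pdc.build_pairs(pet_z, ihc)
    return {"config": cfg, "ihc": ihc, "pet": pet, "wt": wt,
            "pet_z": pet_z, "pairs": pairs}
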