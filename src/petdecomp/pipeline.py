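"""End-to-end orchestration: simulate -> z-score -> pair -> fit -> decompose.

``run_all`` executes the whole analysis on synthetic cohorts and writes a
fixed set of artifacts to an output directory:

* ``pet.csv``, ``wt.csv``, ``ihc.csv`` — generated training cohorts;
* ``pairs.csv`` — the paired regression design;
* ``table1.csv`` — the nested-model ladder (R², corrected R², coefficients
  with bootstrap CIs, overall F-test p);
* ``summary.json`` — the model-averaged coefficient summary and fold range;
* ``shares.csv`` — per-genotype fibrillar/nonfibrillar contribution shares;
* ``val_pet.csv``, ``val_wt.csv``, ``val_ihc.csv``, ``bias.csv`` — an
  independent validation study (a base cohort plus a microglial-dysfunction
  variant with halved fibrillar fraction) and its prediction-bias report;
* ``manifest.json`` — config hash, seed, per-stage row counts, output paths.

Runs are bit-reproducible: all randomness derives from the config seed and
no artifact embeds a timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .cohorts import read_cohort, write_cohort, z_score_cohort
from .decompose import contribution_table, validation_bias
from .errors import PetdecompError
from .pairing import build_pairs, compute_heterogeneity
from .regression import LADDER, bootstrap_ci, fit_ladder, summarize_coefficients
from .simulate import (SimConfig, config_to_yaml, default_config, generate_ihc,
                       generate_pet, provenance_line, trem2_scenario)

log = logging.getLogger("petdecomp")

VALIDATION_SEED_OFFSET = 1000003  # derived validation-cohort stream
FIBRILLAR_SHIFT = 0.5


def _write(df: pd.DataFrame, path: Path, schema: str | None, provenance: str) -> None:
    if schema is None:
        with open(path, "w") as fh:
            fh.write(f"# {provenance}\n")
            df.to_csv(fh, index=False)
    else:
        write_cohort(df, path, schema, provenance)


def simulate_study(config: SimConfig, out_dir: Path, prefix: str = "") -> dict:
    """Generate and write one study's IHC, PET and wild-type tables."""
    ihc = generate_ihc(config)
    pet, wt = generate_pet(config)
    prov = provenance_line(config)
    paths = {}
    for name, df, schema in ((f"{prefix}ihc", ihc, "ihc"), (f"{prefix}pet", pet, "pet"),
                             (f"{prefix}wt", wt, "pet")):
        path = out_dir / f"{name}.csv"
        _write(df, path, schema, prov)
        paths[name] = path
    return {"ihc": ihc, "pet": pet, "wt": wt, "paths": paths}


def ladder_report(pairs: pd.DataFrame, n_boot: int, seed: int, unit: str
                  ) -> tuple[pd.DataFrame, list, list]:
    """Fit the five-model ladder with bootstrap CIs; return the report table."""
    fits = fit_ladder(pairs)
    cis = [bootstrap_ci(pairs, spec, n_boot=n_boot, seed=seed + k, unit=unit)
           for k, (_, spec) in enumerate(LADDER)]
    rows = []
    for (name, model), ci in zip(fits, cis):
        row = {"model": name, "r2": model.r2_, "adjusted_r2": model.adjusted_r2_,
               "n_rows": model.n_rows_, "f_test_p": model.f_pvalue_}
        for pred in ("fibrillar", "nonfibrillar", "heterogeneity", "age"):
            if pred in model.coefficients_:
                lo, hi = ci.ci[pred]
                row[f"b_{pred}"] = model.coefficients_[pred]
                row[f"b_{pred}_ci_low"] = lo
                row[f"b_{pred}_ci_high"] = hi
        rows.append(row)
    return pd.DataFrame(rows), fits, cis


def run_all(config: SimConfig | None = None, out_dir: str | Path = "petdecomp-run",
            n_boot: int = 1000, bootstrap_unit: str = "row",
            ihc_aggregate: str = "mice") -> dict:
    """Run the full pipeline; returns the manifest (also written as JSON)."""
    config = config or default_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.rng_seed,
        "n_boot": n_boot,
        "bootstrap_unit": bootstrap_unit,
        "stages": {},
        "outputs": {},
    }
    config_text = config_to_yaml(config, out / "config.yaml")
    manifest["config_sha256"] = hashlib.sha256(config_text.encode()).hexdigest()

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("simulate")
        train = simulate_study(config, out)
        manifest["stages"]["simulate"] = {
            "n_ihc": len(train["ihc"]), "n_pet": len(train["pet"]), "n_wt": len(train["wt"])}

        stage("pair")
        pet_z = compute_heterogeneity(z_score_cohort(train["pet"], train["wt"]))
        pairs = build_pairs(pet_z, train["ihc"], ihc_aggregate=ihc_aggregate)
        _write(pairs, out / "pairs.csv", None, provenance_line(config))
        manifest["stages"]["pair"] = {
            "n_pairs": len(pairs),
            "per_stratum": pairs.attrs["stratum_counts"].to_dict("records")}

        stage("fit")
        table1, fits, cis = ladder_report(pairs, n_boot, config.rng_seed, bootstrap_unit)
        _write(table1, out / "table1.csv", None,
               f"nested-model ladder, boot={n_boot} unit={bootstrap_unit} seed={config.rng_seed}")
        summary = summarize_coefficients([fits[3][1], fits[4][1]], [cis[3], cis[4]])
        with open(out / "summary.json", "w") as fh:
            json.dump({**summary.to_dict(), "rounded": summary.rounded(),
                       "models": [fits[3][0], fits[4][0]],
                       "n_boot": n_boot, "bootstrap_unit": bootstrap_unit,
                       "seed": config.rng_seed}, fh, indent=2)
        manifest["stages"]["fit"] = {
            "r2_ladder": [m.r2_ for _, m in fits],
            "b_fib_mean": summary.b_fib_mean, "b_nonfib_mean": summary.b_nonfib_mean,
            "fold_ratio": summary.fold_ratio}

        stage("decompose")
        shares = pd.concat([contribution_table(train["ihc"], summary),
                            contribution_table(train["ihc"], summary, per_age=True)],
                           ignore_index=True)
        _write(shares, out / "shares.csv", None, provenance_line(config))
        manifest["stages"]["decompose"] = {"n_groups": len(shares)}

        stage("validate")
        # Trem2 validation builds on the compact-plaque (high-fibrillarity) model
        base = max(config.profiles,
                   key=lambda p: sum(p.fibrillar_fraction_mean) / len(p.fibrillar_fraction_mean))
        val_config = dataclasses.replace(
            config,
            profiles=[base, trem2_scenario(base, FIBRILLAR_SHIFT)],
            rng_seed=(config.rng_seed + VALIDATION_SEED_OFFSET) % (2**31),
        )
        val = simulate_study(val_config, out, prefix="val_")
        val_pet_z = z_score_cohort(val["pet"], val["wt"])
        bias = validation_bias(val_pet_z, val["ihc"], summary)
        _write(bias, out / "bias.csv", None, provenance_line(val_config))
        manifest["stages"]["validate"] = {
            "n_strata": len(bias),
            "mean_abs_deviation_full": float(bias["deviation_full"].abs().mean()),
            "mean_abs_deviation_fibrillar_only":
                float(bias["deviation_fibrillar_only"].abs().mean())}
    except PetdecompError as exc:
        failed = list(manifest["stages"])
        stage_name = ["simulate", "pair", "fit", "decompose", "validate"][len(failed)]
        raise PetdecompError(f"stage {stage_name!r} failed: {exc}") from exc

    manifest["outputs"] = {p.name: str(p) for p in sorted(out.glob("*.csv"))}
    manifest["outputs"]["summary.json"] = str(out / "summary.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_pairs(path) -> pd.DataFrame:
    """Read a pairs.csv written by the pipeline or CLI."""
    return pd.read_csv(path, comment="#")


def pair_from_files(pet_path, wt_path, ihc_path, ihc_aggregate: str = "mice",
                    age_matched: bool = False) -> pd.DataFrame:
    """Convenience: read cohorts, z-score, attach heterogeneity, pair."""
    pet = read_cohort(pet_path, "pet")
    wt = read_cohort(wt_path, "pet")
    ihc = read_cohort(ihc_path, "ihc")
    pet_z = compute_heterogeneity(z_score_cohort(pet, wt, age_matched=age_matched))
    return build_pairs(pet_z, ihc, ihc_aggregate=ihc_aggregate)
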