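"""End-to-end orchestration: simulate → cluster → parentage → relatedness →
covariates → survival → growth, driven by one YAML config and one seed.

Every stochastic stage receives a child seed spawned deterministically from
the global seed, and all artifacts are written with fixed numeric formatting
and sorted JSON keys, so two runs with the same config are byte-identical.
The manifest records the seeds, per-stage row counts (the cohort bookkeeping
identity: cohort = selfing + immigrant + ambiguous + single-donor) and every
file written.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (GenotypeTable, PhenotypeTable, allele_frequencies,
                 read_wide_csv, write_genepop, write_wide_csv)
from .simulate import SimConfig, simulate_all
from .admixture import (align_runs, best_k, evanno_delta_k, run_k_range,
                        RunSet)
from .parentage import assign_paternity, calibrate_delta, category_table
from .relatedness import relatedness_for_pairs
from .parental_stats import (DEFAULT_SIGNED_FST, assemble_covariates,
                             signed_fst_contrast)
from .survival import code_survival, fit_model_set, km_by_group
from .growth import compute_rgr, fit_growth_by_period

logger = logging.getLogger("seedfit")

FLOAT_FMT = "%.10g"

DEFAULTS = {
    "seed": 0,
    "outdir": "seedfit_run",
    "cluster": {"k_min": 1, "k_max": 6, "reps": 5,
                "burnin": 2000, "iters": 10000, "k_fixed": None},
    "parentage": {"n_sim": 10000, "n_candidates": None,
                  "error_rate": 0.001, "max_mismatch": 2,
                  "sampled_fraction": 1.0, "typed_fraction": 1.0},
    "stats": {"signed_fst": list(DEFAULT_SIGNED_FST)},
    "survival": {"ties": "efron"},
    "growth": {"chains": 3, "iters": 4000, "burnin": 1000,
               "statistics": ["qdis", "fdis"]},
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        cfg = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        cfg = dict(path_or_dict)
    merged = json.loads(json.dumps(DEFAULTS))
    for key, val in cfg.items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def _validate(cfg: dict) -> None:
    if "simulate" not in cfg and "paths" not in cfg:
        raise ValueError("config needs either a 'simulate' or a 'paths' block")
    if "paths" in cfg and "simulate" not in cfg:
        required = ("adults", "seedlings", "mothers", "phenotypes_dir")
        missing = [k for k in required if k not in cfg["paths"]]
        if missing:
            raise ValueError(f"paths block missing {missing}")
        absent = [k for k in required
                  if not Path(cfg["paths"][k]).exists()]
        if absent:
            raise ValueError(
                f"missing input files: {[cfg['paths'][k] for k in absent]}")
    if cfg.get("seed") is None:
        raise ValueError("a global seed is required")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


class StageError(RuntimeError):
    def __init__(self, stage, err):
        super().__init__(f"stage '{stage}' failed: {err}")
        self.stage = stage


def run_pipeline(config) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    cfg = load_config(config)
    _validate(cfg)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(int(cfg["seed"]))
    stage_seeds = {name: int(child.generate_state(1)[0] % (2 ** 31))
                   for name, child in zip(
                       ("simulate", "cluster", "parentage", "growth"),
                       ss.spawn(4))}
    manifest = {"version": __version__, "seed": int(cfg["seed"]),
                "stage_seeds": stage_seeds, "counts": {}, "files": [],
                "config": cfg}

    def emit(df, name):
        _write_csv(df, outdir / name)
        manifest["files"].append(name)

    # ---- stage: inputs (simulate or load) --------------------------------
    stage = "simulate" if "simulate" in cfg else "load"
    try:
        if "simulate" in cfg:
            sim_kwargs = dict(cfg["simulate"] or {})
            sim_kwargs["rng_seed"] = stage_seeds["simulate"]
            sim = SimConfig(**sim_kwargs)
            adults, seedlings, phen, truth = simulate_all(sim)
            write_wide_csv(adults, outdir / "adults.csv")
            write_genepop(adults, outdir / "adults.gen")
            write_wide_csv(seedlings, outdir / "seedlings_genotypes.csv")
            phen.write_dir(outdir)
            truth.write_json(outdir / "truth.json")
            mothers = truth.parents[["seedling_id", "mother_id"]]
            emit(mothers, "mothers.csv")
            manifest["files"] += ["adults.csv", "adults.gen",
                                  "seedlings_genotypes.csv", "seedlings.csv",
                                  "survival.csv", "heights.csv", "truth.json"]
        else:
            paths = cfg["paths"]
            adults = read_wide_csv(paths["adults"])
            seedlings = read_wide_csv(paths["seedlings"])
            mothers = pd.read_csv(paths["mothers"])
            phen = PhenotypeTable.read_dir(paths["phenotypes_dir"])
        manifest["counts"]["n_adults"] = adults.n
        manifest["counts"]["n_seedlings"] = seedlings.n
    except Exception as err:
        raise StageError(stage, err) from err

    emit(adults.missing_report().merge(
        seedlings.missing_report(), on="locus",
        suffixes=("_adults", "_seedlings")), "missing_data_report.csv")

    # ---- stage: admixture clustering ------------------------------------
    try:
        ccfg = cfg["cluster"]
        if ccfg.get("k_fixed"):
            k_sel = int(ccfg["k_fixed"])
            runs = run_k_range(adults, k_sel, k_sel, reps=ccfg["reps"],
                               burnin=ccfg["burnin"], iters=ccfg["iters"],
                               seed=stage_seeds["cluster"])
        else:
            runs = run_k_range(adults, ccfg["k_min"], ccfg["k_max"],
                               reps=ccfg["reps"], burnin=ccfg["burnin"],
                               iters=ccfg["iters"],
                               seed=stage_seeds["cluster"])
            tab = evanno_delta_k(runs)
            emit(tab, "evanno.csv")
            from .admixture import mean_ln_prob
            (outdir / "runs.json").write_text(json.dumps(
                {str(k): [mean_ln_prob(f) for f in fits_k]
                 for k, fits_k in runs.fits.items()}, sort_keys=True))
            manifest["files"].append("runs.json")
            k_sel = best_k(runs)
        aligned = align_runs(RunSet(fits={k_sel: runs.fits[k_sel]}))
        fits = aligned.fits[k_sel]
        q_mean = np.mean([f.q for f in fits], axis=0)
        f_mean = np.mean([f.f for f in fits], axis=0)
        q_table = pd.DataFrame(q_mean, index=fits[0].ids,
                               columns=[f"Q{k+1}" for k in range(k_sel)])
        emit(q_table.reset_index(names="id"), "q_matrix.csv")
        emit(pd.DataFrame({"cluster": np.arange(1, k_sel + 1),
                           "fst": f_mean}), "cluster_fst.csv")
        manifest["counts"]["k_selected"] = k_sel
    except Exception as err:
        raise StageError("cluster", err) from err

    # ---- stage: paternity ------------------------------------------------
    try:
        pcfg = cfg["parentage"]
        freqs = allele_frequencies(adults.concat(seedlings))
        emit(freqs.to_frame(), "allele_frequencies.csv")
        n_cand = pcfg["n_candidates"] or adults.n
        calib = calibrate_delta(freqs, n_sim=pcfg["n_sim"],
                                n_candidates=n_cand,
                                sampled_fraction=pcfg["sampled_fraction"],
                                typed_fraction=pcfg["typed_fraction"],
                                error_rate=pcfg["error_rate"],
                                seed=stage_seeds["parentage"])
        parentage = assign_paternity(seedlings, mothers, adults, freqs, calib,
                                     max_mismatch=pcfg["max_mismatch"])
        emit(parentage, "parentage.csv")
        emit(category_table(parentage), "parentage_categories.csv")
        cat = parentage["category"].value_counts().to_dict()
        manifest["counts"]["categories"] = {k: int(v) for k, v in
                                            sorted(cat.items())}
        manifest["counts"]["delta_crit_95"] = float(calib.delta_crit_95)
    except Exception as err:
        raise StageError("parentage", err) from err

    # ---- stage: relatedness ---------------------------------------------
    try:
        single = parentage[parentage["category"] == "single_donor"]
        pairs = sorted({(m, f) for m, f in
                        zip(single["mother_id"], single["best_father_id"])})
        rel = relatedness_for_pairs(adults, pairs, allele_frequencies(adults))
        emit(rel, "relatedness.csv")
        manifest["counts"]["n_parent_pairs"] = len(pairs)
    except Exception as err:
        raise StageError("relatedness", err) from err

    # ---- stage: covariates ----------------------------------------------
    try:
        scfg = cfg["stats"]
        if scfg["signed_fst"] == "estimate":
            fst = signed_fst_contrast(f_mean)
        else:
            fst = np.asarray(scfg["signed_fst"], dtype=float)
            if len(fst) != k_sel:
                raise ValueError(
                    f"signed_fst length {len(fst)} != selected K {k_sel}")
        cov = assemble_covariates(parentage, q_table, fst, rel, phen)
        emit(cov, "covariates.csv")
        manifest["counts"]["n_covariate_rows"] = len(cov)
    except Exception as err:
        raise StageError("covariates", err) from err

    # ---- stage: survival -------------------------------------------------
    try:
        records = code_survival(phen)
        records = records[records["seedling_id"].isin(cov["seedling_id"])]
        emit(records, "survival_records.csv")
        _, table = fit_model_set(records, cov, ties=cfg["survival"]["ties"],
                                 skip_divergent=True)
        emit(table, "survival_models.csv")
        for stat in ("qdis", "fdis"):
            curves = km_by_group(records, cov, statistic=stat)
            km = pd.concat([sf.assign(group=g) for g, sf in curves.items()],
                           ignore_index=True)
            emit(km, f"km_{stat}.csv")
        manifest["counts"]["n_events"] = int(records["event"].sum())
    except Exception as err:
        raise StageError("survival", err) from err

    # ---- stage: growth ----------------------------------------------------
    try:
        gcfg = cfg["growth"]
        rgr = compute_rgr(phen.heights)
        rgr = rgr[rgr["seedling_id"].isin(cov["seedling_id"])]
        emit(rgr, "rgr.csv")
        gseed = np.random.SeedSequence(stage_seeds["growth"])
        for stat, child in zip(gcfg["statistics"],
                               gseed.spawn(len(gcfg["statistics"]))):
            summ = fit_growth_by_period(
                rgr, cov, statistic=stat,
                chains=gcfg["chains"], iters=gcfg["iters"],
                burnin=gcfg["burnin"],
                seed=int(child.generate_state(1)[0] % (2 ** 31)))
            emit(summ, f"growth_{stat}.csv")
        manifest["counts"]["n_growth_records"] = len(rgr)
    except Exception as err:
        raise StageError("growth", err) from err

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1, default=str))
    logger.info("pipeline complete: %s", outdir)
    return manifest
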