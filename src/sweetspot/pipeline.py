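"""End-to-end orchestration: simulate -> instruments -> screen -> fit -> power.

A run is driven by a YAML config and writes per-stage CSVs plus a JSON
manifest recording the seed, every tunable, and digests of all inputs and
outputs, so a run can be audited and reproduced byte-for-byte.

Config schema (all blocks optional except one of ``simulate`` / ``cohort``)::

    seed: 1
    simulate:                 # generate a synthetic cohort ...
      n_participants: 10000
      missingness_rate: 0.01
    cohort: path/to/dir       # ... or load one written by write_cohort
    screen:
      alpha: 0.05
      r_max: 0.9
      miss_max: 0.24
      exempt: []
    fit:
      alpha: 0.05
      k_eval: 10
      covariates: []          # optional covariate-adjusted re-run
      row_filter: null        # optional pandas query expression
    power:
      n_replication: 282
      sigma: 0.07
      psi_std: -0.24
      alpha: 0.05
      target_power: 0.8
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import (CohortConfig, PhenotypeSpec, default_phenotype_specs,
                       generate_cohort, write_cohort, read_cohort)
from .instruments import InstrumentMetadata, compute_instruments
from .screen import prefilter_phenotypes, run_screen, select_health_related
from .segmented import sweet_spot_scan, adjustment_concordance
from .power import select_replication_subset

__all__ = ["run_pipeline", "load_config"]

logger = logging.getLogger("sweetspot")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "simulate" not in cfg and "cohort" not in cfg:
        raise ValueError("config needs a 'simulate' block or a 'cohort' path")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _cohort_config(block: dict, seed: int) -> CohortConfig:
    block = dict(block or {})
    specs = block.pop("phenotype_specs", None)
    if specs is not None:
        specs = [PhenotypeSpec(**s) for s in specs]
    else:
        specs = default_phenotype_specs()
    if "age_range" in block:
        block["age_range"] = tuple(block["age_range"])
    return CohortConfig(phenotype_specs=specs, seed=seed, **block)


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 seed: int | None = None) -> Path:
    """Run all stages in order; returns the output directory.

    Every stage writes its table before the next stage starts, so each
    reported number is traceable to a stage CSV.  Any stage error
    propagates with the failing stage named.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    # one root seed; independent child streams per stochastic stage
    ss = np.random.SeedSequence(seed)
    sim_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))

    handler = logging.FileHandler(out / "log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    manifest: dict = {"version": __version__, "seed": seed,
                      "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
                      "stages": {}, "tunables": {}, "outputs": {}}

    try:
        stage = "simulate/load"
        if "simulate" in config:
            cc = _cohort_config(config["simulate"], sim_seed)
            cohort, registry = generate_cohort(cc)
            write_cohort(cohort, registry, out)
            logger.info("simulated cohort: n=%d, %d phenotypes",
                        len(cohort), len(cc.phenotype_specs))
            meta = InstrumentMetadata.for_synthetic_cohort(
                cc.n_deficits, cc.n_chronic_flags)
            phenotypes = [s.name for s in cc.phenotype_specs]
        else:
            cohort, registry = read_cohort(config["cohort"])
            logger.info("loaded cohort from %s: n=%d", config["cohort"],
                        len(cohort))
            meta = InstrumentMetadata.for_synthetic_cohort()
            phenotypes = list(registry["phenotypes"])
        manifest["stages"][stage] = {"n_participants": len(cohort),
                                     "n_phenotypes": len(phenotypes),
                                     "simulate_seed": sim_seed}

        stage = "instruments"
        meta.to_yaml(out / "instrument_metadata.yaml")
        scores, cutoffs = compute_instruments(cohort, meta)
        scores.to_csv(out / "instrument_scores.csv", index=False)
        pd.DataFrame([{"instrument": k, "q1": c.q1, "q2": c.q2, "q3": c.q3}
                      for k, c in cutoffs.items()]
                     ).to_csv(out / "quartile_cutoffs.csv", index=False)
        manifest["stages"][stage] = {
            "cutoffs": {k: [c.q1, c.q2, c.q3] for k, c in cutoffs.items()}}
        logger.info("instrument scores computed")

        stage = "screen"
        sc = config.get("screen", {}) or {}
        alpha = float(sc.get("alpha", 0.05))
        kept, drop_log = prefilter_phenotypes(
            cohort, phenotypes, r_max=float(sc.get("r_max", 0.9)),
            miss_max=float(sc.get("miss_max", 0.24)),
            exempt=tuple(sc.get("exempt", ())))
        drop_log.to_csv(out / "prefilter_drops.csv", index=False)
        logger.info("prefilter: kept %d of %d phenotypes (%d dropped)",
                    len(kept), len(phenotypes), len(drop_log))
        records, skipped = run_screen(cohort, scores, kept, alpha=alpha,
                                      min_group_size=int(
                                          sc.get("min_group_size", 30)))
        records.to_csv(out / "screen_records.csv", index=False)
        skipped.to_csv(out / "screen_skipped.csv", index=False)
        selection = select_health_related(records, alpha)
        selection.to_csv(out / "screen_selection.csv", index=False)
        selected = selection.loc[selection["selected"], "phenotype"].tolist()
        m_screen = int(records["m_tests"].iloc[0]) if len(records) else 0
        manifest["stages"][stage] = {
            "alpha": alpha, "n_kept": len(kept),
            "n_dropped": len(drop_log), "n_tests_performed": len(records),
            "n_skipped": len(skipped), "bonferroni_denominator": m_screen,
            "n_selected": len(selected)}
        logger.info("screen: %d tests, %d skipped strata, %d phenotypes "
                    "selected (Bonferroni m=%d)", len(records), len(skipped),
                    len(selected), m_screen)

        stage = "fit"
        fc = config.get("fit", {}) or {}
        fit_alpha = float(fc.get("alpha", 0.05))
        k_eval = int(fc.get("k_eval", 10))
        fits = sweet_spot_scan(cohort, scores, selected, alpha=fit_alpha,
                               k_eval=k_eval,
                               row_filter=fc.get("row_filter"))
        fits.to_csv(out / "sweet_spots.csv", index=False)
        n_ss = int((fits["relationship"] == "nonmonotonic_sweet_spot").sum()) \
            if len(fits) else 0
        n_nc = int((~fits["converged"]).sum()) if len(fits) else 0
        manifest["stages"][stage] = {
            "alpha": fit_alpha, "k_eval": k_eval,
            "bonferroni_denominator": int(fits["m_tests"].iloc[0])
            if len(fits) else 0,
            "n_fits": len(fits), "n_sweet_spots": n_ss,
            "n_nonconverged": n_nc}
        logger.info("fit: %d fits, %d sweet spots, %d non-converged",
                    len(fits), n_ss, n_nc)
        covs = fc.get("covariates") or []
        if covs:
            fits_adj = sweet_spot_scan(cohort, scores, selected,
                                       alpha=fit_alpha, k_eval=k_eval,
                                       covariates=list(covs),
                                       row_filter=fc.get("row_filter"))
            fits_adj.to_csv(out / "sweet_spots_adjusted.csv", index=False)
            r2 = adjustment_concordance(fits, fits_adj)
            manifest["stages"]["fit_adjusted"] = {
                "covariates": list(covs), "breakpoint_r2": r2}
            logger.info("covariate-adjusted re-run: breakpoint r^2 = %s", r2)

        stage = "power"
        pc = config.get("power", {}) or {}
        if pc:
            sd_map = {p: float(cohort[p].std(skipna=True)) for p in selected}
            subset, threshold = select_replication_subset(
                fits[fits["relationship"] == "nonmonotonic_sweet_spot"]
                if len(fits) else fits,
                n_replication=int(pc.get("n_replication", 282)),
                sigma=float(pc.get("sigma", 0.07)),
                psi_std=float(pc.get("psi_std", -0.24)),
                alpha=float(pc.get("alpha", 0.05)),
                target_power=float(pc.get("target_power", 0.8)),
                phenotype_sd=sd_map)
            pd.DataFrame({"phenotype": subset}).to_csv(
                out / "replication_plan.csv", index=False)
            manifest["stages"][stage] = {
                "min_detectable_slope_diff": threshold,
                "n_replication": int(pc.get("n_replication", 282)),
                "n_phenotypes_for_replication": len(subset)}
            logger.info("replication plan: threshold %.4f, %d phenotypes",
                        threshold, len(subset))
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    manifest["tunables"] = {
        "quantile_rule": "inclusive linear interpolation",
        "level_boundaries": "half-open, ties to the less-healthy side",
        "min_group_size": int((config.get("screen") or {})
                              .get("min_group_size", 30)),
        "segmented_tol": 1e-8, "segmented_max_iter": 50,
        "psi_interior_quantiles": [0.02, 0.98], "grid_points": 501,
        "k_eval": int((config.get("fit") or {}).get("k_eval", 10)),
    }
    manifest["runtime_seconds"] = round(time.time() - t0, 2)
    for f in sorted(out.glob("*.csv")) + [out / "truth.json"]:
        if f.exists():
            manifest["outputs"][f.name] = _sha256(f)
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
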