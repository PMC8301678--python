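"""End-to-end pipeline driver: metrics -> regression -> calibration -> size screen.

Writes every stage's CSV output plus a JSON summary and a log that records
versions, seed and the configuration echo, so any stage can be re-run
bit-identically.  On failure all partial outputs of the run are removed.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    evaluate_pairs,
    loess_summary,
    pairs_frame,
    predictive_reference,
    select_calibrators,
)
from .dataio import DataError, PipelineConfig, read_individuals, write_summaries
from .metrics import summaries_frame, summarize_study
from .regression import fit_model, pseudo_r2
from .size_assoc import size_screen
from .synthetic_data import SimulationConfig, generate_study

__all__ = ["run_pipeline"]

log = logging.getLogger("morphotest")


def _setup_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        stream = logging.StreamHandler(sys.stderr)
        stream.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(stream)
    return handler


def _simulation_config(cfg: PipelineConfig) -> SimulationConfig:
    from .synthetic_data import wsbl_like_config

    spec = dict(cfg.simulate or {})
    preset = spec.pop("preset", None)
    if preset == "wsbl_like":
        return wsbl_like_config(seed=cfg.seed, **spec)
    if preset not in (None, "default"):
        raise DataError(f"unknown simulate preset {preset!r}")
    spec.setdefault("seed", cfg.seed)
    if "prevalence_grid" in spec:
        spec["prevalence_grid"] = tuple(spec["prevalence_grid"])
    if "sample_size_range" in spec:
        spec["sample_size_range"] = tuple(spec["sample_size_range"])
    return SimulationConfig(**spec)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns a dict of output paths and key numbers."""
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out_dir)
    written: list[Path] = [out_dir / "run.log"]
    try:
        log.info("morphotest %s | seed=%s", __version__, cfg.seed)
        log.info("config: %s", json.dumps(cfg.__dict__, default=str, sort_keys=True))

        if cfg.individuals is not None:
            individuals = read_individuals(cfg.individuals)
            log.info("read %d individuals from %s", len(individuals), cfg.individuals)
        else:
            sim_cfg = _simulation_config(cfg)
            individuals, meta = generate_study(sim_cfg)
            path = out_dir / "individuals.csv"
            individuals.to_csv(path, index=False)
            written.append(path)
            path = out_dir / "samples.csv"
            meta.to_csv(path, index=False)
            written.append(path)
            log.info("simulated %d individuals in %d samples", len(individuals), len(meta))

        summaries = summarize_study(individuals, threshold=cfg.q_threshold)
        sframe = summaries_frame(summaries)
        path = out_dir / "sample_summaries.csv"
        write_summaries(sframe, path)
        written.append(path)

        report: dict = {
            "version": __version__,
            "seed": cfg.seed,
            "n_individuals": int(len(individuals)),
            "n_samples": int(len(summaries)),
        }

        # regression stage: population-level models (M1/M4) always; the
        # correctness GLMM needs variation in both responses
        fits = {}
        for mid in ("M1", "M4", "M6"):
            try:
                fit = fit_model(mid, individuals, q_threshold=cfg.q_threshold)
            except ValueError as exc:
                log.warning("model %s skipped: %s", mid, exc)
                continue
            fits[mid] = fit
            coef = pd.DataFrame(
                {
                    "term": fit.params.index,
                    "estimate": fit.params.to_numpy(),
                    "se": fit.bse.to_numpy(),
                }
            )
            coef["z"] = coef["estimate"] / coef["se"]
            path = out_dir / f"model_{mid}_coefficients.csv"
            coef.to_csv(path, index=False)
            written.append(path)
            r2m, r2c = pseudo_r2(fit) if fit.converged else (np.nan, np.nan)
            report[f"model_{mid}"] = {
                "aic": fit.aic,
                "loglik": fit.loglik,
                "converged": fit.converged,
                "method": fit.method,
                "sigma2_alpha": fit.sigma2_alpha,
                "r2_marginal": r2m,
                "r2_conditional": r2c,
            }
            log.info("fitted %s: AIC=%.1f method=%s", mid, fit.aic, fit.method)

        # calibration stage: pair search against the fitted references
        if "M4" in fits and "M6" in fits and len(summaries) >= 2:
            ref_ppv, ref_npv = predictive_reference(fits["M6"])
            pairs = evaluate_pairs(
                summaries,
                reference_prevalence=fits["M4"],
                reference_ppv=ref_ppv,
                reference_npv=ref_npv,
                grid_step=cfg.grid_step,
            )
            pframe = pairs_frame(pairs)
            path = out_dir / "pair_evaluations.csv"
            pframe.to_csv(path, index=False)
            written.append(path)
            report["n_pairs"] = int(len(pframe))
            for target in ("prevalence", "predictive"):
                try:
                    curve = loess_summary(pairs, target=target, span=cfg.loess_span)
                except ValueError as exc:
                    log.warning("loess (%s) skipped: %s", target, exc)
                    continue
                path = out_dir / f"loess_{target}.csv"
                curve.to_csv(path, index=False)
                written.append(path)
            for purpose in ("prevalence", "predictive"):
                try:
                    params = select_calibrators(
                        summaries,
                        purpose,
                        pure_bounds=(cfg.pure_low, cfg.pure_high),
                        mixed_bounds=(cfg.mixed_low, cfg.mixed_high),
                    )
                    report[f"calibrators_{purpose}"] = {
                        "p_t_tros": params.p_t_tros,
                        "p_t_edu": params.p_t_edu,
                        "provenance": params.provenance,
                    }
                except ValueError as exc:
                    log.warning("calibrator selection (%s): %s", purpose, exc)

        # size screen
        if "length_mm" in individuals.columns and individuals["length_mm"].notna().any():
            screen = size_screen(individuals, q_threshold=cfg.q_threshold)
            path = out_dir / "size_screen.csv"
            screen.to_csv(path, index=False)
            written.append(path)
            report["size_screen"] = {
                "informative_cells": int(screen["informative"].sum()),
                "significant_after_correction": int(screen["significant"].fillna(False).sum()),
            }

        path = out_dir / "summary.json"
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, default=float, sort_keys=True)
        written.append(path)
        report["outputs"] = [str(p) for p in written]
        log.info("pipeline complete: %d output files", len(written))
        return report
    except Exception:
        for p in written:
            if p.name != "run.log" and p.exists():
                p.unlink()
        log.exception("pipeline failed; partial outputs removed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
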