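"""End-to-end orchestration: summaries -> covariate screening -> single-species
model sets -> two-species interaction factors -> activity overlaps.

Every report table is written as CSV; a machine-readable JSON log records
each fitted model, its criterion value, and the seed, so re-running with the
same inputs and seed reproduces the outputs byte for byte.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activity as act
from . import cooccurrence as co
from . import detections as det
from . import occupancy as occ
from .habitat import screen_collinear, standardize
from .simulate import default_scenario, simulate_detections, simulate_stations


@dataclass
class PipelineConfig:
    """Thresholds and inputs for one full analysis run."""

    records_path: str | None = None
    effort_path: str | None = None
    covariates_path: str | None = None
    scenario_seed: int | None = None      # simulate when no paths given
    dominant_species: str | None = None
    detection_candidates: list[str] = field(
        default_factory=lambda: ["trail_width_max", "undergrowth_mean", "season"])
    occupancy_candidates: list[str] = field(
        default_factory=lambda: ["large_stem_density", "small_stem_density",
                                 "canopy_height_mean", "canopy_height_sd",
                                 "shannon_h"])
    min_events: int = 50
    min_events_activity: int = 30
    correlation_threshold: float = 0.70
    delta_max: float = 6.0
    independence_hours: float = 1.0
    occasion_days: int = 6
    n_boot: int = 0
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("correlation_threshold", "delta_max", "independence_hours",
                     "occasion_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def species_inclusion_filter(summaries: pd.DataFrame, min_events: int = 50) -> list[str]:
    """Focal species: strictly more than ``min_events`` independent events."""
    keep = summaries.loc[summaries["n_events"] > min_events, "species"]
    return sorted(keep)


def _univariate_scores(histories: dict[str, det.DetectionHistory],
                       covariates: pd.DataFrame, candidates: list[str],
                       seed: int) -> dict[str, float]:
    """Cross-species significance score per covariate: mean |estimate/SE|
    from univariate occupancy fits (the collinearity tie-breaker)."""
    scores: dict[str, list[float]] = {c: [] for c in candidates}
    for hist in histories.values():
        for c in candidates:
            try:
                fit = occ.fit_occu(hist, covariates, occ.OccuModelSpec((c,), ()),
                                   seed=seed, n_restarts=2)
            except (ValueError, np.linalg.LinAlgError):
                continue
            coef = fit.coefficients()
            row = coef.loc[coef["term"] == f"psi_{c}"].iloc[0]
            if row["se"] > 0 and np.isfinite(row["se"]):
                scores[c].append(abs(row["estimate"] / row["se"]))
    return {c: float(np.mean(v)) if v else 0.0 for c, v in scores.items()}


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and write the report bundle under ``outdir``.

    Returns a dict of the in-memory report tables keyed by stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "models": []}
    reports: dict = {}

    # --- inputs -----------------------------------------------------------
    if config.records_path is not None:
        efforts = det.read_efforts(config.effort_path)
        records = det.read_records(config.records_path, efforts)
        covariates = pd.read_csv(config.covariates_path, index_col="station")
    else:
        scenario = default_scenario(seed=config.scenario_seed
                                    if config.scenario_seed is not None
                                    else config.seed)
        efforts, covariates = simulate_stations(scenario)
        records, _truth = simulate_detections(scenario, efforts, covariates)
        log["scenario"] = "builtin-default"
    records = det.independence_filter(records, config.independence_hours)

    # --- stage 1: survey summaries (capture rates, naive occupancy) -------
    summary = det.summarize_all(records, efforts)
    summary.to_csv(outdir / "survey_summary.csv", index=False)
    reports["summary"] = summary

    focal = species_inclusion_filter(summary, config.min_events)
    activity_species = species_inclusion_filter(summary, config.min_events_activity)
    if not focal:
        raise RuntimeError("pipeline: no species passes the event threshold")
    log["focal_species"] = focal
    log["activity_species"] = activity_species

    histories = {
        sp: det.build_history(records, efforts, sp, config.occasion_days)
        for sp in focal
    }

    # --- stage 2: covariate screening -------------------------------------
    numeric = [c for c in config.occupancy_candidates if c in covariates.columns]
    covs_std = standardize(covariates, numeric + [
        c for c in config.detection_candidates
        if c in covariates.columns and covariates[c].dtype != object])
    scores = _univariate_scores(histories, covs_std, numeric, config.seed)
    retained = screen_collinear(covs_std[numeric], scores,
                                config.correlation_threshold)
    log["covariate_scores"] = scores
    log["retained_covariates"] = retained

    # --- stage 3: single-species model sets -------------------------------
    avg_rows = []
    best_covs: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {}
    for sp in focal:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mset = occ.selection_workflow(
                histories[sp], covs_std,
                [c for c in config.detection_candidates
                 if c in covs_std.columns],
                retained, n_boot=config.n_boot, seed=config.seed,
                delta_max=config.delta_max)
        for _, row in mset.table().iterrows():
            log["models"].append({"species": sp, **{k: (v if not isinstance(v, float)
                                 else round(v, 6)) for k, v in row.items()}})
        top = mset.fits[0].spec
        best_covs[sp] = (top.psi_covariates, top.p_covariates)
        avg = mset.averaged.copy()
        avg.insert(0, "species", sp)
        avg.insert(1, "criterion", mset.criterion)
        avg.insert(2, "chat", mset.chat)
        avg_rows.append(avg)
    averaged = pd.concat(avg_rows, ignore_index=True)
    averaged.to_csv(outdir / "occupancy_averaged.csv", index=False)
    reports["occupancy"] = averaged

    # --- stage 4: two-species SIFs ----------------------------------------
    dominant = config.dominant_species
    if dominant is None:
        dominant = summary.loc[summary["species"].isin(focal)] \
            .sort_values("n_events", ascending=False)["species"].iloc[0]
    sif_rows = []
    if dominant in histories:
        psi_c, p_c = best_covs.get(dominant, ((), ()))
        for sp in focal:
            if sp == dominant:
                continue
            param_covs = None
            if best_covs.get(sp, ((), ()))[0]:
                param_covs = {"psiA": psi_c, "psiBA": best_covs[sp][0],
                              "psiBa": best_covs[sp][0]}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits = co.fit_two_species(histories[dominant], histories[sp],
                                          covariates=covs_std,
                                          param_covariates=param_covs,
                                          seed=config.seed)
                sif = co.sif_uncertainty(fits[0])
            for _, row in co.model_table(fits).iterrows():
                log["models"].append({"pair": f"{dominant}/{sp}",
                                      **{k: (round(v, 6) if isinstance(v, float) else v)
                                         for k, v in row.items()}})
            sif_rows.append({
                "dominant": dominant, "subordinate": sp,
                "best_model": fits[0].constraint,
                "phi": sif.phi, "phi_se": sif.phi_se,
                "phi_lcl": sif.phi_ci[0], "phi_ucl": sif.phi_ci[1],
                "phi_interpretation": sif.phi_interpretation,
                "delta": sif.delta, "delta_se": sif.delta_se,
                "delta_lcl": sif.delta_ci[0], "delta_ucl": sif.delta_ci[1],
                "delta_interpretation": sif.delta_interpretation,
            })
    sif_table = pd.DataFrame(sif_rows)
    sif_table.to_csv(outdir / "sif_table.csv", index=False)
    reports["sif"] = sif_table

    # --- stage 5: activity overlaps ---------------------------------------
    samples = {}
    for sp in activity_species:
        sub = records.loc[records["species"] == sp, "timestamp"]
        if len(sub) >= 2:
            samples[sp] = act.CircularSample(sp, act.timestamps_to_radians(sub))
    pairs = [(a, b) for i, a in enumerate(sorted(samples)) for b in sorted(samples)[i + 1:]]
    overlaps = (act.overlap_table(samples, pairs)
                if pairs else pd.DataFrame(columns=["pair", "ovl_core",
                                                    "ovl_general", "kappa"]))
    overlaps.to_csv(outdir / "activity_overlap.csv", index=False)
    reports["activity"] = overlaps

    ww_rows = []
    for sp in activity_species:
        if sp == dominant or sp not in samples:
            continue
        try:
            res = act.with_without_comparison(records, dominant, sp)
        except ValueError:
            continue
        ww_rows.append({"species": sp, "ovl_core": res.ovl_core,
                        "ovl_general": res.ovl_general, "kappa": res.kappa_used,
                        "n_with": res.n_with, "n_without": res.n_without,
                        "low_sample": res.low_sample})
    ww = pd.DataFrame(ww_rows)
    ww.to_csv(outdir / "with_without_dominant.csv", index=False)
    reports["with_without"] = ww

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
    reports["log"] = log
    return reports
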