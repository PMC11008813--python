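"""End-to-end orchestration: simulate -> qc -> fit -> cluster -> compare ->
replicate -> report, from a validated YAML/dict configuration.

Every stage draws its randomness from an explicit per-stage seed derived
from the run seed, and the run directory receives a manifest (config hash,
package version, per-stage seeds) so deterministic stages re-run
bit-identically and seeded stages re-run statistically identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .cohort import (
    CohortConfig,
    EffectSpec,
    generate_vertex_data,
    sample_design,
    sample_truth,
)
from .inference import clusterwise_p, fdr_adjust, spin_test
from .io import save_ground_truth, write_cohort_table, write_text_maps
from .models import ModelSpec, fit_vertex_lme
from .phenotype import main_analysis_view, standardize_covariates
from .qc import fit_smooth_trend, flag_outlier_observations
from .replicability import split_half_replicability
from .reporting import aging_equivalence, annual_change, total_measure_effect
from .surface import build_spin_null, make_icosphere

log = logging.getLogger("vertexspan")

__all__ = ["RunConfig", "run_pipeline", "load_config"]

_STAGES = ("simulate", "qc", "fit", "cluster", "compare", "replicate", "report")


class CohortSection(BaseModel):
    name: str
    n_subjects: int = Field(ge=0)
    age_range: tuple[float, float]
    visit_counts: tuple[int, ...] = (2,)
    visit_probs: tuple[float, ...] = (1.0,)
    interval_mean: float = 2.0
    interval_sd: float = 0.5
    n_sites: int = 3
    bw_mean: float = 3.4
    bw_sd: float = 0.6

    @field_validator("age_range")
    @classmethod
    def _ordered(cls, v):
        if v[1] < v[0]:
            raise ValueError("age_range must be (lo, hi) with hi >= lo")
        return v

    def to_config(self) -> CohortConfig:
        return CohortConfig(**self.model_dump())


class EffectSection(BaseModel):
    b0_mean: float = 100.0
    amplitudes: dict[str, float] = Field(
        default_factory=lambda: {"b0": 1.0, "age": 1.0, "sex": 0.5, "bw": 1.0,
                                 "time": -0.3, "bw_time": 0.0, "discord": 0.0}
    )
    smooth_iterations: int = 20
    sigma_u: float = 1.0
    sigma_e: float = 1.0
    site_offset_sd: float = 0.5
    corrupt_fraction: float = 0.0

    def to_spec(self) -> EffectSpec:
        return EffectSpec(**self.model_dump())


class RunConfig(BaseModel):
    """Validated configuration for one pipeline run."""

    seed: int = 0
    mesh_subdivisions: int = Field(default=3, ge=0, le=7)
    cohorts: list[CohortSection]
    effects: EffectSection = Field(default_factory=EffectSection)
    measure: str = "area"
    contrast: str = "bw"
    stages: list[str] = Field(default_factory=lambda: list(_STAGES))
    cft: float = 2.0
    n_null: int = 200
    n_spins: int = 1000
    n_splits: int = 10
    age_window: tuple[float, float] = (50.0, 60.0)

    @field_validator("stages")
    @classmethod
    def _known(cls, v):
        unknown = [s for s in v if s not in _STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {list(_STAGES)}")
        return v


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


def _stage_seed(base: int, stage: str) -> int:
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the configured stages in order and write all artifacts.

    Returns the run directory.  Stage inputs are held in memory; requesting
    a stage whose upstream never ran raises a dependency error naming it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    config_json = json.dumps(config.model_dump(), sort_keys=True, default=str)
    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "stage_seeds": {s: _stage_seed(config.seed, s) for s in config.stages},
        "stages": [],
    }

    mesh_l = make_icosphere(config.mesh_subdivisions, "left")
    mesh_r = make_icosphere(config.mesh_subdivisions, "right")
    state: dict = {}

    for stage in _STAGES:
        if stage not in config.stages:
            continue
        seed = _stage_seed(config.seed, stage)
        t0 = time.time()
        log.info("stage %s (seed %d)", stage, seed)
        sdir = out / stage
        sdir.mkdir(exist_ok=True)

        if stage == "simulate":
            truth = sample_truth(mesh_l, mesh_r, config.effects.to_spec(), seed)
            table = sample_design([c.to_config() for c in config.cohorts], seed + 1)
            data = generate_vertex_data(table, truth, seed + 2, measure=config.measure)
            write_cohort_table(table, sdir / "cohort_table.csv")
            save_ground_truth(truth, sdir)
            state.update(table=table, data=data, truth=truth)

        elif stage == "qc":
            _require(state, "data", stage, "simulate")
            trend = fit_smooth_trend(state["data"], state["table"])
            report = flag_outlier_observations(
                trend, state["table"]["observation_id"].to_numpy()
            )
            report.to_frame().to_csv(sdir / "outlier_report.csv", index=False)
            (sdir / "qc_params.json").write_text(json.dumps(
                {"k": report.k, "vertex_count_threshold": report.vertex_count_threshold}
            ))
            keep = ~report.excluded
            state["table"] = state["table"][keep].reset_index(drop=True)
            state["data"] = state["data"].subset_rows(keep)

        elif stage == "fit":
            _require(state, "data", stage, "simulate")
            table = main_analysis_view(state["table"])
            keep = state["table"]["observation_id"].isin(table["observation_id"]).to_numpy()
            data = state["data"].subset_rows(keep)
            table, scaling = standardize_covariates(
                table, ["baseline_age", "bw", "time"]
            )
            spec = ModelSpec(contrast=config.contrast)
            emap = fit_vertex_lme(data, table, spec)
            write_text_maps(
                {"estimate": emap.estimate, "se": emap.se,
                 "t": emap.tstat, "log10p": emap.log10p},
                sdir / f"effectmap_{config.contrast}.tsv",
            )
            state.update(fit_table=table, fit_data=data, effect_map=emap,
                         scaling=scaling, spec=spec)

        elif stage == "cluster":
            _require(state, "effect_map", stage, "fit")
            clusters = clusterwise_p(
                state["fit_data"], state["fit_table"], state["spec"],
                cft=config.cft, n_null=config.n_null, seed=seed,
            )
            clusters.table.to_csv(sdir / "clusters.csv", index=False)
            write_text_maps({"cluster_id": clusters.labels.astype(float)},
                            sdir / "cluster_labels.tsv")
            state["clusters"] = clusters

        elif stage == "compare":
            _require(state, "effect_map", stage, "fit")
            spins = build_spin_null(mesh_l, mesh_r, config.n_spins, seed)
            per_cohort = {}
            for cohort, idx in state["fit_table"].groupby("cohort").groups.items():
                mask = state["fit_table"].index.isin(idx)
                sub_tbl = state["fit_table"][mask].reset_index(drop=True)
                if sub_tbl["subject_id"].nunique() < 10:
                    continue
                per_cohort[cohort] = fit_vertex_lme(
                    state["fit_data"].subset_rows(mask), sub_tbl, state["spec"],
                    refine_tol=1e-3,
                )
            names = sorted(per_cohort)
            comps = []
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    comps.append(spin_test(
                        per_cohort[a].estimate, per_cohort[b].estimate, spins,
                        label_a=a, label_b=b,
                    ))
            if comps:
                qs = fdr_adjust([c.p_spin for c in comps])
                rows = [{"map_a": c.label_a, "map_b": c.label_b, "r": c.r,
                         "p_spin": c.p_spin, "q": q, "n_perm": c.n_perm}
                        for c, q in zip(comps, qs)]
                import pandas as pd

                pd.DataFrame(rows).to_csv(sdir / "spatial_comparisons.csv", index=False)
            state["comparisons"] = comps

        elif stage == "replicate":
            _require(state, "effect_map", stage, "fit")
            rep = split_half_replicability(
                state["fit_data"], state["fit_table"], state["spec"],
                n_splits=config.n_splits, seed=seed, cft=config.cft,
                n_null=config.n_null,
            )
            (sdir / "replicability.json").write_text(json.dumps(rep.summary(), indent=2))
            write_text_maps({"exploratory": rep.exploratory}, sdir / "exploratory_map.tsv")
            state["replicability"] = rep

        elif stage == "report":
            _require(state, "effect_map", stage, "fit")
            report = {}
            for cohort, idx in state["fit_table"].groupby("cohort").groups.items():
                mask = state["fit_table"].index.isin(idx)
                sub_tbl = state["fit_table"][mask].reset_index(drop=True)
                sub_data = state["fit_data"].subset_rows(mask)
                try:
                    bw_sd_g = state["scaling"].bw_sd_grams(str(cohort))
                except KeyError:
                    bw_sd_g = None
                tot = total_measure_effect(sub_data, sub_tbl, state["spec"],
                                           bw_sd_grams=bw_sd_g)
                entry = {"effect_per_sd": tot.effect_per_sd, "beta": tot.beta,
                         "se": tot.se, "mean_total": tot.mean_total,
                         "percent_of_total": tot.percent_of_total,
                         "bw_sd_grams": bw_sd_g}
                lo, hi = config.age_window
                ages = sub_tbl["baseline_age_raw"] if "baseline_age_raw" in sub_tbl else sub_tbl["baseline_age"]
                window_tbl = sub_tbl.copy()
                window_tbl["baseline_age"] = ages
                if ((ages >= lo) & (ages <= hi)).any():
                    try:
                        slope, slope_se = annual_change(sub_data, window_tbl, (lo, hi))
                        eq = aging_equivalence(tot.effect_per_sd, slope)
                        entry.update(annual_slope=slope, annual_slope_se=slope_se,
                                     equivalence_years=eq.equivalence_years,
                                     equivalence_years_rounded=eq.equivalence_years_rounded)
                    except (ValueError, ZeroDivisionError) as exc:
                        entry["annual_change_error"] = str(exc)
                report[str(cohort)] = entry
            (sdir / "effect_report.json").write_text(json.dumps(report, indent=2))
            state["report"] = report

        manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 2)})

    manifest["total_seconds"] = round(time.time() - t_start, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _require(state: dict, key: str, stage: str, producer: str) -> None:
    if key not in state:
        raise RuntimeError(
            f"stage {stage!r} needs output of stage {producer!r}, which did not run"
        )
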