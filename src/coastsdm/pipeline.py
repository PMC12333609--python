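"""Declarative pipeline orchestration: config, staged execution, manifest.

Stages run in a fixed canonical order; every stochastic stage derives its
seed deterministically from the master seed, so a config re-run is
bit-identical.  Dependencies of an enabled stage are computed on demand
(and cached) even when their own stage toggle is off; toggles control
which stages execute and write outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._rng import derive_seed
from .design import extract_design
from .evaluation import (
    ModelSettings,
    ablation_citizen_science,
    run_engines,
    tune_gam,
    tune_maxent,
)
from .gam import build_smooth, deviance_importance
from .grid import FeatureGeometry, read_stack, write_geotiff, write_stack
from .landscape import LandscapeParams, simulate_study
from .maxent import percent_contribution, permutation_importance
from .occurrences import OccurrenceSet, merge_occurrences
from .selection import concurvity_index, prune_collinear

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("coastsdm")

STAGES = ("simulate", "prepare", "select", "tune", "fit", "importance", "ablate", "report")


@dataclass
class RunConfig:
    outdir: str = "coastsdm_run"
    master_seed: int = 0
    stages: list[str] = field(default_factory=lambda: ["simulate", "prepare", "select",
                                                       "fit", "importance", "report"])
    # inputs (used when "simulate" is off)
    stack_dir: str | None = None
    occurrences_csv: str | None = None
    study_area_geojson: str | None = None
    # synthetic landscape
    landscape: dict = field(default_factory=dict)
    n_survey: int = 20
    n_citizen: int = 49
    # model settings (fixed presets unless tuning is enabled)
    settings: dict = field(default_factory=dict)
    # tuning-loop sizes
    tune_repeats: int = 50
    tune_n_bg_candidates: int = 30
    concurvity_threshold: float = 0.8
    auto_prune_concurvity: bool = False

    def model_settings(self) -> ModelSettings:
        return ModelSettings(**self.settings)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**(yaml.safe_load(text) or {}))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


class _Pipeline:
    def __init__(self, config: RunConfig):
        self.cfg = config
        self.outdir = pathlib.Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "config": dataclasses.asdict(config),
            "config_hash": config.config_hash(),
            "versions": {"numpy": np.__version__, "pandas": pd.__version__},
            "stages": {},
        }
        self._cache: dict = {}

    # -- cached dependencies ------------------------------------------------
    def stack(self):
        if "stack" not in self._cache:
            if "simulate" in self.cfg.stages or self.cfg.stack_dir is None:
                self._simulate()
            else:
                self._cache["stack"] = read_stack(self.cfg.stack_dir)
        return self._cache["stack"]

    def occurrences(self) -> OccurrenceSet:
        if "occurrences" not in self._cache:
            if "simulate" in self.cfg.stages or self.cfg.occurrences_csv is None:
                self._simulate()
            else:
                self._cache["occurrences"] = OccurrenceSet.from_csv(self.cfg.occurrences_csv)
        return self._cache["occurrences"]

    def study_area(self) -> FeatureGeometry:
        if "study_area" not in self._cache:
            if self.cfg.study_area_geojson and "simulate" not in self.cfg.stages:
                obj = json.loads(pathlib.Path(self.cfg.study_area_geojson).read_text())
                self._cache["study_area"] = FeatureGeometry.from_geojson(obj)
            else:
                self._simulate()
        return self._cache["study_area"]

    def _simulate(self):
        if "truth" in self._cache:
            return
        params = LandscapeParams(**self.cfg.landscape)
        params.seed = derive_seed(self.cfg.master_seed, "landscape-master")
        stack, truth, sb, cb, occ = simulate_study(
            params, self.cfg.n_survey, self.cfg.n_citizen
        )
        self._cache.update(stack=stack, truth=truth, survey_bias=sb,
                           citizen_bias=cb, occurrences=occ,
                           study_area=truth.study_area)

    def settings(self) -> ModelSettings:
        if "settings" not in self._cache:
            s = self.cfg.model_settings()
            if s.predictors is None:
                sel = self._cache.get("selection")
                if sel is not None:
                    s.predictors = [n for n in sel.retained if n != "depth"]
            self._cache["settings"] = s
        return self._cache["settings"]

    # -- stages -------------------------------------------------------------
    def stage_simulate(self) -> dict:
        self._simulate()
        stack_dir = self.outdir / "stack"
        write_stack(self._cache["stack"], stack_dir)
        self._cache["occurrences"].to_csv(self.outdir / "occurrences.csv")
        truth = self._cache["truth"]
        write_geotiff(truth.true_suitability, self.outdir / "true_suitability.tif")
        (self.outdir / "study_area.geojson").write_text(
            json.dumps(truth.study_area.to_geojson()))
        (self.outdir / "landscape_params.json").write_text(json.dumps(
            dataclasses.asdict(truth.generating_params), default=str, indent=2))
        return {"stack_dir": str(stack_dir),
                "occurrences": str(self.outdir / "occurrences.csv")}

    def stage_prepare(self) -> dict:
        stack = self.stack()
        occ = self.occurrences()
        survey = occ.subset_source("survey")
        citizen = occ.subset_source("citizen")
        merged, report = merge_occurrences(survey, citizen, self.study_area())
        self._cache["occurrences"] = merged
        return {"merge_report": report, "n_layers": len(stack.names)}

    def stage_select(self) -> dict:
        stack = self.stack()
        occ = self.occurrences()
        # A uniform reference background over valid cells for the
        # single-variable AIC comparisons.
        from .grid import RasterGrid
        from .occurrences import draw_background

        ref = stack.reference
        uniform = ref.with_values(
            np.where(ref.nodata_mask, np.nan, 1.0), ref.nodata_mask.copy())
        bg = draw_background(uniform, max(200, len(occ)),
                             derive_seed(self.cfg.master_seed, "selection-bg"))
        design = extract_design(stack, occ.xy, bg.xy)
        report = prune_collinear(stack, design, k=self.settings().gam_k)
        self._cache["selection"] = report
        self._cache.pop("settings", None)  # recompute with the pruned set
        (self.outdir / "selection.json").write_text(report.to_json())
        return {"retained": report.retained,
                "removed": [r["name"] for r in report.removed]}

    def stage_tune(self) -> dict:
        stack = self.stack().subset(self.settings().predictors or self.stack().names)
        occ = self.occurrences()
        from .evaluation import ModelSettings as _MS
        from .occurrences import build_bias_surface, draw_background

        s = self.settings()
        bias = build_bias_surface(occ, self.study_area(), stack.reference,
                                  s.bandwidth, s.buffer, s.focal_window)
        pool = draw_background(bias, s.pool_size,
                               derive_seed(self.cfg.master_seed, "tune-pool"))
        gam_table, gam_sel = tune_gam(
            occ.xy, pool, stack, repeats=self.cfg.tune_repeats,
            n_bg_candidates=self.cfg.tune_n_bg_candidates,
            seed=derive_seed(self.cfg.master_seed, "tune-gam"))
        mx_table, mx_sel = tune_maxent(
            occ.xy, pool, stack, repeats=self.cfg.tune_repeats,
            n_bg_candidates=self.cfg.tune_n_bg_candidates,
            seed=derive_seed(self.cfg.master_seed, "tune-maxent"))
        gam_table.to_csv(self.outdir / "tuning_gam.csv", index=False)
        mx_table.to_csv(self.outdir / "tuning_maxent.csv", index=False)
        s.gam_k = int(gam_sel["k"])
        s.maxent_beta = float(mx_sel["beta"])
        s.maxent_background = int(mx_sel["n_background"])
        return {"gam_selected": gam_sel, "maxent_selected": mx_sel}

    def stage_fit(self) -> dict:
        run = run_engines(self.occurrences(), self.stack(), self.study_area(),
                          self.settings(), derive_seed(self.cfg.master_seed, "fit"))
        self._cache["run"] = run
        for engine in ("gam", "maxent"):
            unc = run[engine]["uncertainty"]
            write_geotiff(run[engine]["prediction"], self.outdir / f"{engine}_suitability.tif")
            write_geotiff(unc.standard_error, self.outdir / f"{engine}_se.tif")
            write_geotiff(unc.coefficient_of_variation, self.outdir / f"{engine}_cv.tif")
        gam_fit = run["gam"]["fit"]
        conc = concurvity_index(gam_fit)
        flagged = [n for n, v in conc.items() if v > self.cfg.concurvity_threshold]
        (self.outdir / "gam_fit.json").write_text(json.dumps(gam_fit.to_json_dict()))
        (self.outdir / "maxent.lambdas").write_text(run["maxent"]["fit"].to_lambdas_text())
        return {
            "gam": {"mean_auc": run["gam"]["cv"]["mean_auc"],
                    "mean_tss": run["gam"]["cv"]["mean_tss"],
                    "deviance_explained": gam_fit.deviance_explained,
                    "concurvity": conc, "concurvity_flagged": flagged},
            "maxent": {"mean_auc": run["maxent"]["cv"]["mean_auc"],
                       "mean_tss": run["maxent"]["cv"]["mean_tss"],
                       "regularized_gain": run["maxent"]["fit"].regularized_gain,
                       "unregularized_gain": run["maxent"]["fit"].unregularized_gain},
        }

    def stage_importance(self) -> dict:
        if "run" not in self._cache:
            self.stage_fit()
        run = self._cache["run"]
        s = self.settings()
        gam_design = run["gam"]["design"]
        specs = [build_smooth(gam_design.table[n].to_numpy(float), s.gam_k, n)
                 for n in gam_design.predictor_names]
        dev_table = deviance_importance(gam_design, specs)
        contrib = percent_contribution(run["maxent"]["fit"])
        perm = permutation_importance(
            run["maxent"]["fit"], run["maxent"]["design"].presences(),
            run["maxent"]["design"].background(),
            derive_seed(self.cfg.master_seed, "permutation"))
        dev_table.to_csv(self.outdir / "gam_importance.csv", index=False)
        contrib.merge(perm, on="predictor").to_csv(
            self.outdir / "maxent_importance.csv", index=False)
        return {
            "gam_top": dev_table.iloc[0]["predictor"],
            "maxent_contribution_top": contrib.iloc[0]["predictor"],
            "maxent_permutation_top": perm.iloc[0]["predictor"],
        }

    def stage_ablate(self) -> dict:
        report = ablation_citizen_science(
            self.occurrences(), self.stack(), self.study_area(), self.settings(),
            derive_seed(self.cfg.master_seed, "ablate"))
        for engine in ("gam", "maxent"):
            key = f"{engine}_difference"
            if key in report:
                write_geotiff(report[key], self.outdir / f"ablation_{key}.tif")
        (self.outdir / "ablation_summary.json").write_text(
            json.dumps(report["summaries"], indent=2))
        self._cache["ablation"] = report
        return report["summaries"]

    def stage_report(self) -> dict:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.manifest, indent=2, default=str))
        return {"manifest": str(path)}

    # -- driver -------------------------------------------------------------
    def run(self) -> dict:
        for stage in STAGES:
            if stage not in self.cfg.stages:
                continue
            log.info("stage %s: starting", stage)
            t0 = time.perf_counter()
            try:
                outputs = getattr(self, f"stage_{stage}")()
                self.manifest["stages"][stage] = {
                    "status": "ok",
                    "seconds": round(time.perf_counter() - t0, 3),
                    "outputs": outputs,
                }
            except Exception as err:  # noqa: BLE001 - manifest records failure
                log.exception("stage %s failed", stage)
                self.manifest["stages"][stage] = {
                    "status": "failed", "error": f"{type(err).__name__}: {err}",
                    "seconds": round(time.perf_counter() - t0, 3),
                }
                break
        if "report" not in self.cfg.stages:
            (self.outdir / "manifest.json").write_text(
                json.dumps(self.manifest, indent=2, default=str))
        return self.manifest


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in canonical order; returns the manifest."""
    return _Pipeline(config).run()
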