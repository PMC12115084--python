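"""End-to-end pipeline: survey -> risk -> drivers -> SDM -> suitability.

Driven by a YAML/JSON config (:class:`PipelineConfig`).  Any input path
left unset is generated synthetically under the output directory, so a
bare config with only ``output_dir`` runs a fully reproducible demo.
Every stage writes its results under ``output_dir`` and the manifest
records versions, seeds and SHA-256 hashes of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__, drivers, maxent, risk, suitability, survey, synth
from .rasters import EnvStack, write_ascii_grid

logger = logging.getLogger("invade")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    output_dir: str = "invade_out"
    survey_csv: str | None = None
    occurrence_csv: str | None = None
    raster_dir: str | None = None  # current-scenario stack (.asc per layer)
    scenario_raster_dirs: dict[str, str] = field(default_factory=dict)
    scoresheet_json: str | None = None
    invader: str = "Solidago canadensis"
    screening_threshold: float = 0.75
    split_ratio: float = 0.75
    n_background: int = 10000
    reg_multipliers: tuple[float, ...] = (0.5, 1.0, 2.0)
    feature_classes: tuple[str, ...] = ("linear", "quadratic", "hinge")
    transform: str = "cloglog"
    seed: int = 42
    # synthetic-demo knobs (used only when the matching input is unset)
    demo_grid: tuple[int, int] = (60, 60)
    demo_n_occurrences: int = 400
    demo_n_plots: int = 595

    def __post_init__(self) -> None:
        if not 0 < self.screening_threshold < 1:
            raise ValueError("screening_threshold must be in (0, 1)")
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must be in (0, 1)")
        if self.n_background <= 0:
            raise ValueError("n_background must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = sorted(set(data) - set(known))
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        for key in ("reg_multipliers", "feature_classes", "demo_grid"):
            if key in known and isinstance(known[key], list):
                known[key] = tuple(known[key])
        return cls(**known)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    rng_seed = config.seed
    manifest: dict = {"version": __version__, "seed": rng_seed, "stages": [], "outputs": {}}
    artifacts: list[str] = []

    def record(stage: str, **info) -> None:
        manifest["stages"].append({"name": stage, **info})
        logger.info("stage %s done", stage)

    # ---- inputs (generate whatever is missing) ------------------------
    stage = "inputs"
    try:
        if config.raster_dir:
            stack = EnvStack.from_directory(config.raster_dir, categorical={"landcover"})
        else:
            stack = synth.gen_landscape(
                synth.LandscapeSpec(
                    n_rows=config.demo_grid[0], n_cols=config.demo_grid[1],
                    seed=rng_seed,
                )
            )
            stack.to_directory(os.path.join(out, "rasters", "current"))
        scenario_stacks: dict[tuple[str, str], EnvStack] = {}
        if config.scenario_raster_dirs:
            for tag, path in config.scenario_raster_dirs.items():
                scen, _, period = tag.partition("_")
                scenario_stacks[(scen, period)] = EnvStack.from_directory(
                    path, categorical={"landcover"}
                )
        else:
            scenario_stacks = synth.gen_scenario_stacks(stack, seed=rng_seed + 100)

        if config.survey_csv:
            plots = survey.read_survey(config.survey_csv)
        else:
            plots = synth.gen_survey(
                stack, synth.SurveySpec(n_plots=config.demo_n_plots, seed=rng_seed + 1)
            )
            survey.write_survey(plots, os.path.join(out, "survey.csv"))
            artifacts.append(os.path.join(out, "survey.csv"))

        if config.occurrence_csv:
            occ = maxent.OccurrenceSet.from_csv(config.occurrence_csv)
        else:
            truth = synth.TruthModel(
                coef_linear={"bio16": 0.1, "bio6": 0.3},
                coef_quadratic={"bio8": -0.004},
            )
            occ = synth.gen_occurrences(
                stack, truth, n=config.demo_n_occurrences, seed=rng_seed + 2
            )
            occ.to_csv(os.path.join(out, "occurrences.csv"))
            artifacts.append(os.path.join(out, "occurrences.csv"))

        if config.scoresheet_json:
            sheet = risk.RiskScoresheet.from_json(config.scoresheet_json)
        else:
            sheet = synth.gen_risk_scoresheet(1, seed=rng_seed + 3, species=config.invader)
        record(stage, n_plots=len(plots), n_occurrences=len(occ), n_scenarios=len(scenario_stacks))
    except Exception as err:  # noqa: BLE001 - stage context matters more
        raise StageError(stage, err) from err

    # ---- survey stage -------------------------------------------------
    stage = "survey"
    try:
        occ_rate = survey.occurrence_rate(plots, config.invader)
        fam = survey.family_composition(plots)
        summary = survey.community_summary(plots)
        inv_rel, oth_rel = [], []
        for p in plots:
            for m in survey.relative_metrics(p):
                (inv_rel if m.species_name == config.invader else oth_rel).append(m.rel_height)
        ttest = survey.welch_t_test(inv_rel, oth_rel) if len(inv_rel) > 1 else None
        summary.to_csv(os.path.join(out, "community_summary.csv"), index=False)
        artifacts.append(os.path.join(out, "community_summary.csv"))
        with open(os.path.join(out, "survey_stats.json"), "w") as fh:
            json.dump(
                {
                    "occurrence_rate": occ_rate,
                    "family_composition": fam,
                    "welch_t_rel_height": ttest,
                },
                fh, indent=2,
            )
        artifacts.append(os.path.join(out, "survey_stats.json"))
        record(stage, occurrence_rate_pct=round(occ_rate["rate"], 1))
    except Exception as err:
        raise StageError(stage, err) from err

    # ---- risk stage ---------------------------------------------------
    stage = "risk"
    try:
        result = risk.assess(sheet)
        with open(os.path.join(out, "risk_result.json"), "w") as fh:
            json.dump(result.to_dict(), fh, indent=2)
        artifacts.append(os.path.join(out, "risk_result.json"))
        record(stage, composite=round(result.P, 2), level=result.level)
    except Exception as err:
        raise StageError(stage, err) from err

    # ---- drivers stage ------------------------------------------------
    stage = "drivers"
    try:
        table = drivers.build_driver_table(plots, stack, config.invader)
        screen = drivers.collinearity_screen(table, threshold=config.screening_threshold)
        kept = [c for c in table.columns if c in screen["retained"] or c == drivers.RESPONSE]
        fit = drivers.fit_glm(table[kept])
        fit.table.to_csv(os.path.join(out, "glm_coefficients.csv"))
        artifacts.append(os.path.join(out, "glm_coefficients.csv"))
        with open(os.path.join(out, "glm_fit.json"), "w") as fh:
            json.dump({**fit.to_json_dict(), "screen": {
                "retained": screen["retained"], "dropped": screen["dropped"]}}, fh, indent=2)
        artifacts.append(os.path.join(out, "glm_fit.json"))
        record(stage, r_squared=round(fit.r_squared, 3), n=fit.n)
    except Exception as err:
        raise StageError(stage, err) from err

    # ---- sdm stage ----------------------------------------------------
    stage = "sdm"
    try:
        occ_valid = occ.filter_valid(stack)
        bg_env, _ = maxent.sample_background(stack, n=config.n_background, seed=rng_seed + 10)
        pres_env_all = stack.sample(occ_valid.points[:, 0], occ_valid.points[:, 1])
        screen = maxent.spearman_screen(
            pres_env_all, background_env=bg_env, names=stack.names,
            threshold=config.screening_threshold, categorical=stack.categorical,
        )
        names = screen["retained"]
        cols = [stack.names.index(n) for n in names]
        pres_env = pres_env_all[:, cols]
        bg_env_r = bg_env[:, cols]
        train, test = maxent.split_train_test(
            np.arange(len(pres_env)), ratio=config.split_ratio, seed=rng_seed + 11
        )
        tuned = maxent.tune_model(
            pres_env[train], bg_env_r, names,
            categorical=stack.categorical & set(names),
            reg_multipliers=config.reg_multipliers,
            feature_class_sets=(config.feature_classes,),
            seed=rng_seed + 12,
        )
        model = tuned["best"]["model"]
        auc_train = maxent.auc(model, pres_env[train], bg_env_r)
        auc_test = maxent.auc(model, pres_env[test], bg_env_r)
        contrib = maxent.ContributionReport(
            percent_contribution=maxent.percent_contribution(model),
            permutation_importance=maxent.permutation_importance(
                model, pres_env[test], bg_env_r, seed=rng_seed + 13
            ),
            jackknife=maxent.jackknife_gains(
                model.feature_set, pres_env[train], bg_env_r,
                reg_multiplier=tuned["best"]["reg_multiplier"],
            ),
        )
        model.to_json(os.path.join(out, "maxent_model.json"))
        artifacts.append(os.path.join(out, "maxent_model.json"))
        contrib.to_frame().to_csv(os.path.join(out, "contributions.csv"), index=False)
        artifacts.append(os.path.join(out, "contributions.csv"))
        with open(os.path.join(out, "sdm_eval.json"), "w") as fh:
            json.dump(
                {
                    "auc_train": auc_train, "auc_test": auc_test,
                    "split_ratio": config.split_ratio, "seed": rng_seed,
                    "retained_variables": names, "dropped_variables": screen["dropped"],
                    "reg_multiplier": tuned["best"]["reg_multiplier"],
                },
                fh, indent=2,
            )
        artifacts.append(os.path.join(out, "sdm_eval.json"))

        surfaces = {("current", ""): maxent.predict_surface(model, stack)}
        for key, scen_stack in scenario_stacks.items():
            surfaces[key] = maxent.predict_surface(model, scen_stack)
        for (scen, period), surf in surfaces.items():
            tag = scen if not period else f"{scen}_{period}"
            path = os.path.join(out, f"suitability_{tag}.asc")
            write_ascii_grid(path, surf, stack.origin[0], stack.origin[1], stack.cell_size)
            artifacts.append(path)
        record(stage, auc_test=round(auc_test, 3), n_retained=len(names))
    except Exception as err:
        raise StageError(stage, err) from err

    # ---- suitability stage --------------------------------------------
    stage = "suitability"
    try:
        current = surfaces[("current", "")]
        breaks = suitability.jenks_breaks(current[~np.isnan(current)], k=4, seed=rng_seed)
        cell_area = stack.cell_area()
        reports = []
        for (scen, period), surf in surfaces.items():
            cm = suitability.classify(surf, breaks, cell_size=stack.cell_size)
            reports.append(
                suitability.class_areas(cm, cell_area, scenario=scen or "current", period=period)
            )
        current_report = reports[0]
        deltas = [
            suitability.scenario_delta(current_report, r) for r in reports[1:]
        ]
        table_df = suitability.scenario_table(reports)
        table_df.to_csv(os.path.join(out, "scenario_table.csv"), index=False)
        artifacts.append(os.path.join(out, "scenario_table.csv"))
        with open(os.path.join(out, "scenario_deltas.json"), "w") as fh:
            json.dump(
                [
                    {
                        "scenario": d.scenario, "period": d.period,
                        "area_change_km2": d.area_change_km2,
                        "total_suitable_change_points": d.total_suitable_change_points,
                    }
                    for d in deltas
                ],
                fh, indent=2,
            )
        artifacts.append(os.path.join(out, "scenario_deltas.json"))
        record(
            stage,
            breaks=[round(b, 4) for b in breaks.breaks],
            current_total_suitable_pct=round(current_report.total_suitable_pct, 2),
        )
    except Exception as err:
        raise StageError(stage, err) from err

    # ---- manifest -----------------------------------------------------
    stage = "manifest"
    manifest["outputs"] = {os.path.relpath(p, out): _sha256(p) for p in artifacts}
    manifest["stages"].append({"name": stage})
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
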