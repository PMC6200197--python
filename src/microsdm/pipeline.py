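"""End-to-end pipeline: terrain → interpolation → SDM → scenario → report.

The pipeline reproduces a microscale habitat analysis either from measured
inputs (points CSV, patch GeoJSON, factor-sample CSV, scenario config) or
from the synthetic study system, writing every intermediate layer plus a
machine-readable summary into a run directory.

Stages
------
1. **simulate** (synthetic runs) — terrain points, true factor fields,
   presence raster from a known logistic response, patch polygons.
2. **terrain** — DEM (0.1 m), slope, aspect (+4-code reclass), TPI (1 m
   circular neighbourhood), six-class landform map, patch overlay areas.
3. **interpolate** — ordinary kriging of every sampled factor from the
   54-point design, with leave-one-out validation (MPE, RMSSE).
4. **fit** — presence–absence GLM on the topographic + kriged stack,
   screened by the AUC gate; permutation factor importance. Synthetic runs
   also refit on the true factor fields as a ground-truth recovery check.
5. **scenario** — trench counterfactual, probability prediction,
   three-class suitability with area accounting and strata report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as mio
from .errors import MicrosdmError, PipelineError
from .fieldstats import anova_lsd
from .geostat import cross_validate, krige_factor
from .raster import RasterGrid, write_ascii_grid
from .scenario import (
    ScenarioSpec,
    apply_scenario,
    reclassify_suitability,
    suitability_report,
)
from .sdm import (
    FactorStack,
    PresenceAbsenceGLM,
    SDMResults,
    build_training,
    select_model,
)
from .synthetic import (
    ResponseSpec,
    TerrainSpec,
    generate_factor_fields,
    generate_presence,
    generate_sampling_design,
    generate_terrain,
    generate_trenches,
    sample_stack,
    trench_count_for_area,
)
from .terrain import (
    classify_microtopography,
    compute_aspect,
    compute_slope,
    compute_tpi,
    grid_dem,
    overlay_class_areas,
    patches_from_mask,
    rasterize_polygons,
    reclassify_aspect,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "default_response"]

logger = logging.getLogger(__name__)


def default_response(seed: int = 0) -> ResponseSpec:
    """The bundled ground-truth response: the species favours the mild,
    moist, fertile end of the gradient (cool growing-season soil, moist
    spring soil, higher total N), with an intercept giving roughly the
    1:3 presence:absence imbalance of a patchy distribution."""
    return ResponseSpec(
        true_coefficients={
            "UT_avg_summer_autumn": -3.0,
            "UM_avg_spring": 3.0,
            "N_total": 2.0,
        },
        intercept=-2.0,
        seed=seed,
    )


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, with field-standard defaults.

    Grid and classification defaults: 0.1 m cells, 1 m TPI radius, TPI
    cuts (−0.3, −0.05, 0.15, 0.4) SD, 7° slope cut, AUC gate 0.9,
    suitability thresholds 0.5/0.75, α = 0.05.
    """

    # input paths (None → synthesize)
    points_csv: str | None = None
    patches_geojson: str | None = None
    samples_csv: str | None = None
    scenario_config: str | None = None
    # synthetic specs
    terrain: TerrainSpec = field(default_factory=TerrainSpec)
    response: ResponseSpec | None = None
    trench_density_per_ha: float = 600.0
    # grid / classification
    cell_size: float = 0.1
    tpi_radius: float = 1.0
    tpi_cuts: tuple = (-0.3, -0.05, 0.15, 0.4)
    slope_cut: float = 7.0
    # geostatistics
    variogram_family: str = "spherical"
    # model
    l2: float = 0.0
    auc_threshold: float = 0.9
    importance_permutations: int = 3
    # suitability
    t_low: float = 0.5
    t_high: float = 0.75
    # misc
    alpha: float = 0.05
    seed: int = 0
    write_rasters: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["terrain"] = dataclasses.asdict(self.terrain)
        d["response"] = dataclasses.asdict(self.response) if self.response else None
        return d


@dataclass
class PipelineResult:
    """Everything the pipeline computed, plus the run directory."""

    run_dir: str
    dem: RasterGrid
    microtopo: RasterGrid
    presence: RasterGrid
    class_areas: pd.DataFrame
    cv_summary: pd.DataFrame
    results: SDMResults
    importance: pd.DataFrame
    suitability: "object"
    strata_report: pd.DataFrame
    summary: dict
    recovery: dict | None = None


def _write(grid: RasterGrid, run_dir: str, name: str, enabled: bool) -> None:
    if enabled:
        write_ascii_grid(grid, os.path.join(run_dir, name))


def run_pipeline(config: PipelineConfig, run_dir: str) -> PipelineResult:
    """Execute every stage and write artifacts + ``summary.json`` to
    ``run_dir``. A stage failure raises :class:`PipelineError` naming the
    stage; artifacts written so far are left in place."""
    os.makedirs(run_dir, exist_ok=True)
    log_path = os.path.join(run_dir, "run.log")
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("microsdm")
    root.addHandler(handler)
    try:
        return _run(config, run_dir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, run_dir: str) -> PipelineResult:
    seed = int(config.seed)
    synthetic = config.points_csv is None
    wr = config.write_rasters

    # ---- stage: simulate / load points --------------------------------
    stage = "simulate"
    try:
        if synthetic:
            tspec = dataclasses.replace(config.terrain, seed=seed)
            points = generate_terrain(tspec)
            mio.write_points_csv(points, os.path.join(run_dir, "points.csv"))
        else:
            points = mio.read_points_csv(config.points_csv)
    except MicrosdmError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: terrain ------------------------------------------------
    stage = "terrain"
    try:
        dem = grid_dem(points, cell_size=config.cell_size)
        slope = compute_slope(dem)
        aspect = compute_aspect(dem)
        aspect_class = reclassify_aspect(aspect)
        tpi = compute_tpi(dem, radius=config.tpi_radius)
        microtopo = classify_microtopography(
            tpi, slope, tpi_cuts=config.tpi_cuts, slope_cut=config.slope_cut
        )
        for name, g in [("dem", dem), ("slope", slope), ("aspect", aspect),
                        ("aspect_class", aspect_class), ("tpi", tpi),
                        ("microtopo", microtopo)]:
            _write(g, run_dir, f"{name}.asc", wr)
    except MicrosdmError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: presence (patches) -------------------------------------
    stage = "presence"
    try:
        true_stack = None
        if synthetic:
            response = config.response or default_response(seed + 1)
            response = dataclasses.replace(response, seed=seed + 1)
            true_stack = generate_factor_fields(dem, tpi, seed=seed + 4)
            presence_draw = generate_presence(true_stack, response)
            patches = patches_from_mask(presence_draw)
            mio.write_geojson_polygons(
                patches, os.path.join(run_dir, "patches.geojson")
            )
            presence = rasterize_polygons(patches, dem)
        else:
            response = None
            patches = mio.read_geojson_polygons(config.patches_geojson)
            presence = rasterize_polygons(patches, dem)
        _write(presence, run_dir, "presence.asc", wr)
        class_areas = overlay_class_areas(microtopo, presence)
        class_areas.to_csv(os.path.join(run_dir, "patch_class_areas.csv"),
                           index=False)
    except MicrosdmError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: interpolate --------------------------------------------
    stage = "interpolate"
    try:
        if synthetic:
            design = generate_sampling_design(microtopo, seed=seed + 2)
            samples = sample_stack(true_stack, design)
            mio.write_samples_csv(samples, os.path.join(run_dir, "samples.csv"))
        else:
            samples = mio.read_samples_csv(config.samples_csv)
        meta_cols = {"x", "y", "row", "col", "gully_type", "microtopo"}
        factor_cols = [c for c in samples.columns if c not in meta_cols]
        kriged = {}
        cv_rows = []
        if wr:
            os.makedirs(os.path.join(run_dir, "kriged"), exist_ok=True)
        for fac in factor_cols:
            pred, var, vg = krige_factor(
                samples, fac, dem, family=config.variogram_family
            )
            kriged[fac] = pred
            _write(pred, run_dir, os.path.join("kriged", f"{fac}.asc"), wr)
            if vg.degenerate:
                cv_rows.append({"factor": fac, "mpe": 0.0, "rmsse": np.nan,
                                "degenerate": True})
            else:
                rep = cross_validate(
                    samples["x"].to_numpy(), samples["y"].to_numpy(),
                    samples[fac].to_numpy(), vg, factor=fac,
                )
                cv_rows.append({
                    "factor": fac,
                    "mpe": rep.mean_prediction_error,
                    "rmsse": rep.rms_standardized_error,
                    "degenerate": False,
                })
        cv_summary = pd.DataFrame(cv_rows)
        cv_summary.to_csv(os.path.join(run_dir, "kriging_cv.csv"), index=False)
        # field statistics on the sample table (group letters per factor)
        stats_rows = []
        for fac in factor_cols:
            try:
                res = anova_lsd(samples[fac], samples["microtopo"],
                                alpha=config.alpha)
            except MicrosdmError:
                continue
            for _, r in res.group_stats.iterrows():
                stats_rows.append({
                    "factor": fac, "group": r["group"], "n": int(r["n"]),
                    "mean": round(r["mean"], 2), "se": round(r["se"], 2),
                    "letters": res.letters[r["group"]],
                    "F": round(res.f_statistic, 3), "p": res.p_value,
                })
        pd.DataFrame(stats_rows).to_csv(
            os.path.join(run_dir, "factor_group_stats.csv"), index=False
        )
    except MicrosdmError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: fit -----------------------------------------------------
    stage = "fit"
    try:
        stack_layers = {"altitude": dem, "slope": slope,
                        "aspect_class": aspect_class}
        stack_layers.update(kriged)
        stack = FactorStack(stack_layers)
        train = build_training(presence, stack)
        model = PresenceAbsenceGLM(train)
        results = model.fit(l2=config.l2)
        selected = select_model([results], threshold=config.auc_threshold)
        selected.to_json(os.path.join(run_dir, "model.json"))
        importance = selected.factor_importance(
            k=config.importance_permutations, seed=seed + 5
        )
        importance.to_csv(os.path.join(run_dir, "importance.csv"), index=False)
        recovery = None
        if synthetic:
            # ground-truth check: refit the generating model (the response's
            # own factors, true fields) and compare coefficient signs
            truth_stack = FactorStack({
                n: true_stack[n] for n in response.true_coefficients
            })
            truth_train = build_training(presence, truth_stack)
            truth_res = PresenceAbsenceGLM(truth_train).fit(l2=config.l2)
            signs = {}
            for name, coef in response.true_coefficients.items():
                est = truth_res.params.get(name, np.nan)
                signs[name] = {
                    "true": coef,
                    "estimated": float(est),
                    "sign_recovered": bool(np.sign(est) == np.sign(coef)),
                }
            big = [s for n, s in signs.items()
                   if abs(response.true_coefficients[n]) >= 1.0]
            recovery = {
                "signs": signs,
                "recovery_rate_large_coefs": (
                    100.0 * sum(s["sign_recovered"] for s in big) / len(big)
                    if big else np.nan
                ),
                "truth_fit_auc": truth_res.training_auc,
            }
    except MicrosdmError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: scenario ------------------------------------------------
    stage = "scenario"
    try:
        if config.scenario_config is not None:
            spec = mio.read_scenario_config(config.scenario_config)
        else:
            area = (dem.n_valid * dem.cell_area)
            n_trench = trench_count_for_area(area, config.trench_density_per_ha)
            trenches = generate_trenches(dem, n_trench, seed=seed + 3)
            # reference-stand replacement values: the mean of each kriged
            # factor layer over valley presence cells — the species' core
            # habitat, the conditions a thriving reference stand recreates,
            # expressed on the interpolated scale the model was trained on.
            # (All-presence means are diluted by marginal cells near the
            # decision boundary.)
            pres = presence.mask & (presence.values == 1)
            core = pres & (microtopo.values == 1)
            if not core.any():
                core = pres
            replacements = {
                fac: float(np.nanmean(kriged[fac].values[core]))
                for fac in kriged
            }
            spec = ScenarioSpec(trenches=trenches, replacements=replacements)
            mio.write_geojson_polygons(
                trenches, os.path.join(run_dir, "trenches.geojson")
            )
            mio.write_scenario_config(
                spec, os.path.join(run_dir, "scenario.json"), "trenches.geojson"
            )
        scen_stack = apply_scenario(stack, spec)
        prob = selected.predict(scen_stack)
        _write(prob, run_dir, "probability_scenario.asc", wr)
        suit = reclassify_suitability(prob, t_low=config.t_low,
                                      t_high=config.t_high)
        _write(suit.grid, run_dir, "suitability.asc", wr)
        suit.areas.to_csv(os.path.join(run_dir, "suitability_areas.csv"),
                          index=False)
        strata = suitability_report(suit, microtopo, spec.trenches)
        strata.to_csv(os.path.join(run_dir, "suitability_strata.csv"),
                      index=False)
    except MicrosdmError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: report --------------------------------------------------
    stage = "report"
    try:
        summary = {
            "seed": seed,
            "config": config.to_dict(),
            "n_points": len(points),
            "grid": {"n_rows": dem.n_rows, "n_cols": dem.n_cols,
                     "cell_size": dem.cell_size,
                     "valid_area_m2": dem.n_valid * dem.cell_area},
            "presence": {
                "n_presence": int((presence.values == 1).sum()),
                "n_absence": int((presence.values == 0).sum()),
                "patch_area_m2": float((presence.values == 1).sum())
                * presence.cell_area,
            },
            "patch_class_areas": class_areas.to_dict(orient="records"),
            "kriging_cv": cv_summary.to_dict(orient="records"),
            "model": {
                "kind": selected.model_kind,
                "training_auc": selected.training_auc,
                "accuracy_band": selected.accuracy_band,
                "converged": selected.converged,
                "l2": selected.l2,
                "n_factors": len(selected.model.factor_names),
            },
            "importance_top5": importance.head(5).to_dict(orient="records"),
            "suitability": {
                "thresholds": [suit.t_low, suit.t_high],
                "areas": suit.areas.to_dict(orient="records"),
            },
            "strata": strata.to_dict(orient="records"),
            "recovery": recovery,
        }
        with open(os.path.join(run_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    except (MicrosdmError, OSError) as exc:
        raise PipelineError(stage, str(exc)) from exc

    return PipelineResult(
        run_dir=run_dir, dem=dem, microtopo=microtopo, presence=presence,
        class_areas=class_areas, cv_summary=cv_summary, results=selected,
        importance=importance, suitability=suit, strata_report=strata,
        summary=summary, recovery=recovery,
    )
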