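"""End-to-end orchestration: scene -> metrics -> models -> maps -> emissions.

Stage order mirrors the estimation chain:

1. simulate the scene (or accept one built elsewhere),
2. post-fire LiDAR metric rasters on the 30 m grid,
3. LiDAR biomass model calibrated on the field plots (70/30 split, grid
   search with 10-fold CV),
4. post-fire LiDAR AGB map, H50 correction, corrected AGB map,
5. stratified pixel sampling (unburned + low severity) against the
   corrected LiDAR AGB reference,
6. optical models for the pre-fire and post-fire images, wall-to-wall maps,
7. dilution-bias correction of every map against its reference pairs,
8. biomass consumption for three method pairs, severity-stratum
   aggregation, combustion completeness, carbon and CO2-equivalent,
9. uncertainty: two-step RMSE composition, residual correlogram,
   autocorrelation-aware stratum standard errors, variances of correlated
   differences.

Every stage derives its random seed deterministically from the scene seed,
so a rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import emissions as em
from . import svr
from .correction import (H50AUCWReference, correct_h50, corrected_agb_map,
                         fit_h50_aucw_reference)
from .extrapolation import AGBMap, build_training_table, predict_agb_map
from .lidar import normalize_intensity, rasterize_metrics
from .optical import build_feature_stack
from .scene import SEVERITY_CODES, Scene, SceneConfig, filter_plots, generate_scene
from .uncertainty import (Correlogram, UncertaintyBudget, compose_two_step_error,
                          difference_variance, fit_correlogram, stratum_mean_se)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)

METHOD_PAIRS = (
    ("landsat_pre", "landsat_post"),
    ("landsat_pre", "lidar"),
    ("landsat_pre", "lidar_corrected"),
)


@dataclass
class PipelineConfig:
    """Everything a full run needs; nested scene config carries the seed."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    n_optical_samples: int = 514
    calibration_fraction: float = 0.7
    lidar_features: tuple[str, ...] = svr.EXPERT_FEATURES_LIDAR
    optical_features: tuple[str, ...] = svr.EXPERT_FEATURES_OPTICAL
    cv_folds: int = 10
    histogram_bins: int = 10
    correlogram_max_lag_m: float = 300.0
    min_reference_agb: float = 1.0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        scene = SceneConfig(**d.pop("scene", {}))
        return cls(scene=scene, **d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineResult:
    """Everything a run produces, ready for rendering or assertions."""

    config: PipelineConfig
    scene: Scene
    metric_stack: dict[str, np.ndarray]
    corrected_stack: dict[str, np.ndarray]
    lidar_model: object
    h50_reference: H50AUCWReference
    optical_models: dict[str, object]
    maps: dict[str, AGBMap]
    fit_tables: dict[str, pd.DataFrame]
    reports: dict[str, em.EmissionReport]
    cc_table: pd.DataFrame
    budget: UncertaintyBudget
    timings_s: dict[str, float]

    @property
    def true_consumed_Tg(self) -> float:
        sc = self.scene
        m = sc.perimeter
        return float(sc.true_consumed_Mg_ha()[m].sum()) * sc.config.cell_area_ha * 1e-6

    def headline_consumed_Tg(self) -> float:
        return self.reports["landsat_pre-lidar_corrected"].total()


def _seed(base: int, k: int) -> int:
    return int(np.random.SeedSequence([base, 9000 + k]).generate_state(1)[0] % (2**31))


def _manifold_anchors(X, y, feature_names, reference,
                      h50_anchors=(0.5, 1.5, 3.0)):
    """Anchor points/values for model selection below the plot support.

    The calibration plots' AGB follows a tight power law in the median
    canopy height; extrapolating that trend to low-stature points placed on
    the intact-forest H50-AUCW curve supplies target predictions where no
    plot can exist (the cover filter removes near-bare plots).
    """
    names = list(feature_names)
    h50 = X[:, names.index("H50")]
    ok = (h50 > 0) & (y > 0)
    coef = np.polyfit(np.log(h50[ok]), np.log(y[ok]), 1)
    points = np.zeros((len(h50_anchors), len(names)))
    values = np.empty(len(h50_anchors))
    for i, h in enumerate(h50_anchors):
        points[i, names.index("H50")] = h
        points[i, names.index("AUCW")] = reference(np.array([h]))[0]
        values[i] = float(np.exp(coef[1] + coef[0] * np.log(h)))
    return points, values


def _fit_table(y_cal, p_cal, y_val, p_val, n_features: int) -> pd.DataFrame:
    rows = []
    rows.append(svr.fit_metrics(y_cal, p_cal, n_features, "calibration"))
    if y_val.size:
        rows.append(svr.fit_metrics(y_val, p_val, n_features, "validation"))
        rows.append(svr.fit_metrics(np.concatenate([y_cal, y_val]),
                                    np.concatenate([p_cal, p_val]),
                                    n_features, "combined"))
    return pd.DataFrame([dataclasses.asdict(r) for r in rows]).set_index("label")


def run_pipeline(config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None,
                 scene: Scene | None = None) -> PipelineResult:
    """Run every stage on a (generated or supplied) scene.

    When ``out_dir`` is given, maps, tables, models and the JSON report are
    written there; see :func:`write_outputs`.
    """
    if config is None:
        config = PipelineConfig()
    cfg = config
    base_seed = cfg.scene.seed
    timings: dict[str, float] = {}

    def tic(stage):
        timings[stage] = time.perf_counter()

    def toc(stage):
        timings[stage] = time.perf_counter() - timings[stage]
        log.info("stage %-18s %.1f s", stage, timings[stage])

    tic("simulate")
    if scene is None:
        scene = generate_scene(cfg.scene)
    toc("simulate")

    # ---- post-fire LiDAR metrics --------------------------------------
    tic("lidar_metrics")
    ref_range = scene.reference_range_m
    stack = rasterize_metrics(
        (normalize_intensity(t, ref_range) for t in scene.iter_tiles("post")),
        scene.shape)
    toc("lidar_metrics")

    # ---- LiDAR model on field plots -----------------------------------
    tic("train_lidar")
    plots = filter_plots(scene.plots)
    feats = cfg.lidar_features
    Xp = np.array([[stack[f][p.cell] for f in feats] for p in plots])
    yp = np.array([p.plot_agb_Mg_ha for p in plots])
    cal, val = svr.split_calibration_validation(
        yp, cfg.calibration_fraction, seed=_seed(base_seed, 1))
    # the intact-forest H50-AUCW curve, needed both for the fire correction
    # and for anchoring model selection below the plot support
    unburned = scene.severity == 0
    usable = unburned & np.isfinite(stack["H50"]) & (stack["H50"] > 0)
    reference = fit_h50_aucw_reference(stack["H50"][usable],
                                       stack["AUCW"][usable])
    # low-stature anchors: no plot can have near-zero canopy (such plots are
    # excluded by the cover filter), so the model's behavior below the
    # support is pinned to the power-law trend of the calibration plots
    # evaluated on the intact-forest structural curve
    anchors, anchor_vals = _manifold_anchors(Xp[cal], yp[cal], feats, reference)
    h_star, g_star, _, lidar_model = svr.grid_search_cv(
        Xp[cal], yp[cal], k=cfg.cv_folds, seed=_seed(base_seed, 2),
        feature_names=feats, anchor_points=anchors,
        anchor_values=anchor_vals, anchor_calibration=(Xp, yp))
    fit_tables = {"lidar": _fit_table(
        yp[cal], lidar_model.predict(Xp[cal]),
        yp[val], lidar_model.predict(Xp[val]), len(feats))}
    rmse1 = float(fit_tables["lidar"].loc["combined", "rmse"])
    rel1 = float(fit_tables["lidar"].loc["combined", "rel_rmse_pct"])
    toc("train_lidar")

    # ---- LiDAR AGB maps and the H50 correction ------------------------
    tic("h50_correction")
    agb_lidar = corrected_agb_map(stack, lidar_model)  # uncorrected features
    corrected = correct_h50(stack, reference, scene.perimeter)
    agb_lidar_corr = corrected_agb_map(corrected, lidar_model)
    maps: dict[str, AGBMap] = {
        "lidar": AGBMap(np.maximum(agb_lidar, 0.0), "lidar"),
        "lidar_corrected": AGBMap(np.maximum(agb_lidar_corr, 0.0),
                                  "lidar_corrected"),
    }
    # dilution-bias correction against the plot pairs (unburned buffer,
    # where corrected and uncorrected estimates coincide)
    est_plots = lidar_model.predict(Xp)
    for key in ("lidar", "lidar_corrected"):
        maps[key] = em.bias_correct(maps[key], yp, est_plots)
    toc("h50_correction")

    # ---- optical extrapolation ----------------------------------------
    tic("train_optical")
    ref_map = maps["lidar_corrected"].values
    feat_pre = build_feature_stack(scene.reflectance_pre, scene.dem)
    feat_post = build_feature_stack(scene.reflectance_post, scene.dem)
    sample_mask = ((scene.severity == SEVERITY_CODES["unburned"])
                   | (scene.severity == SEVERITY_CODES["low"]))
    sample_mask &= np.isfinite(ref_map) & (ref_map >= cfg.min_reference_agb)
    sample_idx = svr.stratified_histogram_sample(
        ref_map, sample_mask, n=cfg.n_optical_samples,
        bins=cfg.histogram_bins, seed=_seed(base_seed, 3))

    optical_models: dict[str, object] = {}
    paired_residuals: dict[str, np.ndarray] = {}
    for date, feat in (("pre", feat_pre), ("post", feat_post)):
        table = build_training_table(sample_idx, feat, ref_map,
                                     cfg.optical_features)
        Xo = table.loc[:, list(cfg.optical_features)].to_numpy()
        yo = table["agb"].to_numpy()
        cal_o, val_o = svr.split_calibration_validation(
            yo, cfg.calibration_fraction, seed=_seed(base_seed, 4))
        _, _, _, model_o = svr.grid_search_cv(
            Xo[cal_o], yo[cal_o], k=cfg.cv_folds,
            seed=_seed(base_seed, 5), feature_names=cfg.optical_features)
        optical_models[date] = model_o
        fit_tables[f"landsat_{date}"] = _fit_table(
            yo[cal_o], model_o.predict(Xo[cal_o]),
            yo[val_o], model_o.predict(Xo[val_o]), len(cfg.optical_features))
        agb_map = predict_agb_map(model_o, feat, f"landsat_{date}")
        est_samples = model_o.predict(Xo)
        maps[f"landsat_{date}"] = em.bias_correct(agb_map, yo, est_samples)
        paired_residuals[date] = est_samples - yo
    rel2 = {d: float(fit_tables[f"landsat_{d}"].loc["combined", "rel_rmse_pct"])
            for d in ("pre", "post")}
    rmse2 = {d: float(fit_tables[f"landsat_{d}"].loc["combined", "rmse"])
             for d in ("pre", "post")}
    toc("train_optical")

    # ---- consumption, strata, carbon ----------------------------------
    tic("emissions")
    severity = scene.severity
    inside = scene.perimeter
    reports: dict[str, em.EmissionReport] = {}
    cc_rows = {}
    pre_map = maps["landsat_pre"]
    for pre_name, post_name in METHOD_PAIRS:
        pair = f"{pre_name}-{post_name}"
        delta = em.consumption_map(pre_map, maps[post_name])
        delta = np.where(inside, delta, np.nan)
        reports[pair] = em.aggregate_by_stratum(
            delta, severity, pixel_area_ha=scene.config.cell_area_ha,
            method_pair=pair)
        cc = {}
        for name in em.BURNED_STRATA:
            m = inside & (severity == SEVERITY_CODES[name])
            pre_stock = float(np.nansum(pre_map.values[m])) \
                * scene.config.cell_area_ha * 1e-6
            cc[name] = em.combustion_completeness(
                reports[pair].table.loc[name, "delta_biomass_Tg"], pre_stock)
        cc_rows[pair] = cc
    cc_table = pd.DataFrame(cc_rows).T
    toc("emissions")

    # ---- uncertainty ---------------------------------------------------
    tic("uncertainty")
    sigma_rel = compose_two_step_error(rel1, rel2["pre"])
    resid = np.where(sample_mask, maps["landsat_pre"].values - ref_map, np.nan)
    try:
        rho = fit_correlogram(resid, cell_size_m=scene.config.cell_size_m,
                              max_lag_m=cfg.correlogram_max_lag_m)
    except ValueError:
        rho = Correlogram(phi_m=1e-6)
    r_pair = float(np.corrcoef(paired_residuals["pre"],
                               paired_residuals["post"])[0, 1])
    budget = UncertaintyBudget(
        rmse1_Mg_ha=rmse1, rmse2_Mg_ha=rmse2["pre"],
        rel_rmse1_pct=rel1, rel_rmse2_pct=rel2["pre"], correlogram=rho)
    for name in em.BURNED_STRATA:
        m = inside & (severity == SEVERITY_CODES[name])
        mean_pre = float(np.nanmean(pre_map.values[m]))
        mean_post = float(np.nanmean(maps["lidar_corrected"].values[m]))
        se_pre = stratum_mean_se(sigma_rel / 100.0 * mean_pre, m, rho,
                                 scene.config.cell_size_m)
        se_post = stratum_mean_se(rel1 / 100.0 * mean_post, m, rho,
                                  scene.config.cell_size_m)
        var_d = difference_variance(se_pre**2, se_post**2,
                                    r_pair * se_pre * se_post)
        budget.stratum_se_Mg_ha[name] = float(np.sqrt(var_d))
        mass_factor = int(m.sum()) * scene.config.cell_area_ha * 1e-6
        budget.stratum_se_delta_Tg[name] = float(np.sqrt(var_d)) * mass_factor
    budget.stratum_se_delta_Tg["total"] = float(
        np.sqrt(sum(v**2 for k, v in budget.stratum_se_delta_Tg.items()
                    if k in em.BURNED_STRATA)))
    toc("uncertainty")

    result = PipelineResult(
        config=cfg, scene=scene, metric_stack=stack,
        corrected_stack=corrected, lidar_model=lidar_model,
        h50_reference=reference, optical_models=optical_models, maps=maps,
        fit_tables=fit_tables, reports=reports, cc_table=cc_table,
        budget=budget, timings_s=timings)
    if out_dir is not None:
        write_outputs(result, Path(out_dir))
    return result


def write_outputs(result: PipelineResult, out_dir: Path) -> None:
    """Render CSV tables, GeoTIFF-style rasters and the JSON report."""
    from . import io as fio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, table in result.fit_tables.items():
        table.round(4).to_csv(out_dir / f"fit_{name}.csv")
    for pair, report in result.reports.items():
        report.table.round(4).to_csv(out_dir / f"emissions_{pair}.csv")
    result.cc_table.round(4).to_csv(out_dir / "combustion_completeness.csv")
    for name, agb_map in result.maps.items():
        fio.write_raster(out_dir / f"agb_{name}.tif", agb_map.values,
                         cell_size_m=result.scene.config.cell_size_m)
    fio.write_raster(out_dir / "severity.tif",
                     result.scene.severity.astype(np.int16),
                     cell_size_m=result.scene.config.cell_size_m)
    report = render_report(result)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))


def render_report(result: PipelineResult) -> dict:
    """Summary dictionary (numbers rounded to 2 decimals as in print)."""
    budget = result.budget
    out = {
        "headline": {
            "consumed_biomass_Tg": round(result.headline_consumed_Tg(), 2),
            "carbon_TgC": round(0.5 * result.headline_consumed_Tg(), 2),
            "co2e_Tg": round(0.5 * em.CO2_PER_C * result.headline_consumed_Tg(), 2),
            "uncertainty_Tg": round(budget.stratum_se_delta_Tg.get("total", 0.0), 2),
        },
        "true_consumed_Tg": round(result.true_consumed_Tg, 2),
        "model_fits": {k: v.round(4).to_dict("index")
                       for k, v in result.fit_tables.items()},
        "two_step_rel_rmse_pct": round(budget.rel_sigma_modeling_pct, 1),
        "emissions": {k: v.table.round(2).to_dict("index")
                      for k, v in result.reports.items()},
        "combustion_completeness": result.cc_table.round(2).to_dict("index"),
        "h50_reference": {"a": round(result.h50_reference.a, 4),
                          "b": round(result.h50_reference.b, 4)},
        "timings_s": {k: round(v, 1) for k, v in result.timings_s.items()},
    }
    return out
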