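"""Monte-Carlo two-stage upscaling: ensemble fits, prediction stacks,
CI95/uncertainty surfaces, reference-pixel filters and scenario drivers.

Two national-scale scenarios are supported:

* ``nfi_direct`` — satellite layers calibrated directly with noisy
  realizations of inventory-plot AGB.
* ``lidar_two_stage`` — plot AGB first upscaled to LiDAR strips
  (stage 1), the strip predictions then used as training data for the
  wall-to-wall satellite model (stage 2). Realization r of stage 2 consumes
  realization r of stage 1, so field error propagates through both stages.
* ``lidar_two_stage_screened`` — as above, but strip pixels whose stage-1
  relative uncertainty reaches 50% are excluded from stage-2 training.

Per-pixel uncertainty is summarized by the half-width of the empirical 95%
confidence interval across the ensemble, and by its ratio to the ensemble
mean (relative uncertainty, %).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._rng import child_seed
from .error_budget import ErrorBudget, RealizationSet, generate_realizations
from .model_tree import ModelTree, TrainConfig
from .scene import NODATA, PREDICTOR_NAMES, SyntheticScene, _write_layer
from .validation import stratified_split

logger = logging.getLogger(__name__)

CARBON_FRACTION = 0.48


@dataclass
class UncertaintySurface:
    """Per-pixel ensemble mean (t/ha), CI95 half-width (t/ha) and relative
    uncertainty (%); NaN marks nodata."""

    mean_agb: np.ndarray
    ci95_halfwidth: np.ndarray
    rel_uncertainty: np.ndarray


def residual_outlier_mask(observed: np.ndarray, predicted: np.ndarray,
                          k: float = 2.0) -> np.ndarray:
    """Keep-mask: True where |observed - predicted| <= k * SD(residuals).

    Screens reference plots whose model residuals are extreme — e.g. plots
    disturbed between field and remote-sensing acquisitions. Zero residual
    SD keeps everything.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    if observed.size < 3:
        raise ValueError("need at least 3 points")
    if k <= 0:
        raise ValueError("k must be > 0")
    resid = observed - predicted
    sd = resid.std(ddof=1)
    if sd == 0:
        return np.ones(observed.shape, dtype=bool)
    return np.abs(resid) <= k * sd


def mc_fit_predict(realizations: RealizationSet, train_predictors: np.ndarray,
                   target_predictors: np.ndarray,
                   config: TrainConfig | None = None,
                   learner_factory=None) -> np.ndarray:
    """Fit one model per realization and predict the target pixels.

    ``train_predictors`` is (m, p) at the m training units;
    ``target_predictors`` is (P, p) for the prediction domain. Training rows
    with non-finite predictors are dropped (count logged); target rows with
    non-finite predictors predict NaN. Negative predictions are clamped to
    zero. Returns an (n, P) prediction stack.
    """
    train_x = np.asarray(train_predictors, dtype=float)
    target_x = np.asarray(target_predictors, dtype=float)
    if train_x.ndim == 1:
        train_x = train_x[:, None]
    if target_x.ndim == 1:
        target_x = target_x[:, None]
    values = realizations.values
    if values.shape[0] < 2:
        raise ValueError("need at least 2 realizations")
    if values.shape[1] != train_x.shape[0]:
        raise ValueError("realization width must match training rows")
    good_train = np.isfinite(train_x).all(axis=1)
    dropped = int((~good_train).sum())
    if dropped:
        logger.info("mc_fit_predict: dropped %d training rows with nodata predictors", dropped)
    train_x = train_x[good_train]
    values = values[:, good_train]
    good_target = np.isfinite(target_x).all(axis=1)
    target_ok = target_x[good_target]

    if learner_factory is None:
        cfg = config or TrainConfig()
        learner_factory = lambda: ModelTree(cfg)    # noqa: E731

    stack = np.full((values.shape[0], target_x.shape[0]), np.nan)
    for r in range(values.shape[0]):
        model = learner_factory().fit(train_x, values[r])
        stack[r, good_target] = np.clip(model.predict(target_ok), 0.0, None)
    return stack


def ci95(stack: np.ndarray) -> np.ndarray:
    """Per-pixel CI95 half-width: (q97.5 - q2.5) / 2 across realizations,
    linear-interpolation empirical quantiles. All-NaN pixels stay NaN."""
    stack = np.asarray(stack, dtype=float)
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 realizations")
    any_finite = np.isfinite(stack).any(axis=0)
    out = np.full(stack.shape[1:], np.nan)
    if any_finite.any():
        sub = stack[:, any_finite]
        lo, hi = np.nanpercentile(sub, [2.5, 97.5], axis=0)
        out[any_finite] = (hi - lo) / 2.0
    return out


def relative_uncertainty(stack: np.ndarray, mean_guard: float = 1.0) -> UncertaintySurface:
    """Ensemble mean, CI95 half-width and 100*CI95/mean per pixel.

    Pixels whose ensemble mean falls below ``mean_guard`` (t/ha) get NaN
    relative uncertainty — the ratio is unstable as the mean approaches zero.
    """
    stack = np.asarray(stack, dtype=float)
    half = ci95(stack)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(np.isfinite(stack), stack, np.nan), axis=0)
    rel = np.full_like(mean, np.nan)
    ok = np.isfinite(mean) & (mean >= mean_guard) & np.isfinite(half)
    rel[ok] = 100.0 * half[ok] / mean[ok]
    return UncertaintySurface(mean_agb=mean, ci95_halfwidth=half, rel_uncertainty=rel)


def uncertainty_screen(surface: UncertaintySurface, threshold: float = 50.0) -> np.ndarray:
    """Keep-mask: relative uncertainty strictly below ``threshold`` percent
    and defined."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    rel = surface.rel_uncertainty
    return np.isfinite(rel) & (rel < threshold)


def forest_mask(tree_cover: np.ndarray, threshold: float = 10.0) -> np.ndarray:
    """Forest where tree cover strictly exceeds ``threshold`` percent
    (FAO-style definition)."""
    return np.asarray(tree_cover, dtype=float) > threshold


def total_carbon(agb: np.ndarray, pixel_area_ha: float,
                 factor: float = CARBON_FRACTION) -> float:
    """Total aboveground carbon (t C) over non-nodata pixels."""
    if not 0 < factor <= 1:
        raise ValueError("carbon fraction must be in (0, 1]")
    agb = np.asarray(agb, dtype=float)
    return float(np.nansum(agb) * pixel_area_ha * factor)


@dataclass
class ScenarioParams:
    """Knobs of a scenario run; defaults follow the reference workflow:
    100 realizations, the default field-error budget, 2-SD outlier screen,
    50% uncertainty screen, 15-degree slope exclusion, >10% tree-cover
    forest mask."""

    n_realizations: int = 100
    eps_field_pct: float | None = None      # None -> ErrorBudget.default().total_pct
    seed: int = 0
    train_config: TrainConfig = field(default_factory=TrainConfig)
    outlier_k: float = 2.0
    screen_threshold_pct: float = 50.0
    mean_guard: float = 1.0
    slope_max_deg: float = 15.0
    forest_cover_threshold_pct: float = 10.0
    stage2_max_train: int = 4000
    cal_fraction: float = 0.67
    agb_class_width: float = 30.0
    n_agb_classes: int = 10


@dataclass
class ScenarioResult:
    surface: UncertaintySurface
    stack: np.ndarray
    report: dict


SCENARIOS = ("nfi_direct", "lidar_two_stage", "lidar_two_stage_screened")


def _plots_for_training(scene: SyntheticScene, params: ScenarioParams):
    """Slope filter applied to the full plot list; returns (plots, report)."""
    plots = [p for p in scene.plots if p.slope_deg <= params.slope_max_deg]
    report = {
        "n_plots_total": len(scene.plots),
        "n_plots_steep_excluded": len(scene.plots) - len(plots),
        "n_plots_usable": len(plots),
    }
    return plots, report


def run_scenario(scene: SyntheticScene, scenario: str,
                 params: ScenarioParams | None = None) -> ScenarioResult:
    """Run one national-scale scenario on a scene.

    Returns the forest-masked uncertainty surface, the raw prediction stack
    and a report of plot/pixel counts at every filter step plus the total
    aboveground carbon of the mean map.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    params = params or ScenarioParams()
    eps = params.eps_field_pct
    if eps is None:
        eps = ErrorBudget.default().total_pct
    cfg = scene.config
    plots, report = _plots_for_training(scene, params)
    report.update({"scenario": scenario, "seed": params.seed,
                   "eps_field_pct": float(eps),
                   "n_realizations": params.n_realizations})
    sat_all = scene.predictor_matrix()          # (pixels, p)
    pixels = scene.shape[0] * scene.shape[1]

    if scenario == "nfi_direct":
        # strip plots are reserved for the LiDAR stage; the national model
        # is calibrated/validated on the remainder
        off_strip = [p for p in plots
                     if not scene.strip_mask[p.pixel(cfg.pixel_size)]]
        cal, val = stratified_split(off_strip, params.agb_class_width,
                                    params.n_agb_classes, params.cal_fraction,
                                    seed=child_seed(params.seed, "split"))
        report["n_plots_calibration"] = len(cal)
        report["n_plots_validation"] = len(val)
        if len(cal) < params.train_config.min_leaf_size:
            raise ValueError("too few calibration plots")
        rc = np.array([p.pixel(cfg.pixel_size) for p in cal])
        flat = rc[:, 0] * scene.shape[1] + rc[:, 1]
        train_x = sat_all[flat]
        base = np.array([p.agb for p in cal])
        realz = generate_realizations(base, eps, params.n_realizations,
                                      master_seed=child_seed(params.seed, "nfi_realizations"))
        stack = mc_fit_predict(realz, train_x, sat_all, params.train_config)
    else:
        strip_flat = np.flatnonzero(scene.strip_mask.ravel())
        on_strip = [p for p in plots
                    if scene.strip_mask[p.pixel(cfg.pixel_size)]]
        report["n_plots_on_strips"] = len(on_strip)
        if not on_strip:
            raise ValueError("no plots fall on the LiDAR strips")
        metrics_all = scene.metric_matrix()     # (pixels, k), NaN off-strip
        rc = np.array([p.pixel(cfg.pixel_size) for p in on_strip])
        flat = rc[:, 0] * scene.shape[1] + rc[:, 1]
        metrics_plots = metrics_all[flat]
        base = np.array([p.agb for p in on_strip])

        # outlier screen on a single fit against the un-noised response
        screen_model = ModelTree(params.train_config).fit(metrics_plots, base)
        keep = residual_outlier_mask(base, screen_model.predict(metrics_plots),
                                     k=params.outlier_k)
        report["n_plots_outlier_excluded"] = int((~keep).sum())
        report["n_plots_stage1_training"] = int(keep.sum())
        metrics_plots, base = metrics_plots[keep], base[keep]
        if base.size < params.train_config.min_leaf_size:
            raise ValueError("too few strip plots after outlier screening")

        realz = generate_realizations(base, eps, params.n_realizations,
                                      master_seed=child_seed(params.seed, "lidar_realizations"))
        stage1 = mc_fit_predict(realz, metrics_plots, metrics_all[strip_flat],
                                params.train_config)      # (n, strip pixels)
        s1_surface = relative_uncertainty(stage1, params.mean_guard)
        report["n_strip_pixels"] = int(strip_flat.size)

        train_sel = np.ones(strip_flat.size, dtype=bool)
        if scenario == "lidar_two_stage_screened":
            train_sel = uncertainty_screen(s1_surface, params.screen_threshold_pct)
            report["n_strip_pixels_below_screen"] = int(train_sel.sum())
            if train_sel.sum() < params.train_config.min_leaf_size:
                raise ValueError("uncertainty screen removed nearly all training pixels")
        sel_idx = np.flatnonzero(train_sel)
        if sel_idx.size > params.stage2_max_train:
            sub_rng = np.random.default_rng(child_seed(params.seed, "stage2_subsample"))
            sel_idx = np.sort(sub_rng.choice(sel_idx, params.stage2_max_train, replace=False))
        report["n_stage2_training_pixels"] = int(sel_idx.size)

        train_x = sat_all[strip_flat[sel_idx]]
        stage1_sel = RealizationSet(values=stage1[:, sel_idx],
                                    base=np.nanmean(stage1[:, sel_idx], axis=0),
                                    eps_field_pct=eps, master_seed=params.seed)
        stack = mc_fit_predict(stage1_sel, train_x, sat_all, params.train_config)
        report["stage1_mean_rel_uncertainty_pct"] = float(
            np.nanmean(s1_surface.rel_uncertainty))

    stack = stack.reshape(params.n_realizations, *scene.shape)
    surface = relative_uncertainty(stack.reshape(params.n_realizations, pixels),
                                   params.mean_guard)
    mean = surface.mean_agb.reshape(scene.shape)
    half = surface.ci95_halfwidth.reshape(scene.shape)
    rel = surface.rel_uncertainty.reshape(scene.shape)
    fmask = forest_mask(scene.predictor_layers["tree_cover"],
                        params.forest_cover_threshold_pct)
    mean = np.where(fmask, mean, np.nan)
    half = np.where(fmask, half, np.nan)
    rel = np.where(fmask, rel, np.nan)
    surface = UncertaintySurface(mean_agb=mean, ci95_halfwidth=half, rel_uncertainty=rel)
    report["n_forest_pixels"] = int(fmask.sum())
    report["mean_forest_agb_t_ha"] = float(np.nanmean(mean)) if fmask.any() else float("nan")
    report["mean_rel_uncertainty_pct"] = float(np.nanmean(rel)) if np.isfinite(rel).any() else float("nan")
    report["total_agc_t"] = total_carbon(mean, cfg.pixel_area_ha)
    return ScenarioResult(surface=surface, stack=stack, report=report)


def write_surfaces(result: ScenarioResult, outdir: str | Path) -> Path:
    """Persist a scenario result: agb_mean/agb_ci95/agb_uncert TIFFs
    (float32, nodata -9999) and report.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_layer(outdir / "agb_mean.tif", result.surface.mean_agb)
    _write_layer(outdir / "agb_ci95.tif", result.surface.ci95_halfwidth)
    _write_layer(outdir / "agb_uncert.tif", result.surface.rel_uncertainty)
    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=1)
    return outdir
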