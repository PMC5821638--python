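"""Validating a biomass map at pixel and hexagon scales.

Splits the plot network into calibration and validation sets stratified by
30 t/ha biomass classes, maps the scene with the direct NFI scenario, and
compares the map with held-out plots per pixel and per forest-area-weighted
hexagon.
"""

import numpy as np

from agbmc import (
    ScenarioParams,
    SceneConfig,
    fit_stats,
    forest_fraction_for_zones,
    forest_mask,
    generate_scene,
    hex_mesh,
    run_scenario,
    stratified_split,
    zonal_weighted_validation,
)

scene = generate_scene(SceneConfig(grid_rows=120, grid_cols=120,
                                   plot_spacing=500.0, seed=2))
result = run_scenario(scene, "nfi_direct",
                      ScenarioParams(n_realizations=30, seed=2))

plots = [p for p in scene.plots if p.slope_deg <= 15.0
         and not scene.strip_mask[p.pixel(100.0)]]
cal, val = stratified_split(plots, class_width=30.0, n_classes=10,
                            cal_fraction=0.67, seed=2)
print(f"plots: {len(cal)} calibration / {len(val)} validation")

mean_map = result.surface.mean_agb
obs, pred = [], []
for p in val:
    v = mean_map[p.pixel(100.0)]
    if np.isfinite(v):
        obs.append(p.agb)
        pred.append(v)
px = fit_stats(np.array(obs), np.array(pred))
print(f"pixel scale  : R2 {px.r2:.2f}, RMSE {px.rmse:.1f} t/ha, "
      f"bias {px.bias:+.1f} t/ha (n={px.n})")

zones = hex_mesh((0, 0, 12_000, 12_000), hex_area=4e6)
zones = forest_fraction_for_zones(
    zones, forest_mask(scene.predictor_layers["tree_cover"]), 100.0)
pairs, hx = zonal_weighted_validation(mean_map, val, zones, 100.0)
print(f"hexagon scale: R2 {hx.r2:.2f}, RMSE {hx.rmse:.1f} t/ha, "
      f"bias {hx.bias:+.1f} t/ha ({len(pairs)} hexagons)")
# Pixel-scale agreement is strong on this clean synthetic scene; at hexagon
# scale each cell holds only a handful of validation plots, so the plot-side
# mean is noisy and the correlation drops — with real inventories the
# aggregation works the other way, averaging out plot-scale error.
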