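"""Calibration/validation splitting and multi-scale map validation.

Plots are split into calibration and validation sets stratified by biomass
class (default ten 30 t/ha classes, last open-ended, 67% calibration per
class). Maps are validated at pixel level against held-out plots and at
zone level (hexagons or arbitrary regions), where both the map mean and the
plot mean within each zone are weighted by the zone's forest fraction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon, box

from .scene import PlotRecord


@dataclass
class FitStats:
    """Goodness-of-fit summary: squared Pearson correlation, root-mean-square
    error and bias (mean of predicted - observed)."""

    r2: float
    rmse: float
    bias: float
    n: int
    r2_defined: bool = True


@dataclass
class Zone:
    geometry: Polygon
    zone_id: int
    forest_fraction: float = 1.0

    def __post_init__(self):
        if self.geometry.is_empty:
            raise ValueError("zone geometry must be non-empty")
        if not 0.0 <= self.forest_fraction <= 1.0:
            raise ValueError("forest_fraction must be in [0, 1]")


def stratified_split(plots: list[PlotRecord], class_width: float = 30.0,
                     n_classes: int = 10, cal_fraction: float = 0.67,
                     seed: int = 0) -> tuple[list[PlotRecord], list[PlotRecord]]:
    """Partition plots into (calibration, validation) stratified by AGB class.

    Classes are [0, w), [w, 2w), ...; the last class is open-ended. Within
    each class, round-half-up of cal_fraction * n_c plots go to calibration
    (uniformly at random, reproducible from ``seed``), the rest to
    validation.
    """
    if class_width <= 0:
        raise ValueError("class_width must be > 0")
    if not 0 < cal_fraction < 1:
        raise ValueError("cal_fraction must be in (0, 1)")
    if not plots:
        return [], []
    rng = np.random.default_rng(seed)
    agb = np.array([p.agb for p in plots])
    classes = np.minimum((agb // class_width).astype(int), n_classes - 1)
    cal: list[PlotRecord] = []
    val: list[PlotRecord] = []
    for c in range(n_classes):
        idx = np.flatnonzero(classes == c)
        if idx.size == 0:
            continue
        n_cal = int(math.floor(cal_fraction * idx.size + 0.5))
        picked = rng.choice(idx, size=n_cal, replace=False) if n_cal else np.array([], dtype=int)
        picked_set = set(picked.tolist())
        for i in idx:
            (cal if i in picked_set else val).append(plots[i])
    return cal, val


def fit_stats(observed: np.ndarray, predicted: np.ndarray) -> FitStats:
    """R^2 (squared Pearson r), RMSE and bias of predictions.

    Zero variance in either vector leaves r2 undefined (NaN, flagged) while
    RMSE and bias are still returned.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    diff = pred - obs
    rmse = float(np.sqrt((diff**2).mean()))
    bias = float(diff.mean())
    if obs.std() == 0 or pred.std() == 0:
        return FitStats(r2=float("nan"), rmse=rmse, bias=bias, n=obs.size,
                        r2_defined=False)
    r = np.corrcoef(obs, pred)[0, 1]
    return FitStats(r2=float(r**2), rmse=rmse, bias=bias, n=obs.size)


def hex_mesh(bounds: tuple[float, float, float, float], hex_area: float) -> list[Zone]:
    """Flat-topped hexagonal tessellation covering ``bounds``.

    ``hex_area`` is the cell area in the bounds' squared units; the edge
    length follows from A = (3*sqrt(3)/2) * s^2. Cells are clipped at the
    bounds; empty intersections are dropped.
    """
    xmin, ymin, xmax, ymax = bounds
    if hex_area <= 0:
        raise ValueError("hex_area must be > 0")
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("degenerate bounds")
    s = math.sqrt(2.0 * hex_area / (3.0 * math.sqrt(3.0)))
    dx = 1.5 * s
    dy = math.sqrt(3.0) * s
    clip = box(xmin, ymin, xmax, ymax)
    zones: list[Zone] = []
    zid = 0
    i = 0
    cx = xmin
    while cx <= xmax + s:
        y0 = ymin + (dy / 2.0 if i % 2 else 0.0)
        cy = y0 - dy
        while cy <= ymax + dy:
            hexagon = Polygon(
                (cx + s * math.cos(a), cy + s * math.sin(a))
                for a in (k * math.pi / 3.0 for k in range(6))
            )
            cell = hexagon.intersection(clip)
            if not cell.is_empty and cell.area > 0:
                zones.append(Zone(geometry=cell, zone_id=zid))
                zid += 1
            cy += dy
        i += 1
        cx += dx
    return zones


def zonal_weighted_validation(
    map_mean: np.ndarray,
    plots: list[PlotRecord],
    zones: list[Zone],
    pixel_size: float,
) -> tuple[list[dict], FitStats]:
    """Forest-area-weighted zone-level comparison of a map with plots.

    For each zone, the mean of the map over the zone's valid (non-nodata)
    pixels and the mean AGB of in-zone plots are both multiplied by the
    zone's forest fraction; zones with no plots, no valid pixels or zero
    forest fraction are dropped. Pixel centres are at
    ((col + 0.5) * pixel_size, (row + 0.5) * pixel_size). Returns the
    per-zone pair records and FitStats over the pairs.
    """
    map_mean = np.asarray(map_mean, dtype=float)
    rows, cols = map_mean.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    px = (xx.ravel() + 0.5) * pixel_size
    py = (yy.ravel() + 0.5) * pixel_size
    vals = map_mean.ravel()
    plot_x = np.array([p.x for p in plots])
    plot_y = np.array([p.y for p in plots])
    plot_agb = np.array([p.agb for p in plots])
    pairs: list[dict] = []
    for zone in zones:
        if zone.forest_fraction == 0:
            continue
        in_zone_px = shapely.contains_xy(zone.geometry, px, py)
        zvals = vals[in_zone_px]
        zvals = zvals[np.isfinite(zvals)]
        in_zone_plots = shapely.contains_xy(zone.geometry, plot_x, plot_y) \
            if plots else np.array([], dtype=bool)
        if zvals.size == 0 or not in_zone_plots.any():
            continue
        w = zone.forest_fraction
        pairs.append({
            "zone_id": zone.zone_id,
            "obs": float(plot_agb[in_zone_plots].mean() * w),
            "pred": float(zvals.mean() * w),
            "weight": w,
            "n_plots": int(in_zone_plots.sum()),
        })
    if len(pairs) < 2:
        return pairs, FitStats(r2=float("nan"), rmse=float("nan"),
                               bias=float("nan"), n=len(pairs), r2_defined=False)
    obs = np.array([p["obs"] for p in pairs])
    pred = np.array([p["pred"] for p in pairs])
    return pairs, fit_stats(obs, pred)


def zones_to_geojson(zones: list[Zone], path=None) -> str:
    """Serialize zones as a GeoJSON FeatureCollection."""
    features = []
    for z in zones:
        features.append({
            "type": "Feature",
            "properties": {"zone_id": z.zone_id, "forest_fraction": z.forest_fraction},
            "geometry": shapely.geometry.mapping(z.geometry),
        })
    doc = json.dumps({"type": "FeatureCollection", "features": features})
    if path is not None:
        with open(path, "w") as fh:
            fh.write(doc)
    return doc


def zones_from_geojson(source) -> list[Zone]:
    from pathlib import Path

    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    doc = json.loads(text)
    zones = []
    for feat in doc["features"]:
        geom = shapely.geometry.shape(feat["geometry"])
        props = feat.get("properties", {})
        zones.append(Zone(geometry=geom, zone_id=int(props.get("zone_id", len(zones))),
                          forest_fraction=float(props.get("forest_fraction", 1.0))))
    return zones


def forest_fraction_for_zones(zones: list[Zone], forest: np.ndarray,
                              pixel_size: float) -> list[Zone]:
    """Fill each zone's forest_fraction from a boolean forest raster."""
    forest = np.asarray(forest, dtype=bool)
    rows, cols = forest.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    px = (xx.ravel() + 0.5) * pixel_size
    py = (yy.ravel() + 0.5) * pixel_size
    fvals = forest.ravel()
    out = []
    for z in zones:
        inside = shapely.contains_xy(z.geometry, px, py)
        frac = float(fvals[inside].mean()) if inside.any() else 0.0
        out.append(Zone(geometry=z.geometry, zone_id=z.zone_id, forest_fraction=frac))
    return out
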