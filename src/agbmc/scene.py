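"""Scene containers and disk round-trip.

A scene is a planar raster stack (one shared grid, pixel size in metres) with
a "true" aboveground-biomass (AGB) field, wall-to-wall predictor layers
(SAR backscatter, optical reflectance, NDVI, tree cover, terrain),
strip-limited LiDAR metrics, and a network of 1-ha inventory plots each
composed of four 0.04-ha subplots.

On disk a scene is a directory of single-band float32 TIFFs (nodata -9999),
a ``plots.csv`` table and a ``scene.yaml`` echoing the configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

NODATA = -9999.0

#: wall-to-wall predictor layers, in the order used for model matrices
PREDICTOR_NAMES = (
    "hh", "hv", "red", "nir", "swir1", "swir2",
    "ndvi", "tree_cover", "altitude", "slope",
)


@dataclass(frozen=True)
class SarConfig:
    """Backscatter-vs-AGB curves per polarization, dB domain.

    gamma0(AGB) = a_db + b_db * (1 - exp(-alpha * AGB)); ``looks`` is the
    gamma-speckle shape parameter (number of looks) of the intensity images.
    """

    hh_a_db: float = -12.0
    hh_b_db: float = 6.0
    hh_alpha: float = 0.015
    hv_a_db: float = -20.0
    hv_b_db: float = 10.0
    hv_alpha: float = 0.025
    looks: float = 4.0


@dataclass(frozen=True)
class OpticalConfig:
    """Saturating reflectance curves: base + amp * (1 - exp(-AGB/efold)) + noise."""

    red_base: float = 0.15
    red_amp: float = -0.10
    red_efold: float = 60.0
    nir_base: float = 0.25
    nir_amp: float = 0.15
    nir_efold: float = 80.0
    swir1_base: float = 0.20
    swir1_amp: float = -0.12
    swir1_efold: float = 70.0
    swir2_base: float = 0.15
    swir2_amp: float = -0.10
    swir2_efold: float = 70.0
    noise_sd: float = 0.005


@dataclass(frozen=True)
class SceneConfig:
    """Everything needed to generate a synthetic scene deterministically.

    Defaults emulate a dry-to-subhumid forest landscape: mean AGB ~45 t/ha,
    SD ~35 t/ha, maximum 160 t/ha, 1-ha (100 m) pixels, a 1-km inventory
    grid of 1-ha plots with four 0.04-ha subplots, and sparse LiDAR strips.
    The strips cover ~5% of the scene, so only ~5% of the plot network
    supports the strip-level model while the rest calibrates the national
    model — the order-of-magnitude training asymmetry between airborne
    sampling and a wall-to-wall inventory that drives two-stage error
    propagation.
    """

    grid_rows: int = 200
    grid_cols: int = 200
    pixel_size: float = 100.0          # m
    agb_mean: float = 45.0             # t/ha
    agb_sd: float = 35.0               # t/ha
    agb_max: float = 160.0             # t/ha
    correlation_length: float = 500.0  # m, exponential-covariance scale
    plot_spacing: float = 700.0        # m between plot centres
    subplots_per_plot: int = 4
    subplot_area: float = 0.04         # ha
    subplot_noise_pct: float = 10.0    # relative measurement noise per subplot
    geolocation_sd: float = 10.0       # m, plot-centre jitter
    lidar_strip_width: int = 5         # pixels
    lidar_coverage_fraction: float = 0.05
    n_lidar_metrics: int = 12
    lidar_noise_frac: float = 0.1      # per-metric noise SD as fraction of signal SD
    lidar_shared_noise_frac: float = 0.2   # CV of the latent canopy factor shared by all metrics
    sar: SarConfig = field(default_factory=SarConfig)
    optical: OpticalConfig = field(default_factory=OpticalConfig)
    tree_cover_midpoint: float = 25.0  # t/ha AGB at 50% cover
    tree_cover_scale: float = 8.0      # t/ha logistic scale
    seed: int = 0

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size**2 / 1e4

    def validate(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be positive")
        for name in ("pixel_size", "correlation_length", "plot_spacing",
                     "subplot_area", "agb_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.agb_sd < 0 or self.agb_mean < 0:
            raise ValueError("agb_mean and agb_sd must be >= 0")
        if self.agb_max < self.agb_mean:
            raise ValueError("agb_max must be >= agb_mean")
        if not 0.0 <= self.lidar_coverage_fraction <= 1.0:
            raise ValueError("lidar_coverage_fraction must be in [0, 1]")
        if self.n_lidar_metrics < 1:
            raise ValueError("n_lidar_metrics must be >= 1")
        if self.lidar_strip_width < 1:
            raise ValueError("lidar_strip_width must be >= 1")
        if self.plot_spacing < self.pixel_size:
            raise ValueError("plot_spacing must be at least one pixel")
        if self.sar.looks <= 0:
            raise ValueError("SAR looks must be > 0")
        if self.geolocation_sd < 0 or self.subplot_noise_pct < 0:
            raise ValueError("noise parameters must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        if "sar" in d and isinstance(d["sar"], dict):
            d["sar"] = SarConfig(**d["sar"])
        if "optical" in d and isinstance(d["optical"], dict):
            d["optical"] = OpticalConfig(**d["optical"])
        return cls(**d)


@dataclass
class PlotRecord:
    """One 1-ha inventory plot: centre location (m), per-subplot AGB (t/ha),
    plot AGB (subplot mean extrapolated to 1 ha) and terrain slope."""

    plot_id: int
    x: float
    y: float
    subplot_agb: tuple[float, ...]
    agb: float
    slope_deg: float

    def pixel(self, pixel_size: float) -> tuple[int, int]:
        """(row, col) of the pixel containing the plot centre."""
        return int(self.y // pixel_size), int(self.x // pixel_size)


@dataclass
class SyntheticScene:
    config: SceneConfig
    true_agb: np.ndarray
    predictor_layers: dict[str, np.ndarray]
    lidar_metrics: dict[str, np.ndarray]   # NaN outside strip_mask
    strip_mask: np.ndarray                 # boolean raster
    plots: list[PlotRecord]

    @property
    def shape(self) -> tuple[int, int]:
        return self.true_agb.shape

    def predictor_matrix(self, names: tuple[str, ...] = PREDICTOR_NAMES) -> np.ndarray:
        """(n_pixels, n_layers) matrix in a fixed layer order."""
        return np.column_stack([self.predictor_layers[n].ravel() for n in names])

    def metric_matrix(self) -> np.ndarray:
        names = sorted(self.lidar_metrics)
        return np.column_stack([self.lidar_metrics[n].ravel() for n in names])

    def plot_pixels(self) -> np.ndarray:
        """(n_plots, 2) array of (row, col) per plot."""
        px = self.config.pixel_size
        return np.array([p.pixel(px) for p in self.plots], dtype=int)

    def plot_agb(self) -> np.ndarray:
        return np.array([p.agb for p in self.plots], dtype=float)


def _write_layer(path: Path, arr: np.ndarray) -> None:
    out = np.asarray(arr, dtype=np.float32).copy()
    out[~np.isfinite(out)] = NODATA
    tifffile.imwrite(path, out)


def _read_layer(path: Path) -> np.ndarray:
    arr = tifffile.imread(path).astype(float)
    arr[arr == NODATA] = np.nan
    return arr


def write_scene(scene: SyntheticScene, outdir: str | Path) -> Path:
    """Persist a scene as a directory of TIFF layers + plots.csv + scene.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_layer(outdir / "true_agb.tif", scene.true_agb)
    for name, arr in scene.predictor_layers.items():
        _write_layer(outdir / f"pred_{name}.tif", arr)
    for name, arr in scene.lidar_metrics.items():
        _write_layer(outdir / f"lidar_{name}.tif", arr)
    tifffile.imwrite(outdir / "strip_mask.tif", scene.strip_mask.astype(np.uint8))
    rows = []
    for p in scene.plots:
        row = {"plot_id": p.plot_id, "x": p.x, "y": p.y}
        for i, v in enumerate(p.subplot_agb, start=1):
            row[f"agb_sub{i}"] = v
        row["agb_plot"] = p.agb
        row["slope_deg"] = p.slope_deg
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "plots.csv", index=False)
    with open(outdir / "scene.yaml", "w") as fh:
        yaml.safe_dump(scene.config.to_dict(), fh)
    return outdir


def read_scene(indir: str | Path) -> SyntheticScene:
    indir = Path(indir)
    with open(indir / "scene.yaml") as fh:
        config = SceneConfig.from_dict(yaml.safe_load(fh))
    true_agb = _read_layer(indir / "true_agb.tif")
    predictor_layers = {}
    lidar_metrics = {}
    for f in sorted(indir.glob("pred_*.tif")):
        predictor_layers[f.stem[len("pred_"):]] = _read_layer(f)
    for f in sorted(indir.glob("lidar_*.tif")):
        lidar_metrics[f.stem[len("lidar_"):]] = _read_layer(f)
    strip_mask = tifffile.imread(indir / "strip_mask.tif").astype(bool)
    df = pd.read_csv(indir / "plots.csv")
    sub_cols = sorted(c for c in df.columns if c.startswith("agb_sub"))
    plots = [
        PlotRecord(
            plot_id=int(r["plot_id"]), x=float(r["x"]), y=float(r["y"]),
            subplot_agb=tuple(float(r[c]) for c in sub_cols),
            agb=float(r["agb_plot"]), slope_deg=float(r["slope_deg"]),
        )
        for _, r in df.iterrows()
    ]
    return SyntheticScene(config, true_agb, predictor_layers, lidar_metrics,
                          strip_mask, plots)
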