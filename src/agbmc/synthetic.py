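"""Synthetic scene generation.

Builds landscapes with the statistical structure the upscaling analysis
assumes: a spatially autocorrelated AGB field; a regular grid of 1-ha
inventory plots (four 0.04-ha subplots each) with geolocation jitter and
subplot measurement noise; partial-coverage LiDAR strips carrying
plot-scale canopy metrics that rise monotonically with AGB; and satellite
layers (dual-pol L-band backscatter with gamma speckle, saturating optical
reflectance, NDVI, tree cover, terrain).

Everything is deterministic given ``SceneConfig.seed``; each component draws
from its own hashed sub-seed so layers never perturb each other's noise.
"""

from __future__ import annotations

import numpy as np

from ._rng import child_rng
from .sar import ndvi as _ndvi
from .sar import power_to_db
from .scene import PlotRecord, SceneConfig, SyntheticScene


def gaussian_random_field(shape: tuple[int, int], corr_len_px: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-SD Gaussian random field, exponential covariance.

    Spectral synthesis: white noise filtered in Fourier space with the 2-D
    exponential-covariance spectral density S(k) ~ (1 + (kL)^2)^(-3/2).
    """
    if corr_len_px <= 0:
        raise ValueError("correlation length must be > 0")
    white = rng.standard_normal(shape)
    ky = np.fft.fftfreq(shape[0])[:, None] * 2 * np.pi
    kx = np.fft.fftfreq(shape[1])[None, :] * 2 * np.pi
    k2 = ky**2 + kx**2
    spectrum = (1.0 + k2 * corr_len_px**2) ** -1.5
    field = np.fft.ifft2(np.fft.fft2(white) * np.sqrt(spectrum)).real
    field -= field.mean()
    sd = field.std()
    if sd > 0:
        field /= sd
    return field


def generate_true_agb(config: SceneConfig) -> np.ndarray:
    """Spatially autocorrelated AGB field (t/ha), clipped to [0, agb_max]."""
    config.validate()
    shape = (config.grid_rows, config.grid_cols)
    if config.agb_sd == 0:
        return np.full(shape, float(config.agb_mean))
    rng = child_rng(config.seed, "true_agb")
    z = gaussian_random_field(shape, config.correlation_length / config.pixel_size, rng)
    agb = config.agb_mean + config.agb_sd * z
    return np.clip(agb, 0.0, config.agb_max)


def simulate_plots(scene: SyntheticScene, config: SceneConfig) -> list[PlotRecord]:
    """Place inventory plots on a regular grid with geolocation jitter.

    Each plot samples ``subplots_per_plot`` subplot AGB values at its pixel,
    perturbed by relative measurement noise; plot AGB is the subplot mean
    (densities in t/ha, so the mean is the 1-ha extrapolation). Slope is read
    from the scene's slope layer.
    """
    config.validate()
    rng = child_rng(config.seed, "plots")
    px = config.pixel_size
    extent_x = config.grid_cols * px
    extent_y = config.grid_rows * px
    xs = np.arange(config.plot_spacing / 2, extent_x, config.plot_spacing)
    ys = np.arange(config.plot_spacing / 2, extent_y, config.plot_spacing)
    slope = scene.predictor_layers.get("slope")
    plots: list[PlotRecord] = []
    pid = 0
    noise = config.subplot_noise_pct / 100.0
    for y0 in ys:
        for x0 in xs:
            x = x0 + rng.normal(0.0, config.geolocation_sd) if config.geolocation_sd > 0 else x0
            y = y0 + rng.normal(0.0, config.geolocation_sd) if config.geolocation_sd > 0 else y0
            x = float(np.clip(x, 0.0, extent_x - 1e-9))
            y = float(np.clip(y, 0.0, extent_y - 1e-9))
            row, col = int(y // px), int(x // px)
            truth = float(scene.true_agb[row, col])
            if noise > 0:
                subs = truth * (1.0 + noise * rng.standard_normal(config.subplots_per_plot))
            else:
                subs = np.full(config.subplots_per_plot, truth)
            subs = np.clip(subs, 0.0, None)
            slope_deg = float(slope[row, col]) if slope is not None else 0.0
            plots.append(PlotRecord(
                plot_id=pid, x=x, y=y,
                subplot_agb=tuple(float(s) for s in subs),
                agb=float(subs.mean()), slope_deg=slope_deg,
            ))
            pid += 1
    return plots


def _strip_mask(config: SceneConfig) -> np.ndarray:
    """Vertical strips of ``lidar_strip_width`` columns covering roughly
    ``lidar_coverage_fraction`` of the scene."""
    mask = np.zeros((config.grid_rows, config.grid_cols), dtype=bool)
    f = config.lidar_coverage_fraction
    if f <= 0:
        return mask
    if f >= 1:
        mask[:] = True
        return mask
    period = max(config.lidar_strip_width, int(round(config.lidar_strip_width / f)))
    cols = np.arange(config.grid_cols)
    mask[:, (cols % period) < config.lidar_strip_width] = True
    return mask


def simulate_lidar(scene: SyntheticScene, config: SceneConfig) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Strip-limited plot-scale LiDAR metrics.

    Metric k follows a power law of the local canopy state,
    m_k = a_k * (AGB * u)^b_k + noise, with coefficients drawn once per
    metric from its own sub-seed. The latent factor u (lognormal-free
    multiplicative Gaussian, CV = ``lidar_shared_noise_frac``) is shared by
    all metrics of a pixel: stands of equal biomass differ in canopy
    structure, so even a perfect regression of metrics on AGB retains
    irreducible plot-level scatter — the residual scatter that strip-level
    biomass models show against field plots. Metrics are NaN outside the
    strip mask. Returns (metrics, strip_mask).
    """
    config.validate()
    mask = _strip_mask(config)
    agb = scene.true_agb
    shared = config.lidar_shared_noise_frac
    if shared > 0:
        latent_rng = child_rng(config.seed, "lidar_latent")
        u = np.clip(1.0 + shared * latent_rng.standard_normal(agb.shape), 0.05, None)
    else:
        u = 1.0
    canopy = np.clip(agb, 0.0, None) * u
    metrics: dict[str, np.ndarray] = {}
    for k in range(config.n_lidar_metrics):
        rng = child_rng(config.seed, f"lidar_metric_{k}")
        a = rng.uniform(0.5, 2.0)
        b = rng.uniform(0.4, 1.2)
        signal = a * np.power(canopy, b)
        sd = signal[mask].std() if mask.any() else signal.std()
        noise_sd = config.lidar_noise_frac * sd
        layer = signal + (rng.standard_normal(agb.shape) * noise_sd if noise_sd > 0 else 0.0)
        layer = np.where(mask, layer, np.nan)
        metrics[f"m{k:02d}"] = layer
    return metrics, mask


def _sar_layer(agb: np.ndarray, a_db: float, b_db: float, alpha: float,
               looks: float, rng: np.random.Generator | None) -> np.ndarray:
    """Backscatter in dB: saturating dB curve, speckled in linear power."""
    gamma_db = a_db + b_db * (1.0 - np.exp(-alpha * np.clip(agb, 0.0, None)))
    power = 10.0 ** (gamma_db / 10.0)
    if rng is not None:
        if looks <= 0:
            raise ValueError("looks must be > 0")
        power = power * rng.gamma(looks, 1.0 / looks, size=agb.shape)
    return power_to_db(power)


def simulate_satellite(scene: SyntheticScene, config: SceneConfig,
                       speckle: bool = True) -> dict[str, np.ndarray]:
    """Wall-to-wall predictor layers.

    SAR: gamma-nought dB curves saturating with AGB, multiplied by
    gamma-distributed speckle (shape = number of looks) in linear power.
    Optical: saturating monotone reflectance curves plus Gaussian noise;
    NDVI from red/NIR; tree cover a noiseless logistic of AGB scaled to
    [0, 100]; altitude and slope from independent random fields.
    """
    config.validate()
    agb = scene.true_agb
    sar, opt = config.sar, config.optical
    layers: dict[str, np.ndarray] = {}
    hh_rng = child_rng(config.seed, "sar_hh") if speckle else None
    hv_rng = child_rng(config.seed, "sar_hv") if speckle else None
    layers["hh"] = _sar_layer(agb, sar.hh_a_db, sar.hh_b_db, sar.hh_alpha, sar.looks, hh_rng)
    layers["hv"] = _sar_layer(agb, sar.hv_a_db, sar.hv_b_db, sar.hv_alpha, sar.looks, hv_rng)

    for band in ("red", "nir", "swir1", "swir2"):
        base = getattr(opt, f"{band}_base")
        amp = getattr(opt, f"{band}_amp")
        efold = getattr(opt, f"{band}_efold")
        rng = child_rng(config.seed, f"optical_{band}")
        refl = base + amp * (1.0 - np.exp(-agb / efold))
        if opt.noise_sd > 0:
            refl = refl + rng.standard_normal(agb.shape) * opt.noise_sd
        layers[band] = np.clip(refl, 1e-4, None)

    layers["ndvi"] = _ndvi(layers["red"], layers["nir"])
    cover = 100.0 / (1.0 + np.exp(-(agb - config.tree_cover_midpoint) / config.tree_cover_scale))
    layers["tree_cover"] = np.clip(cover, 0.0, 100.0)

    terrain_rng = child_rng(config.seed, "terrain")
    corr_px = config.correlation_length / config.pixel_size
    alt_field = gaussian_random_field(agb.shape, corr_px, terrain_rng)
    slope_field = gaussian_random_field(agb.shape, corr_px, terrain_rng)
    layers["altitude"] = np.clip(1500.0 + 400.0 * alt_field, 0.0, None)
    layers["slope"] = 10.0 * np.abs(slope_field)
    return layers


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Full deterministic scene: AGB field, satellite layers, LiDAR strips, plots."""
    config.validate()
    true_agb = generate_true_agb(config)
    scene = SyntheticScene(config=config, true_agb=true_agb, predictor_layers={},
                           lidar_metrics={}, strip_mask=np.zeros_like(true_agb, dtype=bool),
                           plots=[])
    scene.predictor_layers = simulate_satellite(scene, config)
    scene.lidar_metrics, scene.strip_mask = simulate_lidar(scene, config)
    scene.plots = simulate_plots(scene, config)
    return scene
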