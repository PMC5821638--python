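"""Field-error budget and Monte-Carlo realization generation.

The error of field-estimated plot AGB is composed of three independent
relative components — tree-measurement error, allometric-model error and
within-plot sampling error — combined in quadrature:

    eps_field = sqrt(eps_measurement^2 + eps_allometry^2 + eps_sampling^2)

The sampling component follows from the plot design: four 0.04-ha subplots
per 1-ha plot versus the sampling intensity required for a +/-10% estimate.
Realizations multiply the reference AGB by (1 + eps_field * X), X ~ N(0,1),
independently per plot and realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import counter_rng

DEFAULT_N_REALIZATIONS = 100


def sampling_intensity(n_plots: float, subplot_area: float, reference_area: float) -> float:
    """Sampled fraction of a reference area, in percent."""
    if n_plots < 0:
        raise ValueError("n_plots must be >= 0")
    if subplot_area <= 0 or reference_area <= 0:
        raise ValueError("areas must be > 0")
    return 100.0 * n_plots * subplot_area / reference_area


def required_subplots(intensity: float, pixel_area: float, subplot_area: float) -> float:
    """Fractional number of subplots needed to reach ``intensity`` (%) in a pixel."""
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    if pixel_area <= 0 or subplot_area <= 0:
        raise ValueError("areas must be > 0")
    return intensity / 100.0 * pixel_area / subplot_area


def sampling_error(base_uncertainty: float, required: float, sampled: float) -> float:
    """Scale a base uncertainty (%) by sqrt(required / sampled) subplots."""
    if sampled <= 0:
        raise ValueError("sampled count must be > 0")
    if required <= 0:
        raise ValueError("required count must be > 0")
    if base_uncertainty < 0:
        raise ValueError("base_uncertainty must be >= 0")
    return base_uncertainty * np.sqrt(required / sampled)


def compose_error(components) -> float:
    """Root-sum-square of independent relative error components (%)."""
    comps = np.asarray(list(components), dtype=float)
    if comps.size == 0:
        return 0.0
    if (comps < 0).any():
        raise ValueError("error components must be >= 0")
    return float(np.sqrt((comps**2).sum()))


@dataclass(frozen=True)
class ErrorBudget:
    """Relative field-error components in percent; total is their RSS."""

    measurement_pct: float = 10.0
    allometry_pct: float = 11.0
    sampling_pct: float = field(default=0.0)

    def __post_init__(self):
        for name in ("measurement_pct", "allometry_pct", "sampling_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_pct(self) -> float:
        return compose_error([self.measurement_pct, self.allometry_pct, self.sampling_pct])

    @classmethod
    def default(cls) -> "ErrorBudget":
        """Budget for a 1-ha plot of four 0.04-ha subplots: 10% measurement,
        11% allometry, and sampling error derived from the intensity needed
        for a +/-10% estimate (160 subplots per 50 ha)."""
        intensity = sampling_intensity(160, 0.04, 50.0)          # 12.8 %
        required = required_subplots(intensity, 1.0, 0.04)       # 3.2 subplots
        samp = sampling_error(10.0, required, 4.0)               # 8.94 %
        return cls(measurement_pct=10.0, allometry_pct=11.0, sampling_pct=samp)


@dataclass
class RealizationSet:
    """n Monte-Carlo noisy copies of a reference AGB vector.

    ``values`` is an (n, m) matrix; row r is reproducible from
    (master_seed, r) alone.
    """

    values: np.ndarray
    base: np.ndarray
    eps_field_pct: float
    master_seed: int

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def save(self, path: str | Path) -> None:
        """Long-format CSV (realization, plot_id, agb) + YAML sidecar."""
        path = Path(path)
        n, m = self.values.shape
        df = pd.DataFrame({
            "realization": np.repeat(np.arange(n), m),
            "plot_id": np.tile(np.arange(m), n),
            "agb": self.values.ravel(),
        })
        df.to_csv(path, index=False)
        meta = {"eps_field_pct": float(self.eps_field_pct),
                "master_seed": int(self.master_seed),
                "n": int(n), "base": [float(v) for v in self.base]}
        with open(path.with_suffix(".yaml"), "w") as fh:
            yaml.safe_dump(meta, fh)

    @classmethod
    def load(cls, path: str | Path) -> "RealizationSet":
        path = Path(path)
        df = pd.read_csv(path)
        with open(path.with_suffix(".yaml")) as fh:
            meta = yaml.safe_load(fh)
        n, m = meta["n"], len(meta["base"])
        values = df.sort_values(["realization", "plot_id"])["agb"].to_numpy().reshape(n, m)
        return cls(values=values, base=np.asarray(meta["base"], dtype=float),
                   eps_field_pct=meta["eps_field_pct"], master_seed=meta["master_seed"])


def generate_realizations(base: np.ndarray, eps_field: float,
                          n: int = DEFAULT_N_REALIZATIONS,
                          master_seed: int = 0) -> RealizationSet:
    """Multiplicative-normal realizations: base * (1 + eps_field/100 * X).

    X ~ N(0, 1) i.i.d. per (realization, element); negative products are
    clipped to zero. Row r draws from a counter-based sub-seed so it can be
    regenerated independently of the others.
    """
    base = np.asarray(base, dtype=float)
    if (base < 0).any():
        raise ValueError("base AGB must be >= 0")
    if eps_field < 0:
        raise ValueError("eps_field must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    eps = eps_field / 100.0
    values = np.empty((n, base.size))
    for r in range(n):
        x = counter_rng(master_seed, r).standard_normal(base.size)
        values[r] = base * (1.0 + eps * x)
    np.clip(values, 0.0, None, out=values)
    return RealizationSet(values=values, base=base, eps_field_pct=float(eps_field),
                          master_seed=int(master_seed))
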