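"""SAR and optical preprocessing.

Multi-temporal speckle filtering (Quegan-style), equivalent number of looks
(ENL), NDVI and block aggregation. All speckle arithmetic is done in linear
power; dB conversion happens only at the boundaries.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter

DB_FLOOR = -50.0


def power_to_db(power: np.ndarray | float) -> np.ndarray:
    """10*log10(power), floored at -50 dB for non-positive power."""
    power = np.asarray(power, dtype=float)
    out = np.full(power.shape, DB_FLOOR)
    pos = power > 0
    out[pos] = 10.0 * np.log10(power[pos])
    return np.maximum(out, DB_FLOOR)


def db_to_power(db: np.ndarray | float) -> np.ndarray:
    return 10.0 ** (np.asarray(db, dtype=float) / 10.0)


def quegan_filter(stack: np.ndarray, window: int = 7) -> np.ndarray:
    """Multi-temporal speckle filter over M co-registered intensity images.

    J_k(x) = (<I_k>_w(x) / M) * sum_i I_i(x) / <I_i>_w(x)

    with <.>_w the local mean over a ``window`` x ``window`` box
    (mirror-padded at edges). Input and output are linear power, shape
    (M, rows, cols). Pixels where any local mean is non-positive pass
    through unfiltered. With M=1 the formula collapses to the identity.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must have shape (M, rows, cols)")
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    m = stack.shape[0]
    local = np.stack([uniform_filter(stack[i], size=window, mode="mirror")
                      for i in range(m)])
    bad = (local <= 0).any(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_sum = np.where(bad, 0.0, (stack / local)).sum(axis=0)
        filtered = local / m * ratio_sum
    return np.where(bad[None, :, :], stack, filtered)


def enl(values: np.ndarray) -> float:
    """Equivalent number of looks of a homogeneous region: mean^2 / variance."""
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need at least two finite values")
    var = values.var(ddof=1)
    if var == 0:
        raise ValueError("zero variance: ENL undefined")
    return float(values.mean() ** 2 / var)


def ndvi(red: np.ndarray, nir: np.ndarray) -> np.ndarray:
    """(NIR - red) / (NIR + red); NaN where both reflectances are zero."""
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (nir - red) / denom
    out = np.where(denom == 0, np.nan, out)
    return out


def block_aggregate(raster: np.ndarray, factor: int, method: str = "mean") -> np.ndarray:
    """Aggregate a raster by an integer factor.

    ``mean`` averages each factor x factor block (trailing partial blocks
    averaged over the cells present, NaN-aware); ``nearest`` takes the block's
    top-left pixel centre — the convention for categorical layers.
    """
    raster = np.asarray(raster, dtype=float)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return raster.copy()
    rows, cols = raster.shape
    if method == "nearest":
        return raster[::factor, ::factor].copy()
    if method != "mean":
        raise ValueError(f"unknown method: {method}")
    out_r = -(-rows // factor)
    out_c = -(-cols // factor)
    padded = np.full((out_r * factor, out_c * factor), np.nan)
    padded[:rows, :cols] = raster
    blocks = padded.reshape(out_r, factor, out_c, factor).swapaxes(1, 2)
    with np.errstate(invalid="ignore"):
        return np.nanmean(blocks.reshape(out_r, out_c, factor * factor), axis=2)
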