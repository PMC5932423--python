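"""IR decision-map extraction: exponential hot/cold stretching, smoothing, normalization.

A microbolometer frame carries absolute-intensity information: objects hotter
or colder than ambient are the behaviourally relevant ones.  The map is built
by exponentially stretching the byte-scale frame and its photographic
negative, so both temperature extremes are boosted while mid-scale (ambient)
pixels are suppressed, then combining the two with a second exponential,
Gaussian-smoothing, and min-max normalizing.  The result is a continuous
decision field in [0, 1]: ~1 on thermally extreme objects, ~0 on background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .imaging import IRFrame

__all__ = [
    "SegmentationMap",
    "EXP_SCALE",
    "exp_stretch",
    "combine_exp",
    "smooth_and_normalize",
    "default_sigma",
    "segment",
]

#: Exponential scaling constant applied on the 0..255 byte scale.
EXP_SCALE = 0.025


@dataclass(frozen=True)
class SegmentationMap:
    """Smoothed, normalized IR decision map.

    ``values`` lie in [0, 1] (all zeros only for a constant source frame);
    ``sigma`` records the Gaussian smoothing scale in pixels.
    """

    values: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("SegmentationMap requires a 2-D array")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("SegmentationMap values must lie in [0, 1]")
        object.__setattr__(self, "values", v)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def exp_stretch(ir: IRFrame) -> tuple[np.ndarray, np.ndarray]:
    """Exponentially scale a thermal frame and its negative.

    Returns ``(I_e, I_Ne)`` with ``I_e = exp(0.025 * I)`` and
    ``I_Ne = exp(0.025 * (255 - I))`` elementwise on the byte scale.  Hot
    pixels dominate ``I_e``, cold pixels dominate ``I_Ne``; ambient mid-scale
    pixels are small in both.  Both outputs are >= 1.
    """
    byte = ir.raw.astype(np.float64)
    return np.exp(EXP_SCALE * byte), np.exp(EXP_SCALE * (255.0 - byte))


def combine_exp(i_e: np.ndarray, i_ne: np.ndarray) -> np.ndarray:
    """Combine the two stretched frames with a second exponential rescale.

    ``raw_map = exp(0.025 * (I_e + I_Ne))``.  The construction is invariant
    under byte inversion of the source frame, which is what makes hot and
    cold objects equally "important".  The largest exponent for byte input is
    0.025 * (e^{6.375} + 1) ≈ 14.7, comfortably finite in float64.
    """
    i_e = np.asarray(i_e, dtype=np.float64)
    i_ne = np.asarray(i_ne, dtype=np.float64)
    if i_e.shape != i_ne.shape:
        raise ValueError(f"shape mismatch: {i_e.shape} vs {i_ne.shape}")
    out = np.exp(EXP_SCALE * (i_e + i_ne))
    if not np.isfinite(out).all():
        raise FloatingPointError("combine_exp overflowed; inputs exceed the byte-scale ceiling")
    return out


def smooth_and_normalize(raw_map: np.ndarray, sigma: float) -> SegmentationMap:
    """Gaussian-smooth the raw map and min-max normalize to [0, 1].

    Reflect padding avoids dark halos at the frame border.  A constant raw
    map has zero dynamic range; it normalizes to all zeros with a warning
    rather than dividing by zero.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    smoothed = gaussian_filter(np.asarray(raw_map, dtype=np.float64), sigma=sigma, mode="reflect")
    lo, hi = smoothed.min(), smoothed.max()
    if hi - lo <= 0:
        warnings.warn("constant IR map: segmentation has zero dynamic range", stacklevel=2)
        return SegmentationMap(np.zeros_like(smoothed), sigma)
    return SegmentationMap((smoothed - lo) / (hi - lo), sigma)


def default_sigma(shape: tuple[int, int]) -> float:
    """Default smoothing scale: 2% of the shorter frame side, at least 1 px."""
    return max(1.0, 0.02 * min(shape))


def segment(ir: IRFrame, sigma: float | None = None) -> SegmentationMap:
    """Full IR segmentation chain: stretch, combine, smooth, normalize."""
    if sigma is None:
        sigma = default_sigma(ir.shape)
    i_e, i_ne = exp_stretch(ir)
    return smooth_and_normalize(combine_exp(i_e, i_ne), sigma)
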