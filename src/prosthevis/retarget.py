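"""Importance-driven nonlinear scene compression (retargeting).

Retinal prostheses stimulate a narrow visual tunnel; fitting a wide scene
into it by uniform rescaling shrinks the key objects below recognizability.
Instead, each image line is given a *shrinkability* distribution inversely
proportional to a per-pixel importance (gradient magnitude of the processed
scene plus the IR decision map), and the line is resampled with a continuous
forward area-weighted mapping (Fant's resampling) so that low-importance
pixels absorb nearly all of the compression.

For a line of importances M(j) and a shrink amount of K pixels,

    S(j) = K * (1/M(j)) / sum_j(1/M(j)),     sum_j S(j) = K,

and pixel j's unit width shrinks to 1 - S(j).  S(j) <= 1 keeps the
cumulative output coordinate monotone, which Fant resampling requires.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .imaging import GrayImage, box_resample
from .segmentation import SegmentationMap
from .simplify import GradientMap

__all__ = [
    "IMPORTANCE_FLOOR",
    "importance_matrix",
    "shrinkability",
    "fant_resample_line",
    "retarget",
    "linear_rescale",
]

#: Lower bound on importance so the reciprocal in the shrinkability is defined.
IMPORTANCE_FLOOR = 1e-3


def importance_matrix(grad_processed: GradientMap, seg: SegmentationMap) -> np.ndarray:
    """Per-pixel importance: normalized gradient plus IR decision map.

    Both inputs live in [0, 1]; the sum is floored at
    :data:`IMPORTANCE_FLOOR` so downstream reciprocals stay bounded.  The IR
    term gives thermally extreme objects weight even where they are visually
    flat.
    """
    g = grad_processed.normalized
    if g.shape != seg.values.shape:
        raise ValueError(f"dimension mismatch: {g.shape} vs {seg.values.shape}")
    return np.maximum(g + seg.values, IMPORTANCE_FLOOR)


def shrinkability(m_line: np.ndarray, shrink_amount: float) -> np.ndarray:
    """Per-pixel shrink weights along one line, summing exactly to K.

    S(j) = (1/M(j)) / sum(1/M) rescaled by K: high-importance pixels receive
    little shrink.  At K = 1 the weights sum to 1 by construction.
    """
    m = np.asarray(m_line, dtype=np.float64)
    if m.ndim != 1:
        raise ValueError("shrinkability operates on a single line")
    if np.any(m <= 0):
        raise ValueError("importance values must be strictly positive")
    if not 0 < shrink_amount < m.size:
        raise ValueError(f"shrink amount must lie in (0, {m.size}), got {shrink_amount}")
    inv = 1.0 / m
    return shrink_amount * inv / inv.sum()


def fant_resample_line(line: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Continuous forward resampling of one line under shrink weights ``s``.

    Input pixel j, occupying the unit interval [j, j+1), is mapped to an
    output interval of width 1 - s(j); the output pixel at [k, k+1) takes
    the area-weighted average of every input pixel whose image overlaps it.
    Since the output widths tile [0, L - K] exactly, each output pixel's
    weights sum to 1 and a constant line stays constant.
    """
    line = np.asarray(line, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    if line.shape != s.shape or line.ndim != 1:
        raise ValueError("line and shrink weights must be 1-D and equal length")
    if np.any(s < 0) or np.any(s > 1.0 + 1e-12):
        raise ValueError("shrink weights must lie in [0, 1] (monotone cumulative map)")
    k = s.sum()
    out_len = int(round(line.size - k))
    if out_len < 1:
        raise ValueError("shrink amount leaves no output pixels")
    widths = 1.0 - s
    edges = np.concatenate([[0.0], np.cumsum(widths)])
    # piecewise-linear cumulative intensity: slope line[j] on [edges[j], edges[j+1])
    cum_intensity = np.concatenate([[0.0], np.cumsum(line * widths)])
    sample_pts = np.linspace(0.0, edges[-1], out_len + 1)
    return np.diff(np.interp(sample_pts, edges, cum_intensity)) / (edges[-1] / out_len)


def _shrink_field(m: np.ndarray, k: int, smooth_sigma: float) -> np.ndarray:
    """Per-row shrinkability field for removing ``k`` columns.

    Rows are computed independently from the importance, lightly smoothed
    across rows to avoid jagged edges in the resampled image, renormalized
    to sum exactly k per row, and capped below 1 (waterfilling the residual)
    so every row's cumulative map remains monotone.
    """
    inv = 1.0 / m
    s = k * inv / inv.sum(axis=1, keepdims=True)
    if smooth_sigma > 0 and m.shape[0] > 2:
        s = gaussian_filter1d(s, sigma=smooth_sigma, axis=0, mode="nearest")
        s *= k / s.sum(axis=1, keepdims=True)
    cap = 1.0 - 1e-6
    for _ in range(32):
        over = s > cap
        if not over.any():
            break
        excess = (s - cap).clip(min=0).sum(axis=1, keepdims=True)
        room = np.where(over, 0.0, cap - s)
        s = np.where(over, cap, s)
        scale = np.divide(excess, room.sum(axis=1, keepdims=True),
                          out=np.zeros_like(excess), where=room.sum(axis=1, keepdims=True) > 0)
        s = s + room * scale
    return s


def retarget(
    img: GrayImage,
    m: np.ndarray,
    shrink_cols: int,
    shrink_rows: int,
    smooth_sigma: float = 1.0,
) -> GrayImage:
    """Remove ``shrink_cols`` columns then ``shrink_rows`` rows nonlinearly.

    The column pass resamples every row under its own shrinkability
    distribution derived from the importance matrix ``m`` (the importance is
    resampled alongside the image so the row pass sees consistent
    geometry).  A flat importance matrix degrades gracefully to a uniform —
    i.e. linear — rescale.
    """
    m = np.asarray(m, dtype=np.float64)
    if m.shape != img.shape:
        raise ValueError("importance matrix must match the image dimensions")
    if not 0 <= shrink_cols < img.width or not 0 <= shrink_rows < img.height:
        raise ValueError("shrink amounts must be smaller than the image dimensions")
    m = np.maximum(m, IMPORTANCE_FLOOR)
    px = img.pixels

    if shrink_cols > 0:
        s = _shrink_field(m, shrink_cols, smooth_sigma)
        px = np.stack([fant_resample_line(row, sr) for row, sr in zip(px, s)])
        m = np.maximum(
            np.stack([fant_resample_line(row, sr) for row, sr in zip(m, s)]),
            IMPORTANCE_FLOOR,
        )
    if shrink_rows > 0:
        s = _shrink_field(m.T, shrink_rows, smooth_sigma)
        px = np.stack([fant_resample_line(col, sc) for col, sc in zip(px.T, s)]).T
    return GrayImage(np.clip(px, 0.0, 1.0))


def linear_rescale(img: GrayImage, target_w: int, target_h: int) -> GrayImage:
    """Uniform area-averaging rescale to ``target_w`` x ``target_h``."""
    if target_w < 2 or target_h < 2:
        raise ValueError("target dimensions must be at least 2x2")
    return GrayImage(np.clip(box_resample(img.pixels, (target_h, target_w)), 0.0, 1.0))
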