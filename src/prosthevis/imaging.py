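"""Canonical image containers, raster I/O, and the synthetic paired-scene generator.

All processing stages exchange :class:`GrayImage` objects whose pixels live on
the unit range [0, 1].  Thermal frames are kept on the native 8-bit scale as
:class:`IRFrame`, because the exponential segmentation constants are defined on
bytes; conversions happen explicitly at module boundaries.

The synthetic generator emulates an optically co-registered visible/thermal
camera pair looking at a textured room containing a few thermally extreme
objects (a standing person, a hot cup, a glass of iced water).  It returns the
ground-truth object masks so downstream geometry claims can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import yaml

__all__ = [
    "GrayImage",
    "IRFrame",
    "SceneObject",
    "SceneFixture",
    "load_gray",
    "save_gray",
    "to_byte",
    "from_byte",
    "box_resample",
    "resize_to",
    "generate_scene",
    "standard_scene",
    "save_fixture",
    "load_fixture",
]

# Rec.601 luma weights for collapsing colour input to luminance.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale intensity field on the unit range.

    Parameters
    ----------
    pixels
        2-D float array with values in [0, 1].
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"GrayImage requires a 2-D array, got ndim={px.ndim}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(f"GrayImage must be at least 2x2, got {px.shape}")
        if not np.isfinite(px).all():
            raise ValueError("GrayImage pixels must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError(
                f"GrayImage pixels must lie in [0, 1], got range "
                f"[{px.min():.4g}, {px.max():.4g}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class IRFrame:
    """An 8-bit thermal frame with its gain mapping.

    ``gain_range`` declares the temperature interval (t_min, t_max) in degrees
    Celsius that the camera's automatic gain control maps linearly onto byte
    values 0..255 (e.g. 0 °C to 40 °C).
    """

    raw: np.ndarray
    gain_range: tuple[float, float] = (0.0, 40.0)

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw)
        if raw.ndim != 2 or raw.shape[0] < 2 or raw.shape[1] < 2:
            raise ValueError(f"IRFrame requires a 2-D array of at least 2x2, got {raw.shape}")
        if not np.issubdtype(raw.dtype, np.integer):
            if not np.allclose(raw, np.round(raw)):
                raise ValueError("IRFrame raw values must be integers")
            raw = np.round(raw).astype(np.int64)
        if raw.min() < 0 or raw.max() > 255:
            raise ValueError("IRFrame raw values must lie in [0, 255]")
        object.__setattr__(self, "raw", raw.astype(np.uint8))
        t_min, t_max = self.gain_range
        if not t_min < t_max:
            raise ValueError(f"gain_range requires t_min < t_max, got {self.gain_range}")
        object.__setattr__(self, "gain_range", (float(t_min), float(t_max)))

    @property
    def shape(self) -> tuple[int, int]:
        return self.raw.shape

    def temperature_to_byte(self, temperature_c: float) -> int:
        """Gain-map a temperature (°C) to its byte level (round-half-up)."""
        t_min, t_max = self.gain_range
        frac = (temperature_c - t_min) / (t_max - t_min)
        return int(np.clip(np.floor(frac * 255.0 + 0.5), 0, 255))

    def to_gray(self) -> GrayImage:
        """Unit-range view of the thermal intensities (byte / 255)."""
        return GrayImage(self.raw.astype(np.float64) / 255.0)


@dataclass(frozen=True)
class SceneObject:
    """One geometric object in a synthetic scene.

    shape : "disk" or "rect"
    position : (row, col) centre in pixels
    size : radius for disks; (half_height, half_width) or scalar for rects
    visible_contrast : signed offset from the 0.5 background mean in the
        visible channel
    temperature_c : nominal object temperature in °C (a thermal plateau)
    """

    shape: str
    position: tuple[float, float]
    size: float | tuple[float, float]
    visible_contrast: float
    temperature_c: float
    label: str = "object"


@dataclass(frozen=True)
class SceneFixture:
    """A co-registered synthetic visible/IR pair with ground truth."""

    visible: GrayImage
    ir: IRFrame
    masks: list[tuple[str, np.ndarray, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.visible.shape != self.ir.shape:
            raise ValueError(
                f"visible {self.visible.shape} and ir {self.ir.shape} must share dimensions"
            )

    def object_mask(self) -> np.ndarray:
        """Union of all ground-truth object masks."""
        out = np.zeros(self.visible.shape, dtype=bool)
        for _, mask, _ in self.masks:
            out |= mask
        return out


def load_gray(path: str | Path) -> GrayImage:
    """Read a PNG/TIFF raster as a unit-range grayscale image.

    Colour input collapses to luminance with Rec.601 weights; 8-bit value v
    maps to v/255 and 16-bit to v/65535.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = iio.imread(path)
    if raw.size == 0:
        raise ValueError(f"{path}: zero-sized image")
    arr = np.asarray(raw, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    if np.issubdtype(raw.dtype, np.integer):
        arr = arr / (65535.0 if raw.dtype.itemsize > 1 else 255.0)
    return GrayImage(np.clip(arr, 0.0, 1.0))


def save_gray(img: GrayImage, path: str | Path) -> None:
    """Write a GrayImage as an 8-bit PNG/TIFF raster."""
    iio.imwrite(Path(path), to_byte(img))


def to_byte(img: GrayImage) -> np.ndarray:
    """Quantize a unit-range image to uint8 with round-half-up (0.5 -> 128)."""
    return np.floor(img.pixels * 255.0 + 0.5).astype(np.uint8)


def from_byte(arr: np.ndarray) -> GrayImage:
    """Inverse of :func:`to_byte`: byte v maps to v/255."""
    arr = np.asarray(arr)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("byte image values must lie in [0, 255]")
    return GrayImage(arr.astype(np.float64) / 255.0)


def _axis_box_resample(arr: np.ndarray, out_len: int, axis: int) -> np.ndarray:
    """Exact area-averaging resample along one axis (uniform intervals)."""
    arr = np.moveaxis(np.asarray(arr, dtype=np.float64), axis, 0)
    in_len = arr.shape[0]
    if out_len == in_len:
        return np.moveaxis(arr, 0, axis)
    # output pixel k covers [k*r, (k+1)*r) in input coordinates, r = in/out
    edges = np.arange(out_len + 1) * (in_len / out_len)
    cum = np.concatenate([np.zeros((1,) + arr.shape[1:]), np.cumsum(arr, axis=0)])
    lo = np.floor(edges).astype(int).clip(0, in_len)
    frac = edges - lo
    # integral of the piecewise-constant signal up to each edge
    vals = cum[lo] + frac.reshape((-1,) + (1,) * (arr.ndim - 1)) * arr[lo.clip(max=in_len - 1)]
    out = np.diff(vals, axis=0) / (in_len / out_len)
    return np.moveaxis(out, 0, axis)


def box_resample(arr: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Area-averaging resample of a 2-D array to ``out_shape`` (rows, cols)."""
    out = _axis_box_resample(arr, out_shape[0], axis=0)
    return _axis_box_resample(out, out_shape[1], axis=1)


def resize_to(img: GrayImage, shape: tuple[int, int]) -> GrayImage:
    """Resize to a common grid (area average down, bilinear up).

    The visible/IR pair is assumed pixel-registered by the optics; this helper
    only reconciles differing sensor resolutions.
    """
    h, w = shape
    if h <= img.height and w <= img.width:
        return GrayImage(np.clip(box_resample(img.pixels, shape), 0.0, 1.0))
    from scipy.ndimage import zoom

    out = zoom(img.pixels, (h / img.height, w / img.width), order=1)
    return GrayImage(np.clip(out[:h, :w], 0.0, 1.0))


def _paint_object(obj: SceneObject, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one object: (boolean mask, shading field in [0.85, 1])."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    r0, c0 = obj.position
    if obj.shape == "disk":
        rad = float(obj.size)  # type: ignore[arg-type]
        if r0 - rad < 0 or r0 + rad >= h or c0 - rad < 0 or c0 + rad >= w:
            raise ValueError(f"object {obj.label!r} extends out of bounds")
        dist = np.hypot(rr - r0, cc - c0)
        mask = dist <= rad
        shading = 1.0 - 0.15 * np.clip(dist / max(rad, 1.0), 0.0, 1.0)
    elif obj.shape == "rect":
        if np.isscalar(obj.size):
            hh = hw = float(obj.size)  # type: ignore[arg-type]
        else:
            hh, hw = (float(s) for s in obj.size)  # type: ignore[misc]
        if r0 - hh < 0 or r0 + hh >= h or c0 - hw < 0 or c0 + hw >= w:
            raise ValueError(f"object {obj.label!r} extends out of bounds")
        mask = (np.abs(rr - r0) <= hh) & (np.abs(cc - c0) <= hw)
        shading = 1.0 - 0.15 * np.clip((rr - (r0 - hh)) / max(2 * hh, 1.0), 0.0, 1.0)
    else:
        raise ValueError(f"unknown object shape {obj.shape!r}")
    return mask, shading


def generate_scene(
    width: int,
    height: int,
    objects: Sequence[SceneObject] = (),
    background_texture_amplitude: float = 0.08,
    seed: int = 0,
    ambient_temp_c: float = 20.0,
    gain_range: tuple[float, float] = (0.0, 40.0),
    ir_noise_sigma: float = 1.0,
) -> SceneFixture:
    """Generate a deterministic co-registered visible/IR scene.

    The visible channel is a mid-gray textured background (band-limited noise
    of the given amplitude) with flat, mildly shaded shapes painted over it.
    The thermal channel is an ambient plateau plus per-object temperature
    plateaus, gain-mapped to bytes, with additive Gaussian sensor noise
    (``ir_noise_sigma`` byte levels).  Identical seed and arguments yield a
    bit-identical fixture.
    """
    if width < 32 or height < 32:
        raise ValueError("scene dimensions must be at least 32x32")
    t_min, t_max = gain_range
    for obj in objects:
        if not t_min <= obj.temperature_c <= t_max:
            raise ValueError(
                f"object {obj.label!r} temperature {obj.temperature_c} outside gain range {gain_range}"
            )
    rng = np.random.default_rng(seed)
    shape = (height, width)

    # visible: band-limited texture around mid-gray
    visible = np.full(shape, 0.5)
    if background_texture_amplitude > 0:
        from scipy.ndimage import gaussian_filter

        noise = gaussian_filter(rng.standard_normal(shape), sigma=1.5)
        std = noise.std()
        if std > 0:
            visible += background_texture_amplitude * noise / std
    ir_frame = IRFrame(np.zeros(shape, dtype=np.uint8), gain_range)
    ambient_byte = ir_frame.temperature_to_byte(ambient_temp_c)
    ir = np.full(shape, float(ambient_byte))

    masks: list[tuple[str, np.ndarray, float]] = []
    for obj in objects:
        mask, shading = _paint_object(obj, shape)
        visible[mask] = np.clip(0.5 + obj.visible_contrast, 0.0, 1.0) * shading[mask]
        ir[mask] = float(ir_frame.temperature_to_byte(obj.temperature_c))
        # later objects override earlier ones
        masks = [(lbl, m & ~mask, t) for lbl, m, t in masks]
        masks.append((obj.label, mask, obj.temperature_c))

    if ir_noise_sigma > 0:
        ir = ir + rng.normal(0.0, ir_noise_sigma, shape)
    ir_bytes = np.clip(np.floor(ir + 0.5), 0, 255).astype(np.uint8)
    return SceneFixture(
        visible=GrayImage(np.clip(visible, 0.0, 1.0)),
        ir=IRFrame(ir_bytes, gain_range),
        masks=masks,
        seed=seed,
    )


def standard_scene(seed: int = 0, width: int = 128, height: int = 128) -> SceneFixture:
    """The package's reference fixture: a warm person, a cold glass, clutter.

    A standing person (body + head, 36 °C) warmer than the 20 °C ambient, a
    glass of iced water (4 °C), and a thermally neutral high-contrast box
    that only the visible channel distinguishes from background.
    """
    sy, sx = height / 128.0, width / 128.0
    objects = [
        SceneObject("rect", (82 * sy, 64 * sx), (26 * sy, 11 * sx), 0.32, 36.0, "body"),
        SceneObject("disk", (46 * sy, 64 * sx), 9 * min(sy, sx), 0.30, 36.0, "head"),
        SceneObject("disk", (96 * sy, 26 * sx), 8 * min(sy, sx), -0.18, 4.0, "glass"),
        SceneObject("rect", (30 * sy, 104 * sx), (9 * sy, 9 * sx), -0.30, 20.0, "box"),
    ]
    return generate_scene(width, height, objects, background_texture_amplitude=0.08, seed=seed)


def save_fixture(fix: SceneFixture, out_dir: str | Path) -> None:
    """Serialize a fixture as visible.png / ir.png / masks.png / spec.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_gray(fix.visible, out / "visible.png")
    iio.imwrite(out / "ir.png", fix.ir.raw)
    labels = np.zeros(fix.visible.shape, dtype=np.uint8)
    meta = []
    for i, (label, mask, temp) in enumerate(fix.masks, start=1):
        labels[mask] = i
        meta.append({"id": i, "label": label, "temperature_c": float(temp)})
    iio.imwrite(out / "masks.png", labels)
    spec = {
        "seed": int(fix.seed),
        "ir_gain_range": [float(v) for v in fix.ir.gain_range],
        "objects": meta,
    }
    (out / "spec.yaml").write_text(yaml.safe_dump(spec))


def load_fixture(in_dir: str | Path) -> SceneFixture:
    in_dir = Path(in_dir)
    spec = yaml.safe_load((in_dir / "spec.yaml").read_text())
    visible = load_gray(in_dir / "visible.png")
    ir = IRFrame(iio.imread(in_dir / "ir.png"), tuple(spec["ir_gain_range"]))
    labels = iio.imread(in_dir / "masks.png")
    masks = [
        (o["label"], labels == o["id"], float(o["temperature_c"])) for o in spec["objects"]
    ]
    return SceneFixture(visible=visible, ir=ir, masks=masks, seed=int(spec["seed"]))
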