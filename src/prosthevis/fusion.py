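"""IR/visible fusion: decision-map weighted blends and the visible-assisted IR cartoon.

The segmentation map acts as a per-pixel convex blend weight between two
renderings of the scene.  Both blend orderings are provided exactly as
defined: the edge-weighted fusion places the raw visible image on thermally
extreme regions (so a hot person keeps natural shading) while the cartoon
fusion places the cartoon there.  The reverse modality renders the thermal
scene itself, smoothed, with the visible scene's edges overlaid.
"""

from __future__ import annotations

import numpy as np

from .imaging import GrayImage, IRFrame
from .segmentation import SegmentationMap
from .simplify import DiffusionParams, GradientMap, anisotropic_diffuse

__all__ = ["fuse_edge_weighted", "fuse_cartoon", "ir_cartoon"]


def _check_shapes(seg: SegmentationMap, *imgs: GrayImage) -> None:
    for img in imgs:
        if img.shape != seg.values.shape:
            raise ValueError(
                f"dimension mismatch: segmentation {seg.values.shape} vs image {img.shape}"
            )


def fuse_edge_weighted(
    seg: SegmentationMap, visible: GrayImage, edge_weighted_img: GrayImage
) -> GrayImage:
    """Blend raw visible (on hot/cold objects) with the edge-weighted scene.

    out = seg * visible + (1 - seg) * edge_weighted, a pointwise convex
    combination: thermally important regions keep full visible detail while
    the ambient background is reduced to its weighted edges.
    """
    _check_shapes(seg, visible, edge_weighted_img)
    s = seg.values
    return GrayImage(s * visible.pixels + (1.0 - s) * edge_weighted_img.pixels)


def fuse_cartoon(seg: SegmentationMap, cartoon: GrayImage, visible: GrayImage) -> GrayImage:
    """Blend the cartoon (on hot/cold objects) with the raw visible scene.

    out = seg * cartoon + (1 - seg) * visible.  Note the deliberate
    asymmetry with :func:`fuse_edge_weighted`: here the thermally important
    regions receive the simplified rendering.
    """
    _check_shapes(seg, cartoon, visible)
    s = seg.values
    return GrayImage(s * cartoon.pixels + (1.0 - s) * visible.pixels)


def ir_cartoon(
    ir: IRFrame,
    visible_grad: GradientMap,
    dp: DiffusionParams = DiffusionParams(),
) -> GrayImage:
    """Visible-assisted IR cartoon: smoothed thermal field with visible edges.

    In the thermal modality absolute intensity is the signal, so the IR
    frame is anisotropically diffused (not quantized) and the visible
    scene's normalized gradient is overlaid as dark contours:
    out = (1 - |grad_visible|_norm) * diffused_IR.
    """
    if visible_grad.normalized.shape != ir.shape:
        raise ValueError("IR frame and visible gradient dimensions differ")
    smoothed = anisotropic_diffuse(ir.to_gray(), dp)
    return GrayImage(np.clip((1.0 - visible_grad.normalized) * smoothed.pixels, 0.0, 1.0))
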