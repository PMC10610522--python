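"""Scan-sector ("cone") mask refinement and application.

An echocardiographic screen capture contains the pie-slice imaging sector
plus overlay annotations (text, ECG trace, patient data).  This module
refines a detected sector mask — smoothing its jagged boundary back to the
regular cone-beam shape and dilating it to recover clipped corners — and
applies it to a frame so everything outside the sector is blanked.

A detector is deliberately not bundled: any upstream cone detector's mask
can be supplied, and :func:`extract_cone_geometric` provides a weight-free
default (Otsu threshold -> largest component -> filled convex hull, exact
for convex sectors) so the pipeline runs end to end without one.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import binary_dilation, binary_fill_holes
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import closing, convex_hull_image, disk, opening

__all__ = [
    "smooth_cone_mask",
    "dilate_cone_mask",
    "apply_cone",
    "extract_cone_geometric",
    "largest_component",
]


def _as_bool_mask(mask) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-D binary image")
    return mask > 0 if mask.dtype != bool else mask


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest connected foreground component of a binary mask."""
    lab = measure.label(mask)
    if lab.max() == 0:
        raise ValueError("mask has no foreground pixels")
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == counts.argmax()


def smooth_cone_mask(mask: np.ndarray, radius: int = 2) -> np.ndarray:
    """Low-pass filter the sector boundary back to a regular cone shape.

    Keeps the largest connected component, then applies morphological
    closing followed by opening with a disk structuring element (diameter
    ``2*radius + 1``, default 5 px) and fills interior holes.  Satellite
    blobs, 1-px boundary notches and pinholes disappear; an already-smooth
    filled sector is a fixed point up to ~1 px of boundary movement.
    """
    mask = _as_bool_mask(mask)
    if not mask.any():
        raise ValueError("cannot smooth an empty mask")
    out = largest_component(mask)
    se = disk(radius)
    out = closing(out, se)
    out = opening(out, se)
    out = binary_fill_holes(out)
    if not out.any():  # degenerate input thinner than the element
        return largest_component(mask)
    return largest_component(out)


def dilate_cone_mask(mask: np.ndarray, iterations: int = 2) -> np.ndarray:
    """Expand the sector mask to recover clipped cone-beam corners.

    Uses a 3x3 rectangular structuring element; extensive (output is a
    superset of the input) and monotone in the input mask.
    """
    mask = _as_bool_mask(mask)
    if not mask.any():
        raise ValueError("cannot dilate an empty mask")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    return binary_dilation(mask, structure=np.ones((3, 3), bool), iterations=iterations)


def apply_cone(frame: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Blank every pixel outside the sector mask (inside pixels unchanged)."""
    frame = np.asarray(frame)
    mask = _as_bool_mask(mask)
    if frame.shape != mask.shape:
        raise ValueError(
            f"frame {frame.shape} and mask {mask.shape} sizes do not match"
        )
    if not mask.any():
        raise ValueError("cone mask is empty")
    return np.where(mask, frame, 0).astype(frame.dtype)


def extract_cone_geometric(frame: np.ndarray) -> np.ndarray:
    """Weight-free sector extraction for frames with a dark surround.

    Thresholds the frame with Otsu's method, keeps the largest connected
    component and returns its filled convex hull — exact for a convex
    sector and deterministic.  Small bright overlays (text strips) form
    separate components and are discarded.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be single-channel")
    if frame.max() == frame.min():
        raise ValueError("frame is constant; no cone to extract")
    thresh = threshold_otsu(frame)
    fg = frame > thresh
    if not fg.any():
        raise ValueError("frame is entirely below the Otsu threshold")
    comp = largest_component(fg)
    return convex_hull_image(comp)
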