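"""Heuristic anatomical correction of four-chamber segmentation masks.

A four-chamber segmentation network occasionally predicts a ventricle mask
that runs past the valve plane and wraps around its same-side atrium — an
anatomically impossible vertical overlap.  This module implements the
rule-based corrector for that defect:

1. reduce each predicted class to its largest connected component;
2. per side, flag an overlap when the ventricle's maximum y (bottom) row
   exceeds the atrium's minimum y (top) row;
3. measure the Euclidean distance between the two most extreme points of
   the side's masks — the ventricle's topmost pixel and the atrium's
   bottommost pixel;
4. if that distance exceeds the side's threshold (right side 68.5 px,
   left side 76.5 px, in 128x128-frame pixels), clip every ventricle pixel
   at or below the atrium's top row; smaller overlaps are regular
   anatomical contact and are left alone;
5. optionally erode all masks equally for display.

The thresholds are calibrated on 128x128 working frames; for masks at any
other resolution they are rescaled proportionally to the frame diagonal.

Classes: 1 left ventricle, 2 left atrium, 3 right ventricle, 4 right
atrium; sides are (1, 2) = left and (3, 4) = right.  Coordinates are
(x=column, y=row), y increasing downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion
from skimage import measure

__all__ = [
    "ChamberMask",
    "CorrectionParams",
    "SideReport",
    "CorrectionReport",
    "extract_chambers",
    "overlap_test",
    "extreme_distance",
    "apply_cut",
    "correct_labelmap",
    "erode_for_display",
    "TotalErasureError",
]

REFERENCE_DIAGONAL = float(np.hypot(128, 128))

SIDE_OF = {1: "left", 2: "left", 3: "right", 4: "right"}
ROLE_OF = {1: "ventricle", 2: "atrium", 3: "ventricle", 4: "atrium"}


class TotalErasureError(ValueError):
    """A cut would erase the whole ventricle — a pathological prediction."""


def _extreme_points(mask: np.ndarray):
    """(top, bottom) extreme pixels as (x, y); ties resolve to smallest x."""
    rows = np.flatnonzero(mask.any(axis=1))
    r_top, r_bot = rows[0], rows[-1]
    x_top = int(np.flatnonzero(mask[r_top])[0])
    x_bot = int(np.flatnonzero(mask[r_bot])[0])
    return (x_top, int(r_top)), (x_bot, int(r_bot))


@dataclass
class ChamberMask:
    """A single chamber's binary mask plus its identity and row extremes."""

    class_id: int
    mask: np.ndarray
    top: tuple  # (x, y) with minimal y
    bottom: tuple  # (x, y) with maximal y

    @classmethod
    def from_mask(cls, class_id: int, mask: np.ndarray) -> "ChamberMask":
        if not mask.any():
            raise ValueError(f"empty mask for class {class_id}")
        top, bottom = _extreme_points(mask)
        return cls(class_id, mask, top, bottom)

    @property
    def side(self) -> str:
        return SIDE_OF[self.class_id]

    @property
    def role(self) -> str:
        return ROLE_OF[self.class_id]

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class CorrectionParams:
    """Cut thresholds (pixels on the 128x128 working frame) and the display
    erosion settings (3x3 rectangular element by default)."""

    right_threshold: float = 68.5
    left_threshold: float = 76.5
    erosion_element: tuple = (3, 3)
    erosion_iterations: int = 1

    def __post_init__(self):
        if self.right_threshold <= 0 or self.left_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.erosion_iterations < 0:
            raise ValueError("erosion_iterations must be >= 0")

    def threshold_for(self, side: str, frame_shape) -> float:
        """Side threshold rescaled by frame diagonal for other resolutions."""
        base = self.right_threshold if side == "right" else self.left_threshold
        scale = float(np.hypot(*frame_shape)) / REFERENCE_DIAGONAL
        return base * scale


@dataclass
class SideReport:
    """Outcome of the overlap decision on one side."""

    overlap_detected: bool = False
    distance: float | None = None
    threshold: float | None = None
    cut_applied: bool = False
    pixels_removed: int = 0
    total_erasure: bool = False
    chambers_present: bool = False

    def to_dict(self) -> dict:
        return {
            "overlap_detected": self.overlap_detected,
            "distance": self.distance,
            "threshold": self.threshold,
            "cut_applied": self.cut_applied,
            "pixels_removed": self.pixels_removed,
            "total_erasure": self.total_erasure,
            "chambers_present": self.chambers_present,
        }


@dataclass
class CorrectionReport:
    sides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {side: rep.to_dict() for side, rep in self.sides.items()}


def extract_chambers(label_map: np.ndarray) -> dict:
    """One ChamberMask per class present, reduced to its largest connected
    component (spurious extra blobs are a known failure mode of the
    predictor).  Absent classes are simply missing from the dict."""
    label_map = np.asarray(label_map)
    out = {}
    for cid in (1, 2, 3, 4):
        m = label_map == cid
        if not m.any():
            continue
        lab = measure.label(m)
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        out[cid] = ChamberMask.from_mask(cid, lab == counts.argmax())
    return out


def _check_pair(ventricle: ChamberMask, atrium: ChamberMask):
    if ventricle.role != "ventricle" or atrium.role != "atrium":
        raise ValueError("expected a (ventricle, atrium) pair")
    if ventricle.side != atrium.side:
        raise ValueError(
            f"side mismatch: classes {ventricle.class_id} and {atrium.class_id}"
        )


def overlap_test(ventricle: ChamberMask, atrium: ChamberMask) -> bool:
    """True when the ventricle's bottom row strictly exceeds the atrium's
    top row — vertical overlap impossible in a real apical view."""
    _check_pair(ventricle, atrium)
    return ventricle.bottom[1] > atrium.top[1]


def extreme_distance(ventricle: ChamberMask, atrium: ChamberMask) -> float:
    """Euclidean distance between the side's two most extreme points: the
    ventricle's topmost pixel and the atrium's bottommost pixel."""
    _check_pair(ventricle, atrium)
    (x1, y1), (x2, y2) = ventricle.top, atrium.bottom
    return float(np.hypot(x1 - x2, y1 - y2))


def apply_cut(ventricle: ChamberMask, atrium: ChamberMask) -> ChamberMask:
    """Remove every ventricle pixel at rows >= the atrium's top row."""
    _check_pair(ventricle, atrium)
    if not overlap_test(ventricle, atrium):
        raise ValueError("no overlap: nothing to cut")
    cut_row = atrium.top[1]
    new = ventricle.mask.copy()
    new[cut_row:, :] = False
    if not new.any():
        raise TotalErasureError(
            f"cut at row {cut_row} would erase ventricle {ventricle.class_id}"
        )
    return ChamberMask.from_mask(ventricle.class_id, new)


def correct_labelmap(
    label_map: np.ndarray, params: CorrectionParams | None = None
):
    """Run the per-side overlap decision on a label map.

    Each side is treated independently: a cut fires only when the side
    shows vertical overlap AND its extreme-point distance exceeds the
    side threshold.  A cut that would erase the whole ventricle is
    reported (``total_erasure``) and skipped rather than failing the
    frame.  Returns the corrected map and a per-side report.
    """
    params = params or CorrectionParams()
    label_map = np.asarray(label_map)
    chambers = extract_chambers(label_map)
    out = label_map.copy()
    report = CorrectionReport()
    for side, (v_id, a_id) in (("left", (1, 2)), ("right", (3, 4))):
        rep = SideReport()
        report.sides[side] = rep
        if v_id not in chambers or a_id not in chambers:
            continue
        rep.chambers_present = True
        ventricle, atrium = chambers[v_id], chambers[a_id]
        rep.overlap_detected = overlap_test(ventricle, atrium)
        rep.distance = extreme_distance(ventricle, atrium)
        rep.threshold = params.threshold_for(side, label_map.shape)
        if not (rep.overlap_detected and rep.distance > rep.threshold):
            continue
        try:
            cut = apply_cut(ventricle, atrium)
        except TotalErasureError:
            rep.total_erasure = True
            continue
        rep.cut_applied = True
        removed = ventricle.mask & ~cut.mask
        rep.pixels_removed = int(removed.sum())
        out[removed] = 0
    return out, report


def erode_for_display(
    label_map: np.ndarray, params: CorrectionParams | None = None
) -> np.ndarray:
    """Erode every chamber mask with the same element and iterations.

    Purely cosmetic: separates touching masks visually.  Because all
    masks shrink under the same element, congruent chambers keep their
    exact area ratio.  Background grows; class identities are preserved.
    """
    params = params or CorrectionParams()
    label_map = np.asarray(label_map)
    if params.erosion_iterations == 0:
        return label_map.copy()
    se = np.ones(params.erosion_element, dtype=bool)
    out = np.zeros_like(label_map)
    for cid in np.unique(label_map):
        if cid == 0:
            continue
        m = binary_erosion(
            label_map == cid, structure=se, iterations=params.erosion_iterations
        )
        out[m] = cid
    return out
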