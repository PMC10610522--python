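"""Synthetic echocardiogram phantoms with ground-truth label maps.

The generator emulates the statistical structure a four-chamber B-mode
segmentation pipeline has to cope with: a pie-slice scan sector (the
"cone") on a black background, four dark elliptical chamber cavities
embedded in brighter myocardium-like tissue, multiplicative spatially
correlated speckle inside the sector, and constant-intensity "burn-in"
strips outside the sector emulating on-screen text/ECG annotations.
Frames are independent stills — no cardiac-cycle dynamics.

Class convention (fixed repo-wide): 0 background, 1 left ventricle,
2 left atrium, 3 right ventricle, 4 right atrium.  Ventricles sit above
their same-side atria, as in the apical four-chamber view; following
clinical display convention the anatomical left chambers are drawn on the
image right (pure label semantics — geometry is configurable).

Coordinates are 0-based with the row index increasing downward; a pixel
coordinate is written (x=column, y=row).

``inject_leak`` manufactures the segmentation defect the heuristic
corrector targets: a connected protrusion of one chamber's label running
toward and around its same-side neighbour, overwriting background only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "ChamberSpec",
    "PhantomConfig",
    "PhantomScene",
    "ScenePlacementError",
    "generate_scene",
    "render",
    "inject_leak",
    "ADJACENT_CHAMBER",
]

#: same-side ventricle<->atrium pairing
ADJACENT_CHAMBER = {1: 2, 2: 1, 3: 4, 4: 3}

VENTRICLES = (1, 3)
ATRIA = (2, 4)


class ScenePlacementError(ValueError):
    """Raised when chambers cannot be placed inside the cone sector."""


@dataclass(frozen=True)
class ChamberSpec:
    """One elliptical chamber cavity.

    center/semi_axes are in pixels as (x=column, y=row); rotation in
    degrees (counter-clockwise); intensity in [0, 1] — cavities are darker
    than the surrounding tissue.
    """

    class_id: int
    center: tuple
    semi_axes: tuple
    rotation: float
    intensity: float


@dataclass(frozen=True)
class PhantomConfig:
    """Tunable scene parameters; defaults give a 112x112 apical-view-like
    phantom whose chamber spans are in proportion to clinical frames."""

    frame_size: tuple = (112, 112)
    cone_apex: tuple = (0.5, 0.02)  # fractions of (width, height)
    cone_half_angle: float = 45.0  # degrees around the downward axis
    cone_depth: float = 0.95  # fraction of frame height
    tissue_intensity: float = 0.55
    artifact_intensity: float = 0.85
    speckle_scale: float = 0.35
    speckle_corr_sigma: float = 1.0  # px, correlation length of speckle
    # base chamber geometry as fractions of (width, height); jittered per seed
    chamber_geometry: dict = field(
        default_factory=lambda: {
            1: ((0.607, 0.348), (0.116, 0.170), 0.20),  # left ventricle
            2: ((0.616, 0.688), (0.107, 0.116), 0.20),  # left atrium
            3: ((0.357, 0.375), (0.107, 0.143), 0.20),  # right ventricle
            4: ((0.375, 0.696), (0.098, 0.116), 0.20),  # right atrium
        }
    )
    max_attempts: int = 50


@dataclass(frozen=True)
class PhantomScene:
    """Ground-truth geometry from which a frame + label map are rendered."""

    frame_size: tuple
    cone_apex: tuple  # (x, y) pixels
    cone_half_angle: float
    cone_depth: float  # pixels
    chambers: tuple  # 4 ChamberSpec
    artifact_bands: tuple  # ((row0, row1, col0, col1), ...) half-open
    speckle_scale: float
    speckle_corr_sigma: float
    tissue_intensity: float
    artifact_intensity: float
    seed: int


def cone_sector_mask(frame_size, apex, half_angle_deg, depth) -> np.ndarray:
    """Boolean mask of the scan sector (apex at top, axis pointing down)."""
    h, w = frame_size
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - apex[0]
    dy = yy - apex[1]
    r = np.hypot(dx, dy)
    ang = np.degrees(np.arctan2(np.abs(dx), dy))  # 0 along downward axis
    return (dy >= 0) & (r <= depth) & (ang <= half_angle_deg)


def ellipse_mask(frame_size, center, semi_axes, rotation_deg) -> np.ndarray:
    h, w = frame_size
    yy, xx = np.mgrid[0:h, 0:w]
    th = np.radians(rotation_deg)
    dx = xx - center[0]
    dy = yy - center[1]
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _scene_masks(scene: PhantomScene):
    cone = cone_sector_mask(
        scene.frame_size, scene.cone_apex, scene.cone_half_angle, scene.cone_depth
    )
    chambers = {
        ch.class_id: ellipse_mask(
            scene.frame_size, ch.center, ch.semi_axes, ch.rotation
        )
        for ch in scene.chambers
    }
    return cone, chambers


def _validate_scene(scene: PhantomScene):
    """Return None if valid, else a human-readable constraint failure."""
    cone, chambers = _scene_masks(scene)
    for cid, m in chambers.items():
        if not m.any():
            return f"chamber {cid} renders to zero pixels"
        if (m & ~cone).any():
            return f"chamber {cid} extends outside the cone sector"
    ids = sorted(chambers)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if (chambers[a] & chambers[b]).any():
                return f"chambers {a} and {b} overlap"
    for v in VENTRICLES:
        a = ADJACENT_CHAMBER[v]
        if not (
            np.flatnonzero(chambers[v].any(axis=1))[0]
            < np.flatnonzero(chambers[a].any(axis=1))[0]
        ):
            return f"ventricle {v} does not sit above atrium {a}"
    return None


def generate_scene(config: PhantomConfig | None = None, seed: int = 0) -> PhantomScene:
    """Draw a jittered scene satisfying all placement invariants.

    The base geometry is perturbed (center, semi-axes, rotation, cavity
    intensity) by a seeded RNG; invalid draws are retried up to
    ``config.max_attempts`` times with progressively smaller jitter before
    giving up with the violated constraint in the error message.
    """
    config = config or PhantomConfig()
    h, w = config.frame_size
    if h < 64 or w < 64:
        raise ValueError("frame size must be at least 64x64")
    rng = np.random.default_rng(seed)
    apex = (config.cone_apex[0] * w, config.cone_apex[1] * h)
    depth = config.cone_depth * h
    bands = (
        (0, max(1, int(0.018 * h)), int(0.05 * w), int(0.43 * w)),
        (max(2, int(0.027 * h)), max(3, int(0.045 * h)), int(0.54 * w), int(0.93 * w)),
    )
    failure = None
    for attempt in range(config.max_attempts):
        shrink = 1.0 / (1.0 + 0.1 * attempt)
        chambers = []
        for cid, (c, ax, rot_jit) in sorted(config.chamber_geometry.items()):
            cx = c[0] * w + rng.uniform(-2, 2) * shrink
            cy = c[1] * h + rng.uniform(-1, 1) * shrink
            a = ax[0] * w + rng.uniform(-1, 1) * shrink
            b = ax[1] * h + rng.uniform(-1, 1) * shrink
            rot = rng.uniform(-8, 8) * rot_jit * 5 * shrink
            inten = rng.uniform(0.12, 0.25)
            chambers.append(
                ChamberSpec(cid, (cx, cy), (max(a, 2.0), max(b, 2.0)), rot, inten)
            )
        scene = PhantomScene(
            frame_size=(h, w),
            cone_apex=apex,
            cone_half_angle=config.cone_half_angle,
            cone_depth=depth,
            chambers=tuple(chambers),
            artifact_bands=bands,
            speckle_scale=config.speckle_scale,
            speckle_corr_sigma=config.speckle_corr_sigma,
            tissue_intensity=config.tissue_intensity,
            artifact_intensity=config.artifact_intensity,
            seed=seed,
        )
        failure = _validate_scene(scene)
        if failure is None:
            return scene
    raise ScenePlacementError(
        f"could not place chambers after {config.max_attempts} attempts: {failure}"
    )


def render(scene: PhantomScene):
    """Render a scene to an 8-bit grayscale frame and its label map.

    Returns
    -------
    frame : (H, W) uint8 — zero outside the cone except artifact bands;
        multiplicative correlated speckle applied only inside the cone.
    label_map : (H, W) uint8 with values in {0..4}.
    """
    failure = _validate_scene(scene)
    if failure is not None:
        raise ScenePlacementError(failure)
    cone, chambers = _scene_masks(scene)
    h, w = scene.frame_size
    base = np.zeros((h, w), dtype=float)
    base[cone] = scene.tissue_intensity
    label_map = np.zeros((h, w), dtype=np.uint8)
    for ch in scene.chambers:
        m = chambers[ch.class_id]
        base[m] = ch.intensity
        label_map[m] = ch.class_id
    if scene.speckle_scale > 0:
        rng = np.random.default_rng(scene.seed + 1)
        raw = rng.rayleigh(scale=1.0, size=(h, w))
        corr = gaussian_filter(raw, sigma=scene.speckle_corr_sigma)
        corr /= corr.mean()
        noise = 1.0 + scene.speckle_scale * (corr - 1.0)
        base[cone] *= np.clip(noise, 0.0, None)[cone]
    for r0, r1, c0, c1 in scene.artifact_bands:
        band = np.zeros((h, w), dtype=bool)
        band[r0:r1, c0:c1] = True
        base[band & ~cone] = scene.artifact_intensity
    frame = np.clip(np.round(base * 255.0), 0, 255).astype(np.uint8)
    return frame, label_map


def inject_leak(
    label_map: np.ndarray, from_class: int, extent: int, seed: int = 0
) -> np.ndarray:
    """Extend ``from_class`` by a connected protrusion toward (and possibly
    past) its same-side neighbour, overwriting background pixels only.

    The protrusion starts at the chamber's extreme row facing the
    neighbour and advances ~``extent`` rows as a drifting band that routes
    around the neighbour on the chamber's outer side, mimicking a
    ventricle mask wrapping around its atrium.  ``extent`` 0 is identity.
    """
    label_map = np.asarray(label_map)
    if from_class not in ADJACENT_CHAMBER:
        raise ValueError(f"no adjacent chamber defined for class {from_class}")
    src = label_map == from_class
    if not src.any():
        raise ValueError(f"class {from_class} not present in the label map")
    out = label_map.copy()
    if extent == 0:
        return out
    if extent < 0:
        raise ValueError("extent must be >= 0")
    to_class = ADJACENT_CHAMBER[from_class]
    tgt = label_map == to_class
    if not tgt.any():
        raise ValueError(
            f"adjacent chamber (class {to_class}) not present in the label map"
        )
    rng = np.random.default_rng(seed)
    h, w = label_map.shape
    src_rows = np.flatnonzero(src.any(axis=1))
    tgt_rows = np.flatnonzero(tgt.any(axis=1))
    down = tgt_rows.mean() > src_rows.mean()  # ventricle leaking downward
    start_row = src_rows[-1] if down else src_rows[0]
    cols = np.flatnonzero(src[start_row])
    center = float(cols.mean())
    # drift outward: away from the frame's vertical midline
    src_cols = np.flatnonzero(src.any(axis=0))
    outward = -1.0 if src_cols.mean() < w / 2 else 1.0
    half_width = max(2, int(0.03 * w))
    step = 1 if down else -1
    drift = outward * rng.uniform(0.5, 0.9)
    for i in range(1, extent + 1):
        r = start_row + step * i
        if r < 0 or r >= h:
            break
        c = center + drift * i + rng.uniform(-0.5, 0.5)
        c0 = int(np.clip(c - half_width, 0, w - 1))
        c1 = int(np.clip(c + half_width, 0, w - 1)) + 1
        seg = out[r, c0:c1]
        seg[seg == 0] = from_class
    return out
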