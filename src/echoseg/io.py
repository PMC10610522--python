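"""PNG I/O for frames, binary cone masks and indexed label maps.

Label maps are written as indexed (palette) PNGs with the class id stored
in the palette position, so files round-trip exactly and still display
with distinct colours.  Cone masks are 8-bit PNGs with 0/255 values.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

__all__ = [
    "load_gray",
    "save_gray",
    "load_labelmap",
    "save_labelmap",
    "load_mask",
    "save_mask",
]

# background, LV, LA, RV, RA
_PALETTE = [
    (0, 0, 0),
    (230, 60, 60),
    (235, 200, 60),
    (70, 120, 230),
    (150, 80, 200),
]


def load_gray(path) -> np.ndarray:
    """Read a grayscale frame (any PNG/JPEG; converted to 8-bit L)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def save_gray(path, frame: np.ndarray) -> None:
    Image.fromarray(np.asarray(frame, dtype=np.uint8), mode="L").save(path)


def save_labelmap(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels, dtype=np.uint8)
    im = Image.fromarray(labels, mode="P")
    pal = []
    for rgb in _PALETTE:
        pal.extend(rgb)
    pal.extend([0] * (768 - len(pal)))
    im.putpalette(pal)
    im.save(path)


def load_labelmap(path) -> np.ndarray:
    """Read an indexed-PNG label map (palette index = class id)."""
    with Image.open(path) as im:
        if im.mode == "P":
            return np.asarray(im, dtype=np.uint8)
        return np.asarray(im.convert("L"), dtype=np.uint8)


def save_mask(path, mask: np.ndarray) -> None:
    save_gray(path, np.where(np.asarray(mask) > 0, 255, 0).astype(np.uint8))


def load_mask(path) -> np.ndarray:
    return load_gray(path) > 127
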