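"""PNG reading/writing for frames and label masks.

Frames are 8-bit grayscale PNG; masks are 8-bit indexed PNG with labels
{0: background, 1: acetabulum-ilium complex, 2: femoral head}.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

# Palette for indexed masks: background dark, bone yellow-ish, head blue-ish.
_MASK_PALETTE = [0, 0, 0, 230, 200, 60, 80, 140, 230]


def write_frame(path: str | Path, image: np.ndarray) -> None:
    """Write a float image in [0, 1] as an 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8), mode="L").save(path)


def read_frame(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG back to floats in [0, 1]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=float) / 255.0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1, 2)).all():
        raise ValueError("mask labels must be in {0, 1, 2}")
    im = Image.fromarray(arr.astype(np.uint8), mode="P")
    im.putpalette(_MASK_PALETTE + [0] * (768 - len(_MASK_PALETTE)))
    im.save(path)


def read_mask(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im, dtype=np.uint8)
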