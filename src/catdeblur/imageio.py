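"""PNG/JPEG reading and writing (8-bit, RGB order)."""
from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .cat import quantize


def load_image(path) -> np.ndarray:
    """Load an image as float64; HxW for grayscale files, HxWx3 for color."""
    with Image.open(Path(path)) as im:
        if im.mode in ("L", "I;16", "I"):
            arr = np.asarray(im.convert("L"), dtype=np.float64)
        else:
            arr = np.asarray(im.convert("RGB"), dtype=np.float64)
    return arr


def save_image(path, img: np.ndarray) -> None:
    """Quantize to 8-bit and write; 2-D arrays become single-channel PNGs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = quantize(img)
    mode = "L" if arr.ndim == 2 else "RGB"
    Image.fromarray(arr, mode=mode).save(path)
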