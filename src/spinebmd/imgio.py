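"""Grayscale raster I/O.

Internally every image is a float64 array in [0, 1]. On disk two dialects
are supported: 8-bit PNG (default; 255 gray levels are plenty for the
phantom dynamic range) and 16-bit TIFF for callers who need finer
quantization. The round-trip error is bounded by half a gray step.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image


def write_image(path: str | Path, raster: np.ndarray) -> None:
    """Write a [0,1] float raster as 8-bit PNG or 16-bit TIFF by extension."""
    path = Path(path)
    arr = np.asarray(raster, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D raster, got shape {arr.shape}")
    if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
        raise ValueError("raster values must lie in [0, 1]")
    arr = np.clip(arr, 0.0, 1.0)
    suffix = path.suffix.lower()
    if suffix == ".png":
        Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L").save(path)
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, np.round(arr * 65535).astype(np.uint16))
    else:
        raise ValueError(f"unsupported image extension: {suffix}")


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG or 16-bit TIFF back to a [0,1] float raster."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".png":
        arr = np.asarray(Image.open(path).convert("L"), dtype=np.float64)
        return arr / 255.0
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path).astype(np.float64)
        return arr / 65535.0
    raise ValueError(f"unsupported image extension: {suffix}")
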