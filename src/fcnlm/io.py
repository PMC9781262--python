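"""Grayscale image reading and writing (PNG, TIFF, PGM).

Images are handled as 2-D float arrays on a 0-255 scale throughout the
pipeline; quantization to 8-bit happens only at write time.  RGB inputs
are collapsed to luminance (ITU-R BT.601).
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image"]

_FORMATS = {".png", ".tif", ".tiff", ".pgm"}


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a grayscale image as a 2-D float field on the 0-255 scale.

    RGB(A) content is converted by luminance; 16-bit integer content is
    rescaled to 0-255; float content is passed through unchanged.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    try:
        arr = iio.imread(p)
    except Exception as exc:  # noqa: BLE001 - rewrap with the format name
        raise OSError(f"could not read {p.suffix or 'image'} file {p}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise OSError(f"unsupported channel layout {arr.shape} in {p}")
        rgb = arr[..., :3].astype(float)
        arr = rgb @ np.array([0.299, 0.587, 0.114])
    elif arr.ndim != 2:
        raise OSError(f"expected a 2-D grayscale image in {p}, got shape {arr.shape}")
    out = np.asarray(arr, dtype=float)
    if np.issubdtype(np.asarray(arr).dtype, np.integer) and np.asarray(arr).dtype.itemsize > 1:
        out = out * (255.0 / np.iinfo(np.asarray(arr).dtype).max)
    return out


def write_image(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write a float image as 8-bit grayscale, clipping to [0, 255].

    The file is written to a temporary sibling and renamed into place, so
    a failure never leaves a partial output behind.
    """
    p = Path(path)
    if p.suffix.lower() not in _FORMATS:
        raise OSError(f"unsupported output format {p.suffix!r} (use PNG/TIFF/PGM)")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    data = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    fd, tmp = tempfile.mkstemp(suffix=p.suffix, dir=p.parent or ".")
    os.close(fd)
    try:
        iio.imwrite(tmp, data)
        os.replace(tmp, p)
    except Exception:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
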