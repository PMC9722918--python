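"""TIFF and table I/O helpers.

Images are read and written with :mod:`tifffile`; calibration is never
inferred from file metadata — the caller always supplies ``pixel_size_um``
explicitly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .types import CalibratedImage, ParameterError


def read_image(path: str | Path, pixel_size_um: float) -> CalibratedImage:
    """Read a single-channel 2-D TIFF as a :class:`CalibratedImage`."""
    arr = tifffile.imread(str(path))
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise ParameterError(f"{path}: expected a single-channel 2-D image, got shape {arr.shape}")
    depth = 16 if arr.dtype == np.uint16 else (8 if arr.dtype == np.uint8 else None)
    return CalibratedImage(arr, pixel_size_um, bit_depth=depth)


def write_image(path: str | Path, img: CalibratedImage) -> None:
    """Write image intensities as TIFF (dtype preserved; floats as float32)."""
    data = img.data
    if data.dtype.kind == "f":
        data = data.astype(np.float32)
    tifffile.imwrite(str(path), data)


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    """Write a label map as 16-bit TIFF (errors if > 65535 labels)."""
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ParameterError("label map has more than 65535 labels; cannot store as 16-bit TIFF")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def read_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)
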