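"""Core calibrated-image container shared by all image-processing stages.

Every segmentation and morphology operation works in physical units (µm),
so the pixel grid always travels with its calibration.  Label maps are
plain ``int32`` arrays with 0 = background; helpers for relabelling live
in :mod:`mitorhythm.segmentation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ParameterError(ValueError):
    """A parameter violates its documented constraint."""


@dataclass(frozen=True)
class CalibratedImage:
    """A 2-D single-channel intensity image with physical pixel size.

    Parameters
    ----------
    data
        2-D array of finite, non-negative intensities.  Stored as given
        (uint8/uint16 input is kept; processing stages promote to float).
    pixel_size_um
        Edge length of one pixel in µm (isotropic pixels assumed).
    bit_depth
        Optional note on the acquisition bit depth (8 or 16); purely
        informational.
    """

    data: np.ndarray
    pixel_size_um: float
    bit_depth: int | None = field(default=None)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise ParameterError(f"image must be 2-D, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ParameterError("image intensities must be finite")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be > 0")
        object.__setattr__(self, "data", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    def um_to_px(self, um: float) -> float:
        """Convert a physical length to pixels under this calibration."""
        return um / self.pixel_size_um

    def with_data(self, data: np.ndarray) -> "CalibratedImage":
        """New image with the same calibration and different pixels."""
        return CalibratedImage(data, self.pixel_size_um, self.bit_depth)
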