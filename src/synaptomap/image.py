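"""Core image container shared by every stage of the pipeline.

The analysis operates on single optical sections: one 2-D intensity grid
per fluorescence channel, with a physical pixel size attached.  Multi-channel
acquisitions are handled as separate planes (one per marker).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ImagePlane"]


@dataclass
class ImagePlane:
    """A single-channel 2-D fluorescence image with physical calibration.

    Parameters
    ----------
    pixels:
        2-D array of non-negative intensities.  Stored as float64 so the
        processing chain (background subtraction, smoothing) does not lose
        precision, but values are expected to fit the declared bit depth.
    pixel_size_nm:
        Physical edge length of one pixel, in nanometres.
    channel:
        Marker name ("psd95", "vglut2", "pap", ...); informational.
    bit_depth:
        Native acquisition bit depth (8 or 16); controls the histogram
        used by automatic thresholding and the TIFF dtype on write.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    channel: str = ""
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("intensities must be non-negative")
        if self.pixels.size and self.pixels.max() > self.max_value:
            raise ValueError(
                f"intensities exceed {self.max_value} for bit_depth={self.bit_depth}"
            )

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def pixel_area_um2(self) -> float:
        return (self.pixel_size_nm / 1000.0) ** 2

    def with_pixels(self, pixels: np.ndarray) -> "ImagePlane":
        """Copy of this plane with new pixel data and identical calibration."""
        return replace(self, pixels=np.asarray(pixels, dtype=np.float64))
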