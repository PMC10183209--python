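"""Core raster-image container.

All image computation in the toolkit operates on :class:`RasterImage`, an
H x W x 3 array of sRGB values in [0, 1].  Images carry an identifier, an
optional substrate-category label, and the integer seed they were generated
from (absent for images loaded from disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError, ValidationError


@dataclass
class RasterImage:
    """An sRGB raster with values in [0, 1].

    Parameters
    ----------
    pixels
        ``(height, width, 3)`` float array, each channel in ``[0, 1]``.
    image_id
        Identifier, unique within a bank.
    category
        Optional substrate-category label (e.g. ``"bark"``).
    seed
        Integer seed the image was generated from, or ``None``.
    """

    pixels: np.ndarray
    image_id: str
    category: str | None = None
    seed: int | None = field(default=None)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise DimensionError(
                f"pixels must be (H, W, 3), got shape {self.pixels.shape}"
            )
        h, w = self.pixels.shape[:2]
        if h < 2 or w < 2:
            raise DimensionError(f"images must be at least 2x2, got {h}x{w}")
        if not np.isfinite(self.pixels).all():
            raise ValidationError("pixel values must be finite")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValidationError("pixel values must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]
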