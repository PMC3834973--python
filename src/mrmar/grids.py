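"""Core raster containers.

The whole pipeline operates on 2-D scalar rasters: CT slices in
Hounsfield-like (or normalized) units, pseudo-MR slices in arbitrary
units, and boolean masks marking corrupted pixels.  The coordinate
convention throughout the package is row-major, 0-based ``(row, col)``
with row 0 at the top of the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass
class ImageGrid:
    """A 2-D scalar image with physical pixel spacing.

    Parameters
    ----------
    pixels
        2-D float array of intensities.  Must be finite everywhere.
    pixel_spacing
        ``(row_mm, col_mm)`` physical size of one pixel; both positive.
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError(
                f"ImageGrid requires a non-empty 2-D array, got shape {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("ImageGrid pixels must be finite (no NaN/Inf)")
        rs, cs = self.pixel_spacing
        if not (rs > 0 and cs > 0):
            raise ValidationError(f"pixel_spacing must be positive, got {self.pixel_spacing}")
        self.pixel_spacing = (float(rs), float(cs))

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def normalized(self) -> "ImageGrid":
        """Affine rescale of the intensities onto [0, 1] over the observed range."""
        lo = float(self.pixels.min())
        hi = float(self.pixels.max())
        if hi == lo:
            raise ValidationError("cannot normalize a constant image")
        return ImageGrid((self.pixels - lo) / (hi - lo), self.pixel_spacing)

    def copy(self) -> "ImageGrid":
        return ImageGrid(self.pixels.copy(), self.pixel_spacing)


@dataclass
class ArtifactMask:
    """Boolean raster marking corrupted pixels (True = corrupted)."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 2 or self.flags.size == 0:
            raise ValidationError(
                f"ArtifactMask requires a non-empty 2-D boolean array, got shape {self.flags.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.flags.shape

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    def copy(self) -> "ArtifactMask":
        return ArtifactMask(self.flags.copy())


def require_same_shape(*arrays, what: str = "inputs") -> None:
    """Raise :class:`ValidationError` unless all arrays share one shape."""
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValidationError(f"shape mismatch between {what}: {sorted(shapes)}")
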