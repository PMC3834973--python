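"""Parallel-beam projection engine.

Forward projection (discrete Radon transform), ramp-filtered
back-projection, and metal-trace computation.  This is the engine under
both the streak-artifact simulator and the sinogram-interpolation MAR
baseline.

Geometry and conventions
------------------------
Views are parametrized by an angle theta in degrees over [0, 180) and a
signed detector offset ``s`` (same physical units as the pixel
spacing).  With image-centered coordinates ``x = (col - cc) * col_mm``
and ``y = (row - rc) * row_mm``, the ray at ``(theta, s)`` is the line
``x cos(theta) + y sin(theta) = s``; a projection value is the line
integral of the image along that ray, evaluated by sampling at the
pixel pitch with bilinear interpolation.

Back-projection uses the classical FBP discretization: each view is
ramp-filtered (Ram-Lak, optionally Hann-apodized) in the Fourier
domain on a zero-padded grid, then smeared back along its rays with
linear interpolation across detector bins and weighted by
``pi / n_angles``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import ValidationError
from .grids import ArtifactMask, ImageGrid


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam acquisition geometry.

    ``angles_deg`` must be strictly increasing within [0, 180);
    ``n_bins * bin_spacing`` must cover the diagonal of any image the
    geometry is used with (checked per operation).
    """

    angles_deg: np.ndarray
    n_bins: int
    bin_spacing: float = 1.0

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles_deg, dtype=np.float64)
        object.__setattr__(self, "angles_deg", angles)
        if angles.ndim != 1 or angles.size == 0:
            raise ValidationError("angles_deg must be a non-empty 1-D array")
        if np.any(np.diff(angles) <= 0):
            raise ValidationError("view angles must be strictly increasing")
        if angles[0] < 0 or angles[-1] >= 180:
            raise ValidationError("view angles must lie in [0, 180)")
        if self.n_bins < 1:
            raise ValidationError("n_bins must be positive")
        if self.bin_spacing <= 0:
            raise ValidationError("bin_spacing must be positive")

    @property
    def n_angles(self) -> int:
        return int(self.angles_deg.size)

    @property
    def bin_offsets(self) -> np.ndarray:
        """Signed physical detector offsets, centered on the rotation axis."""
        return (np.arange(self.n_bins) - (self.n_bins - 1) / 2.0) * self.bin_spacing

    @classmethod
    def default_for(
        cls,
        shape: tuple[int, int],
        pixel_spacing: tuple[float, float] = (1.0, 1.0),
        n_angles: int = 180,
        bin_spacing: float | None = None,
    ) -> "Geometry":
        """Uniform [0, 180) geometry covering ``shape`` with a central bin."""
        if bin_spacing is None:
            bin_spacing = float(min(pixel_spacing))
        diag = math.hypot(shape[0] * pixel_spacing[0], shape[1] * pixel_spacing[1])
        n_bins = int(math.ceil(diag / bin_spacing)) + 3
        if n_bins % 2 == 0:  # odd count puts one bin exactly on the rotation axis
            n_bins += 1
        angles = np.arange(n_angles) * (180.0 / n_angles)
        return cls(angles, n_bins, bin_spacing)


@dataclass
class Sinogram:
    """Projection data indexed ``(angle index, bin index)``, line-integral units."""

    values: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (self.geometry.n_angles, self.geometry.n_bins)
        if self.values.shape != expected:
            raise ValidationError(
                f"sinogram shape {self.values.shape} does not match geometry {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("sinogram values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "Sinogram":
        return Sinogram(self.values.copy(), self.geometry)


@dataclass
class TraceMask:
    """Boolean mask over sinogram bins; True = ray intersects metal."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 2:
            raise ValidationError("trace mask must be 2-D (angles x bins)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.flags.shape


def _check_coverage(shape, pixel_spacing, geom: Geometry) -> None:
    diag = math.hypot(shape[0] * pixel_spacing[0], shape[1] * pixel_spacing[1])
    if geom.n_bins * geom.bin_spacing < diag:
        raise ValidationError(
            f"detector ({geom.n_bins} bins x {geom.bin_spacing}) does not cover "
            f"the image diagonal ({diag:.1f})"
        )


def forward_project(img: ImageGrid, geom: Geometry) -> Sinogram:
    """Discrete Radon transform of ``img`` under ``geom``.

    Linear in the image; rays are sampled at the finer pixel pitch with
    bilinear interpolation and summed (rectangle rule).
    """
    _check_coverage(img.shape, img.pixel_spacing, geom)
    sp_r, sp_c = img.pixel_spacing
    rc = (img.n_rows - 1) / 2.0
    cc = (img.n_cols - 1) / 2.0
    diag = math.hypot(img.n_rows * sp_r, img.n_cols * sp_c)
    step = 0.5 * min(sp_r, sp_c)  # half the pixel pitch: keeps ray sums close to true line integrals
    n_samples = int(math.ceil(diag / step)) + 1
    t = (np.arange(n_samples) - (n_samples - 1) / 2.0) * step
    s = geom.bin_offsets

    out = np.empty((geom.n_angles, geom.n_bins))
    for i, ang in enumerate(geom.angles_deg):
        th = math.radians(ang)
        cos_t, sin_t = math.cos(th), math.sin(th)
        # ray point = s * (cos, sin) + t * (-sin, cos) in (x, y)
        x = s[:, None] * cos_t - t[None, :] * sin_t
        y = s[:, None] * sin_t + t[None, :] * cos_t
        rows = y / sp_r + rc
        cols = x / sp_c + cc
        vals = map_coordinates(img.pixels, [rows, cols], order=1, mode="constant", cval=0.0)
        out[i] = vals.sum(axis=1) * step
    return Sinogram(out, geom)


def _ramp_filter(n_bins: int, bin_spacing: float, apodization: str) -> tuple[np.ndarray, int]:
    n_fft = 64
    while n_fft < 2 * n_bins:
        n_fft *= 2
    freqs = np.fft.fftfreq(n_fft, d=bin_spacing)
    filt = np.abs(freqs)
    if apodization == "hann":
        f_max = 0.5 / bin_spacing
        filt *= 0.5 * (1.0 + np.cos(np.pi * freqs / f_max))
    elif apodization != "ramlak":
        raise ValidationError(f"unknown apodization '{apodization}' (ramlak|hann)")
    return filt, n_fft


def fbp_reconstruct(
    sino: Sinogram,
    out_shape: tuple[int, int],
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
    apodization: str = "ramlak",
) -> ImageGrid:
    """Ramp-filtered back-projection of ``sino`` onto an ``out_shape`` grid."""
    geom = sino.geometry
    _check_coverage(out_shape, pixel_spacing, geom)
    filt, n_fft = _ramp_filter(geom.n_bins, geom.bin_spacing, apodization)

    padded = np.zeros((geom.n_angles, n_fft))
    padded[:, : geom.n_bins] = sino.values
    filtered = np.real(np.fft.ifft(np.fft.fft(padded, axis=1) * filt[None, :], axis=1))
    filtered = filtered[:, : geom.n_bins]

    sp_r, sp_c = pixel_spacing
    rc = (out_shape[0] - 1) / 2.0
    cc = (out_shape[1] - 1) / 2.0
    y = (np.arange(out_shape[0]) - rc) * sp_r
    x = (np.arange(out_shape[1]) - cc) * sp_c
    xx, yy = np.meshgrid(x, y)

    s0 = geom.bin_offsets[0]
    recon = np.zeros(out_shape)
    for i, ang in enumerate(geom.angles_deg):
        th = math.radians(ang)
        s = xx * math.cos(th) + yy * math.sin(th)
        idx = (s - s0) / geom.bin_spacing
        recon += np.interp(idx.ravel(), np.arange(geom.n_bins), filtered[i]).reshape(out_shape)
    recon *= math.pi / geom.n_angles
    return ImageGrid(recon, pixel_spacing)


def metal_trace(
    metal: ArtifactMask,
    geom: Geometry,
    threshold: float = 0.0,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> TraceMask:
    """Sinogram bins whose forward projection of the metal mask exceeds ``threshold``.

    An empty metal mask yields an empty trace; the trace is monotone in
    the mask (a superset mask can only add flagged bins).
    """
    if threshold < 0:
        raise ValidationError("trace threshold must be >= 0")
    as_img = ImageGrid(metal.flags.astype(np.float64), pixel_spacing)
    proj = forward_project(as_img, geom)
    return TraceMask(proj.values > threshold)


def reconstruction_circle(shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the inscribed reconstruction circle (pixel units)."""
    rc = (shape[0] - 1) / 2.0
    cc = (shape[1] - 1) / 2.0
    rr, cci = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    radius = min(shape) / 2.0
    return (rr - rc) ** 2 + (cci - cc) ** 2 <= radius**2


def save_sinogram(sino: Sinogram, path) -> None:
    """Persist as float32 TIFF plus a JSON sidecar holding the geometry."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(str(path), sino.values.astype(np.float32))
    meta = {
        "angles_deg": [float(a) for a in sino.geometry.angles_deg],
        "n_bins": sino.geometry.n_bins,
        "bin_spacing": sino.geometry.bin_spacing,
    }
    with open(path.with_name(path.name + ".json"), "w") as fh:
        json.dump(meta, fh, sort_keys=True)
        fh.write("\n")


def load_sinogram(path) -> Sinogram:
    import tifffile

    path = Path(path)
    values = tifffile.imread(str(path)).astype(np.float64)
    with open(path.with_name(path.name + ".json")) as fh:
        meta = json.load(fh)
    geom = Geometry(np.asarray(meta["angles_deg"]), int(meta["n_bins"]), float(meta["bin_spacing"]))
    return Sinogram(values, geom)
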