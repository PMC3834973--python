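"""Synthetic fixtures: head-like CT phantoms, dental implants, a
metal-corrupted acquisition model, and a paired pseudo-MR image.

The patient data behind the method is not public, so validation runs on
a simulated stand-in: an ellipse-stack head phantom (air / soft tissue /
bone on a normalized intensity scale), metal disks inserted into the
"jaw" band, and a projection-domain corruption model that reproduces
the streak phenomenology of dental implants — beam hardening
(sub-linear measured attenuation on rays through metal), detector
saturation (photon starvation ceiling), and Poisson counting noise.

The pseudo-MR is a tissue-wise intensity remap of the *clean* anatomy
(bone dark, soft tissue bright), reflecting that dental metal degrades
MR far less than CT; optionally a signal-void halo around the metal
emulates susceptibility dropout.  CT and MR are co-registered by
construction (an optional rigid shift emulates misregistration).

All randomness is seeded; every output is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .grids import ArtifactMask, ImageGrid, require_same_shape
from .projection import (
    Geometry,
    Sinogram,
    TraceMask,
    fbp_reconstruct,
    forward_project,
    metal_trace,
)

# Normalized tissue intensity convention
AIR = 0.0
SOFT_TISSUE = 0.3
BRAIN = 0.32
BONE = 0.7
METAL = 3.0


@dataclass(frozen=True)
class Ellipse:
    """One painted ellipse: center/axes in pixels, rotation in degrees."""

    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]  # (row semi-axis, col semi-axis)
    rotation_deg: float
    intensity: float


@dataclass
class PhantomSpec:
    """Declarative anatomy: later ellipses overwrite earlier (painter's order).

    ``texture_amp_soft`` / ``texture_amp_bone`` add a fixed, deterministic
    smooth modulation to soft-tissue (0.1 < I < 0.5) and bone (I >= 0.5)
    pixels, emulating the intensity heterogeneity of real anatomy
    (diploë, marrow, gray/white matter); with both 0 the rasterization
    paints the exact tissue intensities.
    """

    grid: tuple[int, int]
    ellipses: list[Ellipse] = field(default_factory=list)
    texture_amp_soft: float = 0.0
    texture_amp_bone: float = 0.0

    def __post_init__(self) -> None:
        rows, cols = self.grid
        if rows < 1 or cols < 1:
            raise ValidationError("phantom grid must be positive")
        for e in self.ellipses:
            r, c = e.center
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValidationError(f"ellipse center {e.center} outside grid {self.grid}")
            if e.axes[0] <= 0 or e.axes[1] <= 0:
                raise ValidationError("ellipse axes must be positive")
            reach = max(e.axes)
            if r - reach < -0.5 or r + reach > rows - 0.5 or c - reach < -0.5 or c + reach > cols - 0.5:
                raise ValidationError(f"ellipse at {e.center} extends outside the grid")


@dataclass
class ImplantSpec:
    """Metal inserts: per-implant (row, col) center, radius (px), intensity."""

    centers: list[tuple[float, float]] = field(default_factory=list)
    radii: list[float] = field(default_factory=list)
    intensity: float = METAL

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.radii):
            raise ValidationError("one radius per implant center required")
        if any(r <= 0 for r in self.radii):
            raise ValidationError("implant radii must be positive")
        if self.centers and self.intensity < 2.0:
            raise ValidationError("metal intensity must be >= 2.0 on the normalized scale")

    @property
    def count(self) -> int:
        return len(self.centers)


@dataclass
class PhysicsConfig:
    """Projection-domain corruption model.

    ``saturation_cap``: line-integral ceiling emulating photon
    starvation; ``None`` resolves to 0.95x the maximum uncorrupted line
    integral through metal, ``inf`` disables saturation and hardening.
    ``beam_hardening_gamma`` > 1 bends metal-trace bins sub-linear.
    ``noise_photons``: incident photon count I0 for Poisson noise
    (``None`` disables noise).  ``attenuation_scale`` converts
    normalized intensity x path length into optical depth so that I0
    yields realistic count statistics.  ``recon_clip`` bounds the
    reconstructed image, emulating the finite stored dynamic range of
    clinical CT (metal and bloom saturate at the ceiling, as they do in
    12-bit HU images); ``None`` disables clipping.
    """

    saturation_cap: float | None = None
    beam_hardening_gamma: float = 1.6
    noise_photons: float | None = 1.0e5
    trace_threshold: float = 0.25
    attenuation_scale: float = 0.1
    recon_clip: tuple[float, float] | None = (-0.25, 1.25)

    def __post_init__(self) -> None:
        if self.saturation_cap is not None and self.saturation_cap <= 0:
            raise ValidationError("saturation_cap must be positive")
        if self.beam_hardening_gamma < 1.0:
            raise ValidationError("beam_hardening_gamma must be >= 1")
        if self.noise_photons is not None and self.noise_photons <= 0:
            raise ValidationError("noise_photons must be positive")
        if self.trace_threshold < 0:
            raise ValidationError("trace_threshold must be >= 0")
        if self.attenuation_scale <= 0:
            raise ValidationError("attenuation_scale must be positive")
        if self.recon_clip is not None and self.recon_clip[0] >= self.recon_clip[1]:
            raise ValidationError("recon_clip must be an increasing (lo, hi) pair")


@dataclass
class MRSynthesisConfig:
    """Pseudo-MR synthesis: tissue remap, smoothing, noise, metal void.

    ``tissue_map`` sends each CT tissue intensity to an MR intensity by
    nearest-class lookup; ``None`` means the identity remap (MR carries
    the clean CT values unchanged — the idealized injective contrast).
    The default is bone-dark / soft-tissue-bright.  ``void_radius`` > 0
    zeroes a halo of that pixel radius around metal.  ``shift`` rigidly
    translates the MR by whole pixels to emulate misregistration
    (default off).
    """

    tissue_map: dict[float, float] | None = field(
        default_factory=lambda: {
            AIR: 0.02,
            SOFT_TISSUE: 0.85,
            BRAIN: 0.75,
            # extra anchors so textured bone (wide intensity spread) maps dark
            0.45: 0.15,
            BONE: 0.15,
            1.0: 0.15,
        }
    )
    void_radius: float = 0.0
    smoothing_sigma: float = 1.0
    noise_sigma: float = 0.02
    shift: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.smoothing_sigma < 0 or self.noise_sigma < 0 or self.void_radius < 0:
            raise ValidationError("sigmas and void_radius must be >= 0")
        if self.tissue_map is not None and any(
            v < 0 or not math.isfinite(v) for v in self.tissue_map.values()
        ):
            raise ValidationError("remapped MR intensities must be finite and >= 0")


def default_head_spec(size: int = 128) -> PhantomSpec:
    """Head-like slice: soft-tissue oval, bone rim, brain, and a bone jaw arc."""
    s = size / 128.0
    c = (size - 1) / 2.0
    ellipses = [
        Ellipse((c, c), (58 * s, 46 * s), 0.0, BONE),  # outer skull table
        Ellipse((c, c), (54 * s, 42 * s), 0.0, SOFT_TISSUE),  # soft interior
        Ellipse((c - 10 * s, c), (36 * s, 30 * s), 0.0, BRAIN),  # brain
        Ellipse((c + 36 * s, c), (14 * s, 24 * s), 0.0, BONE),  # mandible arc (outer)
        Ellipse((c + 34 * s, c), (10 * s, 19 * s), 0.0, SOFT_TISSUE),  # oral soft tissue
        Ellipse((c + 31 * s, c), (4 * s, 9 * s), 0.0, AIR + 0.02),  # airway
    ]
    return PhantomSpec((size, size), ellipses, texture_amp_soft=0.05, texture_amp_bone=0.2)


def default_implants(count: int, size: int = 128, radius: float = 5.0) -> ImplantSpec:
    """1-8 metal disks along the jaw arc, deterministic placement.

    Implants are packed like fillings on adjacent teeth (centers within
    +/-10 px of the midline at the 128 scale), so multiple implants
    merge into wide metal traces — the regime in which
    interpolation-based sinogram repair loses the most raw data.
    """
    if not 1 <= count <= 8:
        raise ValidationError("implant count must be in 1..8")
    s = size / 128.0
    c = (size - 1) / 2.0
    off = np.linspace(-10, 10, count) if count > 1 else np.array([0.0])
    cols = off * s + c
    rows = (40 - 0.010 * off**2) * s + c
    centers = [(float(r), float(col)) for r, col in zip(rows, cols)]
    return ImplantSpec(centers, [radius * s] * count)


def make_phantom(spec: PhantomSpec, pixel_spacing: tuple[float, float] = (1.0, 1.0)) -> ImageGrid:
    """Deterministic rasterization of the ellipse stack (painter's order)."""
    rows, cols = spec.grid
    rr, cc = np.meshgrid(np.arange(rows, dtype=float), np.arange(cols, dtype=float), indexing="ij")
    img = np.zeros(spec.grid)
    for e in spec.ellipses:
        th = math.radians(e.rotation_deg)
        dr = rr - e.center[0]
        dc = cc - e.center[1]
        u = dr * math.cos(th) + dc * math.sin(th)
        v = -dr * math.sin(th) + dc * math.cos(th)
        inside = (u / e.axes[0]) ** 2 + (v / e.axes[1]) ** 2 <= 1.0
        img[inside] = e.intensity
    if spec.texture_amp_soft or spec.texture_amp_bone:
        tex = np.sin(rr / 6.0) * np.cos(cc / 7.5) + 0.6 * np.sin((rr + cc) / 9.0)
        soft = (img > 0.1) & (img < 0.5)
        bone = img >= 0.5
        img[soft] += spec.texture_amp_soft * tex[soft]
        img[bone] += spec.texture_amp_bone * tex[bone]
    return ImageGrid(img, pixel_spacing)


def insert_implants(clean_ct: ImageGrid, imp: ImplantSpec) -> tuple[ImageGrid, ArtifactMask]:
    """Paint metal disks; the mask is True exactly where metal overwrote tissue."""
    out = clean_ct.pixels.copy()
    mask = np.zeros(clean_ct.shape, dtype=bool)
    rr, cc = np.meshgrid(
        np.arange(clean_ct.n_rows, dtype=float),
        np.arange(clean_ct.n_cols, dtype=float),
        indexing="ij",
    )
    for (r, c), rad in zip(imp.centers, imp.radii):
        ir, ic = int(round(r)), int(round(c))
        if not (0 <= ir < clean_ct.n_rows and 0 <= ic < clean_ct.n_cols):
            raise ValidationError(f"implant center {(r, c)} outside the image")
        if clean_ct.pixels[ir, ic] <= AIR + 0.05:
            raise ValidationError(f"implant at {(r, c)} is outside the body")
        disk = (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
        out[disk] = imp.intensity
        mask |= disk
    return ImageGrid(out, clean_ct.pixel_spacing), ArtifactMask(mask)


def corrupt_sinogram(
    sino: Sinogram, trace: TraceMask, phys: PhysicsConfig, seed: int | None = None
) -> Sinogram:
    """Apply beam hardening + saturation on the metal trace, then Poisson noise.

    Metal-trace bins are remapped ``v -> cap * (v / cap)^gamma`` and
    clipped at the cap; Poisson noise (seeded) perturbs the whole
    sinogram through the count domain ``I = I0 * exp(-scale * v)``.
    """
    require_same_shape(sino.values, trace.flags, what="sinogram and trace")
    vals = sino.values.copy()
    if trace.flags.any():
        cap = phys.saturation_cap
        if cap is None:
            cap = 0.95 * float(vals[trace.flags].max())
        if math.isfinite(cap):
            v = vals[trace.flags]
            with np.errstate(invalid="ignore"):
                hardened = cap * np.power(np.clip(v, 0.0, None) / cap, phys.beam_hardening_gamma)
            vals[trace.flags] = np.minimum(hardened, cap)
    if phys.noise_photons is not None:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(phys.noise_photons * np.exp(-phys.attenuation_scale * vals))
        counts = np.maximum(counts, 1)
        vals = -np.log(counts / phys.noise_photons) / phys.attenuation_scale
    return Sinogram(vals, sino.geometry)


def simulate_artifact_ct(
    ct_with_metal: ImageGrid,
    metal_mask: ArtifactMask,
    geom: Geometry,
    phys: PhysicsConfig,
    seed: int | None = None,
) -> tuple[ImageGrid, TraceMask]:
    """Forward project, corrupt the metal trace, reconstruct with FBP, clip."""
    require_same_shape(ct_with_metal.pixels, metal_mask.flags, what="CT and metal mask")
    sino = forward_project(ct_with_metal, geom)
    trace = metal_trace(metal_mask, geom, phys.trace_threshold, ct_with_metal.pixel_spacing)
    corrupted = corrupt_sinogram(sino, trace, phys, seed)
    recon = fbp_reconstruct(corrupted, ct_with_metal.shape, ct_with_metal.pixel_spacing)
    if phys.recon_clip is not None:
        recon = ImageGrid(
            np.clip(recon.pixels, phys.recon_clip[0], phys.recon_clip[1]),
            recon.pixel_spacing,
        )
    return recon, trace


def synthesize_mr(
    clean_ct: ImageGrid,
    metal_mask: ArtifactMask | None,
    cfg: MRSynthesisConfig | None = None,
    seed: int | None = None,
) -> ImageGrid:
    """Pseudo-MR paired with ``clean_ct``: remap, smooth, noise, metal void."""
    cfg = cfg or MRSynthesisConfig()
    if metal_mask is not None:
        require_same_shape(clean_ct.pixels, metal_mask.flags, what="CT and metal mask")
    if cfg.tissue_map is None:
        mr = clean_ct.pixels.astype(np.float64).copy()
    else:
        classes = np.asarray(sorted(cfg.tissue_map.keys()))
        targets = np.asarray([cfg.tissue_map[k] for k in classes])
        # nearest-class lookup
        idx = np.abs(clean_ct.pixels[..., None] - classes[None, None, :]).argmin(axis=-1)
        mr = targets[idx].astype(np.float64)
    if cfg.smoothing_sigma > 0:
        mr = ndimage.gaussian_filter(mr, cfg.smoothing_sigma)
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        mr = mr + rng.normal(0.0, cfg.noise_sigma, mr.shape)
    if cfg.void_radius > 0 and metal_mask is not None and metal_mask.flags.any():
        dist = ndimage.distance_transform_edt(~metal_mask.flags)
        mr[dist <= cfg.void_radius] = 0.0
    if cfg.shift != (0, 0):
        mr = np.roll(mr, cfg.shift, axis=(0, 1))
    return ImageGrid(mr, clean_ct.pixel_spacing)
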