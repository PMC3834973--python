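"""Image file I/O.

Reference formats are float32 TIFF (lossless) and NIfTI-1; grayscale
PNG (8/16-bit) is supported with an affine quantization recorded in a
JSON sidecar so that re-reading recovers the float values to within one
quantization step.  Raw ``.npy`` float grids round-trip exactly.

The sidecar for ``img.png`` is ``img.png.json`` and carries
``pixel_spacing`` plus, for integer formats, ``scale``/``offset`` such
that ``float = int * scale + offset``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ImageIOError, ValidationError
from .grids import ImageGrid

_INT_FORMATS = {".png"}
_FLOAT_TIFF = {".tif", ".tiff"}
_NIFTI = {".nii", ".gz"}  # .nii.gz ends with .gz


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            return json.load(fh)
    return {}


def _write_sidecar(path: Path, meta: dict) -> None:
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, sort_keys=True, indent=1)
        fh.write("\n")


def read_image(path, format_hint: str | None = None) -> ImageGrid:
    """Read a 2-D grayscale image into an :class:`ImageGrid`.

    PNG/TIFF are read as-is (integer values mapped to float, applying
    the sidecar affine when present); NIfTI volumes contribute their
    first slice and carry spacing in the header.  RGB input is refused.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such image file: {path}")
    suffix = (format_hint or path.suffix).lower()

    if suffix in _NIFTI or path.name.endswith(".nii.gz"):
        import nibabel as nib

        vol = nib.load(str(path))
        data = np.asanyarray(vol.dataobj).astype(np.float64)
        if data.ndim == 3:
            data = data[:, :, 0]
        elif data.ndim != 2:
            raise ImageIOError(f"unsupported NIfTI dimensionality {data.ndim} in {path}")
        zooms = vol.header.get_zooms()
        spacing = (float(zooms[0]), float(zooms[1]))
        if not np.all(np.isfinite(data)):
            raise ValidationError(f"NaN/Inf pixels in {path}")
        return ImageGrid(data, spacing)

    if suffix == ".npy":
        data = np.load(path)
    elif suffix in _FLOAT_TIFF:
        import tifffile

        data = tifffile.imread(str(path))
    elif suffix in _INT_FORMATS:
        import imageio.v3 as iio

        data = iio.imread(str(path))
    else:
        raise ImageIOError(f"unsupported image format '{suffix}' for {path}")

    data = np.asarray(data)
    if data.ndim == 3:
        raise ImageIOError(
            f"{path} has {data.shape[-1]} channels; convert to single-channel grayscale first"
        )
    if data.ndim != 2:
        raise ImageIOError(f"{path} is not a 2-D image (shape {data.shape})")
    data = data.astype(np.float64)
    if not np.all(np.isfinite(data)):
        raise ValidationError(f"NaN/Inf pixels in {path}")

    meta = _read_sidecar(path)
    if "scale" in meta:
        data = data * float(meta["scale"]) + float(meta.get("offset", 0.0))
    spacing = tuple(meta.get("pixel_spacing", (1.0, 1.0)))
    return ImageGrid(data, spacing)


def write_image(img: ImageGrid, path) -> None:
    """Write an :class:`ImageGrid`; the format follows the file suffix.

    float32 TIFF and ``.npy`` are lossless; 16-bit PNG quantizes onto
    the observed range and records the affine in the sidecar.
    """
    path = Path(path)
    if not path.parent.exists():
        raise ImageIOError(f"parent directory does not exist: {path.parent}")
    suffix = path.suffix.lower()
    meta = {"pixel_spacing": list(img.pixel_spacing)}

    if path.name.endswith(".nii.gz") or suffix in _NIFTI:
        import nibabel as nib

        affine = np.diag([img.pixel_spacing[0], img.pixel_spacing[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(img.pixels.astype(np.float32), affine), str(path))
        return
    if suffix == ".npy":
        np.save(path, img.pixels)
        _write_sidecar(path, meta)
        return
    if suffix in _FLOAT_TIFF:
        import tifffile

        tifffile.imwrite(str(path), img.pixels.astype(np.float32))
        _write_sidecar(path, meta)
        return
    if suffix in _INT_FORMATS:
        import imageio.v3 as iio

        lo = float(img.pixels.min())
        hi = float(img.pixels.max())
        span = hi - lo if hi > lo else 1.0
        quant = np.round((img.pixels - lo) / span * 65535.0).astype(np.uint16)
        meta["scale"] = span / 65535.0
        meta["offset"] = lo
        iio.imwrite(str(path), quant)
        _write_sidecar(path, meta)
        return
    raise ImageIOError(f"unsupported image format '{suffix}' for {path}")


def write_mask(mask, path) -> None:
    """Write a boolean mask as an 8-bit PNG (255 = corrupted)."""
    import imageio.v3 as iio

    path = Path(path)
    if not path.parent.exists():
        raise ImageIOError(f"parent directory does not exist: {path.parent}")
    iio.imwrite(str(path), np.where(mask.flags, 255, 0).astype(np.uint8))


def read_mask(path):
    """Read a mask PNG written by :func:`write_mask`."""
    from .grids import ArtifactMask

    import imageio.v3 as iio

    data = np.asarray(iio.imread(str(path)))
    if data.ndim != 2:
        raise ImageIOError(f"mask {path} is not single-channel")
    return ArtifactMask(data > 127)
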