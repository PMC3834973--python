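"""MR-similarity-guided restoration of corrupted CT pixels.

For every corrupted CT pixel, the window around the same position in
the co-registered MR image is searched for the neighbor whose MR value
is most similar to the MR value at the center; the CT value at that
neighbor's position — provided it is uncorrupted — replaces the
corrupted pixel.  If the most similar neighbor is itself corrupted in
CT, the next most similar is tried, and so on.  Uncorrupted pixels are
left untouched, bit-exact.

Borders are handled by edge replication (the first/last ``margin``
rows and columns are replicated outward) so that the window is defined
everywhere.

Neighborhoods in which *every* donor is corrupted cannot be restored in
one sweep; the sweep is therefore repeated, with pixels corrected in
sweep ``p`` becoming legal donors in sweep ``p + 1``, up to
``max_passes`` sweeps.  Within one sweep all donor values are read from
the pre-sweep image, so the result does not depend on pixel scan order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .grids import ArtifactMask, ImageGrid, require_same_shape


@dataclass
class CorrectionConfig:
    window: int = 5
    max_passes: int = 5
    fallback: str = "neighborhood_mean"  # or "leave"
    reinsert_metal: bool = False

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValidationError("window must be an odd integer >= 3")
        if self.max_passes < 1:
            raise ValidationError("max_passes must be >= 1")
        if self.fallback not in ("leave", "neighborhood_mean"):
            raise ValidationError("fallback must be 'leave' or 'neighborhood_mean'")


def window_offsets(window: int) -> list[tuple[int, int]]:
    """Non-center window offsets in row-major order (the tie-break order)."""
    m = window // 2
    return [
        (dr, dc)
        for dr in range(-m, m + 1)
        for dc in range(-m, m + 1)
        if not (dr == 0 and dc == 0)
    ]


def pad_replicate(img: ImageGrid, margin: int) -> ImageGrid:
    """Replicate-pad ``img`` by ``margin`` pixels on every side.

    Edge replication is well defined for any margin (a 1x1 image padded
    by 2 becomes a 5x5 constant image), so only negative margins are
    rejected.
    """
    if margin < 0:
        raise ValidationError("margin must be >= 0")
    return ImageGrid(np.pad(img.pixels, margin, mode="edge"), img.pixel_spacing)


def find_donor(
    mr_window: np.ndarray, ct_corruption_window: np.ndarray
) -> tuple[int, int] | None:
    """Donor offset for the (corrupted) center of one window, or None.

    Candidates are all non-center window positions ranked by ascending
    absolute MR difference to the window center, ties broken by
    row-major order; the first candidate whose CT position is
    uncorrupted wins.  Returns the ``(drow, dcol)`` offset relative to
    the center.
    """
    mr_window = np.asarray(mr_window, dtype=np.float64)
    corrupt = np.asarray(ct_corruption_window, dtype=bool)
    require_same_shape(mr_window, corrupt, what="donor-search windows")
    w = mr_window.shape[0]
    if mr_window.shape != (w, w) or w % 2 == 0:
        raise ValidationError("donor search expects an odd square window")
    m = w // 2
    center = mr_window[m, m]
    best: tuple[float, int] | None = None
    for k, (dr, dc) in enumerate(window_offsets(w)):
        if corrupt[m + dr, m + dc]:
            continue
        dist = abs(mr_window[m + dr, m + dc] - center)
        if best is None or dist < best[0]:
            best = (dist, k)
    if best is None:
        return None
    return window_offsets(w)[best[1]]


def _fallback_neighborhood_mean(
    work: np.ndarray, residual: np.ndarray, window: int
) -> np.ndarray:
    m = window // 2
    padded = np.pad(work, m, mode="edge")
    pres = np.pad(residual, m, mode="edge")
    rr, cc = np.nonzero(residual)
    total = np.zeros(rr.size)
    count = np.zeros(rr.size)
    for dr, dc in window_offsets(window):
        ok = ~pres[rr + m + dr, cc + m + dc]
        total += np.where(ok, padded[rr + m + dr, cc + m + dc], 0.0)
        count += ok
    out = work.copy()
    has = count > 0
    out[rr[has], cc[has]] = total[has] / count[has]
    return out


def correct_image(
    ct: ImageGrid,
    mr: ImageGrid,
    mask: ArtifactMask,
    cfg: CorrectionConfig | None = None,
    metal_mask: ArtifactMask | None = None,
) -> tuple[ImageGrid, ArtifactMask]:
    """Replace every masked CT pixel with the value at its best MR-similar donor.

    Returns ``(corrected, residual_mask)`` where the residual mask flags
    pixels that never received a donor within ``max_passes`` sweeps
    (before any fallback fill).  Unmasked pixels are bit-identical to
    the input.  With ``reinsert_metal`` and a ``metal_mask``, the metal
    pixels are restored to their input values at the end.
    """
    cfg = cfg or CorrectionConfig()
    require_same_shape(ct.pixels, mr.pixels, mask.flags, what="CT, MR and mask")
    if mask.flags.all():
        raise ValidationError("no uncorrupted pixels available: mask covers the whole image")

    m = cfg.window // 2
    offsets = window_offsets(cfg.window)
    work = ct.pixels.copy()
    cur = mask.flags.copy()

    for _ in range(cfg.max_passes):
        if not cur.any():
            break
        pct = np.pad(work, m, mode="edge")
        pmr = np.pad(mr.pixels, m, mode="edge")
        pmask = np.pad(cur, m, mode="edge")
        rr, cc = np.nonzero(cur)
        center_mr = pmr[rr + m, cc + m]

        dists = np.empty((len(offsets), rr.size))
        donors = np.empty((len(offsets), rr.size))
        for k, (dr, dc) in enumerate(offsets):
            pr, pc = rr + m + dr, cc + m + dc
            d = np.abs(pmr[pr, pc] - center_mr)
            d[pmask[pr, pc]] = np.inf  # corrupted donors are skipped
            dists[k] = d
            donors[k] = pct[pr, pc]
        best = np.argmin(dists, axis=0)  # first min wins: row-major tie-break
        found = np.isfinite(dists[best, np.arange(rr.size)])
        work[rr[found], cc[found]] = donors[best[found], np.flatnonzero(found)]
        cur[rr[found], cc[found]] = False

    residual = ArtifactMask(cur.copy())
    if cur.any() and cfg.fallback == "neighborhood_mean":
        work = _fallback_neighborhood_mean(work, cur, cfg.window)
    if cfg.reinsert_metal and metal_mask is not None:
        require_same_shape(ct.pixels, metal_mask.flags, what="CT and metal mask")
        work[metal_mask.flags] = ct.pixels[metal_mask.flags]
    return ImageGrid(work, ct.pixel_spacing), residual
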