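"""White-matter mask preprocessing.

External T1 segmentation leaves tiny gray-matter islands fully enclosed
by white matter (a partial-volume artifact); those holes are filled when
smaller than a pixel-area cutoff, the mask is smoothed and re-binarized,
and an interior region — the mask eroded by a boundary margin — defines
where detections are accepted, suppressing false positives along the
white-matter boundary.

Order of the preparation pipeline is fixed: fill -> smooth; the interior
region is computed separately and applied after detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_formats import BinaryMask2D

__all__ = [
    "MaskPrepParams",
    "fill_small_holes",
    "smooth_and_rebinarize",
    "interior_region",
    "prep_mask",
]


@dataclass(frozen=True)
class MaskPrepParams:
    """Mask preparation thresholds.

    hole_area_max_px
        Enclosed background components strictly smaller than this many
        pixels are filled (default 200).
    smooth_sigma_px
        Gaussian smoothing sd in pixels (default 1).
    boundary_margin_px
        Chebyshev erosion margin defining the interior region
        (default 8).
    rebinarize_level
        Threshold applied to the smoothed 0/1 field (default 0.5, which
        approximately conserves mask area).
    """

    hole_area_max_px: int = 200
    smooth_sigma_px: float = 1.0
    boundary_margin_px: int = 8
    rebinarize_level: float = 0.5

    def __post_init__(self) -> None:
        if self.hole_area_max_px < 0:
            raise ValueError("hole_area_max_px must be >= 0")
        if self.smooth_sigma_px < 0:
            raise ValueError("smooth_sigma_px must be >= 0")
        if self.boundary_margin_px < 0:
            raise ValueError("boundary_margin_px must be >= 0")
        if not 0.0 < self.rebinarize_level < 1.0:
            raise ValueError("rebinarize_level must lie in (0, 1)")


def fill_small_holes(mask: BinaryMask2D, max_area: int) -> BinaryMask2D:
    """Fill enclosed background components with area strictly < ``max_area``.

    A hole is a 4-connected background component that does not touch the
    image border (the outer background is never filled).  Larger holes
    are left untouched.  Idempotent.
    """
    m = mask.pixels
    background = ~m
    # 4-connectivity for background components: the complement of an
    # 8-connected foreground.
    labels, n = ndimage.label(background, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n == 0:
        return BinaryMask2D(m.copy(), mask.slice_index, mask.geometry)
    border_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    fill = np.zeros(n + 1, dtype=bool)
    for lab in range(1, n + 1):
        if lab not in border_labels and counts[lab] < max_area:
            fill[lab] = True
    out = m | fill[labels]
    return BinaryMask2D(out, mask.slice_index, mask.geometry)


def smooth_and_rebinarize(mask: BinaryMask2D, sigma: float, level: float = 0.5) -> BinaryMask2D:
    """Gaussian-blur the 0/1 field with sd ``sigma`` px, threshold at ``level``."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return BinaryMask2D(mask.pixels.copy(), mask.slice_index, mask.geometry)
    blurred = ndimage.gaussian_filter(mask.pixels.astype(float), sigma, mode="reflect")
    return BinaryMask2D(blurred > level, mask.slice_index, mask.geometry)


def interior_region(mask: BinaryMask2D, margin_px: int) -> BinaryMask2D:
    """Pixels whose Chebyshev distance to the nearest background exceeds ``margin_px``.

    Equivalent to erosion by a ``(2*margin+1)**2`` square structuring
    element (pixels beyond the image border count as background).  May
    return an empty mask.
    """
    if margin_px < 0:
        raise ValueError("margin_px must be >= 0")
    if margin_px == 0:
        return BinaryMask2D(mask.pixels.copy(), mask.slice_index, mask.geometry)
    # iterated 3x3 erosion == erosion by the (2m+1)^2 square (Chebyshev balls)
    eroded = ndimage.binary_erosion(
        mask.pixels,
        structure=np.ones((3, 3), dtype=bool),
        iterations=margin_px,
        border_value=0,
    )
    return BinaryMask2D(eroded, mask.slice_index, mask.geometry)


def prep_mask(
    mask: BinaryMask2D, params: MaskPrepParams = MaskPrepParams()
) -> tuple[BinaryMask2D, BinaryMask2D]:
    """Full preparation: fill small holes, smooth, and derive the interior.

    Returns ``(prepped, interior)``; detections are later gated on the
    interior while intensity normalization uses the full prepped mask.
    """
    filled = fill_small_holes(mask, params.hole_area_max_px)
    smoothed = smooth_and_rebinarize(filled, params.smooth_sigma_px, params.rebinarize_level)
    interior = interior_region(smoothed, params.boundary_margin_px)
    return smoothed, interior
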