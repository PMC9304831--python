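"""From vesselness maps to PVS objects.

The vesselness map is thresholded inside the white-matter interior
region, connected components become candidate objects, objects whose
mean normalized intensity lies outside ``k`` standard deviations of the
candidate population's mean are dropped, and a reviewer edit list of
removals is applied (the review step only removes markings; none are
ever added).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .io_formats import BinaryMask2D, Slice2D
from .vesselness import VesselnessMap

__all__ = [
    "SegmentationParams",
    "PVSObject",
    "threshold_vesselness",
    "extract_objects",
    "intensity_outlier_filter",
    "apply_edit_list",
]

_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationParams:
    vesselness_threshold: float = 0.4
    intensity_sd_k: float = 2.0
    connectivity: int = 8
    min_object_px: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.vesselness_threshold < 1.0:
            raise ValueError("vesselness_threshold must lie in (0, 1)")
        if self.intensity_sd_k < 0:
            raise ValueError("intensity_sd_k must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_object_px < 1:
            raise ValueError("min_object_px must be >= 1")


@dataclass
class PVSObject:
    """One connected component marked as a candidate perivascular space.

    ``bbox`` is the tight axis-aligned bound ``(row_min, col_min,
    row_max, col_max)``, half-open.  Shape descriptors (mm units) are
    filled by the quantify stage and are ``None`` until then.
    """

    object_id: int
    slice_index: int
    pixel_set: list[tuple[int, int]] | None
    area_px: int
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]
    mean_intensity: float
    area_mm2: float | None = None
    volume_mm3: float | None = None
    eq_diameter_mm: float | None = None
    long_axis_mm: float | None = None
    short_axis_mm: float | None = None


def threshold_vesselness(
    vmap: VesselnessMap, interior: BinaryMask2D, threshold: float
) -> BinaryMask2D:
    """Pixels with vesselness strictly above ``threshold`` inside the interior."""
    if vmap.values.shape != interior.pixels.shape:
        raise ValueError("vesselness map and interior mask shapes differ")
    out = (vmap.values > threshold) & interior.pixels
    return BinaryMask2D(out, vmap.slice_index, interior.geometry)


def extract_objects(
    binary: BinaryMask2D,
    slice_: Slice2D,
    connectivity: int = 8,
    min_object_px: int = 1,
    id_offset: int = 0,
) -> list[PVSObject]:
    """Connected components of ``binary`` as PVS objects.

    Object ordering (and ids, offset by ``id_offset``) is deterministic:
    row-major by first pixel encountered.  ``mean_intensity`` averages
    the paired (normalized) slice over the component's pixels.
    """
    structure = _STRUCTURE_8 if connectivity == 8 else _STRUCTURE_4
    labels, n = ndimage.label(binary.pixels, structure=structure)
    objects: list[PVSObject] = []
    if n == 0:
        return objects
    slices_ = ndimage.find_objects(labels)
    oid = id_offset
    for lab in range(1, n + 1):
        sl = slices_[lab - 1]
        region = labels[sl] == lab
        area = int(region.sum())
        if area < min_object_px:
            continue
        rr, cc = np.nonzero(region)
        rows = rr + sl[0].start
        cols = cc + sl[1].start
        oid += 1
        objects.append(
            PVSObject(
                object_id=oid,
                slice_index=binary.slice_index,
                pixel_set=list(zip(rows.tolist(), cols.tolist())),
                area_px=area,
                bbox=(
                    int(rows.min()),
                    int(cols.min()),
                    int(rows.max()) + 1,
                    int(cols.max()) + 1,
                ),
                centroid=(float(rows.mean()), float(cols.mean())),
                mean_intensity=float(slice_.pixels[rows, cols].mean()),
            )
        )
    return objects


def intensity_outlier_filter(objects: Sequence[PVSObject], k: float = 2.0) -> list[PVSObject]:
    """Drop objects whose mean intensity is an outlier of the candidate pool.

    With mu and s the mean and (sample) standard deviation of the
    candidates' mean intensities — pooled across a subject's slices —
    an object is retained iff ``|mean_intensity - mu| <= k*s``.  With
    fewer than 3 candidates, zero spread, or non-finite ``k``, all are
    retained.
    """
    objects = list(objects)
    if len(objects) < 3 or not math.isfinite(k):
        return objects
    vals = np.array([o.mean_intensity for o in objects], dtype=float)
    mu = vals.mean()
    s = vals.std(ddof=1)
    if s == 0:
        return objects
    keep = np.abs(vals - mu) <= k * s
    return [o for o, k_ in zip(objects, keep) if k_]


def apply_edit_list(
    objects: Sequence[PVSObject], edits: Iterable[tuple[int, str]]
) -> list[PVSObject]:
    """Apply reviewer edits.  The only supported action is ``remove``.

    Duplicate removals are idempotent; an unknown id or action raises.
    """
    known = {o.object_id for o in objects}
    to_remove: set[int] = set()
    for object_id, action in edits:
        if action != "remove":
            raise ValueError(f"unsupported edit action {action!r} (only 'remove')")
        if object_id not in known:
            raise KeyError(f"edit list references unknown object_id {object_id}")
        to_remove.add(object_id)
    return [o for o in objects if o.object_id not in to_remove]
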