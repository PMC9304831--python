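"""Per-object shape descriptors and per-subject summary measures.

Each marked object lives on a single slice; objects on adjacent slices
are counted independently (no 3-D linking).  Per object: in-plane area,
slab volume (area x slice thickness), equivalent diameter, and the
major/minor axis lengths of the ellipse with the same normalized second
central moments as the pixel set.  Per subject: count, total and median
volume, density (count per cm^3 of white matter), and medians of the
three length descriptors.

Object volume uses the 2 mm slab thickness only (structures are
observed within the excited slab), while white-matter volume uses the
full slice pitch (thickness + gap) so that coverage of the whole
compartment is accounted for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.measure import regionprops

from .io_formats import BinaryMask2D, VolumeGeometry
from .segmentation import PVSObject

__all__ = ["SubjectPVSStats", "object_shape", "subject_stats"]


@dataclass
class SubjectPVSStats:
    """The per-subject quantification measures.

    ``density_per_cm3`` is the object count per cm^3 of white matter;
    the raw count / WM-mm^3 ratio is exposed as ``density_per_mm3``.
    Medians are ``None`` (absent) when the subject has no objects.
    """

    pvs_count: int
    total_volume_mm3: float
    median_volume_mm3: float | None
    density_per_cm3: float
    median_eq_diameter_mm: float | None
    median_long_axis_mm: float | None
    median_short_axis_mm: float | None
    wm_volume_mm3: float

    @property
    def density_per_mm3(self) -> float:
        return self.density_per_cm3 / 1000.0


def object_shape(obj: PVSObject, geom: VolumeGeometry) -> PVSObject:
    """Fill an object's shape descriptors (mm units) in place and return it.

    area_mm2 = area_px * dr * dc;  volume = area_mm2 * slice thickness;
    eq_diameter = sqrt(4 * area_mm2 / pi) (so pi/4 * eq_d^2 == area
    exactly); axis lengths come from the region's normalized second
    central moments, evaluated with the physical pixel spacing.
    """
    if obj.pixel_set is None:
        raise ValueError(f"object {obj.object_id} carries no pixel set")
    if obj.area_px < 1:
        raise ValueError("object must contain at least one pixel")
    dr, dc = geom.in_plane_spacing_mm
    obj.area_mm2 = obj.area_px * dr * dc
    obj.volume_mm3 = obj.area_mm2 * geom.slice_thickness_mm
    obj.eq_diameter_mm = math.sqrt(4.0 * obj.area_mm2 / math.pi)

    rows = np.array([p[0] for p in obj.pixel_set])
    cols = np.array([p[1] for p in obj.pixel_set])
    r0, c0 = rows.min(), cols.min()
    local = np.zeros((rows.max() - r0 + 1, cols.max() - c0 + 1), dtype=np.uint8)
    local[rows - r0, cols - c0] = 1
    props = regionprops(local, spacing=(dr, dc))[0]
    obj.long_axis_mm = float(props.axis_major_length)
    obj.short_axis_mm = float(props.axis_minor_length)
    return obj


def _median(values: list[float]) -> float | None:
    if not values:
        return None
    return float(np.median(values))


def subject_stats(
    objects: Sequence[PVSObject],
    wm_masks: Sequence[BinaryMask2D],
    geom: VolumeGeometry,
) -> SubjectPVSStats:
    """Aggregate a subject's retained objects into the summary measures.

    ``wm_masks`` are the prepared per-slice white-matter masks; WM
    volume = total WM pixel count x pixel area x slice pitch.
    Permutation-invariant in object order.
    """
    if not wm_masks:
        raise ValueError("need at least one white-matter mask slice")
    wm_px = int(sum(int(m.pixels.sum()) for m in wm_masks))
    wm_volume_mm3 = wm_px * geom.pixel_area_mm2 * geom.slice_pitch_mm
    if wm_volume_mm3 <= 0:
        raise ValueError("white-matter masks are empty")

    objects = [object_shape(o, geom) if o.volume_mm3 is None else o for o in objects]
    volumes = [o.volume_mm3 for o in objects]
    count = len(objects)
    return SubjectPVSStats(
        pvs_count=count,
        # fsum: exactly rounded, hence invariant to object order
        total_volume_mm3=math.fsum(volumes),
        median_volume_mm3=_median(volumes),
        density_per_cm3=count / (wm_volume_mm3 / 1000.0),
        median_eq_diameter_mm=_median([o.eq_diameter_mm for o in objects]),
        median_long_axis_mm=_median([o.long_axis_mm for o in objects]),
        median_short_axis_mm=_median([o.short_axis_mm for o in objects]),
        wm_volume_mm3=wm_volume_mm3,
    )
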