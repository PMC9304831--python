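"""Agreement between two marking sets.

Object-level agreement uses bounding boxes: two markings on the same
slice are consistent when their boxes, each dilated by a physical
tolerance (default 4 mm), intersect.  Matching is many-to-many — any
overlap counts.  Sensitivity is the matched fraction of the reference
set; the matched fraction of the candidate set is precision (reported
here under that name; detection problems have no countable true
negatives, so a specificity in the strict sense does not exist and the
term is kept only as an output alias).

Voxel-level agreement between two binarized marking volumes reports the
Dice score 2|A&B|/(|A|+|B|), the Jaccard fraction |A&B|/|A|B|, and both
directed overlap fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import BinaryMask2D, VolumeGeometry
from .segmentation import PVSObject

__all__ = [
    "MatchParams",
    "MatchResult",
    "VoxelAgreement",
    "boxes_overlap",
    "match_markings",
    "voxel_agreement",
]


@dataclass(frozen=True)
class MatchParams:
    """Bounding-box matching tolerance.

    ``dilate_both`` applies the tolerance to each box (boxes match when
    the gap per axis is <= 2*tol); switching it off dilates only one.
    """

    tolerance_mm: float = 4.0
    dilate_both: bool = True

    def __post_init__(self) -> None:
        if self.tolerance_mm < 0:
            raise ValueError("tolerance_mm must be >= 0")


@dataclass
class MatchResult:
    n_reference: int
    n_candidate: int
    n_reference_matched: int
    n_candidate_matched: int
    sensitivity: float | None
    precision: float | None

    @property
    def specificity(self) -> float | None:
        """Alias kept for comparability with the published terminology."""
        return self.precision


@dataclass
class VoxelAgreement:
    dice: float | None
    jaccard: float | None
    fraction_of_a: float | None
    fraction_of_b: float | None


def _boxes_overlap_1d(a0: float, a1: float, b0: float, b1: float, reach: float) -> bool:
    # half-open [x0, x1); gap between occupied extents must not exceed reach
    return (b0 - a1) <= reach and (a0 - b1) <= reach


def boxes_overlap(
    a: PVSObject | tuple,
    b: PVSObject | tuple,
    tol_px: float,
    dilate_both: bool = True,
) -> bool:
    """True iff the two boxes, dilated by ``tol_px``, intersect (closed).

    Accepts objects or raw half-open ``(r0, c0, r1, c1)`` boxes; objects
    must lie on the same slice.
    """
    if isinstance(a, PVSObject) and isinstance(b, PVSObject):
        if a.slice_index != b.slice_index:
            raise ValueError(
                f"cannot compare boxes across slices ({a.slice_index} vs {b.slice_index}); "
                "matching is per-slice"
            )
        box_a, box_b = a.bbox, b.bbox
    else:
        box_a = a.bbox if isinstance(a, PVSObject) else tuple(a)
        box_b = b.bbox if isinstance(b, PVSObject) else tuple(b)
    reach = 2.0 * tol_px if dilate_both else float(tol_px)
    return _boxes_overlap_1d(box_a[0], box_a[2], box_b[0], box_b[2], reach) and _boxes_overlap_1d(
        box_a[1], box_a[3], box_b[1], box_b[3], reach
    )


def match_markings(
    reference: Sequence[PVSObject],
    candidate: Sequence[PVSObject],
    params: MatchParams,
    geom: VolumeGeometry,
) -> MatchResult:
    """Many-to-many per-slice bounding-box matching.

    A marking is matched when at least one marking of the other set on
    the same slice overlaps it under :func:`boxes_overlap` with
    ``tol_px = tolerance_mm / in-plane spacing``.  Undefined rates
    (empty set) are returned as ``None``.
    """
    dr, dc = geom.in_plane_spacing_mm
    if abs(dr - dc) > 1e-9:
        raise ValueError("anisotropic in-plane spacing is not supported by the matcher")
    tol_px = params.tolerance_mm / dr

    by_slice_cand: dict[int, list[PVSObject]] = {}
    for o in candidate:
        by_slice_cand.setdefault(o.slice_index, []).append(o)

    ref_matched = 0
    cand_matched_ids: set[int] = set()
    for r in reference:
        hit = False
        for c in by_slice_cand.get(r.slice_index, ()):
            if boxes_overlap(r.bbox, c.bbox, tol_px, params.dilate_both):
                hit = True
                cand_matched_ids.add(id(c))
        if hit:
            ref_matched += 1

    n_ref, n_cand = len(reference), len(candidate)
    return MatchResult(
        n_reference=n_ref,
        n_candidate=n_cand,
        n_reference_matched=ref_matched,
        n_candidate_matched=len(cand_matched_ids),
        sensitivity=(ref_matched / n_ref) if n_ref else None,
        precision=(len(cand_matched_ids) / n_cand) if n_cand else None,
    )


def _collect(masks) -> np.ndarray:
    if isinstance(masks, np.ndarray):
        return masks.astype(bool)
    return np.stack([m.pixels for m in masks], axis=-1).astype(bool)


def voxel_agreement(mask_a, mask_b) -> VoxelAgreement:
    """Voxel-for-voxel overlap between two marking volumes.

    Accepts boolean arrays or sequences of :class:`BinaryMask2D` with
    identical geometry.  Both-empty inputs yield absent metrics.
    """
    a, b = _collect(mask_a), _collect(mask_b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    inter = int((a & b).sum())
    union = na + nb - inter
    if na + nb == 0:
        return VoxelAgreement(None, None, None, None)
    return VoxelAgreement(
        dice=2.0 * inter / (na + nb),
        jaccard=inter / union if union else None,
        fraction_of_a=inter / na if na else None,
        fraction_of_b=inter / nb if nb else None,
    )
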