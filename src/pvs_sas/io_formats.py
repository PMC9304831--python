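"""Reading and writing volumes, masks and cohort tables.

Images and binary masks travel as NIfTI-1 volumes; cohort tables as
UTF-8 CSV with a header row.  In-memory, a volume is a list of
:class:`Slice2D` objects sharing one :class:`VolumeGeometry`.

Index convention: ``(row, col, slice)``, 0-based, half-open ranges;
physical position = index x spacing.  The NIfTI ``(i, j, k)`` axes map
to ``(row, col, slice)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGeometry",
    "Slice2D",
    "BinaryMask2D",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_cohort_table",
    "write_cohort_table",
    "read_edit_list",
    "write_objects_csv",
    "read_objects_csv",
]


@dataclass(frozen=True)
class VolumeGeometry:
    """Acquisition geometry of an axial T2 volume.

    The scanner stores a single through-plane spacing (the slice
    *pitch*); acquisition protocols with an inter-slice gap need the
    pitch decomposed into ``slice_thickness_mm + slice_gap_mm``, which
    NIfTI headers cannot represent — hence both are carried explicitly.
    """

    n_rows: int
    n_cols: int
    n_slices: int
    in_plane_spacing_mm: tuple[float, float] = (0.2, 0.2)
    slice_thickness_mm: float = 2.0
    slice_gap_mm: float = 0.6

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0 or self.n_slices <= 0:
            raise ValueError("image dimensions must be positive")
        dr, dc = self.in_plane_spacing_mm
        if dr <= 0 or dc <= 0:
            raise ValueError("in-plane spacing must be strictly positive")
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice thickness must be strictly positive")
        if self.slice_gap_mm < 0:
            raise ValueError("slice gap must be non-negative")

    @property
    def slice_pitch_mm(self) -> float:
        """Effective through-plane spacing: thickness plus gap."""
        return self.slice_thickness_mm + self.slice_gap_mm

    @property
    def pixel_area_mm2(self) -> float:
        dr, dc = self.in_plane_spacing_mm
        return dr * dc

    def close_to(self, other: "VolumeGeometry", tol_mm: float = 1e-6) -> bool:
        return (
            (self.n_rows, self.n_cols, self.n_slices)
            == (other.n_rows, other.n_cols, other.n_slices)
            and math.isclose(self.in_plane_spacing_mm[0], other.in_plane_spacing_mm[0], abs_tol=tol_mm)
            and math.isclose(self.in_plane_spacing_mm[1], other.in_plane_spacing_mm[1], abs_tol=tol_mm)
            and math.isclose(self.slice_thickness_mm, other.slice_thickness_mm, abs_tol=tol_mm)
            and math.isclose(self.slice_gap_mm, other.slice_gap_mm, abs_tol=tol_mm)
        )


@dataclass
class Slice2D:
    """One axial intensity plane (arbitrary scanner units)."""

    pixels: np.ndarray
    slice_index: int
    geometry: VolumeGeometry

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("slice pixels must be a 2-D matrix")
        if self.pixels.shape != (self.geometry.n_rows, self.geometry.n_cols):
            raise ValueError(
                f"slice shape {self.pixels.shape} does not match geometry "
                f"({self.geometry.n_rows}, {self.geometry.n_cols})"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("slice contains non-finite pixel values")


@dataclass
class BinaryMask2D:
    """A boolean plane paired with the slice it annotates."""

    pixels: np.ndarray
    slice_index: int
    geometry: VolumeGeometry

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask pixels must be a 2-D matrix")
        if self.pixels.shape != (self.geometry.n_rows, self.geometry.n_cols):
            raise ValueError(
                f"mask shape {self.pixels.shape} does not match geometry "
                f"({self.geometry.n_rows}, {self.geometry.n_cols})"
            )


def _geometry_from_header(
    img: nib.Nifti1Image, slice_thickness_mm: float | None, slice_gap_mm: float | None
) -> VolumeGeometry:
    shape = img.shape
    zooms = img.header.get_zooms()[:3]
    pitch = float(zooms[2])
    if slice_thickness_mm is None and slice_gap_mm is None:
        thickness, gap = pitch, 0.0
    elif slice_thickness_mm is not None:
        thickness = float(slice_thickness_mm)
        gap = pitch - thickness if slice_gap_mm is None else float(slice_gap_mm)
    else:
        gap = float(slice_gap_mm)
        thickness = pitch - gap
    if thickness <= 0 or gap < -1e-9:
        raise ValueError(
            f"slice pitch {pitch} mm cannot be decomposed into "
            f"thickness {thickness} mm + gap {gap} mm"
        )
    return VolumeGeometry(
        n_rows=shape[0],
        n_cols=shape[1],
        n_slices=shape[2],
        in_plane_spacing_mm=(float(zooms[0]), float(zooms[1])),
        slice_thickness_mm=thickness,
        slice_gap_mm=max(gap, 0.0),
    )


def read_volume(
    path: str | Path,
    slice_thickness_mm: float | None = None,
    slice_gap_mm: float | None = None,
) -> tuple[list[Slice2D], VolumeGeometry]:
    """Read a 3-D NIfTI volume into per-slice planes.

    The header carries only the slice pitch; pass ``slice_thickness_mm``
    (and optionally ``slice_gap_mm``) to decompose it when the protocol
    used gapped slices.  With neither given, the pitch is taken as the
    thickness and the gap as zero.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected 3D volume, got shape {img.shape}")
    data = np.asanyarray(img.dataobj).astype(float)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"volume {path} contains non-finite voxels")
    geom = _geometry_from_header(img, slice_thickness_mm, slice_gap_mm)
    slices = [Slice2D(data[:, :, k], k, geom) for k in range(geom.n_slices)]
    return slices, geom


def _volume_affine(geom: VolumeGeometry) -> np.ndarray:
    dr, dc = geom.in_plane_spacing_mm
    return np.diag([dr, dc, geom.slice_pitch_mm, 1.0])


def write_volume(slices: Sequence[Slice2D], path: str | Path) -> None:
    """Write slices (one shared geometry) as a 3-D NIfTI volume."""
    if not slices:
        raise ValueError("no slices to write")
    geom = slices[0].geometry
    for s in slices:
        if not s.geometry.close_to(geom):
            raise ValueError("slices do not share one geometry")
    data = np.stack([s.pixels for s in sorted(slices, key=lambda s: s.slice_index)], axis=2)
    img = nib.Nifti1Image(data.astype(np.float64), _volume_affine(geom))
    img.header.set_zooms((geom.in_plane_spacing_mm[0], geom.in_plane_spacing_mm[1], geom.slice_pitch_mm))
    nib.save(img, str(path))


def write_mask(masks: Sequence[BinaryMask2D], path: str | Path) -> None:
    """Write binary masks as a 0/1-valued NIfTI volume (1 = marked)."""
    if not masks:
        raise ValueError("no masks to write")
    geom = masks[0].geometry
    for m in masks:
        if not m.geometry.close_to(geom):
            raise ValueError("masks do not share one geometry")
    data = np.stack(
        [m.pixels for m in sorted(masks, key=lambda m: m.slice_index)], axis=2
    ).astype(np.uint8)
    img = nib.Nifti1Image(data, _volume_affine(geom))
    img.header.set_zooms((geom.in_plane_spacing_mm[0], geom.in_plane_spacing_mm[1], geom.slice_pitch_mm))
    nib.save(img, str(path))


def read_mask(
    path: str | Path,
    slice_thickness_mm: float | None = None,
    slice_gap_mm: float | None = None,
) -> tuple[list[BinaryMask2D], VolumeGeometry]:
    """Read a binary (0/1) NIfTI volume as per-slice masks."""
    slices, geom = read_volume(path, slice_thickness_mm, slice_gap_mm)
    masks = [BinaryMask2D(s.pixels > 0.5, s.slice_index, geom) for s in slices]
    return masks, geom


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = (
    "id",
    "group",
    "age",
    "gender",
    "tleq_ce",
    "tleq_oc",
    "madrs",
    "brain_vol",
    "csf_vol",
)

# optional per-subject PVS measure columns, matched to SubjectPVSStats fields
_MEASURE_COLUMNS = (
    "pvs_count",
    "total_volume_mm3",
    "median_volume_mm3",
    "density_per_cm3",
    "median_eq_diameter_mm",
    "median_long_axis_mm",
    "median_short_axis_mm",
    "wm_volume_mm3",
)


def read_cohort_table(path: str | Path):
    """Read a cohort CSV into typed :class:`~pvs_sas.stats.CohortRecord` rows.

    Required columns: ``id, group, age, gender, tleq_ce, tleq_oc, madrs,
    brain_vol, csf_vol``.  Blank optional cells become ``None`` (absent),
    never zero.  PVS measure columns, when present, populate the
    record's ``stats``.
    """
    from .quantify import SubjectPVSStats
    from .stats import CohortRecord

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort table not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError("no records in cohort table") from None
    if df.empty:
        raise ValueError("no records in cohort table")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")

    def _opt(row, col) -> float | None:
        if col not in row or pd.isna(row[col]):
            return None
        return float(row[col])

    records = []
    for _, row in df.iterrows():
        if pd.isna(row["age"]):
            raise ValueError(f"subject {row['id']}: missing age")
        try:
            age = float(row["age"])
        except (TypeError, ValueError):
            raise ValueError(f"subject {row['id']}: non-numeric age {row['age']!r}") from None
        measures = {c: _opt(row, c) for c in _MEASURE_COLUMNS}
        stats = None
        if measures["pvs_count"] is not None:
            stats = SubjectPVSStats(
                pvs_count=int(measures["pvs_count"]),
                total_volume_mm3=measures["total_volume_mm3"] or 0.0,
                median_volume_mm3=measures["median_volume_mm3"],
                density_per_cm3=measures["density_per_cm3"] or 0.0,
                median_eq_diameter_mm=measures["median_eq_diameter_mm"],
                median_long_axis_mm=measures["median_long_axis_mm"],
                median_short_axis_mm=measures["median_short_axis_mm"],
                wm_volume_mm3=measures["wm_volume_mm3"] or 0.0,
            )
        records.append(
            CohortRecord(
                subject_id=str(row["id"]),
                group=str(row["group"]),
                age=age,
                gender=str(row["gender"]),
                tleq_ce=_opt(row, "tleq_ce"),
                tleq_oc=_opt(row, "tleq_oc"),
                madrs=_opt(row, "madrs"),
                brain_vol_mm3=_opt(row, "brain_vol"),
                csf_vol_mm3=_opt(row, "csf_vol"),
                stats=stats,
            )
        )
    return records


def write_cohort_table(records, path: str | Path) -> None:
    """Write cohort records (inverse of :func:`read_cohort_table`)."""
    rows = []
    for r in records:
        row = {
            "id": r.subject_id,
            "group": r.group,
            "age": r.age,
            "gender": r.gender,
            "tleq_ce": r.tleq_ce,
            "tleq_oc": r.tleq_oc,
            "madrs": r.madrs,
            "brain_vol": r.brain_vol_mm3,
            "csf_vol": r.csf_vol_mm3,
        }
        if r.stats is not None:
            s = r.stats
            row.update(
                pvs_count=s.pvs_count,
                total_volume_mm3=s.total_volume_mm3,
                median_volume_mm3=s.median_volume_mm3,
                density_per_cm3=s.density_per_cm3,
                median_eq_diameter_mm=s.median_eq_diameter_mm,
                median_long_axis_mm=s.median_long_axis_mm,
                median_short_axis_mm=s.median_short_axis_mm,
                wm_volume_mm3=s.wm_volume_mm3,
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Object tables and reviewer edit lists
# ---------------------------------------------------------------------------


def write_objects_csv(objects, path: str | Path) -> None:
    """Export segmented objects, one row per object."""
    rows = []
    for o in objects:
        rows.append(
            {
                "object_id": o.object_id,
                "slice_index": o.slice_index,
                "area_px": o.area_px,
                "row_min": o.bbox[0],
                "col_min": o.bbox[1],
                "row_max": o.bbox[2],
                "col_max": o.bbox[3],
                "centroid_row": o.centroid[0],
                "centroid_col": o.centroid[1],
                "mean_intensity": o.mean_intensity,
                "area_mm2": o.area_mm2,
                "volume_mm3": o.volume_mm3,
                "eq_diameter_mm": o.eq_diameter_mm,
                "long_axis_mm": o.long_axis_mm,
                "short_axis_mm": o.short_axis_mm,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "object_id",
            "slice_index",
            "area_px",
            "row_min",
            "col_min",
            "row_max",
            "col_max",
            "centroid_row",
            "centroid_col",
            "mean_intensity",
            "area_mm2",
            "volume_mm3",
            "eq_diameter_mm",
            "long_axis_mm",
            "short_axis_mm",
        ],
    ).to_csv(path, index=False)


def read_objects_csv(path: str | Path):
    """Read an object table back into :class:`~pvs_sas.segmentation.PVSObject`.

    The pixel set is not stored in the CSV; round-tripped objects carry
    bounding boxes, centroids and shape descriptors, which is what the
    overlap validation consumes.
    """
    from .segmentation import PVSObject

    df = pd.read_csv(path)
    objects = []
    for _, row in df.iterrows():
        def _f(col):
            return None if pd.isna(row[col]) else float(row[col])

        objects.append(
            PVSObject(
                object_id=int(row["object_id"]),
                slice_index=int(row["slice_index"]),
                pixel_set=None,
                area_px=int(row["area_px"]),
                bbox=(
                    int(row["row_min"]),
                    int(row["col_min"]),
                    int(row["row_max"]),
                    int(row["col_max"]),
                ),
                centroid=(float(row["centroid_row"]), float(row["centroid_col"])),
                mean_intensity=float(row["mean_intensity"]),
                area_mm2=_f("area_mm2"),
                volume_mm3=_f("volume_mm3"),
                eq_diameter_mm=_f("eq_diameter_mm"),
                long_axis_mm=_f("long_axis_mm"),
                short_axis_mm=_f("short_axis_mm"),
            )
        )
    return objects


def read_edit_list(path: str | Path) -> list[tuple[int, str]]:
    """Read a reviewer edit list CSV with columns ``object_id, action``."""
    df = pd.read_csv(path)
    for col in ("object_id", "action"):
        if col not in df.columns:
            raise ValueError(f"edit list missing column {col!r}")
    return [(int(r["object_id"]), str(r["action"]).strip()) for _, r in df.iterrows()]
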