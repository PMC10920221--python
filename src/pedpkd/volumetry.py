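"""Kidney volumetry from MRI segmentations.

Two estimators are provided:

* the stereological (Cavalieri) method — the cross-sectional area of the
  kidney is traced on every slice and the volume is the sum of the areas
  (mm^2) times the section thickness (mm), divided by 1000 to give ml;
* the ellipsoid approximation — (pi/6) x length x width x depth from three
  orthogonal axes measured on the images.

Total kidney volume (TKV) is the sum of the two per-kidney volumes and is
height-adjusted (htTKV, ml/m) by dividing by body height in meters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import EmptySeriesError, InvalidInputError

KIDNEY_SIDES = ("left", "right")

#: accepted conventions for the single "length" entering the ellipsoid formula
LENGTH_CONVENTIONS = ("mean", "sagittal", "coronal", "max")


@dataclass(frozen=True)
class SliceAreaSeries:
    """Ordered per-slice cross-sectional areas for one kidney.

    Slices are assumed contiguous (no gap or overlap): the acquisition
    protocol this models uses contiguous 4-mm sections.

    Parameters
    ----------
    kidney_side : {"left", "right"}
    areas_mm2 : sequence of float
        One traced area per slice, mm^2, in anatomical order. All >= 0.
    slice_thickness_mm : float
        Section thickness, mm. Must be > 0.
    """

    kidney_side: str
    areas_mm2: tuple
    slice_thickness_mm: float

    def __post_init__(self):
        if self.kidney_side not in KIDNEY_SIDES:
            raise InvalidInputError(f"kidney_side must be one of {KIDNEY_SIDES}, got {self.kidney_side!r}")
        areas = tuple(float(a) for a in self.areas_mm2)
        object.__setattr__(self, "areas_mm2", areas)
        if len(areas) == 0:
            raise InvalidInputError("slice-area series must contain at least one slice")
        if any((not math.isfinite(a)) or a < 0 for a in areas):
            raise InvalidInputError("slice areas must be finite and >= 0")
        if not (math.isfinite(self.slice_thickness_mm) and self.slice_thickness_mm > 0):
            raise InvalidInputError("slice thickness must be a positive, finite number of mm")

    @property
    def n_slices(self) -> int:
        return len(self.areas_mm2)


@dataclass(frozen=True)
class OrthogonalAxes:
    """Three orthogonal kidney axes (mm): sagittal and coronal maximal
    lengths, width and depth, as measured per kidney on MRI."""

    sagittal_length_mm: float
    coronal_length_mm: float
    width_mm: float
    depth_mm: float

    def __post_init__(self):
        for name in ("sagittal_length_mm", "coronal_length_mm", "width_mm", "depth_mm"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise InvalidInputError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class VolumeSet:
    """Per-patient volume summary (all volumes ml; htTKV ml/m)."""

    left_ml: Optional[float] = None
    right_ml: Optional[float] = None
    tkv_ml: Optional[float] = None
    httkv_ml_per_m: Optional[float] = None
    ellipsoid_tkv_ml: Optional[float] = None

    @classmethod
    def from_kidneys(
        cls,
        left_ml: Optional[float],
        right_ml: Optional[float],
        height_m: Optional[float] = None,
        ellipsoid_tkv_ml: Optional[float] = None,
        allow_unilateral: bool = False,
    ) -> "VolumeSet":
        """Build a :class:`VolumeSet` from per-kidney volumes.

        TKV is only defined when both kidneys are present; with
        ``allow_unilateral=True`` a single kidney is passed through but
        TKV (and htTKV) stay undefined.
        """
        if left_ml is not None and right_ml is not None:
            tkv = total_kidney_volume(left_ml, right_ml)
        elif allow_unilateral:
            tkv = None
        else:
            raise InvalidInputError(
                "both kidney volumes are required (pass allow_unilateral=True to accept one)"
            )
        httkv = None
        if tkv is not None and height_m is not None:
            httkv = height_adjusted_tkv(tkv, height_m)
        return cls(
            left_ml=left_ml,
            right_ml=right_ml,
            tkv_ml=tkv,
            httkv_ml_per_m=httkv,
            ellipsoid_tkv_ml=ellipsoid_tkv_ml,
        )


def stereological_volume(series: SliceAreaSeries) -> float:
    """Cavalieri volume of one kidney, ml.

    volume = (sum of slice areas, mm^2) x (section thickness, mm) / 1000.
    """
    return float(np.sum(series.areas_mm2)) * series.slice_thickness_mm / 1000.0


def total_kidney_volume(left_ml: float, right_ml: float) -> float:
    """TKV (ml) = left + right kidney volume."""
    if left_ml < 0 or right_ml < 0:
        raise InvalidInputError("kidney volumes must be >= 0")
    return float(left_ml) + float(right_ml)


def height_adjusted_tkv(tkv_ml: float, height_m: float) -> float:
    """htTKV (ml/m) = TKV / height. Height must be in meters and > 0."""
    if not (math.isfinite(height_m) and height_m > 0):
        raise InvalidInputError("height must be > 0 meters")
    if tkv_ml < 0:
        raise InvalidInputError("TKV must be >= 0")
    return float(tkv_ml) / float(height_m)


def ellipsoid_volume(axes: OrthogonalAxes, length_convention: str = "mean") -> float:
    """Ellipsoid kidney volume, ml: (pi/6) x length x width x depth / 1000.

    The measurements report two maximal lengths (sagittal and coronal);
    which one enters the equation is a convention. The default uses their
    arithmetic mean; ``length_convention`` may be any of
    ``{"mean", "sagittal", "coronal", "max"}``.
    """
    if length_convention not in LENGTH_CONVENTIONS:
        raise InvalidInputError(f"length_convention must be one of {LENGTH_CONVENTIONS}")
    if length_convention == "mean":
        length = 0.5 * (axes.sagittal_length_mm + axes.coronal_length_mm)
    elif length_convention == "sagittal":
        length = axes.sagittal_length_mm
    elif length_convention == "coronal":
        length = axes.coronal_length_mm
    else:
        length = max(axes.sagittal_length_mm, axes.coronal_length_mm)
    return math.pi / 6.0 * length * axes.width_mm * axes.depth_mm / 1000.0


def areas_from_mask(
    label_mask: np.ndarray,
    voxel_spacing: Sequence[float],
    label_value: int = 1,
    slice_axis: int = 2,
    kidney_side: str = "left",
) -> SliceAreaSeries:
    """Per-slice areas from a 3-D integer segmentation volume.

    Each slice along ``slice_axis`` contributes
    (number of voxels equal to ``label_value``) x in-plane voxel area (mm^2);
    the slice thickness is the between-slice spacing. Leading and trailing
    empty slices are trimmed so the series spans the labeled extent.
    """
    mask = np.asarray(label_mask)
    if mask.ndim != 3:
        raise InvalidInputError(f"label mask must be 3-D, got {mask.ndim}-D")
    spacing = tuple(float(s) for s in voxel_spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise InvalidInputError("voxel_spacing must be three positive lengths in mm")
    if slice_axis not in (0, 1, 2):
        raise InvalidInputError("slice_axis must be 0, 1 or 2")

    hits = mask == label_value
    counts = hits.sum(axis=tuple(ax for ax in range(3) if ax != slice_axis))
    nonzero = np.flatnonzero(counts)
    if nonzero.size == 0:
        raise EmptySeriesError(f"label {label_value} not present in mask")
    counts = counts[nonzero[0] : nonzero[-1] + 1]

    in_plane = [spacing[ax] for ax in range(3) if ax != slice_axis]
    voxel_area = in_plane[0] * in_plane[1]
    return SliceAreaSeries(
        kidney_side=kidney_side,
        areas_mm2=tuple(float(c) * voxel_area for c in counts),
        slice_thickness_mm=spacing[slice_axis],
    )
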