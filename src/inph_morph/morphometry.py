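"""The six iNPH-specific morphometric indices.

Linear measurements are caliper-style voxel extents: along an axis the
extent of a set of voxels is ``(last - first + 1) * spacing`` (boundary to
boundary, bridging any interior gaps), which mirrors how a manual caliper
spans the full structure. Frontal horns are delimited as lateral-ventricle
voxels anterior to the AC coronal plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .segmentation_volumetrics import compute_volumes
from .volume_model import (
    CompartmentVolumes,
    CoronalSlice,
    LabeledVolume,
    LandmarkSet,
    MeasurementError,
    MorphometricIndices,
    coronal_plane_at,
    extract_coronal_slice,
)

__all__ = [
    "WidthMeasurement",
    "RatioMeasurement",
    "frontal_horn_mask",
    "evans_index",
    "z_evans_index",
    "callosal_angle",
    "bvr",
    "cvr",
    "measure_all",
    "evans_ratio",
    "z_evans_ratio",
    "cvr_ratio",
]


# ---------------------------------------------------------------------------
# Ratio arithmetic (the final stage of each index, usable on manual calipers)


def evans_ratio(horn_width_mm: float, cranial_width_mm: float) -> float:
    """Maximal frontal-horn x-width over maximal cranial x-width."""
    if cranial_width_mm <= 0:
        raise MeasurementError("cranial width must be positive")
    return horn_width_mm / cranial_width_mm


def z_evans_ratio(ventricular_z_mm: float, cranial_z_mm: float) -> float:
    """Maximal ventricular z-length over midline cranial z-length at the AC."""
    if cranial_z_mm <= 0:
        raise MeasurementError("cranial z-length must be positive")
    return ventricular_z_mm / cranial_z_mm


def cvr_ratio(convexity_ml: float, total_ventricles_ml: float) -> float:
    """Convexity-SAS volume over total ventricular volume."""
    if total_ventricles_ml == 0:
        raise ZeroDivisionError("total ventricular volume is zero; CVR undefined")
    return convexity_ml / total_ventricles_ml


# ---------------------------------------------------------------------------
# Measurement containers


@dataclass(frozen=True)
class WidthMeasurement:
    """A caliper measurement along one anatomical axis."""

    length_mm: float
    axis: str  # "x" or "z"
    location: str  # slice/plane identifier for audit
    endpoints: tuple[tuple[float, float, float], tuple[float, float, float]]


@dataclass(frozen=True)
class RatioMeasurement:
    """A dimensionless index with its two underlying width measurements."""

    value: float
    numerator: WidthMeasurement
    denominator: WidthMeasurement

    def __float__(self) -> float:
        return float(self.value)


# ---------------------------------------------------------------------------
# Extent helpers


def _first_last(mask_1d: np.ndarray) -> tuple[int, int] | None:
    idx = np.flatnonzero(mask_1d)
    if idx.size == 0:
        return None
    return int(idx[0]), int(idx[-1])


def _extent_mm(mask_1d: np.ndarray, spacing: float) -> float:
    fl = _first_last(mask_1d)
    if fl is None:
        return 0.0
    return (fl[1] - fl[0] + 1) * spacing


def _column_extents(mask_2d: np.ndarray, spacing: float) -> np.ndarray:
    """Boundary-to-boundary extent along axis 1 for every row of a 2D mask."""
    n = mask_2d.shape[1]
    idx = np.arange(n)
    has = mask_2d.any(axis=1)
    first = np.where(mask_2d, idx[None, :], n).min(axis=1)
    last = np.where(mask_2d, idx[None, :], -1).max(axis=1)
    out = np.where(has, (last - first + 1) * spacing, 0.0)
    return out


# ---------------------------------------------------------------------------
# Operations


def frontal_horn_mask(vol: LabeledVolume, landmarks: LandmarkSet) -> np.ndarray:
    """Lateral-ventricle voxels strictly anterior to the AC coronal plane."""
    lat = vol.mask("lateral_ventricles")
    if not lat.any():
        raise MeasurementError("no lateral-ventricle voxels in the volume")
    plane = coronal_plane_at(landmarks, "AC")
    n, p0 = plane.normal, plane.point
    # separable signed distance over the grid
    dx = n[0] * (vol.axis_coords(0) - p0[0])
    dy = n[1] * (vol.axis_coords(1) - p0[1])
    dz = n[2] * (vol.axis_coords(2) - p0[2])
    dist = dx[:, None, None] + dy[None, :, None] + dz[None, None, :]
    return lat & (dist > 0)


def evans_index(vol: LabeledVolume, landmarks: LandmarkSet) -> RatioMeasurement:
    """Evans index: maximal frontal-horn x-width over the cranial x-width
    measured on the same axial (z) slice."""
    horn = frontal_horn_mask(vol, landmarks)
    if not horn.any():
        raise MeasurementError("frontal horns empty anterior to the AC plane")
    dx = vol.spacing[0]
    horn_xz = horn.any(axis=1)  # project over y -> (x, z)
    extents = _column_extents(horn_xz.T, dx)  # per z-slice x-extent
    k = int(np.argmax(extents))
    cran_xz = vol.intracranial_mask.any(axis=1)
    cran_extent = _extent_mm(cran_xz[:, k], dx)
    if cran_extent == 0:
        raise MeasurementError("intracranial space empty on the measured slice")
    xs, zs = vol.axis_coords(0), vol.axis_coords(2)
    h = _first_last(horn_xz[:, k])
    c = _first_last(cran_xz[:, k])
    num = WidthMeasurement(
        length_mm=float(extents[k]),
        axis="x",
        location=f"axial z={zs[k]:.1f}mm",
        endpoints=(
            (xs[h[0]] - dx / 2, float("nan"), zs[k]),
            (xs[h[1]] + dx / 2, float("nan"), zs[k]),
        ),
    )
    den = WidthMeasurement(
        length_mm=cran_extent,
        axis="x",
        location=f"axial z={zs[k]:.1f}mm",
        endpoints=(
            (xs[c[0]] - dx / 2, float("nan"), zs[k]),
            (xs[c[1]] + dx / 2, float("nan"), zs[k]),
        ),
    )
    return RatioMeasurement(evans_ratio(num.length_mm, den.length_mm), num, den)


def _coronal_slice(vol: LabeledVolume, landmarks: LandmarkSet, level: str) -> CoronalSlice:
    return extract_coronal_slice(vol, coronal_plane_at(landmarks, level))


def z_evans_index(vol: LabeledVolume, landmarks: LandmarkSet) -> RatioMeasurement:
    """z-Evans index on the AC coronal slice: maximal ventricular z-extent
    over the cranial z-extent at the midline column (x of the AC)."""
    slc = _coronal_slice(vol, landmarks, "AC")
    vent = slc.labels == slc.schema["lateral_ventricles"]
    if not vent.any():
        raise MeasurementError("AC coronal slice misses the lateral ventricles")
    dz = slc.spacing[1]
    extents = _column_extents(vent, dz)
    i = int(np.argmax(extents))
    i_mid = int(np.argmin(np.abs(slc.x_coords - landmarks.ac[0])))
    cran = slc.labels != slc.schema["background"]
    cran_extent = _extent_mm(cran[i_mid], dz)
    if cran_extent == 0:
        raise MeasurementError("midline cranial column empty on the AC slice")
    v = _first_last(vent[i])
    c = _first_last(cran[i_mid])
    y = float(landmarks.ac[1])
    num = WidthMeasurement(
        length_mm=float(extents[i]),
        axis="z",
        location=f"AC coronal, column x={slc.x_coords[i]:.1f}mm",
        endpoints=(
            (slc.x_coords[i], y, slc.z_coords[v[0]] - dz / 2),
            (slc.x_coords[i], y, slc.z_coords[v[1]] + dz / 2),
        ),
    )
    den = WidthMeasurement(
        length_mm=cran_extent,
        axis="z",
        location=f"AC coronal, midline x={slc.x_coords[i_mid]:.1f}mm",
        endpoints=(
            (slc.x_coords[i_mid], y, slc.z_coords[c[0]] - dz / 2),
            (slc.x_coords[i_mid], y, slc.z_coords[c[1]] + dz / 2),
        ),
    )
    return RatioMeasurement(z_evans_ratio(num.length_mm, den.length_mm), num, den)


def _roof_points(
    vent: np.ndarray, x_coords: np.ndarray, z_coords: np.ndarray, side: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(x, z) of the topmost ventricle pixel in every column of one side."""
    cols = np.flatnonzero(vent.any(axis=1) & side)
    tops = np.array([np.flatnonzero(vent[i])[-1] for i in cols])
    return x_coords[cols], z_coords[tops]


def callosal_angle(vol: LabeledVolume, landmarks: LandmarkSet) -> float:
    """Opening angle (degrees, measured below the intersection) between
    least-squares lines fitted to the two ventricular roofs on the PC
    coronal slice. Steep roofs (DESH) give small angles; flat collinear
    roofs give 180 degrees."""
    slc = _coronal_slice(vol, landmarks, "PC")
    vent = slc.labels == slc.schema["lateral_ventricles"]
    if not vent.any():
        raise MeasurementError("PC coronal slice misses the lateral ventricles")
    x_mid = float(landmarks.pc[0])
    fits = []
    for name, side in (
        ("left", slc.x_coords < x_mid),
        ("right", slc.x_coords > x_mid),
    ):
        x, z = _roof_points(vent, slc.x_coords, slc.z_coords, side)
        if x.size < 2:
            raise MeasurementError(
                f"fewer than 2 roof points on the {name} side of the PC slice"
            )
        slope = np.polyfit(x, z, 1)[0]
        fits.append(float(slope))
    b_left, b_right = fits
    v_left = np.array([-1.0, -b_left])
    v_right = np.array([1.0, b_right])
    cosang = np.dot(v_left, v_right) / (
        np.linalg.norm(v_left) * np.linalg.norm(v_right)
    )
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def bvr(vol: LabeledVolume, landmarks: LandmarkSet, level: str) -> RatioMeasurement:
    """Brain-per-ventricle ratio on the AC or PC coronal slice.

    Per x-column intersecting the lateral ventricles: (a) the ventricular
    z-extent and (b) the parenchymal z-extent strictly above the ventricle's
    topmost pixel. BVR = max(b) / max(a), maxima over columns.
    """
    slc = _coronal_slice(vol, landmarks, level)
    vent = slc.labels == slc.schema["lateral_ventricles"]
    if not vent.any():
        raise MeasurementError(f"{level} coronal slice misses the lateral ventricles")
    brain = slc.labels == slc.schema["brain_parenchyma"]
    dz = slc.spacing[1]
    vent_extents = _column_extents(vent, dz)
    cols = np.flatnonzero(vent.any(axis=1))
    above = np.zeros(vent.shape[0])
    for i in cols:
        top = np.flatnonzero(vent[i])[-1]
        above[i] = _extent_mm(brain[i, top + 1 :], dz)
    iv = int(np.argmax(vent_extents))
    ib = int(np.argmax(above))
    y = float(landmarks.ac[1] if level.upper() == "AC" else landmarks.pc[1])
    num = WidthMeasurement(
        length_mm=float(above[ib]),
        axis="z",
        location=f"{level} coronal, column x={slc.x_coords[ib]:.1f}mm",
        endpoints=((slc.x_coords[ib], y, np.nan), (slc.x_coords[ib], y, np.nan)),
    )
    den = WidthMeasurement(
        length_mm=float(vent_extents[iv]),
        axis="z",
        location=f"{level} coronal, column x={slc.x_coords[iv]:.1f}mm",
        endpoints=((slc.x_coords[iv], y, np.nan), (slc.x_coords[iv], y, np.nan)),
    )
    if num.length_mm == 0:
        warnings.warn(
            f"no brain parenchyma above the lateral ventricles on the {level} "
            "slice; BVR is 0",
            stacklevel=2,
        )
    return RatioMeasurement(num.length_mm / den.length_mm, num, den)


def cvr(volumes: CompartmentVolumes) -> float:
    """Convexity-SAS volume divided by total ventricular volume."""
    return cvr_ratio(volumes.convexity_sas, volumes.total_ventricles)


def measure_all(vol: LabeledVolume, landmarks: LandmarkSet) -> MorphometricIndices:
    """All six indices of one scan; a component failure propagates with the
    failing index named."""
    results: dict[str, float] = {}
    steps = (
        ("evans", lambda: float(evans_index(vol, landmarks))),
        ("z_evans", lambda: float(z_evans_index(vol, landmarks))),
        ("callosal_angle", lambda: callosal_angle(vol, landmarks)),
        ("bvr_ac", lambda: float(bvr(vol, landmarks, "AC"))),
        ("bvr_pc", lambda: float(bvr(vol, landmarks, "PC"))),
        ("cvr", lambda: cvr(compute_volumes(vol))),
    )
    for name, step in steps:
        try:
            results[name] = step()
        except (MeasurementError, ZeroDivisionError) as exc:
            raise MeasurementError(f"{name}: {exc}") from exc
    return MorphometricIndices(**results)
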