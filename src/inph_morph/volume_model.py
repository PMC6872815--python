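"""Core data model: labeled volumes, compartment schema, landmarks and coronal planes.

All world coordinates are millimetres in a fixed anatomical frame:
``x`` runs left--right, ``y`` posterior--anterior, ``z`` inferior--superior.
Volumes read from disk are reoriented into this frame (closest canonical
RAS orientation), so downstream measurements can always speak of "the x
width" or "the z length" without qualification.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "InphMorphError",
    "SchemaViolationError",
    "FormatError",
    "GeometryError",
    "EmptySliceError",
    "MeasurementError",
    "ParameterError",
    "COMPARTMENT_ROLES",
    "CSF_ROLES",
    "LabelSchema",
    "LabeledVolume",
    "LandmarkSet",
    "CoronalPlane",
    "CoronalSlice",
    "MorphometricIndices",
    "CompartmentVolumes",
    "read_labeled_volume",
    "write_labeled_volume",
    "coronal_plane_at",
    "extract_coronal_slice",
]


# ---------------------------------------------------------------------------
# Errors


class InphMorphError(Exception):
    """Base class for all package errors."""


class SchemaViolationError(InphMorphError):
    """A label code or schema does not satisfy the compartment contract."""


class FormatError(InphMorphError):
    """An input file is not in the expected format."""


class GeometryError(InphMorphError):
    """Degenerate or inconsistent spatial construction."""


class EmptySliceError(GeometryError):
    """A requested plane does not intersect the volume."""


class MeasurementError(InphMorphError):
    """A morphometric measurement cannot be made on this input."""


class ParameterError(InphMorphError):
    """Invalid simulation or analysis parameters."""


# ---------------------------------------------------------------------------
# Compartment schema

#: Non-background compartment roles, in canonical order (codes 1..7 by default).
COMPARTMENT_ROLES: tuple[str, ...] = (
    "brain_parenchyma",
    "lateral_ventricles",
    "third_ventricle",
    "fourth_ventricle",
    "convexity_sas",
    "sylvian_basal",
    "posterior_fossa_sas",
)

#: The CSF compartments (everything intracranial except parenchyma).
CSF_ROLES: tuple[str, ...] = COMPARTMENT_ROLES[1:]

VENTRICLE_ROLES: tuple[str, ...] = (
    "lateral_ventricles",
    "third_ventricle",
    "fourth_ventricle",
)
SAS_ROLES: tuple[str, ...] = ("convexity_sas", "sylvian_basal", "posterior_fossa_sas")


@dataclass(frozen=True)
class LabelSchema:
    """Mapping from compartment role to the integer code used in a label map.

    Background must be 0 and every non-background role must appear exactly
    once with a distinct positive code.
    """

    codes: Mapping[str, int] = field(
        default_factory=lambda: {
            "background": 0,
            **{role: i + 1 for i, role in enumerate(COMPARTMENT_ROLES)},
        }
    )

    def __post_init__(self) -> None:
        roles = set(self.codes)
        expected = {"background", *COMPARTMENT_ROLES}
        if roles != expected:
            missing = expected - roles
            extra = roles - expected
            raise SchemaViolationError(
                f"schema roles mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            )
        if self.codes["background"] != 0:
            raise SchemaViolationError("background code must be 0")
        values = list(self.codes.values())
        if len(set(values)) != len(values):
            raise SchemaViolationError("label codes must be distinct")
        object.__setattr__(self, "codes", dict(self.codes))

    def __getitem__(self, role: str) -> int:
        return self.codes[role]

    @property
    def all_codes(self) -> frozenset[int]:
        return frozenset(self.codes.values())

    def validate_array(self, labels: np.ndarray) -> None:
        """Raise :class:`SchemaViolationError` if unknown codes are present."""
        present = set(np.unique(labels).tolist())
        unknown = present - set(self.codes.values())
        if unknown:
            raise SchemaViolationError(
                f"label codes not in schema: {sorted(int(c) for c in unknown)}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LabelSchema":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise FormatError(f"schema file {path} must map role -> integer code")
        return cls(codes={str(k): int(v) for k, v in data.items()})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dict(self.codes), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Labeled volume


@dataclass
class LabeledVolume:
    """A 3D integer label grid with voxel geometry.

    ``labels[i, j, k]`` sits at world position ``origin + (i*dx, j*dy, k*dz)``
    with axis 0 = x (left--right), axis 1 = y (posterior--anterior) and
    axis 2 = z (inferior--superior).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    schema: LabelSchema = field(default_factory=LabelSchema)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("labels must have an integer dtype")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be 3 positive lengths, got {self.spacing}")
        self.schema.validate_array(self.labels)

    # -- geometry -----------------------------------------------------------

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis."""
        n = self.labels.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    # -- masks --------------------------------------------------------------

    def mask(self, role: str) -> np.ndarray:
        return self.labels == self.schema[role]

    @property
    def intracranial_mask(self) -> np.ndarray:
        return self.labels != self.schema["background"]


def read_labeled_volume(path: str | Path, schema: LabelSchema | None = None) -> LabeledVolume:
    """Read a NIfTI label map, reorienting to the canonical x/y/z frame.

    Non-integer voxel data raise :class:`FormatError`; codes outside the
    schema raise :class:`SchemaViolationError` naming the offending codes.
    """
    schema = schema or LabelSchema()
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise FormatError(f"{path}: label volume contains non-integer values")
        data = rounded.astype(np.int16)
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    return LabeledVolume(
        labels=data, spacing=tuple(zooms), origin=tuple(origin), schema=schema
    )


def write_labeled_volume(vol: LabeledVolume, path: str | Path) -> None:
    """Write a label map as NIfTI (int16, diagonal affine)."""
    img = nib.Nifti1Image(vol.labels.astype(np.int16), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Landmarks and coronal planes


@dataclass(frozen=True)
class LandmarkSet:
    """AC/PC landmark world coordinates (mm).

    The anterior commissure must lie anterior to (larger y than) the
    posterior commissure.
    """

    ac: np.ndarray
    pc: np.ndarray

    def __post_init__(self) -> None:
        ac = np.asarray(self.ac, dtype=float)
        pc = np.asarray(self.pc, dtype=float)
        if ac.shape != (3,) or pc.shape != (3,):
            raise GeometryError("landmarks must be 3-vectors")
        if np.allclose(ac, pc):
            raise GeometryError("AC and PC coincide")
        if ac[1] <= pc[1]:
            raise GeometryError("AC must be anterior to PC (larger y)")
        object.__setattr__(self, "ac", ac)
        object.__setattr__(self, "pc", pc)

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        with open(path) as fh:
            data = json.load(fh)
        try:
            return cls(ac=np.array(data["ac"], float), pc=np.array(data["pc"], float))
        except KeyError as exc:
            raise FormatError(f"{path}: landmark JSON needs 'ac' and 'pc'") from exc

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"ac": self.ac.tolist(), "pc": self.pc.tolist()}, fh, indent=2)


@dataclass(frozen=True)
class CoronalPlane:
    """A plane through a landmark, normal to the AC--PC line (unit normal)."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        point = np.asarray(self.point, dtype=float)
        normal = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(normal)
        if norm == 0:
            raise GeometryError("plane normal is zero")
        object.__setattr__(self, "point", point)
        object.__setattr__(self, "normal", normal / norm)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of world points; positive on the anterior side."""
        return np.asarray(points) @ self.normal - self.point @ self.normal


def coronal_plane_at(landmarks: LandmarkSet, level: str) -> CoronalPlane:
    """The coronal reference plane at the AC or PC.

    The plane passes through the chosen landmark with normal along the
    AC--PC direction (pointing anterior).
    """
    level = level.upper()
    if level not in {"AC", "PC"}:
        raise ParameterError(f"level must be 'AC' or 'PC', got {level!r}")
    direction = landmarks.ac - landmarks.pc
    point = landmarks.ac if level == "AC" else landmarks.pc
    return CoronalPlane(point=point, normal=direction)


# ---------------------------------------------------------------------------
# Coronal slice extraction


@dataclass
class CoronalSlice:
    """A 2D label grid on a coronal reference plane.

    ``labels[i, k]`` indexes x (left--right) and z (inferior--superior);
    ``x_coords``/``z_coords`` give world mm of the pixel centres.
    """

    labels: np.ndarray
    x_coords: np.ndarray
    z_coords: np.ndarray
    spacing: tuple[float, float]
    plane: CoronalPlane
    schema: LabelSchema


def extract_coronal_slice(
    vol: LabeledVolume,
    plane: CoronalPlane,
    thickness_mm: float | None = None,
) -> CoronalSlice:
    """Resample the label content of a coronal slab onto an (x, z) grid.

    Labels are sampled nearest-neighbour so no invalid codes can appear.
    The slab covers signed distances within ``thickness_mm / 2`` of the
    plane (default: one y-voxel); for slabs thicker than one voxel each
    (x, z) pixel takes the most frequent label along the slab, ties going
    to the sample closest to the plane.
    """
    if thickness_mm is None:
        thickness_mm = vol.spacing[1]
    if thickness_mm <= 0:
        raise ParameterError("thickness_mm must be positive")
    n = plane.normal
    if abs(n[1]) < 1e-9:
        raise GeometryError("coronal plane normal has no y component")

    xs = vol.axis_coords(0)
    zs = vol.axis_coords(2)
    x2, z2 = np.meshgrid(xs, zs, indexing="ij")

    # offsets along the normal covering the slab at sub-voxel steps
    step = min(vol.spacing)
    n_off = max(1, int(np.ceil(thickness_mm / step)))
    offsets = (np.arange(n_off) - (n_off - 1) / 2) * (thickness_mm / n_off)
    offsets = offsets[np.argsort(np.abs(offsets), kind="stable")]  # nearest first

    ny = vol.labels.shape[1]
    bg = vol.schema["background"]
    samples = np.full((len(offsets), *x2.shape), bg, dtype=vol.labels.dtype)
    any_inside = np.zeros(x2.shape, dtype=bool)
    ix = np.arange(len(xs))[:, None] * np.ones(len(zs), dtype=int)[None, :]
    kz = np.ones(len(xs), dtype=int)[:, None] * np.arange(len(zs))[None, :]
    for m, d in enumerate(offsets):
        # plane point offset by d along the normal; solve n.(p - p0) = d for y
        px = x2 - d * n[0] - plane.point[0]
        pz = z2 - d * n[2] - plane.point[2]
        y = plane.point[1] + (d * (n @ n) - n[0] * px - n[2] * pz) / n[1]
        j = np.rint((y - vol.origin[1]) / vol.spacing[1]).astype(int)
        inside = (j >= 0) & (j < ny)
        any_inside |= inside
        jj = np.clip(j, 0, ny - 1)
        vals = vol.labels[ix, jj, kz]
        samples[m] = np.where(inside, vals, bg)

    if not any_inside.any():
        raise EmptySliceError("coronal plane does not intersect the volume")

    if len(offsets) == 1:
        out = samples[0]
    else:
        codes = sorted(vol.schema.all_codes)
        counts = np.stack([(samples == c).sum(axis=0) for c in codes])
        # majority label; ties resolved toward the sample nearest the plane
        best = np.argmax(counts, axis=0)
        out = np.array(codes, dtype=vol.labels.dtype)[best]
        top = counts.max(axis=0)
        tied = (counts == top[None]).sum(axis=0) > 1
        if tied.any():
            out[tied] = samples[0][tied]

    return CoronalSlice(
        labels=out,
        x_coords=xs,
        z_coords=zs,
        spacing=(vol.spacing[0], vol.spacing[2]),
        plane=plane,
        schema=vol.schema,
    )


# ---------------------------------------------------------------------------
# Measurement containers


@dataclass(frozen=True)
class MorphometricIndices:
    """The six iNPH-specific indices of one scan.

    Ratios are dimensionless; ``callosal_angle`` is in degrees.
    """

    evans: float
    z_evans: float
    callosal_angle: float
    bvr_ac: float
    bvr_pc: float
    cvr: float

    def __post_init__(self) -> None:
        for name in ("evans", "z_evans"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise MeasurementError(f"{name}={v} outside (0, 1)")
        if not 0 < self.callosal_angle < 180:
            raise MeasurementError(f"callosal_angle={self.callosal_angle} outside (0, 180)")
        for name in ("bvr_ac", "bvr_pc", "cvr"):
            v = getattr(self, name)
            if v < 0:
                raise MeasurementError(f"{name}={v} negative")

    def as_dict(self) -> dict[str, float]:
        return {
            "evans": self.evans,
            "z_evans": self.z_evans,
            "callosal_angle": self.callosal_angle,
            "bvr_ac": self.bvr_ac,
            "bvr_pc": self.bvr_pc,
            "cvr": self.cvr,
        }

    def report(self) -> dict[str, float]:
        """Values at reporting precision: 3 decimals for ratios, whole degrees."""
        d = {k: round(v, 3) for k, v in self.as_dict().items()}
        d["callosal_angle"] = round(self.callosal_angle)
        return d



@dataclass(frozen=True)
class CompartmentVolumes:
    """Per-compartment volumes in mL with derived totals and volume ratios.

    The derived totals are computed, never stored, so the conservation
    identities (TIV = brain + CSF etc.) hold by construction.
    """

    brain_parenchyma: float
    lateral_ventricles: float
    third_ventricle: float
    fourth_ventricle: float
    convexity_sas: float
    sylvian_basal: float
    posterior_fossa_sas: float

    def __post_init__(self) -> None:
        for role in COMPARTMENT_ROLES:
            v = getattr(self, role)
            if v < 0:
                raise ParameterError(f"{role} volume is negative: {v}")
            if v == 0:
                warnings.warn(f"compartment {role} has zero volume", stacklevel=3)

    @property
    def total_ventricles(self) -> float:
        return self.lateral_ventricles + self.third_ventricle + self.fourth_ventricle

    @property
    def total_sas(self) -> float:
        return self.convexity_sas + self.sylvian_basal + self.posterior_fossa_sas

    @property
    def total_csf(self) -> float:
        return self.total_ventricles + self.total_sas

    @property
    def tiv(self) -> float:
        return self.brain_parenchyma + self.total_csf

    def volume(self, role: str) -> float:
        if role in COMPARTMENT_ROLES:
            return float(getattr(self, role))
        derived = {
            "total_ventricles": self.total_ventricles,
            "total_sas": self.total_sas,
            "total_csf": self.total_csf,
            "tiv": self.tiv,
        }
        if role in derived:
            return derived[role]
        raise KeyError(f"unknown compartment role {role!r}")

    def vr(self, role: str) -> float:
        """Volume ratio: compartment volume / total intracranial volume."""
        tiv = self.tiv
        if tiv == 0:
            raise ZeroDivisionError("TIV is zero; volume ratios undefined")
        return self.volume(role) / tiv

    def as_dict(self) -> dict[str, float]:
        d = {role: float(getattr(self, role)) for role in COMPARTMENT_ROLES}
        d.update(
            total_ventricles=self.total_ventricles,
            total_sas=self.total_sas,
            total_csf=self.total_csf,
            tiv=self.tiv,
        )
        return d

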