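"""Parametric DESH phantom: synthetic labeled brain volumes with analytic truth.

The phantom is built from ellipsoids so that every compartment volume and
every morphometric index has a reference value computable from the
continuous geometry, independent of voxelization:

* cranium and brain are concentric-axis ellipsoids; the gap between them
  is the subarachnoid space (SAS), partitioned into convexity, Sylvian/
  basal and posterior-fossa bands by two horizontal planes (a stand-in for
  the tentorium / Sylvian landmarks of a manual partition);
* the two lateral ventricles are mirrored ellipsoids cut by a flat medial
  wall (the septum) and by a tilted planar roof at ``theta`` degrees from
  vertical, so the callosal angle is ``2 * theta`` by construction;
* third and fourth ventricles are small midline ellipsoids.

Reference volumes use closed-form ellipsoid and cap formulas; the doubly
cut lateral ventricles use closed-form cross-section areas integrated to
high precision. Reference index extents are closed-form chord functions
maximized on dense grids. None of these depend on the voxel grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import simpson

from .volume_model import (
    CompartmentVolumes,
    GeometryError,
    LabelSchema,
    LabeledVolume,
    LandmarkSet,
    MorphometricIndices,
    ParameterError,
)

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "phantom_pair"]


def _ellipsoid_volume(semiaxes: Sequence[float]) -> float:
    a, b, c = semiaxes
    return 4.0 / 3.0 * np.pi * a * b * c


def _volume_below(semiaxes: Sequence[float], center_z: float, z: float) -> float:
    """Volume of the ellipsoid part with height <= z (cap formula)."""
    c = semiaxes[2]
    u = np.clip((z - center_z) / c, -1.0, 1.0)
    return _ellipsoid_volume(semiaxes) * (2.0 + 3.0 * u - u**3) / 4.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, landmark and rendering parameters of one DESH phantom.

    All lengths in mm, angles in degrees. The cranium is centred at the
    world origin. ``roof_theta_deg`` is the tilt of each lateral-ventricle
    roof from vertical, so the callosal angle equals ``2 * roof_theta_deg``.
    ``roof_apex_z`` is the roof height at the ventricle-centre column.
    """

    cranium_semiaxes: tuple[float, float, float] = (70.0, 85.0, 62.0)
    brain_semiaxes: tuple[float, float, float] = (64.0, 79.0, 57.0)
    brain_center_z: float = -1.0

    ventricle_x_offset: float = 15.0
    ventricle_center_y: float = -8.0
    ventricle_center_z: float = 8.0
    ventricle_semiaxes: tuple[float, float, float] = (8.0, 42.0, 48.0)
    medial_wall_x: float = 8.0
    roof_theta_deg: float = 31.5
    roof_apex_z: float = 15.0

    third_center: tuple[float, float, float] = (0.0, -10.0, 0.0)
    third_semiaxes: tuple[float, float, float] = (3.5, 25.0, 14.0)
    fourth_center: tuple[float, float, float] = (0.0, -42.0, -34.0)
    fourth_semiaxes: tuple[float, float, float] = (7.0, 11.0, 11.0)

    z_convexity: float = 46.5
    z_posterior_fossa: float = -32.0

    ac: tuple[float, float, float] = (0.0, 12.0, 0.0)
    pc: tuple[float, float, float] = (0.0, -12.0, 0.0)

    spacing: float = 1.0
    noise_sigma: float = 10.0
    brain_intensity: float = 100.0
    csf_intensity: float = 300.0
    seed: int = 0

    # -- construction -------------------------------------------------------

    @classmethod
    def randomized(cls, rng: np.random.Generator, **overrides) -> "PhantomSpec":
        """A random DESH-like spec within physiologic ranges.

        Sizes jitter around the defaults (head axes +/- ~5%, ventricle axes
        +/- ~8%); the roof tilt spans callosal angles of 56-80 degrees,
        covering the reported iNPH spread. The roof apex is placed inside
        its feasible band so the planar-roof construction always holds.
        """
        last_error: Exception | None = None
        for _ in range(20):
            try:
                return cls._randomized_draw(rng, **overrides)
            except GeometryError as exc:  # infeasible corner of the ranges
                last_error = exc
        raise GeometryError(f"could not draw a feasible spec: {last_error}")

    @classmethod
    def _randomized_draw(cls, rng: np.random.Generator, **overrides) -> "PhantomSpec":
        u = rng.uniform
        cran = (u(66, 74), u(80, 90), u(58, 66))
        brain = (cran[0] - u(5, 7), cran[1] - u(5, 7), cran[2] - u(4, 6))
        x_off = u(14, 16)
        a_v, b_v, c_v = u(7.5, 9.0), u(38, 46), u(44, 52)
        z_v = u(6, 10)
        wall = x_off - a_v + u(1.0, 2.0)
        theta = u(28, 40)
        m = 1.0 / np.tan(np.radians(theta))
        # feasible roof band at the PC slice (see validate)
        y_pc = -u(10, 14)
        y_v = u(-10, -6)
        q = (y_pc - y_v) / b_v
        s = np.sqrt(1 - q**2)
        dw = x_off - wall
        bound = z_v + c_v * s * np.sqrt(1 - (dw / (a_v * s)) ** 2) - m * dw
        # keep the roof below the ventricle-centre height at the AC slice's
        # outer tip, so the tip is truncated by the roof rather than ending
        # in a vertical-tangent elliptical sliver (regular voxel convergence)
        y_ac = u(10, 14)
        s_ac = np.sqrt(1 - ((y_ac - y_v) / b_v) ** 2)
        bound = min(bound, z_v + 0.9 * m * a_v * s_ac)
        spec = cls(
            cranium_semiaxes=cran,
            brain_semiaxes=brain,
            brain_center_z=u(-2, 0),
            ventricle_x_offset=x_off,
            ventricle_center_y=y_v,
            ventricle_center_z=z_v,
            ventricle_semiaxes=(a_v, b_v, c_v),
            medial_wall_x=wall,
            roof_theta_deg=theta,
            roof_apex_z=z_v + 0.5 * (bound - z_v),
            third_semiaxes=(u(3, 4), u(22, 28), u(12, 16)),
            fourth_center=(0.0, u(-42, -38), u(-32, -28)),
            fourth_semiaxes=(u(6, 7), u(10, 11), u(9, 10)),
            z_convexity=(brain[2] + u(-2, 0)) * u(0.80, 0.86),
            z_posterior_fossa=u(-34, -30),
            ac=(0.0, y_ac, 0.0),
            pc=(0.0, y_pc, 0.0),
            noise_sigma=0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
            **overrides,
        )
        spec.validate()
        return spec

    # -- derived geometry ---------------------------------------------------

    @property
    def roof_slope(self) -> float:
        """Roof line slope dz/dx toward the midline: cot(theta)."""
        return 1.0 / np.tan(np.radians(self.roof_theta_deg))

    def landmarks(self) -> LandmarkSet:
        return LandmarkSet(ac=np.array(self.ac), pc=np.array(self.pc))

    def ventricle_cross_section(self, y: float) -> tuple[float, float]:
        """Effective (x, z) semi-axes of a lateral ventricle cut at plane y."""
        a, b, c = self.ventricle_semiaxes
        q = (y - self.ventricle_center_y) / b
        if abs(q) >= 1:
            raise GeometryError(f"plane y={y} misses the lateral ventricles")
        s = float(np.sqrt(1 - q**2))
        return a * s, c * s

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.spacing <= 0:
            raise ParameterError("spacing must be positive")
        if not 0 < self.roof_theta_deg < 90:
            raise ParameterError("roof_theta_deg must be in (0, 90)")
        for name in ("cranium_semiaxes", "brain_semiaxes", "ventricle_semiaxes",
                     "third_semiaxes", "fourth_semiaxes"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ParameterError(f"{name} must be positive")
        if self.z_posterior_fossa >= self.z_convexity:
            raise ParameterError("z_posterior_fossa must lie below z_convexity")
        if self.ac[1] <= self.pc[1]:
            raise GeometryError("AC must be anterior to PC")
        if self.ac[0] != self.pc[0] or self.ac[2] != self.pc[2]:
            raise GeometryError(
                "phantom landmarks must share x and z (AC-PC along y) so the "
                "analytic truth holds"
            )
        if not 0 < self.medial_wall_x < self.ventricle_x_offset:
            raise GeometryError("medial wall must sit between midline and ventricle centre")
        a_v = self.ventricle_semiaxes[0]
        if self.ventricle_x_offset - self.medial_wall_x >= a_v:
            raise GeometryError(
                "medial wall lies outside the ventricle ellipsoid; the inner "
                "columns would have non-planar roofs"
            )
        # the AC slice must intersect the lateral ventricles (z-Evans, BVR-AC)
        self.ventricle_cross_section(self.ac[1])
        # on the PC slice, where the callosal angle is fitted, the roof plane
        # must lie at or below the ellipse top on every surviving column so
        # every column's topmost point is planar (exact 2-theta construction)
        dw = self.ventricle_x_offset - self.medial_wall_x
        m = self.roof_slope
        ax, cz = self.ventricle_cross_section(self.pc[1])
        if dw >= ax:
            raise GeometryError("medial wall outside the ventricle cross-section at PC")
        top_at_wall = self.ventricle_center_z + cz * np.sqrt(1 - (dw / ax) ** 2)
        if self.roof_apex_z + m * dw > top_at_wall + 1e-9:
            raise GeometryError(
                "roof plane rises above the ventricle surface at the PC slice; "
                "lower roof_apex_z or move the medial wall outward"
            )
        self._check_containment()

    def _check_containment(self, step: float = 2.5) -> None:
        """Coarse-grid check that ventricles lie strictly inside the brain and
        the brain strictly inside the cranium."""
        A = self.cranium_semiaxes
        xs = np.arange(-A[0], A[0] + step, step)
        ys = np.arange(-A[1], A[1] + step, step)
        zs = np.arange(-A[2], A[2] + step, step)
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij", sparse=True)
        brain = self._inside_brain(X, Y, Z)
        cran = self._inside_cranium(X, Y, Z)
        if np.any(brain & ~cran):
            raise GeometryError("brain is not strictly inside the cranium")
        vent = (
            self._inside_lateral(X, Y, Z)
            | self._inside_ellipsoid(X, Y, Z, self.third_center, self.third_semiaxes)
            | self._inside_ellipsoid(X, Y, Z, self.fourth_center, self.fourth_semiaxes)
        )
        if np.any(vent & ~brain):
            raise GeometryError("ventricles are not strictly inside the brain")

    # -- membership predicates (vectorized over world coordinates) ----------

    @staticmethod
    def _inside_ellipsoid(X, Y, Z, center, semiaxes):
        return (
            ((X - center[0]) / semiaxes[0]) ** 2
            + ((Y - center[1]) / semiaxes[1]) ** 2
            + ((Z - center[2]) / semiaxes[2]) ** 2
        ) <= 1.0

    def _inside_cranium(self, X, Y, Z):
        return self._inside_ellipsoid(X, Y, Z, (0, 0, 0), self.cranium_semiaxes)

    def _inside_brain(self, X, Y, Z):
        return self._inside_ellipsoid(
            X, Y, Z, (0, 0, self.brain_center_z), self.brain_semiaxes
        )

    def _inside_lateral(self, X, Y, Z):
        m = self.roof_slope
        x0 = self.ventricle_x_offset
        left = self._inside_ellipsoid(
            X, Y, Z, (-x0, self.ventricle_center_y, self.ventricle_center_z),
            self.ventricle_semiaxes,
        ) & (X <= -self.medial_wall_x) & (Z <= self.roof_apex_z + m * (X + x0))
        right = self._inside_ellipsoid(
            X, Y, Z, (x0, self.ventricle_center_y, self.ventricle_center_z),
            self.ventricle_semiaxes,
        ) & (X >= self.medial_wall_x) & (Z <= self.roof_apex_z - m * (X - x0))
        return left | right

    # -- analytic truth -----------------------------------------------------

    def lateral_ventricle_volume(self) -> float:
        """Volume of both lateral ventricles (mm^3).

        Per x-column the cross-section is an ellipse in (y, z) truncated
        below the roof line; its area is closed form, integrated over x.
        """
        a, b, c = self.ventricle_semiaxes
        x0, zv = self.ventricle_x_offset, self.ventricle_center_z
        m = self.roof_slope
        # left ventricle spans x in [-x0 - a, -wall]; integrate over the offset
        lo, hi = -a, x0 - self.medial_wall_x  # delta = x - (-x0), delta < 0 outward
        deltas = np.linspace(lo, hi, 4001)
        s = np.sqrt(np.clip(1 - (deltas / a) ** 2, 0.0, None))
        by, cz = b * s, c * s
        roof = self.roof_apex_z + m * deltas  # z limit at each column
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.clip((roof - zv) / np.where(cz > 0, cz, np.inf), -1.0, 1.0)
        area = by * cz * (np.pi / 2 + np.arcsin(t) + t * np.sqrt(1 - t**2))
        return 2.0 * float(simpson(area, x=deltas))

    def analytic_volumes(self) -> CompartmentVolumes:
        """Closed-form compartment volumes in mL."""
        v_cran = _ellipsoid_volume(self.cranium_semiaxes)
        v_brain_ell = _ellipsoid_volume(self.brain_semiaxes)
        v_lat = self.lateral_ventricle_volume()
        v_third = _ellipsoid_volume(self.third_semiaxes)
        v_fourth = _ellipsoid_volume(self.fourth_semiaxes)

        def shell_below(z: float) -> float:
            return _volume_below(self.cranium_semiaxes, 0.0, z) - _volume_below(
                self.brain_semiaxes, self.brain_center_z, z
            )

        shell = v_cran - v_brain_ell
        pf = shell_below(self.z_posterior_fossa)
        conv = shell - shell_below(self.z_convexity)
        sylv = shell - pf - conv
        return CompartmentVolumes(
            brain_parenchyma=(v_brain_ell - v_lat - v_third - v_fourth) / 1000.0,
            lateral_ventricles=v_lat / 1000.0,
            third_ventricle=v_third / 1000.0,
            fourth_ventricle=v_fourth / 1000.0,
            convexity_sas=conv / 1000.0,
            sylvian_basal=sylv / 1000.0,
            posterior_fossa_sas=pf / 1000.0,
        )

    # closed-form chord helpers on a coronal slice at height y

    def _vent_top_bottom(self, y: float, deltas: np.ndarray):
        """Roof-limited top and ellipse bottom of the left ventricle at column
        offsets ``deltas`` (x - centre) on the coronal slice at y."""
        ax, cz = self.ventricle_cross_section(y)
        zv, m = self.ventricle_center_z, self.roof_slope
        half = cz * np.sqrt(np.clip(1 - (deltas / ax) ** 2, 0.0, None))
        inside = np.abs(deltas) <= ax
        top = np.minimum(zv + half, self.roof_apex_z + m * deltas)
        bottom = zv - half
        return np.where(inside & (top >= bottom), top, np.nan), np.where(
            inside & (top >= bottom), bottom, np.nan
        )

    def _column_grid(self, y: float, n: int = 8001) -> np.ndarray:
        ax, _ = self.ventricle_cross_section(y)
        hi = self.ventricle_x_offset - self.medial_wall_x  # innermost allowed delta
        return np.linspace(-ax, min(hi, ax), n)

    def analytic_evans(self) -> float:
        """Frontal-horn width over cranial width on the widest axial slice."""
        a, b, c = self.ventricle_semiaxes
        x0, zv = self.ventricle_x_offset, self.ventricle_center_z
        yv = self.ventricle_center_y
        m = self.roof_slope
        q = max(0.0, (self.ac[1] - yv) / b)
        if q >= 1:
            raise GeometryError("frontal horns vanish anterior to the AC plane")
        ax_eff, cz_eff = a * np.sqrt(1 - q**2), c * np.sqrt(1 - q**2)
        zs = np.linspace(zv - cz_eff, zv + cz_eff, 8001)
        half = ax_eff * np.sqrt(np.clip(1 - ((zs - zv) / cz_eff) ** 2, 0.0, None))
        outer_ell = -x0 - half  # leftmost ellipse bound per height
        outer_roof = -x0 + (zs - self.roof_apex_z) / m  # roof demands x >= this
        outer = np.maximum(outer_ell, outer_roof)
        valid = outer <= -self.medial_wall_x
        if not valid.any():
            raise GeometryError("frontal horn empty on every axial slice")
        widths = np.where(valid, -2.0 * outer, -np.inf)
        k = int(np.argmax(widths))
        z_star = zs[k]
        A = self.cranium_semiaxes
        cran_w = 2.0 * A[0] * np.sqrt(max(0.0, 1 - (z_star / A[2]) ** 2))
        return float(widths[k] / cran_w)

    def analytic_z_evans(self) -> float:
        """Max ventricular z-extent over midline cranial z-extent on the AC slice."""
        y = self.ac[1]
        deltas = self._column_grid(y)
        top, bottom = self._vent_top_bottom(y, deltas)
        extent = np.nanmax(top - bottom)
        A = self.cranium_semiaxes
        w = np.sqrt(max(0.0, 1 - (y / A[1]) ** 2))
        x_mid = self.ac[0]
        cran = 2.0 * A[2] * w * np.sqrt(max(0.0, 1 - (x_mid / (A[0] * w)) ** 2))
        return float(extent / cran)

    def analytic_callosal_angle(self) -> float:
        return 2.0 * self.roof_theta_deg

    def analytic_bvr(self, level: str) -> float:
        """Max brain height above the ventricle roof over max ventricular
        height, per column, on the AC or PC coronal slice."""
        y = self.ac[1] if level.upper() == "AC" else self.pc[1]
        deltas = self._column_grid(y)
        top, bottom = self._vent_top_bottom(y, deltas)
        vent_extent = np.nanmax(top - bottom)
        B = self.brain_semiaxes
        wb = np.sqrt(max(0.0, 1 - (y / B[1]) ** 2))
        bx, bz = B[0] * wb, B[2] * wb
        x = deltas - self.ventricle_x_offset  # left ventricle world x
        brain_top = self.brain_center_z + bz * np.sqrt(
            np.clip(1 - (x / bx) ** 2, 0.0, None)
        )
        above = brain_top - top
        return float(np.nanmax(above) / vent_extent)

    def analytic_indices(self) -> MorphometricIndices:
        vols = self.analytic_volumes()
        return MorphometricIndices(
            evans=self.analytic_evans(),
            z_evans=self.analytic_z_evans(),
            callosal_angle=self.analytic_callosal_angle(),
            bvr_ac=self.analytic_bvr("AC"),
            bvr_pc=self.analytic_bvr("PC"),
            cvr=vols.convexity_sas / vols.total_ventricles,
        )


@dataclass
class PhantomTruth:
    """A voxelized phantom bundled with its analytic reference values."""

    spec: PhantomSpec
    volumes: CompartmentVolumes
    indices: MorphometricIndices
    labeled: LabeledVolume
    intensity: np.ndarray
    landmarks: LandmarkSet = field(init=False)

    def __post_init__(self) -> None:
        self.landmarks = self.spec.landmarks()


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Voxelize a phantom spec and attach its analytic truth.

    The intensity volume renders parenchyma at ``brain_intensity`` and all
    CSF at ``csf_intensity`` (T2-like, CSF hyperintense) with Gaussian noise
    of SD ``noise_sigma`` inside the intracranial mask only.
    """
    spec.validate()
    s = float(spec.spacing)
    A = spec.cranium_semiaxes
    margin = 2 * s
    origin = tuple(-(a + margin) for a in A)
    shape = tuple(int(np.ceil(2 * (a + margin) / s)) + 1 for a in A)
    xs = origin[0] + s * np.arange(shape[0])
    ys = origin[1] + s * np.arange(shape[1])
    zs = origin[2] + s * np.arange(shape[2])
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij", sparse=True)

    schema = LabelSchema()
    labels = np.zeros(shape, dtype=np.int16)
    cran = spec._inside_cranium(X, Y, Z)
    brain = spec._inside_brain(X, Y, Z)
    shell = cran & ~brain
    Zb = np.broadcast_to(Z, shape)
    labels[shell & (Zb < spec.z_posterior_fossa)] = schema["posterior_fossa_sas"]
    labels[shell & (Zb >= spec.z_posterior_fossa) & (Zb < spec.z_convexity)] = schema[
        "sylvian_basal"
    ]
    labels[shell & (Zb >= spec.z_convexity)] = schema["convexity_sas"]
    labels[brain] = schema["brain_parenchyma"]
    labels[
        brain & spec._inside_ellipsoid(X, Y, Z, spec.fourth_center, spec.fourth_semiaxes)
    ] = schema["fourth_ventricle"]
    labels[
        brain & spec._inside_ellipsoid(X, Y, Z, spec.third_center, spec.third_semiaxes)
    ] = schema["third_ventricle"]
    labels[brain & spec._inside_lateral(X, Y, Z)] = schema["lateral_ventricles"]

    vol = LabeledVolume(labels=labels, spacing=(s, s, s), origin=origin, schema=schema)

    intensity = np.zeros(shape, dtype=float)
    intensity[labels == schema["brain_parenchyma"]] = spec.brain_intensity
    csf = cran & (labels != schema["brain_parenchyma"]) & (labels != 0)
    intensity[csf] = spec.csf_intensity
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sigma, size=shape)
        intensity[cran] += noise[cran]

    return PhantomTruth(
        spec=spec,
        volumes=spec.analytic_volumes(),
        indices=spec.analytic_indices(),
        labeled=vol,
        intensity=intensity,
    )


def recovery_errors(truth: PhantomTruth) -> dict[str, dict[str, float]]:
    """Measure a voxelized phantom and compare against its analytic truth.

    Returns per quantity: analytic and measured values, absolute error and
    the resolution-derived tolerance. Tolerances reflect the voxel grid:
    each caliper length is trusted to two voxels, so a ratio index gets
    2*dx/numerator + 2*dx/denominator (floor 2%); the angle gets 2 degrees;
    volumes get 2% plus a voxel layer on the planar cut faces (~2 mL per mm
    of spacing).
    """
    from . import morphometry as mm
    from .segmentation_volumetrics import compute_volumes

    vol, lm = truth.labeled, truth.landmarks
    dx = float(min(vol.spacing))
    out: dict[str, dict[str, float]] = {}

    def ratio_entry(name: str, meas: "mm.RatioMeasurement", analytic: float):
        per_length = 2.0 * dx / meas.numerator.length_mm + 2.0 * dx / meas.denominator.length_mm
        tol = max(0.02, per_length) * analytic
        out[name] = {
            "analytic": analytic,
            "measured": meas.value,
            "abs_error": abs(meas.value - analytic),
            "tolerance": tol,
        }

    ana = truth.indices
    ratio_entry("evans", mm.evans_index(vol, lm), ana.evans)
    ratio_entry("z_evans", mm.z_evans_index(vol, lm), ana.z_evans)
    ratio_entry("bvr_ac", mm.bvr(vol, lm, "AC"), ana.bvr_ac)
    ratio_entry("bvr_pc", mm.bvr(vol, lm, "PC"), ana.bvr_pc)
    ca = mm.callosal_angle(vol, lm)
    out["callosal_angle"] = {
        "analytic": ana.callosal_angle,
        "measured": ca,
        "abs_error": abs(ca - ana.callosal_angle),
        "tolerance": 2.0,
    }

    meas_v = compute_volumes(vol)
    ana_v = truth.volumes
    for role in ana_v.as_dict():
        a, m_ = ana_v.volume(role), meas_v.volume(role)
        out[f"volume:{role}"] = {
            "analytic": a,
            "measured": m_,
            "abs_error": abs(m_ - a),
            "tolerance": 0.02 * a + 2.0 * dx,
        }
    conv_rel = out["volume:convexity_sas"]["tolerance"] / ana_v.convexity_sas
    vent_rel = out["volume:total_ventricles"]["tolerance"] / ana_v.total_ventricles
    cvr_meas = meas_v.convexity_sas / meas_v.total_ventricles
    out["cvr"] = {
        "analytic": ana.cvr,
        "measured": cvr_meas,
        "abs_error": abs(cvr_meas - ana.cvr),
        "tolerance": (conv_rel + vent_rel) * ana.cvr,
    }
    return out


def phantom_pair(spec: PhantomSpec, shrink: float) -> tuple[PhantomTruth, PhantomTruth]:
    """A pre/post-shunt phantom pair.

    The second phantom has all ventricle z-semi-axes scaled by
    ``1 - shrink``; the freed volume is reassigned to the convexity SAS by
    lowering the brain's top surface (its bottom stays fixed), so brain
    parenchyma volume and total CSF are unchanged across the pair while the
    convexity-per-ventricle ratio strictly increases.
    """
    if not 0 <= shrink < 1:
        raise ParameterError("shrink must be in [0, 1)")
    before = generate_phantom(spec)
    if shrink == 0:
        return before, generate_phantom(spec)

    f = 1.0 - shrink
    av, bv, cv = spec.ventricle_semiaxes
    after_spec = replace(
        spec,
        ventricle_semiaxes=(av, bv, cv * f),
        roof_apex_z=spec.ventricle_center_z
        + (spec.roof_apex_z - spec.ventricle_center_z) * f,
        third_semiaxes=(
            spec.third_semiaxes[0],
            spec.third_semiaxes[1],
            spec.third_semiaxes[2] * f,
        ),
        fourth_semiaxes=(
            spec.fourth_semiaxes[0],
            spec.fourth_semiaxes[1],
            spec.fourth_semiaxes[2] * f,
        ),
    )
    freed = (
        before.volumes.total_ventricles
        - after_spec.analytic_volumes().total_ventricles
    ) * 1000.0  # mm^3
    B = spec.brain_semiaxes
    dc = freed / (4.0 / 3.0 * np.pi * B[0] * B[1])
    after_spec = replace(
        after_spec,
        brain_semiaxes=(B[0], B[1], B[2] - dc),
        brain_center_z=spec.brain_center_z - dc,
    )
    after = generate_phantom(after_spec)
    return before, after
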