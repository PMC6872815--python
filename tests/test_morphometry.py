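"""The six iNPH indices on toy grids, with exhaustive brute-force oracles."""

import numpy as np
import pytest

from inph_morph import (
    CompartmentVolumes,
    MeasurementError,
    bvr,
    callosal_angle,
    cvr,
    evans_index,
    frontal_horn_mask,
    measure_all,
    z_evans_index,
)
from inph_morph.phantom import PhantomSpec, generate_phantom

from conftest import SCHEMA, centered_landmarks, make_volume

BRAIN = SCHEMA["brain_parenchyma"]
LAT = SCHEMA["lateral_ventricles"]


# ---------------------------------------------------------------------------
# Brute-force oracles: exhaustive per-voxel searches, independent of the
# vectorized implementation. Valid for axis-aligned landmarks.


def brute_evans(vol, lm):
    xs, ys, zs = (vol.axis_coords(i) for i in range(3))
    best = (-1.0, None)
    for k in range(len(zs)):
        horn_i = [
            i
            for i in range(len(xs))
            for j in range(len(ys))
            if vol.labels[i, j, k] == LAT and ys[j] > lm.ac[1]
        ]
        if not horn_i:
            continue
        width = (max(horn_i) - min(horn_i) + 1) * vol.spacing[0]
        if width > best[0]:
            best = (width, k)
    width, k = best
    cran_i = [
        i
        for i in range(len(xs))
        for j in range(len(ys))
        if vol.labels[i, j, k] != 0
    ]
    cran = (max(cran_i) - min(cran_i) + 1) * vol.spacing[0]
    return width / cran


def _slice_at(vol, y):
    j = int(np.argmin(np.abs(vol.axis_coords(1) - y)))
    return vol.labels[:, j, :]


def brute_z_evans(vol, lm):
    sl = _slice_at(vol, lm.ac[1])
    dz = vol.spacing[2]
    best = 0.0
    for i in range(sl.shape[0]):
        ks = np.flatnonzero(sl[i] == LAT)
        if ks.size:
            best = max(best, (ks[-1] - ks[0] + 1) * dz)
    i_mid = int(np.argmin(np.abs(vol.axis_coords(0) - lm.ac[0])))
    ks = np.flatnonzero(sl[i_mid] != 0)
    return best / ((ks[-1] - ks[0] + 1) * dz)


def brute_bvr(vol, lm, level):
    y = lm.ac[1] if level == "AC" else lm.pc[1]
    sl = _slice_at(vol, y)
    dz = vol.spacing[2]
    vents, aboves = [], []
    for i in range(sl.shape[0]):
        ks = np.flatnonzero(sl[i] == LAT)
        if not ks.size:
            continue
        vents.append((ks[-1] - ks[0] + 1) * dz)
        bs = np.flatnonzero(sl[i, ks[-1] + 1 :] == BRAIN)
        aboves.append((bs[-1] - bs[0] + 1) * dz if bs.size else 0.0)
    return max(aboves) / max(vents)


# ---------------------------------------------------------------------------


class TestEvans:
    def test_concentric_spheres(self):
        n = 71
        c = np.arange(n) - (n - 1) / 2
        X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
        labels = np.where(X**2 + Y**2 + Z**2 <= 30**2, BRAIN, 0)
        labels[X**2 + Y**2 + Z**2 <= 10**2] = LAT
        vol = make_volume(labels.astype(np.int16))
        lm = centered_landmarks(y_ac=-15.0, y_pc=-25.0)
        result = evans_index(vol, lm)
        assert float(result) == pytest.approx(10 / 30, rel=0.06)

    def test_numerator_not_exceeding_denominator(self, default_truth):
        r = evans_index(default_truth.labeled, default_truth.landmarks)
        assert r.numerator.length_mm <= r.denominator.length_mm

    def test_horns_posterior_to_ac_raise(self):
        labels = np.zeros((20, 20, 20), dtype=np.int16)
        labels[5:15, 2:6, 5:15] = LAT  # ventricles only in posterior y rows
        labels[labels == 0] = BRAIN
        vol = make_volume(labels)
        lm = centered_landmarks(y_ac=5.0, y_pc=-9.0)
        with pytest.raises(MeasurementError):
            evans_index(vol, lm)


class TestFrontalHorn:
    def test_mask_is_subset_of_lateral_ventricles(self, default_truth):
        vol = default_truth.labeled
        horn = frontal_horn_mask(vol, default_truth.landmarks)
        assert horn.any()
        assert not (horn & ~vol.mask("lateral_ventricles")).any()

    def test_no_ventricles_raises(self):
        vol = make_volume(np.full((6, 6, 6), BRAIN, dtype=np.int16))
        with pytest.raises(MeasurementError):
            frontal_horn_mask(vol, centered_landmarks())


class TestZEvans:
    def test_full_height_column_saturates_at_one(self):
        labels = np.zeros((11, 9, 30), dtype=np.int16)
        labels[:, :, 5:25] = BRAIN
        i_mid = 5  # x = 0 for this centred grid
        labels[i_mid, :, 5:25] = LAT
        vol = make_volume(labels)
        r = z_evans_index(vol, centered_landmarks(y_ac=1.0, y_pc=-1.0))
        assert float(r) == pytest.approx(1.0)

    def test_slice_missing_ventricles_raises(self):
        labels = np.full((10, 10, 10), BRAIN, dtype=np.int16)
        labels[4, 0:2, 4:6] = LAT  # ventricles far posterior of the AC plane
        vol = make_volume(labels)
        with pytest.raises(MeasurementError):
            z_evans_index(vol, centered_landmarks(y_ac=3.0, y_pc=-3.0))


class TestCallosalAngle:
    def _tent_volume(self, left_slope, right_slope, base=10):
        labels = np.zeros((21, 7, 40), dtype=np.int16)
        xs = np.arange(21) - 10
        for i, x in enumerate(xs):
            if x == 0:
                continue
            if x < 0:
                top = int(round(28 + left_slope * x))
            else:
                top = int(round(28 - right_slope * x))
            labels[i, :, 2 : top + 1] = LAT
        labels[labels == 0] = BRAIN
        return make_volume(labels)

    def test_perpendicular_roofs_give_90_degrees(self):
        vol = self._tent_volume(left_slope=1.0, right_slope=1.0)
        angle = callosal_angle(vol, centered_landmarks(y_ac=2.0, y_pc=0.0))
        assert angle == pytest.approx(90.0, abs=0.5)

    def test_flat_collinear_roofs_give_180_degrees(self):
        vol = self._tent_volume(left_slope=0.0, right_slope=0.0)
        angle = callosal_angle(vol, centered_landmarks(y_ac=2.0, y_pc=0.0))
        assert angle == pytest.approx(180.0, abs=0.5)

    def test_single_roof_point_raises(self):
        labels = np.full((9, 5, 9), BRAIN, dtype=np.int16)
        labels[3, :, 4] = LAT  # one left column only
        labels[6, :, 4] = LAT
        labels[7, :, 4] = LAT
        vol = make_volume(labels)
        with pytest.raises(MeasurementError, match="left"):
            callosal_angle(vol, centered_landmarks(y_ac=1.0, y_pc=0.0))


class TestBvr:
    def test_two_column_toy_gives_half(self):
        labels = np.zeros((9, 5, 60), dtype=np.int16)
        labels[2, :, 0:40] = LAT  # ventricle extent 40
        labels[2, :, 40:50] = BRAIN  # 10 above
        labels[6, :, 0:20] = LAT
        labels[6, :, 20:40] = BRAIN  # 20 above (max)
        vol = make_volume(labels)
        r = bvr(vol, centered_landmarks(y_ac=1.0, y_pc=0.0), "AC")
        assert float(r) == pytest.approx(0.5)

    def test_ventricle_touching_surface_warns_and_returns_zero(self):
        labels = np.zeros((9, 5, 30), dtype=np.int16)
        labels[3:6, :, 5:25] = LAT  # no brain anywhere above
        vol = make_volume(labels)
        with pytest.warns(UserWarning, match="BVR is 0"):
            r = bvr(vol, centered_landmarks(y_ac=1.0, y_pc=0.0), "AC")
        assert float(r) == 0.0


class TestCvr:
    def _vols(self, convexity, lateral):
        return CompartmentVolumes(
            brain_parenchyma=1000.0,
            lateral_ventricles=lateral,
            third_ventricle=0.0,
            fourth_ventricle=0.0,
            convexity_sas=convexity,
            sylvian_basal=50.0,
            posterior_fossa_sas=50.0,
        )

    def test_published_worked_example(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert round(cvr(self._vols(178.0, 118.0)), 2) == 1.51

    def test_equal_volumes_give_unity(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert cvr(self._vols(80.0, 80.0)) == pytest.approx(1.0)

    def test_zero_ventricles_raise(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(ZeroDivisionError):
                cvr(self._vols(80.0, 0.0))


class TestOracleEquivalence:
    """Max-extent searches agree with exhaustive per-voxel brute force."""

    @pytest.mark.parametrize("seed", range(4))
    def test_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.choice(
            [0, BRAIN, LAT], size=(18, 14, 16), p=[0.25, 0.5, 0.25]
        ).astype(np.int16)
        vol = make_volume(labels)
        # off-centre landmark heights avoid nearest-slice ties on even grids
        lm = centered_landmarks(y_ac=1.2, y_pc=-2.2)
        assert float(evans_index(vol, lm)) == pytest.approx(brute_evans(vol, lm))
        assert float(z_evans_index(vol, lm)) == pytest.approx(brute_z_evans(vol, lm))
        for level in ("AC", "PC"):
            assert float(bvr(vol, lm, level)) == pytest.approx(
                brute_bvr(vol, lm, level)
            )


class TestMeasureAll:
    def test_all_indices_populated(self, default_truth):
        idx = measure_all(default_truth.labeled, default_truth.landmarks)
        d = idx.as_dict()
        assert set(d) == {"evans", "z_evans", "callosal_angle", "bvr_ac", "bvr_pc", "cvr"}
        assert all(np.isfinite(v) for v in d.values())

    def test_missing_ventricles_names_failing_index(self):
        vol = make_volume(np.full((8, 8, 8), BRAIN, dtype=np.int16))
        with pytest.raises(MeasurementError, match="^evans"):
            measure_all(vol, centered_landmarks())

    def test_ordering_with_ventricle_size(self, default_spec):
        """Larger ventricles raise Evans and z-Evans and lower BVR and CVR;
        the callosal angle is set by the roof tilt, not the size."""
        from dataclasses import replace

        small = generate_phantom(default_spec)
        a, b, c = default_spec.ventricle_semiaxes
        big_spec = replace(default_spec, ventricle_semiaxes=(a * 1.1, b * 1.05, c * 1.08))
        big = generate_phantom(big_spec)
        s = measure_all(small.labeled, small.landmarks)
        l = measure_all(big.labeled, big.landmarks)
        assert l.evans > s.evans
        assert l.z_evans > s.z_evans
        assert l.bvr_ac < s.bvr_ac
        assert l.cvr < s.cvr
        assert abs(l.callosal_angle - s.callosal_angle) < 1.0

    def test_steeper_roofs_give_smaller_angle(self, default_spec):
        from dataclasses import replace

        steep = generate_phantom(replace(default_spec, roof_theta_deg=29.0))
        shallow = generate_phantom(
            replace(default_spec, roof_theta_deg=38.0, roof_apex_z=13.0)
        )
        a_steep = measure_all(steep.labeled, steep.landmarks).callosal_angle
        a_shallow = measure_all(shallow.labeled, shallow.landmarks).callosal_angle
        assert a_steep == pytest.approx(58.0, abs=2.0)
        assert a_shallow == pytest.approx(76.0, abs=2.0)

    def test_cvr_consistency_with_volume_ratios(self, default_truth):
        """CVR equals convexity VR over total-ventricle VR exactly."""
        from inph_morph import compute_volumes, volume_ratio

        vols = compute_volumes(default_truth.labeled)
        idx = measure_all(default_truth.labeled, default_truth.landmarks)
        assert idx.cvr == pytest.approx(
            volume_ratio(vols, "convexity_sas") / volume_ratio(vols, "total_ventricles")
        )
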