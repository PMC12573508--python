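"""Anatomical frame construction, the torso-axis correction, and sensitivity."""

import numpy as np
import pytest
from scipy.optimize import brentq

from shoulderkin.frames import (
    DegenerateLandmarkError,
    LandmarkSet,
    build_humerus_frame,
    build_scapula_frame,
    build_torso_frame,
    corrected_supine_axis,
    frame_axis_sensitivity,
    opening_angle,
)

from conftest import random_rigid


def angle_between(u, v):
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    return np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)), u @ v))


class TestOpeningAngle:
    def test_perpendicular_construction(self):
        assert opening_angle([0, -100, 0], [0, 0, 0], [-50, 0, 0]) == pytest.approx(
            90.0, abs=1e-12
        )

    def test_collinear_gives_zero(self):
        # xiphoid below SN, C7 directly above along the same line
        assert opening_angle([0, -100, 0], [0, 0, 0], [0, 80, 0]) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_matches_arccos_oracle(self, rng):
        for _ in range(100):
            x, sn, c7 = rng.uniform(-200, 200, size=(3, 3))
            v1 = sn - x
            v2 = c7 - sn
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            expected = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            assert opening_angle(x, sn, c7) == pytest.approx(expected, abs=1e-10)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateLandmarkError):
            opening_angle([0, 0, 0], [0, 0, 0], [1, 1, 1])


class TestCorrectedSupineAxis:
    SN = np.array([0.0, 0.0, 0.0])
    DS = np.array([10.0, -80.0, 0.0])
    C7 = np.array([-60.0, 20.0, 0.0])

    def test_theta_cs_equals_theta_u(self, rng):
        for _ in range(100):
            sn, ds, c7 = rng.uniform(-200, 200, size=(3, 3))
            theta_u = rng.uniform(5.0, 175.0)
            try:
                corr = corrected_supine_axis(sn, ds, c7, theta_u)
            except DegenerateLandmarkError:
                continue
            assert corr.theta_cs == pytest.approx(theta_u, abs=1e-9)

    def test_synthetic_xiphoid_stays_in_plane_at_sternum_distance(self):
        corr = corrected_supine_axis(self.SN, self.DS, self.C7, 150.0)
        n = np.cross(self.DS - self.SN, self.C7 - self.SN)
        n /= np.linalg.norm(n)
        assert abs((corr.synthetic_xiphoid - self.SN) @ n) < 1e-9
        assert np.linalg.norm(corr.synthetic_xiphoid - self.SN) == pytest.approx(
            np.linalg.norm(self.DS - self.SN), abs=1e-9
        )

    def test_fixed_point_when_angle_already_matches(self):
        theta = opening_angle(self.DS, self.SN, self.C7)
        corr = corrected_supine_axis(self.SN, self.DS, self.C7, theta)
        assert angle_between(
            corr.synthetic_xiphoid - self.SN, self.DS - self.SN
        ) < 1e-9

    def test_against_in_plane_scan_oracle(self):
        """Brute-force oracle: rotate the sternum direction in-plane until the
        opening angle hits theta_u, keeping the solution nearest the original
        direction."""
        theta_u = 150.0
        n = np.cross(self.DS - self.SN, self.C7 - self.SN)
        n /= np.linalg.norm(n)
        d0 = (self.DS - self.SN) / np.linalg.norm(self.DS - self.SN)

        def rotated(phi_deg):
            phi = np.radians(phi_deg)
            return (
                np.cos(phi) * d0
                + np.sin(phi) * np.cross(n, d0)
                + (1 - np.cos(phi)) * (n @ d0) * n
            )

        def f(phi_deg):
            return opening_angle(self.SN + 80 * rotated(phi_deg), self.SN, self.C7) - theta_u

        # coarse scan then root refinement; choose the root closest to phi=0
        grid = np.arange(-180.0, 180.0, 0.05)
        vals = np.array([f(p) for p in grid])
        roots = []
        for i in range(len(grid) - 1):
            if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0:
                roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-10))
        assert roots, "oracle found no in-plane solution"
        best = min(roots, key=abs)
        expected_dir = rotated(best)
        corr = corrected_supine_axis(self.SN, self.DS, self.C7, theta_u)
        got_dir = corr.synthetic_xiphoid - self.SN
        assert angle_between(got_dir, expected_dir) < 1e-5

    def test_idempotent_on_its_own_output(self):
        corr = corrected_supine_axis(self.SN, self.DS, self.C7, 150.0)
        again = corrected_supine_axis(
            self.SN, corr.synthetic_xiphoid, self.C7, 150.0
        )
        np.testing.assert_allclose(again.si_axis, corr.si_axis, atol=1e-9)

    def test_invalid_theta_rejected(self):
        from shoulderkin.frames import CorrectionInfeasibleError

        with pytest.raises(CorrectionInfeasibleError):
            corrected_supine_axis(self.SN, self.DS, self.C7, 190.0)


class TestTorsoFrame:
    def test_axis_aligned_construction(self):
        f = build_torso_frame([0, 0, 0], [0, -100, 0], [-80, 0, 0])
        np.testing.assert_allclose(f.y, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(f.x, [1, 0, 0], atol=1e-12)  # anterior
        np.testing.assert_allclose(f.z, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(f.origin, [0, 0, 0], atol=1e-12)

    def test_basis_is_proper_rotation(self, rng):
        for _ in range(50):
            pts = rng.uniform(-200, 200, size=(3, 3))
            try:
                f = build_torso_frame(*pts)
            except DegenerateLandmarkError:
                continue
            np.testing.assert_allclose(f.basis.T @ f.basis, np.eye(3), atol=1e-12)
            assert np.linalg.det(f.basis) == pytest.approx(1.0, abs=1e-12)

    def test_rigid_equivariance(self, rng):
        sn, xp, c7 = [0, 0, 0], [0, -100, 10], [-80, 5, 0]
        base = build_torso_frame(sn, xp, c7)
        for _ in range(20):
            r, t = random_rigid(rng)
            f = build_torso_frame(r @ sn + t, r @ xp + t, r @ c7 + t)
            np.testing.assert_allclose(f.origin, r @ base.origin + t, atol=1e-9)
            np.testing.assert_allclose(f.basis, r @ base.basis, atol=1e-9)

    def test_scale_invariant_directions(self):
        sn, xp, c7 = np.array([[0, 0, 0], [5, -100, 0], [-80, 5, 0]], dtype=float)
        f1 = build_torso_frame(sn, xp, c7)
        f2 = build_torso_frame(3 * sn, 3 * xp, 3 * c7)
        np.testing.assert_allclose(f1.basis, f2.basis, atol=1e-12)

    def test_collinear_rejected(self):
        with pytest.raises(DegenerateLandmarkError):
            build_torso_frame([0, 0, 0], [0, -100, 0], [0, 50, 0])


class TestScapulaFrame:
    def test_axis_aligned_construction(self, scapula_template):
        f = build_scapula_frame(**scapula_template)
        np.testing.assert_allclose(f.z, [0, 0, 1], atol=1e-12)  # lateral
        np.testing.assert_allclose(f.x, [1, 0, 0], atol=1e-12)  # anterior
        np.testing.assert_allclose(f.y, [0, 1, 0], atol=1e-12)  # superior
        np.testing.assert_allclose(f.origin, scapula_template["glenosphere_center"])

    def test_anterior_hint_fixes_normal_sign(self, scapula_template):
        f = build_scapula_frame(**scapula_template, anterior_hint=[-1, 0.1, 0])
        np.testing.assert_allclose(f.x, [-1, 0, 0], atol=1e-12)
        # the triad stays right-handed
        np.testing.assert_allclose(np.cross(f.x, f.y), f.z, atol=1e-12)

    def test_axes_orthogonal(self, rng):
        for _ in range(50):
            gc, ia, ts = rng.uniform(-200, 200, size=(3, 3))
            try:
                f = build_scapula_frame(gc, ia, ts)
            except DegenerateLandmarkError:
                continue
            assert abs(f.x @ f.y) < 1e-12
            assert abs(f.y @ f.z) < 1e-12
            assert abs(f.z @ f.x) < 1e-12

    def test_rigid_equivariance(self, rng, scapula_template):
        gc, ia, ts = (
            scapula_template["glenosphere_center"],
            scapula_template["inferior_angle"],
            scapula_template["trigonum_spinae"],
        )
        base = build_scapula_frame(gc, ia, ts)
        for _ in range(20):
            r, t = random_rigid(rng)
            f = build_scapula_frame(
                r @ gc + t, r @ ia + t, r @ ts + t, anterior_hint=r @ base.x
            )
            np.testing.assert_allclose(f.basis, r @ base.basis, atol=1e-9)


class TestHumerusFrame:
    def test_axis_aligned_construction(self):
        f = build_humerus_frame([0, 0, 0], [0, 1, 0], [30, -40, 0])
        np.testing.assert_allclose(f.y, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(f.x, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(f.z, [0, 0, 1], atol=1e-12)

    def test_gram_schmidt_orthogonality(self, rng):
        for _ in range(50):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            lt = rng.uniform(-100, 100, size=3)
            try:
                f = build_humerus_frame([0, 0, 0], axis, lt)
            except DegenerateLandmarkError:
                continue
            assert abs(f.x @ f.y) < 1e-12

    def test_lt_parallel_to_shaft_rejected(self):
        with pytest.raises(DegenerateLandmarkError):
            build_humerus_frame([0, 0, 0], [0, 1, 0], [0.1, -80, 0])

    def test_non_unit_axis_rejected(self):
        with pytest.raises(ValueError):
            build_humerus_frame([0, 0, 0], [0, 2, 0], [30, -40, 0])

    def test_rigid_equivariance(self, rng):
        gc, axis, lt = np.zeros(3), np.array([0.0, 1.0, 0.0]), np.array([30.0, -40.0, 0.0])
        base = build_humerus_frame(gc, axis, lt)
        for _ in range(20):
            r, t = random_rigid(rng)
            f = build_humerus_frame(r @ gc + t, r @ axis, r @ lt + t)
            np.testing.assert_allclose(f.basis, r @ base.basis, atol=1e-9)


class TestSensitivityAndLandmarkSet:
    def test_sensitivity_bound_monotone_in_perturbation(self):
        lms = {
            "sternal_notch": np.zeros(3),
            "xiphoid": np.array([5.0, -110.0, 0.0]),
            "c7": np.array([-70.0, 10.0, 0.0]),
        }
        bounds = [
            max(
                frame_axis_sensitivity(
                    build_torso_frame, lms, mm, n_samples=100,
                    rng=np.random.default_rng(7),
                ).values()
            )
            for mm in (0.5, 1.0, 2.0, 3.0)
        ]
        assert bounds == sorted(bounds)
        assert bounds[-1] < 15.0  # few-mm noise cannot swing an axis wildly

    def test_unknown_landmark_rejected(self):
        with pytest.raises(ValueError, match="sternal_notch"):
            LandmarkSet("supine", "right", {"sternal_nocht": [0, 0, 0]})

    def test_missing_landmark_named_in_error(self):
        lms = LandmarkSet("supine", "right", {"sternal_notch": [0, 0, 0]})
        with pytest.raises(KeyError, match="trigonum_spinae"):
            lms.require(("trigonum_spinae",), "scapula")

    def test_mirroring_flips_one_coordinate(self):
        lms = LandmarkSet(
            "upright", "left", {"sternal_notch": [1.0, 2.0, 3.0]}
        )
        m = lms.mirrored("xz")
        np.testing.assert_allclose(m["sternal_notch"], [1.0, -2.0, 3.0])
        assert m.side == "right"
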