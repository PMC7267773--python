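"""Rigid-transform algebra: superposition, composition, screw decomposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from protofil.rigid import (
    DegenerateGeometryError,
    NotATwoFoldError,
    PureTranslationError,
    RigidTransform,
    compose,
    invert,
    screw_decompose,
    screw_recompose,
    superpose,
    symmetrize_c2,
)

from conftest import random_rigid_transform


class TestSuperpose:
    def test_identity_on_equal_clouds(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(30, 3))
        t, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(t.translation, 0.0, atol=1e-12)

    def test_recovers_constructed_transform(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(scale=10, size=(50, 3))
        true = RigidTransform(
            Rotation.from_euler("z", 90, degrees=True).as_matrix(),
            np.array([5.0, 0.0, 0.0]))
        t, rmsd = superpose(pts, true.apply(pts))
        assert rmsd <= 1e-9
        assert np.allclose(t.rotation, true.rotation, atol=1e-9)
        assert np.allclose(t.translation, true.translation, atol=1e-9)

    def test_noisy_rmsd_matches_direct_residual_evaluation(self):
        # the reported rmsd must equal the explicitly recomputed residual,
        # and sit near the noise floor for a known perturbation
        rng = np.random.default_rng(2)
        pts = rng.normal(scale=15, size=(100, 3))
        true = random_rigid_transform(rng)
        noisy = true.apply(pts) + rng.normal(scale=0.5, size=pts.shape)
        t, rmsd = superpose(pts, noisy)
        resid = t.apply(pts) - noisy
        direct = np.sqrt(np.mean(np.sum(resid**2, axis=1)))
        assert rmsd == pytest.approx(direct, rel=1e-12)
        # expected rmsd ~ sigma * sqrt(3) reduced slightly by the 6 fitted dof
        assert rmsd == pytest.approx(0.5 * np.sqrt(3), rel=0.10)

    def test_rejects_too_few_or_collinear_points(self):
        with pytest.raises(DegenerateGeometryError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(10.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            superpose(line, line)

    def test_reflection_branch_gives_proper_rotation(self):
        # mirrored target would be fit best by a reflection; det must stay +1
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(40, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        t, _ = superpose(pts, mirrored)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_search_oracle(self):
        # independent oracle: brute-force quaternion grid over rotations,
        # polished by direct numerical minimization of the residual —
        # no SVD closed form anywhere in the oracle path
        from scipy.optimize import minimize

        def oracle_rmsd(moving, fixed):
            a0 = moving - moving.mean(0)
            b0 = fixed - fixed.mean(0)

            def cost(rotvec):
                r = Rotation.from_rotvec(rotvec).as_matrix()
                d = a0 @ r.T - b0
                return np.sqrt(np.mean(np.sum(d**2, axis=1)))

            rng = np.random.default_rng(99)
            quats = rng.normal(size=(4000, 4))
            quats /= np.linalg.norm(quats, axis=1, keepdims=True)
            best_rv, best = None, np.inf
            for q in quats:
                rv = Rotation.from_quat(q).as_rotvec()
                c = cost(rv)
                if c < best:
                    best, best_rv = c, rv
            res = minimize(cost, best_rv, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
            return res.fun

        for seed in range(10):
            r2 = np.random.default_rng(seed)
            pts = r2.normal(scale=8, size=(15, 3))
            true = random_rigid_transform(r2)
            target = true.apply(pts) + r2.normal(scale=0.3, size=pts.shape)
            _, rmsd = superpose(pts, target)
            oracle = oracle_rmsd(pts, target)
            assert rmsd <= oracle + 1e-9  # closed form can't be worse
            assert rmsd == pytest.approx(oracle, abs=1e-3)


class TestComposeInvert:
    def test_compose_with_inverse_is_identity(self):
        rng = np.random.default_rng(5)
        t = random_rigid_transform(rng)
        ident = compose(t, invert(t))
        assert np.allclose(ident.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(ident.translation, 0.0, atol=1e-12)

    def test_rotation_angles_add_about_common_axis(self):
        a = RigidTransform.from_rotvec_deg([0, 0, 1], 30.0)
        b = RigidTransform.from_rotvec_deg([0, 0, 1], 90.0)
        c = compose(a, b)
        s = screw_decompose(c, rise_tolerance=0.0)
        assert s.angle_deg == pytest.approx(120.0, abs=1e-9)
        assert abs(s.axis[2]) == pytest.approx(1.0, abs=1e-9)

    def test_inverse_of_translation(self):
        t = RigidTransform(np.eye(3), np.array([1.0, 2.0, 3.0]))
        assert np.allclose(invert(t).translation, [-1, -2, -3])

    def test_compose_applies_inner_first(self):
        inner = RigidTransform(np.eye(3), np.array([1.0, 0.0, 0.0]))
        outer = RigidTransform(
            Rotation.from_euler("z", 90, degrees=True).as_matrix(), np.zeros(3))
        x = np.array([0.0, 0.0, 0.0])
        assert np.allclose(compose(outer, inner).apply(x), [0.0, 1.0, 0.0], atol=1e-12)


class TestScrewDecompose:
    def test_ccdc61_geometry_right_and_left(self):
        for rise, hand in ((80.0, "right"), (-80.0, "left")):
            t = RigidTransform.from_rotvec_deg([0, 0, 1], 120.0, rise=rise)
            s = screw_decompose(t)
            assert s.angle_deg == pytest.approx(120.0, abs=1e-9)
            assert s.rise == pytest.approx(rise, abs=1e-9)
            assert s.handedness == hand

    def test_offset_axis_point_recovered_on_axis_line(self):
        t = RigidTransform.from_rotvec_deg([0, 0, 1], 40.0, point=(10.0, 0.0, 0.0))
        s = screw_decompose(t)
        assert s.angle_deg == pytest.approx(40.0, abs=1e-8)
        assert s.handedness == "none"
        # point-to-line distance from (10,0,0) along z
        delta = s.axis_point - np.array([10.0, 0.0, 0.0])
        dist = np.linalg.norm(delta - (delta @ s.axis) * s.axis)
        assert dist <= 1e-8

    def test_pure_translation_rejected(self):
        t = RigidTransform(np.eye(3), np.array([0.0, 0.0, 5.0]))
        with pytest.raises(PureTranslationError):
            screw_decompose(t)

    def test_half_turn_reports_unsigned_rise_with_flag(self):
        t = RigidTransform.from_rotvec_deg([1, 0, 0], 180.0, rise=3.0)
        s = screw_decompose(t)
        assert s.axis_sign_ambiguous
        assert s.handedness == "none"
        assert s.rise == pytest.approx(3.0, abs=1e-9)

    def test_roundtrip_over_seeded_random_transforms(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            t = random_rigid_transform(rng)
            s = screw_decompose(t, rise_tolerance=0.0)
            t2 = screw_recompose(s)
            assert np.max(np.abs(t2.rotation - t.rotation)) <= 1e-8
            assert np.linalg.norm(t2.translation - t.translation) <= 1e-6

    def test_conjugation_invariance_of_screw_parameters(self):
        # screw angle, |rise| and handedness are frame-independent
        rng = np.random.default_rng(7)
        for _ in range(50):
            g = random_rigid_transform(rng)
            h = random_rigid_transform(rng)
            sg = screw_decompose(g, rise_tolerance=0.0)
            sc = screw_decompose(compose(compose(h, g), invert(h)), rise_tolerance=0.0)
            assert sc.angle_deg == pytest.approx(sg.angle_deg, abs=1e-6)
            assert abs(sc.rise) == pytest.approx(abs(sg.rise), abs=1e-6)
            if not sg.axis_sign_ambiguous and abs(sg.rise) > 1e-3:
                sg_hand = "right" if sg.rise > 0 else "left"
                sc_hand = "right" if sc.rise > 0 else "left"
                assert sc_hand == sg_hand

    def test_produced_rotations_are_proper_orthonormal(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            t = screw_recompose(screw_decompose(random_rigid_transform(rng),
                                                rise_tolerance=0.0))
            assert abs(np.linalg.det(t.rotation) - 1.0) <= 1e-9
            assert np.max(np.abs(t.rotation.T @ t.rotation - np.eye(3))) <= 1e-9


class TestSymmetrizeC2:
    def test_exact_two_fold_unchanged(self):
        t = RigidTransform.from_rotvec_deg([0, 1, 0], 180.0, point=(2.0, 0.0, 1.0))
        exact, dev, rise = symmetrize_c2(t)
        assert dev == pytest.approx(0.0, abs=1e-9)
        assert rise == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(exact.rotation, t.rotation, atol=1e-9)

    def test_noisy_crystal_dimer_projected(self):
        t = RigidTransform.from_rotvec_deg([0, 1, 0], 178.5, rise=0.8)
        exact, dev, rise = symmetrize_c2(t)
        assert dev == pytest.approx(1.5, abs=1e-9)
        assert rise == pytest.approx(0.8, abs=1e-9)
        s = screw_decompose(exact, rise_tolerance=0.0)
        assert s.angle_deg == pytest.approx(180.0, abs=1e-9)
        assert abs(s.rise) <= 1e-9
        # an exact involution: applying twice is the identity
        twice = compose(exact, exact)
        assert np.allclose(twice.rotation, np.eye(3), atol=1e-9)
        assert np.linalg.norm(twice.translation) <= 1e-7

    def test_far_from_two_fold_rejected(self):
        t = RigidTransform.from_rotvec_deg([0, 1, 0], 150.0)
        with pytest.raises(NotATwoFoldError):
            symmetrize_c2(t)
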