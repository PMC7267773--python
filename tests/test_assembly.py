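"""Generator extraction, ring/helix/spiral classification, filaments, clashes."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from protofil.assembly import (
    UndefinedPeriodError,
    build_filament,
    bundle_clash_score,
    classify_assembly,
    filament_generator,
    interface_transform,
    projection_periodicity,
)
from protofil.rigid import RigidTransform, compose, invert, screw_decompose, transform_power
from protofil.structio import DomainSelection, Structure
from protofil.synthetic import interface_pair_axes, make_interface_pair


def _sel(chain, n_res=85):
    return DomainSelection(chain, (1, n_res))


def _interfaces(fixture):
    cc = interface_transform(fixture, _sel("A"), _sel("B"), label="coiled_coil")
    head = interface_transform(fixture, _sel("A"), _sel("C"), label="head_to_head")
    return head, cc


class TestInterfaceTransform:
    def test_exact_c2_dimer_has_zero_deviation(self, ccdc61_like_fixture):
        fixture, _ = ccdc61_like_fixture
        head, cc = _interfaces(fixture)
        for it in (head, cc):
            assert it.rmsd <= 1e-9
            assert it.c2_deviation_deg == pytest.approx(0.0, abs=1e-6)
            assert it.c2_residual_rise == pytest.approx(0.0, abs=1e-6)
            assert it.matched_residues == 85

    def test_one_degree_axis_perturbation_measured(self, toy_protomer):
        # partner = imperfect two-fold: 179 deg instead of 180
        t = RigidTransform.from_rotvec_deg([1, 0, 0], 179.0, point=(0, 0, 16))
        atoms = list(toy_protomer.atoms)
        partner = toy_protomer.transformed(t, {"A": "B"})
        st = Structure("near_c2", atoms + partner.atoms, "synthetic")
        it = interface_transform(st, _sel("A"), _sel("B"))
        assert it.c2_deviation_deg == pytest.approx(1.0, abs=0.1)

    def test_residue_count_mismatch_raises(self, ccdc61_like_fixture):
        fixture, _ = ccdc61_like_fixture
        with pytest.raises(Exception, match="correspondence|share"):
            interface_transform(fixture, DomainSelection("A", (1, 85)),
                                DomainSelection("B", (1, 2)))


class TestCompositionLaw:
    @pytest.mark.parametrize("alpha", [10.0, 20.0, 30.0, 45.0, 60.0, 80.0])
    @pytest.mark.parametrize("h", [0.0, 5.0, 40.0])
    def test_two_c2_axes_compose_to_screw_2alpha_2h(self, alpha, h):
        head, cc = interface_pair_axes(alpha, h)
        g = compose(head, cc)
        s = screw_decompose(g, rise_tolerance=0.0)
        expected_angle = 2.0 * alpha if 2.0 * alpha <= 180.0 else 360.0 - 2.0 * alpha
        assert s.angle_deg == pytest.approx(expected_angle, abs=1e-8)
        assert abs(s.rise) == pytest.approx(2.0 * h, abs=1e-8)
        if h == 0.0:
            # intersecting axes: pure rotation
            assert abs(s.rise) <= 1e-10

    def test_generator_order_invariance(self, ccdc61_like_fixture):
        fixture, _ = ccdc61_like_fixture
        head, cc = _interfaces(fixture)
        g1 = filament_generator(head, cc)
        g2 = compose(cc.symmetrized(), head.symmetrized())
        c1, c2 = classify_assembly(g1), classify_assembly(g2)
        assert c1.kind == c2.kind
        assert c1.angle_deg == pytest.approx(c2.angle_deg, abs=1e-8)
        assert abs(c1.rise_per_repeat) == pytest.approx(abs(c2.rise_per_repeat), abs=1e-8)
        assert c1.handedness == c2.handedness


class TestClassify:
    def test_sas6_ring_geometry(self):
        g = RigidTransform.from_rotvec_deg([0, 0, 1], 40.0, rise=0.02)
        c = classify_assembly(g)
        assert c.kind == "closed_ring"
        assert c.ring_order == 9

    def test_ccdc61_helix_geometry(self):
        g = RigidTransform.from_rotvec_deg([0, 0, 1], 120.0, rise=-80.0)
        c = classify_assembly(g)
        assert c.kind == "open_helix"
        assert c.handedness == "left"
        assert c.angle_deg == pytest.approx(120.0, abs=1e-9)
        assert c.rise_per_repeat == pytest.approx(-80.0, abs=1e-9)

    def test_cesas6_spiral_geometry(self):
        g = RigidTransform.from_rotvec_deg([0, 0, 1], 40.2, rise=3.0)
        c = classify_assembly(g, angle_tol_deg=2.0, rise_tol=1.0)
        assert c.kind == "spiral"
        assert c.closure_angle_residual == pytest.approx(1.8, abs=1e-9)
        assert c.closure_rise_residual == pytest.approx(27.0, abs=1e-9)

    def test_full_pipeline_on_synthetic_fixtures(self, ccdc61_like_fixture, sas6_ring_fixture):
        fixture, expected = ccdc61_like_fixture
        head, cc = _interfaces(fixture)
        c = classify_assembly(filament_generator(head, cc))
        assert c.kind == "open_helix"
        assert c.angle_deg == pytest.approx(expected["angle_deg"], abs=1e-6)
        assert c.rise_per_repeat == pytest.approx(expected["rise"], abs=1e-6)
        assert c.handedness == expected["handedness"]

        fixture, expected = sas6_ring_fixture
        head, cc = _interfaces(fixture)
        c = classify_assembly(filament_generator(head, cc))
        assert c.kind == "closed_ring"
        assert c.ring_order == 9

    def test_ring_closure_residual_monotone_in_perturbation(self):
        residuals = []
        for eps in (0.0, 0.2, 0.5, 1.0):
            g = RigidTransform.from_rotvec_deg([0, 0, 1], 40.0 + eps, rise=0.0)
            c = classify_assembly(g, angle_tol_deg=10.0)
            residuals.append(c.closure_angle_residual)
        assert residuals == sorted(residuals)

    def test_noise_never_flips_ring_classification(self):
        # 9-fold ring assembly under sigma = 0.3 A coordinate noise, 20 seeds
        from protofil.assembly import generator_from_assembly
        from protofil.synthetic import make_assembly_fixture

        for seed in range(20):
            fixture, _ = make_assembly_fixture(20.0, 0.0, n_repeats=9,
                                               noise_sd=0.3, seed=seed)
            c = classify_assembly(generator_from_assembly(fixture))
            assert c.kind == "closed_ring"
            assert c.ring_order == 9


class TestFilament:
    def test_single_repeat_is_the_cc_dimer(self, ccdc61_like_fixture):
        fixture, _ = ccdc61_like_fixture
        head, cc = _interfaces(fixture)
        g = filament_generator(head, cc)
        protomer = Structure("p", fixture.chain_atoms("A"), "synthetic")
        fil = build_filament(protomer, cc, g, 1)
        subs = fil.subunit_transforms()
        assert len(subs) == 2
        assert np.allclose(subs[0].rotation, np.eye(3))
        assert np.allclose(subs[1].rotation, cc.transform.rotation, atol=1e-9)

    def test_ring_generator_closes_after_nine_repeats(self, sas6_ring_fixture):
        fixture, _ = sas6_ring_fixture
        head, cc = _interfaces(fixture)
        g = filament_generator(head, cc)
        g9 = transform_power(g, 9)
        assert np.max(np.abs(g9.rotation - np.eye(3))) <= 1e-8
        assert np.linalg.norm(g9.translation) <= 1e-6

    def test_axial_extent_matches_rise_arithmetic(self, ccdc61_like_fixture):
        fixture, _ = ccdc61_like_fixture
        head, cc = _interfaces(fixture)
        g = filament_generator(head, cc)
        protomer = Structure("p", fixture.chain_atoms("A"), "synthetic")
        fil = build_filament(protomer, cc, g, 4)
        s = fil.screw
        base = protomer.coordinates()
        centroids = [t.apply(base).mean(axis=0) for t in fil.repeat_transforms]
        # axial separation between first and last repeat = 3 * |rise|
        axial = abs((centroids[3] - centroids[0]) @ s.axis)
        assert axial == pytest.approx(3 * abs(s.rise), rel=1e-9)

    def test_repeat_transform_is_generator_power(self, ccdc61_like_fixture):
        fixture, _ = ccdc61_like_fixture
        head, cc = _interfaces(fixture)
        g = filament_generator(head, cc)
        protomer = Structure("p", fixture.chain_atoms("A"), "synthetic")
        fil = build_filament(protomer, cc, g, 5)
        for k, t in enumerate(fil.repeat_transforms):
            gk = transform_power(g, k)
            assert np.max(np.abs(t.rotation - gk.rotation)) <= 1e-12
            assert np.linalg.norm(t.translation - gk.translation) <= 1e-10


class TestPeriodicity:
    def test_ccdc61_projection_period_is_240_angstrom(self):
        s = screw_decompose(RigidTransform.from_rotvec_deg([0, 0, 1], 120.0, rise=-80.0))
        assert projection_periodicity(s) == pytest.approx(240.0, abs=1e-9)

    def test_fourfold_screw_period(self):
        s = screw_decompose(RigidTransform.from_rotvec_deg([0, 0, 1], 90.0, rise=50.0))
        assert projection_periodicity(s) == pytest.approx(200.0, abs=1e-9)

    def test_no_integer_order_within_tolerance(self):
        s = screw_decompose(RigidTransform.from_rotvec_deg([0, 0, 1], 117.3, rise=30.0))
        with pytest.raises(UndefinedPeriodError, match="integer"):
            projection_periodicity(s, order_tol_deg=2.0)

    def test_ring_input_has_no_period(self):
        s = screw_decompose(RigidTransform.from_rotvec_deg([0, 0, 1], 40.0, rise=0.0))
        with pytest.raises(UndefinedPeriodError, match="ring"):
            projection_periodicity(s)


class TestBundleClash:
    def _filament(self, ccdc61_like_fixture, n=3):
        fixture, _ = ccdc61_like_fixture
        head, cc = _interfaces(fixture)
        g = filament_generator(head, cc)
        protomer = Structure("p", fixture.chain_atoms("A"), "synthetic")
        return build_filament(protomer, cc, g, n)

    def test_distant_pairing_is_compatible(self, ccdc61_like_fixture):
        fil = self._filament(ccdc61_like_fixture)
        pairing = RigidTransform(np.eye(3), np.array([500.0, 0.0, 0.0]))
        rep = bundle_clash_score(fil, pairing)
        assert rep.pair_count_below_cutoff == 0
        assert rep.verdict == "compatible"

    def test_identity_pairing_trivially_clashes(self, ccdc61_like_fixture):
        fil = self._filament(ccdc61_like_fixture)
        rep = bundle_clash_score(fil, RigidTransform.identity())
        n_ca = fil.calpha_coordinates().shape[0]
        assert rep.pair_count_below_cutoff >= n_ca  # every atom self-coincident
        assert rep.verdict == "clashing"

    def test_count_equals_brute_force(self, ccdc61_like_fixture):
        fil = self._filament(ccdc61_like_fixture)
        pairing = RigidTransform(np.eye(3), np.array([22.0, 3.0, 1.0]))
        rep = bundle_clash_score(fil, pairing, cutoff=4.0)
        ca = fil.calpha_coordinates()
        cb = pairing.apply(ca)
        brute = int(np.sum(np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2) < 4.0))
        assert rep.pair_count_below_cutoff == brute

    def test_allowed_pairs_threshold_controls_verdict(self, ccdc61_like_fixture):
        from protofil.synthetic import make_bundle_fixture

        fil, pairing, expected = make_bundle_fixture(designed_contacts=7, seed=3)
        rep0 = bundle_clash_score(fil, pairing, allowed_pairs=0)
        rep10 = bundle_clash_score(fil, pairing, allowed_pairs=10)
        assert rep0.pair_count_below_cutoff == 7
        assert rep0.verdict == "clashing"
        assert rep10.verdict == "compatible"
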