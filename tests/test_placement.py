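"""Placement: axis alignment, constrained MR search, rigid-body refinement."""

import math

import numpy as np
import pytest

from cyclophase import placement as P
from cyclophase.models import rotation_about_axis
from cyclophase.synthetic import axis_from_angles


class TestAlignAxis:
    def test_identity_when_aligned(self, tiny_case):
        m = tiny_case.truth_model
        out = P.align_axis(m, [0, 0, 1], [0, 0, 1])
        assert np.allclose(out.xyz, m.xyz)

    def test_maps_z_onto_tilted_axis(self, tiny_case):
        m = tiny_case.em_model
        out = P.align_axis(m, [0, 0, 1], np.array([70.0, 0.0]))
        ax, _ = P.fit_ring_axis(out)
        target = axis_from_angles(70.0, 0.0)
        assert min(np.linalg.norm(ax - target), np.linalg.norm(ax + target)) < 1e-6

    def test_idempotent(self, tiny_case):
        m = tiny_case.em_model
        once = P.align_axis(m, [0, 0, 1], [1, 1, 1])
        twice = P.align_axis(once, [1, 1, 1], [1, 1, 1])
        assert np.allclose(once.xyz, twice.xyz, atol=1e-9)

    def test_antiparallel_deterministic(self, tiny_case):
        m = tiny_case.em_model
        a = P.align_axis(m, [0, 0, 1], [0, 0, -1])
        b = P.align_axis(m, [0, 0, 1], [0, 0, -1])
        assert np.allclose(a.xyz, b.xyz)
        ax, _ = P.fit_ring_axis(a)
        assert abs(ax[2]) > 1 - 1e-9

    def test_zero_axis_rejected(self, tiny_case):
        with pytest.raises(ValueError):
            P.align_axis(tiny_case.em_model, [0, 0, 0], [0, 0, 1])


class TestMagnificationDiagnostic:
    def test_values(self):
        assert P.magnification_diagnostic(1.0, 180.0) == 0.0
        assert P.magnification_diagnostic(1.1, 10.0) == pytest.approx(1.0)
        d = P.magnification_diagnostic(1.42 / 1.37, 180.0)
        assert d == pytest.approx(180.0 * (1.42 / 1.37 - 1.0))
        assert d > 6.5  # the diameter error exceeds the 6.5 A bound

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            P.magnification_diagnostic(0.0, 180.0)


class TestKabschAndRingFit:
    def test_kabsch_recovers_random_rigid_transform(self, rng):
        pts = rng.uniform(-20, 20, (40, 3))
        rot = rotation_about_axis([0.3, -0.5, 0.81], 0.7)
        trans = np.array([4.0, -2.0, 9.0])
        moved = pts @ rot.T + trans
        r2, t2 = P.kabsch(pts, moved)
        assert np.allclose(r2, rot, atol=1e-10)
        assert np.allclose(t2, trans, atol=1e-9)

    def test_fit_ring_axis(self, tiny_case):
        ax, center = P.fit_ring_axis(tiny_case.truth_model)
        c = abs(float(ax @ tiny_case.axis))
        assert math.degrees(math.acos(min(c, 1.0))) < 0.5
        # center sits on the constructed axis
        delta = center - tiny_case.ring_center
        off_axis = delta - (delta @ tiny_case.axis) * tiny_case.axis
        assert np.linalg.norm(off_axis) < 1.0


class TestScoring:
    def test_identical_intensities_score_one(self, tiny_case):
        refl = tiny_case.refl_obs
        norm = P._ShellNormalizer(refl.cell, refl.hkl)
        assert P.intensity_correlation(refl.f, refl.f, norm) == pytest.approx(1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            P.intensity_correlation(np.ones(10), np.ones(10))

    def test_direct_sf_matches_fft_route(self, tiny_case):
        from cyclophase.fourier import calc_f_at

        model = tiny_case.truth_model
        hkl = tiny_case.refl_obs.hkl[:300]
        a = P.calc_f_direct(model, tiny_case.cell, tiny_case.sg, hkl)
        b = calc_f_at(model, tiny_case.cell, tiny_case.sg, hkl)
        assert np.corrcoef(np.abs(a), np.abs(b))[0, 1] > 0.9999


@pytest.fixture(scope="module")
def tiny_search(tiny_case):
    aligned = P.align_axis(tiny_case.em_model, [0, 0, 1], tiny_case.axis)
    places = P.search_placement(aligned, tiny_case.refl_obs, tiny_case.axis,
                                order=tiny_case.n, psi_step=6.0)
    return aligned, places


class TestSearchPlacement:

    def test_truth_recovered_with_full_model(self, tiny_case, tiny_search):
        aligned, places = tiny_search
        top = places[0]
        # within one translation-grid step of the true position ...
        t_truth = tiny_case.cell.fractionalize(tiny_case.truth_model.centroid())
        assert P._same_placement(tiny_case.cell, top.shift_frac, t_truth, 2.5)
        assert min(top.psi % (360 / tiny_case.n),
                   360 / tiny_case.n - top.psi % (360 / tiny_case.n)) <= 6.0
        # ... and sub-grid polishing reaches near-perfect agreement
        placed = P.apply_placement(aligned, tiny_case.cell, tiny_case.axis, top)
        ax, c = P.fit_ring_axis(placed)
        _, rep = P.rigid_body_refine(placed, tiny_case.refl_obs, ax, c,
                                     per_chain=False, max_refl=1000)
        assert rep.score_after > 0.95

    def test_solution_is_unique(self, tiny_search):
        from cyclophase.pipeline import is_unique_solution

        _, places = tiny_search
        assert is_unique_solution(places)

    def test_decoy_model_has_no_unique_solution(self, tiny_case):
        from cyclophase.pipeline import is_unique_solution
        from cyclophase.synthetic import make_protomer

        # a compact non-ring decoy: nothing in the crystal matches it, so the
        # score landscape is flat and no placement stands out
        blob = make_protomer(n_res=150, n_helices=6, seed=99)
        aligned = P.align_axis(blob, [0, 0, 1], tiny_case.axis)
        places = P.search_placement(aligned, tiny_case.refl_obs, tiny_case.axis,
                                    order=tiny_case.n, psi_step=9.0)
        assert places[0].score < 0.5
        assert not is_unique_solution(places)


class TestRigidBody:
    def test_already_optimal_model_stays(self, tiny_case):
        ax, center = P.fit_ring_axis(tiny_case.truth_model)
        refined, rep = P.rigid_body_refine(
            tiny_case.truth_model, tiny_case.refl_obs, ax, center,
            cycles=1, max_refl=800, refine_rotations=False)
        disp = np.linalg.norm(np.array(rep.translations), axis=1)
        assert disp.max() < 0.05
        assert rep.score_after >= rep.score_before

    def test_score_never_decreases(self, tiny_case, rng):
        ax, center = P.fit_ring_axis(tiny_case.truth_model)
        jittered = tiny_case.truth_model.transformed(
            trans=np.array([0.8, -0.5, 0.6]))
        refined, rep = P.rigid_body_refine(
            jittered, tiny_case.refl_obs, ax, center, cycles=1, max_refl=800,
            refine_rotations=False)
        assert rep.score_after >= rep.score_before - 1e-12

    def test_parameter_recovery_from_perturbation(self, tiny_case):
        # whole-body error of ~3 A / 5 deg must refine back below 0.5 A RMSD
        ax, center = P.fit_ring_axis(tiny_case.truth_model)
        rot = rotation_about_axis([0, 1, 0], math.radians(5.0))
        start = tiny_case.truth_model.transformed(
            rot=rot, trans=center - rot @ center + np.array([1.8, -1.4, 1.6]))
        refined, rep = P.rigid_body_refine(
            start, tiny_case.refl_obs, ax, center, per_chain=False, cycles=3,
            max_refl=1500, trans_tol=0.01, rot_tol=0.02)
        rmsd = np.sqrt(((refined.xyz - tiny_case.truth_model.xyz) ** 2)
                       .sum(axis=1).mean())
        assert rmsd < 0.5

    def test_magnification_inference_direction(self, tiny_case):
        from cyclophase.models import rescale_magnification

        m = 1.05
        start = rescale_magnification(tiny_case.truth_model, m,
                                      center=tiny_case.ring_center)
        ax, center = P.fit_ring_axis(tiny_case.truth_model)
        _, rep = P.rigid_body_refine(start, tiny_case.refl_obs, ax, center,
                                     cycles=2, max_refl=800,
                                     refine_rotations=False)
        assert (rep.radial_shifts < 0).all()
        assert rep.magnification == pytest.approx(m, rel=0.02)
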