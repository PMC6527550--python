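import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from exopath.energymodel import (EnergyParams, LigandView, apply_gate_torsions,
                                 clash_count, interaction_energy,
                                 minimize_pose)
from exopath.structmodel import Atom, Pose, Structure

SIXTH = 2 ** (1 / 6)


def _scene(rec_coords, lig_coords, rec_polar=None, lig_polar=None, radius=1.7):
    atoms = [Atom("C", f"W{i}", i + 1, "WAL", "R", c, radius=radius,
                  polar=0.0 if rec_polar is None else rec_polar[i])
             for i, c in enumerate(np.atleast_2d(rec_coords))]
    lig_coords = np.atleast_2d(lig_coords)
    lig = LigandView(lig_coords, np.full(len(lig_coords), radius),
                     np.zeros(len(lig_coords)) if lig_polar is None
                     else np.asarray(lig_polar, float))
    return Structure(atoms), lig


def _brute_energy(rec, lig_coords, params, rec_polar=None, lig_polar=None,
                  radius=1.7):
    e = 0.0
    rec = np.atleast_2d(rec)
    lig_coords = np.atleast_2d(lig_coords)
    for i, a in enumerate(rec):
        for j, b in enumerate(lig_coords):
            r = np.linalg.norm(a - b)
            if r >= params.cutoff:
                continue
            sigma = params.sigma_scale * 2 * radius / SIXTH
            sr6 = (sigma / r) ** 6
            e += 4 * params.epsilon * (sr6 ** 2 - sr6)
            pi = 0.0 if rec_polar is None else rec_polar[i]
            pj = 0.0 if lig_polar is None else lig_polar[j]
            if pi * pj > 0:
                if r < params.r_hb:
                    g = 1.0
                elif r < params.r_hb_off:
                    t = (r - params.r_hb) / (params.r_hb_off - params.r_hb)
                    g = 0.5 * (1 + np.cos(np.pi * t))
                else:
                    g = 0.0
                e -= params.polar_strength * pi * pj * g
    return e


class TestClashCount:
    def test_isolated_ligand_has_no_clashes(self):
        s, lig = _scene([[50.0, 0, 0]], [[0.0, 0, 0]])
        assert clash_count(s, lig, Pose(), EnergyParams()) == 0

    def test_constructed_overlap_is_one_clash(self):
        # receptor atom at half the radii sum, overlap factor 0.7
        s, lig = _scene([[1.7, 0, 0]], [[0.0, 0, 0]])
        assert clash_count(s, lig, Pose(), EnergyParams(overlap_factor=0.7)) == 1

    def test_matches_brute_force_on_random_scenes(self, rng):
        params = EnergyParams()
        for _ in range(200):
            rec = rng.uniform(-6, 6, (40, 3))
            ligc = rng.uniform(-6, 6, (6, 3))
            s, lig = _scene(rec, ligc)
            brute = sum(
                1 for a in rec for b in ligc
                if np.linalg.norm(a - b) < params.overlap_factor * 3.4)
            assert clash_count(s, lig, Pose(), params) == brute


class TestInteractionEnergy:
    def test_zero_beyond_cutoff(self):
        s, lig = _scene([[20.0, 0, 0]], [[0.0, 0, 0]])
        assert interaction_energy(s, lig, Pose(), EnergyParams()) == 0.0

    def test_lj_closed_form_single_pair(self):
        params = EnergyParams()
        sigma = params.sigma_scale * 3.4 / SIXTH
        s, lig = _scene([[sigma, 0, 0]], [[0.0, 0, 0]])
        assert interaction_energy(s, lig, Pose(), params) == \
            pytest.approx(0.0, abs=1e-10)
        s, lig = _scene([[SIXTH * sigma, 0, 0]], [[0.0, 0, 0]])
        assert interaction_energy(s, lig, Pose(), params) == \
            pytest.approx(-params.epsilon, abs=1e-10)

    def test_coincident_beads_raise(self):
        s, lig = _scene([[0.0, 0, 0]], [[0.0, 0, 0]])
        with pytest.raises(FloatingPointError):
            interaction_energy(s, lig, Pose(), EnergyParams())

    def test_matches_brute_force_with_polar_terms(self, rng):
        params = EnergyParams()
        for _ in range(20):
            rec = rng.uniform(-5, 5, (25, 3))
            ligc = rng.uniform(-5, 5, (5, 3)) + 8.0  # avoid r=0
            rp = rng.integers(0, 2, 25).astype(float)
            lp = rng.integers(0, 2, 5).astype(float)
            s, lig = _scene(rec, ligc, rec_polar=rp, lig_polar=lp)
            expect = _brute_energy(rec, ligc, params, rp, lp)
            got = interaction_energy(s, lig, Pose(), params)
            assert got == pytest.approx(expect, abs=1e-10)

    def test_invariant_under_global_rigid_motion(self, rng):
        params = EnergyParams()
        rec = rng.uniform(-5, 5, (20, 3))
        ligc = rng.uniform(-5, 5, (5, 3)) + 7.0
        s, lig = _scene(rec, ligc)
        e0 = interaction_energy(s, lig, Pose(), params)
        rot = Rotation.from_rotvec([0.4, -1.0, 0.7])
        t = np.array([3.0, -2.0, 11.0])
        s2, lig2 = _scene(rot.apply(rec) + t, rot.apply(ligc) + t)
        e1 = interaction_energy(s2, lig2, Pose(), params)
        assert e1 == pytest.approx(e0, rel=1e-9)
        assert clash_count(s, lig, Pose(), params) == \
            clash_count(s2, lig2, Pose(), params)

    def test_additive_over_noninteracting_subscenes(self, rng):
        params = EnergyParams()
        rec_a = rng.uniform(-3, 3, (10, 3))
        lig_a = rng.uniform(-3, 3, (3, 3)) + 5.0
        far = np.array([200.0, 0, 0])
        rec = np.vstack([rec_a, rec_a + far])
        ligc = np.vstack([lig_a, lig_a + far])
        s, lig = _scene(rec, ligc)
        s_a, lv_a = _scene(rec_a, lig_a)
        e_half = interaction_energy(s_a, lv_a, Pose(), params)
        assert interaction_energy(s, lig, Pose(), params) == \
            pytest.approx(2 * e_half, rel=1e-9)


class TestMinimizePose:
    def test_already_at_minimum_stays(self):
        params = EnergyParams()
        sigma = params.sigma_scale * 3.4 / SIXTH
        s, lig = _scene([[SIXTH * sigma, 0, 0]], [[0.0, 0, 0]])
        pose, _, e = minimize_pose(s, lig, Pose(), params, grad_tol=1e-4)
        assert np.linalg.norm(pose.translation) < 1e-3

    def test_single_pair_converges_to_lj_minimum(self):
        params = EnergyParams()
        sigma = params.sigma_scale * 3.4 / SIXTH
        s, lig = _scene([[1.5 * sigma, 0, 0]], [[0.0, 0, 0]])
        pose, _, e = minimize_pose(s, lig, Pose(), params, max_steps=500,
                                   step_size=0.3, grad_tol=1e-6)
        r = np.linalg.norm(np.array([1.5 * sigma, 0, 0])
                           - (np.zeros(3) + pose.translation))
        assert r == pytest.approx(SIXTH * sigma, abs=1e-3)

    def test_energy_never_increases(self, rng):
        params = EnergyParams()
        rec = rng.uniform(-4, 4, (15, 3))
        ligc = np.array([[9.0, 0.0, 0.0]])
        s, lig = _scene(rec, ligc)
        e0 = interaction_energy(s, lig, Pose(), params)
        _, _, e1 = minimize_pose(s, lig, Pose(), params, max_steps=60)
        assert e1 <= e0 + 1e-12


class TestGateTorsions:
    def test_rotation_about_stored_axis(self, toy_pocket):
        structure, _, ann = toy_pocket
        g = ann.gate_residue_ids[0]
        opened = apply_gate_torsions(structure, {g: 90.0})
        res_map = structure.residue_atom_indices()
        idx = res_map[("R", g)]
        anchor0 = structure.coords[idx[0]]
        np.testing.assert_allclose(opened.coords[idx[0]], anchor0, atol=1e-12)
        # tip retracts from the channel axis and lifts along +z
        tip0, tip1 = structure.coords[idx[-1]], opened.coords[idx[-1]]
        assert np.hypot(*tip1[:2]) > np.hypot(*tip0[:2])
        assert tip1[2] > tip0[2]

    def test_non_flexible_residue_rejected(self, toy_pocket):
        structure, _, _ = toy_pocket
        with pytest.raises(ValueError):
            apply_gate_torsions(structure, {1: 30.0})
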