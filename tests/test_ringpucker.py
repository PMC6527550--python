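import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.spatial.transform import Rotation

from exopath.ringpucker import (FELGrid, MetadConfig, PuckerCoords,
                                canonical_vertices, classify_conformer,
                                cremer_pople, fel_extrema,
                                run_wt_metadynamics)


def _hexagon(rho=1.45, z=None):
    ang = 2 * np.pi * np.arange(6) / 6
    z = np.zeros(6) if z is None else np.asarray(z, float)
    return np.column_stack([rho * np.cos(ang), rho * np.sin(ang), z])


class TestCremerPople:
    def test_planar_ring_has_zero_amplitude(self):
        pc = cremer_pople(_hexagon())
        assert pc.Q < 1e-10

    def test_alternating_chair_closed_form(self):
        z0 = 0.25
        pc = cremer_pople(_hexagon(z=z0 * (-1.0) ** np.arange(6)))
        assert pc.Q == pytest.approx(np.sqrt(6) * z0, rel=1e-12)
        # a pure chair lies on a pole; the O5-up pattern is the 4C1 pole
        assert min(pc.theta, 180.0 - pc.theta) < 1e-9
        assert pc.theta < 1e-9

    def test_pure_q2_pattern_is_equatorial(self):
        # opposite pair out of plane on the same side: a boat, theta = 90
        z = np.zeros(6)
        z[1], z[4] = 0.3, 0.3
        pc = cremer_pople(_hexagon(z=z))
        assert pc.theta == pytest.approx(90.0, abs=1e-6)

    def test_invariant_under_rigid_motion(self, rng):
        ring = _hexagon(z=0.25 * (-1.0) ** np.arange(6))
        pc0 = cremer_pople(ring)
        rot = Rotation.from_rotvec(rng.uniform(-2, 2, 3))
        pc1 = cremer_pople(rot.apply(ring) + rng.uniform(-9, 9, 3))
        assert pc1.Q == pytest.approx(pc0.Q, abs=1e-10)
        assert pc1.theta == pytest.approx(pc0.theta, abs=1e-7)

    def test_cyclic_relabelling_shifts_phase_only(self):
        z = np.zeros(6)
        z[1], z[3] = 0.3, -0.3      # a skew pattern off the poles
        ring = _hexagon(z=z)
        pc0 = cremer_pople(ring)
        shifted = np.roll(ring, -2, axis=0)   # even shift keeps theta
        pc2 = cremer_pople(shifted)
        assert pc2.Q == pytest.approx(pc0.Q, abs=1e-10)
        assert pc2.theta == pytest.approx(pc0.theta, abs=1e-7)
        dphi = (pc2.phi - pc0.phi) % 360
        assert dphi == pytest.approx(240.0, abs=1e-6) or \
            dphi == pytest.approx(0.0, abs=1e-6)

    def test_wrong_atom_count_rejected(self):
        with pytest.raises(ValueError):
            cremer_pople(np.zeros((5, 3)))

    def test_qx_qy_qz_consistency(self):
        pc = PuckerCoords(0.55, 37.0, 123.0)
        assert pc.qx ** 2 + pc.qy ** 2 + pc.qz ** 2 == \
            pytest.approx(pc.Q ** 2, abs=1e-10)


class TestClassification:
    def test_vertex_table_has_38_unique_conformers(self):
        verts = canonical_vertices()
        assert len(verts) == 38
        assert len({v[0] for v in verts}) == 38

    def test_near_pole_is_4c1_for_any_phase(self):
        for phi in (0.0, 90.0, 201.0, 355.0):
            assert classify_conformer(PuckerCoords(0.55, 2.0, phi)) == "4C1"

    def test_zero_amplitude_is_planar(self):
        assert classify_conformer(PuckerCoords(0.0, 0.0, 0.0)) == "planar"

    def test_every_canonical_vertex_classifies_as_itself(self):
        for label, theta, phi in canonical_vertices():
            assert classify_conformer(PuckerCoords(0.55, theta, phi)) == label


class TestFelExtrema:
    def test_hand_built_grid_saddle(self):
        vals = np.full((5, 5), 5.0)
        vals[1, 2] = 0.0          # basin A
        vals[3, 2] = 1.0          # basin B
        vals[2, 2] = 3.0          # the lowest connecting pass
        fel = FELGrid(np.arange(5.0), np.arange(5.0), vals)
        minima, barrier = fel_extrema(fel, basin_a=(1, 2), basin_b=(3, 2))
        assert barrier == pytest.approx(3.0)
        mins = {(m[0], m[1]) for m in minima}
        assert (1.0, 2.0) in mins and (3.0, 2.0) in mins

    def test_single_well_grid_has_one_minimum(self):
        x = np.linspace(-1, 1, 21)
        X, Y = np.meshgrid(x, x, indexing="ij")
        fel = FELGrid(x, x, (X ** 2 + Y ** 2))
        minima, _ = fel_extrema(fel)
        assert len(minima) == 1

    def test_double_well_barrier_matches_ridge_scan(self):
        x = np.linspace(-1.6, 1.6, 81)
        X, Y = np.meshgrid(x, x, indexing="ij")
        V = 3 * (X ** 2 - 1) ** 2 + 0.5 * X + 2 * Y ** 2
        V -= V.min()
        fel = FELGrid(x, x, V)
        minima, barrier = fel_extrema(fel, basin_a=(-1, 0), basin_b=(1, 0))
        xs = np.linspace(-1.05, 1.0, 4001)
        v1 = 3 * (xs ** 2 - 1) ** 2 + 0.5 * xs
        oracle = v1.max() - v1.min()
        assert barrier == pytest.approx(oracle, abs=0.1)


class TestMetadynamics:
    def test_harmonic_well_recovers_the_potential(self):
        fel = run_wt_metadynamics(lambda x, y: 2.0 * (x ** 2 + y ** 2),
                                  MetadConfig(seed=1))
        F, xa, ya = fel.values, fel.x_axis, fel.y_axis
        X, Y = np.meshgrid(xa, ya, indexing="ij")
        V = 2.0 * (X ** 2 + Y ** 2)
        # minimum sits at the well centre
        imin = np.unravel_index(np.argmin(gaussian_filter(F, 3)), F.shape)
        assert np.hypot(xa[imin[0]], ya[imin[1]]) < 0.3
        # free-energy differences track the potential at the resolution of
        # the deposited hills, inside the region the walker samples
        sg = 0.12 / (xa[1] - xa[0])
        Fs, Vs = gaussian_filter(F, sg), gaussian_filter(V, sg)
        ic = np.unravel_index(np.argmin(Vs), Vs.shape)
        err = np.abs((Fs - Fs[ic]) - (Vs - Vs[ic]))[V < 2.0]
        assert err.mean() < 0.15

    def test_symmetric_double_well_gives_zero_delta_f(self):
        fel = run_wt_metadynamics(
            lambda x, y: 3.0 * (x ** 2 - 1.0) ** 2 + 2.0 * y ** 2,
            MetadConfig(seed=3))
        assert abs(fel.metadata["basin_delta_f"]) < 0.3

    def test_asymmetric_double_well_matches_quadrature_oracle(self):
        kT = 0.596
        b = 0.8

        def pot(x, y):
            return 3.0 * (x ** 2 - 1.0) ** 2 + b * x + 2.0 * y ** 2

        xs = np.linspace(-1.8, 1.8, 801)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        V = pot(X, Y)
        w = np.exp(-(V - V.min()) / kT)
        mid = len(xs) // 2
        oracle_df = float(-kT * np.log(w[mid:, :].sum() / w[:mid, :].sum()))
        fel = run_wt_metadynamics(pot, MetadConfig(seed=3))
        assert fel.metadata["basin_delta_f"] == pytest.approx(oracle_df,
                                                              abs=0.5)
        # barrier against a 1-D ridge scan
        v1 = 3.0 * (xs ** 2 - 1) ** 2 + b * xs
        il = xs < 0
        xl = xs[il][np.argmin(v1[il])]
        xr = xs[~il][np.argmin(v1[~il])]
        seg = (xs >= xl) & (xs <= xr)
        oracle_barrier = v1[seg].max() - v1[il].min()
        _, barrier = fel_extrema(fel, basin_a=(-1.0, 0.0), basin_b=(1.0, 0.0),
                                 depth_threshold=2.5)
        assert barrier == pytest.approx(oracle_barrier, abs=1.0)

    def test_convergence_diagnostic_is_small_at_default_budget(self):
        fel = run_wt_metadynamics(
            lambda x, y: 3.0 * (x ** 2 - 1.0) ** 2 + 2.0 * y ** 2,
            MetadConfig(seed=4))
        assert fel.metadata["delta_f_drift"] < 0.2

    def test_non_finite_potential_rejected(self):
        with pytest.raises(ValueError):
            run_wt_metadynamics(lambda x, y: np.log(x), MetadConfig(seed=0))
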