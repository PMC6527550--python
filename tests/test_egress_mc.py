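import numpy as np
import pytest

from exopath.egress_mc import (MCConfig, Trajectory, _MigrationEngine,
                               energy_distance_profile, metropolis_accept,
                               run_migration)
from exopath.energymodel import EnergyParams
from exopath.structmodel import Pose
from exopath.elasticmodes import ANMConfig
from exopath.synthetic import ToyPocketSpec, make_toy_pocket, toy_anm_config

TOY_ANM = toy_anm_config()


class TestMetropolisRule:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(-d, 1.2, rng)
                   for d in np.linspace(0, 50, 20))

    def test_vanishing_temperature_rejects_uphill(self, rng):
        assert not any(metropolis_accept(1.0, 1e-9, rng) for _ in range(50))

    def test_double_well_chain_samples_boltzmann(self):
        # Metropolis chain with symmetric Gaussian proposals on a 1-D double
        # well: basin occupancies must match the quadrature ratio
        rng = np.random.default_rng(7)
        kT = 1.0

        def V(x):
            return 2.0 * (x ** 2 - 1.0) ** 2 + 0.6 * x

        x, n = -1.0, 60_000
        visits = np.zeros(2)
        for _ in range(n):
            prop = x + rng.normal(0, 0.6)
            if metropolis_accept(V(prop) - V(x), kT, rng):
                x = prop
            visits[int(x > 0)] += 1
        xs = np.linspace(-3, 3, 4001)
        w = np.exp(-(V(xs) - V(xs).min()) / kT)
        expect = w[xs > 0].sum() / w[xs <= 0].sum()
        ratio = visits[1] / visits[0]
        assert ratio == pytest.approx(expect, rel=0.15)

    def test_two_state_occupancy_matches_boltzmann(self):
        # chain over two states with energies 0 and dE under the Metropolis
        # rule; occupancy ratio must converge to exp(-dE/kT)
        rng = np.random.default_rng(42)
        dE, kT = 1.0, 1.2
        state, counts = 0, np.zeros(2)
        n = 100_000
        for _ in range(n):
            prop = 1 - state
            delta = dE if prop == 1 else -dE
            if metropolis_accept(delta, kT, rng):
                state = prop
            counts[state] += 1
        ratio = counts[1] / counts[0]
        expect = np.exp(-dE / kT)
        # 3 standard errors of the occupancy estimate
        p = expect / (1 + expect)
        se = 3 * np.sqrt(p * (1 - p) / n) * (1 + ratio) ** 2
        assert abs(ratio - expect) < max(se, 0.03)


class TestMigration:
    def test_deterministic_per_seed(self, toy_pocket, toy_modes):
        structure, ligand, _ = toy_pocket
        cfg = MCConfig(seed=11, max_steps=400)
        t1 = run_migration(structure, ligand.view(), Pose(), toy_modes, cfg)
        t2 = run_migration(structure, ligand.view(), Pose(), toy_modes, cfg)
        assert len(t1.states) == len(t2.states)
        for a, b in zip(t1.states, t2.states):
            assert a.energy == b.energy
            assert a.separation_com == b.separation_com

    def test_energy_bookkeeping_reevaluates(self, toy_pocket, toy_modes):
        structure, ligand, _ = toy_pocket
        cfg = MCConfig(seed=3, max_steps=300)
        tr = run_migration(structure, ligand.view(), Pose(), toy_modes, cfg)
        engine = _MigrationEngine(structure, ligand.view(), toy_modes, cfg,
                                  EnergyParams())
        for st in tr.states[::25]:
            e = engine.energy(st.receptor_offset, st.gate_torsions, st.pose)
            assert e == pytest.approx(st.energy, abs=1e-9)

    def test_separations_start_at_zero(self, toy_pocket, toy_modes):
        structure, ligand, _ = toy_pocket
        tr = run_migration(structure, ligand.view(), Pose(), toy_modes,
                           MCConfig(seed=0, max_steps=50))
        assert tr.states[0].separation_com == 0.0
        assert tr.states[0].separation_c4 == 0.0

    def test_clashing_start_rejected(self, toy_pocket, toy_modes):
        structure, ligand, _ = toy_pocket
        with pytest.raises(ValueError):
            run_migration(structure, ligand.view(),
                          Pose(translation=np.array([0, 0, -3.5])),
                          toy_modes, MCConfig(seed=0, max_steps=10))

    def test_mobile_gates_exit_frozen_gates_do_not(self, toy_pocket,
                                                   toy_modes):
        structure, ligand, _ = toy_pocket
        exits = 0
        for seed in range(3):
            tr = run_migration(structure, ligand.view(), Pose(), toy_modes,
                               MCConfig(seed=seed, max_steps=30000))
            exits += tr.terminated_reason == "distance"
        assert exits >= 2
        frozen = structure.with_coords(structure.coords)
        frozen.flexible_residues = set()
        for seed in range(3):
            tr = run_migration(frozen, ligand.view(), Pose(), None,
                               MCConfig(seed=seed, mode_amp_max=0.0,
                                        max_steps=8000))
            assert tr.terminated_reason == "max_steps"
            assert max(s.separation_com for s in tr.states) < 8.0


class TestGateOpeningMonotonicity:
    def test_wider_gate_opening_never_reduces_exits(self):
        from exopath.elasticmodes import anm_modes
        fractions = []
        for opening in (0.5, 1.8, 3.0):
            spec = ToyPocketSpec(gate_opening=opening)
            s, l, a = make_toy_pocket(spec, certify=False)
            modes = anm_modes(s, toy_anm_config())
            exits = sum(
                run_migration(s, l.view(), Pose(), modes,
                              MCConfig(seed=k, max_steps=12000)
                              ).terminated_reason == "distance"
                for k in range(6))
            fractions.append(exits / 6)
        assert fractions == sorted(fractions)
        assert fractions[-1] > fractions[0]


class TestProfile:
    def test_single_state_single_bin(self, toy_pocket, toy_modes):
        structure, ligand, _ = toy_pocket
        tr = run_migration(structure, ligand.view(), Pose(), toy_modes,
                           MCConfig(seed=0, max_steps=0))
        prof = energy_distance_profile([tr])
        assert len(prof) == 1
        assert prof["count"].item() == 1

    def test_counts_sum_to_accepted_states(self, toy_pocket, toy_modes):
        structure, ligand, _ = toy_pocket
        trs = [run_migration(structure, ligand.view(), Pose(), toy_modes,
                             MCConfig(seed=s, max_steps=500))
               for s in range(2)]
        prof = energy_distance_profile(trs)
        total = sum(sum(1 for st in t.states if st.accepted) for t in trs)
        assert prof["count"].sum() == total

    def test_cavity_well_produces_dwell_bin(self):
        deep = ToyPocketSpec(cavity_well_depth=3.6)
        s, l, a = make_toy_pocket(deep, certify=False)
        from exopath.elasticmodes import anm_modes
        modes = anm_modes(s, TOY_ANM)
        trs = [run_migration(s, l.view(), Pose(), modes,
                             MCConfig(seed=k, max_steps=30000))
               for k in range(6)]
        prof = energy_distance_profile(trs)
        dwell = prof[prof.dwell & (prof.separation_bin > a.barrier_z - 2)
                     & (prof.separation_bin < 14.0)]
        assert len(dwell) >= 1

        flat = ToyPocketSpec(cavity_well_depth=0.0)
        s0, l0, a0 = make_toy_pocket(flat, certify=False)
        modes0 = anm_modes(s0, TOY_ANM)
        trs0 = [run_migration(s0, l0.view(), Pose(), modes0,
                              MCConfig(seed=k, max_steps=30000))
                for k in range(6)]
        prof0 = energy_distance_profile(trs0)
        dwell0 = prof0[prof0.dwell & (prof0.separation_bin > a0.barrier_z - 2)
                       & (prof0.separation_bin < 14.0)]
        assert len(dwell0) == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            energy_distance_profile([])
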