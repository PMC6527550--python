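"""Metropolis Monte-Carlo ligand migration out of the pocket.

Each step perturbs the ligand by a random translation (uniform in a ball)
and rotation (uniform axis, bounded angle), optionally displaces the
receptor backbone along one of the lowest elastic modes, lets the gate side
chains pick the best of a handful of trial torsion angles, optionally
relaxes the pose, and accepts or rejects the move by the Metropolis
criterion at temperature kT.  A trajectory terminates when both the
ring-centroid and the C4-OH-marker separations from their bound positions
exceed the termination distance (default 15 Å), or at the step budget.

The binding-energy-vs-separation profile of an ensemble of trajectories,
with its local-minimum "dwell" bins, is the diagnostic for transient
cavity binding along the exit route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .elasticmodes import ModeSet, displace_structure
from .energymodel import EnergyParams, LigandView, minimize_pose
from .structmodel import Pose, Structure

__all__ = ["MCConfig", "MigrationState", "Trajectory", "mc_step",
           "run_migration", "energy_distance_profile", "metropolis_accept"]


@dataclass
class MCConfig:
    t_max: float = 1.0           # Å, max translation per step
    rot_max: float = 20.0        # deg, max rotation per step
    kT: float = 1.2              # kcal/mol
    mode_amp_max: float = 0.5    # Å, backbone mode displacement bound
    n_low_modes: int = 6         # lowest modes sampled
    gate_trials: int = 5         # torsion angles tried per gate per step
    minimize: bool = False
    max_steps: int = 30000
    d_term: float = 15.0         # Å, termination separation
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.t_max, self.rot_max, self.kT) <= 0:
            raise ValueError("t_max, rot_max and kT must be positive")


@dataclass
class MigrationState:
    pose: Pose
    gate_torsions: dict[int, float]
    receptor_offset: np.ndarray | None   # current backbone displacement field
    energy: float
    separation_com: float
    separation_c4: float
    step: int
    accepted: bool


@dataclass
class Trajectory:
    states: list[MigrationState]
    acceptance_rate: float
    terminated_reason: str               # "distance" | "max_steps"

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"step": s.step, "energy": s.energy, "sep_com": s.separation_com,
             "sep_c4": s.separation_c4, "accepted": s.accepted}
            for s in self.states])


def metropolis_accept(delta_e: float, kT: float, rng: np.random.Generator) -> bool:
    """Accept a move of energy change ΔE with probability min(1, e^(−ΔE/kT))."""
    if delta_e <= 0.0:
        return True
    return bool(rng.random() < np.exp(-delta_e / kT))


_SIXTH_ROOT_2 = 2.0 ** (1.0 / 6.0)


class _MigrationEngine:
    """Array-based receptor bookkeeping shared by all steps of one run.

    Energies computed here follow exactly the pair model of
    :func:`exopath.energymodel.interaction_energy`; the object form is only
    avoided for speed inside the step loop.
    """

    def __init__(self, structure: Structure, ligand: LigandView,
                 modes: ModeSet | None, config: MCConfig,
                 params: EnergyParams):
        self.base_structure = structure
        self.ligand = ligand
        self.modes = modes
        self.config = config
        self.params = params
        self.gate_residues = sorted(structure.flexible_residues)
        self.start_com = ligand.base_coords[:6].mean(axis=0)
        self.start_c4 = ligand.base_coords[7] if len(ligand.base_coords) > 7 \
            else self.start_com
        self.rc0 = structure.coords
        self.radii = structure.radii
        self.polar = np.array([a.polar for a in structure.atoms])
        axes = structure.metadata.get("gate_axes", {})
        res_map = structure.residue_atom_indices()
        self.gate_info = {}
        for g in self.gate_residues:
            pivot, axis, chain = axes[g]
            idx = res_map[(chain, g)]
            self.gate_info[g] = (idx[1:], np.asarray(pivot, float),
                                 np.asarray(axis, float))
        # precompute mode displacement fields at unit max-node amplitude
        self.mode_fields = []
        if modes is not None:
            for k in range(modes.n_modes):
                disp = displace_structure(structure, modes, k, 1.0)
                self.mode_fields.append(disp.coords - self.rc0)

    def receptor_coords(self, offset: np.ndarray | None,
                        torsions: dict[int, float]) -> np.ndarray:
        rc = self.rc0 if offset is None else self.rc0 + offset
        if torsions:
            rc = rc.copy()
            for g, ang in torsions.items():
                idx, pivot, axis = self.gate_info[g]
                rot = Rotation.from_rotvec(np.deg2rad(ang) * axis)
                rc[idx] = rot.apply(rc[idx] - pivot) + pivot
        return rc

    def _pair_energy(self, rc: np.ndarray, rsel: np.ndarray,
                     lig: np.ndarray) -> float:
        p = self.params
        diff = rc[:, None, :] - lig[None, :, :]
        r = np.sqrt(np.sum(diff * diff, axis=2))
        if np.any(r == 0.0):
            raise FloatingPointError("coincident beads")
        within = r < p.cutoff
        if not np.any(within):
            return 0.0
        sigma = p.sigma_scale * (self.radii[rsel][:, None]
                                 + self.ligand.radii[None, :]) / _SIXTH_ROOT_2
        sr6 = np.where(within, (sigma / np.where(within, r, 1.0)) ** 6, 0.0)
        e = float(np.sum(4.0 * p.epsilon * (sr6 * sr6 - sr6)))
        pp = self.polar[rsel][:, None] * self.ligand.polar[None, :]
        if np.any(pp > 0):
            g = np.zeros_like(r)
            g[r < p.r_hb] = 1.0
            mid = (r >= p.r_hb) & (r < p.r_hb_off)
            t = (r[mid] - p.r_hb) / (p.r_hb_off - p.r_hb)
            g[mid] = 0.5 * (1.0 + np.cos(np.pi * t))
            e -= p.polar_strength * float(np.sum(pp * g * within))
        return e

    def energy(self, offset, torsions, pose: Pose) -> float:
        rc = self.receptor_coords(offset, torsions)
        lig = self.ligand.place(pose)
        return self._pair_energy(rc, np.arange(len(rc)), lig)

    def gate_energy(self, g: int, angle: float, offset, lig: np.ndarray
                    ) -> float:
        """Interaction of one gate's mobile beads with the ligand."""
        return float(self.gate_energy_batch(g, np.array([angle]), offset, lig)[0])

    def gate_energy_batch(self, g: int, angles_deg: np.ndarray, offset,
                          lig: np.ndarray) -> np.ndarray:
        """Gate-ligand energies for several trial torsions at once
        (Rodrigues rotation about the gate's fixed axis)."""
        idx, pivot, axis = self.gate_info[g]
        rc = self.rc0[idx] if offset is None else self.rc0[idx] + offset[idx]
        v = rc - pivot
        th = np.deg2rad(np.asarray(angles_deg, float))[:, None, None]
        k = axis
        kxv = np.cross(np.broadcast_to(k, v.shape), v)
        kdv = (v @ k)[:, None] * k
        rot = (v[None] * np.cos(th) + kxv[None] * np.sin(th)
               + kdv[None] * (1.0 - np.cos(th)))
        coords = rot + pivot                     # (n_ang, n_beads, 3)
        p = self.params
        diff = coords[:, :, None, :] - lig[None, None, :, :]
        r = np.sqrt(np.sum(diff * diff, axis=3))
        within = r < p.cutoff
        sigma = p.sigma_scale * (self.radii[idx][:, None]
                                 + self.ligand.radii[None, :]) / _SIXTH_ROOT_2
        sr6 = np.where(within, (sigma[None] / np.where(within, r, 1.0)) ** 6, 0.0)
        e = np.sum(4.0 * p.epsilon * (sr6 * sr6 - sr6), axis=(1, 2))
        pp = self.polar[idx][:, None] * self.ligand.polar[None, :]
        if np.any(pp > 0):
            gsw = np.zeros_like(r)
            gsw[r < p.r_hb] = 1.0
            mid = (r >= p.r_hb) & (r < p.r_hb_off)
            t = (r[mid] - p.r_hb) / (p.r_hb_off - p.r_hb)
            gsw[mid] = 0.5 * (1.0 + np.cos(np.pi * t))
            e = e - p.polar_strength * np.sum(pp[None] * gsw * within, axis=(1, 2))
        return e

    def ligand_near_gates(self, lig: np.ndarray, margin: float = 8.0) -> bool:
        for g, (idx, pivot, axis) in self.gate_info.items():
            if np.linalg.norm(lig[:6].mean(axis=0) - pivot) < margin:
                return True
        return False

    def separations(self, pose: Pose) -> tuple[float, float]:
        coords = self.ligand.place(pose)
        com = coords[:6].mean(axis=0)
        c4 = coords[7] if len(coords) > 7 else com
        return (float(np.linalg.norm(com - self.start_com)),
                float(np.linalg.norm(c4 - self.start_c4)))


def mc_step(state: MigrationState, engine: _MigrationEngine,
            rng: np.random.Generator) -> tuple[MigrationState, bool]:
    """One perturbation-adjustment-Metropolis cycle.

    Proposal: ligand translation uniform in a ball of radius t_max and
    rotation about a uniform axis with angle uniform in [0, rot_max]; then a
    backbone displacement along one uniformly chosen low mode with amplitude
    uniform in ±mode_amp_max; then each gate picks the best of
    ``gate_trials`` random torsion angles; then optional minimisation.
    Rejected proposals return the prior state unchanged.
    """
    cfg = engine.config
    # ligand rigid-body perturbation
    while True:
        u = rng.uniform(-1, 1, 3)
        if np.dot(u, u) <= 1.0:
            break
    dt = u * cfg.t_max
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    ang = rng.uniform(0, np.deg2rad(cfg.rot_max))
    pose = state.pose.compose_rotation(axis * ang)
    pose = Pose(pose.rotation, pose.translation + dt, pose.torsions)

    # backbone mode displacement (precomputed unit fields)
    offset = state.receptor_offset
    if engine.mode_fields and cfg.mode_amp_max > 0:
        k = int(rng.integers(0, min(cfg.n_low_modes, len(engine.mode_fields))))
        amp = rng.uniform(-cfg.mode_amp_max, cfg.mode_amp_max)
        offset = amp * engine.mode_fields[k]

    # gate torsion trial: best of k random angles per gate (gate-local
    # energies; gates interact with the ligand, not with each other)
    torsions = dict(state.gate_torsions)
    if engine.gate_residues and cfg.gate_trials > 0:
        lig = engine.ligand.place(pose)
        if engine.ligand_near_gates(lig):
            tau_max = engine.base_structure.metadata.get("gate_max_torsion",
                                                         100.0)
            for g in engine.gate_residues:
                angles = np.concatenate([[torsions.get(g, 0.0)],
                                         rng.uniform(0, tau_max,
                                                     cfg.gate_trials)])
                es = engine.gate_energy_batch(g, angles, offset, lig)
                torsions[g] = float(angles[int(np.argmin(es))])

    if cfg.minimize:
        st = engine.base_structure.with_coords(
            engine.receptor_coords(offset, torsions))
        try:
            pose, _, _ = minimize_pose(st, engine.ligand, pose, engine.params,
                                       max_steps=15, step_size=0.1)
        except FloatingPointError:
            pass

    try:
        e_new = engine.energy(offset, torsions, pose)
    except FloatingPointError:
        e_new = np.inf
    if not np.isfinite(e_new):
        return state, False                      # auto-reject, logged upstream
    if not metropolis_accept(e_new - state.energy, cfg.kT, rng):
        return state, False
    sep_com, sep_c4 = engine.separations(pose)
    new = MigrationState(pose, torsions, offset, float(e_new), sep_com,
                         sep_c4, state.step + 1, True)
    return new, True


def run_migration(structure: Structure, ligand: LigandView, start_pose: Pose,
                  modes: ModeSet | None, config: MCConfig | None = None,
                  params: EnergyParams | None = None) -> Trajectory:
    """Iterate mc_step until both separations exceed d_term or max_steps."""
    config = config or MCConfig()
    params = params or EnergyParams()
    engine = _MigrationEngine(structure, ligand, modes, config, params)
    rng = np.random.default_rng(config.seed)
    e0 = engine.energy(None, {}, start_pose)
    from .energymodel import clash_count
    if clash_count(structure, ligand, start_pose, params) > 0:
        raise ValueError("start pose clashes with the receptor")
    sep_com, sep_c4 = engine.separations(start_pose)
    state = MigrationState(start_pose, {}, None, float(e0), sep_com, sep_c4,
                           0, True)
    states = [state]
    n_acc = 0
    n_prop = 0
    reason = "max_steps"
    for _ in range(config.max_steps):
        state, acc = mc_step(state, engine, rng)
        n_prop += 1
        if acc:
            n_acc += 1
            states.append(state)
            if (state.separation_com > config.d_term
                    and state.separation_c4 > config.d_term):
                reason = "distance"
                break
    return Trajectory(states, n_acc / max(n_prop, 1), reason)


def energy_distance_profile(trajectories: list[Trajectory],
                            bin_width: float = 0.5,
                            dwell_prominence: float = 0.75) -> pd.DataFrame:
    """Energy statistics and visit counts per separation bin, with dwell flags.

    A bin is flagged as a dwell (transient binding site) when its low-energy
    envelope (10th-percentile energy, which isolates an off-path attractive
    site from the bulk of same-separation visits that a bin mean would dilute
    it with) is a local minimum of at least ``dwell_prominence`` kcal/mol
    topographic prominence, and its visit count exceeds the median count of
    its four nearest neighbouring bins.
    """
    if not trajectories:
        raise ValueError("no trajectories given")
    seps, energies = [], []
    for tr in trajectories:
        for st in tr.states:
            if st.accepted:
                seps.append(st.separation_com)
                energies.append(st.energy)
    seps = np.asarray(seps)
    energies = np.asarray(energies)
    bins = np.floor(seps / bin_width).astype(int)
    order = np.unique(bins)
    mean_e = np.array([energies[bins == b].mean() for b in order])
    low_e = np.array([np.quantile(energies[bins == b], 0.10) for b in order])
    counts = np.array([int((bins == b).sum()) for b in order])
    dwell = np.zeros(len(order), dtype=bool)
    if len(order) >= 3:
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(-low_e, prominence=dwell_prominence)
        for i in peaks:
            # abundance guard: a genuine dwell is a heavily visited bin,
            # not a sparsely sampled tail fluctuation
            if counts[i] > np.median(counts):
                dwell[i] = True
    return pd.DataFrame({
        "separation_bin": (order + 0.5) * bin_width,
        "mean_energy": mean_e,
        "low_energy": low_e,
        "count": counts,
        "dwell": dwell,
    })
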