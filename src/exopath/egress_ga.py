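"""Multi-objective genetic search for ligand exit paths.

A candidate is a fixed-length chain of rigid-body waypoint poses (the first
pinned to the bound pose, consecutive translation steps bounded), evaluated
on two objectives: minimise the summed clash count over waypoints and
maximise the reach (largest separation of the ring centroid from its bound
position).  NSGA-II (non-dominated sorting, binary tournament on
rank/crowding, one-point crossover over waypoint index, Gaussian pose
mutation) evolves a Pareto front; the front's clash-vs-separation profile is
the diagnostic that distinguishes a sealed receptor (no zero-clash bin
beyond the barrier) from one whose gates have moved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .energymodel import EnergyParams, LigandView, apply_gate_torsions
from .structmodel import Pose, Structure

__all__ = ["GAConfig", "PathCandidate", "evolve_exit_paths",
           "clash_vs_separation", "pareto_front"]


def orientation_probe_set() -> list[Rotation]:
    """A coarse, well-spread set of ligand orientations used by grid scans
    and by the waypoint repair operator."""
    rots = [Rotation.identity()]
    for axis in ([1, 0, 0], [0, 1, 0], [1, 1, 0], [1, -1, 0]):
        for angdeg in (45, 90, 135):
            rots.append(Rotation.from_rotvec(
                np.deg2rad(angdeg) * np.asarray(axis, float)
                / np.linalg.norm(axis)))
    for spin in (30, 60):
        rots.append(Rotation.from_rotvec([0, 0, np.deg2rad(spin)]))
    return rots


@dataclass
class GAConfig:
    population: int = 64
    generations: int = 240
    waypoint_count: int = 16
    step_max: float = 1.5            # Å, bound on consecutive translations
    sigma_translation: float = 0.6   # Å, mutation scale
    sigma_rotation: float = 20.0     # deg
    sigma_torsion: float = 25.0      # deg (gate genes, when enabled)
    mutation_prob: float = 0.3
    repair_prob: float = 0.5         # chance of local repair per offspring
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 10:
            raise ValueError("population must be at least 10")
        if self.waypoint_count < 3:
            raise ValueError("need at least 3 waypoints")


@dataclass
class PathCandidate:
    """An evaluated exit-path candidate."""

    translations: np.ndarray          # (n_wp, 3) ring-centroid positions
    rotations: np.ndarray             # (n_wp, 4) quaternions
    gate_torsions: np.ndarray | None  # (n_wp, n_gates) degrees or None
    clash_counts: np.ndarray          # (n_wp,)
    separations: np.ndarray           # (n_wp,) Å from the start centroid

    @property
    def total_clash(self) -> int:
        return int(self.clash_counts.sum())

    @property
    def reach(self) -> float:
        return float(self.separations.max())

    @property
    def free_prefix_reach(self) -> float:
        """Largest separation attained before the first clashing waypoint —
        the distance the ligand actually gets without steric conflict."""
        bad = np.flatnonzero(self.clash_counts > 0)
        k = bad[0] if bad.size else len(self.separations)
        return float(self.separations[:k].max(initial=0.0))

    def waypoints(self) -> list[Pose]:
        return [Pose(q, t) for q, t in zip(self.rotations, self.translations)]


class _Evaluator:
    """Clash evaluation with the gate beads split out so that per-waypoint
    gate torsions do not force a receptor rebuild."""

    def __init__(self, structure: Structure, ligand: LigandView,
                 params: EnergyParams, gate_residues: list[int] | None):
        self.params = params
        self.ligand = ligand
        self.gate_residues = gate_residues or []
        res_map = structure.residue_atom_indices()
        gate_idx = np.concatenate(
            [res_map[(ax[2], g)] for g, ax in
             ((g, structure.metadata["gate_axes"][g]) for g in self.gate_residues)]
        ) if self.gate_residues else np.zeros(0, dtype=int)
        all_idx = np.arange(len(structure))
        static_idx = np.setdiff1d(all_idx, gate_idx)
        coords = structure.coords
        radii = structure.radii
        self.static_tree = cKDTree(coords[static_idx]) if static_idx.size else None
        self.static_radii = radii[static_idx]
        self.structure = structure
        self.r_search = params.overlap_factor * (radii.max() + ligand.radii.max())
        # fast path: with a uniform receptor radius the clash threshold only
        # depends on the ligand bead, so pair counting reduces to fixed-radius
        # ball counts
        self.uniform_r = (self.static_radii.size == 0
                          or np.ptp(self.static_radii) < 1e-12)

    def gate_coords(self, torsions: np.ndarray | None):
        if not self.gate_residues:
            return None, None
        if not hasattr(self, "_gate_idx"):
            res_map = self.structure.residue_atom_indices()
            self._gate_idx = np.concatenate(
                [res_map[("R", g)] for g in self.gate_residues])
            self._gate_rest = (self.structure.coords[self._gate_idx],
                               self.structure.radii[self._gate_idx])
        if torsions is None:
            return self._gate_rest
        st = apply_gate_torsions(self.structure,
                                 dict(zip(self.gate_residues, torsions)))
        return st.coords[self._gate_idx], self._gate_rest[1]

    def clash(self, lig_coords: np.ndarray, gate_xyz, gate_radii) -> int:
        count = 0
        if self.static_tree is not None:
            if self.uniform_r:
                r0 = self.static_radii[0] if self.static_radii.size else 0.0
                for rl in np.unique(self.ligand.radii):
                    sel = self.ligand.radii == rl
                    thr = self.params.overlap_factor * (r0 + rl)
                    count += int(np.sum(self.static_tree.query_ball_point(
                        lig_coords[sel], thr, return_length=True)))
            else:
                nb = self.static_tree.query_ball_point(lig_coords, self.r_search)
                data = self.static_tree.data
                for j, idx in enumerate(nb):
                    if not idx:
                        continue
                    idx = np.asarray(idx)
                    d = np.linalg.norm(data[idx] - lig_coords[j], axis=1)
                    thr = self.params.overlap_factor * (
                        self.static_radii[idx] + self.ligand.radii[j])
                    count += int(np.sum(d < thr))
        if gate_xyz is not None and len(gate_xyz):
            d = np.linalg.norm(gate_xyz[:, None, :] - lig_coords[None, :, :], axis=2)
            thr = self.params.overlap_factor * (
                gate_radii[:, None] + self.ligand.radii[None, :])
            count += int(np.sum(d < thr))
        return count


def _evaluate(T: np.ndarray, Q: np.ndarray, G: np.ndarray | None,
              ev: _Evaluator, base: np.ndarray, start_center: np.ndarray
              ) -> PathCandidate:
    n_wp = len(T)
    clashes = np.zeros(n_wp, dtype=int)
    seps = np.linalg.norm(T - start_center, axis=1)
    for w in range(n_wp):
        rot = Rotation.from_quat(Q[w])
        lig = rot.apply(base) + T[w]
        gx, gr = ev.gate_coords(G[w] if G is not None else None)
        clashes[w] = ev.clash(lig, gx, gr)
    return PathCandidate(T.copy(), Q.copy(), None if G is None else G.copy(),
                         clashes, seps)


def _nondominated_sort(objs: np.ndarray) -> list[np.ndarray]:
    """Fast non-dominated sort on rows of (minimise, minimise)."""
    n = len(objs)
    le = (objs[:, None, :] <= objs[None, :, :]).all(axis=2)
    lt = (objs[:, None, :] < objs[None, :, :]).any(axis=2)
    dominates = le & lt                      # [i, j]: i dominates j
    dom_count = dominates.sum(axis=0)
    fronts: list[np.ndarray] = []
    assigned = np.zeros(n, dtype=bool)
    current = np.flatnonzero(dom_count == 0)
    while current.size:
        fronts.append(current)
        assigned[current] = True
        dom_count = dom_count - dominates[current].sum(axis=0)
        current = np.flatnonzero((dom_count == 0) & ~assigned)
    return fronts


def _crowding(objs: np.ndarray, front: np.ndarray) -> np.ndarray:
    dist = np.zeros(len(front))
    for m in range(objs.shape[1]):
        order = front[np.argsort(objs[front, m])]
        rng_m = objs[order[-1], m] - objs[order[0], m]
        pos = {idx: k for k, idx in enumerate(order)}
        for k, idx in enumerate(order):
            if k == 0 or k == len(order) - 1:
                dist[np.where(front == idx)[0][0]] = np.inf
            elif rng_m > 0:
                dist[np.where(front == idx)[0][0]] += (
                    objs[order[k + 1], m] - objs[order[k - 1], m]) / rng_m
    return dist


def pareto_front(cands: list[PathCandidate]) -> list[PathCandidate]:
    """Non-dominated subset on (total_clash, −reach)."""
    objs = np.array([[c.total_clash, -c.reach] for c in cands], dtype=float)
    fronts = _nondominated_sort(objs)
    return [cands[i] for i in fronts[0]]


def _repair_steps(T: np.ndarray, start: np.ndarray, step_max: float) -> np.ndarray:
    T = T.copy()
    T[0] = start
    for i in range(1, len(T)):
        step = T[i] - T[i - 1]
        norm = np.linalg.norm(step)
        if norm > step_max:
            T[i] = T[i - 1] + step * (step_max / norm)
    return T


def evolve_exit_paths(structure: Structure, ligand: LigandView,
                      start_pose: Pose, receptor_mode: str = "rigid",
                      ga: GAConfig | None = None,
                      params: EnergyParams | None = None,
                      exit_direction: np.ndarray | None = None
                      ) -> list[PathCandidate]:
    """Evolve exit-path candidates and return the final Pareto front.

    ``receptor_mode``: "rigid" (frozen coordinates), "gate-torsions" (gate
    torsion angles become per-waypoint genes), or "mode-displaced" (the
    caller passes an already displaced structure; treated as rigid here).
    ``exit_direction`` seeds part of the initial population with straight
    probes (default +z); the rigid-blocked verdict cannot be affected by
    seeding since it reflects path feasibility, not search effort.
    """
    ga = ga or GAConfig()
    params = params or EnergyParams()
    if receptor_mode not in ("rigid", "gate-torsions", "mode-displaced"):
        raise ValueError(f"unknown receptor mode {receptor_mode!r}")
    use_gates = receptor_mode == "gate-torsions"
    gate_res = sorted(structure.flexible_residues) if use_gates else []
    ev = _Evaluator(structure, ligand, params,
                    gate_res if use_gates else sorted(structure.flexible_residues))
    rng = np.random.default_rng(ga.seed)
    base = ligand.base_coords - ligand.base_coords[:6].mean(axis=0)
    start_center = ligand.base_coords[:6].mean(axis=0) + start_pose.translation
    # verify the start pose is clash-free
    rot0 = Rotation.from_quat(start_pose.rotation)
    lig0 = rot0.apply(base) + start_center
    gx0, gr0 = ev.gate_coords(np.zeros(len(gate_res)) if use_gates else None)
    if ev.clash(lig0, gx0, gr0) > 0:
        raise ValueError("start pose clashes with the receptor")
    n_wp, n_pop = ga.waypoint_count, ga.population
    direction = np.array([0.0, 0.0, 1.0]) if exit_direction is None else (
        np.asarray(exit_direction, float) / np.linalg.norm(exit_direction))

    def random_individual(probe: bool):
        if probe:
            # straight probe in a random direction within a wide cone about
            # the exit direction, so off-axis corridors are also explored
            d = direction + rng.normal(0, 0.55, 3)
            d = d / np.linalg.norm(d)
            extent = rng.uniform(0.3, 1.0) * ga.step_max
            steps = d * extent + rng.normal(0, 0.25, (n_wp, 3))
        else:
            steps = rng.normal(0, 0.5 * ga.step_max, (n_wp, 3))
        T = start_center + np.cumsum(np.vstack([np.zeros(3), steps[1:]]), axis=0)
        T = _repair_steps(T, start_center, ga.step_max)
        Q = np.tile(start_pose.rotation, (n_wp, 1))
        for w in range(1, n_wp):
            rv = rng.normal(0, np.deg2rad(ga.sigma_rotation), 3)
            Q[w] = (Rotation.from_rotvec(rv) * Rotation.from_quat(Q[w - 1])).as_quat()
        G = rng.uniform(0, 90, (n_wp, len(gate_res))) if use_gates else None
        return T, Q, G

    pop = [random_individual(probe=i % 2 == 0) for i in range(n_pop)]
    cands = [_evaluate(T, Q, G, ev, base, start_center) for T, Q, G in pop]

    # selection objectives: total clash and the clash-free prefix reach (the
    # latter rewards candidates that actually thread constrictions; the
    # returned front is recomputed under the reporting objectives)
    def objs_of(cs):
        return np.array([[c.total_clash, -c.free_prefix_reach] for c in cs],
                        dtype=float)

    for _ in range(ga.generations):
        objs = objs_of(cands)
        fronts = _nondominated_sort(objs)
        rank = np.empty(len(cands), dtype=int)
        crowd = np.empty(len(cands))
        for r, f in enumerate(fronts):
            rank[f] = r
            crowd[f] = _crowding(objs, f)

        def tournament():
            i, j = rng.integers(0, len(cands), 2)
            if rank[i] != rank[j]:
                return i if rank[i] < rank[j] else j
            return i if crowd[i] >= crowd[j] else j

        offspring = []
        while len(offspring) < n_pop:
            a, b = tournament(), tournament()
            Ta, Qa, Ga = pop[a]
            Tb, Qb, Gb = pop[b]
            cut = int(rng.integers(1, n_wp))
            T = np.vstack([Ta[:cut], Tb[cut:]])
            Q = np.vstack([Qa[:cut], Qb[cut:]])
            G = (np.vstack([Ga[:cut], Gb[cut:]]) if Ga is not None else None)
            # coherent tail shift: move every waypoint from a random index on
            if rng.random() < 0.3:
                w0 = int(rng.integers(1, n_wp))
                T[w0:] = T[w0:] + rng.normal(0, ga.sigma_translation, 3)
            # mutation
            for w in range(1, n_wp):
                if rng.random() < ga.mutation_prob:
                    T[w] = T[w] + rng.normal(0, ga.sigma_translation, 3)
                if rng.random() < ga.mutation_prob:
                    rv = rng.normal(0, np.deg2rad(ga.sigma_rotation), 3)
                    Q[w] = (Rotation.from_rotvec(rv)
                            * Rotation.from_quat(Q[w])).as_quat()
                if G is not None and rng.random() < ga.mutation_prob:
                    G[w] = np.clip(G[w] + rng.normal(0, ga.sigma_torsion,
                                                     G.shape[1]), 0, 110)
            T = _repair_steps(T, start_center, ga.step_max)
            offspring.append((T, Q, G))
        off_cands = []
        probe_rots = orientation_probe_set()
        for T, Q, G in offspring:
            cand = _evaluate(T, Q, G, ev, base, start_center)
            if rng.random() < ga.repair_prob and cand.clash_counts.any():
                # memetic step: re-orient (and nudge) the first clashing
                # waypoint, keeping the option with the fewest clashes
                w = int(np.flatnonzero(cand.clash_counts > 0)[0])
                best = (cand.clash_counts[w], Q[w].copy(), T[w].copy())
                offsets = np.array([[0, 0, 0], [0.35, 0, 0], [-0.35, 0, 0],
                                    [0, 0.35, 0], [0, -0.35, 0]])
                done = False
                for off in offsets:
                    t_try = T[w] + off
                    if (np.linalg.norm(t_try - T[w - 1]) > ga.step_max or
                        (w + 1 < len(T)
                         and np.linalg.norm(T[w + 1] - t_try) > ga.step_max)):
                        continue
                    for rot in probe_rots:
                        lig = rot.apply(base) + t_try
                        gx, gr = ev.gate_coords(G[w] if G is not None else None)
                        c = ev.clash(lig, gx, gr)
                        if c < best[0]:
                            best = (c, rot.as_quat(), t_try)
                        if c == 0:
                            done = True
                            break
                    if done:
                        break
                if best[0] < cand.clash_counts[w]:
                    Q[w], T[w] = best[1], best[2]
                    cand = _evaluate(T, Q, G, ev, base, start_center)
            off_cands.append(cand)
        # environmental selection over parents + offspring (elitist)
        all_pop = pop + offspring
        all_cands = cands + off_cands
        objs = objs_of(all_cands)
        fronts = _nondominated_sort(objs)
        new_pop, new_cands = [], []
        for f in fronts:
            if len(new_pop) + len(f) <= n_pop:
                chosen = f
            else:
                cd = _crowding(objs, f)
                chosen = f[np.argsort(-cd)][: n_pop - len(new_pop)]
            for i in chosen:
                new_pop.append(all_pop[i])
                new_cands.append(all_cands[i])
            if len(new_pop) == n_pop:
                break
        pop, cands = new_pop, new_cands
    return pareto_front(cands)


def clash_vs_separation(front: list[PathCandidate], bin_width: float = 0.5
                        ) -> pd.DataFrame:
    """Minimum clash count per separation bin over all front waypoints."""
    if not front:
        raise ValueError("empty Pareto front")
    seps = np.concatenate([c.separations for c in front])
    clashes = np.concatenate([c.clash_counts for c in front])
    bins = np.floor(seps / bin_width).astype(int)
    rows = []
    for b in np.unique(bins):
        mask = bins == b
        rows.append({"separation_bin": (b + 0.5) * bin_width,
                     "min_clash": int(clashes[mask].min()),
                     "n_waypoints": int(mask.sum())})
    return pd.DataFrame(rows)


def exit_found(front: list[PathCandidate], exit_separation: float) -> bool:
    """True when the front holds a zero-clash candidate whose clash-free
    waypoints reach beyond ``exit_separation``."""
    for c in front:
        free = c.clash_counts == 0
        if c.total_clash == 0 and c.separations[free].max(initial=0.0) >= exit_separation:
            return True
    return False
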