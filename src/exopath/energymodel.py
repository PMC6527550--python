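"""Simplified receptor–ligand interaction energy and clash scoring.

The model is a 12-6 Lennard-Jones term over heavy-atom pairs within a cutoff
plus a short-range switched attraction between flagged donor/acceptor beads
(a directionless stand-in for active-site hydrogen-bond networks).  A pair
"clashes" when its distance falls below ``overlap_factor`` times the sum of
vdW radii.  A small steepest-descent minimiser relaxes the ligand rigid-body
pose and, optionally, gate torsions.

Units: Å, kcal/mol, degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structmodel import Pose, Structure, geometric_center

__all__ = [
    "EnergyParams",
    "LigandView",
    "clash_count",
    "interaction_energy",
    "minimize_pose",
    "apply_gate_torsions",
]

# 2^(1/6): LJ sigma such that the pair minimum sits at the radii sum
_SIXTH_ROOT_2 = 2.0 ** (1.0 / 6.0)


@dataclass
class EnergyParams:
    """Parameters of the bead-bead interaction model.

    ``sigma_scale`` places the LJ minimum at ``sigma_scale * (r_i + r_j)``;
    with the default of 1.0 two beads rest at their radii sum.  ``r_hb`` and
    ``r_hb_off`` bound the cosine switch of the polar well.
    """

    # kcal/mol, LJ well depth per pair.  Kept small for pseudo-bead walls so
    # that the summed dispersive tails of a deep pocket (hundreds of pairs)
    # do not swamp the designed polar binding sites; steric repulsion is
    # unaffected since the r^-12 wall towers over kT at any epsilon here.
    epsilon: float = 0.02
    sigma_scale: float = 1.0        # dimensionless, on the radii sum
    polar_strength: float = 1.5     # kcal/mol per donor-acceptor pair
    overlap_factor: float = 0.7     # clash when r < overlap_factor*(ri+rj)
    cutoff: float = 12.0            # Å, non-bonded cutoff
    r_hb: float = 3.0               # Å, polar well flat region
    r_hb_off: float = 3.5           # Å, polar well end of switch

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.sigma_scale <= 0:
            raise ValueError("epsilon and sigma_scale must be positive")
        if not (0.0 < self.overlap_factor <= 1.0):
            raise ValueError("overlap_factor must be in (0, 1]")
        if self.cutoff <= self.sigma_scale * 2 * 1.8:
            raise ValueError("cutoff must exceed the largest pair sigma")


@dataclass
class LigandView:
    """Ligand beads in a body frame, with per-bead radii and polar scales.

    ``base_coords`` are the reference coordinates; a :class:`Pose` maps them
    into the receptor frame by rotating about the reference centroid.
    """

    base_coords: np.ndarray
    radii: np.ndarray
    polar: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.base_coords = np.asarray(self.base_coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.polar = np.asarray(self.polar, dtype=float)
        self.pivot = self.base_coords.mean(axis=0)

    def place(self, pose: Pose) -> np.ndarray:
        return pose.apply(self.base_coords, self.pivot)


def _receptor_arrays(structure: Structure):
    return structure.coords, structure.radii, np.array(
        [a.polar for a in structure.atoms], dtype=float
    )


def clash_count(structure: Structure, ligand: LigandView, pose: Pose,
                params: EnergyParams, *, tree: cKDTree | None = None) -> int:
    """Number of receptor-ligand pairs closer than the overlap threshold.

    A cKDTree over the receptor accelerates the search; pass ``tree`` to
    reuse one across many poses of the same receptor.
    """
    rec_coords = structure.coords if tree is None else None
    if tree is None:
        tree = cKDTree(rec_coords)
        rec_radii = structure.radii
    else:
        rec_radii = structure.radii
    lig = ligand.place(pose)
    # conservative search radius: max possible clash threshold
    r_search = params.overlap_factor * (rec_radii.max() + ligand.radii.max())
    count = 0
    neighbours = tree.query_ball_point(lig, r_search)
    rc = tree.data
    for j, idx in enumerate(neighbours):
        if not idx:
            continue
        idx = np.asarray(idx)
        d = np.linalg.norm(rc[idx] - lig[j], axis=1)
        thr = params.overlap_factor * (rec_radii[idx] + ligand.radii[j])
        count += int(np.sum(d < thr))
    return count


def _polar_well(r: np.ndarray, params: EnergyParams) -> np.ndarray:
    """Switched well g(r): 1 below r_hb, cosine fall to 0 at r_hb_off."""
    g = np.zeros_like(r)
    g[r < params.r_hb] = 1.0
    mid = (r >= params.r_hb) & (r < params.r_hb_off)
    t = (r[mid] - params.r_hb) / (params.r_hb_off - params.r_hb)
    g[mid] = 0.5 * (1.0 + np.cos(np.pi * t))
    return g


def interaction_energy(structure: Structure, ligand: LigandView, pose: Pose,
                       params: EnergyParams) -> float:
    """Receptor-ligand energy: LJ 4ε[(σ/r)^12 − (σ/r)^6] within the cutoff
    plus −polar_strength · scale_i · scale_j · g(r) for polar pairs."""
    rec_coords, rec_radii, rec_polar = _receptor_arrays(structure)
    lig = ligand.place(pose)
    diff = rec_coords[:, None, :] - lig[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=2))
    if np.any(r == 0.0):
        raise FloatingPointError("coincident receptor and ligand beads (r = 0)")
    within = r < params.cutoff
    if not np.any(within):
        return 0.0
    sigma = params.sigma_scale * (rec_radii[:, None] + ligand.radii[None, :]) / _SIXTH_ROOT_2
    sr6 = np.where(within, (sigma / np.where(within, r, 1.0)) ** 6, 0.0)
    e_lj = float(np.sum(4.0 * params.epsilon * (sr6 * sr6 - sr6)))
    pp = rec_polar[:, None] * ligand.polar[None, :]
    e_pol = 0.0
    if np.any(pp > 0):
        g = _polar_well(r, params)
        e_pol = -params.polar_strength * float(np.sum(pp * g * within))
    return e_lj + e_pol


def apply_gate_torsions(structure: Structure, torsions: dict[int, float]) -> Structure:
    """Rotate each flexible (gate) residue's mobile beads about its stored axis.

    The generator records for every gate residue a pivot point and a unit
    rotation axis under ``metadata['gate_axes']``; the torsion (degrees)
    swings every bead of the residue except the anchor about that axis.
    """
    axes = structure.metadata.get("gate_axes", {})
    coords = structure.coords
    res_map = structure.residue_atom_indices()
    for res_index, angle in torsions.items():
        if res_index not in structure.flexible_residues:
            raise ValueError(f"residue {res_index} is not flexible")
        pivot, axis, chain = axes[res_index]
        idx = res_map[(chain, res_index)][1:]  # anchor bead stays
        rot = Rotation.from_rotvec(np.deg2rad(angle) * np.asarray(axis, dtype=float))
        coords[idx] = rot.apply(coords[idx] - np.asarray(pivot)) + np.asarray(pivot)
    out = structure.with_coords(coords)
    return out


def _pose_from_dof(pose0: Pose, x: np.ndarray) -> tuple[Pose, dict[int, float]]:
    trans = pose0.translation + x[:3]
    rot = (Rotation.from_rotvec(x[3:6]) * Rotation.from_quat(pose0.rotation)).as_quat()
    return Pose(rot, trans, pose0.torsions.copy()), {}


def minimize_pose(structure: Structure, ligand: LigandView, pose: Pose,
                  params: EnergyParams, *, gate_residues: list[int] | None = None,
                  max_steps: int = 100, step_size: float = 0.2,
                  grad_tol: float = 1e-3) -> tuple[Pose, dict[int, float], float]:
    """Steepest descent with backtracking on rigid-body DOF (+ gate torsions).

    Gradients are numerical central differences (h = 1e-4 Å for translation /
    rotation-vector components, 1e-3 deg for torsions).  Returns the relaxed
    pose, the relaxed gate torsion angles and the final energy; the energy is
    never above the starting value.
    """
    gate_residues = gate_residues or []
    n_rb, n_t = 6, len(gate_residues)
    x = np.zeros(n_rb + n_t)

    def energy_at(x: np.ndarray) -> float:
        p, _ = _pose_from_dof(pose, x[:6])
        s = structure
        if n_t:
            s = apply_gate_torsions(structure, dict(zip(gate_residues, x[6:])))
        return interaction_energy(s, ligand, p, params)

    e = energy_at(x)
    if not np.isfinite(e):
        raise FloatingPointError("non-finite energy at minimisation start")
    h = np.concatenate([np.full(6, 1e-4), np.full(n_t, 1e-3)])
    for _ in range(max_steps):
        grad = np.zeros_like(x)
        for i in range(len(x)):
            dx = np.zeros_like(x)
            dx[i] = h[i]
            grad[i] = (energy_at(x + dx) - energy_at(x - dx)) / (2 * h[i])
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError(f"non-finite gradient at step x={x}")
        gnorm = np.linalg.norm(grad)
        if gnorm < grad_tol:
            break
        step = step_size
        improved = False
        for _ in range(20):  # backtracking line search
            x_new = x - step * grad / gnorm
            e_new = energy_at(x_new)
            if np.isfinite(e_new) and e_new < e:
                x, e = x_new, e_new
                improved = True
                break
            step *= 0.5
        if not improved:
            break
    p, _ = _pose_from_dof(pose, x[:6])
    return p, dict(zip(gate_residues, x[6:])), e
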