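"""Anisotropic network model (ANM) normal modes and mode-directed displacement.

Nodes (one per residue by default, a Cα analogue; a pseudo-atom may be its
own node) are connected by harmonic springs of constant γ within a distance
cutoff.  The Hessian is assembled from the standard super-elements
−γ r̂ r̂ᵀ; its low-frequency eigenvectors approximate collective motions.
The six zero modes span rigid translations and rotations and are excluded
from the reported mode count.

A "cluster" variant groups several residues into one node (the node is the
cluster centroid and all member atoms ride along rigidly); with singleton
clusters it reduces exactly to the plain per-residue ANM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.spatial import cKDTree

from .structmodel import Structure

__all__ = ["ANMConfig", "ModeSet", "build_anm_hessian", "compute_modes",
           "structure_nodes", "anm_modes", "displace_structure"]


@dataclass
class ANMConfig:
    cutoff: float = 15.0        # Å, spring cutoff
    gamma: float = 1.0          # spring constant, arbitrary units
    n_modes: int = 10           # non-rigid modes to report
    node_selection: str = "residue"  # "residue" | "atom"

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.gamma <= 0 or self.n_modes < 1:
            raise ValueError("cutoff, gamma must be > 0 and n_modes >= 1")


@dataclass
class ModeSet:
    """Eigenvalues (ascending, rigid modes removed) and orthonormal 3N mode
    vectors; ``node_ids`` maps node -> member atom indices of the structure."""

    eigenvalues: np.ndarray
    vectors: np.ndarray              # shape (n_modes, N, 3)
    node_ids: list[np.ndarray]
    rigid_eigenvalues: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


def build_anm_hessian(nodes: np.ndarray, config: ANMConfig) -> np.ndarray:
    """Assemble the 3N×3N ANM stiffness operator.

    Off-diagonal blocks are −γ r̂ r̂ᵀ for node pairs within the cutoff;
    diagonal blocks are minus the sum of the off-diagonal blocks in their
    row, which makes the operator exactly symmetric with zero row-block sums.
    """
    nodes = np.asarray(nodes, dtype=float)
    n = len(nodes)
    if n < 2:
        raise ValueError("ANM needs at least two nodes")
    tree = cKDTree(nodes)
    pairs = tree.query_pairs(config.cutoff, output_type="ndarray")
    hess = np.zeros((3 * n, 3 * n))
    for i, j in pairs:
        rij = nodes[j] - nodes[i]
        d = np.linalg.norm(rij)
        if d == 0.0:
            raise ValueError(f"coincident nodes {i} and {j}")
        u = rij / d
        block = -config.gamma * np.outer(u, u)
        hess[3 * i:3 * i + 3, 3 * j:3 * j + 3] += block
        hess[3 * j:3 * j + 3, 3 * i:3 * i + 3] += block
        hess[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        hess[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return hess


def compute_modes(hessian: np.ndarray, n_modes: int,
                  node_ids: list[np.ndarray] | None = None,
                  rigid_tol_factor: float = 1e-8) -> ModeSet:
    """Eigen-decompose the ANM operator and report non-rigid modes.

    Rigid-body modes are identified by |λ| < rigid_tol_factor × λ_max and
    excluded.  Reported vectors are orthonormal, sorted by ascending λ, with
    the sign fixed so the first non-zero component is positive.
    """
    vals, vecs = eigh(hessian)
    lam_max = np.abs(vals).max()
    tol = rigid_tol_factor * max(lam_max, 1.0)
    rigid = np.abs(vals) < tol
    nz = ~rigid
    if nz.sum() < n_modes:
        raise ValueError(
            f"only {int(nz.sum())} non-rigid modes available, {n_modes} requested")
    order = np.argsort(vals[nz])
    vals_nr = vals[nz][order][:n_modes]
    vecs_nr = vecs[:, nz][:, order][:, :n_modes]
    n = hessian.shape[0] // 3
    modes = np.empty((n_modes, n, 3))
    for k in range(n_modes):
        v = vecs_nr[:, k]
        nz_idx = np.flatnonzero(np.abs(v) > 1e-12)
        if nz_idx.size and v[nz_idx[0]] < 0:
            v = -v
        modes[k] = v.reshape(n, 3)
    if node_ids is None:
        node_ids = [np.array([i]) for i in range(n)]
    return ModeSet(vals_nr, modes, node_ids, rigid_eigenvalues=vals[rigid])


def structure_nodes(structure: Structure, node_selection: str = "residue",
                    ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Node positions and node -> atom-index mapping for a structure.

    "residue": one node per (chain, residue) at the centroid of its backbone
    atoms (all atoms if none are flagged backbone) — the cluster variant.
    "atom": every backbone atom is its own node.
    """
    if node_selection == "atom":
        idx = np.flatnonzero(structure.backbone_mask)
        coords = structure.coords[idx]
        return coords, [np.array([i]) for i in idx]
    if node_selection != "residue":
        raise ValueError(f"unknown node selection {node_selection!r}")
    coords = structure.coords
    nodes, ids = [], []
    for _, atom_idx in structure.residue_atom_indices().items():
        bb = atom_idx[structure.backbone_mask[atom_idx]]
        members = bb if bb.size else atom_idx
        nodes.append(coords[members].mean(axis=0))
        ids.append(atom_idx)
    return np.asarray(nodes), ids


def anm_modes(structure: Structure, config: ANMConfig) -> ModeSet:
    """Convenience: nodes -> Hessian -> modes for a structure."""
    nodes, ids = structure_nodes(structure, config.node_selection)
    hess = build_anm_hessian(nodes, config)
    return compute_modes(hess, config.n_modes, node_ids=ids)


def displace_structure(structure: Structure, modes: ModeSet, mode_index: int,
                       amplitude: float) -> Structure:
    """Displace all atoms along one mode, scaled to a max-node amplitude.

    Every atom moves with its node's displacement vector; the mode is scaled
    so that the largest node displacement norm equals ``amplitude`` (Å).
    A signed amplitude selects the mode direction; amplitude 0 is identity.
    """
    shape = modes.vectors[mode_index]
    norms = np.linalg.norm(shape, axis=1)
    peak = norms.max()
    if peak == 0.0:
        raise ValueError("degenerate mode with zero displacement")
    disp_nodes = shape * (amplitude / peak)
    coords = structure.coords
    n_atoms = len(structure)
    disp_atoms = np.zeros((n_atoms, 3))
    for node_disp, atom_idx in zip(disp_nodes, modes.node_ids):
        disp_atoms[atom_idx] = node_disp
    return structure.with_coords(coords + disp_atoms)


def modes_to_tsv(modes: ModeSet, path) -> None:
    """Serialise mode shapes as TSV (node, mode, dx, dy, dz)."""
    with open(path, "w") as fh:
        fh.write("node\tmode\tdx\tdy\tdz\n")
        for k in range(modes.n_modes):
            for i, v in enumerate(modes.vectors[k]):
                fh.write(f"{i}\t{k}\t{v[0]:.6f}\t{v[1]:.6f}\t{v[2]:.6f}\n")
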