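"""Synthetic inputs for every pipeline stage: toy pocket receptors, ring-bead
ligands in named conformers, inhibition-rate tables and SPR dilution series.

The toy pocket emulates, at pseudo-atom scale, the features that make a deep
pocket-shaped exo-hydrolase interesting for product egress: a binding well at
the bottom of a ~13 Å-deep channel (the −1 subsite analogue), a three-residue
constriction halfway up whose side chains must move before a ring ligand can
pass (the toll-like barrier analogue), a lateral alcove with an attractive
site (the transient cavity analogue), and a wall split into two weakly
coupled halves so that the softest elastic mode is a clamshell opening of the
channel.  Construction is certified at build time by an exhaustive pose-grid
scan: the ligand placed in the well is clash-free, no rigid-receptor exit
exists on the grid, and a clash-free corridor opens once the gate side chains
retract.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .elasticmodes import ANMConfig
from .energymodel import LigandView
from .kinetics import KineticDataset, KineticParams, SPRDataset, competitive_rate
from .ringpucker import RING_ORDER, _canonical_patterns, cremer_pople
from .structmodel import Atom, Structure

__all__ = [
    "toy_anm_config",
    "ToyPocketSpec",
    "RingLigand",
    "PocketAnnotations",
    "make_ring_ligand",
    "make_toy_pocket",
    "make_kinetic_dataset",
    "make_spr_dataset",
    "certify_pocket",
    "grid_reachable_separation",
]

SUPPORTED_CONFORMERS = ("4C1", "1C4", "1S3", "B3O", "planar")

#: elastic-network cutoff suited to the toy pocket's 1.7 Å bead lattice
#: (the same footing, relative to node spacing, as a 15 Å cutoff has for
#: Cα-level protein networks)
TOY_ANM_CUTOFF = 3.0


def toy_anm_config(n_modes: int = 6) -> ANMConfig:
    """ANM configuration tuned to the toy pocket's bead spacing."""
    return ANMConfig(cutoff=TOY_ANM_CUTOFF, n_modes=n_modes)

_BEAD_RADIUS = 1.70        # uniform pseudo-bead radius for wall/gate beads
_O_RADIUS = 1.52


@dataclass
class ToyPocketSpec:
    """Geometry and seed of the toy pocket.

    Lengths in Å.  ``gate_opening`` is the radial retraction available to a
    gate side chain at full torsion; ``cavity_well_depth`` (kcal/mol, under
    the default polar strength) sets the attractive site inside the alcove.
    """

    pocket_depth: float = 13.0
    pocket_radius: float = 5.0
    channel_length: float = 13.0
    channel_radius: float = 1.4        # gate aperture radius when closed
    n_gate_residues: int = 3
    gate_opening: float = 3.0
    wall_bead_spacing: float = 1.7
    cavity_well_depth: float = 3.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pocket_depth", "pocket_radius", "channel_length",
                     "channel_radius", "gate_opening", "wall_bead_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cavity_well_depth < 0:
            raise ValueError("cavity_well_depth must be non-negative")


@dataclass
class RingLigand:
    """Six ring beads (O5, C1..C5) plus exocyclic C6 and a C4-OH marker bead.

    ``marker_index`` designates the C4-OH analogue used by the migration
    termination criterion; ``coords`` rows follow ``names``.
    """

    names: list[str]
    coords: np.ndarray
    conformer_label: str
    marker_index: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        ring = self.ring_coords
        d = np.linalg.norm(ring - np.roll(ring, -1, axis=0), axis=1)
        if self.conformer_label != "planar" and not np.all((d > 1.2) & (d < 1.8)):
            raise ValueError("ring bead distances outside the plausible range")

    @property
    def ring_coords(self) -> np.ndarray:
        return self.coords[:6]

    @property
    def radii(self) -> np.ndarray:
        return np.array([_O_RADIUS if n.startswith("O") else _BEAD_RADIUS
                         for n in self.names])

    @property
    def polar(self) -> np.ndarray:
        return np.array([1.0 if n.startswith("O") else 0.0 for n in self.names])

    def view(self) -> LigandView:
        return LigandView(self.coords.copy(), self.radii, self.polar,
                          list(self.names))

    def to_structure(self, chain: str = "L") -> Structure:
        atoms = [Atom(element="O" if n.startswith("O") else "C", name=n,
                      res_index=1, res_name="LIG", chain=chain,
                      position=c.copy(), radius=r, polar=p)
                 for n, c, r, p in zip(self.names, self.coords, self.radii,
                                       self.polar)]
        return Structure(atoms)


@dataclass
class PocketAnnotations:
    minus1_center: np.ndarray
    cavity_center: np.ndarray
    exit_point: np.ndarray
    gate_residue_ids: list[int]
    barrier_z: float
    exit_separation: float


def _conformer_pattern(label: str) -> np.ndarray:
    for lab, z in _canonical_patterns():
        if lab == label:
            return z
    raise ValueError(f"unsupported conformer label {label!r}")


def make_ring_ligand(conformer_label: str = "4C1", Q: float = 0.55,
                     rho: float = 1.34, bond_c6: float = 1.52,
                     bond_o4: float = 1.43) -> RingLigand:
    """Ideal 6-bead pyranose-ring analogue in a named canonical conformer.

    The out-of-plane pattern of the requested conformer is scaled so that the
    Cremer-Pople amplitude is exactly ``Q`` (0 for "planar").  Exocyclic
    beads: C6 on C5 and the C4-OH marker on C4, both tilted out of the ring
    plane so that the ligand's circumscribed radius stays compact.
    """
    if conformer_label not in SUPPORTED_CONFORMERS:
        raise ValueError(
            f"unsupported conformer {conformer_label!r}; expected one of "
            f"{SUPPORTED_CONFORMERS}")
    ang = 2.0 * np.pi * np.arange(6) / 6.0
    xy = np.stack([rho * np.cos(ang), rho * np.sin(ang)], axis=1)

    if conformer_label == "planar":
        ring = np.column_stack([xy, np.zeros(6)])
    else:
        pattern = _conformer_pattern(conformer_label)
        pattern = pattern / np.abs(pattern).max()

        def q_of(scale: float) -> float:
            return cremer_pople(np.column_stack([xy, scale * pattern])).Q - Q

        scale = brentq(q_of, 1e-6, 1.5)
        ring = np.column_stack([xy, scale * pattern])

    centroid = ring.mean(axis=0)

    def exo(parent: int, bond: float, out_frac: float) -> np.ndarray:
        outward = ring[parent] - centroid
        outward /= np.linalg.norm(outward)
        up = np.array([0.0, 0.0, 1.0])
        d = out_frac * outward + np.sqrt(1 - out_frac ** 2) * up
        d /= np.linalg.norm(d)
        return ring[parent] + bond * d

    c6 = exo(5, bond_c6, 0.35)   # on C5
    o4 = exo(4, bond_o4, 0.45)   # on C4 -> the C4-OH marker
    coords = np.vstack([ring, c6, o4])
    names = list(RING_ORDER) + ["C6", "O4H"]
    return RingLigand(names, coords, conformer_label, marker_index=7)


# ---------------------------------------------------------------------------
# toy pocket construction


def _alcove_center(spec: ToyPocketSpec) -> np.ndarray:
    # on the -x half, between the two gate anchors of that domain
    return np.array([-(spec.pocket_radius + 1.0), 0.0,
                     0.74 * spec.channel_length])


def _wall_beads(spec: ToyPocketSpec, rng: np.random.Generator):
    """Thick (two-layer) cylinder wall split into two half-shells, plus a
    floor cap; returns bead coordinates and a bool array marking the +x half.

    The double layer makes each half-shell elastically rigid, so that the
    softest non-rigid normal mode of the assembled pocket is the clamshell
    opening of the two halves about the floor hinge — the toy analogue of a
    two-domain cork-like motion — rather than local flutter of wall beads.
    """
    zs = np.arange(0.0, spec.channel_length + 0.51 * spec.wall_bead_spacing,
                   spec.wall_bead_spacing)
    slit_half = np.deg2rad(20.0)
    coords, domain_a = [], []
    alcove_c = _alcove_center(spec)
    hole_lo = 0.74 * spec.channel_length - 1.3
    hole_hi = 0.74 * spec.channel_length + 1.3
    for layer, R in enumerate((spec.pocket_radius, spec.pocket_radius + 1.6)):
        n_az = int(round(2 * np.pi * R / spec.wall_bead_spacing))
        for z in zs:
            offs = rng.uniform(0, 2 * np.pi / n_az)
            for k in range(n_az):
                az = offs + 2 * np.pi * k / n_az
                azm = az % (2 * np.pi)
                # two slits at ±90° decouple the two half-shells elastically
                if (abs(azm - np.pi / 2) < slit_half or
                        abs(azm - 3 * np.pi / 2) < slit_half):
                    continue
                p = np.array([R * np.cos(az), R * np.sin(az), z])
                # alcove mouth on the -x side, above the gate plane
                if layer == 0 and (hole_lo < z < hole_hi and
                                   abs(azm - np.pi) < np.deg2rad(22)):
                    continue
                # keep the alcove interior hollow
                if layer == 1 and np.linalg.norm(p - alcove_c) < 2.5:
                    continue
                coords.append(p + rng.normal(0.0, 0.06, 3))
                domain_a.append(np.cos(azm) > 0)
    # floor cap: the hinge joining the two halves
    zf = -1.4 * spec.wall_bead_spacing
    for r_ring, n_b in ((0.0, 1), (1.8, 6), (3.6, 12), (4.8, 15), (6.2, 18)):
        for k in range(n_b):
            az = 2 * np.pi * k / n_b + 0.3
            zz = zf if r_ring < 4.0 else zf * 0.5
            coords.append(np.array([r_ring * np.cos(az), r_ring * np.sin(az),
                                    zz]) + rng.normal(0.0, 0.05, 3))
            domain_a.append(False)  # floor belongs to the hinge
    return np.asarray(coords), np.asarray(domain_a)


def _alcove_beads(spec: ToyPocketSpec, rng: np.random.Generator) -> np.ndarray:
    """Outer shell of the lateral alcove behind the wall hole on +x."""
    center = _alcove_center(spec)
    coords = []
    n = 64
    for i in range(n):
        # deterministic spiral points on the outward hemisphere
        t = (i + 0.5) / n
        phi = np.arccos(1 - t)            # polar from the -x axis, outward half
        theta = np.pi * (1 + 5 ** 0.5) * i
        d = np.array([-np.cos(phi),
                      np.sin(phi) * np.cos(theta),
                      np.sin(phi) * np.sin(theta)])
        p = center + 2.9 * d + rng.normal(0, 0.05, 3)
        coords.append(p)
    return np.asarray(coords)


def make_toy_pocket(spec: ToyPocketSpec | None = None, *, certify: bool = True):
    """Build the toy pocket receptor, its ring ligand and site annotations.

    Returns ``(structure, ligand, annotations)``.  With ``certify`` the
    construction is checked by the exhaustive pose-grid scan and a
    construction error is raised if any certified property fails.
    """
    spec = spec or ToyPocketSpec()
    rng = np.random.default_rng(spec.seed)
    wall, domain_a = _wall_beads(spec, rng)
    alcove = _alcove_beads(spec, rng)

    atoms: list[Atom] = []
    res = 0
    backbone: list[bool] = []
    for c, is_a in zip(wall, domain_a):
        res += 1
        atoms.append(Atom("C", "W", res, "WAL", "R", c, radius=_BEAD_RADIUS))
        backbone.append(True)
    for c in alcove:
        res += 1
        atoms.append(Atom("C", "W", res, "CAV", "R", c, radius=_BEAD_RADIUS))
        backbone.append(True)

    # binding-well beads at the pocket floor (the −1 subsite analogue)
    minus1_center = np.array([0.0, 0.0, 1.3])
    for dx in (-0.9, 0.9):
        res += 1
        atoms.append(Atom("O", "OW", res, "WEL", "R",
                          np.array([dx, 0.0, -1.9]), radius=_BEAD_RADIUS,
                          polar=1.0))
        backbone.append(True)

    # cavity attractor; polar scale in units of the default polar strength
    # just inside the alcove mouth, within hydrogen-bond range of poses
    # the channel-side ligand can actually reach
    cavity_center = np.array([-(spec.pocket_radius - 0.4), 0.0,
                              0.74 * spec.channel_length])
    res += 1
    atoms.append(Atom("O", "OC", res, "CAV", "R", cavity_center.copy(),
                      radius=_BEAD_RADIUS, polar=spec.cavity_well_depth / 1.5))
    backbone.append(True)

    # gate residues: 3-bead side chains pointing inward at the barrier plane
    barrier_z = 0.6 * spec.channel_length
    gate_ids: list[int] = []
    gate_axes: dict[int, tuple] = {}
    gate_az = np.deg2rad(np.array([0.0, 140.0, 220.0])[: spec.n_gate_residues])
    anchor_r = spec.pocket_radius - 0.5
    tip_r = spec.channel_radius
    for az in gate_az:
        res += 1
        gate_ids.append(res)
        r_hat = np.array([np.cos(az), np.sin(az), 0.0])
        t_hat = np.array([-np.sin(az), np.cos(az), 0.0])
        anchor = anchor_r * r_hat + np.array([0, 0, barrier_z])
        mid = 0.5 * (anchor_r + tip_r) * r_hat + np.array([0, 0, barrier_z + 0.3])
        tip = tip_r * r_hat + np.array([0, 0, barrier_z])
        for name, pos in (("GA", anchor), ("GB", mid), ("GC", tip)):
            atoms.append(Atom("C", name, res, "GAT", "R", pos.copy(),
                              radius=_BEAD_RADIUS))
            backbone.append(name == "GA")  # only the anchor is backbone-like
        gate_axes[res] = (anchor.copy(), t_hat.copy(), "R")

    # torsion bound realising the spec'd side-chain retraction: at angle tau
    # the tip retreats radially by (anchor_r - tip_r)(1 - cos tau)
    reach = anchor_r - tip_r
    frac = min(max(spec.gate_opening / reach, 0.0), 2.0)
    gate_max_torsion = float(np.degrees(np.arccos(1.0 - frac)))

    structure = Structure(atoms, flexible_residues=set(gate_ids),
                          backbone_mask=np.array(backbone))
    structure.metadata["gate_axes"] = gate_axes
    structure.metadata["gate_max_torsion"] = gate_max_torsion

    ligand = make_ring_ligand("4C1")
    # place the ligand at the well: ring centroid at minus1_center
    ligand = RingLigand(ligand.names,
                        ligand.coords - ligand.ring_coords.mean(axis=0)
                        + minus1_center,
                        ligand.conformer_label, ligand.marker_index)

    exit_sep = spec.channel_length + 2.0
    ann = PocketAnnotations(minus1_center, cavity_center,
                            np.array([0.0, 0.0, spec.channel_length + 2.0]),
                            gate_ids, barrier_z, exit_sep)
    if certify:
        report = certify_pocket(structure, ligand, ann, spec)
        if not report["start_clash_free"]:
            raise ValueError("construction error: ligand clashes at the −1 well")
        if not report["rigid_blocked"]:
            raise ValueError("construction error: rigid receptor is not closed")
        if not report["open_with_gates_retracted"]:
            raise ValueError("construction error: gate retraction opens no corridor")
    return structure, ligand, ann


# ---------------------------------------------------------------------------
# pose-grid certification


def _orientation_set() -> list[Rotation]:
    """A coarse but well-spread set of ligand orientations for grid scans."""
    rots = [Rotation.identity()]
    for axis in ([1, 0, 0], [0, 1, 0], [1, 1, 0], [1, -1, 0]):
        for angdeg in (45, 90, 135):
            rots.append(Rotation.from_rotvec(
                np.deg2rad(angdeg) * np.asarray(axis, float)
                / np.linalg.norm(axis)))
    for spin in (30, 60):
        rots.append(Rotation.from_rotvec([0, 0, np.deg2rad(spin)]))
    return rots


def _grid_free(receptor_coords: np.ndarray, lig: RingLigand,
               centers: np.ndarray, rot: Rotation) -> np.ndarray:
    """Clash-free mask over candidate ligand-centroid positions for one
    orientation (uniform receptor bead radius assumed)."""
    tree = cKDTree(receptor_coords)
    base = lig.coords - lig.ring_coords.mean(axis=0)
    offsets = rot.apply(base)
    thr = 0.7 * (_BEAD_RADIUS + lig.radii)
    free = np.ones(len(centers), dtype=bool)
    for b in range(len(offsets)):
        pts = centers + offsets[b]
        d, _ = tree.query(pts, k=1)
        free &= d >= thr[b]
    return free


def grid_reachable_separation(receptor: Structure, lig: RingLigand,
                              start: np.ndarray, *, step: float = 0.5,
                              radius: float = 4.6, z_range=(-0.5, 16.0),
                              per_orientation: bool = False) -> float:
    """Largest separation from ``start`` reachable through clash-free grid
    poses connected to the start position (6-neighbour flood fill).

    With ``per_orientation`` the flood fill is run for each orientation
    separately (a stricter, continuous-path notion) and the best result is
    returned; otherwise a position is free if any orientation is clash-free,
    which over-approximates reachability and therefore makes a "blocked"
    verdict a strong certificate.
    """
    rc = receptor.coords
    xs = np.arange(-radius, radius + step / 2, step)
    zs = np.arange(z_range[0], z_range[1] + step / 2, step)
    X, Y, Z = np.meshgrid(xs, xs, zs, indexing="ij")
    mask = X ** 2 + Y ** 2 <= radius ** 2
    centers = np.column_stack([X[mask], Y[mask], Z[mask]])
    idx_of = -np.ones(X.shape, dtype=int)
    idx_of[mask] = np.arange(mask.sum())

    rots = _orientation_set()
    frees = [_grid_free(rc, lig, centers, r) for r in rots]
    free_any = np.logical_or.reduce(frees)

    def flood(free: np.ndarray) -> float:
        start_idx = int(np.argmin(np.linalg.norm(centers - start, axis=1)))
        if not free[start_idx]:
            return 0.0
        grid_free = np.zeros(X.shape, dtype=bool)
        grid_free[mask] = free
        seen = np.zeros_like(grid_free)
        ii = np.argwhere(idx_of == start_idx)[0]
        stack = [tuple(ii)]
        seen[tuple(ii)] = True
        best = 0.0
        while stack:
            i, j, k = stack.pop()
            p = centers[idx_of[i, j, k]]
            best = max(best, float(np.linalg.norm(p - start)))
            for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                               (0, 0, 1), (0, 0, -1)):
                ni, nj, nk = i + di, j + dj, k + dk
                if (0 <= ni < X.shape[0] and 0 <= nj < X.shape[1]
                        and 0 <= nk < X.shape[2] and not seen[ni, nj, nk]
                        and grid_free[ni, nj, nk] and idx_of[ni, nj, nk] >= 0):
                    seen[ni, nj, nk] = True
                    stack.append((ni, nj, nk))
        return best

    if per_orientation:
        return max(flood(f) for f in frees)
    return flood(free_any)


def certify_pocket(structure: Structure, ligand: RingLigand,
                   ann: PocketAnnotations, spec: ToyPocketSpec) -> dict:
    """Exhaustive pose-grid certification of the three pocket properties."""
    from .energymodel import EnergyParams, clash_count
    from .structmodel import Pose

    params = EnergyParams()
    start_free = clash_count(structure, ligand.view(), Pose(), params) == 0

    reach_rigid = grid_reachable_separation(structure, ligand,
                                            ann.minus1_center)
    blocked = reach_rigid < ann.exit_separation

    from .energymodel import apply_gate_torsions
    tau = structure.metadata.get("gate_max_torsion", 90.0)
    opened = apply_gate_torsions(structure,
                                 {g: tau for g in ann.gate_residue_ids})
    reach_open = grid_reachable_separation(opened, ligand, ann.minus1_center,
                                           per_orientation=True)
    return {
        "start_clash_free": bool(start_free),
        "rigid_blocked": bool(blocked),
        "rigid_reach": reach_rigid,
        "open_with_gates_retracted": bool(reach_open >= ann.exit_separation),
        "open_reach": reach_open,
    }


# ---------------------------------------------------------------------------
# kinetic and SPR dataset generators


def make_kinetic_dataset(Vmax: float = 1.0, KM: float = 2.0, Ki: float = 2.55,
                         S_grid: np.ndarray | None = None,
                         I_grid: np.ndarray | None = None,
                         replicates: int = 2, noise_cv: float = 0.05,
                         seed: int = 0) -> KineticDataset:
    """Simulated competitive-inhibition rate table.

    Default design mirrors the published assay: six substrate concentrations
    spanning 0.8–6.6 mM and six inhibitor concentrations spanning 0.4–3 × Ki,
    in duplicate.  Rates are the competitive model times (1 + N(0, noise_cv)).
    """
    if min(Vmax, KM, Ki) <= 0 or noise_cv < 0:
        raise ValueError("parameters must be positive and noise_cv >= 0")
    S_grid = np.linspace(0.8, 6.6, 6) if S_grid is None else np.asarray(S_grid, float)
    I_grid = Ki * np.linspace(0.4, 3.0, 6) if I_grid is None else np.asarray(I_grid, float)
    if (S_grid <= 0).any() or (I_grid < 0).any():
        raise ValueError("concentration grids must be non-negative (S positive)")
    rng = np.random.default_rng(seed)
    params = KineticParams(Vmax, KM, Ki)
    rows = []
    for rep in range(replicates):
        for S in S_grid:
            for I in I_grid:
                v = competitive_rate(S, I, params)
                v_obs = v * (1.0 + noise_cv * rng.standard_normal())
                rows.append({"S": S, "I": I, "v": max(v_obs, 1e-12),
                             "replicate": rep})
    return KineticDataset(pd.DataFrame(rows))


def make_spr_dataset(KD: float = 0.16e-3, Rmax: float = 100.0,
                     n_conc: int = 8, noise_cv: float = 0.02,
                     seed: int = 0) -> SPRDataset:
    """Simulated steady-state SPR dilution series.

    Geometric concentration series from 0.1·KD to 10·KD (the published
    design), 1:1 Langmuir responses with multiplicative Gaussian noise, and
    one concentration injected in duplicate.
    """
    if KD <= 0 or Rmax <= 0:
        raise ValueError("KD and Rmax must be positive")
    if n_conc < 4:
        raise ValueError("need at least 4 concentrations for the 1:1 fit")
    rng = np.random.default_rng(seed)
    C = KD * np.geomspace(0.1, 10.0, n_conc)
    C = np.append(C, C[n_conc // 2])   # one duplicated concentration
    req = Rmax * C / (KD + C)
    req_obs = req * (1.0 + noise_cv * rng.standard_normal(len(C)))
    return SPRDataset(pd.DataFrame({"C": C, "Req": np.maximum(req_obs, 0.0)}),
                      Rmax=Rmax)
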