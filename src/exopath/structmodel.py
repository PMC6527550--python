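"""Core structural data model: atoms, structures, rigid-body poses, PDB I/O.

Everything downstream (clash scoring, elastic modes, path searches, Monte
Carlo migration) operates on the three types defined here.  Coordinates are
in Å throughout, axes are right-handed, and only heavy atoms are kept by
default — the egress analysis is a heavy-atom clash problem.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "VDW_RADII",
    "DEFAULT_RADIUS",
    "Atom",
    "Structure",
    "Pose",
    "read_pdb",
    "write_pdb",
    "geometric_center",
    "separation",
]

#: Element-keyed van der Waals radii (Å).  Pseudo-beads (element "X" or
#: unknown) fall back to the carbon-like default.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_RADIUS = 1.70


class PDBFormatError(ValueError):
    """Raised when a PDB file has no atom records or a malformed field."""


@dataclass
class Atom:
    """A (pseudo-)atom with element, identity, position and vdW radius.

    ``polar`` is a donor/acceptor well-depth scale used by the energy model
    (0 means apolar); it is an implementation extra on top of the bare
    crystallographic fields.
    """

    element: str
    name: str
    res_index: int
    res_name: str
    chain: str
    position: np.ndarray
    occupancy: float = 1.0
    radius: float | None = None
    polar: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be a finite 3-vector")
        if not (0.0 < self.occupancy <= 1.0):
            raise ValueError(f"occupancy must be in (0, 1], got {self.occupancy}")
        if self.radius is None:
            self.radius = VDW_RADII.get(self.element.upper(), DEFAULT_RADIUS)
        if self.radius <= 0:
            raise ValueError("vdW radius must be positive")


@dataclass
class Structure:
    """An ordered collection of atoms plus mobility annotations.

    ``flexible_residues`` flags residues whose side-chain torsion is sampled
    (the toy pocket's gate residues); ``backbone_mask`` marks the atoms that
    elastic-network nodes are built from and that mode displacement acts on.
    ``metadata`` carries generator annotations such as gate rotation axes.
    """

    atoms: list[Atom]
    flexible_residues: set[int] = field(default_factory=set)
    backbone_mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        present = {a.res_index for a in self.atoms}
        if not self.flexible_residues <= present:
            raise ValueError("flexible_residues must be a subset of residues present")
        if self.backbone_mask is None:
            self.backbone_mask = np.ones(len(self.atoms), dtype=bool)
        else:
            self.backbone_mask = np.asarray(self.backbone_mask, dtype=bool)
            if self.backbone_mask.shape != (len(self.atoms),):
                raise ValueError("backbone_mask length must match atom count")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array (a fresh copy on every call)."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Return a copy of the structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [dataclasses.replace(a, position=c.copy()) for a, c in zip(self.atoms, coords)]
        return Structure(
            atoms,
            flexible_residues=set(self.flexible_residues),
            backbone_mask=self.backbone_mask.copy(),
            metadata=dict(self.metadata),
        )

    def residue_atom_indices(self) -> dict[tuple[str, int], np.ndarray]:
        """Map (chain, res_index) -> atom index array, in file order."""
        out: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault((a.chain, a.res_index), []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in out.items()}


@dataclass
class Pose:
    """Rigid-body ligand state: unit quaternion (x, y, z, w), translation (Å)
    and optional side-chain torsions in degrees, each in [-180, 180)."""

    rotation: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0]))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    torsions: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.torsions = np.asarray(self.torsions, dtype=float)
        n = np.linalg.norm(self.rotation)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("quaternion must be unit norm")
        self.rotation = self.rotation / n
        self.torsions = (self.torsions + 180.0) % 360.0 - 180.0

    def apply(self, coords: np.ndarray, pivot: np.ndarray) -> np.ndarray:
        """Rotate ``coords`` about ``pivot`` and translate."""
        rot = Rotation.from_quat(self.rotation)
        return rot.apply(coords - pivot) + pivot + self.translation

    def compose_rotation(self, rotvec: np.ndarray) -> "Pose":
        """Pose with an extra rotation (rotation-vector, radians) pre-applied."""
        q = (Rotation.from_rotvec(rotvec) * Rotation.from_quat(self.rotation)).as_quat()
        return Pose(q, self.translation.copy(), self.torsions.copy())


def geometric_center(atoms: Iterable[Atom] | np.ndarray) -> np.ndarray:
    """Unweighted mean position of a non-empty atom subset (or coord array)."""
    if isinstance(atoms, np.ndarray):
        coords = np.asarray(atoms, dtype=float).reshape(-1, 3)
    else:
        coords = np.array([a.position for a in atoms], dtype=float).reshape(-1, 3)
    if coords.shape[0] == 0:
        raise ValueError("geometric_center of an empty atom subset")
    return coords.mean(axis=0)


def separation(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two points (Å)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("separation requires finite inputs")
    return float(np.linalg.norm(a - b))


def read_pdb(path: str | Path, *, keep_hydrogens: bool = False,
             altloc: str = "highest-occupancy") -> Structure:
    """Read fixed-column PDB ATOM/HETATM records into a :class:`Structure`.

    Alternate locations are collapsed to a single conformer per atom: with the
    default policy the altloc of highest occupancy wins, ties going to the one
    first in the file.  Hydrogens are dropped unless ``keep_hydrogens``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports the bad line
        raise PDBFormatError(f"malformed PDB file {path}: {exc}") from exc
    atoms: list[Atom] = []
    if len(st) == 0:
        raise PDBFormatError(f"{path} contains no ATOM/HETATM records")
    model = st[0]
    for chain in model:
        for res in chain:
            # collapse altlocs: group atoms by name, keep highest occupancy
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for at in res:
                if not keep_hydrogens and at.element.name == "H":
                    continue
                prev = best.get(at.name)
                if prev is None:
                    best[at.name] = at
                    order.append(at.name)
                elif altloc == "highest-occupancy" and at.occ > prev.occ:
                    best[at.name] = at
            for name in order:
                at = best[name]
                occ = float(at.occ) if at.occ > 0 else 1.0
                atoms.append(Atom(
                    element=at.element.name,
                    name=name,
                    res_index=res.seqid.num,
                    res_name=res.name,
                    chain=chain.name,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=min(occ, 1.0),
                ))
    if not atoms:
        raise PDBFormatError(f"{path} contains no ATOM/HETATM records")
    return Structure(atoms)


def _pdb_record_lines(structure: Structure) -> list[str]:
    lines = []
    serial = 0
    prev_chain = structure.atoms[0].chain
    for a in structure.atoms:
        if a.chain != prev_chain:
            serial += 1
            lines.append(f"TER   {serial:5d}")
            prev_chain = a.chain
        serial += 1
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        x, y, z = a.position
        lines.append(
            f"ATOM  {serial:5d} {name:<4.4s} {a.res_name:<3.3s} "
            f"{a.chain[:1]}{a.res_index:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element[:2]:>2s}")
    return lines


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a structure as standard fixed-column PDB ATOM records, with a
    TER record between chains; parseable by :func:`read_pdb`."""
    if len(structure) == 0:
        raise ValueError("refusing to write an empty structure")
    lines = _pdb_record_lines(structure) + ["END"]
    try:
        Path(path).write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write PDB to {path}: {exc}") from exc


def write_multimodel_pdb(structures: Sequence[Structure], path: str | Path) -> None:
    """Write a trajectory / path as a multi-MODEL PDB for visualisation."""
    if not structures:
        raise ValueError("no models to write")
    lines = []
    for i, s in enumerate(structures, start=1):
        lines.append(f"MODEL     {i:4d}")
        lines.extend(_pdb_record_lines(s))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
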