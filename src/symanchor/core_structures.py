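"""Coordinate data model, PDB I/O, rigid transforms and cyclic point-group symmetry.

All coordinates are in Angstrom throughout the package; there is no unit
conversion anywhere.  Author residue numbering is preserved verbatim on
read — the channel pore range 321-414 and the toxin range 1-37 are author
numbers, never renumbered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

ROTATION_TOL = 1e-8

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "RigidTransform",
    "SymmetryGroup",
    "read_pdb",
    "write_pdb",
    "apply_transform",
    "make_cn_group",
    "orbit",
    "read_peak_table",
]


class EmptyInputError(ValueError):
    """Raised when an operation receives no usable atoms/records."""


@dataclass
class Atom:
    """A single atom: label, element, position (A), occupancy and B-factor.

    The B-factor is carried through I/O but never interpreted.  Occupancy
    matters for the placement problem: each of the n symmetry-equivalent
    ligand orientations is populated at occupancy 1/n.
    """

    name: str
    element: str
    xyz: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: xyz must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name!r} not in {self.chain_id}:{self.res_name}{self.seq_number}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class Structure:
    """Ordered residue list; the universal currency of geometric operations."""

    residues: list[Residue] = field(default_factory=list)
    id: str = ""

    def __post_init__(self):
        seen = set()
        for r in self.residues:
            if r.key in seen:
                raise ValueError(f"duplicate residue key {r.key} in structure {self.id!r}")
            seen.add(r.key)

    def __len__(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if r.chain_id not in out:
                out.append(r.chain_id)
        return out

    def coords(self) -> np.ndarray:
        if not self.residues:
            return np.zeros((0, 3))
        return np.array([a.xyz for r in self.residues for a in r.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        i = 0
        for r in self.residues:
            for a in r.atoms:
                a.xyz = xyz[i].copy()
                i += 1
        if i != len(xyz):
            raise ValueError("coordinate array length mismatch")

    def select(self, chain_id: str | None = None,
               res_range: tuple[int, int] | None = None,
               atom_names: set[str] | None = None) -> "Structure":
        """Sub-structure by chain / author residue range / atom-name set, order preserved."""
        out: list[Residue] = []
        for r in self.residues:
            if chain_id is not None and r.chain_id != chain_id:
                continue
            if res_range is not None and not res_range[0] <= r.seq_number <= res_range[1]:
                continue
            atoms = [a for a in r.atoms if atom_names is None or a.name in atom_names]
            if atoms:
                out.append(Residue(r.chain_id, r.seq_number, r.res_name, list(atoms),
                                   r.insertion_code))
        return Structure(out, id=self.id)

    def residue(self, chain_id: str, seq_number: int, insertion_code: str = "") -> Residue:
        for r in self.residues:
            if r.key == (chain_id, seq_number, insertion_code):
                return r
        raise KeyError(f"residue {chain_id}:{seq_number}{insertion_code} not found")

    def copy(self) -> "Structure":
        return Structure(
            [Residue(r.chain_id, r.seq_number, r.res_name,
                     [replace(a, xyz=a.xyz.copy()) for a in r.atoms], r.insertion_code)
             for r in self.residues],
            id=self.id,
        )


@dataclass
class RigidTransform:
    """Proper rotation + translation, x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if R.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if np.linalg.norm(R.T @ R - np.eye(3)) > ROTATION_TOL * 100 or \
                abs(np.linalg.det(R) - 1.0) > ROTATION_TOL * 100:
            raise ValueError("rotation must be orthonormal with determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self ∘ other)(x) = self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


def _rotation_about_axis(axis_direction: np.ndarray, angle: float) -> np.ndarray:
    u = np.asarray(axis_direction, dtype=float)
    u = u / np.linalg.norm(u)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


@dataclass
class SymmetryGroup:
    """Cyclic group Cn about an axis in space (identity element first)."""

    axis_point: np.ndarray
    axis_direction: np.ndarray
    order: int
    elements: list[RigidTransform] = field(default_factory=list)

    def axis_distance(self, points: np.ndarray) -> np.ndarray:
        """Perpendicular distance of point(s) from the symmetry axis."""
        p = np.atleast_2d(np.asarray(points, dtype=float)) - self.axis_point
        u = self.axis_direction
        perp = p - np.outer(p @ u, u)
        d = np.linalg.norm(perp, axis=1)
        return d if np.asarray(points).ndim == 2 else d[0]


def make_cn_group(axis_point, axis_direction, n: int) -> SymmetryGroup:
    """Cyclic group of n rotations by 2*pi*k/n about the given axis."""
    if n < 1:
        raise ValueError(f"group order must be >= 1, got {n}")
    axis_point = np.asarray(axis_point, dtype=float)
    axis_direction = np.asarray(axis_direction, dtype=float)
    nrm = np.linalg.norm(axis_direction)
    if nrm == 0:
        raise ValueError("axis direction must be non-zero")
    u = axis_direction / nrm
    elements = []
    for k in range(n):
        R = _rotation_about_axis(u, 2.0 * np.pi * k / n)
        # rotation about a line through axis_point: x -> R(x - p) + p
        t = axis_point - R @ axis_point
        elements.append(RigidTransform(R, t))
    return SymmetryGroup(axis_point, u, n, elements)


def orbit(point, group: SymmetryGroup, merge_tol: float = 0.0):
    """Images of a point under all group elements, merged within merge_tol.

    Returns (points, multiplicities).  A point on the axis collapses to a
    single image with multiplicity n; a point off the axis by more than
    merge_tol yields n distinct images — the n-peak signature of a marker
    atom on an n-fold ambiguous ligand.
    """
    point = np.asarray(point, dtype=float)
    images = np.array([g.apply(point) for g in group.elements])
    merged: list[np.ndarray] = []
    counts: list[int] = []
    for img in images:
        for i, m in enumerate(merged):
            if np.linalg.norm(img - m) <= merge_tol:
                counts[i] += 1
                break
        else:
            merged.append(img)
            counts.append(1)
    return np.array(merged), counts


def apply_transform(s: Structure, t: RigidTransform) -> Structure:
    """Return a new Structure with all coordinates mapped as R x + t."""
    out = s.copy()
    if out.residues:
        out.set_coords(t.apply(out.coords()))
    return out


def read_pdb(path) -> Structure:
    """Read ATOM/HETATM records from a PDB file into a Structure.

    Author chain/residue numbering is kept verbatim.  Alternate locations:
    altloc 'A' or blank is kept, others dropped with a warning (the analysis
    is single-conformer).
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (FileNotFoundError, OSError):
        raise
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc
    residues: list[Residue] = []
    dropped_alt = 0
    for model in st:
        for chain in model:
            for res in chain:
                atoms = []
                for at in res:
                    if at.altloc not in ("", "A", "\x00"):
                        dropped_alt += 1
                        continue
                    atoms.append(Atom(at.name, at.element.name,
                                      np.array([at.pos.x, at.pos.y, at.pos.z]),
                                      occupancy=min(max(at.occ, 0.0), 1.0),
                                      bfactor=at.b_iso))
                if atoms:
                    icode = res.seqid.icode.strip()
                    residues.append(Residue(chain.name, res.seqid.num, res.name,
                                            atoms, icode))
        break  # first model only
    if dropped_alt:
        warnings.warn(f"dropped {dropped_alt} alternate-location atoms (kept altloc A/blank)")
    if not residues:
        raise EmptyInputError(f"no ATOM/HETATM records parsed from {path}")
    return Structure(residues, id=str(path))


def write_pdb(s: Structure, path, models: list[Structure] | None = None) -> None:
    """Write a Structure (or several as MODEL records) in fixed-column PDB format."""
    structures = models if models is not None else [s]
    with open(path, "w") as fh:
        for imodel, st in enumerate(structures, start=1):
            if models is not None:
                fh.write(f"MODEL     {imodel:4d}\n")
            serial = 1
            for r in st.residues:
                for a in r.atoms:
                    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                    fh.write(
                        "ATOM  {:5d} {:4s} {:<3s} {:1s}{:4d}{:1s}   "
                        "{:8.3f}{:8.3f}{:8.3f}{:6.2f}{:6.2f}          {:>2s}\n".format(
                            serial, name, r.res_name[:3], r.chain_id[:1] or "A",
                            r.seq_number, r.insertion_code[:1] or " ",
                            a.xyz[0], a.xyz[1], a.xyz[2], a.occupancy, a.bfactor,
                            a.element[:2]))
                    serial += 1
            if models is not None:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def read_peak_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an anchor-peak table: columns x, y, z[, height].

    Whitespace- or comma-delimited; '#' comments ignored; an optional header
    line is skipped.  Returns (positions (n,3), heights (n,) — NaN if absent).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                if not rows and lineno <= 2:  # header line
                    continue
                raise ValueError(f"{path}:{lineno}: cannot parse peak row {line!r}")
            if len(vals) not in (3, 4):
                raise ValueError(f"{path}:{lineno}: expected 3 or 4 columns, got {len(vals)}")
            rows.append(vals + [np.nan] * (4 - len(vals)))
    if not rows:
        raise EmptyInputError(f"no peaks parsed from {path}")
    arr = np.array(rows)
    return arr[:, :3], arr[:, 3]
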