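"""Toxin-channel interface contacts and mapping of mutant-cycle restraints.

Covers: C4 axis detection from a tetramer, ligand-receptor contact maps
with conventional distance categories, pairwise sequence alignment for
transferring residue numbers between channel homologs (Shaker -> paddle
chimera), annotation of literature double-mutant-cycle pairs with distances
measured in the complex, in-silico lysine-scan rotamer selection, and
superposition of a homologous toxin onto the placed one via the conserved
cysteine/lysine scaffold.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial import cKDTree

from .core_structures import RigidTransform, Structure, SymmetryGroup, make_cn_group
from .superpose import SuperpositionResult, kabsch

__all__ = [
    "Contact",
    "ResidueMapping",
    "MutantCyclePair",
    "detect_axis",
    "contact_map",
    "align_pair",
    "map_restraints",
    "lysine_scan_rotamer",
    "superpose_homolog",
    "HBOND_MAX",
    "PACKING_MAX",
    "ELECTROSTATIC_MAX",
]

# conventional cutoffs; the 6.0 A electrostatic range covers long-range
# charge pairs such as an arginine guanidinium 5.5 A from an aspartate
HBOND_MAX = 3.5
PACKING_MAX = 4.5
ELECTROSTATIC_MAX = 6.0

_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"}, "ASN": {"ND2"}, "GLN": {"NE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}
_CHARGED = {
    "ARG": {"NE", "NH1", "NH2", "CZ"}, "LYS": {"NZ"},
    "ASP": {"OD1", "OD2", "CG"}, "GLU": {"OE1", "OE2", "CD"},
    "HIS": {"ND1", "NE2"},
}
_BACKBONE_DONOR = "N"
_BACKBONE_ACCEPTOR = "O"

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class Contact:
    ligand_residue: tuple[str, int, str]    # (chain, number, res_name)
    receptor_residue: tuple[str, int, str]
    subunit_index: int
    min_distance: float
    closest_atom_pair: tuple[str, str]
    category: str                            # hbond | packing | electrostatic | none


@dataclass
class ResidueMapping:
    source_name: str
    target_name: str
    aligned_pairs: list[tuple[int, int]]
    gaps: list[tuple[str, int]] = field(default_factory=list)

    def map(self, source_number: int) -> int:
        for s, t in self.aligned_pairs:
            if s == source_number:
                return t
        raise KeyError(f"{self.source_name} residue {source_number} is unmapped")


@dataclass
class MutantCyclePair:
    toxin_residue: int
    channel_residue_source: int
    source_label: str = "Shaker"
    coupling_energy_kt: float | None = None
    kds_nM: tuple[float, float, float, float] | None = None
    channel_residue_mapped: int | None = None
    min_distance: float | None = None
    error: str | None = None


def detect_axis(tetramer: Structure) -> tuple[SymmetryGroup, float]:
    """Best-fit C4 axis of a homo-tetramer.

    Chains are paired in chain-ID order; the transform carrying chain i onto
    chain i+1 is fitted by least squares, and its rotation axis (averaged
    over the four successive pairs) defines the group.  Returns the C4 group
    and the mean superposition residual, which must be < 1 A for the
    tetramer to count as symmetric.
    """
    chains = tetramer.chain_ids
    if len(chains) != 4:
        raise ValueError(f"expected 4 chains, found {len(chains)}: {chains}")
    coords = [tetramer.select(chain_id=c).coords() for c in chains]
    n0 = len(coords[0])
    if any(len(c) != n0 for c in coords):
        raise ValueError("chains differ in atom count; not a homo-tetramer")

    axes, points, residuals = [], [], []
    for i in range(4):
        res = kabsch(coords[i], coords[(i + 1) % 4])
        R, t = res.transform.rotation, res.transform.translation
        residuals.append(res.rmsd)
        # rotation axis = eigenvector of R for eigenvalue +1
        w, v = np.linalg.eig(R)
        axis = np.real(v[:, np.argmin(np.abs(w - 1.0))])
        axis /= np.linalg.norm(axis)
        angle = np.arccos(np.clip((np.trace(R) - 1) / 2, -1, 1))
        if abs(np.degrees(angle) - 90.0) > 15.0:
            raise ValueError(
                f"chain {chains[i]}->{chains[(i+1) % 4]} rotation is "
                f"{np.degrees(angle):.1f} deg, not ~90: not C4-arranged")
        if axes and np.dot(axis, axes[0]) < 0:
            axis = -axis
        axes.append(axis)
        # fixed point: solve (I - R) p = t in the plane perpendicular to axis
        p, *_ = np.linalg.lstsq(np.eye(3) - R, t, rcond=None)
        points.append(p)

    residual = float(np.mean(residuals))
    if residual >= 1.0:
        raise ValueError(f"tetramer is not fourfold symmetric (residual {residual:.2f} A)")
    direction = np.mean(axes, axis=0)
    direction /= np.linalg.norm(direction)
    centroid = np.mean(np.vstack(coords).reshape(-1, 3), axis=0)
    # project each pair's fixed point onto the plane through the centroid
    axis_point = np.mean(points, axis=0)
    axis_point = axis_point + ((centroid - axis_point) @ direction) * direction
    return make_cn_group(axis_point, direction, 4), residual


def _categorize(lig_res: str, lig_atom: str, rec_res: str, rec_atom: str,
                distance: float) -> str:
    def donor(res, at):
        return at == _BACKBONE_DONOR or at in _DONORS.get(res, set())

    def acceptor(res, at):
        return at == _BACKBONE_ACCEPTOR or at in _ACCEPTORS.get(res, set())

    def charged(res, at):
        return at in _CHARGED.get(res, set())

    if distance <= HBOND_MAX and (
            (donor(lig_res, lig_atom) and acceptor(rec_res, rec_atom)) or
            (donor(rec_res, rec_atom) and acceptor(lig_res, lig_atom))):
        return "hbond"
    if distance <= ELECTROSTATIC_MAX and charged(lig_res, lig_atom) and \
            charged(rec_res, rec_atom):
        return "electrostatic"
    if distance <= PACKING_MAX:
        return "packing"
    return "none"


def contact_map(ligand: Structure, receptor: Structure,
                max_distance: float = ELECTROSTATIC_MAX) -> list[Contact]:
    """All ligand-residue / receptor-residue pairs within max_distance.

    One Contact per (ligand residue, receptor residue, subunit): the same
    receptor residue number can appear once per subunit, preserving
    "of another subunit" relationships.  Category is a pure function of the
    minimal atom-atom distance and the residue/atom chemistry.
    """
    if not ligand.residues or not receptor.residues:
        raise ValueError("both structures must be non-empty")
    chain_order = receptor.chain_ids
    rec_atoms = [(ri, ai, a.xyz) for ri, r in enumerate(receptor.residues)
                 for ai, a in enumerate(r.atoms)]
    tree = cKDTree(np.array([x for _, _, x in rec_atoms]))
    contacts: dict[tuple[int, int], tuple[float, int, int, int, int]] = {}
    for li, lres in enumerate(ligand.residues):
        for lai, latom in enumerate(lres.atoms):
            for j in tree.query_ball_point(latom.xyz, max_distance):
                ri, rai, rxyz = rec_atoms[j]
                d = float(np.linalg.norm(latom.xyz - rxyz))
                if d > max_distance:
                    continue
                key = (li, ri)
                if key not in contacts or d < contacts[key][0]:
                    contacts[key] = (d, lai, rai, li, ri)
    out = []
    for (li, ri), (d, lai, rai, _, _) in sorted(contacts.items()):
        lres, rres = ligand.residues[li], receptor.residues[ri]
        out.append(Contact(
            ligand_residue=(lres.chain_id, lres.seq_number, lres.res_name),
            receptor_residue=(rres.chain_id, rres.seq_number, rres.res_name),
            subunit_index=chain_order.index(rres.chain_id),
            min_distance=d,
            closest_atom_pair=(lres.atoms[lai].name, rres.atoms[rai].name),
            category=_categorize(lres.res_name, lres.atoms[lai].name,
                                 rres.res_name, rres.atoms[rai].name, d),
        ))
    return out


def align_pair(seq_a: str, seq_b: str, first_a: int = 1, first_b: int = 1,
               name_a: str = "A", name_b: str = "B",
               gap_open: float = 10.0, gap_extend: float = 0.5) -> ResidueMapping:
    """Global pairwise alignment returning aligned residue-number pairs.

    BLOSUM62 scoring with affine gaps.  Residue numbers use the declared
    first-residue numbers of each sequence.
    """
    for name, seq in ((name_a, seq_a), (name_b, seq_b)):
        if not seq:
            raise ValueError(f"sequence {name} is empty")
        bad = set(seq.upper()) - _AA_ALPHABET
        if bad:
            raise ValueError(f"sequence {name} has non-amino-acid characters: {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    pairs: list[tuple[int, int]] = []
    gaps: list[tuple[str, int]] = []
    covered_a, covered_b = set(), set()
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i in range(a1 - a0):
            pairs.append((first_a + a0 + i, first_b + b0 + i))
            covered_a.add(a0 + i)
            covered_b.add(b0 + i)
    gaps += [(name_a, first_a + i) for i in range(len(seq_a)) if i not in covered_a]
    gaps += [(name_b, first_b + i) for i in range(len(seq_b)) if i not in covered_b]
    return ResidueMapping(name_a, name_b, pairs, sorted(gaps))


def map_restraints(pairs: list[MutantCyclePair], mapping: ResidueMapping,
                   ligand: Structure, receptor: Structure) -> list[MutantCyclePair]:
    """Annotate literature mutant-cycle pairs with distances in the complex.

    Each pair's channel residue (source numbering, e.g. Shaker) is mapped to
    the receptor numbering via the alignment; the reported distance is the
    minimum over all four receptor subunits between any atom of the toxin
    residue and any atom of the mapped channel residue.  Unmapped residues
    produce a per-pair error entry; processing continues.  Duplicate channel
    residues coupled to several toxin residues yield one entry each.
    """
    out = []
    for pair in pairs:
        p = MutantCyclePair(pair.toxin_residue, pair.channel_residue_source,
                            pair.source_label, pair.coupling_energy_kt, pair.kds_nM)
        try:
            p.channel_residue_mapped = mapping.map(pair.channel_residue_source)
        except KeyError:
            p.error = "unmapped"
            out.append(p)
            continue
        lig_xyz = [a.xyz for r in ligand.residues
                   if r.seq_number == pair.toxin_residue for a in r.atoms]
        rec_xyz = [a.xyz for r in receptor.residues
                   if r.seq_number == p.channel_residue_mapped for a in r.atoms]
        if not lig_xyz:
            p.error = f"toxin residue {pair.toxin_residue} absent from ligand"
        elif not rec_xyz:
            p.error = f"channel residue {p.channel_residue_mapped} absent from receptor"
        else:
            diff = np.array(lig_xyz)[:, None, :] - np.array(rec_xyz)[None, :, :]
            p.min_distance = float(np.sqrt((diff**2).sum(-1)).min())
        out.append(p)
    return out


# idealized side-chain internal coordinates (bond A, angle deg)
_LYS_CHAIN = [("CB", 1.53, 110.5), ("CG", 1.52, 114.0), ("CD", 1.52, 111.0),
              ("CE", 1.52, 111.0), ("NZ", 1.49, 111.0)]
_CHI_SET = [-60.0, 60.0, 180.0]


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle: float, dihedral: float) -> np.ndarray:
    """NeRF placement: position d given chain a-b-c and internal coords of c-d."""
    ang, dih = np.deg2rad(angle), np.deg2rad(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * np.cos(ang),
                   bond * np.sin(ang) * np.cos(dih),
                   bond * np.sin(ang) * np.sin(dih)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def lysine_scan_rotamer(receptor: Structure, chain_id: str, seq_number: int,
                        toxin_atom_xyz) -> dict:
    """In-silico lysine substitution: pick the rotamer nearest a toxin atom.

    Builds idealized lysine side chains on the residue's backbone over a
    fixed 27-rotamer library (chi1-chi3 in {-60, 60, 180}, chi4 = 180) and
    returns the rotamer minimizing the NZ-to-toxin-atom distance.  Distances
    below 1.5 A are flagged implausible (probe inside the side chain).
    """
    res = receptor.residue(chain_id, seq_number)
    try:
        N, CA, C = (res.atom(n).xyz for n in ("N", "CA", "C"))
    except KeyError as exc:
        raise ValueError(f"residue {chain_id}:{seq_number} lacks backbone atoms") from exc
    toxin_atom_xyz = np.asarray(toxin_atom_xyz, dtype=float)

    best = None
    for idx, (chi1, chi2, chi3) in enumerate(itertools.product(_CHI_SET, repeat=3)):
        chis = [chi1, chi2, chi3, 180.0]
        # CB from backbone with a fixed pseudo-dihedral; then chain by chis
        chain = [N, CA, C]
        atoms = []
        prev3 = (N, C, CA)  # N-C-CA frame places CB at the standard branch
        name, bond, angle = _LYS_CHAIN[0]
        cb = _place_atom(N, C, CA, bond, angle, 122.5)
        atoms.append(cb)
        frame = (N, CA, cb)
        for (name, bond, angle), chi in zip(_LYS_CHAIN[1:], chis):
            new = _place_atom(*frame, bond, angle, chi)
            atoms.append(new)
            frame = (frame[1], frame[2], new)
        nz = atoms[-1]
        d = float(np.linalg.norm(nz - toxin_atom_xyz))
        if best is None or d < best["distance"] - 1e-6:
            best = {"rotamer_index": idx, "chi": tuple(chis), "nz": nz,
                    "distance": d, "tie": False}
        elif abs(d - best["distance"]) <= 1e-6:
            best["tie"] = True
            warnings.warn("lysine rotamer tie; keeping lowest index")
    best["implausible"] = best["distance"] < 1.5
    return best


def superpose_homolog(homolog: Structure, placed_ctx: Structure,
                      scaffold_residues_homolog: list[int],
                      scaffold_residues_ctx: list[int],
                      atom_name: str = "CA") -> tuple[SuperpositionResult, Structure]:
    """Superpose a homologous toxin onto the placed one via a rigid scaffold.

    Default scaffold: the Calpha atoms of the conserved cysteines plus the
    conserved lysine, which are structurally invariant across the toxin
    family.  Returns the superposition result and the transformed homolog.
    """
    if len(scaffold_residues_homolog) != len(scaffold_residues_ctx):
        raise ValueError("scaffold residue lists differ in length")

    def pick(st: Structure, numbers: list[int]) -> np.ndarray:
        xyz, missing = [], []
        for num in numbers:
            found = [r for r in st.residues if r.seq_number == num and r.has_atom(atom_name)]
            if not found:
                missing.append(num)
            else:
                xyz.append(found[0].atom(atom_name).xyz)
        if missing:
            raise ValueError(f"scaffold atoms missing for residues {missing} in {st.id!r}")
        return np.array(xyz)

    res = kabsch(pick(homolog, scaffold_residues_homolog),
                 pick(placed_ctx, scaffold_residues_ctx))
    from .core_structures import apply_transform
    return res, apply_transform(homolog, res.transform)
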