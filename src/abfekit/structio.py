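"""Structure and molecular-graph I/O, superposition, and RMSD utilities.

Coordinates are in Å throughout; residue numbering is 1-based as in PDB.
PDB records follow the wwPDB v3.3 fixed-column layout. Dummy particles
(the lab-frame anchor particles N1-N3) are written as HETATM records with
the reserved residue name ``DUM``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

logger = logging.getLogger("abfekit")

#: Reserved residue name for lab-frame dummy particles.
DUMMY_RESIDUE_NAME = "DUM"

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common variants
    "HIE": "H", "HID": "H", "HIP": "H", "CYX": "C", "ASH": "D", "GLH": "E",
}


class StructureError(ValueError):
    """Malformed structure input or invalid structure operation."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure (protein, ligand, or dummy particle)."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    xyz: tuple[float, float, float]
    is_hetero: bool = False

    def __post_init__(self):
        if self.serial <= 0:
            raise StructureError(f"atom serial must be positive, got {self.serial}")
        if not self.element:
            raise StructureError("atom element must be non-empty")
        if not np.all(np.isfinite(self.xyz)):
            raise StructureError(f"non-finite coordinates for atom {self.serial}")


@dataclass
class Structure:
    """An ordered collection of atoms with unique serial numbers."""

    atoms: list[AtomRecord]
    title: str = ""

    def __post_init__(self):
        if not self.atoms:
            raise StructureError("structure must contain at least one atom")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise StructureError("duplicate atom serial numbers")

    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in atom order."""
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with every atom mapped to ``R @ x + t``."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_atoms = [
            replace(a, xyz=tuple(R @ np.asarray(a.xyz) + t)) for a in self.atoms
        ]
        return Structure(new_atoms, title=self.title)

    def protein_atom_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if not a.is_hetero]

    def ligand_atom_indices(self, residue_name: str | None = None) -> list[int]:
        """Hetero atoms, excluding dummies and (optionally) filtered by residue name."""
        out = []
        for i, a in enumerate(self.atoms):
            if not a.is_hetero or a.residue_name == DUMMY_RESIDUE_NAME:
                continue
            if a.residue_name in ("HOH", "WAT"):
                continue
            if residue_name is not None and a.residue_name != residue_name:
                continue
            out.append(i)
        return out


@dataclass
class MolecularGraph:
    """Ligand connectivity: atoms as (index, element), bonds as index pairs."""

    atoms: list[tuple[int, str]]
    bonds: list[tuple[int, int]]
    names: list[str] | None = None

    def __post_init__(self):
        valid = {i for i, _ in self.atoms}
        seen = set()
        for i, j in self.bonds:
            if i == j:
                raise StructureError(f"self-bond on atom {i}")
            if i not in valid or j not in valid:
                raise StructureError(f"bond ({i}, {j}) references missing atom")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise StructureError(f"duplicate bond {key}")
            seen.add(key)

    def element(self, index: int) -> str:
        return dict(self.atoms)[index]

    def heavy_atoms(self) -> set[int]:
        return {i for i, el in self.atoms if el.upper() != "H"}

    def neighbors(self, index: int) -> set[int]:
        out = set()
        for i, j in self.bonds:
            if i == index:
                out.add(j)
            elif j == index:
                out.add(i)
        return out


@dataclass
class AlignmentResult:
    """Rigid-body superposition: x_ref ≈ rotation @ x_mobile + translation."""

    paired_residues: list[tuple[int, int]]
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self):
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-6):
            raise StructureError("rotation must be proper (det = +1)")
        if self.rmsd < 0:
            raise StructureError("rmsd must be non-negative")


# ---------------------------------------------------------------------------
# PDB reading / writing (wwPDB v3.3 columns)
# ---------------------------------------------------------------------------

def read_structure(path) -> Structure:
    """Read ATOM/HETATM records from a PDB file.

    Alternate locations other than blank or 'A' are dropped with a warning.
    A malformed record raises :class:`StructureError` naming the line number.
    """
    atoms: list[AtomRecord] = []
    title = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("TITLE"):
                title = line[10:].strip()
                continue
            if rec not in ("ATOM  ", "HETATM"):
                continue
            try:
                altloc = line[16]
                if altloc not in (" ", "A"):
                    logger.warning(
                        "dropping altloc %r atom at line %d", altloc, lineno
                    )
                    continue
                serial = int(line[6:11])
                name = line[12:16].strip()
                resname = line[17:20].strip()
                chain = line[21]
                resnum = int(line[22:26])
                xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                element = line[76:78].strip() if len(line) >= 78 else ""
                if not element:
                    element = _element_from_name(name)
                atoms.append(
                    AtomRecord(
                        serial=serial, name=name, element=element,
                        residue_name=resname, chain_id=chain,
                        residue_number=resnum, xyz=xyz,
                        is_hetero=(rec == "HETATM"),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise StructureError(
                    f"{path}: malformed PDB record at line {lineno}: {exc}"
                ) from exc
    if not atoms:
        raise StructureError(f"{path}: no ATOM/HETATM records found")
    return Structure(atoms, title=title)


def _element_from_name(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


def write_structure(s: Structure, path) -> None:
    """Write a Structure as PDB; dummies become HETATM/``DUM`` records."""
    lines = []
    if s.title:
        lines.append(f"TITLE     {s.title}")
    for a in s.atoms:
        if len(a.chain_id) != 1:
            raise StructureError(
                f"chain id {a.chain_id!r} does not fit the one-character PDB field"
            )
        rec = "HETATM" if (a.is_hetero or a.residue_name == DUMMY_RESIDUE_NAME) else "ATOM  "
        # atom names shorter than 4 chars start in column 14
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        x, y, z = a.xyz
        lines.append(
            f"{rec}{a.serial:5d} {name:<4.4s} {a.residue_name:<3.3s} {a.chain_id}"
            f"{a.residue_number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element:>2.2s}"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Molecular graphs (MOL/SDF V2000 via RDKit)
# ---------------------------------------------------------------------------

def read_molecule_graph(path) -> MolecularGraph:
    """Read ligand connectivity from a MOL/SDF (V2000) file."""
    from rdkit import Chem

    mol = Chem.MolFromMolFile(str(path), sanitize=False, removeHs=False)
    if mol is None:
        raise StructureError(f"{path}: cannot parse MOL/SDF V2000 block")
    return graph_from_rdkit(mol)


def graph_from_rdkit(mol) -> MolecularGraph:
    atoms = [(a.GetIdx(), a.GetSymbol()) for a in mol.GetAtoms()]
    bonds = [
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
         max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
    ]
    return MolecularGraph(atoms=atoms, bonds=sorted(bonds))


def graph_from_smiles(smiles: str, add_hs: bool = False) -> MolecularGraph:
    """Build a MolecularGraph from a SMILES string (heavy atoms by default)."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"cannot parse SMILES {smiles!r}")
    if add_hs:
        mol = Chem.AddHs(mol)
    return graph_from_rdkit(mol)


def graph_automorphisms(
    graph: MolecularGraph, max_atoms: int = 60, max_count: int = 10000
) -> list[tuple[int, ...]]:
    """Element-preserving automorphisms of the graph (identity excluded).

    Exhaustive search via graph matching; refuses graphs larger than
    ``max_atoms`` since the caller should then supply permutations directly.
    """
    import networkx as nx
    from networkx.algorithms.isomorphism import GraphMatcher, categorical_node_match

    if len(graph.atoms) > max_atoms:
        raise StructureError(
            f"graph with {len(graph.atoms)} atoms exceeds the automorphism "
            f"search limit ({max_atoms}); supply permutations explicitly"
        )
    g = nx.Graph()
    for i, el in graph.atoms:
        g.add_node(i, element=el)
    g.add_edges_from(graph.bonds)
    matcher = GraphMatcher(g, g, node_match=categorical_node_match("element", None))
    order = [i for i, _ in graph.atoms]
    perms = []
    for mapping in matcher.isomorphisms_iter():
        perm = tuple(mapping[i] for i in order)
        if perm != tuple(order):
            perms.append(perm)
        if len(perms) >= max_count:
            break
    return perms


# ---------------------------------------------------------------------------
# AMBER prmtop dihedral-section decoding
# ---------------------------------------------------------------------------

def read_prmtop_dihedrals(path_or_text) -> list[tuple[int, int, int, int]]:
    """Decode proper heavy-atom dihedral quadruples from AMBER prmtop text.

    Accepts either a path or raw text containing the entries of the
    ``DIHEDRALS_WITHOUT_HYDROGEN`` section (five integers per term). Atom
    indices are decoded as ``|entry| / 3 + 1`` (1-based). A negative third
    entry marks a 1-4 exclusion and the term is retained as a proper
    dihedral; a negative fourth entry marks an improper, which is excluded.
    Redundant terms on the same central bond are retained.
    """
    try:
        with open(path_or_text) as fh:
            text = fh.read()
    except (OSError, TypeError):
        text = str(path_or_text)

    if "%FLAG" in text:
        # extract just the dihedrals-without-hydrogen section
        section = []
        keep = False
        for line in text.splitlines():
            if line.startswith("%FLAG"):
                keep = "DIHEDRALS_WITHOUT_HYDROGEN" in line
                continue
            if line.startswith("%FORMAT"):
                continue
            if keep:
                section.append(line)
        text = "\n".join(section)

    entries = [int(tok) for tok in text.split()]
    if len(entries) % 5 != 0:
        raise StructureError(
            f"dihedral section length {len(entries)} is not a multiple of 5"
        )
    quads = []
    for ofs in range(0, len(entries), 5):
        i, j, k, l = entries[ofs:ofs + 4]
        if l < 0:  # improper dihedral
            continue
        quad = []
        for entry in (i, j, k, l):
            mag = abs(entry)
            if mag % 3 != 0:
                raise StructureError(f"dihedral entry {entry} not divisible by 3")
            quad.append(mag // 3 + 1)
        quads.append(tuple(quad))
    return quads


# ---------------------------------------------------------------------------
# Sequence alignment and rigid superposition
# ---------------------------------------------------------------------------

def global_sequence_align(
    seq_a: str, seq_b: str, match: float = 1.0, mismatch: float = -1.0,
    gap: float = -2.0,
) -> list[tuple[int, int]]:
    """Needleman-Wunsch global alignment; returns 1-based aligned pairs.

    Substitutions count as pairs; gapped positions do not. Traceback ties
    are broken deterministically: diagonal, then up, then left.
    """
    if not seq_a or not seq_b:
        raise StructureError("sequences must be non-empty")
    na, nb = len(seq_a), len(seq_b)
    F = np.zeros((na + 1, nb + 1))
    F[:, 0] = gap * np.arange(na + 1)
    F[0, :] = gap * np.arange(nb + 1)
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            s = match if seq_a[i - 1] == seq_b[j - 1] else mismatch
            F[i, j] = max(F[i - 1, j - 1] + s, F[i - 1, j] + gap, F[i, j - 1] + gap)
    pairs = []
    i, j = na, nb
    while i > 0 and j > 0:
        s = match if seq_a[i - 1] == seq_b[j - 1] else mismatch
        if F[i, j] == F[i - 1, j - 1] + s:          # prefer diagonal
            pairs.append((i, j))
            i, j = i - 1, j - 1
        elif F[i, j] == F[i - 1, j] + gap:          # then up
            i -= 1
        else:                                       # then left
            j -= 1
    pairs.reverse()
    return pairs


def kabsch_superpose(coords_mobile, coords_ref) -> AlignmentResult:
    """Least-squares rigid superposition of paired point sets (Kabsch).

    Returns the proper rotation and translation mapping mobile onto
    reference, with the post-fit RMSD.
    """
    mob = np.asarray(coords_mobile, dtype=float)
    ref = np.asarray(coords_ref, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise StructureError("paired (N, 3) coordinate arrays required")
    if len(mob) < 3:
        raise StructureError("at least 3 point pairs required")
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    mc, rc = mob - cm, ref - cr
    sv = np.linalg.svd(mc, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise StructureError("point set is collinear; superposition is degenerate")
    rot, _ = Rotation.align_vectors(rc, mc)
    R = rot.as_matrix()
    t = cr - R @ cm
    fitted = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return AlignmentResult(
        paired_residues=[(i, i) for i in range(len(mob))],
        rotation=R, translation=t, rmsd=rmsd,
    )


def _protein_residues(s: Structure):
    """Ordered (chain, resnum) -> {atom_name: index} for non-hetero residues."""
    residues: dict[tuple[str, int], dict[str, int]] = {}
    for i, a in enumerate(s.atoms):
        if a.is_hetero:
            continue
        residues.setdefault((a.chain_id, a.residue_number), {})[a.name] = i
    return residues


def protein_sequence(s: Structure) -> tuple[str, list[int]]:
    """One-letter sequence of CA-bearing residues and their CA atom indices."""
    seq, ca_idx = [], []
    for (_, _), atom_map in _protein_residues(s).items():
        if "CA" not in atom_map:
            continue
        resname = s.atoms[atom_map["CA"]].residue_name
        seq.append(_AA3TO1.get(resname, "X"))
        ca_idx.append(atom_map["CA"])
    return "".join(seq), ca_idx


def align_complex_to_reference(complex: Structure, reference: Structure) -> Structure:
    """Sequence-align, superpose on matched CA pairs, transform the complex.

    The whole complex (protein, ligand, anything else) is mapped into the
    frame of the reference protein.
    """
    seq_c, ca_c = protein_sequence(complex)
    seq_r, ca_r = protein_sequence(reference)
    if not seq_c or not seq_r:
        raise StructureError("both structures need protein chains with CA atoms")
    pairs = global_sequence_align(seq_c, seq_r)
    if len(pairs) < 3:
        raise StructureError(f"only {len(pairs)} matched CA pairs; need >= 3")
    mob = np.array([complex.atoms[ca_c[i - 1]].xyz for i, _ in pairs])
    ref = np.array([reference.atoms[ca_r[j - 1]].xyz for _, j in pairs])
    fit = kabsch_superpose(mob, ref)
    return complex.transformed(fit.rotation, fit.translation)


def symmetry_aware_rmsd(coords_a, coords_b, automorphisms=()) -> float:
    """Minimum RMSD over identity plus the supplied index permutations.

    No refitting is performed: the two structures are assumed pre-aligned.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise StructureError("coordinate sets must have equal atom counts")
    n = len(a)
    best = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    for perm in automorphisms:
        if len(perm) != n or sorted(perm) != list(range(n)):
            raise StructureError(f"permutation {perm!r} is not a bijection on {n} atoms")
        r = float(np.sqrt(np.mean(np.sum((a[list(perm)] - b) ** 2, axis=1))))
        best = min(best, r)
    return best
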