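"""Harmonic restraint construction, energies, and window schedules.

Two families of restraint are built from an AnchorSet:

* translational/rotational (TR) restraints tying a molecule to the
  lab-frame dummy particles N1-N3 — one distance, two angles, three
  dihedrals each for ligand (D1, A1, A2, T1-T3) and protein (D2, A3,
  A4, T4-T6);
* conformational restraints — anchor-anchor distances plus dihedrals
  (backbone φ/ψ for the protein, one heavy-atom torsion per central
  bond for the ligand).

Every term is harmonic, ``U = k (x - x0)^2`` with no 1/2 factor; k is in
kcal/mol/Å² for distances and kcal/mol/rad² for angles and dihedrals.
Reference values x0 are stored in degrees for angular terms and converted
to radians inside the energy; dihedral differences are wrapped to
(-180°, 180°]. Per-window spring constants scale linearly with the
attach percentage: ``k_i = attach_rest(i)/100 * k_full``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .anchorgeom import AnchorSet
from .structio import MolecularGraph, Structure

AtomRef = int | str  # structure atom index, or "N1"/"N2"/"N3" dummy label


class RestraintError(ValueError):
    """Invalid restraint definition or evaluation."""


@dataclass(frozen=True)
class HarmonicRestraint:
    """One harmonic term: kind in {distance, angle, dihedral}."""

    kind: str
    atoms: tuple[AtomRef, ...]
    k: float
    x0: float  # Å for distances, degrees for angles/dihedrals
    label: str

    def __post_init__(self):
        arity = {"distance": 2, "angle": 3, "dihedral": 4}
        if self.kind not in arity:
            raise RestraintError(f"unknown restraint kind {self.kind!r}")
        if len(self.atoms) != arity[self.kind]:
            raise RestraintError(
                f"{self.kind} restraint needs {arity[self.kind]} atoms, "
                f"got {len(self.atoms)}"
            )
        if self.k < 0:
            raise RestraintError("spring constant must be non-negative")
        if self.kind == "dihedral" and not -180.0 < self.x0 <= 180.0:
            raise RestraintError("dihedral x0 must lie in (-180, 180]")


@dataclass
class RestraintSet:
    """A labelled group of harmonic terms."""

    terms: list[HarmonicRestraint]
    group: str  # protein_TR | protein_conf | ligand_TR | ligand_conf

    def __post_init__(self):
        labels = [t.label for t in self.terms]
        if len(set(labels)) != len(labels):
            raise RestraintError(f"duplicate labels in group {self.group!r}")

    def labels(self) -> list[str]:
        return [t.label for t in self.terms]


@dataclass
class WindowSchedule:
    """Attach percentages (restraint windows) and/or λ values (alchemical)."""

    attach_rest: list[float] = field(default_factory=list)
    lambdas: list[float] = field(default_factory=list)
    weights: list[float] | None = None

    def __post_init__(self):
        if self.attach_rest:
            a = np.asarray(self.attach_rest, dtype=float)
            if np.any(np.diff(a) < 0):
                raise RestraintError("attach_rest must be monotone non-decreasing")
            if a[0] != 0 or a[-1] != 100:
                raise RestraintError("attach_rest must start at 0 and end at 100")
            if np.any(a < 0) or np.any(a > 100):
                raise RestraintError("attach_rest entries must lie in [0, 100]")
        if self.lambdas and (min(self.lambdas) < 0 or max(self.lambdas) > 1):
            raise RestraintError("lambdas must lie in [0, 1]")
        if self.weights is not None and not np.isclose(sum(self.weights), 1.0):
            raise RestraintError("quadrature weights must sum to 1")


# ---------------------------------------------------------------------------
# Internal-coordinate measurement
# ---------------------------------------------------------------------------

def measure_distance(a, b) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def measure_angle(a, b, c) -> float:
    """Angle a-b-c in degrees; error on collinear/coincident points."""
    v1 = np.asarray(a, float) - np.asarray(b, float)
    v2 = np.asarray(c, float) - np.asarray(b, float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise RestraintError("angle undefined for coincident atoms")
    return float(np.degrees(np.arccos(np.clip(np.dot(v1, v2) / (n1 * n2), -1, 1))))


def measure_dihedral(a, b, c, d) -> float:
    """Signed dihedral a-b-c-d in degrees, in (-180, 180]."""
    p = [np.asarray(x, float) for x in (a, b, c, d)]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise RestraintError("dihedral undefined: three atoms are collinear")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = float(np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2))))
    return 180.0 if ang == -180.0 else ang


def wrap_degrees(delta: float) -> float:
    """Wrap an angular difference into (-180, 180]."""
    out = (delta + 180.0) % 360.0 - 180.0
    return 180.0 if out == -180.0 else out


def _coord(ref: AtomRef, structure: Structure | None, dummies, coords=None):
    if isinstance(ref, str):
        if dummies is None or ref not in dummies:
            raise RestraintError(f"dummy coordinate {ref!r} not supplied")
        return np.asarray(dummies[ref], float)
    if coords is not None:
        return np.asarray(coords[ref], float)
    return np.asarray(structure.atoms[ref].xyz, float)


def measure_term(term: HarmonicRestraint, structure=None, dummies=None, coords=None) -> float:
    pts = [_coord(r, structure, dummies, coords) for r in term.atoms]
    if term.kind == "distance":
        return measure_distance(*pts)
    if term.kind == "angle":
        return measure_angle(*pts)
    return measure_dihedral(*pts)


# ---------------------------------------------------------------------------
# TR restraints
# ---------------------------------------------------------------------------

def _tr_terms(labels, atom_tuples, kinds, k_dist, k_ang):
    terms = []
    for label, atoms, kind in zip(labels, atom_tuples, kinds):
        k = k_dist if kind == "distance" else k_ang
        terms.append(HarmonicRestraint(kind=kind, atoms=atoms, k=k, x0=0.0, label=label))
    return terms


def build_ligand_tr_restraints(
    anchors: AnchorSet, k_dist: float, k_ang: float, start: Structure
) -> RestraintSet:
    """D1 = N1-L1, A1 = N2-N1-L1, A2 = N1-L1-L2, T1-T3 per the dummy frame.

    x0 values are measured from the starting coordinates; by construction
    D1 = 5.00 Å and A1 = 90° on a freshly built AnchorSet.
    """
    a = anchors
    terms = _tr_terms(
        ["D1", "A1", "A2", "T1", "T2", "T3"],
        [("N1", a.L1), ("N2", "N1", a.L1), ("N1", a.L1, a.L2),
         ("N3", "N2", "N1", a.L1), ("N2", "N1", a.L1, a.L2),
         ("N1", a.L1, a.L2, a.L3)],
        ["distance", "angle", "angle", "dihedral", "dihedral", "dihedral"],
        k_dist, k_ang,
    )
    rset = RestraintSet(terms=terms, group="ligand_TR")
    return measure_reference_values(rset, start, dummies=a.dummies())


def build_protein_tr_restraints(
    anchors: AnchorSet, k_dist: float, k_ang: float, start: Structure
) -> RestraintSet:
    """D2 = N1-P1, A3 = N2-N1-P1, A4 = N1-P1-P2, T4-T6 per the dummy frame."""
    a = anchors
    terms = _tr_terms(
        ["D2", "A3", "A4", "T4", "T5", "T6"],
        [("N1", a.P1), ("N2", "N1", a.P1), ("N1", a.P1, a.P2),
         ("N3", "N2", "N1", a.P1), ("N2", "N1", a.P1, a.P2),
         ("N1", a.P1, a.P2, a.P3)],
        ["distance", "angle", "angle", "dihedral", "dihedral", "dihedral"],
        k_dist, k_ang,
    )
    rset = RestraintSet(terms=terms, group="protein_TR")
    return measure_reference_values(rset, start, dummies=a.dummies())


# ---------------------------------------------------------------------------
# Conformational restraints
# ---------------------------------------------------------------------------

def build_protein_conf_restraints(
    anchors: AnchorSet, k_dist: float, k_dih: float,
    bb_range: tuple[int, int] | None, start: Structure,
) -> RestraintSet:
    """Three anchor-anchor distances plus optional backbone φ/ψ dihedrals.

    φ_i = C_{i-1}-N_i-CA_i-C_i and ψ_i = N_i-CA_i-C_i-N_{i+1} are added for
    each residue in [bb_start, bb_end] whose flanking atoms exist; ω angles
    are never restrained (the peptide bond is already rigid).
    """
    a = anchors
    terms = [
        HarmonicRestraint("distance", (a.P1, a.P2), k_dist, 0.0, "DP12"),
        HarmonicRestraint("distance", (a.P2, a.P3), k_dist, 0.0, "DP23"),
        HarmonicRestraint("distance", (a.P1, a.P3), k_dist, 0.0, "DP13"),
    ]
    if bb_range is not None:
        bb_start, bb_end = bb_range
        backbone: dict[int, dict[str, int]] = {}
        for i, atom in enumerate(start.atoms):
            if not atom.is_hetero and atom.name in ("N", "CA", "C"):
                backbone.setdefault(atom.residue_number, {})[atom.name] = i
        in_range = [r for r in range(bb_start, bb_end + 1) if r in backbone]
        if not in_range:
            raise RestraintError(
                f"backbone range {bb_start}-{bb_end} matches no residues"
            )
        for res in range(bb_start, bb_end + 1):
            cur = backbone.get(res, {})
            prev = backbone.get(res - 1, {})
            nxt = backbone.get(res + 1, {})
            if all(n in cur for n in ("N", "CA", "C")) and "C" in prev:
                terms.append(HarmonicRestraint(
                    "dihedral", (prev["C"], cur["N"], cur["CA"], cur["C"]),
                    k_dih, 0.0, f"PHI{res}",
                ))
            if all(n in cur for n in ("N", "CA", "C")) and "N" in nxt:
                terms.append(HarmonicRestraint(
                    "dihedral", (cur["N"], cur["CA"], cur["C"], nxt["N"]),
                    k_dih, 0.0, f"PSI{res}",
                ))
    rset = RestraintSet(terms=terms, group="protein_conf")
    return measure_reference_values(rset, start)


def enumerate_central_bonds(graph: MolecularGraph) -> list[tuple[int, int]]:
    """Heavy-atom bonds through which a heavy-atom proper dihedral exists.

    A bond (b, c) qualifies when b has a heavy neighbour other than c and
    c has a heavy neighbour other than b. Ring bonds are not excepted.
    """
    heavy = graph.heavy_atoms()
    out = []
    for i, j in graph.bonds:
        if i not in heavy or j not in heavy:
            continue
        ni = (graph.neighbors(i) & heavy) - {j}
        nj = (graph.neighbors(j) & heavy) - {i}
        if ni and nj:
            out.append((min(i, j), max(i, j)))
    return sorted(out)


def _dihedral_for_bond(graph: MolecularGraph, bond: tuple[int, int]):
    """Lexicographically smallest heavy quadruple (a, b, c, d) through a bond."""
    heavy = graph.heavy_atoms()
    best = None
    for b, c in (bond, bond[::-1]):
        for a in sorted((graph.neighbors(b) & heavy) - {c}):
            for d in sorted((graph.neighbors(c) & heavy) - {b}):
                quad = (a, b, c, d)
                if best is None or quad < best:
                    best = quad
    return best


def assign_ligand_conformational_restraints(
    graph: MolecularGraph, anchors: AnchorSet, k_dist: float, k_dih: float,
    start: Structure, atom_map: list[int] | None = None,
) -> RestraintSet:
    """Anchor distances (L1-L2, L2-L3, L1-L3) + one torsion per central bond.

    ``atom_map`` maps graph atom indices to structure atom indices; by
    default graph atom *i* is the *i*-th ligand atom of ``start``. The
    torsion for each central bond is the lexicographically smallest
    heavy-atom quadruple, making the (otherwise arbitrary) choice
    reproducible. x0 values come from the starting coordinates.
    """
    if atom_map is None:
        lig = start.ligand_atom_indices()
        if len(lig) < len(graph.atoms):
            raise RestraintError(
                f"graph has {len(graph.atoms)} atoms but structure has "
                f"{len(lig)} ligand atoms"
            )
        atom_map = lig[: len(graph.atoms)]
    a = anchors
    mapped = set(atom_map)
    if not {a.L1, a.L2, a.L3} <= mapped:
        raise RestraintError("ligand anchor atoms are absent from the graph mapping")
    terms = [
        HarmonicRestraint("distance", (a.L1, a.L2), k_dist, 0.0, "DL12"),
        HarmonicRestraint("distance", (a.L2, a.L3), k_dist, 0.0, "DL23"),
        HarmonicRestraint("distance", (a.L1, a.L3), k_dist, 0.0, "DL13"),
    ]
    for n, bond in enumerate(enumerate_central_bonds(graph), start=1):
        quad = _dihedral_for_bond(graph, bond)
        atoms = tuple(atom_map[q] for q in quad)
        terms.append(HarmonicRestraint("dihedral", atoms, k_dih, 0.0, f"TC{n}"))
    rset = RestraintSet(terms=terms, group="ligand_conf")
    return measure_reference_values(rset, start)


# ---------------------------------------------------------------------------
# Energies, scaling, reference values
# ---------------------------------------------------------------------------

def restraint_energy(
    rset: RestraintSet, coords=None, dummies=None, structure: Structure | None = None
) -> float:
    """Total harmonic energy Σ k (x - x0)², kcal/mol.

    ``coords`` may be a mapping atom index -> xyz; otherwise coordinates
    come from ``structure``. Angular displacements are converted to
    radians; dihedral differences wrap to (-180°, 180°].
    """
    total = 0.0
    for term in rset.terms:
        x = measure_term(term, structure=structure, dummies=dummies, coords=coords)
        if term.kind == "distance":
            dx = x - term.x0
        elif term.kind == "angle":
            dx = np.radians(x - term.x0)
        else:
            dx = np.radians(wrap_degrees(x - term.x0))
        total += term.k * dx * dx
    return float(total)


def scale_window(k_full: float, attach_pct: float) -> float:
    """Per-window spring constant: (attach_pct / 100) * k_full."""
    if attach_pct < 0:
        raise RestraintError("attach percentage must be non-negative")
    return attach_pct / 100.0 * k_full


def measure_reference_values(
    rset: RestraintSet, structure: Structure, dummies=None
) -> RestraintSet:
    """Return a copy with x0 set to the value observed in ``structure``."""
    new_terms = []
    for term in rset.terms:
        x0 = measure_term(term, structure=structure, dummies=dummies)
        if term.kind == "dihedral":
            x0 = wrap_degrees(x0)
        new_terms.append(replace(term, x0=x0))
    return RestraintSet(terms=new_terms, group=rset.group)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_restraints_tsv(rset: RestraintSet, path) -> None:
    """Columnar TSV: label, kind, atoms, k, x0, units (engine-agnostic)."""
    import pandas as pd

    rows = []
    for t in rset.terms:
        units = "kcal/mol/A^2;A" if t.kind == "distance" else "kcal/mol/rad^2;deg"
        rows.append({
            "label": t.label, "kind": t.kind,
            "atoms": ",".join(str(a) for a in t.atoms),
            "k": t.k, "x0": t.x0, "units": units, "group": rset.group,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_restraints_tsv(path) -> RestraintSet:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    terms = []
    for _, row in df.iterrows():
        atoms = tuple(
            a if a in ("N1", "N2", "N3") else int(a)
            for a in str(row["atoms"]).split(",")
        )
        terms.append(HarmonicRestraint(
            kind=row["kind"], atoms=atoms, k=float(row["k"]),
            x0=float(row["x0"]), label=str(row["label"]),
        ))
    group = df["group"].iloc[0] if "group" in df else "ligand_TR"
    return RestraintSet(terms=terms, group=group)


def write_amber_nmr_block(rset: RestraintSet, path, dummy_serials=None) -> None:
    """AMBER NMR-style restraint text (&rst namelists), one per term.

    Dummy labels are emitted via ``dummy_serials`` (label -> atom serial);
    the harmonic k maps to rk2 = rk3 and x0 to r2 = r3 with flat walls at
    r1 = x0 - 90 (angles) or x0 - 5 (distances) and symmetrically above.
    """
    lines = []
    for t in rset.terms:
        iat = []
        for a in t.atoms:
            if isinstance(a, str):
                if not dummy_serials or a not in dummy_serials:
                    raise RestraintError(f"no serial supplied for dummy {a}")
                iat.append(dummy_serials[a])
            else:
                iat.append(a + 1)  # serials are 1-based
        pad = 5.0 if t.kind == "distance" else 90.0
        lines.append(
            "&rst iat=" + ",".join(str(i) for i in iat) + ","
            + f" r1={t.x0 - pad:.5f}, r2={t.x0:.5f}, r3={t.x0:.5f},"
            + f" r4={t.x0 + pad:.5f}, rk2={t.k:.5f}, rk3={t.k:.5f}, &end"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
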