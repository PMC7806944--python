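"""Ligand anchor selection, dummy-particle placement, and the pose filter.

The restraint frame is built in a canonical orientation: after the complex
is aligned to the protein reference structure, the ligand anchor L1 is
picked inside a "strike zone" square below the protein anchor P1, the
first dummy particle N1 is placed 5.0 Å from L1 toward P1 along z, the
whole system is rotated about z so that P1, L1 and N1 share one x value
(the yz plane), and N2/N3 complete a right-angled frame. The construction
guarantees the N2-N1-L1 and N1-N2-P1 angles are 90°, which keeps the T1
and T4 dihedral restraints away from gimbal lock.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .structio import Structure, align_complex_to_reference

#: Fixed N1-L1 separation along z, Å.
N1_L1_DISTANCE = 5.0


class AnchorError(ValueError):
    """Invalid anchor-construction input (distinct from an unstable pose)."""


@dataclass(frozen=True)
class StrikeZoneParams:
    """Strike-zone and anchor-distance parameters, Å.

    The zone is a square of side 2*l1_range centred at
    (x_P1 + l1_x, y_P1 + l1_y), perpendicular to z. L1 candidates must
    have a |z - z_P1| distance within [l1_z, l1_zm] (inclusive).
    min_adis/max_adis bound the L1-L2 and L2-L3 separations.
    """

    l1_x: float = 0.0
    l1_y: float = 0.0
    l1_range: float = 2.5
    l1_z: float = 5.5
    l1_zm: float = 14.0
    min_adis: float = 3.0
    max_adis: float = 7.0

    def __post_init__(self):
        if self.l1_range <= 0:
            raise AnchorError("l1_range must be positive")
        if not 0 < self.l1_z < self.l1_zm:
            raise AnchorError("need 0 < l1_z < l1_zm")
        if not 0 < self.min_adis < self.max_adis:
            raise AnchorError("need 0 < min_adis < max_adis")


@dataclass
class AnchorSet:
    """Anchor atom indices (into a Structure) and dummy coordinates (Å)."""

    P1: int
    P2: int
    P3: int
    L1: int
    L2: int
    L3: int
    N1: np.ndarray
    N2: np.ndarray
    N3: np.ndarray

    def __post_init__(self):
        if len({self.P1, self.P2, self.P3, self.L1, self.L2, self.L3}) != 6:
            raise AnchorError("the six anchor atoms must be distinct")

    def dummies(self) -> dict[str, np.ndarray]:
        return {"N1": self.N1, "N2": self.N2, "N3": self.N3}


_SELECTOR_RE = re.compile(r"^:(\d+)@(\S+)$")


def select_atom(structure: Structure, selector: str) -> int:
    """Resolve a ``:residue@atom`` selector (e.g. ``:84@CA``) to an atom index."""
    m = _SELECTOR_RE.match(selector.strip())
    if not m:
        raise AnchorError(f"cannot parse atom selector {selector!r}")
    resnum, name = int(m.group(1)), m.group(2)
    for i, a in enumerate(structure.atoms):
        if a.residue_number == resnum and a.name == name and not a.is_hetero:
            return i
    raise AnchorError(f"no protein atom matches selector {selector!r}")


def _heavy_ligand_indices(structure: Structure, ligand_resname: str | None) -> list[int]:
    return [
        i for i in structure.ligand_atom_indices(ligand_resname)
        if structure.atoms[i].element.upper() != "H"
    ]


def find_l1(
    complex: Structure, P1: int, zone: StrikeZoneParams,
    ligand_resname: str | None = None,
) -> int | None:
    """Select L1: the in-zone ligand heavy atom nearest P1 along z.

    Returns None (pose-unstable signal) when no candidate lies in the zone;
    raises :class:`AnchorError` when the structure has no ligand at all.
    Boundaries are inclusive; ties go to the lowest atom serial.
    """
    ligand = _heavy_ligand_indices(complex, ligand_resname)
    if not ligand:
        raise AnchorError("structure contains no ligand atoms")
    p1 = np.asarray(complex.atoms[P1].xyz)
    cx, cy = p1[0] + zone.l1_x, p1[1] + zone.l1_y
    best = None
    for i in ligand:
        x, y, z = complex.atoms[i].xyz
        if abs(x - cx) > zone.l1_range or abs(y - cy) > zone.l1_range:
            continue
        dz = abs(z - p1[2])
        if not zone.l1_z <= dz <= zone.l1_zm:
            continue
        key = (dz, complex.atoms[i].serial)
        if best is None or key < best[0]:
            best = (key, i)
    return None if best is None else best[1]


def place_n1(L1_xyz, P1_xyz) -> np.ndarray:
    """Place N1 directly above/below L1, 5.0 Å toward P1 along z."""
    l1 = np.asarray(L1_xyz, dtype=float)
    p1 = np.asarray(P1_xyz, dtype=float)
    dz = p1[2] - l1[2]
    if dz == 0:
        raise AnchorError("P1 and L1 share the same z; N1 placement undefined")
    return np.array([l1[0], l1[1], l1[2] + N1_L1_DISTANCE * np.sign(dz)])


def rotate_to_yz_plane(
    complex: Structure, P1: int, L1: int, N1: np.ndarray
) -> tuple[Structure, np.ndarray, np.ndarray]:
    """Rotate about z so P1, L1 and N1 share one x coordinate.

    Returns (rotated structure, rotated N1, 3x3 rotation matrix). Of the two
    solutions the smaller-magnitude angle is used; ties go positive. If P1
    lies directly above L1 any rotation works and the identity is applied.
    """
    p1 = np.asarray(complex.atoms[P1].xyz)
    l1 = np.asarray(complex.atoms[L1].xyz)
    dx, dy = p1[0] - l1[0], p1[1] - l1[1]
    if dx == 0 and dy == 0:
        gamma = 0.0
    else:
        # x' difference = dx cos(g) - dy sin(g) = 0
        gamma = np.arctan2(dx, dy)
        if gamma > np.pi / 2:
            gamma -= np.pi
        elif gamma < -np.pi / 2:
            gamma += np.pi
        elif gamma == -np.pi / 2:
            gamma = np.pi / 2
    c, s = np.cos(gamma), np.sin(gamma)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    rotated = complex.transformed(R, np.zeros(3))
    return rotated, R @ np.asarray(N1, dtype=float), R


def place_n2_n3(P1_xyz, N1_xyz) -> tuple[np.ndarray, np.ndarray]:
    """Place N2 at P1's x,y with N1's z, and N3 above N2 by |N1-N2|."""
    p1 = np.asarray(P1_xyz, dtype=float)
    n1 = np.asarray(N1_xyz, dtype=float)
    n2 = np.array([p1[0], p1[1], n1[2]])
    d = float(np.linalg.norm(n1 - n2))
    if d == 0:
        raise AnchorError("N1 and N2 coincide; dummy frame is degenerate")
    n3 = n2 + np.array([0.0, 0.0, d])
    return n2, n3


def _angle_deg(a, b, c) -> float:
    v1 = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    v2 = np.asarray(c, dtype=float) - np.asarray(b, dtype=float)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _find_by_angle(
    complex: Structure, candidates: list[int], apex_ref, pivot_ref,
    zone: StrikeZoneParams, what: str,
) -> int:
    """Pick the candidate whose apex-pivot-candidate angle is nearest 90°,
    with the pivot-candidate distance inside [min_adis, max_adis]."""
    pivot = np.asarray(pivot_ref, dtype=float)
    apex = np.asarray(apex_ref, dtype=float)
    best = None
    for i in candidates:
        xyz = np.asarray(complex.atoms[i].xyz)
        d = float(np.linalg.norm(xyz - pivot))
        if not zone.min_adis <= d <= zone.max_adis:
            continue
        dev = abs(_angle_deg(apex, pivot, xyz) - 90.0)
        key = (dev, complex.atoms[i].serial)
        if best is None or key < best[0]:
            best = (key, i)
    if best is None:
        raise AnchorError(
            f"no candidate for {what} within [{zone.min_adis}, {zone.max_adis}] Å; "
            "adjust min_adis/max_adis"
        )
    return best[1]


def find_l2(
    complex: Structure, L1: int, N1: np.ndarray, zone: StrikeZoneParams,
    ligand_resname: str | None = None,
) -> int:
    """L2: ligand heavy atom with N1-L1-L2 angle closest to 90°."""
    candidates = [i for i in _heavy_ligand_indices(complex, ligand_resname) if i != L1]
    return _find_by_angle(
        complex, candidates, N1, complex.atoms[L1].xyz, zone, "L2"
    )


def find_l3(
    complex: Structure, L1: int, L2: int, zone: StrikeZoneParams,
    ligand_resname: str | None = None,
) -> int:
    """L3: ligand heavy atom with L1-L2-L3 angle closest to 90°."""
    candidates = [
        i for i in _heavy_ligand_indices(complex, ligand_resname)
        if i not in (L1, L2)
    ]
    return _find_by_angle(
        complex, candidates, complex.atoms[L1].xyz, complex.atoms[L2].xyz, zone, "L3"
    )


def build_anchor_set(
    complex: Structure,
    reference: Structure | None,
    P1: str | int, P2: str | int, P3: str | int,
    zone: StrikeZoneParams,
    ligand_resname: str | None = None,
) -> tuple[Structure, AnchorSet | None]:
    """Full anchor pipeline: align, pick L1, place dummies, pick L2/L3.

    Returns the structure in the canonical (aligned + rotated) frame and
    the AnchorSet, or ``(aligned, None)`` when the pose is unstable (no L1
    inside the strike zone).
    """
    work = align_complex_to_reference(complex, reference) if reference is not None else complex

    def _resolve(sel):
        return select_atom(work, sel) if isinstance(sel, str) else int(sel)

    p1, p2, p3 = _resolve(P1), _resolve(P2), _resolve(P3)
    l1 = find_l1(work, p1, zone, ligand_resname)
    if l1 is None:
        return work, None
    n1 = place_n1(work.atoms[l1].xyz, work.atoms[p1].xyz)
    work, n1, _ = rotate_to_yz_plane(work, p1, l1, n1)
    n2, n3 = place_n2_n3(work.atoms[p1].xyz, n1)
    l2 = find_l2(work, l1, n1, zone, ligand_resname)
    l3 = find_l3(work, l1, l2, zone, ligand_resname)
    anchors = AnchorSet(P1=p1, P2=p2, P3=p3, L1=l1, L2=l2, L3=l3, N1=n1, N2=n2, N3=n3)
    return work, anchors


def check_pose_retention(
    final_frame: Structure, P1: str | int, zone: StrikeZoneParams,
    ligand_resname: str | None = None,
) -> bool:
    """True when the ligand is still in the binding site (an L1 exists).

    The |z| bound at l1_zm is inclusive, matching :func:`find_l1`.
    """
    p1 = select_atom(final_frame, P1) if isinstance(P1, str) else int(P1)
    return find_l1(final_frame, p1, zone, ligand_resname) is not None
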