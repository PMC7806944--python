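"""System-preparation numerics: solvation-box z-padding, the equilibration
restraint-release schedule, and protocol time budgeting.

The z-padding solver inverts the water-count model

    N(buffer_z) = ρ [ A (z_extent + 2 buffer_z) - V_excluded ],
    A = (x_extent + 2 buffer_x)(y_extent + 2 buffer_y),

for the requested number of waters, using a relaxed (0.5-damped) Newton
iteration with a bisection fallback; ρ is the packing density of the
chosen water model in molecules/Å³. Densities are configurable inputs
with documented defaults, not constants of the method.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Default water packing densities, molecules/Å³.
WATER_DENSITY = {"TIP3P": 0.0329, "TIP4PEW": 0.0332, "SPCE": 0.0333}


class SysPrepError(ValueError):
    """Invalid preparation specification."""


@dataclass(frozen=True)
class BoxSpec:
    num_waters: int
    buffer_x: float
    buffer_y: float
    x_extent: float = 0.0
    y_extent: float = 0.0
    z_extent: float = 0.0
    excluded_volume: float = 0.0  # Å³ occupied by solute
    density: float = WATER_DENSITY["TIP3P"]

    def __post_init__(self):
        if self.density <= 0:
            raise SysPrepError("water density must be positive")
        if self.num_waters <= 0:
            raise SysPrepError("target water count must be positive")


@dataclass(frozen=True)
class ProtocolSpec:
    """Per-component (windows, ns per window) plus equilibration time."""

    components: dict[str, tuple[int, float]]
    equilibration_ns: float = 0.0

    def __post_init__(self):
        if self.equilibration_ns < 0:
            raise SysPrepError("times must be non-negative")
        for code, (nw, ns) in self.components.items():
            if nw < 0 or ns < 0:
                raise SysPrepError(f"negative budget entry for component {code!r}")


@dataclass(frozen=True)
class EquilibrationStage:
    index: int
    attach_pct: float
    factor: float  # ligand-TR spring scaling
    steps1: int
    steps2: int
    #: restraints held at full strength throughout equilibration
    maintained: tuple[str, ...] = ("protein_TR", "protein_anchor_distances")


def solve_z_buffer(
    spec: BoxSpec, tol: float = 0.5, relaxation: float = 0.5, max_iter: int = 200
) -> float:
    """buffer_z such that the modelled water count hits the target ± tol.

    Damped Newton on the (monotone) count model; falls back to bisection
    if the iteration stalls. Raises when the target cannot be met with a
    non-negative buffer.
    """
    area = (spec.x_extent + 2 * spec.buffer_x) * (spec.y_extent + 2 * spec.buffer_y)
    if area <= 0:
        raise SysPrepError("cross-sectional area must be positive")

    def count(bz: float) -> float:
        return spec.density * (area * (spec.z_extent + 2 * bz) - spec.excluded_volume)

    if count(0.0) - spec.num_waters > tol:
        raise SysPrepError(
            "target water count unreachable: the box holds more than "
            f"{spec.num_waters} waters even with zero z buffer"
        )
    slope = 2.0 * spec.density * area  # dN/d(buffer_z)
    bz = 10.0
    for _ in range(max_iter):
        resid = count(bz) - spec.num_waters
        if abs(resid) <= tol and bz >= 0:
            return bz
        bz = max(0.0, bz - relaxation * resid / slope)
    # bisection fallback on [0, upper]
    lo, hi = 0.0, 10.0
    while count(hi) < spec.num_waters:
        hi *= 2.0
        if hi > 1e6:
            raise SysPrepError("bisection fallback failed to bracket the target")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if count(mid) < spec.num_waters:
            lo = mid
        else:
            hi = mid
        if abs(count(mid) - spec.num_waters) <= tol:
            return mid
    raise SysPrepError("z-buffer solver did not converge")


def equilibration_schedule(
    release_eq, eq_steps1: int = 0, eq_steps2: int = 0
) -> list[EquilibrationStage]:
    """Staged release of the ligand TR restraints before free-energy runs.

    ``release_eq`` lists non-increasing attach percentages ending at 0
    (the last stage runs with the ligand free in the pocket). Protein TR
    restraints and the protein anchor distances stay on throughout.
    """
    pcts = [float(p) for p in release_eq]
    if not pcts:
        raise SysPrepError("release_eq must not be empty")
    if any(b > a for a, b in zip(pcts, pcts[1:])):
        raise SysPrepError("release_eq percentages must be non-increasing")
    if pcts[-1] != 0:
        raise SysPrepError("release_eq must end at 0 (ligand free)")
    return [
        EquilibrationStage(
            index=i, attach_pct=p, factor=p / 100.0,
            steps1=eq_steps1, steps2=eq_steps2,
        )
        for i, p in enumerate(pcts)
    ]


def protocol_budget(spec: ProtocolSpec) -> dict:
    """Total simulated time: Σ windows × ns/window + equilibration.

    Returns per-component nanoseconds plus totals in ns and μs.
    """
    per_component = {
        code: nw * ns for code, (nw, ns) in spec.components.items()
    }
    total_ns = sum(per_component.values()) + spec.equilibration_ns
    return {
        "per_component_ns": per_component,
        "equilibration_ns": spec.equilibration_ns,
        "total_ns": total_ns,
        "total_us": total_ns / 1000.0,
    }


def default_dd_protocol() -> ProtocolSpec:
    """The reference double-decoupling protocol budget: 16 windows × 6 ns
    for each restraint attach component, 12 decoupling windows (2.4 ns for
    electrostatics, 24/12 ns for Lennard-Jones bound/unbound), 16 × 12 ns
    for the release components, plus 80 ns of equilibration/preparation —
    1.2416 μs in total per pose."""
    return ProtocolSpec(
        components={
            "a": (16, 6.0),   # protein conf attach
            "l": (16, 6.0),   # ligand conf attach
            "t": (16, 6.0),   # ligand TR attach
            "e": (12, 2.4),   # elec decoupling, bound
            "v": (12, 24.0),  # LJ decoupling, bound
            "w": (12, 12.0),  # LJ decoupling, unbound
            "f": (12, 2.4),   # elec decoupling, unbound
            "c": (16, 12.0),  # ligand conf release
            "r": (16, 12.0),  # protein conf release
        },
        equilibration_ns=80.0,
    )
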