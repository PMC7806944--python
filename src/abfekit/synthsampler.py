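"""Synthetic Boltzmann samplers and fixtures standing in for MD sampling.

Every generator here has a closed-form or quadrature-exact reference free
energy, so estimator error is attributable solely to the estimator:

* 1-D harmonic windows — direct Gaussian draws from
  exp[-β(k_sys (x - x_sys)² + k_win (x - x0)²)] (no 1/2 factor, so the
  variance is kT / (2 (k_sys + k_win)));
* a λ-scaled toy alchemical system U(x; λ) = (1-λ) U_A + λ U_B with
  harmonic end states, exactly integrable at every λ;
* a rigid synthetic protein scaffold plus a small-ligand fixture for the
  anchor-geometry pipeline;
* a Metropolis sampler of the six restrained spherical/Euler coordinates
  including the r² sinθ sinΘ Jacobian, for cross-checking the analytic
  translational/rotational release.

All randomness is seeded explicitly; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anchorgeom import StrikeZoneParams
from .freenergy import (
    DEFAULT_TEMPERATURE, ReducedPotentialMatrix, TRReleaseSpec, WindowSamples, kt,
)
from .restraintgen import RestraintSet, WindowSchedule, scale_window
from .structio import AtomRecord, MolecularGraph, Structure


class SamplerError(ValueError):
    """Invalid sampler specification."""


@dataclass(frozen=True)
class HarmonicSystemSpec:
    """Intrinsic harmonic system plus a per-window harmonic restraint."""

    k_sys: float
    x_sys: float
    k_win: float
    x0: float
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0
    n_samples: int = 1000

    def __post_init__(self):
        if self.k_sys <= 0:
            raise SamplerError("intrinsic spring must be positive")
        if self.n_samples < 1:
            raise SamplerError("need at least one sample per window")


@dataclass(frozen=True)
class ToyAlchemicalSpec:
    """U(x; λ) = (1-λ) k_a (x - x_a)² + λ k_b (x - x_b)²."""

    k_a: float
    x_a: float
    k_b: float
    x_b: float
    lambdas: tuple[float, ...]
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0
    n_samples: int = 1000

    def __post_init__(self):
        if self.k_a <= 0 or self.k_b <= 0:
            raise SamplerError("both end-state springs must be positive")


def _rng(seed: int, *streams: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *streams])


# ---------------------------------------------------------------------------
# Harmonic windows
# ---------------------------------------------------------------------------

def _window_gaussian(spec: HarmonicSystemSpec, attach_pct: float):
    """Mean and variance of the restrained Boltzmann density."""
    k_w = scale_window(spec.k_win, attach_pct)
    k_t = spec.k_sys + k_w
    mean = (spec.k_sys * spec.x_sys + k_w * spec.x0) / k_t
    var = kt(spec.temperature) / (2.0 * k_t)
    return mean, var


def sample_harmonic_window(
    spec: HarmonicSystemSpec, window: int, attach_pct: float | None = None
) -> WindowSamples:
    """Exact i.i.d. Boltzmann draws for one attach window.

    ``attach_pct`` defaults to 100 (full restraint); window index seeds an
    independent, reproducible stream.
    """
    pct = 100.0 if attach_pct is None else attach_pct
    mean, var = _window_gaussian(spec, pct)
    rng = _rng(spec.seed, window)
    x = rng.normal(mean, np.sqrt(var), size=(spec.n_samples, 1))
    return WindowSamples(window_index=window, samples=x)


def sample_attach_windows(
    spec: HarmonicSystemSpec, schedule: WindowSchedule
) -> list[WindowSamples]:
    return [
        sample_harmonic_window(spec, i, pct)
        for i, pct in enumerate(schedule.attach_rest)
    ]


def _log_z(spec: HarmonicSystemSpec, attach_pct: float) -> float:
    """ln Z of the restrained Gaussian (no-1/2 spring convention):
    Z = sqrt(π kT / (k_sys + k_w)) · exp[-β k_sys k_w (x0 - x_sys)² / (k_sys + k_w)]."""
    kT = kt(spec.temperature)
    k_w = scale_window(spec.k_win, attach_pct)
    k_t = spec.k_sys + k_w
    return (
        0.5 * np.log(np.pi * kT / k_t)
        - (spec.k_sys * k_w * (spec.x0 - spec.x_sys) ** 2) / (k_t * kT)
    )


def analytic_window_dg(
    spec: HarmonicSystemSpec, window_a: float, window_b: float
) -> float:
    """Closed-form ΔG (kcal/mol) between two attach percentages:
    -kT ln(Z_b / Z_a)."""
    kT = kt(spec.temperature)
    return float(-kT * (_log_z(spec, window_b) - _log_z(spec, window_a)))


# ---------------------------------------------------------------------------
# Toy alchemical model
# ---------------------------------------------------------------------------

def _lambda_gaussian(spec: ToyAlchemicalSpec, lam: float):
    k = (1.0 - lam) * spec.k_a + lam * spec.k_b
    c = ((1.0 - lam) * spec.k_a * spec.x_a + lam * spec.k_b * spec.x_b) / k
    return k, c


def toy_exact_dg(spec: ToyAlchemicalSpec) -> float:
    """Exact ΔG(0 → 1) by 1-D quadrature of the end-state partition
    functions (the closed form (kT/2) ln(k_b/k_a) serves as a cross-check)."""
    from scipy import integrate

    kT = kt(spec.temperature)
    beta = 1.0 / kT

    def z(k, c):
        width = np.sqrt(40.0 / (beta * k))
        val, _ = integrate.quad(
            lambda x: np.exp(-beta * k * (x - c) ** 2),
            c - width, c + width, epsrel=1e-10,
        )
        return val

    z0 = z(spec.k_a, spec.x_a)
    z1 = z(spec.k_b, spec.x_b)
    return float(-kT * np.log(z1 / z0))


def generate_toy_alchemical(
    spec: ToyAlchemicalSpec,
) -> tuple[list[WindowSamples], ReducedPotentialMatrix, float]:
    """Seeded per-window ∂U/∂λ samples, the reduced-potential matrix over
    all λ windows, and the exact ΔG."""
    beta = 1.0 / kt(spec.temperature)
    lams = np.asarray(spec.lambdas, float)
    xs, dudl_windows = [], []
    for i, lam in enumerate(lams):
        k, c = _lambda_gaussian(spec, lam)
        rng = _rng(spec.seed, 1, i)
        x = rng.normal(c, np.sqrt(1.0 / (2.0 * beta * k)), size=spec.n_samples)
        xs.append(x)
        dudl = spec.k_b * (x - spec.x_b) ** 2 - spec.k_a * (x - spec.x_a) ** 2
        dudl_windows.append(WindowSamples(window_index=i, samples=dudl))
    all_x = np.concatenate(xs)
    u = beta * (
        np.outer(1.0 - lams, spec.k_a * (all_x - spec.x_a) ** 2)
        + np.outer(lams, spec.k_b * (all_x - spec.x_b) ** 2)
    )
    rpm = ReducedPotentialMatrix(u, np.full(len(lams), spec.n_samples))
    return dudl_windows, rpm, toy_exact_dg(spec)


def sample_dudl_at_nodes(
    spec: ToyAlchemicalSpec, nodes, n_samples: int | None = None
) -> list[WindowSamples]:
    """∂U/∂λ samples drawn at arbitrary λ nodes (for TI-GQ), independent of
    the MBAR window streams."""
    beta = 1.0 / kt(spec.temperature)
    n = n_samples or spec.n_samples
    out = []
    for i, lam in enumerate(np.asarray(nodes, float)):
        k, c = _lambda_gaussian(spec, lam)
        rng = _rng(spec.seed, 2, i)
        x = rng.normal(c, np.sqrt(1.0 / (2.0 * beta * k)), size=n)
        dudl = spec.k_b * (x - spec.x_b) ** 2 - spec.k_a * (x - spec.x_a) ** 2
        out.append(WindowSamples(window_index=i, samples=dudl))
    return out


# ---------------------------------------------------------------------------
# Multivariate restraint-coordinate windows (synthetic MD stand-in)
# ---------------------------------------------------------------------------

def sample_restraint_windows(
    rset: RestraintSet, schedule: WindowSchedule, k_sys: float,
    temperature: float = DEFAULT_TEMPERATURE, n_samples: int = 2000, seed: int = 0,
    stream: int = 0,
) -> tuple[list[WindowSamples], float]:
    """Independent Gaussian samples of every restraint coordinate per window.

    Each coordinate fluctuates about its own reference x0 with an intrinsic
    spring ``k_sys`` (Å² units for distances, rad² for angles), to which the
    window-scaled restraint spring adds. Returns the windows (columns in
    restraint order, degrees for angular coordinates) and the exact
    attach ΔG, which is the sum of independent 1-D closed forms.
    """
    windows = []
    exact = 0.0
    for r, term in enumerate(rset.terms):
        spec = HarmonicSystemSpec(
            k_sys=k_sys, x_sys=0.0, k_win=term.k, x0=0.0,
            temperature=temperature, seed=seed, n_samples=n_samples,
        )
        exact += analytic_window_dg(spec, 0.0, 100.0)
    for i, pct in enumerate(schedule.attach_rest):
        cols = []
        for r, term in enumerate(rset.terms):
            k_w = scale_window(term.k, pct)
            k_t = k_sys + k_w
            var = kt(temperature) / (2.0 * k_t)  # rad² or Å²
            rng = _rng(seed, 3, stream, i, r)
            dx = rng.normal(0.0, np.sqrt(var), size=n_samples)
            if term.kind in ("angle", "dihedral"):
                dx = np.degrees(dx)
            cols.append(term.x0 + dx)
        windows.append(WindowSamples(window_index=i, samples=np.column_stack(cols)))
    return windows, exact


# ---------------------------------------------------------------------------
# Synthetic complex fixture
# ---------------------------------------------------------------------------

_RES_NAMES = ["ALA", "GLY", "SER", "VAL", "LEU", "THR", "PHE", "ASP", "LYS", "GLU"]


@dataclass
class SyntheticComplex:
    complex: Structure
    reference: Structure
    ligand_graph: MolecularGraph
    ligand_atom_map: list[int]
    P1: str
    P2: str
    P3: str
    zone: StrikeZoneParams
    ligand_resname: str = "LIG"


def _helix_backbone(n_res: int, rng) -> list[AtomRecord]:
    """Cα trace on an ideal helix (2.3 Å radius, 1.5 Å rise, 100°/residue)
    with N and C placed off the trace so φ/ψ torsions are well defined.
    Axis along x, lifted to z = +8 so the binding site sits below."""
    atoms = []
    serial = 1
    for i in range(n_res):
        ang = np.radians(100.0 * i)
        ca = np.array([1.5 * i, 2.3 * np.cos(ang), 8.0 + 2.3 * np.sin(ang)])
        # local frame pointing along the chain
        tangent = np.array([1.5, -2.3 * np.sin(ang) * np.radians(100),
                            2.3 * np.cos(ang) * np.radians(100)])
        tangent /= np.linalg.norm(tangent)
        up = np.array([0.0, np.cos(ang), np.sin(ang)])
        n_pos = ca - 1.45 * tangent + 0.4 * up
        c_pos = ca + 1.52 * tangent + 0.4 * up
        resname = _RES_NAMES[int(rng.integers(len(_RES_NAMES)))]
        for name, pos in (("N", n_pos), ("CA", ca), ("C", c_pos)):
            atoms.append(AtomRecord(
                serial=serial, name=name, element=name[0],
                residue_name=resname, chain_id="A", residue_number=i + 1,
                xyz=tuple(pos), is_hetero=False,
            ))
            serial += 1
    return atoms


def _ligand_fixture(center: np.ndarray, rng, start_serial: int):
    """12 heavy atoms: a 6-ring (1.5 Å bonds) plus a 6-atom tail; small
    seeded jitter keeps dihedrals out of exact degeneracy."""
    ring = [
        center + np.array([1.5 * np.cos(a), 1.5 * np.sin(a), 0.0])
        for a in np.radians(np.arange(0, 360, 60))
    ]
    tail_dir = np.array([0.77, 0.0, 0.64])
    tail = [ring[0] + 1.5 * (j + 1) * tail_dir for j in range(6)]
    coords = ring + tail
    coords = [c + rng.normal(0.0, 0.08, size=3) for c in coords]
    elements = ["C"] * 6 + ["C", "N", "C", "O", "C", "C"]
    atoms = []
    for j, (pos, el) in enumerate(zip(coords, elements)):
        atoms.append(AtomRecord(
            serial=start_serial + j, name=f"{el}{j + 1}", element=el,
            residue_name="LIG", chain_id="B", residue_number=1,
            xyz=tuple(pos), is_hetero=True,
        ))
    bonds = [(i, (i + 1) % 6) for i in range(6)] + [(0, 6)] + [
        (6 + j, 7 + j) for j in range(5)
    ]
    graph = MolecularGraph(
        atoms=list(enumerate(elements)),
        bonds=sorted((min(a, b), max(a, b)) for a, b in bonds),
        names=[a.name for a in atoms],
    )
    return atoms, graph


def _random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    quat = rng.normal(size=4)
    R = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return R, t


def make_synthetic_complex(
    seed: int = 0, n_res: int = 30, zone: StrikeZoneParams | None = None,
    ligand_z_offset: float = 7.0, displace: float = 0.0,
) -> SyntheticComplex:
    """Rigid scaffold + ligand fixture for the anchor-geometry pipeline.

    The reference structure is the protein in the canonical frame; the
    returned complex carries a random rigid transform that alignment must
    undo. ``displace`` shifts the ligand in z (use > l1_zm - l1_z to force
    the pose-unstable path).
    """
    zone = zone or StrikeZoneParams()
    rng = _rng(seed, 4)
    protein_atoms = _helix_backbone(n_res, rng)
    p1_res = n_res // 2
    p1_idx = next(
        i for i, a in enumerate(protein_atoms)
        if a.residue_number == p1_res and a.name == "CA"
    )
    p1 = np.asarray(protein_atoms[p1_idx].xyz)
    center = np.array([
        p1[0] + zone.l1_x, p1[1] + zone.l1_y,
        p1[2] - ligand_z_offset - displace,
    ])
    ligand_atoms, graph = _ligand_fixture(
        center, rng, start_serial=protein_atoms[-1].serial + 1
    )
    reference = Structure([a for a in protein_atoms], title="synthetic reference")
    canonical = Structure(protein_atoms + ligand_atoms, title="synthetic complex")
    R, t = _random_rigid_transform(rng)
    moved = canonical.transformed(R, t)
    lig_map = list(range(len(protein_atoms), len(canonical.atoms)))
    return SyntheticComplex(
        complex=moved, reference=reference, ligand_graph=graph,
        ligand_atom_map=lig_map,
        P1=f":{p1_res}@CA", P2=f":{p1_res - 5}@CA", P3=f":{p1_res + 5}@CA",
        zone=zone,
    )


# ---------------------------------------------------------------------------
# Metropolis sampling of the TR coordinates
# ---------------------------------------------------------------------------

def sample_tr_coordinates(
    spec: TRReleaseSpec, n: int, seed: int = 0, scale: float = 1.0,
    step_sizes=None, burn_in: int = 500, thin: int = 5,
) -> tuple[WindowSamples, float]:
    """Metropolis sampling of (r, θ, φ, Θ, Φ, Ψ) under the scaled TR
    restraint, with the r² sinθ sinΘ Jacobian in the target density.

    Angular outputs are in degrees (matching restraint-coordinate TSVs);
    ``scale`` multiplies all force constants (a release window). Returns
    the samples and the Metropolis acceptance rate.
    """
    beta = 1.0 / kt(spec.temperature)
    refs = np.array([
        spec.r0, np.radians(spec.theta0), np.radians(spec.phi0),
        np.radians(spec.Theta0), np.radians(spec.Phi0), np.radians(spec.Psi0),
    ])
    ks = np.array([spec.k_d] + [spec.k_a] * 5) * scale
    if step_sizes is None:
        # ~1 sigma of each restrained coordinate, clipped for weak springs
        step_sizes = np.minimum(np.sqrt(1.0 / (2.0 * beta * np.maximum(ks, 1e-12))),
                                [2.0, 0.6, 1.0, 0.6, 1.0, 1.0])
    rng = _rng(seed, 5)

    def log_density(x):
        r, th, ph, TH, PH, PS = x
        if r <= 0 or not 0 < th < np.pi or not 0 < TH < np.pi:
            return -np.inf
        d = x - refs
        for a in (2, 4, 5):  # periodic dihedral differences
            d[a] = (d[a] + np.pi) % (2 * np.pi) - np.pi
        u = float(np.sum(ks * d * d))
        return -beta * u + 2.0 * np.log(r) + np.log(np.sin(th)) + np.log(np.sin(TH))

    x = refs.copy()
    logp = log_density(x)
    accepted = 0
    total = 0
    kept = []
    n_steps = burn_in + n * thin
    for step in range(n_steps):
        prop = x + rng.normal(0.0, step_sizes)
        for a in (2, 4, 5):
            prop[a] = (prop[a] + np.pi) % (2 * np.pi) - np.pi
        lp = log_density(prop)
        total += 1
        if np.log(rng.uniform()) < lp - logp:
            x, logp = prop, lp
            accepted += 1
        if step >= burn_in and (step - burn_in) % thin == 0:
            kept.append(x.copy())
    out = np.array(kept[:n])
    out[:, 1:] = np.degrees(out[:, 1:])
    return (
        WindowSamples(window_index=0, samples=out),
        accepted / total,
    )
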