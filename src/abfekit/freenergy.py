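"""Free-energy estimators: MBAR, TI with Gaussian quadrature, the
semi-analytic release of the translational/rotational restraints, and
block-based uncertainties.

All free energies are in kcal/mol. The gas constant is
R = 1.98720425864083e-3 kcal/(mol K) and the default temperature 298.15 K.
The standard state is 1 M, i.e. one molecule per 1661 Å³.

MBAR is solved in its standard self-consistent form,

    f_i = -ln Σ_n exp(-u_i(x_n)) / Σ_k N_k exp(f_k - u_k(x_n)),

with log-sum-exp stabilisation; u are reduced (dimensionless) potentials.
Per-component uncertainties follow the block convention: the trajectory is
split into N_b contiguous blocks, the estimator is re-run per block, and

    σ = sqrt( (1/N_b) Σ_n (x_n - x̄)² )

with x̄ the full-trajectory estimate (a deliberately conservative spread,
not a textbook sample standard deviation). Component σ values combine in
quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import logsumexp

from .restraintgen import RestraintSet, WindowSchedule, scale_window

#: Gas constant, kcal/(mol K).
R_KCAL = 1.98720425864083e-3
#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 298.15
#: Standard-state volume per molecule at 1 M, Å³.
STANDARD_VOLUME = 1661.0

#: Component letter codes and the estimation methods each admits.
COMPONENT_METHODS = {
    "a": {"MBAR"}, "l": {"MBAR"}, "t": {"MBAR"},
    "e": {"MBAR", "TI-GQ"}, "v": {"MBAR", "TI-GQ"},
    "w": {"MBAR", "TI-GQ"}, "f": {"MBAR", "TI-GQ"},
    "b": {"analytical"}, "c": {"MBAR"}, "r": {"MBAR"},
}


class EstimatorError(ValueError):
    """Invalid estimator input."""


class ConvergenceError(RuntimeError):
    """MBAR self-consistent iteration failed to converge."""


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    return R_KCAL * temperature


@dataclass
class WindowSamples:
    """Per-window scalar samples: restraint coordinates, ∂U/∂λ, or u rows."""

    window_index: int
    samples: np.ndarray  # (N, R) coordinate vectors or (N,) scalars

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise EstimatorError("window must contain at least one sample")

    @property
    def count(self) -> int:
        return self.samples.shape[0]


@dataclass
class ReducedPotentialMatrix:
    """u[k, n] = β U_k(x_n), with samples of all windows concatenated."""

    u: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.sum() != self.u.shape[1]:
            raise EstimatorError("window counts do not sum to the sample total")
        if not np.all(np.isfinite(self.u)):
            raise EstimatorError("reduced potentials must be finite")

    def block_split(self, n_blocks: int) -> list["ReducedPotentialMatrix"]:
        """Split each window's contiguous samples into n_blocks sub-matrices."""
        starts = np.concatenate([[0], np.cumsum(self.counts)])
        out = []
        for b in range(n_blocks):
            cols, cnts = [], []
            for w, n in enumerate(self.counts):
                idx = np.arange(starts[w], starts[w + 1])
                block = split_blocks(idx, n_blocks)[b]
                cols.append(block)
                cnts.append(len(block))
            sel = np.concatenate(cols)
            out.append(ReducedPotentialMatrix(self.u[:, sel], np.array(cnts)))
        return out


@dataclass
class TRReleaseSpec:
    """Inputs of the semi-analytic TR-release term.

    r0 is the N1-L1 reference distance (Å, 5.00 by construction);
    theta0/Theta0 are reference angles and phi0/Phi0/Psi0 reference
    dihedrals, all in degrees. k_d is in kcal/mol/Å², k_a in kcal/mol/rad²
    (shared by the five angular restraints).
    """

    k_d: float
    k_a: float
    r0: float = 5.0
    theta0: float = 90.0
    phi0: float = 0.0
    Theta0: float = 90.0
    Phi0: float = 0.0
    Psi0: float = 0.0
    temperature: float = DEFAULT_TEMPERATURE
    standard_volume: float = STANDARD_VOLUME

    def __post_init__(self):
        if self.k_d <= 0 or self.k_a <= 0:
            raise EstimatorError("force constants must be positive (integrals diverge)")
        if not (0 < self.theta0 < 180 and 0 < self.Theta0 < 180):
            raise EstimatorError("polar reference angles must lie in (0, 180)")


@dataclass
class BlockAnalysis:
    N_b: int
    x_bar: float
    x_n: list[float]
    sigma: float


@dataclass
class ComponentEstimate:
    """A named free-energy component (Table-style letter code)."""

    code: str
    dG: float
    sigma: float
    method: str
    n_windows: int = 0
    n_samples: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise EstimatorError("sigma must be non-negative")
        if self.code in COMPONENT_METHODS and self.method not in COMPONENT_METHODS[self.code]:
            raise EstimatorError(
                f"method {self.method!r} is not valid for component {self.code!r}"
            )


# ---------------------------------------------------------------------------
# Reduced potentials from restraint-coordinate samples
# ---------------------------------------------------------------------------

def reduced_potentials(
    windows: list[WindowSamples], schedule: WindowSchedule, rset: RestraintSet,
    temperature: float = DEFAULT_TEMPERATURE,
) -> ReducedPotentialMatrix:
    """u[i, n] = β Σ_r k_ir (x_nr - x0_r)², k_ir scaled per window.

    Sample columns follow the restraint order of ``rset``; angular columns
    are in degrees and converted internally, dihedral differences wrapped.
    """
    R = len(rset.terms)
    pcts = schedule.attach_rest
    if len(windows) != len(pcts):
        raise EstimatorError("one WindowSamples per attach_rest entry required")
    beta = 1.0 / kt(temperature)
    x = np.vstack([
        w.samples.reshape(w.count, -1) for w in windows
    ])
    if x.shape[1] != R:
        raise EstimatorError(
            f"samples have {x.shape[1]} coordinates but the set has {R} restraints"
        )
    counts = np.array([w.count for w in windows])
    # squared displacement per restraint, in Å² or rad²
    d2 = np.empty_like(x)
    for r, term in enumerate(rset.terms):
        diff = x[:, r] - term.x0
        if term.kind == "dihedral":
            diff = (diff + 180.0) % 360.0 - 180.0
        if term.kind in ("angle", "dihedral"):
            diff = np.radians(diff)
        d2[:, r] = diff * diff
    k_full = np.array([t.k for t in rset.terms])
    u = np.empty((len(pcts), x.shape[0]))
    for i, pct in enumerate(pcts):
        k_i = np.array([scale_window(k, pct) for k in k_full])
        u[i] = beta * d2 @ k_i
    return ReducedPotentialMatrix(u, counts)


# ---------------------------------------------------------------------------
# MBAR
# ---------------------------------------------------------------------------

def mbar_free_energies(
    rpm: ReducedPotentialMatrix, temperature: float = DEFAULT_TEMPERATURE,
    tol: float = 1e-8, max_iter: int = 10000,
) -> np.ndarray:
    """Per-window free energies G_i (kcal/mol), gauge G_0 = 0.

    Self-consistent iteration with log-sum-exp stabilisation; converges
    when the largest change in any reduced free energy is below ``tol``
    (in kT). Raises :class:`ConvergenceError` with the residual otherwise.
    """
    u = rpm.u
    log_n = np.log(rpm.counts)
    n_win = u.shape[0]
    f = np.zeros(n_win)
    for _ in range(max_iter):
        # log denominator per sample: logsumexp_k [ log N_k + f_k - u_k(x_n) ]
        log_denom = logsumexp(log_n[:, None] + f[:, None] - u, axis=0)
        f_new = -logsumexp(-u - log_denom[None, :], axis=1)
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            return f * kt(temperature)
    raise ConvergenceError(
        f"MBAR did not converge in {max_iter} iterations (residual {delta:.3e} kT)"
    )


def mbar_delta_g(
    rpm: ReducedPotentialMatrix, temperature: float = DEFAULT_TEMPERATURE, **kw
) -> float:
    """Free-energy difference last window minus first, kcal/mol."""
    g = mbar_free_energies(rpm, temperature, **kw)
    return float(g[-1] - g[0])


def mbar_standard_error(
    rpm: ReducedPotentialMatrix, temperature: float = DEFAULT_TEMPERATURE,
    i: int = 0, j: int = -1,
) -> float:
    """Asymptotic standard error of G_j - G_i, kcal/mol.

    Uses the estimator's own covariance: with W the N×K matrix of
    normalised mixture weights W_nk = exp(f_k - u_k(x_n)) / Σ_l N_l
    exp(f_l - u_l(x_n)) and W = U S Vᵀ its thin SVD,
    Θ = V S (I - S Vᵀ diag(N) V S)⁺ S Vᵀ and
    var(f_j - f_i) = Θ_ii + Θ_jj - 2 Θ_ij (in kT² units).
    """
    kT = kt(temperature)
    f = mbar_free_energies(rpm, temperature) / kT
    log_n = np.log(rpm.counts)
    log_denom = logsumexp(log_n[:, None] + f[:, None] - rpm.u, axis=0)
    W = np.exp((f[:, None] - rpm.u - log_denom[None, :]).T)  # N x K
    _, S, Vt = np.linalg.svd(W, full_matrices=False)
    V = Vt.T
    inner = np.eye(len(rpm.counts)) - (
        np.diag(S) @ Vt @ np.diag(rpm.counts.astype(float)) @ V @ np.diag(S)
    )
    theta = V @ np.diag(S) @ np.linalg.pinv(inner, rcond=1e-10) @ np.diag(S) @ Vt
    var = theta[i, i] + theta[j, j] - 2.0 * theta[i, j]
    return float(np.sqrt(max(var, 0.0)) * kT)


def mbar_with_blocks(
    rpm: ReducedPotentialMatrix, n_blocks: int,
    temperature: float = DEFAULT_TEMPERATURE,
) -> tuple[float, BlockAnalysis]:
    """Full-trajectory ΔG plus the block-spread σ (conservative)."""
    full = mbar_delta_g(rpm, temperature)
    blocks = [mbar_delta_g(b, temperature) for b in rpm.block_split(n_blocks)]
    return full, block_sigma(full, blocks)


# ---------------------------------------------------------------------------
# Thermodynamic integration with Gaussian quadrature
# ---------------------------------------------------------------------------

def gauss_legendre_01(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights mapped to [0, 1]; weights sum to 1."""
    x, w = np.polynomial.legendre.leggauss(order)
    return (x + 1.0) / 2.0, w / 2.0


def ti_gauss_quadrature(nodes, weights, dudl_means) -> float:
    """ΔG = Σ_i w_i ⟨∂U/∂λ⟩_i over λ in [0, 1]."""
    nodes = np.asarray(nodes, float)
    weights = np.asarray(weights, float)
    means = np.asarray(dudl_means, float)
    if not (len(nodes) == len(weights) == len(means)):
        raise EstimatorError("nodes, weights and means must have equal length")
    if not np.isclose(weights.sum(), 1.0, atol=1e-10):
        raise EstimatorError("quadrature weights must sum to 1 over [0, 1]")
    return float(weights @ means)


def ti_with_blocks(
    nodes, weights, dudl_windows: list[WindowSamples], n_blocks: int
) -> tuple[float, BlockAnalysis]:
    """TI-GQ estimate with block-spread σ from per-node sample blocks."""
    means = [float(np.mean(w.samples)) for w in dudl_windows]
    full = ti_gauss_quadrature(nodes, weights, means)
    blocks = []
    for b in range(n_blocks):
        bm = [
            float(np.mean(split_blocks(np.ravel(w.samples), n_blocks)[b]))
            for w in dudl_windows
        ]
        blocks.append(ti_gauss_quadrature(nodes, weights, bm))
    return full, block_sigma(full, blocks)


# ---------------------------------------------------------------------------
# Semi-analytic TR release
# ---------------------------------------------------------------------------

def analytic_tr_release(spec: TRReleaseSpec) -> float:
    """Standard-state release of the six ligand TR restraints, kcal/mol.

    ΔG = kT ln(C°/8π²) + kT ln[I_r I_θ I_φ] + kT ln[I_Θ I_Φ I_Ψ], where
    the translational triple integral factors into I_r = ∫ r² e^{-βu_r} dr,
    I_θ = ∫ sinθ e^{-βu_θ} dθ over [0, π], I_φ over [0, 2π], and the
    orientational (Euler angle) triple integral factors likewise. Dihedral
    displacements are taken periodic, so I over a full turn is independent
    of the reference value. Adaptive quadrature, relative tolerance 1e-8;
    the radial integral is truncated where the integrand falls below 1e-16
    of its peak.
    """
    kT = kt(spec.temperature)
    beta = 1.0 / kT
    c0 = 1.0 / spec.standard_volume

    half_width = np.sqrt(16.0 * np.log(10.0) / (beta * spec.k_d))
    r_lo = max(0.0, spec.r0 - half_width)
    r_hi = spec.r0 + half_width
    i_r, _ = integrate.quad(
        lambda r: r * r * np.exp(-beta * spec.k_d * (r - spec.r0) ** 2),
        r_lo, r_hi, epsrel=1e-8, limit=200,
    )

    def polar(theta0_deg):
        t0 = np.radians(theta0_deg)
        val, _ = integrate.quad(
            lambda t: np.sin(t) * np.exp(-beta * spec.k_a * (t - t0) ** 2),
            0.0, np.pi, epsrel=1e-8, limit=200, points=[t0],
        )
        return val

    def periodic():
        # ∫ over a full turn of exp(-β k Δ²) with Δ wrapped to (-π, π]
        val, _ = integrate.quad(
            lambda d: np.exp(-beta * spec.k_a * d * d),
            -np.pi, np.pi, epsrel=1e-8, limit=200, points=[0.0],
        )
        return val

    i_theta = polar(spec.theta0)
    i_Theta = polar(spec.Theta0)
    i_per = periodic()  # shared by φ, Φ, Ψ

    return float(
        kT * np.log(c0 / (8.0 * np.pi**2))
        + kT * np.log(i_r * i_theta * i_per)
        + kT * np.log(i_Theta * i_per * i_per)
    )


def tr_release_stiff_limit(spec: TRReleaseSpec) -> float:
    """Gaussian (stiff-spring) closed form of the TR release term."""
    kT = kt(spec.temperature)
    c0 = 1.0 / spec.standard_volume
    s0, S0 = np.sin(np.radians(spec.theta0)), np.sin(np.radians(spec.Theta0))
    arg = (
        (c0 / (8.0 * np.pi**2)) * spec.r0**2 * s0 * S0
        * np.pi**3 * kT**3 / np.sqrt(spec.k_d * spec.k_a**5)
    )
    return float(kT * np.log(arg))


# ---------------------------------------------------------------------------
# Blocks and uncertainty combination
# ---------------------------------------------------------------------------

def split_blocks(samples, n_blocks: int) -> list:
    """Contiguous order-preserving split; sizes differ by at most one,
    with the remainder going to the last blocks."""
    samples = list(samples) if not isinstance(samples, np.ndarray) else samples
    n = len(samples)
    if n_blocks < 2:
        raise EstimatorError("need at least 2 blocks")
    if n < n_blocks:
        raise EstimatorError(f"cannot split {n} samples into {n_blocks} blocks")
    base, rem = divmod(n, n_blocks)
    sizes = [base] * (n_blocks - rem) + [base + 1] * rem
    out, start = [], 0
    for size in sizes:
        out.append(samples[start:start + size])
        start += size
    return out


def block_sigma(full_estimate: float, block_estimates) -> BlockAnalysis:
    """σ = sqrt((1/N_b) Σ (x_n - x̄)²) with x̄ the full-trajectory value."""
    xs = [float(x) for x in block_estimates]
    if len(xs) < 2:
        raise EstimatorError("block analysis needs at least 2 blocks")
    sigma = float(np.sqrt(np.mean((np.asarray(xs) - full_estimate) ** 2)))
    return BlockAnalysis(N_b=len(xs), x_bar=float(full_estimate), x_n=xs, sigma=sigma)


def block_standard_error(analysis: BlockAnalysis) -> float:
    """SE of the full estimate: σ_blocks / sqrt(N_b) (each block holds 1/N_b
    of the data, so block estimates scatter ~sqrt(N_b) wider than x̄)."""
    return analysis.sigma / np.sqrt(analysis.N_b)


def combine_sigma_quadrature(sigmas) -> float:
    """sqrt(Σ σ_i²); the reported uncertainty of a component sum."""
    arr = np.asarray(list(sigmas), dtype=float)
    if arr.size == 0:
        return 0.0
    if np.any(arr < 0):
        raise EstimatorError("sigmas must be non-negative")
    return float(np.sqrt(np.sum(arr**2)))


# ---------------------------------------------------------------------------
# Window-sample TSV interchange
# ---------------------------------------------------------------------------

def write_window_samples(windows: list[WindowSamples], path, columns=None) -> None:
    """TSV with a ``window`` column plus one column per restraint label
    (or ``dudl``/``u_k`` for scalar series)."""
    import pandas as pd

    frames = []
    for w in windows:
        data = w.samples.reshape(w.count, -1)
        cols = columns or [f"x{r}" for r in range(data.shape[1])]
        df = pd.DataFrame(data, columns=cols)
        df.insert(0, "window", w.window_index)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_window_samples(path) -> list[WindowSamples]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if "window" not in df.columns:
        raise EstimatorError("window-sample TSV needs a 'window' column")
    out = []
    for idx, grp in df.groupby("window", sort=True):
        vals = grp.drop(columns="window").to_numpy(dtype=float)
        out.append(WindowSamples(window_index=int(idx), samples=vals))
    return out
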