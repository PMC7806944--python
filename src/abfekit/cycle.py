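"""Assembly of the standard binding free energy from its components.

The cycle sums the component free energies of the restrained dissociation
path,

    -ΔG°_bind = ΔG_p,att + (ΔG_l,conf,att + ΔG_l,TR,att) + ΔG_trans
                + (ΔG_l,conf,rel + ΔG_l,TR,rel) + ΔG_p,rel,

with the transfer term built from the electrostatic and Lennard-Jones
decoupling components: for double decoupling (DD)
ΔG_trans = (ΔG_elec,bound + ΔG_LJ,bound) - (ΔG_elec,unbound + ΔG_LJ,unbound),
while for simultaneous decoupling-recoupling (SDR) the e/v components
already contain the bound-minus-unbound differences. Components are stored
as the ΔG of the named process, so the sum is applied literally; ΔG°_bind
is reported negative-favourable. Multiple poses combine by Boltzmann sum,
ΔG°_bind = -RT ln Σ_i exp(-βΔG°_i), over stable poses only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .freenergy import (
    ComponentEstimate, DEFAULT_TEMPERATURE, R_KCAL, combine_sigma_quadrature,
)

DD_CODES = frozenset("altevwfbcr")
SDR_CODES = frozenset("altevbcr")


class CycleError(ValueError):
    """Invalid cycle assembly or pose combination."""


@dataclass(frozen=True)
class ThermoContext:
    temperature: float = DEFAULT_TEMPERATURE
    R: float = R_KCAL
    standard_concentration: float = 1.0  # molar

    def __post_init__(self):
        if self.temperature <= 0:
            raise CycleError("temperature must be positive")

    @property
    def RT(self) -> float:
        return self.R * self.temperature


@dataclass
class CycleResult:
    method: str  # "DD" | "SDR"
    components: dict[str, ComponentEstimate]
    dG_bind: float
    sigma: float
    dd_dist: float | None = None


@dataclass
class PoseResult:
    pose_id: str
    stable: bool
    dG: float | None = None
    sigma: float | None = None
    cycle: CycleResult | None = None

    def __post_init__(self):
        if not self.stable and self.dG is not None:
            raise CycleError("unstable poses carry no free energy")


def _require(components: dict[str, ComponentEstimate], codes) -> None:
    missing = sorted(set(codes) - set(components))
    if missing:
        raise CycleError(f"missing components: {', '.join(missing)}")


def _assemble(components, trans: float, method: str, ctx, dd_dist=None) -> CycleResult:
    c = components
    minus_dg = (
        c["a"].dG + c["l"].dG + c["t"].dG + trans
        + c["c"].dG + c["b"].dG + c["r"].dG
    )
    sigma = combine_sigma_quadrature(est.sigma for est in c.values())
    return CycleResult(
        method=method, components=dict(c), dG_bind=-minus_dg, sigma=sigma,
        dd_dist=dd_dist,
    )


def transfer_terms(
    components: dict[str, ComponentEstimate], method: str = "DD"
) -> dict[str, float]:
    """Electrostatic and Lennard-Jones parts of the transfer free energy.

    DD: ΔG_elec = ΔG_elec,bound - ΔG_elec,unbound (e - f) and
    ΔG_LJ = ΔG_LJ,bound - ΔG_LJ,unbound (v - w); for SDR the e and v
    components already are those differences.
    """
    c = components
    if method == "DD":
        _require(c, {"e", "v", "w", "f"})
        return {"elec": c["e"].dG - c["f"].dG, "lj": c["v"].dG - c["w"].dG}
    _require(c, {"e", "v"})
    return {"elec": c["e"].dG, "lj": c["v"].dG}


def assemble_dd(
    components: dict[str, ComponentEstimate], ctx: ThermoContext | None = None
) -> CycleResult:
    """DD cycle: transfer = (e + v) - (f + w), bound minus unbound."""
    ctx = ctx or ThermoContext()
    _require(components, DD_CODES)
    c = components
    trans = (c["e"].dG + c["v"].dG) - (c["f"].dG + c["w"].dG)
    return _assemble(c, trans, "DD", ctx)


def assemble_sdr(
    components: dict[str, ComponentEstimate], ctx: ThermoContext | None = None,
    dd_dist: float = 0.0,
) -> CycleResult:
    """SDR cycle: e and v are already bound-minus-unbound differences.

    ``dd_dist`` (the z separation between the bound ligand and its bulk
    copy) is recorded as metadata. Supplying f or w is an error: those
    components do not exist in the SDR method.
    """
    ctx = ctx or ThermoContext()
    extra = {"f", "w"} & set(components)
    if extra:
        raise CycleError(
            f"components {sorted(extra)} are not part of the SDR method"
        )
    _require(components, SDR_CODES)
    c = components
    trans = c["e"].dG + c["v"].dG
    return _assemble(c, trans, "SDR", ctx, dd_dist=dd_dist)


def combine_poses(
    poses: list[PoseResult], ctx: ThermoContext | None = None
) -> tuple[float, str]:
    """Boltzmann combination over stable poses; also returns the best pose.

    ΔG°_bind = -RT ln Σ_i exp(-ΔG°_i / RT). The result is bounded between
    the best single-pose value and that value minus RT ln N_pose.
    """
    ctx = ctx or ThermoContext()
    stable = [p for p in poses if p.stable and p.dG is not None]
    if not stable:
        raise CycleError("no stable pose to combine")
    dgs = np.array([p.dG for p in stable])
    combined = float(-ctx.RT * logsumexp(-dgs / ctx.RT))
    best = stable[int(np.argmin(dgs))].pose_id
    return combined, best


def kd_from_dg(dG: float, ctx: ThermoContext | None = None) -> float:
    """Dissociation constant in molar: Kd = C° exp(ΔG°_bind / RT)."""
    ctx = ctx or ThermoContext()
    if not np.isfinite(dG):
        raise CycleError("binding free energy must be finite")
    return float(ctx.standard_concentration * np.exp(dG / ctx.RT))


def report(results: list[PoseResult], path, ctx: ThermoContext | None = None) -> None:
    """Per-pose TSV (components, ΔG°_bind ± σ) plus a combined final row."""
    import pandas as pd

    ctx = ctx or ThermoContext()
    codes = sorted({
        code for p in results if p.cycle for code in p.cycle.components
    })
    rows = []
    for p in results:
        row = {"pose_id": p.pose_id, "stable": p.stable}
        for code in codes:
            if p.cycle and code in p.cycle.components:
                est = p.cycle.components[code]
                row[f"dG_{code}"] = round(est.dG, 4)
                row[f"sigma_{code}"] = round(est.sigma, 4)
        if p.stable and p.dG is not None:
            row["dG_bind"] = round(p.dG, 4)
            row["sigma"] = round(p.sigma or 0.0, 4)
        rows.append(row)
    if any(p.stable and p.dG is not None for p in results):
        combined, best = combine_poses(results, ctx)
        rows.append({
            "pose_id": "combined", "stable": True,
            "dG_bind": round(combined, 4), "best_pose": best,
        })
    columns = ["pose_id", "stable"]
    for code in codes:
        columns += [f"dG_{code}", f"sigma_{code}"]
    columns += ["dG_bind", "sigma", "best_pose"]
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False)
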