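"""Lumped hydraulics of a slowly gelling fluid transiting the pumped tube.

Gelation happens on the minutes scale while a pump cycle lasts well under a
second, so the model is quasi-static: the peristaltic detail is collapsed
into a target mean flow and per-pump pressure capacities, and only the slow
evolution of hydraulic resistance is resolved.

State: the material age tau(x, t) (residence time since entering the tube),
advected downstream with the mean velocity while aging at unit rate,

    dtau/dt + ubar dtau/dx = 1,       tau(0, t) = 0,

solved with a first-order upwind scheme under the CFL condition.  From the
ages, the age- and shear-dependent apparent viscosity gives per-segment
Poiseuille resistances ``8 mu dx / (pi a^4)``; the pumps form a series
network of pressure sources, each limited to its capacity ``p_cap``.  While
the demanded rise ``Q0 * R_tot`` is within the summed capacity the flow
holds at the target; beyond it the flow drops to ``sum(p_cap) / R_tot`` —
which lengthens residence times, thickens the fluid further, and can run
away.  A clog is declared the first time the flow falls below 10 % of its
initial value.

Note that at *matched total* capacity this series model makes load splitting
exactly neutral: identical pumps in series each carry an equal share of the
demand wherever the resistance sits, so single and cascade trajectories
coincide and the cascade ordering holds with equality.  The cascade's
strict advantage appears at matched *per-unit* capacity — the experimental
situation, where every channel of the same pump head is identical hardware
and adding a unit adds its full capacity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fluids import GellingViscosity, apparent_viscosity
from .geometry import CascadeConfig

__all__ = [
    "AgeField",
    "ClogReport",
    "advect_age",
    "simulate_transit",
    "compare_configurations",
    "default_capacity",
    "CLOG_FLOW_FRACTION",
]

#: Flow fraction of the initial value below which the tube counts as clogged.
CLOG_FLOW_FRACTION = 0.1


@dataclass
class AgeField:
    """Material age tau(x) >= 0 on the axial grid, pinned to 0 at the inlet."""

    x: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.x.ndim != 1 or self.x.size < 2:
            raise ValueError("age field needs a 1D grid of >= 2 points")
        if self.tau.shape != self.x.shape:
            raise ValueError("tau and x shapes differ")
        if np.any(self.tau < 0):
            raise ValueError("material age must be non-negative")

    @classmethod
    def fresh(cls, x) -> "AgeField":
        x = np.asarray(x, dtype=float)
        return cls(x=x, tau=np.zeros_like(x))


def advect_age(age: AgeField, ubar, dt: float) -> AgeField:
    """One upwind step of dtau/dt + ubar dtau/dx = 1.

    ``ubar`` is the mean axial velocity (scalar or per-node array), m/s.
    Ages grow by ``dt`` and are transported downstream; the upstream
    boundary (inlet for forward flow) is pinned at age 0.  Violating the
    CFL bound ``dt <= dx / max |ubar|`` raises a ``ValueError``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x, tau = age.x, age.tau
    dx = x[1] - x[0]
    u = np.broadcast_to(np.asarray(ubar, dtype=float), x.shape)
    umax = float(np.max(np.abs(u)))
    if umax * dt > dx * (1.0 + 1e-12):
        raise ValueError(
            f"CFL violation: dt={dt:g} s exceeds dx/max|u| = {dx / umax:g} s"
        )
    new = tau + dt
    upwind = np.zeros_like(tau)
    fwd = u >= 0.0
    upwind[1:] = np.where(fwd[1:], u[1:] * (tau[1:] - tau[:-1]) / dx, 0.0)
    upwind[:-1] += np.where(~fwd[:-1], u[:-1] * (tau[1:] - tau[:-1]) / dx, 0.0)
    new -= dt * upwind
    if fwd[0]:
        new[0] = 0.0
    else:
        new[-1] = 0.0
    return AgeField(x=x, tau=np.maximum(new, 0.0))


def default_capacity(config: CascadeConfig, fluid, pump_index: int) -> float:
    """Capacity heuristic: the pump's maximum deliverable pressure rise.

    Taken from the lubrication model as the cycle-peak pressure difference
    across the pump footprint at the configured occlusion.
    """
    from .solver import cycle_average, solve_flow

    sol = solve_flow(config, fluid, periods=2, steps_per_period=64,
                     discard_periods=1)
    pump = config.pumps[pump_index]
    lo, hi = pump.footprint
    i_lo = int(np.argmin(np.abs(sol.x - lo)))
    i_hi = int(np.argmin(np.abs(sol.x - hi)))
    rise = sol.p[sol.analyzed_slice][:, i_hi] - sol.p[sol.analyzed_slice][:, i_lo]
    return float(np.max(np.abs(rise)))


@dataclass
class ClogReport:
    """Time history of the lumped transit simulation for one configuration."""

    config: CascadeConfig
    fluid: object
    t: np.ndarray
    flow: np.ndarray                # m^3/s
    demand: np.ndarray              # Pa, total pressure demand Q0 * R_tot
    delivered: np.ndarray           # (nt, n_pumps) per-pump delivered rise, Pa
    capacities: np.ndarray          # (n_pumps,) Pa
    segment_drop: np.ndarray        # (nt, n_pumps) drop of each pump's span, Pa
    clog_time: Optional[float]
    target_flow: float
    warning: Optional[str] = None

    @property
    def clogged(self) -> bool:
        return self.clog_time is not None

    def sustained_fraction(self, level: float = 0.5) -> float:
        """Fraction of the horizon with flow above ``level`` x initial."""
        return float(np.mean(self.flow >= level * self.target_flow))

    def load_fraction(self) -> np.ndarray:
        """Per-pump peak delivered rise as a fraction of its capacity."""
        return self.delivered.max(axis=0) / self.capacities


def _segment_resistances(config: CascadeConfig, r_per_node: np.ndarray,
                         x: np.ndarray) -> np.ndarray:
    """Series resistance of each pump's span: pump i owns (x_i, x_{i+1}];
    the first pump additionally owns the suction run [0, x_1]."""
    centers = [p.center for p in config.pumps]
    cuts = ([0] + [int(np.searchsorted(x, c, side="right")) for c in centers[1:]]
            + [x.size])
    segs = np.empty(len(centers))
    for i in range(len(centers)):
        segs[i] = r_per_node[cuts[i]:cuts[i + 1]].sum()
    return segs


def simulate_transit(config: CascadeConfig, fluid, target_flow: float,
                     t_end: float, capacities: Sequence[float] | None = None,
                     dt: float | None = None, nx: int = 201) -> ClogReport:
    """Quasi-static transit of a gelling fluid with capacity-limited pumps.

    ``target_flow`` is the flow rate the pumps displace when unconstrained
    (m^3/s); ``capacities`` are the per-pump maximum pressure rises (Pa),
    defaulting to each pump's configured ``capacity``.
    """
    if not config.pumps:
        raise ValueError("configuration has no pumps")
    if target_flow <= 0:
        raise ValueError("target flow must be positive")
    warning = None
    if not isinstance(fluid, GellingViscosity):
        warning = ("fluid model has no age dependence; resistance is constant "
                   "and no clog can develop")
        warnings.warn(warning, stacklevel=2)

    if capacities is None:
        capacities = [p.capacity for p in config.pumps]
        if any(c is None for c in capacities):
            raise ValueError(
                "pump capacities must be given (config capacity fields or "
                "the capacities argument)"
            )
    caps = np.asarray([float(c) for c in capacities])
    if caps.size != len(config.pumps):
        raise ValueError("one capacity per pump required")

    r0 = config.tube.inner_radius
    area = np.pi * r0 ** 2
    x = np.linspace(0.0, config.tube.length, nx)
    dx = x[1] - x[0]
    u0 = target_flow / area
    if dt is None:
        dt = 0.5 * dx / u0
    n_steps = max(2, int(math.ceil(t_end / dt)))

    age = AgeField.fresh(x)
    Q = target_flow
    ts, flows, demands = [], [], []
    delivered_hist, seg_hist = [], []
    clog_time = None
    for k in range(n_steps + 1):
        t = k * dt
        gwall = 4.0 * Q / (np.pi * r0 ** 3)
        mu = np.asarray(apparent_viscosity(fluid, np.full(x.shape, gwall), age.tau))
        r_per_node = 8.0 * mu * dx / (np.pi * r0 ** 4)
        # total resistance summed in grid order: configurations that share a
        # fluid and total capacity follow bit-identical flow trajectories
        r_tot = float(r_per_node.sum())
        segs = _segment_resistances(config, r_per_node, x)
        demand = target_flow * r_tot
        if demand <= caps.sum():
            Q = target_flow
            delivered = caps / caps.sum() * demand
        else:
            Q = caps.sum() / r_tot
            delivered = caps.copy()
        ts.append(t)
        flows.append(Q)
        demands.append(demand)
        delivered_hist.append(delivered)
        seg_hist.append(Q * segs)
        if clog_time is None and Q < CLOG_FLOW_FRACTION * target_flow:
            clog_time = t
        if k < n_steps:
            ubar = Q / area
            sub = max(1, int(math.ceil(ubar * dt / dx)))  # keep CFL if Q grew
            for _ in range(sub):
                age = advect_age(age, ubar, dt / sub)

    return ClogReport(config=config, fluid=fluid, t=np.asarray(ts),
                      flow=np.asarray(flows), demand=np.asarray(demands),
                      delivered=np.asarray(delivered_hist), capacities=caps,
                      segment_drop=np.asarray(seg_hist), clog_time=clog_time,
                      target_flow=target_flow, warning=warning)


def compare_configurations(reports: Sequence[ClogReport]) -> pd.DataFrame:
    """Side-by-side clog metrics for configurations run on the same fluid."""
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    f0 = reports[0].fluid
    for r in reports[1:]:
        if r.fluid is not f0 and r.fluid != f0:
            raise ValueError("reports use different fluids; comparison invalid")
    rows = []
    for r in reports:
        rows.append({
            "n_pumps": len(r.config.pumps),
            "total_capacity_pa": float(r.capacities.sum()),
            "clog_time_s": np.nan if r.clog_time is None else r.clog_time,
            "clogged": r.clogged,
            "sustained_fraction": r.sustained_fraction(),
            "final_flow_fraction": float(r.flow[-1] / r.target_flow),
            "peak_load_fraction": float(r.load_fraction().max()),
        })
    return pd.DataFrame(rows)
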