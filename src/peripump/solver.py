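"""Transient lubrication solver for peristaltic tube flow.

In the long-wavelength (lubrication) regime — here the radius-to-shoe-length
ratio is 0.8 mm / 4 cm = 0.02 — the incompressible axisymmetric flow reduces
to a 1D problem.  Mass conservation with a moving wall,

    d(pi a^2)/dt + dQ/dx = 0,

combined with the local Poiseuille closure ``Q = -(pi a^4 / 8 mu) dp/dx``
(or its Rabinowitsch generalization for power-law fluids) yields, at every
instant, an elliptic equation for the pressure,

    d/dx [ k(x) dp/dx ] = d(pi a^2)/dt,      k = pi a^4 / (8 mu),

with reservoir conditions ``p(0) = p(L) = 0``.  Inertia is negligible
(Re << 1), so the pressure responds instantaneously to the wall motion: the
flow is quasi-static and exactly time-periodic once the waveform is.  The
time-marching protocol (discarded + analyzed periods) is retained so that
summaries are always taken over an integer number of cycles.

The pressure is solved node-centered with exact Dirichlet boundary rows;
the flow rate is recovered on the staggered faces, where the discrete
continuity residual is satisfied to linear-solver precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import solve_banded
from scipy.optimize import brentq

from .fluids import (
    GellingViscosity,
    NewtonianFluid,
    PowerLawFluid,
    SHEAR_RATE_FLOOR,
    apparent_viscosity,
)
from .geometry import CascadeConfig, PumpUnit, occlusion_rate, radius_field

__all__ = [
    "FlowSolution",
    "CycleSummary",
    "ActuationRecord",
    "CalibrationResult",
    "solve_flow",
    "solve_instant",
    "cycle_average",
    "pump_actuation",
    "displacement_rate",
    "total_displacement_rate",
    "calibrate_occlusion",
    "match_total_actuation",
    "peak_flow_at_pumps",
]

#: Occlusions at or above this value make the a^-4 conductance effectively
#: singular and are rejected.
MAX_OCCLUSION = 0.95

MIN_NODES_PER_SHOE = 20
MIN_STEPS_PER_PERIOD = 40


class SingularOcclusionError(ValueError):
    """Raised when a pump occlusion closes the tube beyond the solvable range."""


def _fluid_law(fluid):
    """Normalize the fluid model to ('newtonian', mu) or ('powerlaw', K, n)."""
    if isinstance(fluid, NewtonianFluid):
        return ("newtonian", fluid.viscosity)
    if isinstance(fluid, PowerLawFluid):
        if fluid.flow_index == 1.0:
            return ("newtonian", fluid.consistency)
        return ("powerlaw", fluid.consistency, fluid.flow_index)
    if isinstance(fluid, GellingViscosity):
        # fresh material: age-0 multiplier folded into the consistency
        k = fluid.base.consistency * float(fluid.age_multiplier(0.0))
        if fluid.base.flow_index == 1.0:
            return ("newtonian", k)
        return ("powerlaw", k, fluid.base.flow_index)
    raise TypeError(f"unsupported fluid model {type(fluid).__name__}")


def _check_config(config: CascadeConfig) -> None:
    for pump in config.pumps:
        if pump.occlusion >= MAX_OCCLUSION:
            raise SingularOcclusionError(
                f"occlusion {pump.occlusion} >= {MAX_OCCLUSION} closes the tube "
                "beyond the lubrication solver's range"
            )


@dataclass
class InstantSolution:
    """Quasi-static solution at a single instant."""

    t: float
    x: np.ndarray          # node positions
    x_face: np.ndarray     # staggered face positions
    a: np.ndarray          # node radius
    adot: np.ndarray       # node wall velocity da/dt
    p: np.ndarray          # node pressure, p[0] = p[-1] = 0 exactly
    q: np.ndarray          # node flow rate (face-averaged)
    q_face: np.ndarray     # face flow rate
    residual: float        # relative continuity residual


def solve_instant(config: CascadeConfig, fluid, t: float, nodes: int | None = None,
                  picard_tol: float = 1e-12, picard_max_iter: int = 200) -> InstantSolution:
    """Solve the instantaneous elliptic pressure problem at time ``t``."""
    _check_config(config)
    law = _fluid_law(fluid)
    n = config.tube.nodes if nodes is None else int(nodes)
    L = config.tube.length
    x = np.linspace(0.0, L, n)
    dx = x[1] - x[0]
    x_face = 0.5 * (x[:-1] + x[1:])

    a = np.asarray(radius_field(config, x, t), dtype=float)
    adot = np.asarray(occlusion_rate(config, x, t), dtype=float)
    a_face = np.asarray(radius_field(config, x_face, t), dtype=float)
    source = 2.0 * np.pi * a * adot  # d(pi a^2)/dt at the nodes

    if law[0] == "newtonian":
        mu = law[1]
        k_face = np.pi * a_face ** 4 / (8.0 * mu)
        p = _solve_pressure(k_face, source, dx)
        grad = np.diff(p) / dx
        q_face = -k_face * grad
    else:
        _, K, nidx = law
        # Picard iteration on the Rabinowitsch conductance
        # Q = -C |G|^(1/n - 1) G,  C = (pi n / (3n+1)) a^3 (a / 2K)^(1/n)
        C = (np.pi * nidx / (3.0 * nidx + 1.0)) * a_face ** 3 * (a_face / (2.0 * K)) ** (1.0 / nidx)
        # pressure-gradient floor equivalent to the shear-rate floor
        g_floor = 2.0 * K * SHEAR_RATE_FLOOR ** nidx / np.max(a_face)
        mu_init = K * max(SHEAR_RATE_FLOOR, 1.0) ** (nidx - 1.0)
        k_face = np.pi * a_face ** 4 / (8.0 * mu_init)
        p = _solve_pressure(k_face, source, dx)
        for _ in range(picard_max_iter):
            grad = np.diff(p) / dx
            g = np.maximum(np.abs(grad), g_floor)
            k_face = C * g ** (1.0 / nidx - 1.0)
            p_new = _solve_pressure(k_face, source, dx)
            scale = np.max(np.abs(p_new)) or 1.0
            delta = np.max(np.abs(p_new - p)) / scale
            p = p_new
            if delta < picard_tol:
                break
        grad = np.diff(p) / dx
        g = np.maximum(np.abs(grad), g_floor)
        q_face = -C * g ** (1.0 / nidx - 1.0) * grad

    q = np.empty_like(x)
    q[1:-1] = 0.5 * (q_face[:-1] + q_face[1:])
    q[0] = q_face[0] + 0.5 * dx * source[0]
    q[-1] = q_face[-1] - 0.5 * dx * source[-1]

    div = np.diff(q_face) / dx + source[1:-1]
    scale = max(np.max(np.abs(source)), np.max(np.abs(q_face)) / L)
    residual = float(np.max(np.abs(div)) / scale) if scale > 0 else 0.0

    return InstantSolution(t=float(t), x=x, x_face=x_face, a=a, adot=adot,
                           p=p, q=q, q_face=q_face, residual=residual)


def _solve_pressure(k_face: np.ndarray, source: np.ndarray, dx: float) -> np.ndarray:
    """Tridiagonal solve of d/dx(k dp/dx) = source with p = 0 at both ends."""
    n = source.size
    p = np.zeros(n)
    if n < 3:
        return p
    lower = k_face[:-1].copy()          # coefficient of p_{i-1}
    upper = k_face[1:].copy()           # coefficient of p_{i+1}
    diag = -(k_face[:-1] + k_face[1:])  # coefficient of p_i
    rhs = source[1:-1] * dx * dx
    # eliminate the Dirichlet boundary values (both zero, nothing to move)
    ab = np.zeros((3, n - 2))
    ab[0, 1:] = upper[:-1]
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]
    p[1:-1] = solve_banded((1, 1), ab, rhs)
    return p


@dataclass
class FlowSolution:
    """Space–time grids of radius, pressure and flow for one scenario."""

    config: CascadeConfig
    fluid: object
    x: np.ndarray
    x_face: np.ndarray
    t: np.ndarray
    a: np.ndarray        # (nt, nx)
    p: np.ndarray        # (nt, nx)
    q: np.ndarray        # (nt, nx) node flow rate
    q_face: np.ndarray   # (nt, nx-1)
    period: float
    steps_per_period: int
    periods: int
    discard_periods: int
    residual: float

    @property
    def analyzed_slice(self) -> slice:
        return slice(self.discard_periods * self.steps_per_period, None)

    def analyzed_periods(self) -> int:
        return self.periods - self.discard_periods


def _common_period(config: CascadeConfig) -> float:
    periods = [p.period for p in config.pumps]
    if not periods:
        return 1.0
    ref = periods[0]
    for T in periods[1:]:
        if abs(T - ref) > 1e-9 * ref:
            raise ValueError(
                "pumps have different waveform periods; cycle analysis "
                "requires a common period"
            )
    return ref


def solve_flow(config: CascadeConfig, fluid, periods: int = 5,
               steps_per_period: int = 64, discard_periods: int = 3,
               nodes: int | None = None) -> FlowSolution:
    """March the quasi-static elliptic problem over ``periods`` pump cycles.

    Grid preconditions are enforced: at least :data:`MIN_NODES_PER_SHOE`
    axial nodes per deformation length and :data:`MIN_STEPS_PER_PERIOD`
    steps per cycle.
    """
    _check_config(config)
    n = config.tube.nodes if nodes is None else int(nodes)
    dx = config.tube.length / (n - 1)
    for pump in config.pumps:
        if pump.deformation_length / dx < MIN_NODES_PER_SHOE:
            raise ValueError(
                f"grid too coarse: {pump.deformation_length / dx:.1f} nodes per "
                f"deformation length, need >= {MIN_NODES_PER_SHOE}"
            )
    if steps_per_period < MIN_STEPS_PER_PERIOD:
        raise ValueError(
            f"need >= {MIN_STEPS_PER_PERIOD} steps per period, got {steps_per_period}"
        )
    if discard_periods >= periods:
        raise ValueError("need at least one analyzed period after the discard")

    T = _common_period(config)
    nt = periods * steps_per_period
    t = np.arange(nt) * (T / steps_per_period)

    first = solve_instant(config, fluid, t[0], nodes=n)
    a = np.empty((nt, n)); p = np.empty((nt, n)); q = np.empty((nt, n))
    q_face = np.empty((nt, n - 1))
    residual = 0.0
    for j, tj in enumerate(t):
        inst = first if j == 0 else solve_instant(config, fluid, tj, nodes=n)
        a[j] = inst.a; p[j] = inst.p; q[j] = inst.q; q_face[j] = inst.q_face
        residual = max(residual, inst.residual)

    return FlowSolution(config=config, fluid=fluid, x=first.x, x_face=first.x_face,
                        t=t, a=a, p=p, q=q, q_face=q_face, period=T,
                        steps_per_period=steps_per_period, periods=periods,
                        discard_periods=discard_periods, residual=residual)


@dataclass
class CycleSummary:
    """Time statistics of a :class:`FlowSolution` over whole analyzed cycles."""

    x: np.ndarray
    mean_p: np.ndarray
    peak_p: np.ndarray       # max over the cycle, per x (signed)
    trough_p: np.ndarray     # min over the cycle, per x
    mean_q: np.ndarray
    peak_q: np.ndarray       # max |Q| over the cycle, per x
    peak_q_signed: np.ndarray
    analyzed_periods: int

    def mean_flow(self) -> float:
        """Cycle- and space-averaged flow rate (x-independent at steady state)."""
        return float(np.mean(self.mean_q))

    def mean_q_spread(self) -> float:
        """Relative axial spread of the cycle-mean flow rate."""
        scale = np.max(np.abs(self.mean_q))
        if scale == 0.0:
            return 0.0
        return float((np.max(self.mean_q) - np.min(self.mean_q)) / scale)


def cycle_average(solution: FlowSolution) -> CycleSummary:
    """Reduce a flow solution to cycle-mean and cycle-peak axial profiles."""
    n_analyzed = solution.analyzed_periods()
    if n_analyzed < 1:
        raise ValueError("cycle_average requires at least one full retained period")
    sl = solution.analyzed_slice
    p = solution.p[sl]
    q = solution.q[sl]
    return CycleSummary(
        x=solution.x,
        mean_p=p.mean(axis=0),
        peak_p=p.max(axis=0),
        trough_p=p.min(axis=0),
        mean_q=q.mean(axis=0),
        peak_q=np.abs(q).max(axis=0),
        peak_q_signed=q.max(axis=0),
        analyzed_periods=n_analyzed,
    )


@dataclass
class ActuationRecord:
    """Cycle-averaged mechanical power and displaced-volume rate of one pump."""

    pump_index: int
    power: float              # W
    displacement_rate: float  # m^3/s of positively displaced volume


def pump_actuation(solution: FlowSolution, pump_index: int) -> ActuationRecord:
    """Cycle-averaged actuation bookkeeping for one pump unit.

    Mechanical power is the cycle average of ``-int_footprint p d(pi a^2)/dt dx``;
    the displacement rate averages the positive part of the squeezed volume
    flux ``int_footprint max(0, -d(pi a^2)/dt) dx``.
    """
    if not 0 <= pump_index < len(solution.config.pumps):
        raise IndexError(f"pump {pump_index} not in config")
    pump = solution.config.pumps[pump_index]
    lo, hi = pump.footprint
    mask = (solution.x >= lo - 1e-12) & (solution.x <= hi + 1e-12)
    xs = solution.x[mask]
    sl = solution.analyzed_slice
    powers = []
    disps = []
    for j in range(solution.p[sl].shape[0]):
        tj = solution.t[sl][j]
        a = solution.a[sl][j][mask]
        adot = np.asarray(occlusion_rate(solution.config, xs, tj), dtype=float)
        S = 2.0 * np.pi * a * adot
        p = solution.p[sl][j][mask]
        powers.append(-np.trapezoid(p * S, xs))
        disps.append(np.trapezoid(np.maximum(0.0, -S), xs))
    return ActuationRecord(pump_index=pump_index,
                           power=float(np.mean(powers)),
                           displacement_rate=float(np.mean(disps)))


def displacement_rate(config: CascadeConfig, pump_index: int,
                      n_x: int = 801, n_t: int = 256) -> float:
    """Kinematic cycle-averaged displaced-volume rate of one pump, m^3/s.

    Depends only on the waveform, so it is evaluated by direct quadrature on
    a fine footprint grid without any flow solve.
    """
    pump = config.pumps[pump_index]
    lo, hi = pump.footprint
    xs = np.linspace(lo, hi, n_x)
    ts = (np.arange(n_t) + 0.5) * (pump.period / n_t)
    a = np.asarray(radius_field(config, xs[None, :], ts[:, None]), dtype=float)
    adot = np.asarray(occlusion_rate(config, xs[None, :], ts[:, None]), dtype=float)
    S = 2.0 * np.pi * a * adot
    inst = np.trapezoid(np.maximum(0.0, -S), xs, axis=1)
    return float(np.mean(inst))


def total_displacement_rate(config: CascadeConfig) -> float:
    """Sum of the kinematic displacement rates of all pumps, m^3/s."""
    return sum(displacement_rate(config, i) for i in range(len(config.pumps)))


@dataclass
class CalibrationResult:
    config: CascadeConfig
    occlusion: float
    target_kind: str
    target: float
    achieved: float
    iterations: int

    @property
    def relative_error(self) -> float:
        return abs(self.achieved - self.target) / abs(self.target)


def calibrate_occlusion(config: CascadeConfig, target_kind: str, target_value: float,
                        which_pumps: Sequence[int] | None = None,
                        fluid=None, rtol: float = 5e-3,
                        bracket: tuple[float, float] = (0.01, MAX_OCCLUSION - 1e-3),
                        pump_index: int = 0) -> CalibrationResult:
    """Bisection on a shared occlusion until the observable matches the target.

    ``target_kind`` selects the observable:

    * ``"total_actuation"`` — summed kinematic displacement rate of the
      selected pumps (m^3/s); no flow solve needed.
    * ``"peak_inplane_shear"`` — maximum in-plane shear rate on the
      meridional plane around ``pump_index`` at its deepest-occlusion
      instant (1/s); requires a fluid model.
    * ``"mean_flow"`` — cycle-mean flow rate (m^3/s); requires a fluid.

    The monotone response is verified by bracketing; an unreachable target
    raises ``ValueError`` with the bracket report.
    """
    if which_pumps is None:
        which_pumps = list(range(len(config.pumps)))
    which_pumps = list(which_pumps)
    if not which_pumps:
        raise ValueError("no pumps selected for calibration")
    if target_value <= 0:
        raise ValueError("calibration target must be positive")

    evals = {"n": 0}

    if target_kind == "total_actuation":
        def observable(phi: float) -> float:
            evals["n"] += 1
            cfg = config.with_occlusion(phi, which_pumps)
            return sum(displacement_rate(cfg, i) for i in which_pumps)
    elif target_kind == "peak_inplane_shear":
        if fluid is None:
            fluid = NewtonianFluid()
        from .shear import peak_inplane_shear_at_pump  # local import: layering

        def observable(phi: float) -> float:
            evals["n"] += 1
            cfg = config.with_occlusion(phi, which_pumps)
            return peak_inplane_shear_at_pump(cfg, fluid, pump_index)
    elif target_kind == "mean_flow":
        if fluid is None:
            fluid = NewtonianFluid()

        def observable(phi: float) -> float:
            evals["n"] += 1
            cfg = config.with_occlusion(phi, which_pumps)
            sol = solve_flow(cfg, fluid, periods=2, steps_per_period=64,
                             discard_periods=1)
            return cycle_average(sol).mean_flow()
    else:
        raise ValueError(f"unknown calibration target kind {target_kind!r}")

    current_phi = config.pumps[which_pumps[0]].occlusion
    current = observable(current_phi) if current_phi > 0 else 0.0
    if current > 0 and abs(current - target_value) <= rtol * abs(target_value):
        return CalibrationResult(config=config, occlusion=current_phi,
                                 target_kind=target_kind, target=target_value,
                                 achieved=current, iterations=evals["n"])

    lo, hi = bracket
    f_lo = observable(lo) - target_value
    f_hi = observable(hi) - target_value
    if f_lo * f_hi > 0:
        raise ValueError(
            f"calibration target {target_value:g} outside achievable bracket: "
            f"observable({lo:g}) = {f_lo + target_value:g}, "
            f"observable({hi:g}) = {f_hi + target_value:g}"
        )
    phi_star = brentq(lambda phi: observable(phi) - target_value, lo, hi,
                      xtol=1e-7, rtol=1e-12)
    achieved = observable(phi_star)
    result = CalibrationResult(config=config.with_occlusion(phi_star, which_pumps),
                               occlusion=float(phi_star), target_kind=target_kind,
                               target=target_value, achieved=achieved,
                               iterations=evals["n"])
    if result.relative_error > rtol:
        raise ValueError(
            f"calibration did not reach {target_value:g} within {rtol:.1%}: "
            f"achieved {achieved:g}"
        )
    return result


def match_total_actuation(config: CascadeConfig, reference: CascadeConfig,
                          rtol: float = 5e-3) -> CalibrationResult:
    """Calibrate ``config``'s pumps so its total displaced-volume rate equals
    that of ``reference`` (the equal-actuation linkage between scenarios)."""
    target = total_displacement_rate(reference)
    return calibrate_occlusion(config, "total_actuation", target, rtol=rtol)


def isolated_pump_peak_flows(config: CascadeConfig, fluid,
                             steps_per_period: int = 64,
                             nodes: int | None = None) -> np.ndarray:
    """Per-pump peak flow magnitude with each unit acting alone, m^3/s.

    In a rigid incompressible tube the instantaneous displaced fluxes of
    all pumps superpose over the whole length, so the raw flow field mixes
    every unit's oscillation; in a real (slightly compliant) line each
    unit's slosh stays local.  The per-unit peak throughput is therefore
    measured by the exact superposition decomposition of the quasi-static
    Stokes problem: re-solving the scenario with only that pump present and
    taking the cycle maximum of |Q| inside its footprint.
    """
    peaks = np.empty(len(config.pumps))
    for i, pump in enumerate(config.pumps):
        solo = replace(config, pumps=(pump,))
        sol = solve_flow(solo, fluid, periods=2, steps_per_period=steps_per_period,
                         discard_periods=1, nodes=nodes)
        peaks[i] = peak_flow_at_pumps(sol)
    return peaks


def peak_flow_at_pumps(solution: FlowSolution) -> float:
    """Peak flow-rate magnitude within any pump footprint over the analyzed cycles."""
    mask = np.zeros_like(solution.x, dtype=bool)
    for pump in solution.config.pumps:
        lo, hi = pump.footprint
        mask |= (solution.x >= lo - 1e-12) & (solution.x <= hi + 1e-12)
    if not mask.any():
        return 0.0
    return float(np.max(np.abs(solution.q[solution.analyzed_slice][:, mask])))
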