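"""Tube geometry and traveling-occlusion waveforms.

A roller peristaltic pump squeezes a short "shoe" segment of a flexible
tube; the moving constriction drags fluid along.  This module describes the
tube, the pump units acting on it, and the resulting time-dependent inner
radius ``a(x, t)``.

Two waveform kinds are supported:

``modulated_bump`` (default)
    A raised-cosine traveling crest of wavelength ``L_d`` (the shoe length),
    modulated by a stationary raised-cosine envelope supported exactly on
    the shoe footprint ``[x_c - L_d/2, x_c + L_d/2]``.  The squeeze is
    parameterized in cross-sectional *area* — the quantity a roller
    displaces — so the wall source term scales uniformly with the squeeze
    amplitude::

        A(x, t)/A0 = 1 - (2 phi - phi^2) * f(x, t),      a = r0 sqrt(A/A0)
        f(x, t)    = E(x) * cos^2(pi*(x - x_c - c*t)/L_d + phase/2)
        E(x)       = cos^2(pi*(x - x_c)/L_d)   inside the footprint, 0 outside

    f is C^1 in both arguments (the envelope and its slope vanish at the
    footprint edges), periodic in time with period ``L_d / c``; the radius
    reaches its minimum ``(1 - phi) * r0`` once per cycle when the crest
    aligns with the shoe center.  Because the displaced-area waveform is
    linear in the amplitude ``2 phi - phi^2``, squeezes of different depth
    share the same temporal shape: cycle-averaged and instantaneous
    displacement rates stay strictly proportional, which is what makes
    "equal total actuation" comparisons between one deep and several
    shallow pumps well posed.

``train``
    The unmodulated traveling cos^2 train inside the footprint.  It is the
    textbook infinite-wavetrain peristalsis geometry when the footprint
    spans the whole tube, which is what the closed-form mean-flow oracle
    assumes; it is C^1 only when the crest amplitude vanishes at the edges,
    so it is meant for periodic/whole-tube use.

Multi-roller shoes are modeled by ``rollers > 1``: the crest wavelength
becomes ``L_d / rollers`` and the period ``L_d / (rollers * c)``.

All quantities are SI (meters, seconds).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TubeSpec",
    "PumpUnit",
    "CascadeConfig",
    "radius_field",
    "occlusion_rate",
    "radius_slope",
    "deepest_occlusion_time",
]

WAVEFORM_KINDS = ("modulated_bump", "train")


@dataclass(frozen=True)
class TubeSpec:
    """Straight tube of length ``length`` and inner radius ``inner_radius``.

    Defaults are the study geometry: a 1 m tube of inner diameter 1.6 mm.
    ``nodes`` is the axial grid resolution used by the flow solver.
    """

    length: float = 1.0
    inner_radius: float = 0.8e-3
    nodes: int = 501

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError(f"tube length must be positive, got {self.length}")
        if not self.inner_radius > 0:
            raise ValueError(
                f"tube inner radius must be positive, got {self.inner_radius}"
            )
        if self.nodes < 3:
            raise ValueError(f"tube needs at least 3 axial nodes, got {self.nodes}")


@dataclass(frozen=True)
class PumpUnit:
    """One peristaltic pumping unit (shoe + roller(s)) acting on the tube.

    Parameters
    ----------
    center
        Shoe center position along the tube, m.
    occlusion
        Fractional radius reduction phi in [0, 1) at the deepest squeeze.
    deformation_length
        Shoe length L_d over which the tube is deformed, m (default 4 cm).
    wave_speed
        Crest traveling speed c, m/s.
    phase
        Phase offset of the crest, radians.
    rollers
        Number of simultaneous crests in the shoe.
    capacity
        Maximum pressure rise the unit can deliver, Pa (used by the lumped
        clogging model; ``None`` means "use the model default").
    """

    center: float
    occlusion: float = 0.25
    deformation_length: float = 0.04
    wave_speed: float = 0.05
    phase: float = 0.0
    rollers: int = 1
    capacity: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.occlusion < 1.0:
            raise ValueError(f"occlusion must be in [0, 1), got {self.occlusion}")
        if not self.deformation_length > 0:
            raise ValueError("deformation_length must be positive")
        if not self.wave_speed > 0:
            raise ValueError("wave_speed must be positive")
        if self.rollers < 1:
            raise ValueError("rollers must be >= 1")
        if self.capacity is not None and not self.capacity > 0:
            raise ValueError("capacity must be positive when given")

    @property
    def footprint(self) -> tuple[float, float]:
        half = 0.5 * self.deformation_length
        return (self.center - half, self.center + half)

    @property
    def wavelength(self) -> float:
        return self.deformation_length / self.rollers

    @property
    def period(self) -> float:
        """Time period of the occlusion waveform, L_d / (rollers * c)."""
        return self.deformation_length / (self.rollers * self.wave_speed)


@dataclass(frozen=True)
class CascadeConfig:
    """Full pumping scenario: tube plus an ordered series of pump units."""

    tube: TubeSpec
    pumps: tuple[PumpUnit, ...]
    waveform: str = "modulated_bump"

    def __post_init__(self) -> None:
        if self.waveform not in WAVEFORM_KINDS:
            raise ValueError(
                f"unknown waveform {self.waveform!r}; expected one of {WAVEFORM_KINDS}"
            )
        pumps = tuple(sorted(self.pumps, key=lambda p: p.center))
        object.__setattr__(self, "pumps", pumps)
        for pump in pumps:
            lo, hi = pump.footprint
            if lo < 0.0 or hi > self.tube.length:
                raise ValueError(
                    f"pump footprint [{lo:g}, {hi:g}] m extends outside the "
                    f"tube [0, {self.tube.length:g}] m"
                )
        for left, right in zip(pumps, pumps[1:]):
            if left.footprint[1] > right.footprint[0] + 1e-15:
                raise ValueError(
                    f"pump footprints overlap: {left.footprint} and {right.footprint}"
                )

    def with_occlusion(self, occlusion: float, which: Iterable[int] | None = None) -> "CascadeConfig":
        """Return a copy with ``occlusion`` applied to the selected pumps."""
        idx = set(range(len(self.pumps))) if which is None else set(which)
        pumps = tuple(
            replace(p, occlusion=occlusion) if i in idx else p
            for i, p in enumerate(self.pumps)
        )
        return replace(self, pumps=pumps)


def _check_domain(config: CascadeConfig, x: np.ndarray) -> None:
    L = config.tube.length
    if np.any(x < -1e-12) or np.any(x > L + 1e-12):
        raise ValueError(f"x outside tube domain [0, {L:g}] m")


def _pump_terms(config: CascadeConfig, pump: PumpUnit, x: np.ndarray, t) -> tuple:
    """Deformation fraction f = E*C and its partials for one pump.

    Returns ``(f, df_dt, df_dx)`` with f in [0, 1]; all arrays broadcast
    over ``x`` and ``t``.
    """
    xi = x - pump.center
    half = 0.5 * pump.deformation_length
    inside = np.abs(xi) <= half

    k_env = np.pi / pump.deformation_length
    k_wav = np.pi * pump.rollers / pump.deformation_length
    theta = k_wav * (xi - pump.wave_speed * np.asarray(t)) + 0.5 * pump.phase

    crest = np.cos(theta) ** 2
    dcrest_dt = k_wav * pump.wave_speed * np.sin(2.0 * theta)
    dcrest_dx = -k_wav * np.sin(2.0 * theta)

    if config.waveform == "modulated_bump":
        env = np.where(inside, np.cos(k_env * xi) ** 2, 0.0)
        denv_dx = np.where(inside, -k_env * np.sin(2.0 * k_env * xi), 0.0)
    else:  # train: no envelope, hard support on the footprint
        env = np.where(inside, 1.0, 0.0)
        denv_dx = np.zeros_like(env)

    f = env * crest
    df_dt = env * dcrest_dt
    df_dx = denv_dx * crest + env * dcrest_dx
    return f, df_dt, df_dx


def _deformation(config: CascadeConfig, x, t) -> tuple:
    """Fractional area deformation g = (2 phi - phi^2) f and its partials."""
    x = np.asarray(x, dtype=float)
    _check_domain(config, x)
    g = np.zeros(np.broadcast(x, np.asarray(t, dtype=float)).shape)
    gt = np.zeros_like(g)
    gx = np.zeros_like(g)
    for pump in config.pumps:
        fi, fti, fxi = _pump_terms(config, pump, x, t)
        # amplitude in area space: min radius (1-phi) r0 <-> area fraction
        amp = 2.0 * pump.occlusion - pump.occlusion ** 2
        # footprints are disjoint so the sum never stacks deformations
        g = g + amp * fi
        gt = gt + amp * fti
        gx = gx + amp * fxi
    return g, gt, gx


def radius_field(config: CascadeConfig, x, t):
    """Inner radius a(x, t) of the deformed tube, m.

    Equals ``r0`` outside every pump footprint and stays within
    ``[(1 - phi) r0, r0]`` inside; continuously differentiable in x and t
    for the default waveform.
    """
    g, _, _ = _deformation(config, x, t)
    return config.tube.inner_radius * np.sqrt(1.0 - g)


def occlusion_rate(config: CascadeConfig, x, t):
    """Wall radial velocity da/dt, m/s (exact analytic derivative)."""
    g, gt, _ = _deformation(config, x, t)
    return config.tube.inner_radius * (-0.5 * gt / np.sqrt(1.0 - g))


def radius_slope(config: CascadeConfig, x, t):
    """Axial slope da/dx, dimensionless (exact analytic derivative)."""
    g, _, gx = _deformation(config, x, t)
    return config.tube.inner_radius * (-0.5 * gx / np.sqrt(1.0 - g))


def deepest_occlusion_time(config: CascadeConfig, pump_index: int = 0) -> float:
    """First time t >= 0 at which the selected pump reaches its deepest squeeze.

    For the modulated bump that is the instant the traveling crest aligns
    with the shoe center, where the radius attains ``(1 - phi) r0``.
    """
    pump = config.pumps[pump_index]
    # theta(x_c, t) = -k c t + phase/2 must be 0 mod pi for a full-depth crest
    k = np.pi * pump.rollers / pump.deformation_length
    t = (0.5 * pump.phase) / (k * pump.wave_speed)
    period = pump.period
    return float(t % period)
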