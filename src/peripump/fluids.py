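"""Rheology models for the pumped fluid.

Three constitutive models are provided:

* :class:`NewtonianFluid` — constant viscosity.  The headline single- vs
  dual-pump comparisons are reported as ratios, which in the Stokes regime
  do not depend on the viscosity value, so a Newtonian fluid of mu = 1 Pa s
  (the order of magnitude of a 5–6 % w/v gelatin sol) is the default
  simulation fluid.
* :class:`PowerLawFluid` — shear-thinning apparent viscosity
  ``K * gdot**(n - 1)`` with a floor shear rate guarding the singularity at
  the tube axis.  ``n = 1`` reproduces the Newtonian model exactly.
* :class:`GellingViscosity` — a power-law base whose viscosity is scaled by
  a logistic function of the material age tau, rising from ~1 to a plateau
  multiplier ``m_inf`` around the gelation onset time.  This is the
  rise-to-plateau envelope of a transglutaminase-cross-linked gelatin sol
  (onset on the ten-minute scale); the brief non-monotone transient seen in
  rheometry is deliberately not modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NewtonianFluid",
    "PowerLawFluid",
    "GellingViscosity",
    "apparent_viscosity",
    "SHEAR_RATE_FLOOR",
]

#: Floor shear rate (1/s) below which the power-law viscosity is clamped.
SHEAR_RATE_FLOOR = 1e-3


@dataclass(frozen=True)
class NewtonianFluid:
    viscosity: float = 1.0  # Pa s
    density: float = 1000.0  # kg/m^3

    def __post_init__(self) -> None:
        if not self.viscosity > 0:
            raise ValueError("viscosity must be positive")
        if not self.density > 0:
            raise ValueError("density must be positive")


@dataclass(frozen=True)
class PowerLawFluid:
    """Ostwald–de Waele fluid: apparent viscosity K * gdot**(n-1)."""

    consistency: float = 1.0  # Pa s^n
    flow_index: float = 0.8  # dimensionless, (0, 1]
    density: float = 1000.0  # kg/m^3

    def __post_init__(self) -> None:
        if not self.consistency > 0:
            raise ValueError("consistency K must be positive")
        if not 0.0 < self.flow_index <= 1.0:
            raise ValueError(
                f"flow index n must be in (0, 1], got {self.flow_index}"
            )
        if not self.density > 0:
            raise ValueError("density must be positive")


@dataclass(frozen=True)
class GellingViscosity:
    """Power-law fluid whose viscosity rises with material age.

    The age multiplier is logistic,

        m(tau) = 1 + (m_inf - 1) / (1 + exp(-(tau - onset_time)/rise_time)),

    non-decreasing in tau and bounded by ``m_inf``.  Defaults: onset at
    600 s (the sol–gel transition takes over ten minutes), rise over ~2 min.
    """

    base: PowerLawFluid = field(default_factory=PowerLawFluid)
    plateau_multiplier: float = 50.0  # m_inf >= 1
    onset_time: float = 600.0  # s
    rise_time: float = 120.0  # s

    def __post_init__(self) -> None:
        if not self.plateau_multiplier >= 1.0:
            raise ValueError("plateau multiplier m_inf must be >= 1")
        if not self.onset_time >= 0:
            raise ValueError("onset_time must be non-negative")
        if not self.rise_time > 0:
            raise ValueError("rise_time must be positive")

    def age_multiplier(self, age):
        age = np.asarray(age, dtype=float)
        if np.any(age < 0):
            raise ValueError("material age must be non-negative")
        z = np.clip((age - self.onset_time) / self.rise_time, -700.0, 700.0)
        return 1.0 + (self.plateau_multiplier - 1.0) / (1.0 + np.exp(-z))


def apparent_viscosity(model, shear_rate, age=0.0):
    """Apparent viscosity in Pa s at the given shear rate (1/s) and age (s).

    Accepts scalars or arrays; negative shear rates or ages raise a
    ``ValueError``.  The power-law branch is clamped at
    :data:`SHEAR_RATE_FLOOR` so the viscosity stays bounded where the local
    shear rate vanishes (tube axis).
    """
    shear_rate = np.asarray(shear_rate, dtype=float)
    if np.any(shear_rate < 0):
        raise ValueError("shear rate must be non-negative")
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr < 0):
        raise ValueError("material age must be non-negative")

    if isinstance(model, NewtonianFluid):
        return np.broadcast_to(
            np.float64(model.viscosity), np.broadcast(shear_rate, age_arr).shape
        ).copy() if shear_rate.shape or age_arr.shape else float(model.viscosity)
    if isinstance(model, PowerLawFluid):
        gdot = np.maximum(shear_rate, SHEAR_RATE_FLOOR)
        mu = model.consistency * gdot ** (model.flow_index - 1.0)
        return mu if mu.shape else float(mu)
    if isinstance(model, GellingViscosity):
        mu = apparent_viscosity(model.base, shear_rate) * model.age_multiplier(age_arr)
        mu = np.asarray(mu)
        return mu if mu.shape else float(mu)
    raise TypeError(f"unknown fluid model {type(model).__name__}")
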