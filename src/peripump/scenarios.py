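"""Scenario presets and analytic test fixtures.

The presets reproduce the study configurations on a 1 m tube of inner
diameter 1.6 mm with 4 cm pump shoes: a single pump at 0.1 m, dual pumps at
0.1 and 0.5 m, and a secondary-pump distance sweep at 0.2 / 0.3 / 0.4 /
0.5 m with the first pump fixed at 0.1 m.  The single scenario carries an
equal-actuation linkage to the dual scenario: its occlusion is calibrated
so that its total cycle-averaged displaced-volume rate matches the dual
total, the operational reading of "identical power supply".

``make_fixture`` builds analytic velocity fields (Poiseuille, rigid motion,
pure planar extension) with their closed-form shear metrics attached; these
are the oracles the field and shear machinery is verified against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fields import VelocityField
from .fluids import NewtonianFluid
from .geometry import CascadeConfig, PumpUnit, TubeSpec

__all__ = [
    "ScenarioPreset",
    "Fixture",
    "build_study_scenarios",
    "make_fixture",
    "DEFAULT_DUAL_OCCLUSION",
]

#: Default per-pump occlusion of the dual (cascade) scenario.  Chosen so the
#: equal-actuation calibration of the single pump stays comfortably inside
#: the solvable occlusion range (the displacement rate saturates in phi).
DEFAULT_DUAL_OCCLUSION = 0.25

SWEEP_POSITIONS = (0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class ScenarioPreset:
    """A named configuration plus its fluid and calibration directive."""

    name: str
    config: CascadeConfig
    fluid: object = field(default_factory=NewtonianFluid)
    calibration: Optional[dict] = None


def _pump(center: float, occlusion: float = DEFAULT_DUAL_OCCLUSION) -> PumpUnit:
    return PumpUnit(center=center, occlusion=occlusion)


def build_study_scenarios(dual_occlusion: float = DEFAULT_DUAL_OCCLUSION) -> list:
    """The study's scenario set: single, dual, and the distance sweep."""
    tube = TubeSpec()
    fluid = NewtonianFluid()
    dual = ScenarioPreset(
        name="dual_0.1_0.5",
        config=CascadeConfig(tube=tube, pumps=(_pump(0.1, dual_occlusion),
                                               _pump(0.5, dual_occlusion))),
        fluid=fluid,
    )
    single = ScenarioPreset(
        name="single_0.1",
        config=CascadeConfig(tube=tube, pumps=(_pump(0.1, dual_occlusion),)),
        fluid=fluid,
        calibration={"kind": "equal_actuation", "reference": dual.name},
    )
    presets = [single, dual]
    for pos in SWEEP_POSITIONS:
        presets.append(ScenarioPreset(
            name=f"sweep_{pos:.1f}",
            config=CascadeConfig(tube=tube, pumps=(_pump(0.1, dual_occlusion),
                                                   _pump(pos, dual_occlusion))),
            fluid=fluid,
        ))
    return presets


def get_preset(name: str, **kwargs) -> ScenarioPreset:
    for preset in build_study_scenarios(**kwargs):
        if preset.name == name:
            return preset
    raise KeyError(f"unknown scenario preset {name!r}")


@dataclass
class Fixture:
    """An analytic velocity field with its closed-form metrics attached."""

    kind: str
    field: VelocityField
    expected: dict


def make_fixture(kind: str, radius: float = 0.8e-3, length: float = 0.02,
                 nx: int = 41, ny: int = 81, flow: float = 1e-8,
                 speed: float = 0.01, rate: float = 10.0) -> Fixture:
    """Analytic velocity-field fixtures on a rectangular meridional grid.

    * ``poiseuille`` — steady tube flow of flow rate ``flow`` in a radius
      ``radius`` tube; wall in-plane shear 4Q/(pi a^3).
    * ``rigid`` — uniform translation at ``speed``; every metric is zero.
    * ``pure_extension`` — planar straining u = rate*x, v = -rate*y.
    """
    x = np.linspace(0.0, length, nx)
    y = np.linspace(-radius, radius, ny)
    X, Y = np.meshgrid(x, y, indexing="ij")
    if kind == "poiseuille":
        u = (2.0 * flow / (np.pi * radius ** 2)) * (1.0 - Y ** 2 / radius ** 2)
        v = np.zeros_like(u)
        g = 4.0 * flow / (np.pi * radius ** 3)  # wall |du/dy|
        expected = {
            "max_eps": g,
            "max_eta": 0.0,
            "wall_dudy": -g,
            "max_gamma_substitution": math.sqrt(2.0) * g,
            "max_gamma_true_axisymmetric": g,
            "flow": flow,
        }
    elif kind == "rigid":
        u = np.full(X.shape, speed)
        v = np.zeros_like(u)
        expected = {
            "max_eps": 0.0,
            "max_eta": 0.0,
            "max_gamma_substitution": 0.0,
            "max_gamma_true_axisymmetric": 0.0,
        }
    elif kind == "pure_extension":
        u = rate * X
        v = -rate * Y
        # du/dx = rate, dv/dy = -rate, all off-diagonals vanish
        expected = {
            "max_eps": 0.0,
            "max_eta": 0.0,
            "max_gamma_substitution": math.sqrt(10.0) * rate,
            "max_gamma_true_axisymmetric": math.sqrt(6.0) * rate,
        }
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    fld = VelocityField.from_rectangular(x, y, u, v)
    return Fixture(kind=kind, field=fld, expected=expected)
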