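"""Shared fixtures: scenario presets and the heavier calibrated runs.

Session scope is used for anything that runs the flow solver so that the
acceptance tests and the module tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from peripump import NewtonianFluid, solve_flow
from peripump.scenarios import build_study_scenarios
from peripump.shear import analyze_scenario
from peripump.solver import calibrate_occlusion, match_total_actuation


@pytest.fixture(scope="session")
def fluid():
    return NewtonianFluid()


@pytest.fixture(scope="session")
def presets():
    return {p.name: p for p in build_study_scenarios()}


@pytest.fixture(scope="session")
def dual_config(presets):
    return presets["dual_0.1_0.5"].config


@pytest.fixture(scope="session")
def single_equal_actuation(presets, dual_config):
    """Single-pump config calibrated to the dual scenario's total actuation."""
    return match_total_actuation(presets["single_0.1"].config, dual_config)


@pytest.fixture(scope="session")
def solution_single(single_equal_actuation, fluid):
    return solve_flow(single_equal_actuation.config, fluid)


@pytest.fixture(scope="session")
def solution_dual(dual_config, fluid):
    return solve_flow(dual_config, fluid)


@pytest.fixture(scope="session")
def report_single(single_equal_actuation, fluid):
    return analyze_scenario(single_equal_actuation.config, fluid, name="single")


@pytest.fixture(scope="session")
def report_dual(dual_config, fluid):
    return analyze_scenario(dual_config, fluid, name="dual")


@pytest.fixture(scope="session")
def anchored_single(presets, fluid):
    """Single scenario with its peak in-plane shear anchored at 885 1/s."""
    cal = calibrate_occlusion(presets["single_0.1"].config, "peak_inplane_shear",
                              885.0, fluid=fluid)
    report = analyze_scenario(cal.config, fluid, name="single_anchored",
                              calibration=cal)
    return report


@pytest.fixture(scope="session")
def anchored_dual(presets, fluid):
    """Dual scenario with the first pump's in-plane shear anchored at 435 1/s."""
    cal = calibrate_occlusion(presets["dual_0.1_0.5"].config, "peak_inplane_shear",
                              435.0, fluid=fluid, pump_index=0)
    report = analyze_scenario(cal.config, fluid, name="dual_anchored",
                              calibration=cal)
    return report


@pytest.fixture(scope="session")
def sweep_reports(presets, fluid):
    """Distance-sweep shear reports, ordered by secondary pump position."""
    out = []
    for pos in (0.2, 0.3, 0.4, 0.5):
        p = presets[f"sweep_{pos:.1f}"]
        out.append(analyze_scenario(p.config, p.fluid, name=p.name))
    return out
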