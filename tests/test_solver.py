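"""Lubrication solver: conservation, linearity, closed-form oracle, calibration."""

import numpy as np
import pytest

from peripump.fluids import NewtonianFluid, PowerLawFluid
from peripump.geometry import CascadeConfig, PumpUnit, TubeSpec, radius_field
from peripump.solver import (
    SingularOcclusionError,
    calibrate_occlusion,
    cycle_average,
    displacement_rate,
    isolated_pump_peak_flows,
    match_total_actuation,
    pump_actuation,
    solve_flow,
    solve_instant,
    total_displacement_rate,
)


def test_zero_occlusion_means_no_flow(fluid):
    cfg = CascadeConfig(tube=TubeSpec(),
                        pumps=(PumpUnit(center=0.1, occlusion=0.0),))
    sol = solve_flow(cfg, fluid, periods=2, discard_periods=1)
    assert np.all(sol.p == 0.0)
    assert np.all(sol.q == 0.0)
    summary = cycle_average(sol)
    assert summary.mean_flow() == 0.0
    assert np.all(summary.peak_q == 0.0)


def test_continuity_residual_below_tolerance(solution_single, solution_dual):
    assert solution_single.residual < 1e-6
    assert solution_dual.residual < 1e-6


def test_reservoir_pressure_rows_exactly_zero(solution_single, solution_dual):
    for sol in (solution_single, solution_dual):
        assert np.all(sol.p[:, 0] == 0.0)
        assert np.all(sol.p[:, -1] == 0.0)


def test_mean_flow_is_axially_uniform(solution_single, solution_dual):
    assert cycle_average(solution_single).mean_q_spread() < 0.01
    assert cycle_average(solution_dual).mean_q_spread() < 0.01


def test_mean_pressure_profile_shape(solution_single):
    """Cycle-mean pressure peaks by the pump and declines linearly to the outlet."""
    summary = cycle_average(solution_single)
    x, p = summary.x, summary.mean_p
    i_max = int(np.argmax(p))
    assert 0.08 <= x[i_max] <= 0.16
    tail = x >= 0.2
    slope, intercept = np.polyfit(x[tail], p[tail], 1)
    fit = slope * x[tail] + intercept
    assert slope < 0
    assert np.max(np.abs(p[tail] - fit)) < 0.01 * p.max()
    assert abs(p[tail][-1]) < 0.01 * p.max()


def test_periodic_train_matches_closed_form_mean_flow():
    """Infinite-wavetrain mean flow: Q = c pi (<a^2> - <a^-2>/<a^-4>)."""
    lam, L, phi, c = 0.06, 0.96, 0.35, 0.05
    tube = TubeSpec(length=L, inner_radius=0.8e-3, nodes=2001)
    pump = PumpUnit(center=L / 2, occlusion=phi, deformation_length=L,
                    wave_speed=c, rollers=int(round(L / lam)))
    cfg = CascadeConfig(tube=tube, pumps=(pump,), waveform="train")
    s = np.linspace(0.0, lam, 4001)
    a = np.asarray(radius_field(cfg, L / 2 - lam / 2 + s, 0.0))
    m2 = np.trapezoid(a ** 2, s) / lam
    m_2 = np.trapezoid(a ** -2.0, s) / lam
    m_4 = np.trapezoid(a ** -4.0, s) / lam
    q_closed = c * np.pi * (m2 - m_2 / m_4)
    sol = solve_flow(cfg, NewtonianFluid(), periods=2, discard_periods=1)
    summary = cycle_average(sol)
    mid = (sol.x > 0.2) & (sol.x < 0.76)
    q_num = summary.mean_q[mid].mean()
    assert q_num == pytest.approx(q_closed, rel=0.02)


def test_pressure_linear_in_viscosity(dual_config):
    i1 = solve_instant(dual_config, NewtonianFluid(viscosity=1.0), 0.3)
    i2 = solve_instant(dual_config, NewtonianFluid(viscosity=2.0), 0.3)
    np.testing.assert_allclose(i2.p, 2.0 * i1.p, rtol=1e-12)
    np.testing.assert_allclose(i2.q, i1.q, rtol=1e-12)


def test_power_law_index_one_reduces_to_newtonian(dual_config):
    inewt = solve_instant(dual_config, NewtonianFluid(viscosity=2.0), 0.2)
    ipl = solve_instant(dual_config,
                        PowerLawFluid(consistency=2.0, flow_index=1.0), 0.2)
    np.testing.assert_allclose(ipl.p, inewt.p, rtol=1e-12)


def test_power_law_solver_converges(dual_config):
    inst = solve_instant(dual_config,
                         PowerLawFluid(consistency=1.0, flow_index=0.7), 0.0)
    assert inst.residual < 1e-6
    assert np.max(np.abs(inst.p)) > 0.0
    # shear thinning relieves pressure relative to the Newtonian fluid
    newt = solve_instant(dual_config, NewtonianFluid(viscosity=1.0), 0.0)
    assert np.max(np.abs(inst.p)) < np.max(np.abs(newt.p))


def test_actuation_zero_for_idle_pump(fluid):
    cfg = CascadeConfig(tube=TubeSpec(),
                        pumps=(PumpUnit(center=0.1, occlusion=0.0),))
    sol = solve_flow(cfg, fluid, periods=2, discard_periods=1)
    record = pump_actuation(sol, 0)
    assert record.power == 0.0
    assert record.displacement_rate == 0.0


def test_identical_dual_pumps_displace_equally(solution_dual):
    r0 = pump_actuation(solution_dual, 0)
    r1 = pump_actuation(solution_dual, 1)
    assert r0.displacement_rate == pytest.approx(r1.displacement_rate, rel=0.02)


def test_forward_wave_power_non_negative(solution_single, solution_dual):
    for sol in (solution_single, solution_dual):
        for i in range(len(sol.config.pumps)):
            assert pump_actuation(sol, i).power >= 0.0


def test_actuation_missing_pump_errors(solution_single):
    with pytest.raises(IndexError):
        pump_actuation(solution_single, 3)


def test_calibration_fixed_point(dual_config):
    target = total_displacement_rate(dual_config)
    result = calibrate_occlusion(dual_config, "total_actuation", target)
    assert result.config == dual_config
    assert result.relative_error < 5e-3


def test_calibration_matches_target(presets, dual_config):
    cal = match_total_actuation(presets["single_0.1"].config, dual_config)
    assert cal.relative_error < 5e-3
    achieved = total_displacement_rate(cal.config)
    assert achieved == pytest.approx(total_displacement_rate(dual_config), rel=5e-3)
    # the single pump must squeeze deeper than each of the dual pumps
    assert cal.occlusion > dual_config.pumps[0].occlusion


def test_calibrated_dual_per_pump_peak_is_half_of_single(
        single_equal_actuation, dual_config, fluid):
    """Equal-actuation bookkeeping: each dual unit's isolated peak flow at the
    shared pump position is half the single pump's."""
    peak_single = isolated_pump_peak_flows(single_equal_actuation.config, fluid)[0]
    peaks_dual = isolated_pump_peak_flows(dual_config, fluid)
    assert peaks_dual[0] == pytest.approx(0.5 * peak_single, rel=0.02)


def test_calibration_unreachable_target_reports_bracket(dual_config):
    huge = 100.0 * total_displacement_rate(dual_config)
    with pytest.raises(ValueError, match="bracket"):
        calibrate_occlusion(dual_config, "total_actuation", huge)


def test_singular_occlusion_rejected(fluid):
    cfg = CascadeConfig(tube=TubeSpec(),
                        pumps=(PumpUnit(center=0.1, occlusion=0.96),))
    with pytest.raises(SingularOcclusionError):
        solve_flow(cfg, fluid)


def test_grid_preconditions_enforced(dual_config, fluid):
    with pytest.raises(ValueError, match="nodes per"):
        solve_flow(dual_config, fluid, nodes=101)
    with pytest.raises(ValueError, match="steps per period"):
        solve_flow(dual_config, fluid, steps_per_period=16)
    with pytest.raises(ValueError, match="analyzed period"):
        solve_flow(dual_config, fluid, periods=3, discard_periods=3)


def test_displacement_rate_scales_with_area_amplitude(dual_config):
    """The area-parameterized squeeze makes D proportional to 2 phi - phi^2."""
    d1 = displacement_rate(dual_config.with_occlusion(0.2), 0)
    d2 = displacement_rate(dual_config.with_occlusion(0.6), 0)
    amp = lambda phi: 2 * phi - phi ** 2
    assert d2 / d1 == pytest.approx(amp(0.6) / amp(0.2), rel=1e-6)
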