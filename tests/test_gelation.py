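"""Residence-time advection and the lumped clogging network."""

import numpy as np
import pytest

from peripump.fluids import GellingViscosity, NewtonianFluid, PowerLawFluid
from peripump.gelation import (
    AgeField,
    advect_age,
    compare_configurations,
    simulate_transit,
)
from peripump.geometry import CascadeConfig, PumpUnit, TubeSpec

Q0 = 2e-9  # m^3/s, transit time ~ 1000 s in the 1 m tube


@pytest.fixture(scope="module")
def single_cfg():
    return CascadeConfig(tube=TubeSpec(), pumps=(PumpUnit(0.1, occlusion=0.5),))


@pytest.fixture(scope="module")
def dual_cfg():
    return CascadeConfig(tube=TubeSpec(), pumps=(PumpUnit(0.1, occlusion=0.25),
                                                 PumpUnit(0.5, occlusion=0.25)))


@pytest.fixture(scope="module")
def gel():
    return GellingViscosity(base=PowerLawFluid(consistency=1.0, flow_index=0.8),
                            plateau_multiplier=50.0, onset_time=600.0,
                            rise_time=120.0)


def fresh_demand(cfg, gel):
    r0 = cfg.tube.inner_radius
    gw = 4.0 * Q0 / (np.pi * r0 ** 3)
    mu = gel.base.consistency * gw ** (gel.base.flow_index - 1.0)
    return Q0 * 8.0 * mu * cfg.tube.length / (np.pi * r0 ** 4)


def test_stagnant_fluid_ages_uniformly():
    age = AgeField.fresh(np.linspace(0, 1, 11))
    for _ in range(10):
        age = advect_age(age, 0.0, 1.0)
    assert np.all(age.tau[1:] == 10.0)
    assert age.tau[0] == 0.0  # inlet pinned


def test_steady_state_age_is_transit_time():
    x = np.linspace(0, 1, 101)
    u = 2e-3
    age = AgeField.fresh(x)
    dt = 0.5 * (x[1] - x[0]) / u
    for _ in range(3000):
        age = advect_age(age, u, dt)
    np.testing.assert_allclose(age.tau, x / u, atol=dt)
    assert age.tau[-1] == pytest.approx(1.0 / u, rel=1e-3)


def test_cfl_violation_raises():
    age = AgeField.fresh(np.linspace(0, 1, 101))
    with pytest.raises(ValueError, match="CFL"):
        advect_age(age, 1.0, 1.0)


def test_non_gelling_fluid_never_clogs(single_cfg):
    with pytest.warns(UserWarning, match="no age dependence"):
        report = simulate_transit(single_cfg, NewtonianFluid(), Q0, 600.0,
                                  capacities=[1e6])
    assert not report.clogged
    assert report.warning is not None
    assert np.all(report.flow == Q0)


def test_zero_gelation_flow_constant(single_cfg, gel):
    inert = GellingViscosity(base=gel.base, plateau_multiplier=1.0,
                             onset_time=gel.onset_time, rise_time=gel.rise_time)
    report = simulate_transit(single_cfg, inert, Q0, 1200.0,
                              capacities=[2.0 * fresh_demand(single_cfg, gel)])
    assert not report.clogged
    assert np.all(report.flow == Q0)


def test_strong_gelation_clogs_in_finite_time(single_cfg, gel):
    fast = GellingViscosity(base=gel.base, plateau_multiplier=1e4,
                            onset_time=60.0, rise_time=20.0)
    report = simulate_transit(single_cfg, fast, Q0, 3600.0,
                              capacities=[2.0 * fresh_demand(single_cfg, gel)])
    assert report.clogged
    assert report.clog_time < 1200.0
    # clog time is the first threshold crossing
    i = np.searchsorted(report.t, report.clog_time)
    assert np.all(report.flow[:i] >= 0.1 * Q0)


@pytest.mark.parametrize("m_inf", [20.0, 100.0])
@pytest.mark.parametrize("t_on", [300.0, 900.0])
def test_single_clogs_no_later_than_cascade(single_cfg, dual_cfg, gel, m_inf, t_on):
    """At matched total capacity the cascade sustains flow at least as long."""
    g = GellingViscosity(base=gel.base, plateau_multiplier=m_inf,
                         onset_time=t_on, rise_time=120.0)
    cap = 2.0 * fresh_demand(single_cfg, gel)
    rs = simulate_transit(single_cfg, g, Q0, 3600.0, capacities=[cap])
    rd = simulate_transit(dual_cfg, g, Q0, 3600.0, capacities=[cap / 2, cap / 2])
    ts = np.inf if rs.clog_time is None else rs.clog_time
    td = np.inf if rd.clog_time is None else rd.clog_time
    dt = rs.t[1] - rs.t[0]
    assert ts <= td + dt
    assert rd.sustained_fraction() >= rs.sustained_fraction() - dt / rs.t[-1]


def test_cascade_strictly_better_at_matched_per_unit_capacity(single_cfg, dual_cfg, gel):
    cap = 2.0 * fresh_demand(single_cfg, gel)
    rs = simulate_transit(single_cfg, gel, Q0, 3600.0, capacities=[cap])
    rd = simulate_transit(dual_cfg, gel, Q0, 3600.0, capacities=[cap, cap])
    assert rs.clogged
    ts = rs.clog_time
    td = np.inf if rd.clog_time is None else rd.clog_time
    assert td > ts * 1.1


def test_clog_time_monotone_in_gelation_parameters(single_cfg, gel):
    cap = 2.0 * fresh_demand(single_cfg, gel)

    def clog(m_inf, t_on):
        g = GellingViscosity(base=gel.base, plateau_multiplier=m_inf,
                             onset_time=t_on, rise_time=120.0)
        r = simulate_transit(single_cfg, g, Q0, 3600.0, capacities=[cap])
        return np.inf if r.clog_time is None else r.clog_time

    times_m = [clog(m, 600.0) for m in (10.0, 30.0, 100.0)]
    assert times_m[0] >= times_m[1] >= times_m[2]
    times_t = [clog(50.0, t_on) for t_on in (300.0, 600.0, 1200.0)]
    assert times_t[0] <= times_t[1] <= times_t[2]


def test_series_network_balance(single_cfg, dual_cfg, gel):
    cap = 2.0 * fresh_demand(single_cfg, gel)
    for cfg, caps in ((single_cfg, [cap]), (dual_cfg, [cap / 2, cap / 2])):
        r = simulate_transit(cfg, gel, Q0, 1800.0, capacities=caps)
        drops = r.segment_drop.sum(axis=1)
        rises = r.delivered.sum(axis=1)
        assert np.max(np.abs(drops - rises)) <= 1e-9 * np.max(rises)


def test_dual_per_pump_load_is_half_of_single(single_cfg, dual_cfg, gel):
    cap = 10.0 * fresh_demand(single_cfg, gel)  # never saturates
    rs = simulate_transit(single_cfg, gel, Q0, 1200.0, capacities=[cap])
    rd = simulate_transit(dual_cfg, gel, Q0, 1200.0, capacities=[cap / 2, cap / 2])
    load_s = rs.delivered.max(axis=0)[0]
    load_d = rd.delivered.max(axis=0)
    assert load_d[0] + load_d[1] == pytest.approx(load_s, rel=1e-9)
    assert load_d[0] == pytest.approx(0.5 * load_s, rel=1e-9)


def test_compare_identical_configurations(single_cfg, gel):
    cap = 2.0 * fresh_demand(single_cfg, gel)
    r1 = simulate_transit(single_cfg, gel, Q0, 1200.0, capacities=[cap])
    r2 = simulate_transit(single_cfg, gel, Q0, 1200.0, capacities=[cap])
    table = compare_configurations([r1, r2])
    assert table.iloc[0].equals(table.iloc[1])


def test_compare_mismatched_fluids_rejected(single_cfg, gel):
    cap = 2.0 * fresh_demand(single_cfg, gel)
    r1 = simulate_transit(single_cfg, gel, Q0, 600.0, capacities=[cap])
    other = GellingViscosity(base=gel.base, plateau_multiplier=5.0,
                             onset_time=600.0, rise_time=120.0)
    r2 = simulate_transit(single_cfg, other, Q0, 600.0, capacities=[cap])
    with pytest.raises(ValueError, match="different fluids"):
        compare_configurations([r1, r2])


def test_invalid_inputs(single_cfg, gel):
    with pytest.raises(ValueError, match="target flow"):
        simulate_transit(single_cfg, gel, -1.0, 100.0, capacities=[1.0])
    with pytest.raises(ValueError, match="capacit"):
        simulate_transit(single_cfg, gel, Q0, 100.0)
    with pytest.raises(ValueError, match="no pumps"):
        simulate_transit(CascadeConfig(tube=TubeSpec(), pumps=()), gel, Q0,
                         100.0, capacities=[])
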