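"""Shear metrics, plane extraction and histograms against closed forms."""

import numpy as np
import pandas as pd
import pytest

from peripump.fields import compute_gradients
from peripump.scenarios import make_fixture
from peripump.shear import (
    PlaneField,
    ShearMetrics,
    compare_conditions,
    extensional_strain,
    extract_plane,
    inplane_shear,
    shear_histogram,
    total_shear_magnitude,
)


@pytest.mark.parametrize("kind", ["poiseuille", "rigid", "pure_extension"])
@pytest.mark.parametrize("convention", ["substitution", "true_axisymmetric"])
def test_metrics_match_closed_forms(kind, convention):
    """eps, eta and |gdot| on analytic fixtures agree with closed forms to 0.5%."""
    fx = make_fixture(kind)
    metrics = ShearMetrics.from_field(fx.field, convention=convention)
    tol = 0.005
    scale = max(fx.expected["max_eps"], 1e-9)
    assert np.max(np.abs(metrics.eps)) == pytest.approx(
        fx.expected["max_eps"], abs=tol * scale)
    assert np.max(np.abs(metrics.eta)) == pytest.approx(
        fx.expected["max_eta"], abs=tol * scale)
    key = f"max_gamma_{convention}"
    gscale = max(fx.expected[key], 1e-9)
    assert np.max(metrics.gamma) == pytest.approx(fx.expected[key],
                                                  abs=tol * gscale)


def test_poiseuille_total_shear_is_sqrt2_wall_shear():
    fx = make_fixture("poiseuille")
    g = compute_gradients(fx.field, method="numeric")
    wall = np.abs(g.dudy[:, -1])
    gamma = total_shear_magnitude(g)
    np.testing.assert_allclose(gamma[:, -1], np.sqrt(2.0) * wall, rtol=1e-10)
    eps = inplane_shear(g)
    assert np.max(np.abs(extensional_strain(g))) < 1e-9
    np.testing.assert_allclose(np.abs(eps[:, -1]), wall, rtol=1e-10)


def test_total_shear_zero_iff_gradients_zero():
    fx = make_fixture("rigid")
    g = compute_gradients(fx.field, method="numeric")
    assert np.max(total_shear_magnitude(g)) < 1e-9


def test_yz_plane_equals_meridional_profile(report_dual):
    """By axisymmetry the disk values at radius rho equal the meridional
    values at y = rho (and the Poiseuille-like profile rises to the wall)."""
    fx = make_fixture("poiseuille")
    metrics = ShearMetrics.from_field(fx.field)
    yz = extract_plane(metrics, "yz", x0=float(fx.field.x[3]))
    col = 3
    pos = metrics.sigma >= 0
    np.testing.assert_allclose(yz.values, metrics.gamma[col, pos], rtol=0)
    assert yz.values[0] == pytest.approx(0.0, abs=1e-9)
    assert np.all(np.diff(yz.values) >= -1e-9)  # monotone to the wall


def test_yz_outside_window_errors(report_dual):
    fx = make_fixture("poiseuille")
    metrics = ShearMetrics.from_field(fx.field)
    with pytest.raises(ValueError, match="outside"):
        extract_plane(metrics, "yz", x0=10.0)
    with pytest.raises(ValueError, match="unknown plane"):
        extract_plane(metrics, "xz")


def test_histogram_uniform_field_in_first_bin():
    vals = np.full((5, 7), 50.0)
    w = np.ones_like(vals)
    plane = PlaneField(plane="xy_meridional", values=vals, weights=w, coords={})
    hist = shear_histogram(plane, bin_width=100.0)
    assert hist.frequency[0] == pytest.approx(1.0, abs=1e-12)
    assert hist.bin_edges[0] == 0.0


def test_histogram_normalization(report_single, report_dual):
    for report in (report_single, report_dual):
        for pump in report.pumps:
            for hist in (pump.hist_xy, pump.hist_yz):
                assert abs(hist.frequency.sum() - 1.0) <= 1e-9
                assert np.all(np.diff(hist.bin_edges) > 0)


def test_histogram_invalid_bin_width():
    plane = PlaneField(plane="xy_meridional", values=np.ones((3, 3)),
                       weights=np.ones((3, 3)), coords={})
    with pytest.raises(ValueError, match="bin width"):
        shear_histogram(plane, bin_width=0.0)


def test_extensional_strain_much_smaller_than_shear(report_dual):
    """Slender geometry: max |eta| is an order below max |eps| (ratio ~ a/L_d)."""
    assert report_dual.max_eta("xy") < 0.1 * report_dual.max_eps("xy")


def test_total_to_inplane_ratio_band(anchored_single):
    """Wall-shear dominance puts max|gdot| / max|eps| in the sqrt(2) band."""
    ratio = anchored_single.max_gamma("xy") / anchored_single.max_eps("xy")
    assert 1.40 <= ratio <= 1.50


def test_compare_report_with_itself(report_dual):
    table = compare_conditions([report_dual, report_dual])
    ratios = table[[c for c in table.columns if c.startswith("ratio_")]]
    folds = table[[c for c in table.columns if c.startswith("fold_")]]
    assert np.allclose(ratios.to_numpy(dtype=float), 1.0)
    assert np.allclose(folds.to_numpy(dtype=float), 0.0)


def test_compare_requires_two_reports(report_dual):
    with pytest.raises(ValueError):
        compare_conditions([report_dual])


def test_report_maxima_attained_at_stored_points(report_dual):
    for pump in report_dual.pumps:
        x_at, y_at = pump.xy.argmax_gamma
        lo = pump.center - 2 * 0.04
        hi = pump.center + 2 * 0.04
        assert lo <= x_at <= hi
        assert abs(y_at) <= report_dual.summary.x.max()


def test_compare_table_columns(report_single, report_dual):
    table = compare_conditions([report_single, report_dual])
    assert {"plane", "metric", "single", "dual"} <= set(table.columns)
    assert "fold_reduction_dual" in table.columns
    row = table[(table.plane == "xy") & (table.metric == "max_total_shear")]
    assert float(row["fold_reduction_dual"].iloc[0]) > 0.0
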