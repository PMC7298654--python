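"""Shear-rate metrics, plane extraction, histograms and scenario reports.

Three scalar fields are computed from the velocity-gradient tensor:

* in-plane shear rate      ``eps = du/dy + dv/dx``
* extensional strain rate  ``eta = du/dx + dv/dy``
* total shear-rate magnitude from all nine gradients,

    |gdot| = [ 2(du/dx)^2 + 2(dv/dy)^2 + 2(dw/dz)^2
               + (dv/dx + du/dy)^2 + (dw/dy + dv/dz)^2
               + (du/dz + dw/dx)^2 ]^(1/2)

with the out-of-plane entries filled per the tensor's convention.

Plane maxima are reported at the instant of deepest occlusion within a
cycle (the constriction crest aligned with the shoe center), on the
meridional (xy) window around each pump and on the transverse (yz) disk at
each pump center.  Frequency distributions are area-weighted: meridional
cell areas dx * dy for the xy plane, annular areas for the yz disk, so the
Cartesian resampling of the axisymmetric profile introduces no bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fields import (
    VelocityField,
    VelocityGradientTensor,
    compute_gradients,
    reconstruct_instant,
)
from .geometry import CascadeConfig, deepest_occlusion_time
from .solver import (
    CalibrationResult,
    CycleSummary,
    cycle_average,
    solve_flow,
)

__all__ = [
    "ShearMetrics",
    "ShearHistogram",
    "AxialProfile",
    "PlaneStats",
    "ShearReport",
    "inplane_shear",
    "extensional_strain",
    "total_shear_magnitude",
    "extract_plane",
    "shear_histogram",
    "analyze_scenario",
    "compare_conditions",
    "peak_inplane_shear_at_pump",
]

DEFAULT_BIN_WIDTH = 100.0  # 1/s, matching the 100 / 600 1/s breakpoints


def inplane_shear(grad: VelocityGradientTensor) -> np.ndarray:
    """In-plane shear rate eps = du/dy + dv/dx, 1/s."""
    return grad.dudy + grad.dvdx


def extensional_strain(grad: VelocityGradientTensor) -> np.ndarray:
    """Extensional strain rate eta = du/dx + dv/dy, 1/s."""
    return grad.dudx + grad.dvdy


def total_shear_magnitude(grad: VelocityGradientTensor) -> np.ndarray:
    """Total shear-rate magnitude from all nine velocity gradients, 1/s."""
    return np.sqrt(
        2.0 * grad.dudx ** 2
        + 2.0 * grad.dvdy ** 2
        + 2.0 * grad.dwdz ** 2
        + (grad.dvdx + grad.dudy) ** 2
        + (grad.dwdy + grad.dvdz) ** 2
        + (grad.dudz + grad.dwdx) ** 2
    )


@dataclass
class ShearMetrics:
    """eps, eta and |gdot| sampled on a meridional body-fitted grid."""

    x: np.ndarray
    sigma: np.ndarray
    a: np.ndarray
    y: np.ndarray       # (nx, ns)
    eps: np.ndarray
    eta: np.ndarray
    gamma: np.ndarray
    convention: str
    t: float

    @classmethod
    def from_field(cls, fld: VelocityField,
                   convention: str = "substitution",
                   method: str = "auto") -> "ShearMetrics":
        grad = compute_gradients(fld, convention=convention, method=method)
        return cls(x=fld.x, sigma=fld.sigma, a=fld.a, y=fld.y,
                   eps=inplane_shear(grad), eta=extensional_strain(grad),
                   gamma=total_shear_magnitude(grad), convention=convention,
                   t=fld.t)


@dataclass
class PlaneField:
    """One metric restricted to a plane, with area weights for histograms."""

    plane: str              # "xy_meridional" or "yz_cross_section"
    values: np.ndarray
    weights: np.ndarray     # same shape; proportional to represented area
    coords: dict

    def maximum(self) -> tuple[float, tuple]:
        idx = np.unravel_index(np.argmax(np.abs(self.values)), self.values.shape)
        location = tuple(c[idx] if np.ndim(c) > 0 else c
                         for c in self.coords.values())
        return float(np.abs(self.values)[idx]), location


def extract_plane(metrics: ShearMetrics, plane: str, metric: str = "gamma",
                  x0: float | None = None) -> PlaneField:
    """Restrict one metric to the xy meridional window or a yz cross-section.

    ``plane`` is ``"xy"`` (the meridional window the metrics were computed
    on) or ``"yz"`` (the transverse disk at ``x0``, by axisymmetry equal to
    the meridional radial profile at the nearest grid column).
    """
    values = getattr(metrics, metric)
    if plane == "xy":
        dx = np.gradient(metrics.x)
        dsig = np.gradient(metrics.sigma)
        # meridional cell area: dx * dy with dy = a * dsigma
        w = dx[:, None] * metrics.a[:, None] * dsig[None, :]
        return PlaneField(plane="xy_meridional", values=values, weights=w,
                          coords={"x": np.broadcast_to(metrics.x[:, None], values.shape),
                                  "y": metrics.y})
    if plane == "yz":
        if x0 is None:
            raise ValueError("yz plane extraction needs the section position x0")
        if not metrics.x.min() - 1e-12 <= x0 <= metrics.x.max() + 1e-12:
            raise ValueError(f"x0={x0:g} outside the sampled window")
        col = int(np.argmin(np.abs(metrics.x - x0)))
        pos = metrics.sigma >= 0.0
        rho = metrics.a[col] * metrics.sigma[pos]
        vals = values[col, pos]
        drho = np.gradient(rho)
        w = 2.0 * np.pi * rho * drho          # annular area weights
        w[0] = np.pi * (0.5 * drho[0]) ** 2   # axis cell
        return PlaneField(plane="yz_cross_section", values=vals, weights=w,
                          coords={"x": x0, "rho": rho})
    raise ValueError(f"unknown plane {plane!r}")


@dataclass
class ShearHistogram:
    """Area-weighted frequency distribution of a shear metric."""

    bin_edges: np.ndarray   # 1/s, strictly increasing
    frequency: np.ndarray   # sums to 1
    plane: str
    scenario: str = ""
    pump_index: int | None = None
    metric: str = "gamma"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo_per_s": self.bin_edges[:-1],
            "bin_hi_per_s": self.bin_edges[1:],
            "frequency": self.frequency,
        })


def shear_histogram(plane_field: PlaneField, bin_width: float = DEFAULT_BIN_WIDTH,
                    scenario: str = "", pump_index: int | None = None,
                    metric: str = "gamma") -> ShearHistogram:
    """Area-weighted histogram of |values| with uniform bins of ``bin_width``."""
    if not bin_width > 0:
        raise ValueError("bin width must be positive")
    vals = np.abs(plane_field.values).ravel()
    w = plane_field.weights.ravel()
    if vals.size == 0:
        raise ValueError("empty plane field")
    top = max(float(vals.max()), bin_width)
    n_bins = int(math.ceil(top / bin_width - 1e-12))
    edges = np.arange(n_bins + 1) * bin_width
    hist, _ = np.histogram(vals, bins=edges, weights=w)
    total = hist.sum()
    if total <= 0:
        raise ValueError("plane field has zero total weight")
    return ShearHistogram(bin_edges=edges, frequency=hist / total,
                          plane=plane_field.plane, scenario=scenario,
                          pump_index=pump_index, metric=metric)


@dataclass
class AxialProfile:
    """A quantity sampled along the tube axis with its sampling-rule tag."""

    x: np.ndarray
    value: np.ndarray
    name: str
    units: str
    tag: str = "y = r/2"


@dataclass
class PlaneStats:
    plane: str
    max_eps: float
    max_eta: float
    max_gamma: float
    argmax_gamma: tuple

    def to_dict(self) -> dict:
        return {
            "plane": self.plane,
            "max_inplane_shear_per_s": self.max_eps,
            "max_extensional_strain_per_s": self.max_eta,
            "max_total_shear_per_s": self.max_gamma,
            "argmax_total_shear": [float(c) for c in self.argmax_gamma],
        }


@dataclass
class PumpShear:
    pump_index: int
    center: float
    instant: float
    xy: PlaneStats
    yz: PlaneStats
    hist_xy: ShearHistogram
    hist_yz: ShearHistogram


@dataclass
class ShearReport:
    """Per-scenario shear summary: plane maxima, histograms, axial profiles."""

    name: str
    convention: str
    pumps: list
    profiles: list
    summary: CycleSummary
    calibration: Optional[CalibrationResult] = None

    def max_gamma(self, plane: str = "xy") -> float:
        return max(getattr(p, plane).max_gamma for p in self.pumps)

    def max_eps(self, plane: str = "xy") -> float:
        return max(getattr(p, plane).max_eps for p in self.pumps)

    def max_eta(self, plane: str = "xy") -> float:
        return max(getattr(p, plane).max_eta for p in self.pumps)

    def max_pressure(self) -> float:
        """Cycle-peak instantaneous pressure (slosh-dominated; see docs)."""
        return float(np.max(self.summary.peak_p))

    def max_mean_pressure(self) -> float:
        """Maximum of the cycle-mean axial pressure profile."""
        return float(np.max(self.summary.mean_p))

    def to_dict(self) -> dict:
        return {
            "scenario": self.name,
            "convention": self.convention,
            "weighting": "area",
            "pumps": [
                {
                    "pump_index": p.pump_index,
                    "center_m": p.center,
                    "instant_s": p.instant,
                    "xy": p.xy.to_dict(),
                    "yz": p.yz.to_dict(),
                }
                for p in self.pumps
            ],
            "max_pressure_pa": self.max_pressure(),
            "max_cycle_mean_pressure_pa": self.max_mean_pressure(),
            "mean_flow_m3_s": self.summary.mean_flow(),
            "calibration": None if self.calibration is None else {
                "target_kind": self.calibration.target_kind,
                "target": self.calibration.target,
                "achieved": self.calibration.achieved,
                "occlusion": self.calibration.occlusion,
            },
        }


def _pump_window(config: CascadeConfig, pump_index: int,
                 half_width: float | None, nx: int) -> np.ndarray:
    pump = config.pumps[pump_index]
    if half_width is None:
        half_width = pump.deformation_length
    lo = max(0.0, pump.center - half_width)
    hi = min(config.tube.length, pump.center + half_width)
    x = np.linspace(lo, hi, nx)
    # make sure the shoe center itself is a sample (yz section lives there)
    i = int(np.argmin(np.abs(x - pump.center)))
    x[i] = pump.center
    return x


def analyze_pump_plane(config: CascadeConfig, fluid, pump_index: int,
                       convention: str = "substitution",
                       half_width: float | None = None, nx: int = 201,
                       n_sigma: int = 129, nodes: int | None = None,
                       t: float | None = None) -> ShearMetrics:
    """Shear metrics on the meridional window of one pump at its deepest instant."""
    if t is None:
        t = deepest_occlusion_time(config, pump_index)
    x = _pump_window(config, pump_index, half_width, nx)
    fld = reconstruct_instant(config, fluid, t, x=x, n_sigma=n_sigma, nodes=nodes)
    return ShearMetrics.from_field(fld, convention=convention)


def peak_inplane_shear_at_pump(config: CascadeConfig, fluid, pump_index: int,
                               convention: str = "substitution",
                               nx: int = 201, n_sigma: int = 129) -> float:
    """Maximum |eps| on the pump's meridional window at deepest occlusion."""
    metrics = analyze_pump_plane(config, fluid, pump_index, convention=convention,
                                 nx=nx, n_sigma=n_sigma)
    return float(np.max(np.abs(metrics.eps)))


def _plane_stats(metrics: ShearMetrics, plane: str, x0: float | None = None) -> PlaneStats:
    def mx(metric):
        fld = extract_plane(metrics, plane, metric=metric, x0=x0)
        return fld.maximum()

    eps, _ = mx("eps")
    eta, _ = mx("eta")
    gamma, where = mx("gamma")
    return PlaneStats(plane=plane, max_eps=eps, max_eta=eta, max_gamma=gamma,
                      argmax_gamma=where)


def analyze_scenario(config: CascadeConfig, fluid, name: str = "scenario",
                     convention: str = "substitution",
                     periods: int = 5, steps_per_period: int = 64,
                     discard_periods: int = 3,
                     half_width: float | None = None, nx_window: int = 201,
                     n_sigma: int = 129, bin_width: float = DEFAULT_BIN_WIDTH,
                     calibration: Optional[CalibrationResult] = None) -> ShearReport:
    """Full shear report for one scenario.

    Runs the lubrication solver over whole cycles for the axial profiles,
    then reconstructs the meridional field around each pump at its
    deepest-occlusion instant for plane maxima and histograms.
    """
    solution = solve_flow(config, fluid, periods=periods,
                          steps_per_period=steps_per_period,
                          discard_periods=discard_periods)
    summary = cycle_average(solution)

    pump_reports = []
    for i, pump in enumerate(config.pumps):
        t_star = deepest_occlusion_time(config, i)
        metrics = analyze_pump_plane(config, fluid, i, convention=convention,
                                     half_width=half_width, nx=nx_window,
                                     n_sigma=n_sigma, t=t_star)
        xy = _plane_stats(metrics, "xy")
        yz = _plane_stats(metrics, "yz", x0=pump.center)
        hist_xy = shear_histogram(extract_plane(metrics, "xy"), bin_width,
                                  scenario=name, pump_index=i)
        hist_yz = shear_histogram(extract_plane(metrics, "yz", x0=pump.center),
                                  bin_width, scenario=name, pump_index=i)
        pump_reports.append(PumpShear(pump_index=i, center=pump.center,
                                      instant=t_star, xy=xy, yz=yz,
                                      hist_xy=hist_xy, hist_yz=hist_yz))

    profiles = [
        AxialProfile(x=summary.x, value=summary.mean_p, name="pressure_mean",
                     units="Pa"),
        AxialProfile(x=summary.x, value=summary.peak_p, name="pressure_peak",
                     units="Pa"),
        AxialProfile(x=summary.x, value=summary.mean_q, name="flow_mean",
                     units="m^3/s"),
        AxialProfile(x=summary.x, value=summary.peak_q, name="flow_peak",
                     units="m^3/s"),
    ]
    return ShearReport(name=name, convention=convention, pumps=pump_reports,
                       profiles=profiles, summary=summary,
                       calibration=calibration)


def compare_conditions(reports: Sequence[ShearReport]) -> pd.DataFrame:
    """Tabulate plane maxima across scenarios with ratios and fold reductions.

    The first report is the reference (e.g. single pumping); for every other
    report the table carries ``ratio = reference / other`` and
    ``fold_reduction = (reference - other) / other``.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    planes = ("xy", "yz")
    rows = []
    ref = reports[0]
    for plane in planes:
        for metric, getter in (("max_inplane_shear", "max_eps"),
                               ("max_extensional_strain", "max_eta"),
                               ("max_total_shear", "max_gamma")):
            ref_val = getattr(ref, getter)(plane)
            row = {"plane": plane, "metric": metric, ref.name: ref_val}
            for other in reports[1:]:
                if len(other.pumps) == 0:
                    raise ValueError(f"report {other.name!r} has no pump planes")
                val = getattr(other, getter)(plane)
                row[other.name] = val
                if val > 0:
                    row[f"ratio_{other.name}"] = ref_val / val
                    row[f"fold_reduction_{other.name}"] = (ref_val - val) / val
                elif ref_val == val:  # both identically zero
                    row[f"ratio_{other.name}"] = 1.0
                    row[f"fold_reduction_{other.name}"] = 0.0
            rows.append(row)
    for metric, getter in (("max_cycle_mean_pressure", "max_mean_pressure"),
                           ("max_instantaneous_pressure", "max_pressure")):
        ref_val = getattr(ref, getter)()
        row = {"plane": "axial", "metric": metric, ref.name: ref_val}
        for other in reports[1:]:
            val = getattr(other, getter)()
            row[other.name] = val
            if val > 0:
                row[f"ratio_{other.name}"] = ref_val / val
                row[f"fold_reduction_{other.name}"] = (ref_val - val) / val
            elif ref_val == val:
                row[f"ratio_{other.name}"] = 1.0
                row[f"fold_reduction_{other.name}"] = 0.0
        rows.append(row)
    return pd.DataFrame(rows)
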