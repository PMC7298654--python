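"""Meridional velocity field and velocity-gradient tensors.

The lubrication solution carries only ``Q(x, t)`` and ``a(x, t)``; the 2D
meridional field is reconstructed from the locally parabolic (Poiseuille)
axial profile consistent with the instantaneous flow rate,

    u(x, y) = (2 Q / (pi a^2)) (1 - y^2 / a^2),

and the radial velocity follows by exact radial integration of the
axisymmetric continuity equation from the axis, which lands on the wall
velocity ``v(x, +-a) = +-da/dt`` identically because the axial flow-rate
gradient is taken from the continuity identity ``dQ/dx = -d(pi a^2)/dt``.

Fields are sampled on a body-fitted grid (x, sigma) with sigma = y/a in
[-1, 1], so the moving wall is always the last grid line and no stencil
ever crosses the fluid boundary.  Physical-space gradients are obtained
either from the closed-form lubrication expressions (scenario fields) or by
central differences plus the sigma -> y chain rule (sampled fixtures).

The nine-component gradient tensor supports two conventions for the
out-of-plane entries:

* ``substitution`` — the azimuthal velocity w and the z derivatives
  are replaced by their v / y counterparts (w := v, d()/dz := d()/dy
  analogues).  On a wall-shear dominated field this makes the total
  shear-rate magnitude ~ sqrt(2) times the in-plane shear.
* ``true_axisymmetric`` — the exact cylindrical entries for swirl-free
  axisymmetric flow: w = 0 and dw/dz = v/y (axis limit dv/dy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

from .geometry import CascadeConfig, occlusion_rate, radius_field, radius_slope
from .solver import FlowSolution, solve_instant

__all__ = [
    "VelocityField",
    "VelocityGradientTensor",
    "CONVENTIONS",
    "reconstruct_velocity",
    "reconstruct_instant",
    "velocity_at",
    "compute_gradients",
    "flux_profile",
    "divergence",
]

CONVENTIONS = ("substitution", "true_axisymmetric")


@dataclass
class AnalyticBundle:
    """Closed-form ingredients for exact lubrication gradients (per x node)."""

    Q: np.ndarray
    Q_x: np.ndarray
    Q_xx: np.ndarray
    a: np.ndarray
    a_x: np.ndarray
    a_t: np.ndarray
    a_xx: np.ndarray
    a_xt: np.ndarray


@dataclass
class VelocityField:
    """Axial/radial velocity sampled on a body-fitted meridional grid.

    ``u`` and ``v`` have shape ``(nx, n_sigma)``; ``y = a[:, None] * sigma``
    are the signed physical radial positions, spanning wall to wall.
    """

    x: np.ndarray
    sigma: np.ndarray
    a: np.ndarray
    u: np.ndarray
    v: np.ndarray
    t: float = 0.0
    a_x: Optional[np.ndarray] = None
    analytic: Optional[AnalyticBundle] = None

    @property
    def y(self) -> np.ndarray:
        return self.a[:, None] * self.sigma[None, :]

    @classmethod
    def from_rectangular(cls, x, y, u, v, t: float = 0.0) -> "VelocityField":
        """Wrap a field sampled on a plain rectangular (x, y) grid.

        The grid is interpreted as body-fitted with constant radius
        ``max |y|``; intended for analytic test fixtures.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        radius = float(np.max(np.abs(y)))
        if radius == 0.0:
            raise ValueError("y grid must have nonzero extent")
        return cls(x=x, sigma=y / radius, a=np.full(x.size, radius),
                   u=np.asarray(u, dtype=float), v=np.asarray(v, dtype=float),
                   t=t, a_x=np.zeros(x.size))


def _waveform_second_derivs(config: CascadeConfig, x: np.ndarray, t: float,
                            h: float | None = None):
    """a_xx and a_xt by tiny-step central differences of the analytic slopes."""
    if h is None:
        scales = [p.deformation_length for p in config.pumps] or [config.tube.length]
        h = 1e-5 * min(scales)
    L = config.tube.length
    xm = np.clip(x - h, 0.0, L)
    xp = np.clip(x + h, 0.0, L)
    dx = xp - xm
    a_xx = (np.asarray(radius_slope(config, xp, t)) -
            np.asarray(radius_slope(config, xm, t))) / dx
    a_xt = (np.asarray(occlusion_rate(config, xp, t)) -
            np.asarray(occlusion_rate(config, xm, t))) / dx
    return a_xx, a_xt


def reconstruct_velocity(solution: FlowSolution, t: float,
                         x: np.ndarray | None = None,
                         n_sigma: int = 129) -> VelocityField:
    """Reconstruct the meridional (u, v) field at time ``t``.

    ``x`` defaults to the solver's axial grid; a finer window can be passed
    for shear analysis around a pump.  ``t`` may be any instant (the
    quasi-static elliptic problem is re-solved exactly at it).
    """
    tspan = (float(solution.t[0]), float(solution.t[-1]) + solution.period)
    if not (tspan[0] - 1e-12 <= t <= tspan[1] + 1e-12):
        raise ValueError(f"t={t:g} outside solution span {tspan}")
    if x is None:
        x = solution.x.copy()
    return reconstruct_instant(solution.config, solution.fluid, t, x=x,
                               n_sigma=n_sigma, nodes=solution.x.size)


def reconstruct_instant(config: CascadeConfig, fluid, t: float,
                        x: np.ndarray | None = None, n_sigma: int = 129,
                        nodes: int | None = None) -> VelocityField:
    """Quasi-static field reconstruction straight from a configuration."""
    inst = solve_instant(config, fluid, t, nodes=nodes)
    # flow-rate interpolant over faces, pinned by the end-node values
    xq = np.concatenate(([inst.x[0]], inst.x_face, [inst.x[-1]]))
    qq = np.concatenate(([inst.q[0]], inst.q_face, [inst.q[-1]]))
    spline = CubicSpline(xq, qq)

    if x is None:
        x = inst.x.copy()
    else:
        x = np.asarray(x, dtype=float)
        if np.any(x < 0) or np.any(x > config.tube.length):
            raise ValueError("requested x window outside the tube")
    if n_sigma < 3:
        raise ValueError("need at least 3 radial samples")
    sigma = np.linspace(-1.0, 1.0, n_sigma)

    a = np.asarray(radius_field(config, x, t), dtype=float)
    a_t = np.asarray(occlusion_rate(config, x, t), dtype=float)
    a_x = np.asarray(radius_slope(config, x, t), dtype=float)
    a_xx, a_xt = _waveform_second_derivs(config, x, t)
    Q = spline(x)
    Q_x = -2.0 * np.pi * a * a_t                      # continuity identity
    Q_xx = -2.0 * np.pi * (a_x * a_t + a * a_xt)

    s = sigma[None, :]
    A = a[:, None]
    u = (2.0 * Q[:, None] / (np.pi * A ** 2)) * (1.0 - s ** 2)
    v = -(2.0 / np.pi) * (
        Q_x[:, None] / A * (0.5 * s - 0.25 * s ** 3)
        + (Q * a_x)[:, None] / A ** 2 * (-s + s ** 3)
    )
    bundle = AnalyticBundle(Q=Q, Q_x=Q_x, Q_xx=Q_xx, a=a, a_x=a_x, a_t=a_t,
                            a_xx=a_xx, a_xt=a_xt)
    return VelocityField(x=x, sigma=sigma, a=a, u=u, v=v, t=float(t),
                         a_x=a_x, analytic=bundle)


def velocity_at(solution: FlowSolution, t: float, x: float, y: float):
    """Point evaluation of (u, v); raises if (x, y) lies outside the fluid."""
    fld = reconstruct_velocity(solution, t, x=np.asarray([float(x)]), n_sigma=3)
    a = fld.a[0]
    if abs(y) > a * (1 + 1e-12):
        raise ValueError(f"|y|={abs(y):g} m outside the fluid (a={a:g} m)")
    Q = fld.analytic.Q[0]
    Qx = fld.analytic.Q_x[0]
    ax = fld.analytic.a_x[0]
    s = y / a
    u = (2.0 * Q / (np.pi * a ** 2)) * (1.0 - s ** 2)
    v = -(2.0 / np.pi) * (Qx / a * (0.5 * s - 0.25 * s ** 3)
                          + Q * ax / a ** 2 * (-s + s ** 3))
    return float(u), float(v)


@dataclass
class VelocityGradientTensor:
    """The nine velocity gradients on the sampling grid, 1/s each.

    ``convention`` records how the out-of-plane (w, z) entries were filled.
    """

    x: np.ndarray
    y: np.ndarray  # (nx, ns) physical radial positions
    dudx: np.ndarray
    dudy: np.ndarray
    dudz: np.ndarray
    dvdx: np.ndarray
    dvdy: np.ndarray
    dvdz: np.ndarray
    dwdx: np.ndarray
    dwdy: np.ndarray
    dwdz: np.ndarray
    convention: str


def _base_partials_numeric(fld: VelocityField):
    if fld.x.size < 3 or fld.sigma.size < 3:
        raise ValueError("grid too coarse for central differences (< 3 points)")
    a = fld.a[:, None]
    a_x = (fld.a_x if fld.a_x is not None else np.gradient(fld.a, fld.x))[:, None]
    s = fld.sigma[None, :]

    du_dxs = np.gradient(fld.u, fld.x, axis=0, edge_order=2)
    du_ds = np.gradient(fld.u, fld.sigma, axis=1, edge_order=2)
    dv_dxs = np.gradient(fld.v, fld.x, axis=0, edge_order=2)
    dv_ds = np.gradient(fld.v, fld.sigma, axis=1, edge_order=2)

    # chain rule from the body-fitted (x, sigma) grid to physical (x, y)
    dudy = du_ds / a
    dudx = du_dxs - s * (a_x / a) * du_ds
    dvdy = dv_ds / a
    dvdx = dv_dxs - s * (a_x / a) * dv_ds
    return dudx, dudy, dvdx, dvdy


def _base_partials_analytic(fld: VelocityField):
    b = fld.analytic
    s = fld.sigma[None, :]
    A = b.a[:, None]
    Q = b.Q[:, None]
    Qx = b.Q_x[:, None]
    Qxx = b.Q_xx[:, None]
    ax = b.a_x[:, None]
    axx = b.a_xx[:, None]

    dudy = -4.0 * Q * s / (np.pi * A ** 3)
    dudx = (2.0 / np.pi) * (Qx / A ** 2 * (1.0 - s ** 2)
                            + Q * ax / A ** 3 * (4.0 * s ** 2 - 2.0))
    dvdy = -(2.0 / np.pi) * (Qx / A ** 2 * (0.5 - 0.75 * s ** 2)
                             + Q * ax / A ** 3 * (3.0 * s ** 2 - 1.0))
    # v = -(2/pi) [Q_x P + (Q a_x) S] with P, S polynomials in y and a;
    # differentiate in x at fixed y (P_a = S by a pleasant identity)
    P = (0.5 * s - 0.25 * s ** 3) / A
    S = (-s + s ** 3) / A ** 2
    S_a = (3.0 * s - 5.0 * s ** 3) / A ** 3
    dvdx = -(2.0 / np.pi) * (
        Qxx * P + Qx * S * ax + (Qx * ax + Q * axx) * S + Q * ax * S_a * ax
    )
    return dudx, dudy, dvdx, dvdy


def compute_gradients(fld: VelocityField, convention: str = "substitution",
                      method: str = "auto") -> VelocityGradientTensor:
    """Assemble the nine velocity gradients under the chosen convention.

    ``method`` is ``"analytic"`` (closed-form lubrication expressions,
    available when the field carries its reconstruction bundle),
    ``"numeric"`` (central differences, one-sided at boundaries) or
    ``"auto"`` (analytic when available).
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    if method == "auto":
        method = "analytic" if fld.analytic is not None else "numeric"
    if method == "analytic":
        if fld.analytic is None:
            raise ValueError("field carries no analytic bundle")
        dudx, dudy, dvdx, dvdy = _base_partials_analytic(fld)
    elif method == "numeric":
        dudx, dudy, dvdx, dvdy = _base_partials_numeric(fld)
    else:
        raise ValueError(f"unknown method {method!r}")

    y = fld.y
    if convention == "substitution":
        # w := v and z-derivatives replaced by their y/v counterparts
        return VelocityGradientTensor(
            x=fld.x, y=y,
            dudx=dudx, dudy=dudy, dudz=dudy,
            dvdx=dvdx, dvdy=dvdy, dvdz=dvdy,
            dwdx=dvdx, dwdy=dvdy, dwdz=dvdy,
            convention=convention,
        )
    # exact swirl-free axisymmetric tensor: w = 0, dw/dz = v/y (axis: dv/dy)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_over_y = np.where(np.abs(fld.sigma)[None, :] < 1e-12, dvdy,
                            fld.v / np.where(y == 0.0, 1.0, y))
    zero = np.zeros_like(dudx)
    return VelocityGradientTensor(
        x=fld.x, y=y,
        dudx=dudx, dudy=dudy, dudz=zero,
        dvdx=dvdx, dvdy=dvdy, dvdz=zero,
        dwdx=zero, dwdy=zero, dwdz=v_over_y,
        convention=convention,
    )


def flux_profile(fld: VelocityField) -> np.ndarray:
    """Axial profile of 2 pi int_0^a u y dy — should reproduce Q(x)."""
    pos = fld.sigma >= 0.0
    s = fld.sigma[pos]
    integrand = fld.u[:, pos] * s[None, :]
    return 2.0 * np.pi * fld.a ** 2 * np.trapezoid(integrand, s, axis=1)


def divergence(fld: VelocityField, method: str = "auto") -> np.ndarray:
    """Discrete axisymmetric divergence du/dx + dv/dy + v/y of the field."""
    tensor = compute_gradients(fld, convention="true_axisymmetric", method=method)
    return tensor.dudx + tensor.dvdy + tensor.dwdz
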