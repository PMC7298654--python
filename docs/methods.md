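# Methods

`peripump` models the pumping stage of online gel-fiber extrusion: a slowly
gelling polymer solution (e.g. a gelatin/transglutaminase sol that needs on
the order of ten minutes to cross-link) is driven along a narrow flexible
tube by one or several roller-peristaltic pumping units acting in series
("cascade pumping").  The package answers two questions quantitatively:
how does splitting a fixed actuation budget over several units change the
shear-rate exposure of the fluid (and hence of suspended cells), and how
does it change the system's ability to keep pumping as gelation raises the
hydraulic resistance.

## Flow model

### Geometry and waveform

The tube is a straight cylinder, by default 1 m long with a 1.6 mm inner
diameter.  Each pump unit occupies a 4 cm "shoe" over which the tube wall
is depressed by a traveling constriction.  The constriction is a
raised-cosine crest of wavelength equal to the shoe length, modulated by a
raised-cosine envelope that (together with its slope) vanishes at the shoe
edges, so the radius field is C^1 everywhere, deforms nothing outside the
footprint, and is time-periodic with period `L_d / c`.

The squeeze depth is parameterized in **cross-sectional area**:

    A(x, t) / A0 = 1 - (2*phi - phi^2) * f(x, t),    a = r0 * sqrt(A / A0),

with `f in [0, 1]` the envelope-times-crest shape and `phi` the occlusion
(the fractional radius reduction at the deepest point, so the minimum
radius is `(1 - phi) r0`).  The displaced volume is what a roller actually
controls, and this parameterization makes the wall source term
`-d(pi a^2)/dt` exactly linear in the amplitude `2 phi - phi^2`: squeezes
of different depth share the same temporal shape, so the cycle-averaged
and instantaneous displacement rates of a deep pump and of several shallow
pumps can be matched consistently.  With a radius-space crest this is not
true — the source shape itself drifts with depth and "equal actuation"
comparisons become ambiguous.

Roller kinematics (speed, depth, phase) are not published for the system
the package emulates; they are exposed as configuration parameters with
defaults `c = 0.05 m/s` and a dual-scenario occlusion of 0.25 per pump
(see Calibration).

### Lubrication closure

With shoe radius-to-length ratio 0.8 mm / 4 cm = 0.02 and Re << 1, the
long-wavelength (lubrication) limit applies.  Mass conservation with the
moving wall and the local Poiseuille closure give, at every instant,

    d/dx [ (pi a^4 / 8 mu) dp/dx ] = d(pi a^2)/dt,    p(0) = p(L) = 0,

a 1D elliptic problem solved with a tridiagonal finite-volume scheme
(node-centered pressure, staggered flow-rate faces).  The flow responds
instantaneously (quasi-static Stokes), so the solution is exactly
time-periodic; the marching protocol (3 discarded + 2 analyzed cycles, 64
steps per cycle) is kept so all summaries cover whole cycles.  Discrete
continuity holds to linear-solver precision on the staggered grid (the
tested bound is 1e-6 in relative scale; in practice ~1e-13).

Power-law fluids replace the closure with the Rabinowitsch form
`Q = -(pi n / (3n+1)) a^3 (a |dp/dx| / 2K)^(1/n) sign(dp/dx)`, solved by
Picard iteration on the effective conductance; `n = 1` reproduces the
Newtonian operator exactly.  Occlusions `phi >= 0.95` are rejected (the
`a^-4` conductance becomes numerically singular), and the power-law
viscosity is clamped below a floor shear rate of 1e-3 1/s so it stays
bounded on the tube axis.

The default simulation fluid is Newtonian with mu = 1 Pa s, rho =
1000 kg/m^3 — the order of magnitude of a 5–6 % w/v gelatin sol.  All
headline comparisons are single-to-dual ratios, which in the Stokes regime
are independent of mu (pressure is linear in mu; flow and shear rates do
not depend on it at fixed kinematics).

## Velocity field and shear metrics

The meridional field is reconstructed from the locally parabolic profile
`u = (2Q / pi a^2)(1 - y^2/a^2)`; the radial velocity follows by exact
radial integration of axisymmetric continuity, using the identity
`dQ/dx = -d(pi a^2)/dt`, which lands on the wall velocity `v(+-a) =
+-da/dt` identically.  Fields are sampled on a body-fitted grid
`(x, sigma = y/a)` so no stencil crosses the moving wall; gradients come
either from the closed-form lubrication expressions (used for scenario
analysis — grid-refinement changes of reported maxima are then at
round-off level) or from second-order central/one-sided differences plus
the chain rule (used for externally supplied fields and verified against
the analytic path to better than 2 %, and against Poiseuille/rigid/pure-
extension closed forms to machine precision).

Scalar metrics on the meridional plane:

* in-plane shear `eps = du/dy + dv/dx`,
* extensional strain `eta = du/dx + dv/dy`,
* total shear-rate magnitude `|gdot|` from all nine velocity gradients,

      |gdot|^2 = 2(du/dx)^2 + 2(dv/dy)^2 + 2(dw/dz)^2 + (dv/dx + du/dy)^2
                 + (dw/dy + dv/dz)^2 + (du/dz + dw/dx)^2.

Axisymmetric swirl-free flow has no azimuthal velocity, but the
convention used for the out-of-plane entries is selectable:

* `substitution` (default): the azimuthal component and the z
  derivatives are replaced by their radial counterparts (`w := v`,
  `du/dz := du/dy`, `dw/dx := dv/dx`, `dw/dy := dv/dy`, `dv/dz := dv/dy`,
  `dw/dz := dv/dy`).  On a wall-shear dominated field this yields
  `|gdot| ~ sqrt(2) |eps|`, which is the relation the reference contour
  maxima used for calibration satisfy (1285/885 = 1.452, 624/435 =
  1.434); the substitution convention is therefore the default.
* `true_axisymmetric`: the exact cylindrical entries (`w = 0`,
  `dw/dz = v/y` with the axis limit `dv/dy`).

Plane maxima are taken at the instant of deepest occlusion (crest aligned
with the shoe center), on an `x` window of +-L_d around each pump.  The
transverse (yz) disk at a pump center carries, by axisymmetry, the
meridional radial profile; its histogram is annulus-weighted, and the
meridional histogram is cell-area weighted (`dx * a dsigma`), so sampling
density does not bias frequencies.  Whether the reference frequency distributions were area- or
node-count-weighted is unknown; area weighting is
chosen and recorded in the report metadata.  Default bin width is
100 1/s, matching the 100 / 600 1/s breakpoints used in the comparison.

## Equal actuation, calibration, per-unit peak flow

"Identical power supply" between the single- and dual-pump scenarios is
operationalized as an identical **total cycle-averaged displaced-volume
rate** (the single pump matches the sum of the two dual pumps, which split
it equally).  This is the quantity a positive-displacement unit controls,
and with the area-linear waveform it fixes the 2:1 per-unit relationship
exactly.  Mechanical power `-(integral) p d(pi a^2)/dt dx` is also
reported for transparency but is not the matching variable (it depends on
the pressure field and hence on where a unit sits along the tube).

Calibration is by bisection/Brent on a shared occlusion of the selected
pumps, to 0.5 % relative, for three observable kinds: total displacement
rate (kinematic, no flow solve), cycle-mean flow, and peak in-plane shear
at a pump window (the anchor used to pin the free amplitude against a
reported contour maximum, e.g. 885 1/s for the single scenario).  The
dual-scenario default occlusion of 0.25 keeps the equal-actuation
counterpart of the single pump (~0.65) safely inside the solvable range,
since the displacement amplitude `2 phi - phi^2` saturates toward
`phi -> 1`.

Per-unit peak flow is measured by superposition: the quasi-static Stokes
problem is linear in the wall sources, and in a strictly rigid
incompressible 1D tube the oscillatory displaced flux of every unit
superposes instantly over the whole length, which mixes the units'
sloshes (a real, slightly compliant line localizes them).  Each unit's
peak throughput is therefore the cycle maximum of |Q| in its footprint
with that unit acting alone.  For the same reason the comparative
*pressure* quantity is the maximum of the cycle-mean axial pressure
profile — the quasi-steady profile that rises to a maximum at the (last)
pump and decays linearly to the outlet — rather than the instantaneous
field, whose extrema are set by the coherent slosh of the displaced flux
and are nearly identical in both scenarios regardless of load splitting.
Cycle-peak pressures are still computed and stored in every report.

## Gelation and clogging

Gelation acts on the minutes scale, pump cycles on the sub-second scale
(separation >= 1e3), so the clogging model is quasi-static and lumped:

* Material age `tau(x, t)` (residence time) obeys
  `dtau/dt + ubar dtau/dx = 1` with inlet age 0, advanced by first-order
  upwinding under an enforced CFL bound.
* Apparent viscosity is a shear-thinning power law times a logistic age
  multiplier `1 + (m_inf - 1) / (1 + exp(-(tau - t_on)/t_rise))`,
  non-decreasing and bounded by `m_inf`.  Defaults `t_on = 600 s` (the
  sol–gel transition takes over ten minutes), `t_rise = 120 s`,
  `m_inf = 50`.  The brief rise-then-dip transient seen in rheometry is
  deliberately not modeled — only the rise-to-plateau envelope that
  controls resistance build-up.
* The tube is a series resistance network `8 mu(x) dx / (pi r0^4)`; the
  pumps are pressure sources limited to a capacity `p_cap`.  Flow holds at
  the target while the demand `Q0 R_tot` is within the summed capacity and
  drops to `sum(p_cap) / R_tot` beyond it; slower flow lengthens residence
  times, thickens the fluid, and can run away.  A clog is declared when
  the flow first falls below 10 % of its initial value (clogging is characterized only
  qualitatively in the reference system, so the threshold is a package
  choice).

A structural property of this linear series network is worth stating
plainly: at exactly matched **total** stall pressure, load splitting is
neutral — single and cascade configurations follow identical flow
trajectories, so the "cascade clogs no earlier" ordering holds with
equality.  The cascade's strict advantage appears at matched **per-unit**
capacity, which is the experimentally relevant situation (every channel of
a multi-channel pump head is identical hardware, so adding a unit adds its
full capacity).  Both orderings are asserted in the test suite.

Pump capacity defaults can be taken from the lubrication model as the
cycle-peak pressure rise across the footprint at the calibrated occlusion
(`gelation.default_capacity`).

## Scenario presets and what the generator does not emulate

`build_study_scenarios()` returns the reference configurations verbatim:
`single_0.1`, `dual_0.1_0.5`, and `sweep_0.2|0.3|0.4|0.5` (first pump
fixed at 0.1 m), all on the 1 m / ID 1.6 mm tube with 4 cm shoes, plus the
equal-actuation linkage between the single and dual presets.  Everything
is deterministic — there is no random number generation anywhere in the
pipeline, and repeated runs are byte-identical.

The generator emulates geometry and actuation, not the unpublished FEM
material model: absolute pressures and flow rates depend on the assumed
viscosity and wave speed and are therefore reported but only ratio- and
anchor-calibrated quantities are treated as reproducible against the reference values.  In
this model the local shear state at a pump is set entirely by its own
kinematics, so the secondary-pump distance sweep yields plane maxima that
are constant to round-off across separations — consistent with the reference
observation that the first pump's environment is unchanged and with the
secondary-pump variation being small (~4 %), but not reproducing the
small monotone decrease itself (tests assert non-increase and
first-pump invariance).  Likewise the passive tube is rigid: wall
compliance outside the shoe, fluid–structure interaction, swirl and 3D
effects are out of scope.

## Numerical defaults and problem sizes

* Axial grid: 501 nodes over 1 m (>= 20 nodes per 4 cm shoe is enforced;
  refinement to 1001 nodes changes reported maxima by < 2 %).
* Time: 64 steps per cycle (>= 40 enforced), 3 discarded + 2 analyzed
  cycles.
* Shear windows: 201 x 129 body-fitted samples over +-L_d per pump.
* Closed-form wavetrain oracle: a 16-wavelength `train` waveform on a
  0.96 m tube (2001 nodes) against
  `Q = c pi (<a^2> - <a^-2> / <a^-4>)`; agreement is ~0.01 %, tested at
  2 %.
* Clogging: 201 axial nodes, upwind dt at CFL 0.5 of the fresh-flow
  velocity, 3600 s horizon.

At these sizes the full test suite runs in well under a minute on one
CPU, and `scripts/acceptance.py` in a few seconds.

## Known limitations

* The substitution convention is a faithful implementation of an
  internally inconsistent approximation (axisymmetric flow has `w = 0`,
  not `w ~ v`); the exact convention is provided alongside it.
* Instantaneous pressure extrema are slosh-dominated artifacts of the
  rigid-tube idealization (see above) and should not be read as tube
  burst loads.
* The clogging model has no spatially resolved gel front, no reaction
  chemistry, and its 10 % flow threshold is a convention; it is validated
  by orderings and conservation properties, not against quantitative
  clogging data (none is published for the emulated system).
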