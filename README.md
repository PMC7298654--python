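# peripump

A simulator for **cascade peristaltic pumping** of slowly gelling fluids in
narrow tubes, built for extrusion-bioprinting fluidics: shaping gel fibers
*online* (inside the tube) requires driving a sol that may take ten minutes
to cross-link through a meter of 1.6 mm tubing, and the two things that
break this process are the shear-rate exposure of suspended cells and the
hydraulic-resistance build-up that ends in channel clogging.  Splitting the
actuation over several roller-pump units in series ("cascade pumping")
changes both, and this package quantifies by how much.

It is aimed at people designing peristaltic extrusion lines — tube
geometry, pump placement, occlusion depth, wave speed and fluid rheology
are all configuration parameters — and at anyone who wants a transparent,
tested reference model of multi-unit peristalsis in the lubrication limit.

## Model in brief

* **Flow.** Long-wavelength (lubrication) axisymmetric tube flow with a
  moving wall: at each instant `d/dx[(πa⁴/8μ) dp/dx] = ∂(πa²)/∂t` with
  reservoir pressures `p(0)=p(L)=0`; Newtonian or power-law (Rabinowitsch
  closure) rheology.  The occlusion waveform is a traveling raised-cosine
  crest confined to each pump's 4 cm shoe, parameterized by displaced
  cross-sectional area so actuation comparisons are well posed.
* **Shear metrics.** From the reconstructed meridional field (u, v):
  in-plane shear `ε = ∂u/∂y + ∂v/∂x`, extensional strain
  `η = ∂u/∂x + ∂v/∂y`, and the total shear-rate magnitude from all nine
  velocity gradients,
  `|γ̇| = [2(∂u/∂x)² + 2(∂v/∂y)² + 2(∂w/∂z)² + (∂v/∂x+∂u/∂y)² +
  (∂w/∂y+∂v/∂z)² + (∂u/∂z+∂w/∂x)²]^{1/2}`, with the out-of-plane entries
  filled either by the w≈v substitution convention (default) or by the
  exact axisymmetric tensor.  Plane maxima, axial profiles and
  area-weighted frequency distributions are reported per pump.
* **Clogging.** A lumped residence-time model: material age advects with
  the mean flow, an age-dependent (logistic, rise-to-plateau) viscosity
  multiplier raises the series hydraulic resistance, and capacity-limited
  pump pressure sources let the flow collapse — a clog — when gelation
  outruns the available head.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

Compare single pumping (one unit at 0.1 m) against dual pumping (units at
0.1 m and 0.5 m) on the 1 m, ID 1.6 mm tube at equal total actuation —
the single pump's occlusion is calibrated so its cycle-averaged
displaced-volume rate equals the dual total:

```python
from peripump import NewtonianFluid
from peripump.scenarios import build_study_scenarios
from peripump.shear import analyze_scenario, compare_conditions
from peripump.solver import match_total_actuation

presets = {p.name: p for p in build_study_scenarios()}
fluid = NewtonianFluid()
dual = presets["dual_0.1_0.5"].config
cal = match_total_actuation(presets["single_0.1"].config, dual)
print(f"single occlusion calibrated to {cal.occlusion:.3f} "
      f"(dual total displacement {cal.target:.3e} m^3/s)")
single_report = analyze_scenario(cal.config, fluid, name="single")
dual_report = analyze_scenario(dual, fluid, name="dual")
table = compare_conditions([single_report, dual_report])
cols = ["plane", "metric", "single", "dual", "fold_reduction_dual"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:,.3g}"))
```

prints

```
single occlusion calibrated to 0.646 (dual total displacement 4.398e-08 m^3/s)
plane                     metric   single     dual  fold_reduction_dual
   xy          max_inplane_shear 1.88e+03      121                 14.5
   xy     max_extensional_strain     29.3     2.18                 12.4
   xy            max_total_shear 2.66e+03      172                 14.5
   yz          max_inplane_shear 1.88e+03      121                 14.5
   yz     max_extensional_strain        0        0                    0
   yz            max_total_shear 2.66e+03      172                 14.5
axial    max_cycle_mean_pressure  1.6e+04      992                 15.2
axial max_instantaneous_pressure 7.81e+04 6.64e+04                0.176
```

Reading it: to deliver the same total displaced volume, the single pump
must squeeze to occlusion 0.65 (versus 0.25 per dual unit), and forcing
twice the per-unit flux through that much narrower gap multiplies its wall
shear — here a 14.5-fold reduction in the maximum total shear rate (1/s)
when the load is split, and a 15-fold reduction in the maximum of the
quasi-steady (cycle-mean) pressure profile (Pa).  The instantaneous
pressure extrema are dominated by the oscillatory slosh of the displaced
flux in a rigid line and barely distinguish the scenarios — see the
methods note for why the cycle-mean profile is the meaningful comparison.
Shear units are 1/s throughout; η ≪ ε because the geometry is slender.

The same analyses are scriptable from the shell:

```sh
peripump simulate     --config scenario.yaml --out run/
peripump shear-report --config scenario.yaml --out report/
peripump compare      --runs report_a/ report_b/
peripump sweep        --out sweep/
peripump clogging     --config gelling.yaml --out clog/ --capacity 20000
```

Each run directory contains `shear_summary.json`, per-pump histogram CSVs,
`pressure_profile.csv` / `flow_profile.csv`, and a `manifest.json` with
SHA-256 checksums; re-running an identical configuration reproduces every
file byte for byte.

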