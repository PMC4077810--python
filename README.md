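# floodsel

Habitat-selection and movement analysis for GPS-collared herbivores in
flood-pulsed landscapes — a tested, desk-scale pipeline covering every
stage from collar calibration to field statistics, driven by a
synthetic-data generator so the whole analysis runs and is verifiable
without any field data.

The package is aimed at movement ecologists who want the classical
collar-study toolchain as inspectable, unit-tested Python: stationary
collar calibration, seasonal minimum convex polygons, movement-based
kernel utilisation distributions, Manly design-III selection ratios,
k-means movement-state segmentation with compositional time budgets, and
the standard field statistics (disc-pasture-meter biomass, herd
demography, ordinal body condition).

## The statistics at the core

* **MDT** — minimum distance threshold: the radius of the 95% circular
  error probability of a stationary collar; displacements below it are
  resting.
* **MCP availability** — 100% convex hulls define what is available, per
  individual (third order) and per population season-year (second order).
* **MKDE utilisation distribution** — Gaussian kernels laid along
  interpolated paths between time-correlated fixes, with bridge variance
  h(p)² = h_min² + 4p(1−p)·D·Δt, h_min = MDT + 50 m, and a time threshold
  T_max = MCP diameter / (10 × median hourly distance).
* **Selection ratios** — w = use/availability per habitat; significant
  when the 95% CI excludes 1; overall log-likelihood chi-square
  X² = 2ΣΣ u·ln(u/(nπ)); seasonal/annual contrasts by Pillai-trace
  MANOVA with per-habitat ANOVAs.
* **Movement states** — rest split at the MDT, then k-means on
  (step length, turning angle) into graze/walk/relocate; time budgets
  compared after an isometric log-ratio transform.
* **Field statistics** — DPM biomass Y = −1633 + 1791√X kg/ha; quadrat
  biomass 10 × summed dry weight; binomial/quasibinomial year tests of
  demographic ratios; proportional-odds model for 1–5 body-condition
  scores.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

```python
from floodsel import simulate, calibration, home_range, mkde, selection

# a 5 x 5 km landscape banded around a water channel, and one collared
# animal that prefers the floodplains
raster = simulate.generate_landscape(100, 100, pixel_size=50.0, seed=1)
spec = simulate.MovementStateSpec.from_study()
traj = simulate.simulate_trajectory(
    raster, spec, {1: 2.0, 2: 2.5, 5: 0.6, 6: 0.5}, n_hours=2000, seed=4,
)

# collar calibration -> MDT
calib = simulate.simulate_calibration_fixes((0, 0), error_sd_m=25, n=120, seed=2)
collar = calibration.calibrate(calib)
print(f"MDT = {collar.mdt_m:.1f} m")

# UD and third-order selection within the individual MCP
params = home_range.RangeParams(
    mdt_m=collar.mdt_m, t_max_h=10.0,
    h_min_m=home_range.smoothing_parameter(collar.mdt_m),
)
steps = mkde.classify_activity(traj, collar.mdt_m, t_max=10.0)
D = mkde.estimate_diffusion(steps)
ud = mkde.ud(traj, raster, params, D)
ind = home_range.mcp(traj[["x", "y"]].to_numpy())
pi = selection.availability(raster, ind.polygon)
use = mkde.ud_weighted_use(ud, raster)
o = {h: use.get(h, 0.0) for h in pi}
o = {h: v / sum(o.values()) for h, v in o.items()}
table = selection.selection_ratios(o, pi, n_fixes=len(traj))
print(table[["habitat", "w", "ci_low", "ci_high", "significant"]].round(2))
```

Output:

```
MDT = 59.2 m
   habitat     w  ci_low  ci_high  significant
0        1  1.42    1.26     1.57         True
1        2  2.18    2.03     2.33         True
2        3  0.97    0.86     1.09        False
3        4  1.13    1.02     1.25         True
4        5  0.63    0.58     0.69         True
5        6  0.47    0.41     0.54         True
```

The animal was simulated with preference weights 2.0 and 2.5 for the two
floodplain classes (habitats 1–2) and 0.6/0.5 for the two dry woodland
classes (5–6); the estimated ratios recover that structure — strong,
significant selection of the floodplains and significant avoidance of the
woodlands. Grassland (3, weight 1) sits at w ≈ 1 as expected; the
marginally significant w = 1.13 for riparian woodland (4, also weight 1)
is the kind of borderline call the unadjusted per-habitat CIs produce —
the `bonferroni` flag exists for exactly this.

A full end-to-end run (simulation → calibration → ranges → UDs →
selection → states → field statistics, with a manifest of outputs):

```sh
floodsel run-all --seed 1 --out runs/demo
```

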