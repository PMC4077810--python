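# Methods

`floodsel` implements a desk-scale version of a GPS-collar habitat-selection
analysis for large herbivores in a flood-pulsed landscape (the motivating
system is African buffalo, *Syncerus caffer*, in the Okavango Delta). This
note records the models, the parameter choices that matter, what the
synthetic-data generator does and does not emulate, and the numerical
decisions taken where the methodology is genuinely open.

## Collar calibration

Each collar's positional error is summarised by the radius of the 95%
circular error probability (CEP95) around the mean of its stationary-test
fixes; that radius becomes the minimum distance threshold (MDT) below which
a displacement cannot be distinguished from collar noise. The quantile of
fix-to-reference distances uses the empirical distribution with linear
interpolation between order statistics; the definition is recorded in the
collar model output because other quantile conventions shift the MDT by a
few metres at n = 100. For isotropic Gaussian error with per-axis SD σ the
CEP95 is σ·√(χ²₀.₉₅,₂) ≈ 2.448σ, which the test suite uses as a closed-form
check. An optional `round_to` (default off) reproduces tables in which MDTs
are reported to the nearest 10 m. The MDT is attached to the collar, not
the animal-season: repeated seasons of one animal reuse the same value.

## Seasons, home ranges and UD parameters

The hydrological year is split into rainy (Dec–Mar), early flood (Apr–Jul)
and late flood (Aug–Nov) seasons; December is assigned to the following
year's rainy season so each rainy season carries one year label. The first
and last 14 days of every animal-season block are trimmed (default
`trim_days = 14`) to keep seasons behaviourally distinct.

Availability is defined by 100% minimum convex polygons (convex hulls via
shapely, no peeling) — at the population level (all animals pooled per
season-year) for second-order selection, and per individual for third
order. The hull "diameter" is the maximum inter-vertex distance, which
equals the point-set diameter for a convex hull.

Two derived parameters drive the utilisation distribution:

* time threshold `T_max = diameter / (10 × median hourly distance)`, the
  interval beyond which successive fixes are treated as serially
  uncorrelated. The median uses only steps with interval 1 h ± 5 min.
  A configurable cap (default 10 h) is applied and flagged in output;
  reported thresholds in comparable field studies never exceed 10 h and a
  cap makes that behaviour explicit rather than coincidental.
* minimum smoothing bandwidth `h_min = MDT + 50 m`, the 50 m allowing for
  the spread of a herd around the collared animal.

## Movement-based kernel density estimation

The UD smooths along interpolated movement paths rather than around raw
fixes. Each active step (displacement > MDT) whose interval Δt ≤ T_max
contributes `n_substeps` (default 10) Gaussian kernels at fractions
p = (k−½)/n_substeps along the segment, with the biased-random-bridge
variance profile

    h(p)² = h_min² + 4·p·(1−p)·D·Δt,

largest mid-step and equal to h_min² at the endpoints. Rest fixes and
fixes beyond the time threshold contribute one kernel of variance h_min²
weighted by their dwell time (elapsed hours), so irregular gaps do not
bias the surface; the first fix carries one nominal hour. The diffusion
coefficient D (m²/h) is a plug-in estimate: the median over active bridged
steps of L²/(4Δt). The median resists the heavy tail produced by rare
relocation steps.

Numerics: kernels are evaluated by the midpoint rule on 50 m cells and
truncated at 4 standard deviations (truncation error < 1e−4 of kernel
mass; tests that need exact agreement raise the truncation radius).
A boundary polyline (veterinary fence) is handled by clip-and-renormalise:
the raster bounding box is split by the line, cells on the far side from
the trajectory centroid are zeroed, and the surface is renormalised to
unit mass. Mirror reflection would preserve more boundary-adjacent detail
but requires a geometry-dependent reflection operator; the clip mode is
recorded in the UD metadata and switchable in principle by passing no
boundary and masking externally. With D → 0 and one substep the estimator
reduces to a fixed-bandwidth KDE with bandwidth h_min, which the tests
verify against an independent dense implementation.

## Selection ratios and tests

Selection ratios w = use/availability follow the design-III convention:
both quantities measured per individual. Second-order use is the habitat
composition of the individual MCP against the population MCP; third-order
use is the UD-weighted habitat mass against the individual MCP
composition. Habitat composition of a polygon counts raster cells whose
centre falls in the polygon. Habitats unavailable to an animal (π = 0) are
excluded from that animal's table and from its degrees of freedom; use of
an unavailable habitat is an error, not a warning.

Confidence intervals are normal-approximation 95% intervals (published
tables of this kind show negative lower bounds, which pins down the
normal approximation; exact reproduction of any specific table is not
possible without raw data). For a single animal with n fixes the variance
of w is o(1−o)/(n·π²); for a season-level table over animals the SE is the
between-animal sample SE of w. Significance is "CI excludes 1". A
Bonferroni adjustment across habitats is available by flag but off by
default, matching the unadjusted convention. The overall test is the
log-likelihood chi-square X² = 2·ΣΣ u·ln(u/(nπ)) with df = Σ(Iₐ−1); it
uses raw fix counts per habitat because continuous UD masses admit no
likelihood. Ratio matrices are compared across seasons/years by a one-way
MANOVA using Pillai's trace (robust to non-normality), with Mahalanobis
distances from group centroids (pooled covariance) for outlier screening
and per-habitat one-way ANOVAs as follow-ups.

## Movement states and time budgets

Fixes with displacement ≤ MDT are resting; active fixes are clustered on
(step length, absolute turning angle) by k-means (k = 3, 20 restarts,
k-means++ seeding, best WCSS) into grazing / walking / relocating,
relabelled by ascending mean raw step length. Clustering uses raw, not
z-scored, features: the states are defined by the spatial scale of
movement, and step length carries essentially all of that signal, while
turning angles are broad (SD ≈ 40–50°) and overlap heavily between
states. Standardising gives the angle dimension equal weight and k-means
then partitions on angle noise rather than movement scale — on synthetic
trajectories with known states, raw-feature clustering recovers ≈ 93% of
active-state labels versus ≈ 55% for standardised features, and only the
raw mode reproduces the distance-ordered cluster structure with large
within-cluster angle spread that the method is meant to find.
`standardise=True` remains available.

Time budgets (proportions of fixes in rest/graze/walk/relocate) are
compositional; group comparisons apply an isometric log-ratio transform
(scikit-bio's fixed Helmert-type basis) before the same Pillai MANOVA.
Zeros are replaced multiplicatively with δ = 0.65/(total fixes), the
smallest detectable proportion scaled below detection. Daily distance sums
step lengths by the calendar day of each step's end fix, with local
midnight at UTC+2 (study-region time); days with fewer than 20 steps are
flagged incomplete.

## Field statistics

Biomass: disc-pasture-meter settling heights convert through the fixed
calibration Y = −1633 + 1791·√X kg/ha (X = mean of 50 drops, cm). Values
below the calibration range (X < 0.83 cm) come out negative and are
flagged, not clamped; log-scale models exclude them. Flooded sites use
four 0.25 m² quadrats: summed dry weight (g over 1 m²) × 10 = kg/ha. The
year × habitat analysis is a two-factor linear model on log biomass with
an F test on the interaction via model comparison.

Demography: per-herd young:adult-female, calf:adult-female and
adult-male:adult-female ratios, summarised as year-level mean ± SD.
Between-year comparisons fit (successes | adult females) ~ year by
binomial logistic regression; the quasibinomial variant scales the
variance by the Pearson dispersion and reports a t statistic on n−2 df.

Body condition: ordinal scores 1–5 are modelled with a proportional-odds
cumulative-logit model, BCS ~ demographic category + year, fitted by
statsmodels' OrderedModel; likelihood-ratio tests come from term deletion.
A herd-level random intercept is available through a Laplace
approximation (one scalar mode per herd, bounded scalar optimisation,
finite-difference curvature); the fixed-effects fit is the tested default
because the random-intercept variance in comparable published analyses is
rarely reported and the Laplace fit is an order of magnitude slower.

## The synthetic-data generator

The generator defines the study conditions the tests run under.

* **Landscape**: a 50 m categorical raster banded by distance to a
  sinuous permanent channel — secondary floodplain nearest, then tertiary
  floodplain, riparian woodland, mopane woodland, mixed acacia woodland —
  with grassland patches throughout (≈ 12% of cells). Band widths are
  distance quantiles (10/15/15/35/25%), giving every class enough area for
  stable availability estimates. `apply_flood(level)` advances an
  inundation front linearly with level and scales floodplain biomass by
  1 − 0.8·level; dry classes are unaffected. The geometry is a stylised
  delta margin, not a map of any real place.
* **Trajectories**: a 4-state Markov chain (rest/graze/walk/relocate)
  whose per-state step-length and turning-angle moments are the
  across-animal means of the bundled per-animal movement-state table
  (rest 22.8 m, graze 224 m, walk 668 m, relocate 1690 m per hour).
  The transition matrix mixes identity with the observed mean time budget
  (persistence 0.6), so the stationary state distribution reproduces that
  budget (≈ 33/43/21/3%). Step lengths are gamma with moment-matched
  mean/SD; headings are a weighted choice over 16 candidate compass
  directions (randomly rotated each step to avoid an angular lattice),
  weighted by the state's folded-normal turning-angle density and by the
  preference weight of the habitat at the candidate endpoint. Candidates
  leaving the raster or crossing the boundary line get zero weight.
* **Collar error**: isotropic bivariate Gaussian per axis.
* **Field tables**: DPM heights are drawn around the habitat-year true
  biomass through the inverse DPM calibration (gamma noise, CV 0.35);
  herd demography is Poisson/binomial with year-dependent calf and young
  probabilities; BCS counts come from the same cumulative-logit model the
  analysis fits, with a Gaussian herd intercept.

What the generator does **not** emulate: collar fix failure beyond
independent per-fix dropout, habitat misclassification, observer error in
herd counts, spatial autocorrelation of biomass between neighbouring
sites, diel rhythm in state switching, and attraction to specific water
points. Passing tests therefore demonstrate the estimators' correctness
and calibration under the stated stochastic model, not robustness to
every field artefact.

## Problem sizes

Default test and pipeline sizes are chosen so the full suite runs in
about a minute on one core: 100×100-cell landscapes (5×5 km), 2 000–8 000
hour trajectories, 500-replicate null calibrations at the use-count
level, 200-replicate power checks for the GLMs, and single large
simulations (n = 200 herds, 10 000 calibration fixes) for parameter
recovery. The acceptance script uses the same sizes.

## Known limitations

* The boundary clip redistributes clipped mass proportionally everywhere
  rather than locally; UDs hard against a fence lose boundary-hugging
  detail.
* The chi-square test uses fix counts, which ignores the UD's temporal
  weighting; animals with large gaps contribute fix-weighted, not
  time-weighted, counts.
* The Laplace CLMM assumes a single scalar intercept per herd and is not
  validated against an external mixed-model fit.
* Group-level CIs use z rather than t quantiles; at 13 animals their
  realised coverage is nearer 93% than 95%, visible in the coverage test's
  tolerance.
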