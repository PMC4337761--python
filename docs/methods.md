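# Methods

## Model

`flywaymap` estimates space use of migrating birds with the dynamic Brownian
bridge movement model. The animal's path between two observed fixes is a
Brownian bridge pinned at the observations, which are themselves corrupted by
isotropic Gaussian positional error. For a fix $z_j$ at time fraction
$\alpha$ between bridge endpoints $(z_a, t_a, \delta_a)$ and
$(z_b, t_b, \delta_b)$:

$z_j \sim N\!\big(z_a + \alpha(z_b - z_a),\; s(\alpha)\,I\big),\qquad
s(\alpha) = T\alpha(1-\alpha)\sigma^2_m + (1-\alpha)^2\delta_a^2 + \alpha^2\delta_b^2$

with $T = t_b - t_a$. The likelihood of a run of fixes conditions every
second fix on the bridge joining its neighbours (fixes at even 1-based
positions are the evaluated "intermediate" observations), so consecutive
terms use disjoint bridges and the product is a proper likelihood.

Assumptions worth stating: movement between fixes is isotropic diffusion
around the straight-line interpolation (no drift term beyond the endpoints);
positional errors are Gaussian, isotropic and independent; and the variance
$\sigma^2_m$ is piecewise constant, switching only at detected breakpoints.
Behavioural structure that violates these (looping detours, correlated
error) surfaces as inflated $\sigma^2_m$, which is the intended reading:
$\sigma^2_m$ is *apparent* mobility, not a biomechanical parameter.

## Dynamic variance estimation

A window of `window_size` fixes slides one fix at a time. Per window the
single-variance fit (k = 1) is compared by
$\mathrm{BIC} = -2\ln L + k\ln n_{int}$ with the best two-variance fit
(k = 2) split at any breakpoint fix outside a margin of `margin` fixes at
each window end; $n_{int}$ is the number of evaluated intermediate fixes
(summed over both halves for the split model). The breakpoint position is
not counted as a BIC parameter; the split fits both halves independently.
$\sigma^2$ is maximized on the log scale with bounded Brent search
(relative tolerance 1e-6). Each non-margin segment averages (unweighted)
the winning variance of every window that covers it; segments inside the
track-end margins inherit the nearest covered estimate. Events shorter than
one window fall back to a single event-wide MLE rather than being dropped,
which keeps short events recorded at coarse Argos duty cycles in the
analysis.

Two estimator properties measured by the test suite are worth knowing.
First, the pooled estimate on constant-variance tracks is biased low by
roughly 10–13% at these window sizes: spurious BIC splits fit halves of the
noise, and likelihood-maximal partitions systematically prefer
lower-variance explanations. Second, windows that straddle a variance
switch only within their margin cannot localize it — the margin exists to
stabilize the half-window fits — so breakpoint-localization rates are
meaningful only over windows whose admissible span contains the switch.

### Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `window_size` (w) | 31 | fixes | standard choice for waterfowl at these duty cycles (~6 d of GPS, ~28 d of Argos data) |
| `margin` (m) | 11 | fixes | breakpoint exclusion zone; minimum 3 (a variance needs 3 fixes) |
| `sigma2_bounds` | (1e-6, 1e7) | m²/s | must admit apparent variances at flight/stopover transitions over ~22 h gaps (~10⁶ m²/s); tighter caps visibly clipped bridge spread |
| `alpha_steps` | 25 | nodes | trapezoid integration over the bridge; halving the step changes no cell by >1e-4 |
| `truncation_radius` | 4 | SD | Gaussian tail cutoff; lost mass restored by final renormalization |

## Rasterization

UD mass is accumulated per segment as the trapezoid-integrated bridge
density, weighted by the segment's elapsed time, evaluated at cell centres
and multiplied by cell area, then renormalized to exactly 1. Two numerical
choices: when the local bridge SD is below half a cell side, the density
evaluation underflows at cell centres and the mass quantum is deposited
directly into the containing cell; and if more than 1e-4 of the
pre-renormalization mass sits in the boundary cell ring, the computation
aborts and asks for a larger grid (for migratory Argos cohorts ~500 km of
padding is a safe default — transition bridges are wide).

The grid lives in a spherical Lambert azimuthal equal-area projection
centred on the data centroid, so cell values are comparable as probability
mass per unit area everywhere on the map; planar distances agree with
great-circle distances within 1.5% over 3,000 km spans. "10 km² grid
resolution" is read as cell *area* (side ≈ 3.162 km); a side-length reading
is available via `cell_side_km`. Cells are half-open: a point on a shared
edge belongs to the larger-index cell.

## Preprocessing

Hourly retention keeps the best-quality fix per animal-hour (G > 3 > 2 > 1 >
0 > A > B > Z; ties keep the earlier fix) and floors timestamps to the hour.
Errors: 23.5 m (GPS), 450 m (class 3) to 7,920 m (class B); the
intermediate class values (630, 1,190, 2,580, 5,070 m) are package defaults
interpolated between the anchored endpoints and should be overridden with
study-specific estimates. The plausibility filter drops class-Z fixes and
then iteratively removes the fix adjacent to the fastest segment whose
removal most reduces the local maximum speed, until no inter-fix speed
exceeds `vmax_kmh` (default 120). This is a deliberately simple
sustained-speed filter; it is not a reimplementation of operational Argos
filter suites.

Migration events are cut at stationary seasonal ranges: maximal fix runs
staying within `stationary_radius_km` (50) of their running centroid for at
least `dwell_days` (21 — long enough that multi-day stopovers are not
mistaken for seasonal residency). The southernmost and northernmost ranges
anchor the winter and breeding labels; ranges near an anchor share its
label, an unlabeled range directly after breeding is a molting site, and
callers can override labels per range (useful when more than two genuine
seasonal ranges exist). An event is *complete* only when it runs from
winter to breeding or vice versa; molt-interior fixes are excluded while
travel to and from the molt site stays in the fall event, with the arrival
and departure fixes retained as leg endpoints. Durations are fractional
days (sub-day migrations occur) floored at 0.01 d so they can always act as
positive weights.

## Aggregation and contours

A parent UD is $\sum_c w_c\,p_c$ renormalized to 1. Event UDs are weighted
by event duration; individuals, populations and species by their mean
migration-event duration (the individual→population weight is not fully
pinned down by convention; the mean keeps the rule identical at every level
above events). Seasons are pooled. The weighted mean is associative under
flat recomputation and invariant to common weight rescaling — both are
tested.

Contours are highest-density cell prefixes: cells sorted by mass descending
(ties broken by row-major index), shortest prefix reaching the nominal
cumulative mass. Regions at increasing levels are nested by construction
and each encloses at least its nominal mass. Polygonization is the exact
lattice union of selected cells (interior holes preserved, no smoothing);
GeoJSON output inverse-projects vertices to WGS84.

## Sensitivity analysis

For each k in 1, 4, 7, … (and the k = n endpoint, appended when n is not on
the 3-step lattice, since the full-sample point anchors the curve at
100 %VI), up to 100 distinct k-combinations are drawn uniformly without
replacement (exhaustive when $\binom{n}{k} \le 100$), aggregated with
duration weights, and compared with the full flyway UD by
$\%VI = 100\sum\min(p,q)$ on raw (uncontoured) UDs. The smoother is a
tricube-weighted local polynomial (span 0.75, degree 2). The asymptote
verdict calls a curve flat when each of the last three LOESS increments is
below 2 percentage points, and reports the final segment slope for
comparing datasets. All sampling is driven by one seed; curves are
bit-reproducible.

## Synthetic data generator

The generator produces cohorts with exact ground truth rather than maximal
realism. Each bird's schedule is piecewise: winter dwell (~100 d), spring
migration along per-individual jittered corridor waypoints (flight speed
60 km/h) with gamma-distributed stopover dwells (mean 4 d at interior
waypoints), breeding dwell (~60 d), an optional molting cluster offset from
the breeding site, fall return, final winter dwell (~60 d). Dwell durations
are gamma with CV 0.25 — variable enough to differ among birds, tight
enough that seasonal residency always clears the segmentation dwell
threshold. On top of the deterministic backbone, each bird carries a
per-axis Ornstein–Uhlenbeck deviation whose diffusion equals the regime's
nominal $\sigma^2_m$ (defaults 200 m²/s flight, 10 m²/s stopover — a 20×
contrast) with relaxation times of 96 h (flight) and 24 h (sites), so
deviation increments over typical sampling gaps are Brownian with the
configured variance to within a few percent. Observation: 60% of birds are
GPS (gamma gaps, mean 4.5 h; 23.5 m error), the rest Argos (mean 22.4 h;
location class drawn from a B-heavy frequency table, class-specific error,
2% class-Z outliers at 15 km error). All randomness flows from one seed
through per-individual spawned substreams; cohorts are bit-reproducible.

What the generator does *not* emulate: wind and topography, habitat
selection, heavy-tailed or correlated Argos error, duty-cycle gaps beyond a
simple on/off pattern, and route fidelity across years. Passing tests
therefore demonstrate the estimator and aggregation machinery under known
diffusive ground truth, not robustness to every artefact of real Argos
archives.

## Problem sizes

The shipped test suite and `scripts/acceptance.py` use cohorts of 6–40
birds on grids of 10–40 km² cells with ~500 km padding, 50 replicates for
constant-variance recovery (n = 201 fixes each), 10 replicates for
two-regime breakpoint detection, 20 GPS birds for the flight/stopover
contrast, and 10⁶ draws for the Monte-Carlo rasterization oracle — sizes at
which every check runs in seconds to a few minutes on one core while
leaving the statistics well-resolved.

## Known limitations

- The per-segment variance is an unweighted mean over covering windows;
  alternative combination rules (likelihood-weighted, median) are not
  implemented.
- No confidence intervals on $\sigma^2_m$ or on UD cells.
- Contours are lattice polygons; no sub-cell interpolation.
- The speed filter is order-dependent in pathological ties (resolved
  deterministically by larger error, then later index).
- Winter/breeding labelling assumes a broadly latitudinal migration; purely
  longitudinal systems need the per-range label override.
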