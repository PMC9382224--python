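# Methods

This package links submesoscale aggregative surface-current features to the
habitat selection, feeding-site selection and feeding rates of a lunge-feeding
marine predator (the motivating system is blue whales foraging over the
California Current, observed with multi-sensor biologging tags against hourly
HF-radar surface currents). Every stage is runnable on synthetic inputs with
known answers; this note records the models, the defaults and why, the
numerical choices, and what the synthetic conditions do and do not show.

## Lagrangian feature proxy: backward-in-time FTLE

Surface-current snapshots alone identify fronts and eddies poorly because the
features are advected and time-dependent. The package therefore computes the
backward-in-time finite-time Lyapunov exponent (FTLE): tracers seeded on a
grid refined 10x relative to the velocity grid (600 m from a 6 km product)
are advected from each analysis hour t0 backward over a horizon T = -48 h,
and the flow map Φ: x(t0) → x(t0+T) is differentiated by central differences
over each seed's four grid neighbours. With the Cauchy–Green tensor
C = (∇Φ)ᵀ(∇Φ),

    FTLE = ln λ_max(C) / (2|T|),    reported in day⁻¹.

Ridges of the backward FTLE mark attracting transport structures where
material accumulates — a proxy for prey-aggregating features. The 48 h
horizon averages over tidal currents while keeping most tracers inside a
coastal domain; hourly fields are computed independently of each other.

Numerics:

- **Advection** is an adaptive Runge–Kutta–Fehlberg 4(5) stepper, vectorised
  across all tracers with a shared step size controlled by the worst
  per-tracer embedded error estimate in metres (tolerance
  `atol_m + rel_tol * step_displacement`, defaults 1 m and 1e-4). Backward
  time is a negative step through the same field. On a uniform flow the
  stepper takes exactly the hourly frames and reproduces the 17.28 km / 48 h
  displacement to 1e-9 relative.
- **Velocity lookup** is bilinear in space within the enclosing cell and
  linear in time between the two bracketing hourly frames (each frame is the
  instantaneous solution at its timestamp; no staggering).
- **Free-slip coast**: a land node adjacent to water across a vertical coast
  edge contributes zero normal (u) velocity and the tangential (v) velocity
  of its water neighbours, and symmetrically for horizontal edges, so
  interpolated flow at the coast slides along it rather than through it. How
  to discretise free slip on a ~6 km grid is not prescribed by the data
  products; this edge-normal suppression is this package's choice and is the
  simplest rule that makes the interpolant honour the boundary condition
  exactly at land nodes.
- **Data gaps** (missing cells inside the water domain): the interpolation
  layer reports them as missing, distinct from out-of-domain queries. The
  FTLE layer fills a gap from the mean of valid cells within one parent-grid
  cell (3x3 neighbourhood); a tracer entering a cell that cannot be filled
  freezes there and is flagged. Real HF-radar pipelines restore gaps
  upstream with dedicated algorithms; that restoration is out of scope here,
  and the one-cell fill merely bounds the error of small residual gaps.
- **Exits**: a tracer crossing the grid hull freezes at the exit point and is
  flagged, so flow-map gradients degrade locally instead of deleting whole
  neighbourhoods. Any FTLE cell whose finite-difference stencil touches a
  frozen tracer is masked invalid; grid-edge cells use one-sided differences
  and are flagged lower-confidence but kept. These policies are recorded in
  the field metadata.
- λ_max of the 2x2 Cauchy–Green tensor uses the closed-form quadratic; it
  agrees with an explicit eigendecomposition to 1e-12 relative.

**Oracles.** A uniform flow has FTLE identically 0 (the flow map is a rigid
translation); a linear saddle with strain rate a day⁻¹ has FTLE = a for any
horizon, since λ_max(C) = e^{2a|T|}. The time-periodic double gyre (the
standard FTLE benchmark) has no closed form; the engine is checked against a
fixed-step RK4 advection of the *closed-form* velocity at 4x denser seeding,
agreeing to ~0.4% RMS of the field maximum on the default test geometry
(5 km velocity grid, 2x seeding, hourly frames of a 24 h-period gyre).
Adding a constant velocity to a *linear* flow is a rigid shift of the
pattern and leaves FTLE unchanged to machine precision — the invariance
check uses the uniform and saddle flows for exactly that reason; for a
nonlinear flow such as the double gyre, adding a constant genuinely alters
trajectories and the identity does not hold.

**Extraction.** A dive (or background point) gets the FTLE value of the
nearest grid cell of the temporally nearest hourly field, provided that
field is within 30 min of the query; an invalid nearest cell falls back to
the nearest valid cell in its 3x3 neighbourhood, and otherwise the value is
missing (a value, not an error).

## Biologging: dives, locations, feeding rates, states

The sampling unit is the dive, an excursion below 10 m in the 1 Hz depth
trace; a dive runs from the first sample beyond the threshold to the first
sample back at it, and the post-dive surface duration runs to the next
downward crossing (the final dive's is missing). GPS fixes are filtered for
unrealistic speeds (> 6 m s⁻¹) by keeping the largest time-ordered subset
whose consecutive implied speeds are all admissible (exact
minimal-removal dynamic program; earliest fixes win ties — the published
filter's internal removal order is not documented, so the minimal-removal
rule was adopted as the best-defined one). Dive-start locations are linearly
interpolated between bracketing fixes when the bracket spans under 15 min.

The dive-cycle feeding rate is

    rate = n_lunges / (dive duration + post-dive surface duration)

in lunges h⁻¹ (the x3600 conversion applied at the formula). Rates are
normalised per individual by percentile rank over that individual's
*feeding* dives (average rank for ties — FR_pct is then invariant to any
strictly monotone transform of an individual's rates), and cut into four
states: non-feeding (no lunges, FR_pct pinned at 0), light (≤ 25), moderate
(25–75) and heavy (≥ 75); the boundary value 75 goes to heavy. Whether
percentile ranks should be taken over feeding dives only or all dives is
ambiguous in the source description; feeding-dives-only is used because the
non-feeding state is pinned to 0% by definition.

## Habitat selection (third order)

Availability is simulated per individual: 10 background points per real
location, uniform in the individual's location bounding box padded by 1°,
time-matched to the real location and FTLE-extracted identically. Points
falling outside FTLE coverage are redrawn up to 100 times, then kept as
missing and excluded *with the count surfaced* (silently dropping them would
bias availability). Individuals are weighted equally per deployment
(weight = 1/(n_locations × n_deployments)) so deployment length does not
dominate.

The test statistic is the one-sided weighted two-sample Kolmogorov–Smirnov
statistic D = sup_x (ECDF_background − ECDF_whale) with weighted ECDFs
(large D: whale values stochastically greater). Because weights invalidate
the classical null distribution, the p-value comes from permutation of the
pooled group labels with weights travelling with their values; under equal
weights D reduces exactly (to 1e-12) to the textbook statistic and the
classical asymptotic p-value is reported alongside.

## Feeding-site selection (fourth order)

Feeding presence per dive is regressed on FTLE with a binomial logit model.
The estimation strategy is generalized estimating equations with individuals
as correlation groups and a working correlation decaying exponentially with
the within-individual time gap — the same mean model as a penalized
quasi-likelihood mixed model with continuous-time AR(1) errors, with robust
(sandwich) inference; under a single individual and independence the fit
reduces to plain logistic regression to 1e-6. Because studies of this kind
have few clusters (here ~10 individuals), the plain sandwich covariance is
biased low; the bias-reduced (Mancl–DeRouen) covariance is used whenever at
least 3 clusters are present, falling back to the model-based covariance
below that (no sandwich estimator is meaningful with one or two clusters).
Complete separation is detected and surfaced as an error. Acceptance is by parameter recovery on
synthetic data (generating slope covered by the fitted 95% CI in ≥ 18/20
replicates at 10 individuals × 500 dives, for both 0.45 and 0 slopes), not
coefficient-for-coefficient replication of any particular mixed-model
implementation.

Null models:

- **Correlated random walks** (non-selecting individuals): 10 simulated
  tracks per individual keeping the real timestamps and feeding labels.
  Tracks are parameterised by the turning-angle concentration r (mean
  resultant length of observed turning angles) and step-length scale h
  (mean observed step length); steps resample the individual's observed
  step lengths scaled to h (preserving the empirical shape — the published
  parameterisation names (h, r) but not distributions) and turning angles
  are wrapped Cauchy with mean resultant length exactly r. Starts are
  uniform inside the minimum convex polygon (convex hull of located dives);
  steps landing on a supplied land geometry are redrawn up to 100 times,
  after which the track restarts from a fresh start point (counted).
- **Time shifts**: timestamps moved forward by 24/48/96/192 h with positions
  and labels unchanged, FTLE re-extracted. On synthetic fields decorrelating
  in < 24 h, fitted slopes for shifts ≥ 48 h attenuate toward 0 relative to
  the unshifted slope, reproducing the qualitative persistence result.

Whether pooled-null or per-track-summarised fits were used in the source
analysis is ambiguous; the CLI reports the pooled fit, and per-track fits
are trivially available through the library.

## Feeding-intensity transition model

With the four states known a priori, the hidden-Markov likelihood
factorises and the transition structure is fit directly (supervised): for
each origin state a multinomial logit of the next state on the FTLE at the
origin dive, with the self-transition as reference category; individuals'
sequences never transition into each other. Γ(x) rows are softmax-normalised
(sum to 1 within 1e-12 by construction); the stationary distribution π(x)
solves πΓ(x) = π by a constrained linear solve, rejecting reducible chains
with a diagnosis.

The pooled, individually weighted (1/(n_feeding_dives × n_deployments))
feeding-rate distribution is cut at its weighted 25th/75th percentiles
(inverted-CDF weighted quantiles) and the weighted mean of each segment
gives the light/moderate/heavy state rates. The estimated overall feeding
rate at FTLE x is Σ_state π_state(x) × rate_state with the non-feeding rate
0, evaluated over x ∈ [−1.25, 1.5] day⁻¹ (values outside are computed but
flagged as extrapolation); confidence curves evaluate the same quantity at
the coefficient interval endpoints β ± 1.96 SE (with the central curve
included in the envelope, since the stationary-rate map need not be
monotone in every coefficient).

## Synthetic study conditions

The generator's defaults define the conditions under which the statistical
guarantees are demonstrated:

- **Flows**: uniform (u0 = 0.1 m s⁻¹), saddle (a = 0.5 day⁻¹), double gyre
  (A = 0.1 m s⁻¹, ε = 0.25, ω defaulting to the classic 2π/10 rad h⁻¹; the
  FTLE-accuracy checks use a 24 h period so that hourly frames resolve the
  oscillation) on a 200 × 100 km planar domain at 6 km spacing (5–10 km in
  speed-sensitive tests), optionally mapped to lon/lat through a local
  equirectangular projection so geographic code paths run on the same
  dynamics. Degradation masks an exact rounded fraction of samples and adds
  Gaussian noise elsewhere.
- **Deployments**: 10 individuals × 7 days by default (tests use 2–4 × 2–5
  days for speed), lognormal dive (600 s) and surface (180 s) durations,
  Poisson lunge counts by state (0/3/6/10 per dive, zero-truncated in
  feeding states so feeding states always lunge), a wrapped-Cauchy
  correlated walk at 1.2 m s⁻¹ with r = 0.7, 20% of dives without a GPS
  fix, and a 4-state multinomial-logit transition model whose FTLE slopes
  grade from −1.5 (toward non-feeding) to +1.5 (toward heavy feeding) times
  a coupling constant, with intercepts set so the stationary feeding
  fraction sits near the ~46% of dives tag data typically show. Movement is
  independent of FTLE by default — so the use-availability test correctly
  reports *no* habitat selection on default simulations — with an optional
  `ftle_taxis` gain that biases heading choice toward high FTLE a
  perception distance (≥ 5 km) ahead for positive-control scenarios. All
  randomness descends from one integer seed via per-individual
  `SeedSequence` spawning.
- **FTLE-like random fields** (for tests that control decorrelation
  directly): spatially smoothed Gaussian fields with AR(1) temporal
  decorrelation (default time constant 6 h), mean 0.3 and SD 0.5 day⁻¹,
  matching the order of magnitude of coastal backward-FTLE values.

What the synthetic conditions do *not* emulate: realistic coastal
oceanography (flows are benchmarks, not the California Current), krill
dynamics, tag measurement error in depth or lunge detection, GPS position
error, and state-dependent movement (speed is state-independent). Passing
tests therefore demonstrate the correctness of the numerics and the
estimators under known generating processes — not that the ecological
conclusions transfer to any particular ocean.

## Problem sizes

The default test and acceptance runs use: 41 × 21 to 81 × 41 velocity
nodes with 2x tracer refinement over 48 h horizons; dense oracles at 4x the
engine seeding with 300 s fixed steps; 20 replicates × (10 × 500) dives for
slope recovery; 20 replicates × 20 000 transitions for coefficient
recovery; and 2 000–10 000 permutations for the weighted K-S null. These
sizes were chosen so each guarantee is demonstrated at comfortable
statistical resolution on a single CPU.

## Known limitations

- The free-slip discretisation and the gap/exit policies are package
  choices (flagged in output metadata); other choices would perturb FTLE
  near coasts and gaps.
- GEE working-correlation estimation with continuous time is the slowest
  step (~8 s per 5 000-dive fit); replicate-heavy auxiliary comparisons use
  independence working correlation (same point estimates asymptotically).
- The weighted K-S permutation p-value treats pooled labels as exchangeable
  within the weighting scheme; with per-individual weights this is an
  approximation whose behaviour is verified empirically (null p uniform
  within Kolmogorov tolerance over 200 simulations).
- Percentile-rank and weighted-quantile tie rules are stated conventions;
  alternative tie rules shift FR_pct by at most one rank unit.
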