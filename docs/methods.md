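# Methods

This note records the statistical models implemented in `lifespanfda`, the
choices made where the methodology leaves room, and what the synthetic
cohorts do and do not establish.

## Distributions as quantile curves

All distributional objects live on a bounded age range [0, T_max] (T_max =
90 days for lifetimes, the observation horizon for event-time densities)
and are represented by their quantile function evaluated on a fixed grid of
201 equispaced probability levels. In this representation the 2-Wasserstein
metric is the L²([0,1]) distance and weighted Fréchet means are weighted
averages followed by a monotonicity projection, so all Wasserstein
computations are linear algebra. Empirical quantiles use the type-1
(left-continuous inverse CDF) convention, which is exact for point masses.

Conversions:

* **quantile → density.** The quantile values with trapezoid weights form a
  weighted importance sample of the distribution; a Gaussian kernel
  estimate with *reflection* at both support ends (removing the O(1)
  boundary bias of densities that do not vanish at 0) is renormalised to
  integrate to one. The default bandwidth is the Silverman rule on the
  implied weighted sample; it is exposed because remaining-lifetime
  densities at large current ages are sharp and can benefit from a smaller
  value. Degenerate inputs (all mass at one point) return a narrow peak
  carrying a `degenerate` flag rather than an error.
* **density → hazard.** λ(u) = f(u)/(1 − F(u)) with F by cumulative
  trapezoid. Beyond the `upper_trim` quantile (default 0.95) the
  denominator amplifies tail estimation error, so values there are masked
  (NaN) instead of reported; the trim level is configurable because no
  principled tail adjustment is implemented.
* **lifetable hazard.** Deaths on day t over the number alive entering day
  t, masked where fewer than 5 remain at risk, then local-linear smoothed
  (default bandwidth 3 days).

## Global Fréchet regression (remaining lifetimes)

The unit of observation is a **cohort cell**: all flies alive past age *a*
that share a covariate combination (diet, or high/low activity). Each cell
contributes the empirical quantile curve of its remaining lifetimes with
predictor (a, indicators). One joint fit pools all cells, so covariate
effects are shared across ages — the fitted map x ↦ F̂ₓ is globally linear
in quantile space. Choices:

* Predictor covariance uses divisor n (not n−1), matching the estimator's
  definition.
* Regression weights can be negative, so the weighted quantile average can
  be non-monotone; the fitted curve is its isotonic (pool-adjacent-
  violators) projection under the probability-grid quadrature weights,
  which is the exact minimiser of the weighted criterion over valid
  quantile functions, then clipped to [0, T_max].
* Cells smaller than `min_cell_size` (default 5 flies) are dropped with a
  warning rather than imputed.
* The activity median split totals each fly's counts over days [0, a] and
  assigns indicator 1 only *strictly above* the cohort median; ties count
  as low, making the split deterministic.

Because every age-a cell reuses the survivors of age a−1, cells are highly
dependent; the fit is a descriptive regression, and no confidence bands are
attached to predicted distributions.

## Product FPCA (activity surfaces)

The panel restricts to flies surviving the whole 32-day window so surfaces
have no missing cells; the mean surface is the pointwise cross-sectional
mean (optional separable local-linear smoothing is off by default for dense
counts). The hour- and day-marginal kernels are trapezoid contractions of
the sample covariance; eigenproblems are solved on quadrature-weighted
symmetric matrices so eigenfunctions are orthonormal in the continuum inner
product. Scores are double trapezoid integrals of the centred surfaces
against product eigenfunctions. Components are reported sorted by fraction
of variance explained — empirical score variance over total centred
variance — not in (j, k) order. Sign convention: each eigenfunction is
flipped so its trapezoid integral is nonnegative (left endpoint decides
near-zero integrals), making repeated fits bit-identical.

Separability of the expansion (products of marginal eigenfunctions) is an
assumption, not a finding: a process with genuinely non-separable
covariance would be summarised suboptimally, which is the price paid for
interpretable per-time-scale components.

## Cox point-process regression (egg laying)

Daily counts become event times by uniform jitter within each day; daily
dish collection destroys within-day timing, so the uniform completion adds
no information and re-binning recovers the counts exactly. Per fly, τ̂ is
the observed event count (the natural estimate of ∫Λ from one realization)
and f̂ a reflected-kernel density of event times; flies with fewer than
`m_min` = 10 events are excluded (kernel densities from fewer events are
unstable) and logged. The cohort is restricted to flies dying after the
horizon T = 35 days so the window is uncensored.

Because the product metric separates, the regression decomposes exactly:
OLS of τ on age-at-death plus global Fréchet regression of the density
quantile curves. Predicted intensities are λ̂ₓ(t) = max(τ̂(x), 0)·f̂ₓ(t);
the clip guards against extrapolated negative τ.

## Concurrent regression (reproductive dynamics)

Y(t) = X(t+1) − X(t) with unit-day denominators; the model is fitted on
t ∈ [10, 35], which requires counts through day 36 and hence flies
surviving past day 36 (no censoring handling). Estimation is raw pointwise
OLS of Y on centred X at each day — exact for noiseless relations and
transparent on a dense daily design — followed by optional local-linear
smoothing of the coefficient curves (default bandwidth 2 days; raw curves
are always retained). Days with fewer than 10 complete pairs or zero
cross-sectional variance are masked. The cross-sectional mean curve is
local-linear smoothed with a 2.5-day rule-of-thumb bandwidth.

Bands are percentile bootstrap (resampling flies with replacement),
pointwise and not simultaneous; a day is flagged significant when zero
falls outside its band. Note that β₀ is defined relative to the
*sample-centred* X, so its bootstrap band remains non-degenerate under a
deterministic relation whenever β₁ ≠ 0 (the resampled cross-sectional mean
moves); only β₁'s band collapses in that case.

## Spherical FPCA (behavior compositions)

Square-root proportions place each day's composition on the positive
orthant of S², where antipodal pairs cannot occur and the Fréchet mean
iteration (tangent averaging, tolerance 1e-10, ≤ 100 iterations) contracts.
Log maps are taken pointwise at each day's mean-curve value — no parallel
transport — and the tangent-valued curves are eigendecomposed in the
quadrature-weighted inner product. At the Fréchet mean the log-mapped data
average to zero day by day (the stationarity condition), so no extra
centring is applied. Days with zero observation totals are masked and the
covariance uses pairwise-complete averaging. Eigenfunction signs follow the
resting component's first nonzero quadrature integral. Reconstructions
exp-map truncated tangent expansions back, so they are unit-norm valid
compositions by construction.

## Synthetic cohorts: what they emulate, and what not

* **Lifespans** are Gompertz with diet acting on the baseline hazard α
  (β = 0.10/day shared; α = 4.0e-4, 2.2e-4, 3.0e-4 per day for C10, C20,
  C50), giving increasing log-hazards, typical ages-at-death of 50–65 days
  on (0, 90), and the C20-best / C10-worst ordering. A `min_age` field
  conditions the inverse-CDF draw on survival, producing survivor cohorts
  (egg cohort past day 36, behavior cohort past day 41) at exact size.
* **Activity** is mean surface + separable Karhunen–Loève expansion with
  Gaussian scores, pushed through a softplus link (sharpness 2; approx.
  linear away from zero while keeping Poisson means valid) and observed as
  Poisson counts. Default score variances (700, 450, 190, 80) are sized so
  the four eigensurfaces explain roughly 13/8/3/1.5% of total count
  variance — most hourly-count variance being shot noise, as in real
  locomotor monitoring. Recovery tests instead use variances (4, 2, 1,
  0.5) with noise off, where the analytic FVE fractions (53.3% leading)
  are exactly known.
* **Egg laying** draws daily counts Poisson around τᵢ·∫f over each day,
  with τᵢ (linked negatively to age-at-death, noise sd 15) and a
  truncated-normal event-time density whose peak (~12 days, drifting
  +0.08 d per day of lifespan) and spread grow with longevity — the
  cost-of-reproduction pattern, and per-fly randomness that makes counts
  overdispersed (doubly stochastic). Densities live on a 40-day horizon so
  both the 35-day Cox window and day-36 counts for the concurrent model
  are covered.
* **Behavior** perturbs a mean composition curve (resting rising from 50%
  to 58%, flying falling from 10% to 6%) on the sphere via three tangent
  components with variances (0.8, 0.12, 0.04) — geodesic deviations of
  0.1–0.3 rad — and observes 12 multinomial draws per day. Exp-mapped
  points that leave the positive orthant (rare at these variances) are
  folded to absolute values, which is what observing proportions implies.

The generators share the estimators' model classes, so passing recovery
tests demonstrates correctness of the implementations under those models —
not robustness to the features real monitoring data add: within-day
autocorrelation of counts, irregular missingness, behavioral states beyond
three categories, non-Gompertz mortality, or measurement artifacts around
death. Qualitative patterns (hazard orderings, cost-of-reproduction signs)
are emulated; no generator parameter was fitted to the request-only
experimental data.

## Problem sizes and numerical tolerances

Tests and the acceptance script run at the cohort sizes of the emulated
experiments where feasible (96 activity flies; 473 egg-laying survivors;
150 flies for truth-recovery fits) and use scaled simulation designs where
a full Monte Carlo would be wasteful: 20 seeds for distribution-regression
error and remaining-lifetime orderings, 200 replicates × 200 bootstrap
resamples for concurrent-band coverage, 60–100 realizations for
kernel-density averages. Orthonormality and tangency are enforced to 1e-6
and 1e-8 respectively; quantile monotonicity violations below 1e-8 of the
curve range are repaired by cumulative max; density normalisation is
checked to 1e-3. Seeds flow from a single master integer through
`SeedSequence` spawning (generators) and `generate_state` (pipeline stage
seeds), so every stage is independently regenerable.

## Known limitations

* The Fréchet regression offers no uncertainty quantification for
  predicted distributions; only the concurrent stage has bands.
* The hazard right tail is masked, not corrected; upper_trim is a blunt
  instrument.
* Local (kernel-weighted) Fréchet regression and forward prediction of
  remaining lifetime from FPC scores are out of scope.
* The product FPCA assumes separable components; the spherical FPCA uses
  pointwise tangent spaces, which is standard but discards cross-day
  curvature coupling.
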