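# Methods

`cansurv` reimplements, as tested library code, the statistical pipeline used
in long-term registry studies of cancer survival: individual records (or
NORDCAN-style aggregated exports) → age-standardized relative (net) survival
per 5-year diagnosis period → Bayesian spline trend models → conditional
5/1-year survival, annual-change curves, plausible-trend segments and
breakpoints → report figures and tidy CSVs. A synthetic-registry module
provides every input with known ground truth, so each stage can be validated
by parameter recovery rather than against unpublishable registry microdata.

## Net survival: the Pohar Perme estimator

Relative survival compares patients with a demographically matched general
population; net survival is the survival patients would have if their cancer
were the only cause of death. For individual *i*, the expected survival
`S_Pi(t)` accumulates life-table annual probabilities along the attained-age /
calendar-year diagonal from diagnosis; partial years enter as fractional
powers (equivalently, a piecewise-constant hazard integrated exactly).

The Pohar Perme estimator weights each individual's at-risk indicator and
event increment by `w_i(t) = 1 / S_Pi(t)`, removing the selection bias that
makes unweighted relative survival drift as high-background-mortality
patients leave the risk set. We use the product-limit form

    S_net(t) = prod_{s_k <= t} (1 - dN~(s_k)/Y~(s_k)) * exp(P(t)),

where `dN~`, `Y~` are weighted death counts and weighted at-risk sums and
`P(t)` is the weighted population-hazard integral
`∫ Σ_i Y_i w_i dΛ_Pi / Y~`. Under a life table with no background mortality
all weights are 1 and `P ≡ 0`, so the estimator coincides *exactly* with
Kaplan–Meier — a reduction the tests assert at 1e-12. The continuous
integral is discretized on the partition of observed times, entry times and
evaluation times, refined so no subinterval exceeds `max_step` (default 0.2
years, i.e. ≈ 73 days); weights and hazards are evaluated at subinterval
midpoints. Variance is the Poisson-type estimator `Σ w_i² dN_i / Y~²` on the
cumulative-excess-hazard scale, mapped through the exponential; 95% CIs are
`S·exp(∓1.96 σ)`. Estimates are reported in percent and may exceed 100
(no clipping — standard relative-survival convention).

Degenerate inputs: if the risk set is exhausted by a censoring, the curve is
undefined (NaN, with a warning) beyond the last exit; it is carried forward
only when the last exit is a death. Individuals whose population cumulative
hazard is identically zero over their risk window take an algebraically
identical constant-weight accumulation path (a pure optimization; the
brute-force oracle tests cover both paths).

### Period construction

Each 5-year diagnosis period 1971–2020 yields one estimate per measure.
The first nine periods use the cohort method (diagnosed in the window,
followed to the 1- or 5-year horizon). The final period uses the hybrid
period + cohort construction: any patient whose person-time intersects the
calendar window contributes, left-truncated at `max(0, window_start − dx)`
and censored at `min(follow-up, horizon, window_end − dx)`; diagnoses from
the penultimate period thereby supply the follow-up years the final period
cannot. The exact windowing algebra used by registry databases is not fully
standardized; this left-truncation reading is one defensible construction
and the estimator supports delayed entry natively.

### Age standardization

The estimator runs within age groups at diagnosis (ages 0–89; older
excluded), and group estimates are combined with fixed external weights
(weighted mean; variance `Σ w² var`). The canonical external weights are
published by IARC and are configuration here; the shipped default is an
ICSS-like stand-in over [0,45), [45,55), [55,65), [65,75), [75,90) with
weights 0.07/0.12/0.23/0.29/0.29. Empty groups are dropped with the
remaining weights renormalized and a warning recorded.

Conditional 5/1-year point estimates are `100·S(5)/S(1)` with delta-method
variance; the Bayesian pipeline instead divides posterior draws (below),
which propagates both fits' uncertainty.

## Trend model

Each series (10 points, percent scale, at period midpoints 1973…2018) is fit
with a Gaussian GAM with identity link: a low-rank thin plate regression
spline with 5 knots. The basis follows the standard 1-D construction:
radial basis `|x−x*|³` over the (standardized) distinct midpoints,
eigen-truncated to the leading 5 eigenvectors, with the orthogonality
constraint against the linear null space absorbed, giving 2 unpenalized
coefficients (intercept, slope) plus 3 penalized smooth coefficients with
penalty `S` (positive semi-definite; round-off negatives clipped).

Priors are explicit because reproducibility requires them: with
`s_y = max(sd(y), 1)` percent, intercept `N(mean(y), (5 s_y)²)`, slope
`N(0, (5 s_y)²)` (standardized time), smooth coefficients
`z ~ N(0, τ² S⁻¹)`, and half-Student-t(3, 2.5 s_y) priors on both τ and the
observation SD σ. These are weakly informative at the scale of survival
percentages.

Sampling: the model is fully conjugate under the inverse-gamma scale-mixture
representation of the half-t, so the default sampler is a blocked Gibbs
sampler (4 chains, 1000 warmup + 2000 draws each): joint Gaussian update of
all coefficients, conjugate τ²/σ² updates, plus an interweaving step that
re-updates log τ on the ancillary scale (`z = τ·u` with `u` fixed) by slice
sampling — without it the τ–z funnel mixes poorly when the data favour a
nearly linear fit. Split-R̂ and bulk ESS (via arviz) are attached to every
fit; R̂ above 1.01 raises unless forced. A fast analytic mode
(`method="conjugate"`) fixes the smoothing parameter at its REML estimate
and draws exactly from the resulting Gaussian/inverse-gamma posterior; it is
used for large simulation studies (it mildly undercovers relative to full
Bayes because smoothing-parameter uncertainty is ignored).

Posterior curves are evaluated on the annual grid spanning the first to last
period midpoint — no extrapolation. Curves are fit on the percent scale.

## Posterior-draw inference

* **Conditional 5/1-year survival**: draw *i* of the 5-year model divided by
  draw *i* of the 1-year model, ×100. The two posteriors are independent, so
  index pairing is a convention; a random re-pairing helper verifies
  insensitivity. The per-draw product identity
  `1-year × ratio / 100 = 5-year` holds to machine precision by
  construction.
* **Derivatives**: central finite differences per draw (step 1 year), exact
  for linear (order 1) and quadratic (order 2) draws. The boundary grid
  years consumed by differencing are excluded from all downstream
  eligibility; no one-sided differences are used at the edges.
* **Plausible trend segments**: maximal runs where the pointwise 95% CrI of
  the first derivative stays on one side of zero, lasting at least 5 years.
* **Breakpoints**: within maximal runs (≥ 3 years) where the second
  derivative's 95% CrI excludes zero, the year of largest |median second
  derivative| (ties to the earliest year); positive curvature =
  acceleration. "At least 5 / 3 years" counts consecutive annual grid
  points by default; `run_units="span"` switches to the year-span reading
  (both are defensible readings of the rule).

Detection characteristics measured on synthetic truths: on flat series the
false-positive rate is ≪ 0.1 breakpoints per series; for a kink in an
otherwise linear trend, localization precision is limited by the 5-knot
basis — the fitted curvature of a kink is a broad plateau whose peak sits
near the adjacent period midpoints, so detected years concentrate within
about one knot spacing (±2–3 years) of the true change year.

## Rates

Age-standardized rates use the Segi world standard population (18 five-year
groups, shipped and normalized): `ASR = Σ w_g (cases_g / py_g) × 100,000`.
Cumulative risk 0–74 uses the exponential form
`100·(1 − exp(−5 Σ_{g≤74} rate_g))`; the product-form alternative is kept as
a test oracle (they differ only in higher-order terms). Rate time series are
smoothed by a penalized cubic B-spline (12 knots at quantiles of x) with the
exact `∫f″²` penalty (2-point Gauss–Legendre per inter-knot interval, exact
for the piecewise-quadratic integrand), solved as augmented least squares so
extreme penalties remain well-posed. λ is exposed directly;
`spar_to_lambda` provides a documented monotone [0,1] parameterization
(`λ = r·256^(3·spar−1)`, `r = tr(B'B)/tr(Ω)`), comparable to but not
bit-identical with other ecosystems' smoothness parameters.

## Synthetic registry

The generator defines the study conditions:

* **Background mortality**: Gompertz–Makeham life tables
  (`h(u) = λ_M + a·e^{bu}`; defaults λ_M = 5e-4, a = 2e-5, b = 0.095, giving
  realistic adult mortality), cell probabilities from the exact one-year
  hazard integral, optional exponential calendar improvement
  (default 0.005/yr where used). Ages 0–109, years 1960–2022.
* **Cohorts**: ages truncated-normal on [0, 89] (default mean 65, SD 12),
  uniform diagnosis dates within the accrual period, independent exponential
  emigration (default 0.005/yr; named as a censoring cause in registry
  practice, rate unreported, hence configurable), administrative censoring
  at the cutoff (default calendar 2021.0 = follow-up through end of 2020).
  Excess (cancer) hazards: constant, piecewise-constant, or cure-mixture —
  all with closed-form net survival for recovery tests. Death time is the
  minimum of the background draw (inverted along the diagonal) and the
  excess draw; `true_net_event` records which cause fired.
* **Aggregated series**: truth(midpoint) + Gaussian noise with stated SE on
  the 10-period 1971–2020 grid. Shipped truth shapes: sigmoids and
  piecewise-linear "waves". Defaults mirror the historical scale of Nordic
  kidney-cancer survival: 5-year survival ~30% in 1971 rising past 70% by
  2020 (> 40 percent-unit gain over 50 years), slopes 0.4 → 1.6 %/yr
  changing at 2000, observation SE 1.0–1.5.

What the generator does *not* emulate: correlated noise across periods
(real NORDCAN estimates share patients between adjacent hybrid windows),
site-specific coding artifacts, age-period-cohort interactions in the
excess hazard, and non-Gaussian estimate uncertainty at low survival.
Passing recovery tests therefore demonstrate correctness of the estimators
and inference rules under the stated models, not robustness to those
real-data features.

## Problem sizes and numerical choices

Simulation studies in the test suite use sizes chosen to make Monte-Carlo
error small relative to the tolerances they check: 200 replicates of
n = 5000 cohorts for CI coverage; 100 replicates for trend-band coverage;
50/500 seeds for breakpoint detection/false-positives (analytic-mode fits).
Discretization: `max_step = 0.2` years for the population-hazard integral;
evaluation at t = 1 and t = 5 exactly. Quantiles are `numpy.percentile`
(linear interpolation). Smoothing-spline and REML systems are solved by
Cholesky/least-squares with eigenvalue clipping guards; the Gibbs sampler
floors variance draws at 1e-12.

## Known limitations

* The hybrid-window algebra and the external standardization weights are
  configurable stand-ins for registry-internal conventions that are not
  fully public.
* Breakpoint years inherit the resolution of the 5-knot spline over 5-year
  periods (≈ ±2–3 years), and edge grid years of a fitted trend are the
  least reliable — the posterior mean there is dominated by a single series
  point.
* The conjugate (fixed-smoothing) mode underestimates band width slightly;
  use the default Gibbs sampler for reported inference.
* No multiple-testing control across populations/measures (deliberately,
  matching standard practice for these descriptive analyses).
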