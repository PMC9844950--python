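# Methods

## Data model and sanitation

An observation is `(ID, lat, lon, u, t)`: WGS84 degrees, `u` the 1-sigma
of two independent normal errors on the coordinates (metres), `t` local
wall-clock time. Consecutive fixes of one device are ≥ 20 minutes apart;
`read_trajectories` restores that invariant by *thinning* (keeping the
earlier fix of a violating pair, duplicates included) rather than
rejecting the device — the spacing is a property of a well-formed feed,
not a validity criterion, and thinning preserves the maximum of data.
Sanitation removes fixes with latitude **and** longitude exactly zero
(the failed-geolocation sentinel; a single zero coordinate is a legal
place on the equator or prime meridian and is kept) and replaces
non-positive `u` with 25 m, the typical Wi-Fi/cell-positioning accuracy.
Both rules are idempotent and never touch valid fields.

## Distance estimation

Geodesics are ellipsoidal (WGS84), computed with Vincenty's inverse
method vectorised over numpy arrays and validated against an independent
Karney-algorithm oracle to sub-millimetre agreement. A spherical formula
would be off by ~0.3%, the same order as quantities the gate is meant to
resolve. Vincenty's non-convergence region (nearly antipodal pairs)
cannot arise between consecutive fixes of a device; such pairs fall back
to the last iterate.

The uncertainty gate zeroes any segment shorter than `r·(uₘ + uₘ₊₁)`
(inclusive boundary, `r = 1`). Each gated segment is attributed to the
calendar day of its **earlier** endpoint, which makes cross-midnight
travel count exactly once and lets the last-fix-of-day → first-fix-of-
next-day segment accrue to the earlier day even when the next day is
itself ineligible. Day boundaries are local wall-clock midnight as
carried by the timestamps; no zone or DST arithmetic is attempted since
timestamps are already local.

Eligibility (≥ n fixes spanning ≥ n hours within the day, n = 12)
guards against daily averages dominated by a few devices observed only
briefly. The stationarity flag uses a strict `L̂ < z` with z = 0.2 km,
absorbing indoor movement.

## Regional stratification and aggregation

A device-day's position is the arithmetic mean of its latitudes and of
its longitudes; longitudes spreading over more than 180° use the
circular mean so an antimeridian-straddling trajectory cannot land on
the wrong side of the planet (no packaged study country straddles it,
but the code must not silently misassign). Point-in-polygon uses
shapely `covers`, so boundaries count as inside; regions are disjoint,
and the first (sorted-id) covering region wins. Device-days covered by
no polygon (coastal GPS noise) are excluded and counted in the log —
the regional indicator is zero for every region and no fallback is
defined.

The country value is `Σ_c w_c · mean_c` with population weights
`w_c = p_c / Σ p_c`. On days where some regions have no eligible device
the weights are renormalised over the covered regions — the weighted
mean is otherwise undefined — and the number of uncovered regions is
logged as a data-quality flag. The daily sample size `N` counts
eligible device-days assigned to some region. M2 is a fraction
internally and a percentage only at the output layer.

Smoothing pools device-days: the q-day value of a region is the pooled
sum divided by the pooled count (days with more devices weigh more),
then country-aggregated with the same weights; the first q−1 days are
emitted missing. With q = 1 this reduces exactly to the daily
estimator. The alternative — smoothing the country series directly —
would weight days equally regardless of sample size and is not used.

## Bootstrap uncertainty

Intervals are percentile-method (linear interpolation between order
statistics) over B = 1000 stratified resamples: each region's
device-days are resampled with replacement at the region's own sample
size and the weighted aggregate recomputed, so regional sample sizes —
part of the design — are held fixed. One shared index resample drives
both the M1 and M2 aggregates per iteration, preserving the devices'
joint structure; `joint_resampling=False` resamples the two values
independently for the literal separate-resampling reading. For smoothed
series the resampling pool is the q-day pooled window, which is what
gives pooled estimates their (correctly narrower) intervals. Resampling
order over regions is deterministic (sorted ids) so a fixed seed yields
bit-identical bounds.

Calibration: over 500 simulated three-region datasets (200 devices split
100/60/40 against a 4:2:1 population ratio, region-specific movement
models), the 95% interval covers the analytic population-weighted mean
95.6% of the time for M1 and 94.6% for M2 (seed 1; other seeds similar).

## Comparison layer

Correlations are Pearson, computed on the two series' common
non-missing days; fewer than 3 days of overlap or a constant series
yields a missing value with a warning. The shift profile correlates
`a(t)` with `b(t + Δ)` for Δ ∈ [−14, 14]: **positive Δ means the
external index trails the mobility metric** (the convention must be
fixed somewhere; it is also stated in the CLI help). Workplaces-type
indices correlate negatively; signed ρ is stored, |ρ| is used for
plots and regression.

Average penetration is the mean daily contributing-trajectory count
divided by the country population (sum of the regions' populations).
The beta regression `|ρ| ~ B(μ, φ)`, `logit(μ) = β₀ + β₁ log₁₀ π`, is
fit by maximum likelihood via statsmodels' `BetaModel` (precision is
log-linked there; the reported φ is the exponentiated parameter).
Boundary values |ρ| ∈ {0, 1} are outside the open beta support, so the
whole response vector is shrunk by `(x·(N−1)+0.5)/N` whenever any value
sits on the boundary (the standard open-interval adjustment, applied
vector-wide and logged). The model-vs-constant test is a Wald F-test of
the slope on the fitted model; under a true zero slope it rejects at
5.0% (200 replicates, seed 1) at the 0.05 level. The pseudo coefficient
of determination is `corr(|ρ|, fitted)²`.

The sensitivity grid recomputes the unsmoothed metrics for all 60
combinations of n ∈ {3, 6, 9, 12, 15}, r ∈ {1, 2, 3},
z ∈ {0.1, 0.2, 0.3, 0.4} km. The device-day table depends only on
(n, r); z merely re-thresholds stored daily distances, so the grid
costs 15 passes, not 60. z cannot move the M1 correlations at all — it
enters only the stationarity flag — and that invariance is asserted in
the tests. r gates segments for *both* metrics in this implementation,
so the corresponding grid property is monotonicity: total distance is
non-increasing in r.

## Synthetic data

The generator emulates the statistical structure the estimators assume,
with every quantity's ground truth recorded. Users live in rectangular
regions (≤ 2° a side, so planar intuition holds for fixtures); their
per-region counts are configurable independently of population to
exercise the weighting. A day is missing (p = 0.1), a stay-at-home day
(p_stay = 0.3 at baseline mobility), or a round trip whose total length
is log-normal — ordinary trips with median 8 km (σ_log = 0.6) scaled by
the day's mobility multiplier, mixed (15%) with short errand-only trips
(median 0.25 km, σ_log = 0.8) that are deliberately *not* scaled: a walk
to the corner shop survives a lockdown. The short component is what
makes the stationarity threshold z and the gate multiplier r
consequential for M2, as real daily-distance distributions have mass in
the 0.1–0.4 km range. The default mobility profile is a lockdown-like
dip with recovery plus a weekend cycle.

Users teleport between stay points at the departure and return instants,
so the true daily distance equals the summed chord lengths and is exactly
recoverable from arbitrarily timed fixes — sampling-time granularity can
never bias the estimand. Positional error is a persistent per-place
offset plus small fix-to-fix jitter (jitter fraction 0.2), with marginal
standard deviation exactly the reported `u`. This correlation structure
is deliberate and is how real Wi-Fi/cell positioning behaves (a parked
phone re-reports the same cached fix): with *independent* per-fix scatter
at the full reported sigma, the distance between two stationary fixes is
Rayleigh with scale u√2 and would clear the r = 1 gate 37% of the time —
no gate at that threshold could suppress such noise, for this generator
or for any real feed matching that error model. Under the correlated
model, stay-day distances are gated to zero essentially always (< 5% of
stay-days show any distance), and a single 5 km trip is recovered within
5%.

Index series are `100·(f(x) − baseline)/|baseline| + noise` from the
true country series, with the baseline the first 14 days, `f` an affine
map (negation gives a workplaces-like index), and the noise sd setting
the attainable correlation via the attenuation `ρ = 1/√(1 + σ²/var)`.

What the generator does **not** emulate: road networks (trips are
straight lines), home/work commuting structure, spatially correlated
outages, or device churn within a day. Passing tests therefore validate
the estimators' arithmetic, calibration and robustness — not the
sociological fidelity of any particular country's series.

### Device-day fast path

Experiments that stress the *aggregation and bootstrap* machinery
(coverage over 500 datasets, the penetration transition over 120
replicate-country-days) draw per-device daily values directly from the
movement model (`simulate_device_days`) instead of reconstructing full
observation streams. The distance estimator's fidelity on full streams
is established separately (oracle equivalence to 1e-9; trip recovery
within 5%; gate suppression of stay-day noise), so the fast path changes
nothing the fuller simulation would measure in those experiments, at two
orders of magnitude less compute.

## Problem sizes used in validation

Oracle equivalence: 1,000 random multi-day trajectories. Gate grid:
exhaustive 201 × 3 × 3 × 3. Bootstrap coverage: 500 datasets × B = 1000.
Beta regression: 200 replicates of 17 countries (recovery at β₀ = 3,
β₁ = 0.5, φ = 20; null at β₁ = 0). Lag recovery: 100 runs, 200-day
series. Penetration transition: 6 penetrations 10⁻⁵·⁵…10⁻³, 20
replicates, 120 days, population 10⁶. End-to-end pipeline: 60 days,
3 regions, 220 devices, ~380k observations.

## Known limitations

* Vincenty (not Karney) geodesics: fine to ~0.5 mm everywhere the
  pipeline uses them, but nearly antipodal pairs fall back approximate.
* The percentile bootstrap has no second-order correction (no BCa); for
  heavily skewed regional distributions at very small samples, coverage
  can drop a point or two below nominal.
* The beta-regression slope test is a Wald F-test; at 17 observations a
  likelihood-ratio test can differ in the third decimal of the p-value.
* Weight renormalisation on days with uncovered regions changes the
  estimand on those days (a covered-population mean); the per-day count
  of uncovered regions is logged so users can filter.
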