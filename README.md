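# mobimetrics

Country-level human-mobility metrics from sparse, noisy smartphone
location trajectories — with honest uncertainty.

With Apple's Mobility Trends Reports discontinued and Google's Community
Mobility Reports frozen, epidemiologists, economists and climate
researchers who used those products as covariates need replacements built
from much smaller location datasets. `mobimetrics` implements a complete
estimation pipeline for such datasets: it turns anonymised per-device
location streams `(ID, lat, lon, u, t)` — where `u` is the 1-sigma
positional uncertainty in metres and `t` a local wall-clock timestamp at
least 20 minutes after the previous fix — into two daily country-level
metrics:

* **M1** — average distance travelled per device, in km;
* **M2** — percentage of devices that moved less than z = 0.2 km in the
  calendar day ("did not move during the 24 h").

## The estimator

For consecutive fixes m, m+1 of one device, the WGS84 geodesic distance
`l` counts only when it clears the **uncertainty gate**

    l̂ = l   if l ≥ r·(uₘ + uₘ₊₁),   else 0          (r = 1)

so a stationary device whose fixes scatter inside the uncertainty disks
accrues no distance. A device's daily distance L̂ sums the gated segments
whose earlier fix falls in the day (the segment bridging midnight counts
once, in the earlier day). Only devices with ≥ n observations spanning
≥ n hours that day contribute (n = 12). The stationarity flag is
Û = 1{L̂ < z}.

Devices are stratified by first-level administrative division: each
device-day is assigned to the region containing its daily mean
coordinates, and the country value is the population-weighted sum of
regional means, `Σ_c w_c · mean_c`, with `w_c = p_c / Σ p_c` — app users
do not mimic the population distribution, and weighting reduces that
bias. A q-day moving average (q ∈ {7, 14, 21, 28}) pools the window's
device-days per region. 95% confidence intervals come from a stratified
non-parametric bootstrap (B = 1000): device-days are resampled with
replacement within each region and the weighted aggregate recomputed;
intervals are empirical percentiles.

The comparison layer correlates the metric series with external
mobility-index time series in the Community Mobility Reports CSV dialect,
computes time-shifted correlation profiles (lags −14…+14 days), and fits
a beta regression `|ρ| ~ B(μ, φ)` with `logit(μ) = β₀ + β₁·log₁₀(π)`
on the average data-set penetration π (mean daily trajectories per
capita) — locating the penetration needed for high agreement with the
external product. A sensitivity grid recomputes everything over
n ∈ {3,…,15}, r ∈ {1,2,3}, z ∈ {0.1,…,0.4} km.

A first-class synthetic module generates trajectories, region polygons,
populations and index series with known ground truth, so the whole
pipeline is testable without any proprietary data.

## Worked example

```python
from mobimetrics import (SimulationConfig, simulate_trajectories, sanitize,
                         compute_daily_stats, aggregate, bootstrap_series,
                         metric_series_frame, EstimationConfig, BootstrapConfig)

sim = simulate_trajectories(SimulationConfig(seed=42, n_days=60))
clean, report = sanitize(sim.trajectories)
stats = compute_daily_stats(clean, EstimationConfig(), regions=sim.region_set)
agg = aggregate(stats, sim.region_set, q=1)
ci = bootstrap_series(stats, sim.region_set, q=1, cfg=BootstrapConfig(B=500, seed=1))
print(metric_series_frame(agg, "SYN", q=1, ci=ci).head())
```

prints (see `examples/01_estimate_metrics.py`):

```
country       date metric  q  estimate   ci_low  ci_high  n_trajectories
    SYN 2020-03-11     M1  1  6.378143 5.504103 7.322853             203
    SYN 2020-03-12     M1  1  5.487071 4.664388 6.434797             196
    SYN 2020-03-14     M1  1  3.425969 2.913056 3.945516             201
```

On 2020-03-11 the 203 eligible devices travelled 6.38 km on average
(95% CI 5.50–7.32); three days into the simulated lockdown the average
has fallen to 3.43 km. The estimated series correlates 0.998 with the
generator's ground truth. The other scripts in `examples/` demonstrate
index comparison and smoothing (`02`), the penetration beta regression
(`03` — slope 2.09 on log₁₀ π, pseudo-R² 0.967, the fitted curve crossing
|ρ| = 0.7 near π ≈ 10⁻⁵) and the sensitivity grid (`04` — |ρ₁| spread
under 0.001 across all 60 (n, r, z) cells).

A thin CLI wraps the same functions for shell pipelines:

```sh
mobimetrics simulate --seed 7 --out-dir data/
mobimetrics compute --trajectories data/trajectories.csv \
    --regions data/regions.geojson --q 1 --q 7 --seed 3 --out-dir out/
mobimetrics compare --metrics out/metrics_q1.csv --cmr data/cmr.csv \
    --regions data/regions.geojson --out-dir cmp/
```

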