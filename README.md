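# driftnet

**Who is polluting whose air?** `driftnet` infers directed,
strength-weighted interaction networks between pollutant time series
measured at many monitoring sites — the transboundary PM2.5 setting, where
fine particulate matter drifts across city and national boundaries with the
synoptic winds. It needs nothing but hourly concentration series: no
emission inventories, no meteorological reanalysis, no chemical transport
model.

The framework has two steps per city pair and calendar-month window:

1. **Lag-scanned cross-correlation.** The Pearson correlation
   P(τ) = Corr(X₁(t), X₂(t−τ)) is scanned over τ ∈ [−168, +168] h (a
   synoptic week either side). P_max = maxP(τ) is the interaction strength;
   T_delay = argmax P(τ) its temporal order (T_delay < 0: city 1 leads,
   candidate direction 1 → 2). Two gates: a t-test that P_max ≠ 0
   (t = r√(n−2)/√(1−r²)) and a one-sided Fisher r-to-z test that P_max
   exceeds the zero-lag correlation P(0).
2. **Granger confirmation.** The lag-derived direction is confirmed with
   the SSR F-test, F = ((RSS_r − RSS_u)/p)/(RSS_u/(T − 2p − 1)): source
   lags must improve an autoregression of the target. Both directions are
   tested; only the candidate direction can create an edge.

Surviving pairs become directed edges (strength P_max, lag |T_delay|) in a
monthly `InteractionNetwork`, exportable as CSV or GeoJSON.

The package also ships the standard plumbing around the statistics —
station-level QC (implausible zeros, >1,000 µg/m³ outliers, duplicates),
station-to-city averaging, timezone harmonisation, monthly windowing — and
a synthetic advection simulator with ground-truth lags and directions so
the entire pipeline is testable end to end without downloading anything.

## Worked example

`examples/03_monthly_network.py` simulates the packaged benchmark — five
cities in a chain under a 12.5 km/h wind (true travel lags 6–18 h from the
source, signal-to-noise 2, realistic data pathologies) — runs the full
pipeline and scores it against the simulator's truth:

```
QC: kept 3605/3665 records (zeros 20, outliers 20, duplicates 20)

January network: 10 directed edges over 5 cities
  C1 -> C2: strength 0.84, lag  6 h, Granger p = 9.4e-24
  C1 -> C3: strength 0.82, lag 10 h, Granger p = 4.7e-17
  C1 -> C4: strength 0.81, lag 14 h, Granger p = 1.0e-06
  C1 -> C5: strength 0.82, lag 18 h, Granger p = 8.5e-05
  C2 -> C3: strength 0.83, lag  4 h, Granger p = 3.2e-30
  C2 -> C4: strength 0.84, lag  8 h, Granger p = 1.9e-16
  C2 -> C5: strength 0.85, lag 12 h, Granger p = 2.5e-14
  C3 -> C4: strength 0.82, lag  4 h, Granger p = 9.9e-27
  C3 -> C5: strength 0.83, lag  8 h, Granger p = 1.7e-25
  C4 -> C5: strength 0.82, lag  4 h, Granger p = 5.2e-16

vs ground truth: direction accuracy 1.00, lag MAE 0.00 h, false edges 0
```

Every downwind-connected pair is recovered with the exact geometric travel
lag (e.g. C1→C5: 225 km / 12.5 km/h = 18 h). Strengths sit near 0.8, the
theoretical correlation of two noisy copies of a shared signal at SNR 2.
The other examples cover a single pair's lag scan, the Granger
confirmation in isolation, and a seasonal wind reversal whose January and
July networks point in opposite directions.

## Command line

A thin CLI wraps the library for shell use:

```bash
driftnet simulate --out sim/                # packaged benchmark scenario
driftnet qc --input sim/records.csv --out qc/
driftnet pairwise --series qc/series.csv --city1 C1 --city2 C3
driftnet network --config run.yaml          # full monthly pipeline
driftnet evaluate --edges out/edges_2018-01.csv --truth sim/truth.csv
```

`run.yaml` holds the input paths, analysis windows and every tunable
(lag grid, minimum overlap, α, Granger max lag and criterion, completeness
threshold, multiplicity method); the resolved configuration is embedded in
every output for reproducibility.

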