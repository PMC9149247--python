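# Methods

`driftnet` infers directed, strength-weighted interaction networks between
pollutant time series measured in many cities. The intended setting is
transboundary fine particulate matter (PM2.5): hourly concentrations from
public monitoring networks, analysed month by month, with no emission
inventories, meteorology or chemistry required. This note records the model,
its assumptions, the tunables, and the design choices made where the design
was genuinely open.

## The two-step framework

**Step 1 — lag-scanned cross-correlation.** For cities 1 and 2 with hourly
series X1, X2, the profile

    P(τ) = Corr(X1(t), X2(t − τ)),   τ ∈ [−168, +168] h

is scanned at 1-hour steps. The default ±168 h range covers one synoptic
week either side; it is configurable (`LagGrid`). The maximum P_max = max_τ
P(τ) measures interaction strength, and T_delay = argmax_τ P(τ) its temporal
order. Sign convention: T_delay < 0 means X2 lags X1 — the best alignment is
obtained by shifting X1 later — so the candidate direction is X1 → X2.

Two gates follow. A two-sided t-test of P_max ≠ 0,
t = r√(n−2)/√(1−r²) on n−2 df, and a one-sided Fisher r-to-z comparison of
P_max against the zero-lag correlation P(0),
z = (atanh r_max − atanh r₀)/√(1/(n_max−3) + 1/(n₀−3)). Correlations use
pairwise-complete overlap; the n fed to each test is the overlap count at
the relevant lag (n_max at T_delay, n₀ at 0), since overlap varies by lag
when hours are missing.

**Step 2 — Granger confirmation.** The direction proposed by the sign of
T_delay is confirmed with the classical sum-of-squared-residuals F-test:
restricted model AR(p) of the target on its own p lags, unrestricted model
adding p lags of the source,

    F = ((RSS_r − RSS_u)/p) / (RSS_u/(T − 2p − 1)).

Both directions are always tested. An edge is created only when the
candidate direction rejects; both rejecting sets a bidirectional flag; a
reverse-only rejection yields no edge and is logged as an anomaly. The test
confirms the lag-derived direction, it does not discover direction.

Pairs surviving both steps become directed edges with strength P_max and lag
|T_delay|, assembled per calendar month into an `InteractionNetwork`.

## Statistical honesty: what the gates do and do not control

P_max is a maximum over ~337 lags. Under an independent white-noise null the
selected maximum is far from zero (≈ √(2 ln 337)/√n), so the raw t-gate
passes essentially always, and the Fisher gate — which compares the selected
maximum against the typical P(0) — also passes far more often than α
(measured ≈ 0.7 at α = 0.05, n = 744; the suite asserts only that the Fisher
gate strictly reduces the t-gate rate). False *edges* are controlled by the
Granger stage, whose F-test is properly calibrated: across simulated
5-white-noise-city windows the mean edge count is ≈ 0.3–0.5 per 10 pairs and
the majority of windows are empty. Users who need family-wise control across
many pairs should enable the Benjamini–Hochberg option (below); the default
reproduces the plain two-gate formulation.

A second documented approximation: P_max and P(0) come from the same data
and are dependent, while the Fisher z treats them as independent samples.
The independent-samples form is the conventional one and is the default; no
dependence correction is offered.

## Granger lag-order selection

The lag order p is selected by AIC (configurable: BIC, or a fixed order)
over 1..p_cap, with two deliberate choices:

* **Selection on the restricted model.** Selecting p by the fit of the
  unrestricted model peeks at the very source lags the F-test then tests;
  measured type-I error was 0.118 at α = 0.05 (n = 744, AR(1) nulls).
  Selecting on the target's own autoregression is independent of the source
  under the null; measured type-I error 0.052, inside [α/2, 2α].
* **Feasibility cap p_cap.** Missing hours are handled by listwise deletion
  of design rows (nothing is imputed anywhere in the package). A row at
  order p needs 2p+1 complete hours, so scattered gaps thin the design
  geometrically (≈ (1−g)^(2p+1) survival at gap rate g); p_cap is the
  largest order whose own design keeps at least max(10p, 2p+5) rows — ten
  rows per searched lag. Rows complete at depth p_cap are complete at every
  shallower depth, giving one common sample on which AIC/BIC values are
  comparable.

When confirming a specific candidate delay of k hours (`confirm_direction`),
the selected order is floored at min(k, p_cap): a parsimonious own-AR
selection picks p ≈ 1–2 for strongly autocorrelated targets, and a model
that does not span the delay cannot confirm it. `granger_test` called
directly keeps the floor at 1, which is what the calibration simulations
exercise.

Stationarity: tests run on raw concentrations by default (hourly windows
within a month are near-stationary); a first-differencing switch is
available and its use is recorded in the result.

## Quality control and ingest

Rules, in order, each itemised in the QC report with per-station count
conservation (retained + removed-by-class = input):

1. missing values → gaps (never imputed);
2. exact 0.0 readings removed as implausible zeros (small positive values
   are retained — the rule is literal);
3. values strictly above 1,000 µg/m³ removed as outliers (exactly 1,000.0
   is retained; the rule is strictly greater-than);
4. duplicated (station, timestamp) keys: exact duplicates collapse to one
   survivor; conflicting duplicates (same key, different values) are all
   dropped — conservative and auditable.

QC is idempotent. After QC, stations within a city are averaged per hour
(arithmetic mean over stations reporting that hour); outlier removal happens
per station *before* averaging, so one bad station never contaminates a city
hour. Timestamps are left-labelled hourly intervals; series are re-labelled
to a common UTC offset (instants unchanged) before any pairwise work —
e.g. Korean/Japanese series at UTC+9 re-labelled to UTC+8.

Monthly windows report a completeness fraction; below the threshold
(default 0.75, configurable) the window is flagged unusable and skipped with
a log entry rather than analysed.

## Numerical and policy choices

* argmax ties: smallest |τ| wins, then the negative lag — deterministic and
  the weakest (shortest-delay) claim.
* T_delay = 0: the Fisher comparison is vacuous; the pair may be
  "significant at lag zero" but yields no directed edge.
* A T_delay on the grid edge is flagged `boundary` and excluded from edges
  by default (an argmax at the scan limit is not a located peak).
* Zero-variance overlap at a lag makes that lag undefined, not an error;
  lags with overlap below `min_overlap` (default 30) are undefined; if no
  lag is defined the pair raises `InsufficientOverlapError`.
* |r| = 1 saturates at 1 − 1e−15 before atanh (with a warning); the t-test
  reports a p-value floored at the smallest positive double.
* α defaults to 0.05 everywhere and is configurable; edge sets are monotone
  in α (stricter α gives a subset).
* Multiple testing across a window's pairs: default "none" (the plain
  formulation); optional Benjamini–Hochberg on the Fisher-gate p-values.
* An optional Bartlett-type effective-sample-size correction
  (n_eff = n(1−ρ₁ρ₂)/(1+ρ₁ρ₂), lag-1 autocorrelations ρ) can replace the raw
  n in both gates; default off, matching the plain formulation.
* Correlations are computed on raw concentrations — no detrending or
  deseasonalising (per-window mean removal is a Pearson no-op).

## The synthetic advection generator

The simulator exists to test the statistics, not to imitate a chemical
transport model. Cities sit on a plane; each calendar month has one wind
(bearing, speed); source cities emit a positive AR(1) signal (marginal mean
60 µg/m³, sd 20, lag-1 coefficient 0.95 by default — a persistent pollution
episode scale); a downwind city receives the source signal delayed by
along-wind distance / speed (rounded to the hourly grid; sub-hour truth is
stored) and attenuated by exp(−decay·distance), on top of a 15 µg/m³
background and its own AR(1) noise (sd 10, coefficient 0.5). With zero decay
the signal-to-noise ratio is emission_sd/noise_sd = 2 everywhere. Ground
truth is geometric: an ordered pair is downwind-connected when the
along-wind separation is positive, the cross-wind offset is within a
corridor (50 km default) and the integer lag is inside the scan range.

Pathologies are injected after signal construction at the rates real agency
feeds exhibit occasionally: 2% missing hours (records dropped), 0.5%
outliers (>1,000 µg/m³), 0.5% exact zeros, 0.5% exact duplicate records.
Outlier/zero hours replace the clean value, so QC turns them into gaps and
the clean series is recoverable up to missing slots — the closed loop the
suite checks record for record.

The packaged benchmark is a 5-city chain at 0/75/125/175/225 km under a
12.5 km/h along-axis wind: source-to-city lags exactly 6, 10, 14, 18 h and
the other downwind pairs at 4–12 h, one January month (744 h), SNR 2, all
pathologies on. Note a 5-city collinear chain cannot keep *all* pairwise
lags within 6–18 h (four adjacent gaps of ≥ 6 h sum to ≥ 24), so recovery is
scored over all ten downwind-connected pairs. The seasonal-reversal variant
adds a July window with the wind reversed and a source at each end of the
chain, mirroring monsoon-driven transport reversal.

What the generator does **not** emulate: dispersion and chemistry, varying
wind within a month, curved trajectories, station-to-station heterogeneity
within a city, diurnal/weekly emission cycles, or heavy-tailed noise.
Passing the benchmark therefore shows the statistics recover lagged,
attenuated common signals under realistic data pathologies — it does not
validate the framework on real atmospheres.

## Problem sizes used in validation

The suite and the acceptance script use: 100 random instances (n ≤ 50,
grid ±5) for oracle agreement; 500 replicates at n = 744 for Granger
type-I calibration and 200 for power; 20 simulated months of the 5-city
benchmark for recovery; one two-window reversal scenario. These sizes give
binomial standard errors below ~0.01 on the calibration rates while keeping
the full validation under a minute on one CPU.

## Known limitations

* The Fisher gate's independence assumption and the max-over-lags selection
  effect (both documented above) mean pair-level significance is not a
  false-positive guarantee; edge-level control rests on the Granger stage.
* Granger confirmation on two noisy copies of one shared signal can weakly
  reject in reverse (each series helps de-noise the other); the lag sign,
  not the F-test, carries the direction, and reverse-only rejections are
  logged, never turned into edges.
* No spatial interpolation, station weighting, distance cutoffs, partial or
  conditional correlations, or multivariate Granger variants.
* Lags live on the hourly grid; sub-hour transport is rounded.
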