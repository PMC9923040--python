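# Methods

## Data model

The unit of raw data is the **session**: one power-on → power-off run of
a personal H₂S monitor, at most 16 h long, holding one instantaneous
reading per 15 s on a grid anchored at the session start. Readings are
on the device's coded scale: 0.0 below the 1.6 ppm limit of detection
(left-censored), multiples of the 0.1 ppm resolution in range, and the
overload code 101 at or beyond the 100 ppm sensor range
(right-censored). Overload readings are carried through every
computation as 101 and never clipped, so sums and maxima on overload
days are explicit lower bounds. Timestamps are local wall clock with no
timezone arithmetic; the devices have no DST awareness and the analysis
never subtracts timestamps across days.

Input files use a canonical CSV dialect defined by this package (one
row per reading, per elided zero-run, or per on/off event; a `#dialect:`
header line guards versioning). Ingestion is tolerant but explicit:
values in (0, 1.6) are coerced to 0.0 — a real device cannot emit them —
while negative values, off-grid timestamps and structural errors are
rejected with line numbers. **Zero-compression** (docking stations elide
maximal runs of below-LOD readings, keeping only their count) is
modelled as a first-class row type; `expand_zero_runs` and
`compress_zero_runs` are exact inverses, and the test suite asserts that
every daily metric is identical on compressed and expanded forms of the
same session. All below-LOD readings are treated as compressible, since
after coercion the stored below-LOD value is always exactly 0.0.

The unit of analysis is the **person-day**: all sessions of one worker
(identified by their personally-assigned device serial) on one calendar
date. A midnight-spanning session belongs wholly to its start date;
with ≤16 h sessions no split rule is needed and none is applied.

## Daily metrics

- **TWA.** `Σ cᵢ · Δt / (480 min)` with Δt = 15 s. The fixed 8-h
  denominator is the default because the monitored population has long
  unexposed stretches and short measured days; dividing by measured
  duration instead (available via `basis="measured"`) answers a
  different question and is not comparable across days of different
  length. Non-detect substitution defaults to 0 and is configurable
  (LOD/2, LOD/√2); with >80% fully-non-detect days any positive
  substitution dominates the TWA, so 0 keeps the estimate a lower bound
  with interpretable bias direction.
- **STEL maximum.** Largest mean over every 60-sample window *within* a
  session; sessions shorter than 15 min use the mean of their available
  samples. Windows never bridge the gap between sessions because the
  instrument restarts its running averages at power-on; bridging would
  average across an unmeasured interval.
- **Peaks.** Maximal contiguous runs of readings ≥ LOD. `gap_merge = g`
  merges runs separated by ≤ g below-LOD samples (gap counts toward
  duration, not height); the default is 0 (pure contiguity) and the knob
  is exposed because short sensor dropouts inside one physical release
  are plausible. Height bands ≤5.0 / 5.1–10.0 / >10.0 ppm are exhaustive
  at the 0.1 ppm resolution.
- **Flags.** Ceiling-value exceedance is strict (>10.0 ppm, i.e. ≥10.1
  at device resolution), so a day whose maximum is exactly 10.0 is *not*
  an exceedance; TWA flags are strict at 5 and 0.5 ppm. Comparisons use
  a 1e-9 guard so resolution-coded floats behave like decimals.

Both peak detection and the rolling STEL are property-tested against
brute-force reference scans (run enumeration; O(n·w) window sweep) over
value pools that include every censoring and band boundary (1.6, 5.0,
5.1, 10.0, 10.1, 100, 101).

## Summary tables

Percentages print as integers rounded half away from zero (`percent`,
implemented in decimal arithmetic), the convention that reproduces the
published-style count tables. The per-SEG table carries counts, their
percentages, and mean/median measured duration; the total row must equal
the column sums and this is a tested invariant. Central tendencies of
TWA are computed on detected days with positive TWA; the mode is taken
after rounding TWA to 0.01 ppm (ties → smaller value) since at this
resolution the mode is the analytically meaningful "<0.01" mass. The
day-maximum histogram anchors a bin edge at 10.05 ppm so one bin
boundary separates compliant from exceedance days, and pools
right-censored maxima into the terminal bin. Peak-count summaries
report, per band, the maximum and median per-day count over detected
days; the per-SEG maximum is the largest per-day count of any worker in
the group. Day-maximum–vs–TWA fits are ordinary least squares on
log₁₀–log₁₀ scale (both quantities span orders of magnitude; a
linear-scale fit is available by flag) over detected days with positive
TWA, requiring ≥3 points.

## Screening experiment

`simulate_detection_rate` draws k distinct days (without replacement by
default — a campaign measures distinct workdays; with-replacement mode
provided, the two differ negligibly at n ≈ 7000) from the pooled day
flags, `n_draws` times under a fixed seed, and reports the fraction of
campaigns containing ≥1 exceedance day next to the closed form
`1 − C(n−x,k)/C(n,k)`. Distinct triples are rejection-sampled from
uniform index draws, which is exact and fast for k ≪ n. Days are pooled
across workers; a per-worker variant would condition the campaign on one
worker's pool and is out of scope.

## Censored statistics

- **Censored ECDF** stacks all below-LOD mass as a single block at the
  LOD; it is nondecreasing, reaches 1, and reduces to the ordinary ECDF
  on uncensored samples.
- **Kruskal–Wallis** (tie-corrected, chi-square p) runs with non-detects
  included as ties at 0 or excluded. Non-detect status is taken from the
  day's above-LOD flag, not by thresholding the tested metric — a
  detected day's TWA is typically below 1.6 ppm and must not be
  re-censored. The statistic is verified against a from-first-principles
  rank computation in the tests.
- **Proportion contrasts** use independent Beta posteriors (flat
  Beta(1,1) prior by default, Jeffreys available), 20 000 Monte Carlo
  draws under a fixed seed, and a symmetric 95% credible interval of
  p_a − p_b; groups "differ" when 0 is outside it. Antisymmetry under
  group swap holds distributionally and is tested to Monte Carlo
  tolerance.
- **Variance decomposition** fits worker-only, SEG-only and SEG+worker
  logistic models of the detection indicator with a small fixed L2
  penalty (α = 1e-3) — the documented rule for complete separation,
  since workers with no detected day are common — and reports the
  unpenalised −2 log-likelihood of the fitted probabilities with the
  design rank as df. Worker labels determine the SEG, so the SEG design
  is nested in the worker design and SEG+worker coincides with the
  worker model up to rank; "within-worker dominates" requires the worker
  model to beat the SEG model by chi-square while SEG adds nothing to
  the worker model at α = 0.05.
- **Lag-1 autocorrelation** pools within-person pairs of adjacent
  entries of a workday grid (pairs never span persons) and computes one
  Pearson correlation. Grids come in three schemes: every workday in
  the person's span with unmeasured days imputed 0 (`calendar_zero`;
  Mon–Fri minus a configurable holiday list, default empty since no
  national calendar is bundled — measured weekend days are kept so the
  scheme lengths stay monotone), measured days only with non-detect days
  as 0 (`detected_zero`), and detected days only (`detected_only`).
  Adjacent grid entries of the sparser schemes may be calendar-distant;
  they are still paired, matching the standard ACF routine run on the
  merged day series. A constant series returns NaN (missing).

## Synthetic cohort generator

The generator is the package's study population. Defaults: 23/15/6/15
workers in sewerage-net / plant / pumping-station / water-net groups;
120 consecutive workdays from 2019-01-01; detectable-day probabilities
0.18/0.21/0.23/0.05 per SEG with worker-level heterogeneity (logit-normal,
σ = 0.8, rescaled so each SEG's mean stays pinned at its configured
rate); P(ceiling exceedance | detected) = 1/3 uniformly across groups;
peak count 1 + NegBinom(0.35, 0.45) (median 1, long tail); peak heights
LOD·exp(X) with X ~ Normal(1.0, 1.3) truncated at 0 — chosen so a single
peak exceeds 10 ppm about a third of the time — drawn from the sub-CV or
super-CV branch of the distribution so the planted day-level exceedance
flag is exact by construction; heights beyond 100 ppm emit the overload
code; peak length Geometric(0.3) samples (median 30 s); measured
duration lognormal with median 293 min and σ = 0.556 (mean ≈ 342 min),
clipped to [15 min, 16 h]; 30% of days split into two sessions; peaks
placed uniformly with ≥1 zero sample between them; flat plateau peak
shape by default (the instrument samples instantaneous values, so no
within-peak shape is observable at 15 s; triangular ramps optional).
Every day yields a truth record (flags, peak list, planted TWA computed
from the emitted readings), and `recovery_report` compares pipeline
estimates to configured rates within 3 binomial standard errors and to
planted flags exactly.

What the generator does **not** emulate: sparse docking (every workday
is measured, unlike a real cohort where only ~10% of workdays yield
data — so calendar-zero and detected-zero grids coincide here), serial
dependence between days (days are independent, so recovered lag-1
autocorrelations are near 0 rather than the few-percent positive values
real data show), task/weather covariates, seasonal structure, sensor
drift, and any correlation between peak count and height beyond their
marginals. Passing recovery tests therefore demonstrate that the
pipeline measures what was planted under the assumed independence
structure, not that real data meet those assumptions.

## Problem sizes and determinism

The default cohort (7080 person-days, ~9200 sessions, ~1100 detected
days) runs through generation, ingestion and metrics in a few seconds;
the test suite uses one session-scoped cohort at these conditions plus
a smaller elevated-rate cohort for module tests. Screening convergence
checks use 10⁵ draws. All randomness flows through
`numpy.random.default_rng` seeded from explicit config fields; the same
seed reproduces cohorts byte-identically, and hypothesis profiles are
derandomised.

## Known limitations

- TWA/STEL on days containing overload readings are lower bounds; no
  imputation above 100 ppm is attempted.
- The peak definition has no minimum duration; a single 15-s reading at
  1.6 ppm is a peak. Gap-merging is available but defaults off.
- The Bayesian proportion contrast treats groups independently; it does
  not model worker clustering of exceedance days.
- The logistic decomposition's −2LL depends (weakly) on the ridge
  strength for separated workers; conclusions are driven by likelihood
  differences far larger than the penalty's effect.
- `percent` follows the half-away-from-zero print convention, which is
  intentionally not banker's rounding.
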