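# Methods

## Scope and model

`ppmir` measures the mutual information rate (MIR, nats/s) between two
stationary point processes observed as strictly increasing event-time series
(seconds). Under the assumption that the two processes never share an event
timestamp, the instantaneous-coupling term of the MIR decomposition is
identically zero and the MIR is exactly the sum of the two directed transfer
entropy rates (TER); no code path adds an instantaneous contribution. Inputs
violating the assumption are rejected; an opt-in, seeded ±1 µs jitter
(`events.jitter_events`) is provided for real recordings quantized on a
shared sampling grid, because silent modification of data should be
explicit.

Stationarity over the analyzed window is assumed, not tested; users of the
per-subject workflow are expected to select stationary epochs themselves.

## History embeddings

The past of a process seen from a time point is approximated by `l`
coordinates: the time since the most recent event, then `l−1` preceding
inter-event intervals (most recent first). At a target event the first
coordinate equals the interval ending at that event, so event-sampled and
random-time-sampled embeddings live in the same space. Joint embeddings
(2`l` columns) put the target block first.

Sampling points without a complete embedding are dropped (standard embedding
practice; the drop count is the difference between the event count and the
row count). Random time points are drawn uniformly from the sub-window in
which both joint embeddings are defined, so that all four entropy terms use
consistently defined samples; their number defaults to the number of usable
target-event rows (the `N_U = N_X` rule). The target rate `λ̄_X` uses the
full span of the target series (last − first event time).

Embedding coordinates are invariant under global time shifts and scale
linearly under time rescaling, which makes the TER scale as 1/time — both
properties are enforced by tests.

## The TER estimator

All distances use the maximum norm; `k = 30` neighbors by default. Two
combinations of the four entropy terms are implemented
(`EstimatorConfig.combine`):

**`knn_ratio` (default).** Each TER is a difference of two log-density
ratios, `ln(p_x/p_u)` evaluated in the joint and in the target-only space,
averaged over event samples. For each event sample the radius of its k-th
nearest neighbor *among the random-time reference embeddings* is used to
range-count the other event samples within it; with the digamma correction
the per-point contribution reduces to `ψ(m_joint+1) − ψ(m_target+1)`,
because ball volumes and the `ψ(k)`, `ψ(N)` constants cancel exactly inside
each ratio. The four entropy terms are still reported (in shared-radius
form) and recombine to the TER value to machine precision.

**`fixed_k`.** Four independent fixed-k estimates: Kozachenko–Leonenko
entropies over the event samples, and cross-entropies of the event samples
against the random-time reference. With `N_U = N_X` and equal `k` the
constants cancel across terms and the TER reduces algebraically to a sum of
log neighbor-distance ratios — an identity the test suite checks to 1e-10.

`knn_ratio` is the default because its small-sample behavior matches what is
known about this estimator family on short, strongly autocorrelated event
data: a negative bias on uncoupled processes at N ≈ 300 that shrinks as N
grows (both checked by the acceptance suite), and near-zero values for
independent Poisson processes at large N. The `fixed_k` combination is
consistent but converges slowly and its short-record bias is positive and
large under strong coupling, which makes the surrogate correction
ineffective; it is retained for the algebraic identity and for comparison.

Degenerate (constant) embedding coordinates make kNN estimation undefined
and raise with a pointer to the input jitter. Near-duplicate rows are broken
by a deterministic seeded jitter of amplitude `1e-8 ×` the per-column
standard deviation applied to embedding matrices before searches; ties in
neighbor searches then have probability zero.

## Surrogates and the corrected MIR

The corrected measure is `cMIR = MIR − median(M surrogate MIR values)`; the
median, not the mean, absorbs asymmetry of the surrogate distribution.
`M = 100` by default (experiment drivers use a scaled-down `M = 20`, noted
in their outputs). A pair is flagged significant when its MIR exceeds the
95th percentile (linear interpolation between order statistics) of the
surrogate values. Note that with only M = 20 surrogates the interpolated
95th percentile sits essentially at the 19th order statistic, so even an
exact null fires at ≈9% rather than 5%; calibration statements should be
made at M = 100.

Engines (all bit-reproducible under a fixed seed):

* **local_permutation** (default): for each TER direction, every at-event
  joint row's source block is replaced by the source block of one of its
  `n_perm_neighbors` nearest rows — in target-block max-norm distance —
  drawn with replacement from a dedicated pool of freshly sampled
  random-time embeddings (disjoint from the estimation reference set, which
  would otherwise contaminate the searches with duplicate rows). Under the
  null "present of the target ⟂ source history | target history" the
  conditional source-history distribution is identical at events and at
  random times, so the donors realize the null exactly while the relation
  between target and source histories is maintained. Only the joint-space
  entropy terms are recomputed per surrogate; the target-only terms are
  unchanged by construction. `n_perm_neighbors = 30`, set equal to `k`:
  structure finer than the estimator's own smoothing scale is invisible to
  it, so tighter conditioning only starves the donor pool. Two design notes
  from development: (i) a plain permutation of source blocks *within* the
  event set (exposed as the operation `surrogates.local_permutation`, with
  exact target-block immutability and source-multiset preservation) does not
  work as a null engine, because the source-block marginal at target events
  already carries the event-locking signature of coupling and any
  permutation preserves it; (ii) drawing donors without replacement
  anti-clusters source blocks locally and biases the surrogate MIR strongly
  downward, whereas with-replacement drawing is the correct iid conditional
  draw. Exact-copy collisions of the with-replacement draw leave a small
  conservative residual (mean null cMIR ≈ −0.03 nats/s at N = 300), making
  this engine err toward specificity — it under-fires, never over-fires.
* **shuffle**: seeded uniform permutation of the inter-event intervals;
  preserves their distribution exactly, destroys serial and cross
  correlation. For renewal processes a reshuffle of both series
  (`apply_to="both"`) is an exactly exchangeable null — the configuration
  used to verify calibration of the significance test.
* **iaaft**: iterative amplitude-adjusted Fourier transform on the interval
  series; alternates spectrum imposition and rank-ordering back to the
  original amplitudes, stopping when the rank order stabilizes (cap 100
  iterations). Amplitude multiset preserved exactly; spectrum approximately.
* **jodi**: autocorrelation-preserving permutation, implemented to its
  contract (the original algorithm is external): seeded greedy pairwise-swap
  descent from a random shuffle, minimizing the summed squared lag-1..5
  autocorrelation discrepancy, with incremental objective updates; stops at
  tolerance 1e-4 or 100 sweeps. Matches lag-1 autocorrelation to <0.05 on
  heartbeat-like series.

Interval-engine surrogates rebuild event series from the surrogated
intervals (start time preserved). By default each TER direction's *source*
process is surrogated (`apply_to="source"`), preserving each target's own
dynamics; `"both"` surrogates the two processes independently and estimates
the MIR of the surrogate pair.

## Simulators

* **Renewal processes**: i.i.d. exponential (Poisson), Gaussian (draws
  resampled until positive, with the truncation fraction logged — the
  parameter grids include settings where ~20% of draws are non-positive) or
  inverse-Gaussian intervals. Series start at `t0` (default 0) and contain
  `n_events − 1` intervals; uncoupled pairs get distinct seeded origins so
  no timestamp is shared.
* **Inverse-Gaussian sampling** uses the Michael–Schucany–Haas
  transformation (chi-square plus a uniform root choice), seeded and
  vectorized; it is cross-checked against `scipy.stats.invgauss` by a KS
  test.
* **HDIG heartbeat model**: interval `w_i ~ IG(mean μ_i, shape λ)` with
  `μ_i = θ0 + Σ_j θ_j (w_{i−j} − θ0)`. The AR regression acts on
  *deviations* from θ0: the literal form (AR on raw intervals with intercept
  θ0) would move the stationary mean to ≈3.9 s for the default pole set,
  contradicting θ0 = 1 s as the mean heart period; the deviation form keeps
  every stated mean exact while preserving the poles and hence the VLF/LF/HF
  spectral peaks (verified at ~0.1 Hz and ~0.25 Hz on long runs). Defaults:
  p = 5 poles {(0.8, ±2π·0.1), (0.92, ±2π·0.25), 0.6}, θ0 = 1 s, λ = 600 s.
  If an extreme excursion drives μ_i ≤ 0 it is clamped at 0.1·θ0 (counted);
  200 warm-up intervals are discarded so reported series are approximately
  stationary.
* **Pulse-arrival delays**: `y_i = x_i + τ_i`, `τ_i = a0 +` AR(2) deviation
  with poles (0.8, ±2π·0.1) (~0.1 Hz), `a0 = 300 ms`; the Gaussian
  innovation SD is derived in closed form from the stationary AR(2)
  variance so that SD(τ) = `σ_PAT` exactly. At the top of the `σ_PAT` grid
  (235 ms) non-positive delays occur by construction (~10% of events); they
  are permitted and counted. Strict-ordering violations of `y` raise by
  default; `on_violation="clip"` lifts offenders minimally (1 ms, logged).
  The experiment drivers clip rather than resample: at `σ_PAT = 235 ms`
  roughly 40% of common-driver realizations contain at least one violation,
  and discarding them would bias the ensemble toward low-variability
  realizations.
* **Common-driver variant**: heartbeat intervals from an AR(3) HDIG model
  with poles {0.92, (0.92, ±2π·0.25)} (the real pole is implemented at
  +0.92 as specified for this scenario), plus an injected `2τ_i` term where
  `τ_i` is the same AR(2) realization used for the delays; `σ_PAT` then
  scales a shared LF component and acts as a coupling parameter. The AR
  history is driven by the raw HDIG intervals (before the `2τ` addition).
  Composite intervals clamped at a 1 ms floor if non-positive (counted).

What the generators emulate: the event-time structure, spectral bands and
coupling mechanisms of short-term cardiovascular variability (heart-period
autocorrelation, ~0.1 Hz delay oscillations, common sympathetic LF drive).
What they do not: respiration, nonstationarity (posture changes, trends),
measurement noise in event detection, ectopic beats, and any marked or
multivariate structure. Passing tests therefore demonstrate estimator
behavior under realistic *stationary* event dynamics, not robustness to
artifacts of real recordings.

## Seeding

One master seed; every generator, random-time draw, jitter stream and
surrogate is derived from it through `numpy.random.SeedSequence` spawn keys
with a fixed layout, so every reported number is reproducible bit-for-bit.
Experiment tables are pure functions of (config, master seed).

## Problem sizes

The test and acceptance protocols use the short-record regime the package
targets: N = 300 events, 20 realizations and M = 20 surrogates for the
coupling-magnitude checks; 50–100 uncoupled pairs for bias and calibration
checks (M = 100 surrogates for calibration); 10 realizations for
monotonicity checks across `σ_PAT` ∈ {10, 235} ms and N ∈ {300, 5000};
N = 10⁴ samples for the closed-form entropy oracles (tolerance 0.05 nats).
Full-scale studies would use 100 realizations and M = 100 throughout; the
reduced replication preserves the sign and ordering relations while
absolute means carry a few-percent standard error.

## Known limitations

* The cMIR correction reproduces the bias of *uncoupled* processes; under
  strong coupling the estimator bias differs and a residual remains, so
  cMIR is a detection-and-comparison measure, not an unbiased MIR estimate
  (at the strongest simulated coupling the large-N MIR is ≈1.6 nats/s at
  l = 1 while the corrected short-record value is ≈0.6).
* The local-permutation engine's with-replacement donor draw leaves a small
  conservative offset (≈−0.03 nats/s at N = 300) in the null mean of cMIR.
* The `knn_ratio` combination is one defensible realization of joint
  four-term estimation; other search-sharing schemes yield the same large-N
  limit but different small-sample bias profiles, so absolute short-record
  values are estimator-specific and only comparisons within one scheme are
  meaningful.
* Surrogate generation dominates runtime (M + 1 MIR estimates per pair);
  network-scale applications with many pairs will find this the bottleneck.
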