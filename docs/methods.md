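# Methods

## Signal model and event definition

All analyses operate on z-scored regional BOLD signals x_i(t), t = 1…T,
sampled every TR seconds (population-SD convention: each column has mean
0 and SD 1 when divided by T; the convention is used consistently for
z-scoring, thresholds and the cross-covariance normalisation). A *source
event* of region i is the window [t − pre, t + post] around an upward
threshold crossing, defined discretely as the first sample at/above
threshold: x[t−1] < θ ≤ x[t]. Defaults: θ = 1 SD (results are typically
stable over 1–2 SD), pre = 2 TR, post = 4 TR — at TR ≈ 2.3 s this covers
the ~10–15 s support of the hemodynamic response. *Target events* are cut
from every other region at the source's surviving crossing times
verbatim, which is what makes all event-level measures directed.

Boundary crossings whose full window does not fit in the scan are dropped
(not padded) so all rows of an event stack align; drop counts are
reported. No minimum inter-event separation is enforced at detection
time; overlapping windows are allowed.

## Correlation estimators

Five estimators are exposed; entry (i, j) of a matrix always uses i as
source:

1. `pearson_full` — whole-series Pearson correlation (symmetric,
   reference measure);
2. `event_single` — Pearson correlation of the k-th source/target event
   pair;
3. `event_mean` — mean of the per-event correlations over usable events
   (per-event correlations undefined on constant segments are excluded
   with a count rather than propagated);
4. `event_concat` — Pearson correlation of the row-major concatenations;
5. `event_average` — Pearson correlation of the average source and
   average target waveforms. This is the default for matrix assembly and
   seed maps.

Event estimators operate on W = pre + post + 1 samples per event, so
their null sampling distribution is much wider than the full-series
Pearson's — a property, not a defect, verified in the test suite. No
small-sample bias correction is applied; the raw estimator is exposed.
Fisher's z-transform is available with |r| clipped at 1 − 1e−7.

## Directionality

Two complementary measures:

* Correlation asymmetry D = R − Rᵀ for an event-method FC matrix R, with
  per-region row sums and the global sum. D is exactly antisymmetric, so
  the complete-matrix global sum and the sum of per-region values are
  identically zero (computed by summing antisymmetric pairs together so
  the zero is exact in floating point, not a summation-order residual);
  information lives in individual entries and per-region contrasts.
  Pairs with an undefined value in either direction are excluded with a
  count.
* Shared-event ratio: the fraction of region i's source events at which
  region j is at/above threshold at the crossing sample. A configurable
  ±w TR tolerance (default 0) absorbs discretisation of the crossing
  sample: at the crossing the signal is on its rising edge, so a
  co-occurring event in the other region may reach threshold one sample
  earlier or later. Not symmetric in (i, j).

Graph summaries (average clustering coefficient, characteristic path
length over connected pairs, disconnected-pair count) are computed on the
binary undirected graph obtained by thresholding the element-wise max (or
mean, configurable) of |R| and |R|ᵀ.

## Delays

**Cross-covariance route.** C_ij(τ) = (1/T) Σ_t x_i(t + τ) x_j(t) for
τ ≥ 0, summed over the overlapping range and divided by the full T;
negative lags are *defined* by the reversal identity C_ij(−τ) := C_ji(τ),
which makes the delay matrix exactly antisymmetric by construction rather
than up to round-off. The delay is the integer lag of the extremum of |C|
(so anticorrelated propagation is captured; a flag restores max-of-C),
refined by the three-point parabola below unless the extremum sits at the
search bound, in which case ±L is returned unrefined.

**Event route.** For each source event: the source peak is the maximum
sample within the event window (parabola-refined when interior); the
target peak is the *closest* peak of x_j within [−6, +8] TR of the
crossing — closeness measured to the source peak, on which the search is
conceptually centred. The per-event lag is the difference of refined peak
times; the mean over events gives τ̄(i, j), and a delay between *average*
events is also provided. When the target search finds no interior peak
and the window's maximum sits on a window edge, the lag is clamped to
exactly −6 or +6 without refinement (the asymmetry between the [−6, +8]
search window and the ±6 clamp is deliberate and kept as specified).
Negative polarity searches local minima (de-activation events) instead.

**Parabolic vertex.** For ordinates (y₋, y₀, y₊) at abscissae (−1, 0, 1)
the sub-sample offset is δ = ½ (y₋ − y₊) / (y₋ − 2y₀ + y₊), clamped to
[−1, 1]; a near-degenerate denominator (|·| < 1e−12) yields δ = 0.

**Peak prominence floor.** Candidate target peaks are strict local maxima
(plateaus contribute their leftmost sample) with prominence ≥ 0.5 SD by
default. The floor is a numerical-robustness choice: discrete noisy
signals contain arbitrarily small ripples that satisfy the strict
local-maximum predicate, and because the closest-peak rule ignores peak
amplitude, such ripples in flat stretches of the target otherwise
pre-empt the true lagged peak whenever they fall nearer the source peak.
Smooth, band-limited real BOLD rarely exhibits them, but additive-noise
surrogates always do. Peaks of any *amplitude* — including sub-threshold
ones — still qualify; only sub-noise ripples are rejected. Setting
`min_prominence=0` restores the literal strict-local-maximum rule.

**Sign conventions.** The two routes follow their respective definitions,
which have opposite orientations: `pearson_delay(i, j) > 0` means i's
pattern is shifted later than j's under the C_ij(τ) indexing (a target
lagging the source by d gives τ(i, j) = −d), whereas
`event_delay(i, j) > 0` means the target peaks *after* the source. Every
result carries its convention string; outputs are in TR units with a
flag to report seconds.

## Synthetic generator

The generator emulates what the estimators assume about real data:

* **Noise**: stationary AR(1), x_t = ρ x_{t−1} + √(1−ρ²) ε_t, default
  ρ = 0.725 — the midpoint of the empirical 0.6–0.85 lag-1
  autocorrelation range of resting-state BOLD — or 1/f^α spectral noise
  with random phases.
* **Events**: a double-gamma HRF (positive lobe peaking at 5 s,
  undershoot at 12 s scaled by 1/6, support truncated at 15 s, unit peak
  amplitude) placed at Poisson onsets, default expectation 8 events per
  104-sample scan (the empirical order of threshold-crossing counts),
  amplitude 3 noise-SDs. A refractory gap of one delay-search-window span
  (15 TR, configurable, may be disabled) separates onsets: events closer
  than the [−6, +8] TR search window would sit inside each other's
  windows and make the closest-peak delay ill-posed by construction, so
  the generator's default conditions keep the estimator's own assumption
  satisfied.
* **Coupling**: each receiver reproduces a chosen fraction (*share*) of a
  driver's events after a configurable lag. Sub-sample lags are exact:
  the *continuous* HRF is shifted before sampling rather than
  interpolating sampled noise. Regions appearing only as receivers carry
  no events of their own; drivers and uncoupled regions get independent
  Poisson trains.
* All randomness flows through a single `numpy.random.default_rng(seed)`
  (PCG64), so outputs are bit-identical across platforms for a fixed
  seed; the ground truth (event onsets, per-pair lag and share) is
  returned beside the data.

What the generator does *not* emulate: scanner drift and physiological
confounds, spatial structure and smoothing, HRF variability across
regions, preprocessing artefacts. Passing recovery tests therefore shows
the estimators are correct under their stated assumptions, not that those
assumptions hold in any particular dataset.

## Test and simulation conditions

Deterministic identities (oracle equality, antisymmetry, parabolic closed
form) are tested exactly (≤1e−12). Stochastic recovery tests use
conditions chosen once as a realistic desk-scale setting: T = 300
samples, event amplitude 3, noise scale 0.1 for lag recovery ("mild"
noise) and 0.3 for directionality-share recovery (with the ±1 TR
tolerance), 100 seeded runs each. The crossing-rate check uses 1000
AR(1) realizations of 104 samples at ρ = 0.725, threshold 1 SD. These
problem sizes keep the full suite in the order of seconds on one CPU.

## Degenerate inputs and numerical choices

Constant columns cannot be z-scored and are rejected with the offending
label; constant event segments yield undefined correlations, excluded
from averages with counts; regions without events produce missing FC/
delay rows plus warnings, and missing entries are excluded pairwise from
asymmetry sums. Table reads reject missing values (the method assumes
complete scans) and name the offending cell; writes use shortest-repr
floats so read/write round trips are exact. An explicit TR always
overrides a NIfTI-header TR, with a warning on mismatch.

## Known limitations

* The closest-peak delay is intrinsically sensitive to neighbouring
  events within the search window; with event spacing below ~15 TR,
  per-event lags of uncoupled regions scatter widely (this is visible,
  and tested, as higher per-event lag SD for independent pairs).
* The event estimators' short windows make single-pair values noisy; they
  are meant to be aggregated (over events, subjects or edges), not read
  individually.
* Correlation-asymmetry sums over a complete matrix are identically zero;
  only sub-matrix or per-region readouts are informative.
* No inference machinery (null models, group statistics) is included.
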