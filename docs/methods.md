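# Methods

This note records the models implemented, the conventions adopted where
the underlying definitions leave room, the parameter defaults and why,
and what the test suite does and does not establish.

## Hindmarsh–Rose simulation

The three-variable HR system (membrane potential X, fast current Y,
slow current Z) is integrated with a fixed-step classical RK4 scheme
compiled with numba.

* **Step size** `dt = 0.01` time units.  The mean inter-spike interval
  in the studied regimes is ≈ 32 time units, so every spike is resolved
  by >3000 steps.  One RK4 step of this smooth low-dimensional system
  has local error far below spike-timing resolution; the first 15 ISIs
  of the chaotic r = 0.0055 orbit agree with an adaptive RK45 reference
  at rtol 1e−9 to 0.13%, and with a dt/2 run to well under 1%.  A fixed
  step also makes runs bit-reproducible across platforms and about two
  orders of magnitude faster than a generic adaptive solver on the same
  problem (≈ 0.08 s per 500-spike series), which is what makes
  full-scale dataset construction (hundreds of such series) routine.
* **Chaotic divergence caveat.**  Positive Lyapunov exponents amplify
  *any* solver-level difference to O(1) within a few tens of intervals
  (measured onset ≈ ISI 21 at r = 0.0055).  Long ISI series from
  chaotic parameters are therefore reproducible as *distributions*, not
  point-by-point; all dataset-level statistics used here are of the
  distributional kind.
* **Initial state** (0, 0, 0), fixed.  Unmeasurable in principle;
  fixing it gives determinism.  The first 20 detected spikes are
  discarded to remove the initial transient (the orbit settles onto its
  attractor within a few spikes).
* **Spike detection**: local maxima of X(t) with X > 1.0 and a minimum
  separation of 5 time units (spike peaks sit near X ≈ 2 while
  subthreshold oscillations stay below 1; the separation suppresses
  numerical double-peaks).  Peak times are refined by a parabolic fit
  through the three samples around each maximum.  "Distance between
  spikes" is the time between consecutive peak maxima.

## Fuzzy entropy

FuzzyEn(m, r1, r2) = ln φ^m − ln φ^(m+1), with φ the average
exponential fuzzy similarity exp(−d^r2 / r1) over ordered template
pairs (i ≠ j), Chebyshev distance d, and templates equal to consecutive
segments minus their own mean.  Conventions adopted where the defining
equations are ambiguous:

* **Template count**: N − m vectors at *both* lengths m and m+1, so the
  two φ averages run over identically sized pair sets (the convention of
  the widely used entropy toolboxes).
* **Exponent grouping**: exp(−(d^r2)/r1), the Chen-style membership.
* **std** (for the relative tolerance r1 = c·std) is the population
  standard deviation of the window itself, recomputed per window.
* **Constant windows** return FuzzyEn = 0 (σ = 0 would zero the
  tolerance; a constant series is maximally regular).

Operating point m=1, r2=1, r1=0.01·std: chosen as the sensitivity
maximum over the sweep grid (m 1–3, r2 1–5, r1 (0.005–0.4)·std) exposed
by `fuzzyen.optimize_params`.  Note that at m=1 the length-1 templates
are identically zero after baseline removal, so φ¹ = 1 and the entropy
is governed entirely by the distribution of first differences of the
window — a useful reading of why it discriminates bursting patterns so
sharply.  The implementation is vectorized O(N²) numpy; tests pin it to
a naive double-loop transcription of the definitions at 1e−12 on random
series, plus offset- and scale-invariance properties.

## Datasets

Standard build: 100 evenly spaced r in [5e−3, 1.5e−2] (endpoints
inclusive), one 500-interval ISI series per r, 100 windows of length
NL = 50 at shift S = 4 (the first 100 of the 113 that fit; first-k is
deterministic), FuzzyEn targets at the default parameters.  Base_1 uses
I_ex = 3.25, Base_2 uses 3.35, Base_1_2 is their concatenation.
Normalization is a single constant — the dataset grand mean —
subtracted from every element; it is recorded on the dataset and stored
in trained models so raw windows can be fed at inference.

## Perceptron sensor

Architecture: NL inputs → NH logistic-sigmoid hidden units → 1 linear
output.  Optimization: scikit-learn's MLPRegressor (squared-error loss,
adam, batch 200, ≤ 500 epochs, tol 1e−6), seeded for reproducibility;
learned weights are extracted into the package's own `SensorWeights`
container whose forward pass is implemented independently (and tested
against a scalar loop).  These optimizer settings are conventional for
a 10,000 × 50 regression problem; at much smaller data scales adam
needs a larger epoch budget (the batch count per epoch shrinks), which
is why some small-data tests raise `max_epochs`.

* **Cross-validation**: K = 10 folds, shuffled once with the run seed;
  the reported metric is the mean over folds.  The normalization
  constant is treated as a property of the dataset (computed on the full
  set before splitting), matching how the sensor would be deployed.
* **Cross-dataset evaluation** centers each dataset by its *own* grand
  mean: the constants differ only in the third decimal between the
  standard builds, and a deployed sensor knows only its own input
  statistics.
* **MAPE** excludes targets that are exactly 0 (possible for constant
  windows).
* **Equal-weight simplification** (NH = 1): replacing the trained input
  weights by their common mean yields a sensor that depends only on the
  window mean — a one-sigmoid integrator that still tracks the
  order/chaos alternation because mean ISI and entropy are strongly
  associated across the r grid.
* **Output averaging**: a trailing moving average (default 20 points)
  over consecutive window estimates; trailing, so the smoothed series
  aligns index-for-index with the raw one and is causal in streaming
  use.

## Sensor characteristics

En_av(chaos), En_av(order): estimator outputs averaged over 100 windows
within each reference series, then across the five series of each group
(chaotic r = 0.0056, 0.0076, 0.0082, 0.0119, 0.0141; regular
r = 0.0068, 0.0070, 0.0099, 0.0105, 0.0108; all at I_ex = 3.25).
**Std_En is the population standard deviation pooled over all 500
individual window estimates of a group** (output smoothing, when
requested, is applied within each series before pooling).  Two readings
of "deviation over five series" are possible — pooled windows, or the
deviation of the five per-series means — and they coincide numerically
at NL = 50 (≈ 0.26–0.36 for FuzzyEn).  The pooled reading is adopted
because it alone produces the known behavior of the characteristics:
Std_En(chaos) falls rapidly with NL (2.8 at NL = 10 to 0.28 at
NL = 100, tracking per-window estimator noise), EnErr falls from ≈ 60%
at NL = 10 to ≈ 13% at NL = 50, and a trailing 20-point average
reduces Std_En roughly by √20 — whereas across-series deviation is
NL-independent and unaffected by smoothing.  EnSens·EnErr = 100 holds
identically whenever EnR > 0; a degenerate estimator (EnR ≤ 0) yields
NaN sensitivity/error with an explicit `defined = False` flag.

A caveat on the perceptron variant: a sensor trained at I_ex = 3.35
and characterized at I_ex = 3.25 operates out of distribution, and its
prediction scatter on the characterization windows adds to Std_En.
How much it adds depends on fine details of the training data that the
simulation protocol does not pin down (see Known limitations), so the
perceptron characterization is reported but is the least reproducible
quantity in the package.

## Synthetic recordings

The voltage-trace pipeline (low-pass filter → relative-height peak
picking → periods) is exercised on synthetic recordings because the
original nerve recordings are not redistributable.  The generator
emulates their two regimes at a 40 kHz sampling rate: **rest** draws
ISIs from a high-CV lognormal (median 1.6 ms), **stimulation**
alternates dense near-regular bursts (0.65 ± 0.04 ms) with quiet gaps;
all periods are clipped to [0.1, 8.8] ms and a biphasic ~1 ms spike
template plus white noise (σ = 0.03) forms the trace.  What it does
*not* emulate: real spike-shape variability and overlap, drifting
baselines, multi-unit activity, recording artifacts.  Passing tests
therefore establish that the *pipeline* (filtering, height-referenced
peak picking, windowed entropy, sensor transfer) behaves correctly on
signals with the documented statistics — not that the specific
published accuracy numbers for real recordings are reproduced.

Filter: zero-phase 4th-order Butterworth (10 kHz default cutoff);
zero-phase preserves peak times.  Peak rule: a sample strictly greater
than its 2 neighbors on each side, kept if ≥ 20% of the global maximum
of the filtered trace.  The relative-height reference means detection
on extremely narrow (sub-sample) pulses can behave differently before
and after filtering; with realistic spike widths filtering only removes
noise peaks.

## Reproduction tolerances

The benchmark drivers compare recomputed values with the published
reference numbers at: means ±2% relative, R² cells ±0.06 absolute,
characteristic entropy means ±0.15 absolute, error percentages ±3
points, dataset element extremes ±15% (extremes of chaotic series are
the least stable statistic under unspecified initial conditions).
Stochastic training and the chaotic-divergence caveat above are why
exact agreement is not the success criterion.

## Known limitations

* **Cross-dataset quantities are the least reproducible.**  The HR
  datasets depend on unstated details (initial conditions select among
  coexisting attractor branches; e.g. the lowest-r series of the
  I_ex = 3.35 build contain a handful of short intervals whose presence
  or absence shifts the dataset's Min_X substantially).  In-distribution
  results (dataset statistics, CV R², the direct-FuzzyEn sensor
  characteristics and the full length sweep) are robust to these
  details; train-on-one-current/test-on-the-other R² and the
  characterization of a transferred perceptron can shift by ~0.1 R² /
  several EnErr points between equally defensible reconstructions.

* Single-orbit determinism means dataset builds have no seed of their
  own; only training/shuffling consume the run seed.
* The NH = 150 variant of the published study is supported by the same
  code path but not exercised by default (NH = 50 is the efficient
  operating point; NH = 150 mainly demonstrates overfitting).
* FuzzyEn cost is O(N²) per window — fine for NL ≤ 100, not intended
  for long series.
* The equal-weight simplified sensor is dataset-specific: its accuracy
  drops sharply when the mean-to-entropy association changes (e.g.
  across datasets with different ISI ranges).
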