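# Methods

## Problem and data model

The package classifies individual heartbeats from a two-lead ECG into the
AAMI superclasses N (normal and bundle-branch/escape beats), S
(supraventricular ectopic) and V (ventricular ectopic), under the
inter-patient protocol: models are trained and evaluated on disjoint sets of
patients (DS1 vs DS2 on MIT-BIH; DS1 is further split by patient into DS11
for training and DS12 for validation during tuning, so no optimization step
ever sees validation patients).  F and Q beats are supported by the I/O and
metric layers but the classification pipeline is three-class, matching the
protocol the shipped benchmark matrix comes from.

The annotation-symbol table mapping MIT-BIH beat symbols to superclasses is
shipped as data (`io_data.AAMI_SYMBOL_MAP`) and can be overridden.  The
partition constants exclude the four paced records (102, 104, 107, 217).
One listing of the test partition circulates with the truncated entry "11";
the package ships the canonical record 111.

## Beat representation

Each annotated beat is cut to a window of [-250 ms, +450 ms] around the R
point (253 samples at 360 Hz), zero-padded at record edges.  The window
covers every morphological sampling region (the latest, R + 500 ms, is
clipped to the window end) so a single window serves all feature blocks.
RR context is attached per beat: pre-RR, post-RR, and the local average of
the pre-RR intervals of the 10 surrounding beats (shrinking at record
edges; the first/last beat fall back to the interval on their other side).

The TVCG point set takes every 2nd sample by default (`n_v = 127`), which
bounds the O(n_v^2) weight matrix while leaving the trajectory shape
intact; the step is configurable.  Each axis — lead A, lead B, time — is
min-max normalized to [0, 1] per beat before distances are computed.
Without this, the time axis (samples, range ~253) would dominate the
Euclidean weights; normalization also makes the descriptors invariant to
per-lead affine rescaling (amplifier gain/offset).  A constant axis maps to
all zeros.

## Complex-network descriptors

The weight matrix holds all pairwise Euclidean distances divided by their
maximum (all-zero case: zero matrix).  "Removing" elements above the
evolving limit T_l is implemented as *edge* removal with the vertex set
fixed — the standard reading in the complex-network shape-analysis
literature, and the only one under which degree statistics remain
well-defined.  The m thresholds are equally spaced from T_0 to T_Q; m = 1
returns [T_0] (guard for the division by m - 1).

Per threshold, with degree k_i and n_v vertices:

* mean degree = (sum k_i) / n_v^2 and max degree = max k_i / n_v — the
  normalization by n_v keeps both in [0, 1] and comparable across beats
  with different point counts;
* the joint degree distribution J(a, b) is the fraction of edges whose
  endpoint degrees form the unordered pair {a, b}; joint entropy is
  -sum J log2 J (bits, 0 log 0 = 0), joint energy is sum J^2, and the mean
  joint degree is sum J(a,b)(a+b)/2 divided by n_v;
* an empty graph yields all five descriptors = 0.

The exact joint-degree formulas are not pinned down by the upstream
shape-descriptor literature in a single canonical form; the definitions
above are this package's, stated precisely and verified against an
independent explicit-loop oracle in the tests.  Because edge sets nest as
T grows, mean and max degree are non-decreasing in T (property-tested).

The default m = 2 makes the assembled vector 178-dimensional
(148 + 13 + 7 + 10); m = 1 gives the 173-dimensional minimum.

## Reference features

*Morphology (148)*: per lead, 10 amplitudes across the QRS, 9 from QRS end
to the T wave, 10 from R - 50 ms to R + 100 ms and 8 from R + 150 ms to
R + 500 ms, each segment resampled by uniform linear interpolation, in
absolute form and divided by the lead's max-abs amplitude in the window.
The 74-raw + 13-fiducial breakdown of the classical feature set is
reconciled as 74 x 2 (absolute + normalized) + 13 = 161.

*Intervals (13)*: the three RR features; per lead QRS duration, T-wave
duration (QRS offset to T end — the delineation convention here detects the
T end, not the T onset) and P-wave presence; plus four normalized RR ratios
(pre/local, post/local, pre/post, mean(pre, post)/local).  The exact
composition of the classical 13 is not fully recoverable; this 9 + 4
reconstruction is the package's.

*Wavelet (7)*: two-level orthonormal Haar DWT of lead A; per sub-band (D1,
D2, A2) the raw lag-1 autocorrelation sum x(n)x(n-1) and the relative
amplitude min(x)/max(x) (0 when max = 0); plus the variance of the QRS
samples.

Standardization is per-feature z-scoring **fitted on training data only**
and reused verbatim on validation/test (checksum-asserted in tests);
undefined values map to 0 after standardization so the vector length is
stable for the selection mask.

## Classifier and metrics

RBF-kernel C-SVC with C = 1, gamma = 1/n_features, one-against-one
multi-class, per-class penalty C * w_c for (N, S, V); solved by
scikit-learn/libsvm with fixed tolerance and cache so repeated runs are
bit-stable.  Metrics follow the AAMI scheme: per class, Se = TP/row-sum,
+P = TP/column-sum, FPR = FP/negatives; overall accuracy = trace/total.
For a 5-class matrix, fusion beats predicted as V are excluded from V's
false positives and +P denominator (the de Chazal convention); the plain
3-class formulas applied to the shipped benchmark matrix reproduce every
published metric value at one-decimal half-up rounding, which is the
presentation-only rounding rule used throughout.  Zero denominators yield 0
and are flagged rather than raising.

## Swarm optimization

Continuous PSO: velocity v = w(t) v + c1 r1 (pbest - x) + c2 r2 (gbest - x)
with fresh uniform draws per particle component, c1 = c2 = 2.05, inertia
linear from 0.9 to 0.4 (w(1) = 0.9 when the run has a single iteration);
synchronous gbest update after each full swarm evaluation; velocities
clamped to v_max = 0.5 (upper - lower) per dimension and positions clipped
to the box.  Non-finite objective values count as -inf.  All randomness
flows from one seeded generator, so every run is exactly reproducible from
(config, seed).

Stage 1 tunes (m, T_0, T_Q) over m in {1..10} (continuous position, rounded
half-up at evaluation), T_0 in [0.001, 0.2], T_Q in [0.1, 1] — thresholds
live on the normalized weight scale, so these are the only consistent
assignments of the three printed ranges — using TVCG + RR features only and
fixed class weights (6, 100, 15).  A particle proposing T_0 > T_Q is
repaired by swapping and re-clipping.  Stage 2 tunes (w1, w2, w3) in
[1, 5] x [10, 200] x [5, 100] on the full vector.  Stage 3 is binary PSO
(bit resampled with probability sigmoid(v); no inertia by default, which
empirically outperforms the inertial variant — an inertial flag exists),
initial population all-ones with small seeded bit-flip noise on all but one
particle; the all-zero mask is infeasible.  Stage fitness values are cached
by parameter/mask key; the cache only short-circuits identical evaluations
and cannot change results.  The weighted-mean fitness option defaults to
the unweighted mean of the three per-class F-scores.

Because the TVCG weight matrix does not depend on (T_0, T_Q, m), stage 1
precomputes it once per beat and sweeps only the thresholding — the
dominant cost otherwise.

## Synthetic generator

One record = one synthetic "patient": Gaussian-bump beats (P, QRS, T per
lead, truncated at 4 sd so bumps have compact support) at RR intervals
scaled by a per-class prematurity factor, with a compensatory pause after
ectopic beats, sinusoidal baseline wander (0.05 mV at 0.33 Hz), white noise
(0.02 mV sd) and a per-record morphology scaling (~5%) that gives patients
individual signatures.  Defaults: 360 Hz, 0.8 s base RR, ~1 mV QRS;
V beats are wide (150 ms vs 80 ms), P-less and T-inverted; S beats are
premature (factor 0.65).  These are typical clinical magnitudes.

The generator creates class structure along exactly the axes the feature
blocks measure (QRS width, prematurity, P presence, amplitude), so the
synthetic classification task is *much* easier than MIT-BIH: held-out mean
F-scores near 1 demonstrate that the pipeline is wired correctly
(inter-patient guard, standardization leakage, feature assembly), not that
the method attains any particular clinical accuracy.  Real inter-patient
difficulty — morphology drift within a patient, inter-patient morphology
overlap, noise bursts, annotation jitter — is deliberately absent.
Fiducials for generated records come from the generator's own configuration
(a delineator would be redundant there); on real records, fiducials must be
supplied (e.g. from an external delineator) or nominal +/- 50 ms / +300 ms
landmarks are used.

## Numerical choices

* 200/600 ms median windows rounded to the nearest odd sample count;
  shrinking windows at edges (length-preserving).
* The 12-tap low-pass is a Hamming-window FIR whose cutoff is bisected so
  the realized response is -3 dB at 35 Hz to machine precision; with 12
  taps the group delay is 5.5 samples and is compensated by a 5-sample
  forward shift (half-sample residual, well below any beat-level feature
  resolution).  The 1 Hz high-pass is the spectral complement of a 1.5 s
  linear-phase low-pass tuned the same way, because no 12-tap FIR can
  realize a 1 Hz corner at 360 Hz.
* Rounding is half-up, applied only at presentation (one decimal for
  percentages).
* Degenerate rules: zero-distance point sets give zero weight matrices;
  empty graphs give zero descriptors; constant axes map to zeros; zero
  metric denominators give 0 with a flag.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use desk-scale problem sizes
chosen to exercise every code path with comfortable margins: 200 random
point sets (n_v <= 12) for the descriptor oracle, 1000 random weight
matrices for the nesting property, a 30-particle/100-iteration 5-D sphere
for PSO, the 20-feature planted toy (40 particles, 60 iterations, 10
seeds) for BPSO, and a 6-patient/~600-beat synthetic corpus for the
end-to-end run.  The published MIT-BIH campaign (100-300 particles,
50-100 generations over tens of thousands of beats) is reproducible with
the same entry points given the database and compute.

## Known limitations

* The joint-degree descriptor formulas and the 13-interval composition are
  package-defined reconstructions (stated above), not recovered from the
  upstream sources.
* The morphology normalization (per-lead max-abs) is one reasonable
  reading of "normalized amplitudes"; others exist.
* WFDB input requires the optional `wfdb` dependency; the CSV dialect is
  the self-contained path.
* The synthetic generator does not model paced beats, fusion morphology
  gradations, or episode dynamics; F and Q classes default to plausible
  but untuned parameters.
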