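# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of `ecgverify`. It states no result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Signal model and synthetic cohorts

Each synthetic subject is a beat template: five Gaussian bumps (P, Q, R, S,
T) with per-wave amplitude (mV), latency relative to R (ms) and width (ms)
drawn once per subject from priors bracketing textbook adult lead-I
morphology. R is fixed at latency 0 and always dominates the other waves in
amplitude, so the template satisfies the fiducial ordering P < Q < R < S < T.
Mean heart rate is uniform on 1.0–1.5 beats/s, the physiological band for a
resting adult. A U wave is deliberately omitted: it contributes nothing to
R-centred verification features here.

A record lays beats along a lognormal inter-beat-interval process with a
per-subject coefficient of variation (prior 0.03–0.08), clipped to
[0.55, 1.8] × the mean interval so beats never overlap. Per-beat
variability is a single multiplicative amplitude factor (s.d. 0.03–0.07)
plus 2 ms s.d. latency jitter on the non-R waves. Abnormal beats —
deterministically round(a·B) of B beats, chosen uniformly — get a
perturbation far outside normal jitter: inverted T, dropped P with halved
T, a deep widened S, or a global 1.7× amplitude surge. The ground-truth R
index of every beat is the sample at which the rendered noise-free signal
attains its beat-local maximum (sub-sample beat centres and neighbouring
wave tails can shift the sampled peak by one sample, so the index is
refined on the clean signal).

Additive contaminants follow the standard single-lead noise taxonomy, with
default amplitudes chosen once as plausible for a reasonably clean
fingertip acquisition against an R wave of roughly 1 mV:

| term | default | rationale |
| --- | --- | --- |
| baseline wander | 0.22 Hz sinusoid, 0.05 mV | respiration band 0.15–0.30 Hz |
| powerline | 60 Hz, 0.02 mV | mains interference (50 Hz selectable) |
| electrode movement | 1–10 Hz band noise, 0.02 mV RMS | motion artefact |
| broadband | 0.02 mV s.d. | sensor/EMG floor |

What the generator does **not** emulate: heart-rate drift and autonomic
variability structure (the IBI process is i.i.d.), morphology drift within
a session, pathological rhythms, electrode pop artefacts, or inter-lead
differences. Passing tests on this data show the pipeline's mechanics and
its comparative trends; they do not certify error rates on clinical
recordings, whose nuisance structure is richer.

Records are exchanged as plain CSV (`# fs=<Hz>` header, one `mV` sample
per row) with a truth sidecar (`sample_index,is_abnormal`); beat matrices
as one-beat-per-row CSV with a label sidecar.

## Preprocessing

The band-pass is a 4th-order Butterworth, 0.5–40 Hz. It is applied
forward-backward (zero phase) by default because the pipeline is offline
and zero-phase filtering leaves R-peak latency untouched; a causal mode
exists for streaming-like use.

R peaks come from the Pan-Tompkins stages: an internal 5–15 Hz band-pass,
five-point derivative, squaring, 150 ms moving-window integration (group
delays compensated so integrated peaks align with the QRS), peak
candidates at a 200 ms refractory distance, adaptive signal/noise
thresholds (0.125 update rate, threshold = noise + 0.25·(signal − noise))
with search-back at 1.66× the running RR average. Each accepted peak is
refined to the local maximum of the filtered signal within ±50 ms — the
original method leaves this unspecified; refinement makes the detected
index coincide with the R sample on clean signals. A constant record short-
circuits to "no detections". Stage parameters live in `PanTompkinsParams`.

Beats are the half-open windows [r − fs/2, r + fs/2): exactly k = fs
samples (k = 200 at 200 Hz), R at position k/2; windows crossing a record
boundary are dropped and counted. No amplitude normalisation is applied —
raw filtered millivolts are the features.

## One-class GMM outlier removal

Normal beats are modelled by an M-component Gaussian mixture (M = 2
default), fitted by EM with the standard responsibility-weighted updates
(weights, means, covariances). Covariances are diagonal by default: at
k = 200 with a few hundred training beats a full covariance is singular;
full covariance with a ridge of 1e−6 × mean diagonal is available.
Initialisation is kmeans++-seeded means, uniform weights, pooled variance;
a variance floor of 1e−6 × the mean pooled variance guards collapsing
components. Termination: relative log-likelihood gain < 1e−6 or 200
iterations, with the per-iteration trace stored on the model.

A beat is abnormal iff its negative log-likelihood under the mixture
exceeds a threshold set at a percentile (default 0.95) of the training
pool's own scores. The percentile form keeps the rule subject-invariant,
and each decision depends only on the fitted model and the beat, so the
rule is usable online. The training pool is built from generator-truth
normal beats — the synthetic stand-in for manual morphology labelling.

## Gaussianity analysis

Shapiro-Wilk is implemented from the AS R94 approximation (Blom-score
weights with the two polynomial-corrected extreme weights; normalising
log-transforms for the p-value, with the separate 3 ≤ n ≤ 11 branch). The
test suite cross-checks it against an independent implementation of the
same algorithm to 1e−6.

Royston's multivariate statistic transforms each variable's W through
R_j = [Φ⁻¹(½ Φ(−z_j))]², z_j = (log(1 − W_j) − m)/s, with m and s the
published polynomials in log n (valid 12 ≤ n ≤ 2000; in this range the
power-transform exponent of the general form is zero, i.e. the transform
acts on log(1 − W)). The aggregate H = e · ΣR_j / p uses the equivalent
degrees of freedom e = p / (1 + (p − 1)·C), where C averages the
off-diagonal terms ρ⁵·(1 − u(1 − ρ)^u / v), u = 0.715, v a polynomial in
log n, over the sample correlations ρ — the published correction that
discounts correlated variables. Under multivariate normality H ≈ χ²(e);
p = 1 collapses exactly to the univariate transform with e = 1.

Sequential forward selection finds a maximal jointly-normal variable set:
Stage 1 discards variables failing Shapiro-Wilk at α (default 0.05);
Stage 2 greedily adds the candidate maximising the Royston p-value of the
enlarged subset (ties to the lowest index, so runs are deterministic),
stopping when no candidate keeps the subset p-value ≥ α or `max_vars` is
reached. Because R_j and the pairwise correlation terms depend only on
single variables and pairs, they are precomputed once; each subset
evaluation is O(p²). The candidate-ranking and stopping rules are this
package's reconstruction of the procedure from its prose description; the
original algorithm listing is not public in usable form. Whether to pool
beats across subjects is left to the caller — the API takes one matrix.

## Heartbeat synthesis

Genuine beats X (n × k) give μ = column means and Σ = the (n−1)-denominator
sample covariance, optionally ridged by `shrinkage` × mean diagonal.
Synthesis draws x = μ + V·√Λ·z with z i.i.d. standard normal and (V, Λ)
the eigendecomposition of Σ. This needs no inversion and is exact for
rank-deficient Σ — the operative case, since the 20-beat baseline yields
rank ≤ 19 in 200 dimensions. Eigenvalues below 1e−10 × the largest are
treated as exact zeros so draws lie strictly in the data's affine span
rather than acquiring numerical-noise components. Shrinkage defaults to 0:
synthetic beats then live in the span of the observed beats, which is the
honest expression of what n = 20 observations support. Synthesized beats
are appended to the genuine class as-is (not re-filtered by the outlier
rule); a caller wanting filtering can apply `classify_beats` explicitly.

`sample_heartbeats` accepts either an integer seed or a numpy Generator;
with a Generator, consecutive calls continue one stream, so a draw of
a + b beats equals a draw of a followed by a draw of b.

## Verification

The base classifier is bagging over B = 50 full-depth Gini decision trees
(unlimited depth, minimum leaf 1, no feature subsampling — the "simple
decision tree" configuration), each tree fit on an n-with-replacement
bootstrap. A probe's confidence is the fraction of trees voting genuine.
The trees are implemented in-package as an exact weighted best-split CART
over presorted features (bootstrap multiplicities become integer sample
weights, so the per-fit argsort is shared by all B trees), with
deterministic tie-breaking (lowest feature index, then lowest threshold);
the test suite pins it against a plain recursive reference CART and
against an established library implementation. This exists because the
experiment designs below need thousands of ensemble fits at n ≈ 500,
k = 200 within practical runtimes.

The parallel ensemble trains L such baggers on identical genuine data and
independently drawn (uniform, without replacement) imposter subsets, and
averages member confidences. Member draws being independent rather than
disjoint is a deliberate reading of "a different imposter set per member";
disjointness is neither necessary for the variance argument nor possible
for large L × subset size.

Metrics: FAR = nFP/I, FRR = 1 − nTP/G, TRR = 1 − FAR, TAR = 1 − FRR, with
acceptance iff confidence ≥ threshold. Because FAR − FRR is monotone
non-increasing in the threshold, its zero crossing is unique; the EER is
the common value of the two curves linearly interpolated between the
bracketing operating points (on a plateau of exact zeros, the lowest such
threshold is reported). This interpolated form is invariant to monotone
score transforms and immune to floating-point ties between equal rational
gaps. TAR/TRR are additionally reported at the fixed 0.5 operating
threshold.

## Benchmark protocol and experiment designs

A benchmark cohort is 30 subjects × 60 s at 200 Hz under the default noise
profile with 10% abnormal beats. Every record is filtered, peak-detected,
segmented; one GMM (M = 2) is fitted on truth-normal beats pooled across
subjects and applied to all detected beats at the 0.95 percentile rule.
Per subject: the first 20 surviving beats train, the next ≤ 40 are genuine
test probes. For each subject the other 29 subjects are split at random
into an imposter-training half and an imposter-test half; training
imposters are drawn from the former, 100 test probes from the latter, so
training and test imposters never share a subject. Pooled EER concatenates
scores across subjects; per-subject TAR/TRR at 0.5 feed the stability
analysis. The split and test draws are seeded per master seed, so grid
cells within a seed are paired and differ only in training draws.

* **Grid** (synthesis × imbalance): synthesis counts {0, 50, 100, 200,
  400} × imposter counts {20, 40, 60, 80, 100, 150, 200, 250}, 20 real
  genuine beats, L = 1, B = 50, over 10 master seeds.
* **Stability**: at 200 synthesized beats and 100 imposters per member,
  each subject's ensemble is retrained for 3 independent imposter
  re-draws; the per-subject standard deviation of TAR/TRR at 0.5 is
  averaged over subjects for L ∈ {1, 5, 10, 20}. The max(L) members are
  trained once per re-draw and an L-ensemble is scored as the mean of the
  first L members — members are i.i.d., so nested prefixes are valid
  ensembles and the grid costs max(L), not ΣL, fits.
* **Redundancy**: (L = 50, B = 1) vs (L = 1, B = 50) on identical data and
  seeds at the best grid cell (200 synthesized, 200 imposters).

These sizes (30 subjects, 60 s records, ≤ 40 genuine / 100 imposter test
probes per subject, 3 re-draws, 10 seeds) are the package's desk-scale
benchmark; they are large enough for the comparative trends to be stable
across seeds while keeping a full run in minutes.

On this benchmark the synthesis and imbalance trends and the stability
trend behave as the method predicts (see `tests/test_acceptance.py` and
the acceptance script's output). The redundancy contrast does **not**
reproduce the expectation that dropping bagging while keeping 50 parallel
members is clearly worse: with only 29 imposter subjects, the 50 members'
independent imposter draws overlap heavily yet still differ more from one
another than bootstrap resamples of a single pool do, so the no-bagging
parallel arm matches or slightly beats single-member bagging here. The
corresponding acceptance test is left failing rather than weakened: the
effect it encodes plausibly requires an imposter population orders of
magnitude more heterogeneous (the original observation came from a
1000+-subject pool) than a desk-scale synthetic cohort provides.

## Determinism

Every stochastic step is seeded. Experiments fan a single master seed out
through hash chains (`numpy SeedSequence`) into per-subject, per-cell and
per-member seeds; any logged cell seed re-runs that cell in isolation with
identical output, and rerunning an experiment command with the same config
and master seed reproduces result CSVs byte for byte.

## Known limitations

* The Royston m, s, u, v polynomials are used for 12 ≤ n ≤ 2000; larger
  samples are rejected rather than extrapolated.
* Diagonal-covariance EM cannot represent within-component sample-to-sample
  correlation of beats; for outlier scoring this costs little, but the
  mixture is not a generative beat model (synthesis uses the full-covariance
  single Gaussian instead).
* WFDB-format I/O is not provided; records travel as CSV.
* The verifier's trees split on raw sample amplitudes; no fiducial
  features, wavelets or learned embeddings are offered beyond the PCA
  comparator.
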