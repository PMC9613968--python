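# Methods

## Scope and data model

A *trial* is a frames × p matrix of joint angles in degrees at a fixed
sampling rate (default 60 Hz), with channels labelled
`<joint>_<side>_<plane>` over hip/knee/ankle × L/R ×
sagittal/frontal/transverse (p = 18 for a full lower-limb trial; any p ≥ 1
is accepted). Gait events are an input, not something the package detects: a
*foot-contact series* lists initial-contact frame indices for one foot, and
a stride is the half-open interval `[IC_i, IC_{i+1})` on the same foot —
single-foot, non-overlapping, which keeps N equal to the number of gait
cycles. Strides shorter than 0.4 s (configurable) are treated as spurious
double contacts and dropped with a warning. Each stride is linearly
resampled onto a 101-point phase grid (0–100% of the cycle, endpoints
included and preserved exactly); normalization is idempotent. Angles are
used as-is — no filtering or detrending — so whatever smoothing the
recording system applied is the only smoothing there is.

## Dimensionality (N95%)

PCA is performed on the covariance of the mean-centered frame-level matrix
(divisor n−1), not the correlation matrix: all channels share units, and
standardizing would erase exactly the absolute-variance information the
variability measures need. Eigenvalues come from `eigh` of the p × p
covariance (identical to an SVD route, cheaper at p = 18) and are clipped
at zero against round-off. N95% is the smallest k whose cumulative percent
variance reaches 95% (comparison is ≥, with a 1e−9 percent tolerance so a
cumulative sum that lands on 100 − ε at the last component cannot miss).
Per-trial N95% is the default; a pooled-frames spectrum per activity is
also provided. Across trials the summary is mean ± sample SD (SD defined
as 0 for a single trial).

A deliberately tested property: because the threshold is *relative*, a
dataset can need fewer components than another while carrying more absolute
variance in every trailing component. The test suite constructs exactly
this pair (one dominant direction over a high uniform floor vs an isotropic
cloud), which is the core argument for reporting absolute variance
alongside percent variance.

## Variability

**Generalized variance** is `det` of the sample covariance, computed
through its eigenvalues: `log GV = Σ log λ_i` is the primary numerical
form, since an 18-channel covariance in degrees² routinely under- or
overflows the determinant in double precision; `GV = exp(log GV)` and
`GV^(1/p)` (geometric-mean variance) are derived from it. If the smallest
eigenvalue is below 1e−10 of the largest the covariance is flagged rank
deficient and GV is reported as 0 (log GV = −∞) rather than a
meaningless tiny determinant. GV is computed on raw trial frames, not on
time-normalized cycles.

**GaitSD** operates on the N × 101 × p normalized cycle tensor:
`GVSD²_k = Σ_j Σ_i (X_ij − X̄_j)² / (T(N−1))` per joint. Two combiners are
exposed because the source formula is typographically ambiguous about
whether the per-joint values are averaged before or after the square root:
the default `mean_of_sd` takes `(1/p) Σ_k √(GVSD²_k)`; the alternative
`sqrt_of_mean` takes `√((1/p) Σ_k GVSD²_k)`. Under homogeneous noise both
converge to the noise SD; under heterogeneous per-joint noise they diverge
(mean of SDs < RMS of SDs), and that divergence is itself tested.

## Nonlinear dynamics

All estimators are deterministic functions of input and settings; there is
no hidden randomness anywhere in the chain.

**AMI delay.** Mutual information between x(t) and x(t+τ) is estimated
with an equal-width 2-D histogram, B = max(16, ⌈n^{1/3}⌉) bins spanning the
series range. The selected delay is the first *windowed* local minimum:
the first lag that is lowest within ±3 lags. A strict three-point rule is
unusable in practice — on a noiseless sinusoid the histogram estimate
plateaus near the quarter-period minimum and wiggles at the bin-resolution
floor, so the three-point rule locks onto jitter several lags early; the
windowed rule recovers the analytic quarter-period minimum. A curve whose
range over lags ≥ 1 is below 5% of AMI(0) (white noise) is treated as
featureless: the argmin over lags ≥ 1 is used and flagged as a fallback.

**Embedding dimension (GFNN).** Kennel's two criteria with R_tol = 15,
A_tol = 2 and attractor size = SD of the series; the selected dimension is
the first with a false-neighbor fraction below 10%. Neighbors within a
Theiler window (default: the delay) are excluded so densely sampled flows
do not pick trivially correlated neighbors, and near-zero neighbor
distances (exact periodic repeats) are clamped at 1e−9 of the attractor
size before the ratio test. If the fraction never drops below threshold
(noise), the maximum dimension is reported with a saturation flag rather
than silently truncated. One measured caveat: for long, clean Lorenz data
the dim-2 false-neighbor fraction is genuinely ~5–8%, already under the
10% cut, so threshold-based selection can return 2 for a system usually
embedded in 3 — the threshold, not the estimator, decides.

**Largest Lyapunov exponent (Rosenstein).** For each embedded point the
nearest neighbor outside a Theiler window of one mean period (estimated
from the dominant spectral peak) is tracked forward; the divergence curve
is the mean of ln d over pairs with d > 0, and the exponent is the
least-squares slope over the fit window times the sampling rate (units:
per second, or per time unit when fs encodes integration step). The
default fit window, steps 0 to half a mean period, suits map-like and
gait-like signals. Densely sampled flows need care: the Lorenz divergence
curve has a non-exponential transient of roughly 0.8 time units before the
exponential regime, so the Lorenz validation fits steps 100–300 (1–3 time
units), giving 0.94 vs 0.907 from an independent Benettin two-trajectory
oracle (3.6%). The fit region is a per-analysis choice and is always
recorded in the result.

**Sample entropy.** SampEn = −ln(A/B) with Chebyshev matching, template
counts over the first n−m start points for both lengths and self-matches
excluded. Pair counting uses a k-d tree (`count_neighbors` at p = ∞),
which is exact, and is verified against an O(n²) direct pair count.
When A or B is zero the result is NaN with a defined-flag — never a silent
infinity.

**CMSE / Complexity Index.** At scale τ the series is coarse-grained by
non-overlapping means at each of the τ offsets; SampEn is averaged over
offsets where it is defined, with the tolerance fixed at 0.2 × SD of the
*raw* series for all scales (a single r across scales is what makes the
profile comparable across τ). CI sums scales 1..20; any undefined scale
makes CI undefined and flagged. Scale 1 reduces to plain SampEn exactly.

**Per-joint pipeline.** The full chain — AMI → GFNN → embed →
LyE, plus CMSE on the raw series — runs on sagittal-plane hip/knee/ankle
channels by default, per trial, with a 500-sample minimum guard.

## Synthetic data

The gait generator emulates the statistical structure the analysis
assumes, not biomechanics. Each of r latent waveforms is a 2–4 harmonic
Fourier curve of cycle phase (the first three shaped loosely like sagittal
hip/knee/ankle angle curves, higher ones distinct single harmonics so the
set is linearly independent), rescaled to a phase-SD of 14 × 0.95^m
degrees so every latent keeps a non-negligible variance share. A p × r
loading matrix with orthonormal columns maps latents to joints, and the
*mean waveform is built inside the span of that loading*, so the
frame-level covariance has exact latent rank r plus an isotropic sensor
noise floor — this is what makes N95% = r recovery well-posed. Per-stride
latent deviations (SD `cycle_noise_sd`, iid or AR(1)-smooth across
strides) enter through the same loadings under a sin²(π·phase) envelope,
which keeps stride boundaries continuous so concatenation injects no
discontinuity spikes into the entropy estimators. Stride durations carry
Gaussian jitter (`stride_duration_cv`) and optionally a chaotic
modulation: duration_i = mean × (1 + depth × (2z_i − 1)) with z_i iterates
of the r = 4 logistic map. At rank 0 the generator emits a fixed
three-template periodic trial with no stochastic part, so a non-constant
signal still reaches the nonlinear estimators. Foot contacts mark stride
starts plus the final boundary, and the ground-truth record (rank, stride
frames, noise SDs, chaos depth) is sufficient to score every downstream
measure.

What the generator does *not* emulate: soft-tissue artifact, sensor drift,
asymmetry, turns, non-stationary activity switches, inter-subject
differences. Passing tests therefore show the estimators recover known
structure under the stated noise model — not that any specific real
activity will behave this way.

Benchmarks: sine; iid Gaussian; pink noise by 1/√f spectral shaping of
white noise (normalized to unit SD); the r = 4 logistic map (transient a
parameter, default 0, so seeded sequences are exactly reproducible from
x₀); Lorenz (σ = 10, ρ = 28, β = 8/3) integrated with RK45 at rtol = atol
= 1e−9 on a fixed dt = 0.01 output grid, 20 time units of transient
discarded, x component returned.

The two-cloud toy generator samples 2-D Gaussians with configurable means
and SPD covariances, reproducing both dissociations: equal dimensionality
with 16-fold GV difference, and equal minor-axis variance with different
N95%.

## Activity suite and ranking

The designed suite has four activities, two trials each, 60 strides per
trial (~4,000 frames at 60 Hz — small enough that the whole pipeline runs
in well under a minute, large enough for stable estimates): a walking
analog (r = 2, low amplitude and noise), a high-dimensional activity
(r = 8), a high-variance activity (doubled amplitude, lifted 2° noise
floor — high variance in *all* directions is what drives det(Σ)), and an
irregular activity (chaotic stride timing, depth 0.25, plus 3° cycle
noise). Measures are aggregated per trial → activity (mean ± SD), ranked
with "larger value = more complex, rank 1 = most complex" (ties get mean
ranks), and cross-measure agreement is summarized with tie-corrected
Kendall's W — the quantitative twin of an otherwise visual comparison of
rank tables.

The designed outcome, asserted in tests: N95% crowns the high-dimensional
activity, generalized variance the high-variance one, CI the irregular
one; W < 1; and the walking analog is ranked simplest by all three
simultaneously. The LyE *global* winner is deliberately not asserted:
Rosenstein slopes are inflated on broadband quasi-periodic signals (the
high-rank activity), an artifact consistent with the measure's known
sensitivity — LyE's chaos-sensitivity is instead asserted as a paired
comparison, chaotic stride timing vs the matched periodic generator at
fixed seeds. This is also why the package reports LyE with its fit window
and flags rather than as a standalone scalar.

## Numerical and degenerate-input conventions

- Constant series: AMI and CMSE raise (zero entropy / zero tolerance);
  SampEn of a constant with explicit r > 0 is 0.
- Rank-deficient covariance: GV = 0 + flag; other measures proceed.
- Undefined entropies propagate as flagged NaN, never ±∞, and undefined
  offsets are excluded from CMSE offset means.
- Trial CSVs are written with `%.17g` and read with round-trip float
  parsing, so save/load is bitwise exact.
- Failed trials inside an activity are recorded with their error and do
  not abort the remaining trials; serialized reports are byte-identical
  across reruns with the same seeds and config.
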