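# Methods

`trajspace` analyzes epoched multichannel neural recordings (trials ×
sensors × samples) as trajectories through a low-dimensional state space,
and ships a synthetic-data generator that reproduces the statistical
structure those analyses assume. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
study does and does not establish about real data.

## State-space model

For each subject, sensor time series are concatenated across trials and
the sensor-by-sensor Pearson correlation matrix is eigendecomposed. The
leading eigenvectors (principal components, PCs) define the state space;
sensor signals are standardized with the fit-scope statistics before
projection, consistent with a correlation-matrix decomposition (a raw
covariance decomposition is available as an option). The default
dimensionality is k = 5 components; `choose_k` instead selects the
smallest k whose cumulative explained variance exceeds a threshold
(default 0.7).

On the k-dimensional trajectories x(t) the package computes:

- **distance** between two trajectories, d(t) = ‖a(t) − b(t)‖;
- **velocity**, v(t) = ‖x(t + Δt) − x(t)‖ / Δt with Δt = 1/fs (600 Hz →
  1.67 ms), either of the trial-averaged trajectory or averaged over
  per-trial velocities (the latter is systematically larger because
  trial noise inflates single-trial path length);
- **state-space volume**, the product over components of the across-trial
  standard deviation, reported as % change from the pre-stimulus baseline
  mean (baseline fixed at [−1.0, −0.25) s);
- **norm/angle decomposition**: the norm ‖x‖ (total signal energy) and
  the angle α = arccos(a·b / ‖a‖‖b‖) between state vectors (relative
  spatial pattern). Across-trial angle dispersion is the mean pairwise
  angle over all C(n,2) unordered trial pairs (O(n²), acceptable at a few
  hundred trials); norm dispersion is the s.d. of the norm across trials.

Component sign is fixed by making each loading column's
largest-magnitude coefficient positive. Across-subject alignment greedily
matches component topographies by maximal absolute correlation in
reference-component order, flipping signs for negative matches and
breaking exact ties toward the lower original index.

## Band extraction on epochs

`filter_epochs` implements zero-phase (forward–backward) fourth-order
Butterworth band-passes with reflect padding and IIR notches (Q = 35) at
line frequencies inside the band. Edge transients make roughly the first
and last 250 ms of an epoch unreliable; analyses that search for extrema
restrict themselves to the epoch interior.

The slow-cortical (SCP) band is nominally 0.05–5 Hz. A 0.05 Hz high-pass
edge has a 20 s period and is not identifiable on a 4 s epoch: applied
epoch-wise it removes each trial's quasi-DC state — precisely the signal
carrying trial-to-trial initial conditions — and couples pre- and
post-stimulus segments through the epoch mean, distorting across-trial
variability. Such sub-epoch edges belong to continuous-recording
preprocessing, which is outside this pipeline (it ingests epochs). The
pipeline therefore extracts the SCP band with a pure 5 Hz low-pass
(`BandSpec(low_hz=None)`); band-limited bands (5–15, 15–30, 30–60,
60–150 Hz) use the ordinary band-pass. Decoding runs on data resampled to
10 Hz (polyphase, anti-aliased; 40 time points per 4 s epoch).

## Decoding

A linear SVM (libsvm via scikit-learn, C = 2⁻⁶) is trained independently
at each time point under five-fold interleaved cross-validation (trial i
→ fold i mod 5). Features are z-scored per time point with training-fold
statistics, which makes the small fixed C meaningful regardless of the
data's physical scale. Training folds are class-balanced by subsampling
the majority class, repeated 10 times with accuracies averaged; test
folds are never subsampled, and the headline metric is balanced accuracy
(mean of per-class accuracies) so imbalanced test sets cannot inflate
scores — the raw fraction correct is recorded alongside. Temporal
generalization trains at each time point and tests at all others under
the same folds. Activation patterns are the Haufe transform: training-set
covariance times decoder weights.

The nearest-template classifier mirrors the norm/angle question: with an
odd–even split, per-class mean vectors are computed from the training
half and each test trial is assigned by the smaller angle to (or smaller
absolute norm difference from) the class mean. Classes that differ only
in direction are decodable from angle but not norm, and vice versa.

## Inference

Time-resolved tests are corrected with cluster-based permutation:
clusters are maximal runs of contiguous time points with pointwise
p < 0.05 (signed statistics additionally require a constant sign), the
cluster mass is the summed statistic, and significance compares the mass
to the 95th (one-tailed) or 97.5th (two-tailed) percentile of the
permutation distribution of maximal cluster masses. Permutation p-values
use (1 + #{null ≥ observed}) / (1 + n_perm), so p is never exactly zero.

Statistics are vectorized over time: the 2×2 repeated-measures ANOVA uses
the 1-df contrast identity (F equals the squared paired t on per-subject
contrast scores; error term = effect × subject), and the one-sample
Wilcoxon signed-rank uses an exact dynamic-programming null for n ≤ 25.

Permutation schemes:

- *condition/cell labels within subject* — for the velocity ANOVA, the
  four cell labels are permuted independently per subject (this exchanges
  exactly what the null hypothesis asserts exchangeable);
- *post-stimulus vs baseline* — per-subject **circular time shifts**. A
  full shuffle of time labels is anticonservative for smooth
  (autocorrelated) time courses because the shuffled null destroys the
  long runs that smoothness alone produces; circular shifts preserve each
  series' autocorrelation while destroying time-locking. The iid shuffle
  remains available and is appropriate for exchangeable points.

Supporting tests: exact binomial proportion test (per-subject decoding vs
chance), Benjamini–Hochberg FDR (statsmodels), Fisher's nonparametric
common-median test for circular samples (the angle-variability
comparison; points exactly at the combined median count with the lower
side), and Cousineau–Morey within-subject s.e.m. (subject-mean
normalization, √(M/(M−1)) correction for M conditions).

## Pre-stimulus similarity → response bias (SDT)

For unseen trials only: per-orientation evoked templates are each
sensor's mean over the post-stimulus window [0, w); each trial's mean
pre-stimulus map over [−w, 0) is spatially correlated with both templates
(within the sensor region under test), and trials are split by the larger
correlation (exact ties to "left", logged). Response bias per group uses
the classic equal-variance SDT estimators with "left" as the signal
class: H = P(respond left | left), FA = P(respond left | right),
d′ = z(H) − z(FA), c = −(z(H) + z(FA))/2; a negative c is a liberal bias
toward "left". Rates of 0 or 1 are corrected with the log-linear rule
(+0.5 per cell, +1 per denominator). Group inference is a paired
two-tailed t-test on c (left-like vs right-like group) per
(window × region) cell, BH-FDR corrected across all cells. Window
lengths default to 100–500 ms and regions to all + five lobes, mapped
from the CTF sensor-name convention (third character: F/C/P/O/T).

## Synthetic study

The generator's defaults are the study conditions: 4 subjects × 300
trials, 273 sensors at 600 Hz, epochs [−1, 3) s, seen-rate 0.489,
accuracy 0.968 (seen) / 0.62 (unseen), response criterion −0.58 (liberal
toward "left"), five latent dimensions.

**Latent geometry.** Each trial's state is a k = 5 dimensional vector
x(t) = r(t)·u(t): the norm r is anchored to a stationary reference
ensemble and carries no condition information; the direction u carries
all of it — encoding the working hypothesis that awareness lives in the
relative activity pattern (angle), not total energy (norm). Trial
deviations are
a slow "state" process (band-limited 0.15–0.8 Hz, σ = 1 per dimension;
slow enough to act as an initial condition, fast enough to survive
epoch-wise filtering) plus within-trial wander (< 4 Hz, σ = 0.4).

**Initial-state dependence.** Whether a trial is seen is *selected* by
its own pre-stimulus state: a probit on the standardized mean
pre-stimulus projection z onto a dedicated latent axis,
P(seen | z) = Φ(az + b), with (a, b) solved in closed form so the
marginal seen-rate equals `p_seen` and the seen−unseen separation of z
equals `initial_offset` (default 0.8 s.d.). This is the only mechanism
compatible with any epoch-wise high-pass or demeaning — an injected
DC offset per condition would be filtered out — and it makes
`initial_offset = 0` exactly the "perception independent of initial
state" null.

**Transient.** After onset the whole state cloud rotates in a fixed
latent plane with angular speed proportional to a gamma density (shape 3)
peaking at `transient_peak_s` = 0.4 s; the total rotation is
`transient_gain_seen` = 3.0 rad for seen vs 0.35 rad for unseen trials
(drastic vs minimal acceleration). The rotation plane spans two latent
axes with equal sensor gain, making the rotation an exact isometry of the
metric the analyses observe: it moves the mean trajectory (velocity,
distance, decodability) without touching norms, angles between trials, or
the across-trial s.d. product. A small orientation-specific evoked bump
(gain 0.4 s.d., peaking at 150 ms) provides the stimulus information that
supports above-chance unseen discrimination and the evoked templates.

**Variability contraction.** In seen trials each trial's angular
deviation about the condition mean is shrunk after onset by a smooth
envelope peaking at 0.7 s; norms are reassigned from the stationary
reference, so the contraction is direction-only. The inner contraction
factor is calibrated once per configuration by deterministic Monte-Carlo
bisection so that the realized per-dimension across-trial s.d. ratio at
the envelope peak equals `contraction` (default 0.88; volume ratio
0.88⁵ ≈ 0.53). Note one realistic confound: because awareness is selected
by the pre-stimulus state, the seen group's baseline variability along
the state axis is itself slightly narrowed, which deepens the apparent
volume reduction by a few points relative to the closed form.

**Sensors.** Latents mix into sensors through a fixed random orthonormal
matrix (reproducible per `mixing_seed`) with per-dimension gains decaying
geometrically from 1.5 to 0.65 (distinct eigenvalues → a realistically
decaying PC spectrum and stable component identity; the two
rotation-plane axes share their geometric-mean gain). Sensor noise is
1/f (exponent 1, band-limited below 150 Hz as by an acquisition
anti-alias filter) plus narrowband alpha (8–12 Hz) and beta (17–25 Hz)
processes with random spectral phases per trial and sensor (no
phase-locking; Rayleigh-distributed envelopes arise naturally); seen
trials quench alpha power after onset by 30%. The signal scale is set so
the top five PCs of SCP-filtered data explain ≈ 70% of variance, the
regime the analyses assume. Arrays are float32 by default (a full
subject is ~0.8 GB); reductions accumulate in float64.

**Behavior.** Seen trials are correct with probability 0.968. Unseen
responses threshold a Gaussian decision variable: ±d′/2 by true
orientation (d′ solved so the marginal accuracy is 0.62 given the
criterion), the innate criterion −0.58, plus `prestim_coupling` (default
0.4) times the trial's standardized pre-stimulus projection on the
orientation axis — so trials whose pre-stimulus pattern resembles the
"left" template answer "left" more often, the effect the
template-similarity analysis recovers (its sign convention: Δc =
c(left-like group) − c(right-like group) < 0 under positive coupling).

**What the synthetic study does not show.** The generator has no sensor
geometry or forward model, no eye/cardiac artifacts, no spatially
correlated noise, no session drift, and its latent dynamics are exactly
the structures the analyses look for. Passing end-to-end tests therefore
demonstrates that the pipeline recovers known structure at realistic
signal-to-noise and trial counts and stays calibrated under nulls — not
that real recordings contain such structure.

## Problem sizes and determinism

All randomness flows from explicit seeds (numpy `SeedSequence` spawning
per subject); reruns with the same configuration and seed reproduce every
numeric output bit-exactly. The test-suite and acceptance runs use
desk-scale sizes chosen to keep the full suite in the tens of minutes:
the end-to-end study runs 4 subjects × 300 trials at the full 273 × 600 Hz
resolution with 200 permutations per cluster test (the reference analyses
used 1000); family-wise-error calibration uses 200 null simulations of 10
subjects × 40 time points; the pre-stimulus coupling recovery uses 50
single-subject runs (120 sensors, [−0.6, 0.6) s epochs) and the null-FDR
check 12 runs of 4 subjects × 200 trials. Cluster p-value resolution at
200 permutations is 1/201 ≈ 0.005.

## Known limitations

- The pipeline ingests epochs only; continuous-recording preprocessing
  (true 0.05 Hz high-pass, ICA artifact removal) is out of scope, and the
  epoch-wise band extraction deliberately omits sub-epoch high-pass edges.
- The angle-dispersion time course is O(n² k) per time point.
- The temporal-generalization implementation re-standardizes per
  train/test time pair from training-fold statistics; with very few
  trials per fold those statistics are noisy.
- `EpochedRecording` supports multi-session metadata but no
  session-aware statistics beyond what the metadata grouping provides.
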