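# Methods

This note documents the models, estimators and numerical choices behind
`ieegdyn`, and what the synthetic generator does and does not emulate.

## Synthetic task sessions (`synthgen`)

### Behavior

Each trial carries a cue with stop probability 0, 0.25 or 0.75. The
participant starts the trial self-paced (press 1.5–2.0 s after the cue,
plus 0–0.5 s slot jitter so trial onsets never lock to ongoing rhythms);
the target reaches the hit lower limit (HLL) uniformly 560–580 ms after
the press and the upper boundary 740–760 ms after it. Go-trial releases
come from a single-accumulator linear-ballistic race:

    distance = threshold − start_offset(context) − U(0, start_jitter)
    drift ~ Normal(drift_mean, 0.5), truncated positive
    release = press + non_decision + distance / drift

Defaults: threshold 1.0, start jitter 0.12, drift mean 4.0 (SD fixed at
0.5), non-decision 0.51 s, start offsets {0%: 0.50, 25%: 0.36, 75%: 0.22}.
Larger offsets encode prior evidence: the fully predictive context starts
closer to threshold, giving faster, less variable, more accurate
responses; because the race distance scales both the mean and SD of the
decision time, RT mean and IQR rise and accuracy falls monotonically with
stop probability. Stop trials carry no release and are excluded from all
neural analyses (they exist so the exclusion logic is exercised).

### Signals

Per channel, the session is a sum of three components (arbitrary units;
z-scoring downstream removes scale):

1. **Aperiodic background** — spectrally shaped Gaussian noise with power
   ∝ f^(−χ), generated per trial segment with the context's exponent
   (defaults 2.0 / 1.85 / 1.7: the spectrum flattens with uncertainty)
   and equal-power crossfaded at segment joins (hard joins inject
   broadband clicks that corrupt steep spectra at high frequencies).
2. **Theta** — a sinusoid at 5 Hz whose instantaneous frequency carries a
   slow mean-reverting AR(1) drift (stationary SD 0.4 Hz, clipped at
   ±0.5 Hz, correlation time ~2 s). A pure bounded random walk was
   rejected because it saturates at the clip bounds and parks the
   frequency off center. Motor channels reuse the theta phase of a paired
   prefrontal channel delayed by 20 ms (prefrontal cortex leads).
3. **Theta-nested HFA** — the 70–150 Hz content of the aperiodic noise is
   carved out and replaced by a spectrally identical, independent draw
   whose envelope is modulated as
   (1 + pac_depth·cos θ) · gain(context) · (1 + slope(context)·(t−press))
   between press and HLL, held to the release and decayed over 0.3 s.
   Real high-gamma is not a standing spectral bump — task modulations
   raise the broadband continuum — so this construction keeps the resting
   spectrum seamless and the 30–45 Hz aperiodic fit unbiased. Non-encoding
   channels (controlled by `encoding_fraction`) receive the
   context-averaged gain and slope.

Defaults were chosen once as plausible for human iEEG: theta standing
~10 dB above the 1/f floor at 5 Hz, phase–amplitude coupling depth 0.6,
ramp slopes {0, 1.2, 0.8} (ramping present only under uncertainty,
strongest at moderate uncertainty) and gains {1.0, 1.15, 1.3}.

What the generator does **not** emulate: epileptic or movement artifacts,
volume conduction and shared references across contacts, non-sinusoidal
theta waveforms, trial-to-trial adaptation, electrode geometry. Passing
tests therefore demonstrate estimator correctness and parameter recovery
under the stated generative model, not robustness to every pathology of
clinical recordings.

Two interactions are worth knowing when designing experiments on the
generator: the context-dependent exponent changes the 70–150 Hz floor in
*every* channel, which is genuine context information (selection
experiments that target the gain/ramp signal should equalize exponents);
and the measured z-slope of the ramp scales with both the context gain
and the exponent's in-band floor, so slope-recovery experiments equalize
those too.

## Preprocessing and HFA (`sigproc`)

Demean, linear detrend, bipolar re-referencing to the next adjacent
contact on the same shaft (synthetic output is already locally referenced
and skips this), zero-phase IIR notches at 50 Hz and harmonics, and
resampling to 512 Hz. Band-pass filtering uses zero-phase forward–backward
windowed-sinc FIR (transition width 0.25 × lower band edge, capped so the
filter stays shorter than the signal): phase preservation matters for
Hilbert envelopes and peak-triggered alignment.

Epochs lock to cue, press, HLL or release with nearest-sample alignment
(no sub-sample interpolation); stop trials and pre-HLL releases are
excluded, correct and late releases kept.

HFA: eight non-overlapping 10 Hz bins spanning 70–150 Hz; per bin,
band-pass → Hilbert magnitude → z-scoring against 1000 values resampled
with replacement from the pooled pre-cue baseline (−0.2 to −0.01 s
relative to cue, pooled across trials per channel); bins averaged last.
The bootstrap distribution is a distribution of *values*, so its mean/SD
converge on the pooled sample statistics and the transform is exactly
scale-invariant (the draw uses indices, not values).

Peak detection uses local maxima with minimum prominence 0.5 z and
minimum separation 50 ms (defaults — the criteria are a design choice,
configurable; the closer of two competing peaks loses). Per-trial peak
metrics take the largest peak, then trim amplitudes and latencies
independently at the within-channel [2.5, 97.5] percentiles (inclusive
bounds, so constant columns survive). Ramping slopes use Huber-weighted
IRLS (c = 1.345, 50 iterations, tol 1e−8, MAD scale): with no residual
beyond the Huber threshold the estimate equals ordinary least squares
exactly. The peak-triggered average re-aligns the preprocessed-but-
unfiltered traces (±0.5 s) and fits a·cos(2πft+φ)+c by nonlinear least
squares, frequency initialized at the PTA's FFT peak; non-convergence is
reported with the FFT frequency and a flag.

## Spectral decomposition (`spectral`)

`fft_spectrum` is a Hanning, zero-padded periodogram on a 0.25 Hz grid
with energy scaling (bins sum to the windowed-signal energy). IRASA
resamples by h and 1/h for h = 1.1…1.9 (step 0.05; rational polyphase
with anti-aliasing), takes the geometric mean of each pair's spectrum and
the median across h as the aperiodic component; oscillatory = total −
aperiodic, pointwise. Internally all three spectra come from Welch
averaging (Hanning segments up to 4 s, 50% overlap, common zero-padded
grid, each normalized by its own window energy — the normalization under
which an exact power law is invariant to the resampling pair). Segment
averaging is essential: the geometric mean of two single-periodogram
estimates is biased low by E[√P]² < E[P], which masquerades as a ~25%
oscillatory residual on pure 1/f input. The spectral slope is an OLS fit
of log10 power on log10 frequency over 30–45 Hz, on the aperiodic
component when available. When estimating context-dependent slopes, use
pre-press windows: movement-evoked HFA is dragged into the 30–45 Hz band
by the resampling step and flattens peri-movement estimates.

Sample entropy follows the standard template-matching convention:
templates of length m and m+1 drawn from the same N−m starting points,
Chebyshev distance, tolerance r × SD of the analyzed series, self-matches
excluded, SampEn = −log(A/B). A constant series yields 0; B = 0 raises an
error rather than returning 0; A = 0 yields +inf (treated as missing by
the sliding version). The sliding estimator (100 ms windows, 20 ms steps,
5 ms terminal boxcar — sub-grid, hence effectively identity) scales r to
each window's own SD by default; `r_scope="global"` is provided because
the two conventions answer different questions (a variance step is
invisible under per-window scaling and visible under global scaling).

Multitaper TFR: per frequency, window length max(200 ms, 2 cycles),
half-bandwidth max(f/8, 1/window) — jointly approximating 200 ms /
quarter-octave smoothing — with floor(2·TW)−1 Slepian tapers (min 1),
evaluated by convolution, then the same bootstrap baseline z as HFA
(default baseline −0.4 to −0.1 s re cue). A single-Hanning mode exists as
a cross-check against a conventional spectrogram.

## Neural information (`encoding`)

Sliding one-way ANOVA (50 ms windows, 2 ms steps; one window-mean per
trial) yields F, p and ω² = (SS_between − df·MSE)/(SS_total + MSE) per
channel and window (MSE = SS_within/(n−G); ω² may be negative and is
reported as-is). Stage 1 flags channels with a consecutive run of
significant windows covering ≥10% of the analysis segment (default
segment: press to 0.5 s after the HLL). Stage 2 applies PCA to the
candidates' F time series (time features centered across channels); a
null distribution of explained-variance spectra comes from shuffling each
channel's series independently across time (1000 permutations), and
components are accepted sequentially — as in parallel analysis — until
one fails its rank-wise 95th percentile. Sequential acceptance keeps the
no-structure false-alarm rate at the per-rank alpha; accepting any rank
anywhere would compound to ~40% with ten components. Channels loading at
or above the 75th percentile (|loading|) on any surviving component are
context-encoding. An empty result is valid.

## Connectivity (`connectivity`)

iPLV per center frequency (3–32 Hz, 2^(1/8) steps, band ± f/4): band-pass
→ Hilbert phase → |imag(mean e^{iΔφ})| over time within trials, averaged
across trials. The null mismatches trial pairings; the permutation values
are resampled with replacement (so the z has unit null variance —
normalizing by the SD of bootstrap *means* would inflate z by √n) and the
iPLV is z-scored against that distribution. Empirical calibration:
P(|z| > 1.96) ≈ 0.05–0.08 under independence. A "distinct peak" is a
local maximum exceeding both neighbors and the spectrum median within
2–13 Hz; pairs without one are discarded.

PSI: complex coherency from trial- and taper-averaged cross-spectra
(Slepian tapers, NW 2.5, K 4, 2 s zero-padding per side), then
imag(Σ_f C*(f)·C(f+δf)) with δf one bin over the peak ± 3 Hz band.
Multitaper matters here: single-Hanning sidelobe leakage from a strong
narrowband peak systematically distorts band-edge phases and can flip the
sign of the summed slope. The null shuffles the frequency ordering of the
band-limited coherency (1000 iterations) and z-scores; swapping the
channel order negates the raw PSI exactly, and time-reversal flips its
sign. Positive z = first channel (prefrontal) leads.

PC power correlations: per-trial Pearson correlation between two
component traces in a fixed window, averaged; null by circularly shifting
the trial assignment of one side (block = one whole trial), z-scored.

## State space (`statespace`)

PCA on the channel × (time·trial) matrix (channel-centered covariance
eigendecomposition); scores reshaped to trials × components × time;
components kept up to 99% cumulative variance. Trajectory distances sum
pairwise condition-mean Euclidean distances over 50 ms windows stepped by
20 ms (25 ms terminal boxcar); state transitions are single-trial
distances between adjacent 50 ms windows overlapping by 20 ms.

Decoding: per component and time point, a closed-form one-dimensional
Gaussian LDA (class means, pooled variance + 1e−4 ridge, uniform priors),
10-fold cross-validation repeated 5 times. Uniform priors are deliberate:
stop-trial exclusion leaves the context classes imbalanced, and empirical
priors would put the permuted-label "chance" at the majority share
instead of 1/number-of-classes (~33% for three classes). Decoding traces
are smoothed (25 ms boxcar), thresholded at chance with below-chance
values zeroed, and clusters of adjacent supra-chance samples scored by
the sum of accuracies; the component with the largest cluster mass wins
(ties to the earlier cluster and lower component index). Validation
recomputes the largest cluster on the winning component under 50 label
shuffles (winning-component-only, to bound cost); the dimension is valid
if the true mass exceeds the null's 95th percentile. Action labels are
within-session RT terciles with ties toward the lower tercile.

Cross-regional generalization trains at every source time point and tests
at every target time point (no cross-validation; the datasets are
independent), cluster-corrected against a label-permutation max-mass null
with 4-connectivity. Trajectory lags are per-trial argmax of the
normalized cross-correlation, averaged; negative lags mean the second
(motor) trace lags the first (prefrontal). The theta component is the
kept PC with the largest trial-averaged IRASA oscillatory power
integrated over 2–13 Hz.

## Statistics (`stats`)

Cluster permutation: sample-wise dependent t (two conditions) or
one-way repeated-measures F (three or more), thresholded at alpha = 0.05;
clusters by adjacency (4-connectivity in 2D); mass = summed statistic;
null = maximum |mass| under sign flipping of unit-wise differences (t) or
within-unit condition-label permutation (F); 10,000 iterations by
default, exact enumeration when 2^units ≤ n_perm (so small single-sample
problems reduce to the exact permutation t test). Monte-Carlo p values
use the (1+B)/(N+1) convention. Empirical family-wise error on null data:
0.056 at nominal 0.05 (1000 datasets, 500 permutations).

Bootstrap balancing resamples larger conditions down to the reference
count (500 times) and averages the statistic; the reference condition is
untouched. The two-sided binomial test doubles the smaller tail (capped
at 1) — at p₀ = 0.5 this coincides with minimum-likelihood summation.
d′ and criterion use the 1/(2N) adjustment for extreme rates. Behavioral
summaries use all go trials with a release for RT, linear-interpolation
quantiles for the IQR, and the response-window definition of accuracy.

## Reproducibility and problem sizes

All stochastic operations take explicit seeds; the pipeline derives
per-stage integer streams from one master seed via `SeedSequence`, making
each stage reproducible in isolation and the whole run byte-identical.
Tests and the acceptance script run on deliberately desk-scale problems —
sessions of 15–80 trials per context with 2–8 channels, 20-seed
replications, permutation counts of 100–500 — chosen so recovery targets
are met with comfortable statistical margins while the whole suite stays
lightweight; the same code paths scale to full sessions unchanged.

## Known limitations

- The ω²/F machinery assumes one-way designs; the unbalanced two-factor
  orthogonalization control is out of scope.
- IRASA aperiodic estimates remain biased near strong oscillatory peaks
  and for spectra steeper than χ ≈ 3.5 at short segment lengths.
- PSI on narrowband coupling is intrinsically low-powered: the phase
  slope only accrues over the coherent bandwidth, so single-session z
  values are small even when the sign is reliable.
- The EDF writer targets continuous 16-bit recordings only (no
  annotations, no discontinuous records).
- Sample entropy is O(N²) per window; long windows at high sampling rates
  get expensive.
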