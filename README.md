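# ieegdyn

Analysis toolkit for context-dependent dynamics in human intracranial EEG
(iEEG), built around a fully synthetic, ground-truth task generator.

## The scientific problem

In a cue-guided motor task, a cue tells the participant how likely it is
(0%, 25% or 75%) that a moving target will stop before the response
landmark (the *hit lower limit*, HLL, reached 560–580 ms after the trial
start; a release within the following 160 ms is correct). Uncertainty
about the upcoming action reshapes both behavior (slower, more variable,
less accurate responses) and prefrontal–motor population activity. The
analyses this package implements ask *how* that predictive context is
encoded:

- **Neural information** — how much trial-to-trial variance of
  high-frequency activity (HFA, 70–150 Hz envelope, a proxy for population
  firing) the context explains, as the bias-corrected effect size
  ω² = (SS_between − df·MSE) / (SS_total + MSE), computed in sliding
  windows, with a two-stage context-encoding electrode selection.
- **Ramping vs. oscillatory dynamics** — robust single-trial HFA slopes
  from trial start to the HLL; IRASA separation of the power spectrum into
  aperiodic (1/f, slope fit 30–45 Hz) and oscillatory parts; time-resolved
  sample entropy SampEn(m, r, N) = −log(p^{m+1}/p^m).
- **Theta-nested HFA** — peak-triggered averages of the raw traces around
  HFA bursts (with a 4-parameter sine fit) and inter-peak-interval
  frequencies, both exposing the ~5 Hz rhythm that paces the bursts.
- **Directed coupling** — the imaginary phase-locking value
  iPLV_f = |imag(n⁻¹ Σ_t e^{i(φ_x−φ_y)})| (insensitive to zero-lag
  mixing) and the phase-slope index PSI = imag(Σ_f C*(f)·C(f+δf)) over the
  pair's iPLV peak band, permutation-z-normalized; positive = prefrontal
  cortex leads.
- **Population state space** — PCA trajectories, Euclidean distances and
  transitions, per-component LDA decoding of context and action (reaction
  time terciles) with cluster-mass permutation validation, cross-regional
  generalization and trajectory lags.
- **Inference** — cluster-based permutation tests (max-sum criterion),
  bootstrap trial balancing, exact two-sided binomial tests, signal
  detection (d′, criterion c).

Because clinical iEEG of this kind cannot be publicly archived, the
`synthgen` module generates complete sessions with known ground truth
(1/f background with context-dependent exponent, jittered ~5 Hz theta,
theta-nested 70–150 Hz bursts with context-dependent ramping and gain, an
inter-regional theta delay, and a linear-ballistic-accumulator behavior
model), so every stage is testable end to end.

## Worked example

```python
from ieegdyn import sigproc, synthgen

cfg = synthgen.SimConfig(n_trials_per_context=15,
                         n_channels={"pfc": 2, "motor": 2},
                         pac_depth=1.0, seed=5)
raw, truth = synthgen.simulate_session(cfg)
ep  = sigproc.epoch(sigproc.preprocess(raw), "hll", (-3.0, 1.0))
hfa = sigproc.extract_hfa(ep, seed=5)
peaks = sigproc.detect_hfa_peaks(hfa, 0.5, 0.05, tmin=-0.6, tmax=0.3)
_, _, fit = sigproc.peak_triggered_average(ep, peaks)
print(fit["frequency"])              # 5.01
print(sigproc.inter_peak_interval(peaks)[1])   # 5.00
```

Both numbers are estimates of the frequency of the rhythm nesting the HFA
bursts — the peak-triggered-average sine fit and the mean inter-peak
frequency — and land on the generator's 5 Hz theta. The scripts in
`examples/` walk through each capability the same way (behavior, ramping,
IRASA, neural information, nesting, connectivity, state-space decoding,
full pipeline) and print what the numbers mean.

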