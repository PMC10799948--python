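"""Simulate one synthetic cue-guided motor session and summarize behavior.

Builds a session with three predictive contexts (0%, 25%, 75% stop
probability), prints the per-context reaction-time mean, IQR and go-trial
accuracy, and writes the session to disk (EDF + CSV + JSON ground truth).
"""

from ieegdyn import stats, synthgen

cfg = synthgen.SimConfig(n_trials_per_context=40, seed=1)
raw, truth = synthgen.simulate_session(cfg)

print(f"session: {raw.n_channels} channels, {raw.n_samples / raw.fs:.0f} s, "
      f"{len(raw.trials)} trials")
print(stats.behavior_summary(raw.trials).round(3).to_string(index=False))
# RT mean and variability (IQR) increase, accuracy decreases, as the cue
# becomes less predictive - the uncertainty cost the task is built around.

paths = synthgen.write_session(raw, "scratch/session_demo", truth)
print("written:", ", ".join(str(p) for p in paths.values()))
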