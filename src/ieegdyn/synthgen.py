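"""Synthetic cue-guided motor task sessions with known ground truth.

Emulates an intracranial-EEG stop-probability task: on every trial a cue
signals the probability (0%, 25%, 75%) that a moving target will stop before
the "hit lower limit" (HLL). The participant presses a key to start the
trial, the target reaches the HLL 560-580 ms later and the upper boundary
160 ms after that; a button release inside that interval is correct.

Generated channels contain

* 1/f aperiodic background with a context-dependent exponent,
* a ~5 Hz theta oscillation (slow frequency jitter),
* a 70-150 Hz band-limited carrier whose envelope is nested in theta phase
  (cosine phase-amplitude coupling) and ramps from press to the HLL with a
  context-dependent slope and gain,
* an inter-regional theta delay (prefrontal cortex leading motor cortex).

Reaction times follow a single-accumulator linear-ballistic race: distance
to threshold = threshold - context start point - uniform start jitter,
drift drawn from a normal with fixed SD 0.5, plus a non-decision time.

All randomness flows from ``SimConfig.seed``; identical configs give
bit-identical sessions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "LbaParams",
    "SimConfig",
    "GroundTruth",
    "RawRecording",
    "simulate_behavior",
    "make_aperiodic_noise",
    "make_nested_burst_channel",
    "simulate_session",
    "write_session",
    "read_session",
]


from .errors import InvalidConfigError


@dataclass
class LbaParams:
    """Single-accumulator linear-ballistic race for go-trial responses.

    ``distance = threshold - start_offset[context] - U(0, start_jitter)``;
    drift ~ Normal(drift_mean, drift_sd) truncated positive; release time =
    press + non_decision + distance/drift. Larger start offsets (more prior
    evidence) shorten the race, so offsets decreasing in stop probability
    yield the slower/noisier responses seen under uncertainty.
    """

    non_decision: float = 0.51
    threshold: float = 1.0
    drift_mean: float = 4.0
    drift_sd: float = 0.5  # fixed variance of the drift
    start_jitter: float = 0.12
    start_offset_by_context: dict = field(
        default_factory=lambda: {0.0: 0.50, 0.25: 0.36, 0.75: 0.22}
    )


@dataclass
class SimConfig:
    fs: float = 512.0
    n_trials_per_context: int = 60
    contexts: tuple = (0.0, 0.25, 0.75)
    n_channels: dict = field(default_factory=lambda: {"pfc": 4, "motor": 4})
    hll_delay_range: tuple = (0.560, 0.580)
    upper_delay_range: tuple = (0.740, 0.760)
    theta_freq: float = 5.0
    theta_jitter: float = 0.5  # bound of the slow random-walk frequency drift, Hz
    pac_depth: float = 0.6
    ramp_slope_by_context: dict = field(
        default_factory=lambda: {0.0: 0.0, 0.25: 1.2, 0.75: 0.8}
    )
    hfa_gain_by_context: dict = field(
        default_factory=lambda: {0.0: 1.0, 0.25: 1.15, 0.75: 1.3}
    )
    aperiodic_exponent_by_context: dict = field(
        default_factory=lambda: {0.0: 2.0, 0.25: 1.85, 0.75: 1.7}
    )
    inter_regional_lag: float = 0.020  # seconds; PFC leads motor
    rt_model: LbaParams = field(default_factory=LbaParams)
    encoding_fraction: float = 1.0
    # amplitude mix (arbitrary units); amp_hfa is relative to the aperiodic
    # floor inside 70-150 Hz (1.0 = spectrally seamless substitution)
    amp_aperiodic: float = 1.0
    amp_theta: float = 0.5
    amp_hfa: float = 1.0
    cue_lead_range: tuple = (1.5, 2.0)  # seconds from cue to self-paced press
    trial_pre: float = 3.0  # segment seconds before press
    trial_post: float = 4.0  # segment seconds after press
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise InvalidConfigError("fs must be positive")
        if self.n_trials_per_context <= 0:
            raise InvalidConfigError("n_trials_per_context must be positive")
        if not 0.0 <= self.pac_depth <= 1.0:
            raise InvalidConfigError("pac_depth must lie in [0, 1]")
        lo, hi = self.hll_delay_range
        ulo, uhi = self.upper_delay_range
        if not (0 < lo < hi < ulo < uhi):
            raise InvalidConfigError("hll_delay_range must precede upper_delay_range")
        if any(n <= 0 for n in self.n_channels.values()):
            raise InvalidConfigError("every ROI needs at least one channel")
        if not 0.0 <= self.encoding_fraction <= 1.0:
            raise InvalidConfigError("encoding_fraction must lie in [0, 1]")
        for p in self.contexts:
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError("contexts are stop probabilities in [0, 1]")


@dataclass
class GroundTruth:
    """Generative parameters actually used, for parameter-recovery tests."""

    true_ramp_slopes: dict
    true_theta_freq: float
    true_exponents: dict
    true_lag: float
    encoding_mask: np.ndarray
    pac_depth: float


@dataclass
class RawRecording:
    """Continuous multichannel recording plus its trial-event table.

    ``signal`` is channels x samples in arbitrary units. ``bipolar`` marks
    data that is already locally referenced (synthetic output is), in which
    case preprocessing skips the bipolar derivation.
    """

    signal: np.ndarray
    fs: float
    roi_labels: list
    trials: pd.DataFrame
    ch_names: list = None
    bipolar: bool = True

    def __post_init__(self):
        if self.ch_names is None:
            counts: dict = {}
            names = []
            for roi in self.roi_labels:
                counts[roi] = counts.get(roi, 0) + 1
                names.append(f"{roi.upper()}{counts[roi]}")
            self.ch_names = names
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("RawRecording signal contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


# ---------------------------------------------------------------------------
# behavior


def simulate_behavior(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a full trial table (schedule, stop flags, press/HLL/release times).

    Trials are laid out sequentially with ``trial_pre + trial_post`` seconds
    per trial and a 2 s session margin; context order is randomly
    interleaved. Go-trial releases come from the LBA-style race; stop trials
    carry no release. ``rt`` is release minus HLL time (NaN for stop trials).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    contexts = np.repeat(np.asarray(config.contexts, float), config.n_trials_per_context)
    rng.shuffle(contexts)
    n = contexts.size
    slot = config.trial_pre + config.trial_post
    cue_lead = rng.uniform(*config.cue_lead_range, size=n)
    # self-paced starts: jitter decorrelates trial onsets from any ongoing rhythm
    t_press = 2.0 + config.trial_pre + slot * np.arange(n) + rng.uniform(0.0, 0.5, size=n)
    t_cue = t_press - cue_lead
    t_hll = t_press + rng.uniform(*config.hll_delay_range, size=n)
    t_upper = t_press + rng.uniform(*config.upper_delay_range, size=n)
    is_stop = rng.random(n) < contexts

    lba = config.rt_model
    offsets = np.array([lba.start_offset_by_context[c] for c in contexts])
    dist = lba.threshold - offsets - rng.uniform(0.0, lba.start_jitter, size=n)
    drift = rng.normal(lba.drift_mean, lba.drift_sd, size=n)
    # truncate the race to positive drifts (re-draw the rare negatives)
    while np.any(drift <= 0.1):
        bad = drift <= 0.1
        drift[bad] = rng.normal(lba.drift_mean, lba.drift_sd, size=int(bad.sum()))
    t_release = t_press + lba.non_decision + dist / drift
    t_release[is_stop] = np.nan
    correct = (t_release >= t_hll) & (t_release <= t_upper)
    correct[is_stop] = True  # withheld response on a stop trial
    rt = t_release - t_hll

    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "context": contexts,
            "is_stop": is_stop,
            "t_cue": t_cue,
            "t_press": t_press,
            "t_hll": t_hll,
            "t_upper": t_upper,
            "t_release": t_release,
            "correct": correct,
            "rt": rt,
        }
    )


# ---------------------------------------------------------------------------
# signal components


def make_aperiodic_noise(
    exponent: float, n: int, fs: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Zero-mean unit-SD noise with expected power spectrum ∝ f^(-exponent).

    White Gaussian noise is shaped in the frequency domain by f^(-exponent/2).
    """
    if exponent < 0:
        raise InvalidConfigError("exponent must be >= 0")
    if n < 2:
        raise InvalidConfigError("need at least 2 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0  # zero mean
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _piecewise_noise(
    seg_exp: list,
    seg_edges: list,
    fs: float,
    rng: np.random.Generator,
    pad: int = 128,
) -> np.ndarray:
    """Aperiodic noise with per-segment exponents, equal-power crossfaded at
    boundaries (hard joins would inject broadband clicks that bias the
    high-frequency end of steep spectra)."""
    n = seg_edges[-1]
    out = np.zeros(n)
    for k, exp in enumerate(seg_exp):
        a, b = seg_edges[k], seg_edges[k + 1]
        if b <= a:
            continue
        lo = max(0, a - pad)
        hi = min(n, b + pad)
        x = make_aperiodic_noise(exp, hi - lo, fs, rng)
        w = np.ones(hi - lo)
        if a > 0:
            ramp = np.sin(np.linspace(0.0, np.pi / 2, a + pad - lo))
            w[: ramp.size] = ramp
        if b < n:
            ramp = np.cos(np.linspace(0.0, np.pi / 2, hi - (b - pad)))
            w[-ramp.size :] = np.minimum(w[-ramp.size :], ramp)
        out[lo:hi] += x * w
    return out


def _theta_phase(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Instantaneous theta phase with slow mean-reverting frequency drift.

    The drift is an AR(1) process (correlation time ~2 s) with stationary
    SD 0.8 x theta_jitter, clipped at +-theta_jitter, so the instantaneous
    frequency explores the full jitter band while staying centered on
    ``theta_freq``.
    """
    rho = 0.999
    sd = config.theta_jitter * 0.8
    eps = rng.standard_normal(n) * sd * np.sqrt(1 - rho**2)
    walk = sps.lfilter([1.0], [1.0, -rho], eps)
    walk = np.clip(walk, -config.theta_jitter, config.theta_jitter)
    f_inst = config.theta_freq + walk
    return 2.0 * np.pi * np.cumsum(f_inst) / config.fs + rng.uniform(0, 2 * np.pi)


def _hfa_taps(fs: float) -> np.ndarray:
    ny = fs / 2.0
    return sps.firwin(257, [70.0 / ny, min(150.0, ny * 0.95) / ny], pass_zero=False)


def _hfa_carrier(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD Gaussian noise band-passed to 70-150 Hz (the HFA band)."""
    white = rng.standard_normal(n)
    x = sps.fftconvolve(white, _hfa_taps(fs), mode="same")
    return x / x.std()


def _modulated_broadband(
    noise: np.ndarray,
    noise2: np.ndarray,
    env: np.ndarray,
    config: SimConfig,
) -> np.ndarray:
    """Replace the 70-150 Hz content of ``noise`` with an envelope-modulated
    carrier of identical spectral shape (the band-passed independent draw
    ``noise2``).

    High-gamma in cortex is not a standing spectral bump: task modulations
    transiently raise the broadband continuum. Carving the band out of the
    1/f noise and re-injecting a spectrally matched, envelope-modulated
    copy keeps the resting spectrum seamless, so the aperiodic slope
    estimate stays unbiased.
    """
    taps = _hfa_taps(config.fs)
    base = noise - sps.fftconvolve(noise, taps, mode="same")
    carrier = sps.fftconvolve(noise2, taps, mode="same")
    return base + config.amp_hfa * carrier * env


def _ramp_gain(
    t: np.ndarray, trials: pd.DataFrame, config: SimConfig, encoding: bool
) -> np.ndarray:
    """Multiplicative HFA envelope: 1 at baseline, context ramp press->HLL.

    Non-encoding channels receive the context-averaged gain and slope so they
    share the average dynamics but carry no context information.
    """
    gain = np.ones_like(t)
    mean_gain = float(np.mean(list(config.hfa_gain_by_context.values())))
    mean_slope = float(np.mean(list(config.ramp_slope_by_context.values())))
    fs = config.fs
    for row in trials.itertuples():
        c = row.context
        g = config.hfa_gain_by_context[c] if encoding else mean_gain
        s = config.ramp_slope_by_context[c] if encoding else mean_slope
        i0 = int(round(row.t_press * fs))
        i1 = int(round(row.t_hll * fs))
        t_end = row.t_release if np.isfinite(row.t_release) else row.t_hll
        i2 = int(round(t_end * fs))
        i3 = int(round((t_end + 0.3) * fs))
        i0, i1, i2, i3 = (min(max(i, 0), t.size) for i in (i0, i1, i2, i3))
        ramp = g * (1.0 + s * (t[i0:i1] - row.t_press))
        gain[i0:i1] = ramp
        peak = ramp[-1] if ramp.size else g
        gain[i1:i2] = peak
        if i3 > i2:  # linear decay back to baseline after release
            gain[i2:i3] = peak + (1.0 - peak) * np.linspace(0, 1, i3 - i2)
    return gain


def make_nested_burst_channel(
    config: SimConfig,
    context: float,
    roi: str = "pfc",
    seed: int | np.random.Generator = 0,
    duration: float = 10.0,
    t_press: float = 4.0,
) -> np.ndarray:
    """Single stand-alone channel: aperiodic + theta + theta-nested ramping HFA.

    Convenience constructor for tests of the nesting analyses; a single go
    trial with the given context starts pressing at ``t_press``.
    """
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * config.fs))
    t = np.arange(n) / config.fs
    hll = t_press + np.mean(config.hll_delay_range)
    trials = pd.DataFrame(
        {
            "context": [context],
            "t_press": [t_press],
            "t_hll": [hll],
            "t_release": [hll + 0.05],
        }
    )
    exponent = config.aperiodic_exponent_by_context[context]
    noise = make_aperiodic_noise(exponent, n, config.fs, rng)
    noise2 = make_aperiodic_noise(exponent, n, config.fs, rng)
    phase = _theta_phase(config, n, rng)
    env = (1.0 + config.pac_depth * np.cos(phase)) * _ramp_gain(t, trials, config, True)
    return (
        config.amp_aperiodic * _modulated_broadband(noise, noise2, env, config)
        + config.amp_theta * np.sin(phase)
    )


# ---------------------------------------------------------------------------
# full session


def simulate_session(config: SimConfig) -> tuple[RawRecording, GroundTruth]:
    """Assemble a full multichannel session plus its ground truth.

    Motor channels reuse the theta component of a paired prefrontal channel
    delayed by ``inter_regional_lag`` (prefrontal cortex leads). The
    aperiodic background is generated per trial segment with the context's
    exponent so that segment spectra carry the context effect.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    trials = simulate_behavior(config, rng)
    n_trials = len(trials)
    slot = config.trial_pre + config.trial_post
    duration = 2.0 + n_trials * slot + 2.0
    n = int(round(duration * config.fs))
    t = np.arange(n) / config.fs
    fs = config.fs

    n_pfc = config.n_channels["pfc"]
    n_mot = config.n_channels["motor"]
    roi_labels = ["pfc"] * n_pfc + ["motor"] * n_mot
    n_ch = n_pfc + n_mot

    n_enc = int(round(config.encoding_fraction * n_ch))
    encoding_mask = np.zeros(n_ch, bool)
    if n_enc:
        encoding_mask[rng.choice(n_ch, size=n_enc, replace=False)] = True

    # per-trial-segment aperiodic noise with context exponents
    seg_edges = [0]
    seg_exp = []
    mean_exp = float(np.mean(list(config.aperiodic_exponent_by_context.values())))
    for row in trials.itertuples():
        start = int(round((row.t_press - config.trial_pre) * fs))
        stop = int(round((row.t_press + config.trial_post) * fs))
        if start > seg_edges[-1]:
            seg_exp.append(mean_exp)
            seg_edges.append(start)
        seg_exp.append(config.aperiodic_exponent_by_context[row.context])
        seg_edges.append(min(stop, n))
    if seg_edges[-1] < n:
        seg_exp.append(mean_exp)
        seg_edges.append(n)

    lag_samp = int(round(config.inter_regional_lag * fs))
    pfc_phases = []
    signal = np.empty((n_ch, n), dtype=np.float64)
    for ch in range(n_ch):
        roi = roi_labels[ch]
        noise = _piecewise_noise(seg_exp, seg_edges, fs, rng)
        noise2 = _piecewise_noise(seg_exp, seg_edges, fs, rng)
        if roi == "pfc":
            phase = _theta_phase(config, n, rng)
            pfc_phases.append(phase)
        else:
            partner = pfc_phases[(ch - n_pfc) % n_pfc]
            phase = np.roll(partner, lag_samp)  # motor theta lags PFC
        env = (1.0 + config.pac_depth * np.cos(phase)) * _ramp_gain(
            t, trials, config, bool(encoding_mask[ch])
        )
        signal[ch] = (
            config.amp_aperiodic * _modulated_broadband(noise, noise2, env, config)
            + config.amp_theta * np.sin(phase)
        )

    raw = RawRecording(signal=signal, fs=fs, roi_labels=roi_labels, trials=trials)
    truth = GroundTruth(
        true_ramp_slopes=dict(config.ramp_slope_by_context),
        true_theta_freq=config.theta_freq,
        true_exponents=dict(config.aperiodic_exponent_by_context),
        true_lag=config.inter_regional_lag,
        encoding_mask=encoding_mask,
        pac_depth=config.pac_depth,
    )
    return raw, truth


# ---------------------------------------------------------------------------
# session I/O: EDF + CSV trials + JSON ground truth


def write_session(
    raw: RawRecording, out_dir: str | Path, truth: GroundTruth | None = None, stem: str = "session"
) -> dict:
    """Write a session to disk: EDF signal, CSV trial table, JSON ground truth."""
    from . import io as _io

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"edf": out_dir / f"{stem}.edf", "trials": out_dir / f"{stem}_trials.csv"}
    _io.write_edf(paths["edf"], raw.signal, raw.fs, raw.ch_names)
    raw.trials.to_csv(paths["trials"], index=False)
    meta = {"roi_labels": raw.roi_labels, "bipolar": raw.bipolar, "fs": raw.fs}
    paths["meta"] = out_dir / f"{stem}_meta.json"
    paths["meta"].write_text(json.dumps(meta, indent=1))
    if truth is not None:
        d = asdict(truth)
        d["encoding_mask"] = truth.encoding_mask.astype(int).tolist()
        paths["truth"] = out_dir / f"{stem}_truth.json"
        paths["truth"].write_text(json.dumps(d, indent=1))
    return paths


def read_session(out_dir: str | Path, stem: str = "session") -> RawRecording:
    """Read back a session written by :func:`write_session`."""
    from . import io as _io

    out_dir = Path(out_dir)
    sig, fs, ch_names = _io.read_edf(out_dir / f"{stem}.edf")
    trials = pd.read_csv(out_dir / f"{stem}_trials.csv")
    meta = json.loads((out_dir / f"{stem}_meta.json").read_text())
    return RawRecording(
        signal=sig,
        fs=meta["fs"],
        roi_labels=meta["roi_labels"],
        trials=trials,
        ch_names=ch_names,
        bipolar=meta["bipolar"],
    )
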