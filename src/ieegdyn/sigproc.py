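"""Preprocessing, HFA extraction and single-trial HFA metrics.

High-frequency activity (HFA, 70-150 Hz) is extracted in eight
non-overlapping 10 Hz bins: band-pass, Hilbert magnitude, z-scoring against
a bootstrapped pre-cue baseline distribution per bin, then averaging across
bins. Binned extraction counteracts the 1/f power drop-off across the band;
the bootstrap baseline makes traces comparable across conditions.

Downstream single-trial metrics: peak amplitude/latency (with percentile
outlier trimming), robust ramping slopes from trial start to the HLL,
peak-triggered averages of the unfiltered traces (which expose the slow
rhythm nesting the HFA bursts), and inter-peak intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import fft as sfft
from scipy.optimize import curve_fit

from .errors import UndefinedResultError
from .synthgen import RawRecording

__all__ = [
    "Epochs",
    "HfaEpochs",
    "PeakSet",
    "preprocess",
    "epoch",
    "extract_hfa",
    "detect_hfa_peaks",
    "peak_metrics",
    "ramping_slope",
    "peak_triggered_average",
    "inter_peak_interval",
]

HFA_BAND_EDGES = tuple(np.arange(70, 151, 10, dtype=float))  # eight 10 Hz bins


@dataclass
class Epochs:
    """Trials x channels x samples, time axis in seconds relative to an event."""

    data: np.ndarray
    fs: float
    t0_event: str
    times: np.ndarray
    trial_meta: pd.DataFrame
    roi_labels: list
    ch_names: list

    def __post_init__(self):
        if self.data.shape[0] != len(self.trial_meta):
            raise ValueError("trial_meta rows must match epochs")

    @property
    def n_trials(self):
        return self.data.shape[0]

    @property
    def n_channels(self):
        return self.data.shape[1]

    def crop(self, tmin: float, tmax: float) -> "Epochs":
        m = (self.times >= tmin) & (self.times <= tmax)
        return replace(self, data=self.data[:, :, m], times=self.times[m])

    def pick_channels(self, idx) -> "Epochs":
        idx = np.atleast_1d(idx)
        return replace(
            self,
            data=self.data[:, idx, :],
            roi_labels=[self.roi_labels[i] for i in idx],
            ch_names=[self.ch_names[i] for i in idx],
        )


@dataclass
class HfaEpochs(Epochs):
    """Baseline-z-scored HFA envelopes; values in z units."""

    band_edges: tuple = HFA_BAND_EDGES
    baseline_window: tuple = (-0.2, -0.01)


@dataclass
class PeakSet:
    """Detected HFA peaks: long table (trial, channel, time, amplitude)."""

    table: pd.DataFrame
    fs: float
    min_prominence_z: float
    min_separation_s: float

    def for_channel(self, channel: int) -> "PeakSet":
        return replace(self, table=self.table[self.table.channel == channel])


# ---------------------------------------------------------------------------
# preprocessing


def _shaft_groups(ch_names: list[str]) -> dict:
    groups: dict = {}
    for i, name in enumerate(ch_names):
        stem = name.rstrip("0123456789")
        groups.setdefault(stem, []).append(i)
    return groups


def preprocess(
    raw: RawRecording,
    notch: float = 50.0,
    target_fs: float = 512.0,
    bipolar: bool | None = None,
) -> RawRecording:
    """Demean, de-trend, locally re-reference, notch-filter, resample.

    Bipolar derivation subtracts the next adjacent contact on the same
    shaft (shaft = shared alphabetic channel-name stem); single-contact
    shafts are dropped with a warning. Data already locally referenced
    (``raw.bipolar``) skip the derivation. Line noise is removed at
    ``notch`` and all harmonics below Nyquist with zero-phase IIR notches.
    """
    sig = np.asarray(raw.signal, float)
    sig = sps.detrend(sig, axis=1, type="linear")  # removes mean + linear trend

    ch_names = list(raw.ch_names)
    roi = list(raw.roi_labels)
    do_bipolar = (not raw.bipolar) if bipolar is None else bipolar
    if do_bipolar:
        out, names, rois = [], [], []
        for stem, idx in _shaft_groups(ch_names).items():
            if len(idx) < 2:
                warnings.warn(f"dropping single-contact shaft {stem!r}")
                continue
            for a, b in zip(idx[:-1], idx[1:]):
                out.append(sig[a] - sig[b])
                names.append(f"{ch_names[a]}-{ch_names[b]}")
                rois.append(roi[a])
        sig = np.array(out)
        ch_names, roi = names, rois

    fs = raw.fs
    f = notch
    while f < fs / 2:
        b, a = sps.iirnotch(f, Q=35.0, fs=fs)
        sig = sps.filtfilt(b, a, sig, axis=1)
        f += notch

    if abs(fs - target_fs) > 1e-9:
        from fractions import Fraction

        frac = Fraction(target_fs / fs).limit_denominator(1000)
        sig = sps.resample_poly(sig, frac.numerator, frac.denominator, axis=1)
        fs = target_fs

    return RawRecording(
        signal=sig, fs=fs, roi_labels=roi, trials=raw.trials, ch_names=ch_names, bipolar=True
    )


# ---------------------------------------------------------------------------
# epoching


_EVENT_COLUMN = {"cue": "t_cue", "press": "t_press", "hll": "t_hll", "release": "t_release"}


def epoch(
    raw: RawRecording, t0_event: str = "hll", window: tuple = (-5.0, 5.0)
) -> Epochs:
    """Cut go-trial epochs locked to an event (nearest-sample alignment).

    Stop trials and trials released before the HLL are excluded; correct and
    late-release trials are kept. Trials whose window leaves the recording
    are dropped with a warning.
    """
    col = _EVENT_COLUMN[t0_event.lower()]
    fs = raw.fs
    i_lo, i_hi = int(round(window[0] * fs)), int(round(window[1] * fs))
    offsets = np.arange(i_lo, i_hi + 1)
    times = offsets / fs

    trials = raw.trials
    go = trials[~trials.is_stop.astype(bool)]
    keep = go[~(go.t_release < go.t_hll)]  # NaN-release rows never satisfy "<"
    rows, data = [], []
    for row in keep.itertuples():
        center = int(round(getattr(row, col) * fs))
        if center + i_lo < 0 or center + i_hi >= raw.n_samples:
            warnings.warn(f"trial {row.trial_id} too close to recording edge; dropped")
            continue
        rows.append(row.Index)
        data.append(raw.signal[:, center + offsets])
    if not data:
        raise ValueError("no usable trials")
    return Epochs(
        data=np.stack(data, axis=0),
        fs=fs,
        t0_event=t0_event.lower(),
        times=times,
        trial_meta=trials.loc[rows].reset_index(drop=True),
        roi_labels=list(raw.roi_labels),
        ch_names=list(raw.ch_names),
    )


# ---------------------------------------------------------------------------
# HFA extraction


def bandpass_fir(
    x: np.ndarray, fs: float, lo: float, hi: float, axis: int = -1
) -> np.ndarray:
    """Zero-phase forward-backward windowed-sinc band-pass.

    Transition width = 0.25 x lower band edge, as a compromise between
    roll-off and filter length; phase preservation is what matters for
    Hilbert envelopes and peak-triggered alignment.
    """
    trans = 0.25 * lo
    numtaps = int(np.ceil(3.3 * fs / trans)) // 2 * 2 + 1
    # keep the filter (and filtfilt padding) shorter than the signal
    max_taps = (np.asarray(x).shape[axis] - 1) // 4 // 2 * 2 + 1
    numtaps = min(numtaps, max_taps)
    if numtaps < 9:
        raise ValueError("signal too short for the requested band")
    ny = fs / 2
    taps = sps.firwin(numtaps, [lo / ny, min(hi, 0.99 * ny) / ny], pass_zero=False)
    return sps.filtfilt(taps, [1.0], x, axis=axis, padlen=numtaps)


def _baseline_masks(epochs: Epochs, baseline: tuple) -> list[np.ndarray]:
    """Per-trial boolean masks of the cue-relative baseline window."""
    col = _EVENT_COLUMN[epochs.t0_event]
    masks = []
    for row in epochs.trial_meta.itertuples():
        cue_rel = row.t_cue - getattr(row, col)
        m = (epochs.times >= cue_rel + baseline[0]) & (epochs.times <= cue_rel + baseline[1])
        if not m.any():
            raise ValueError("baseline window empty; widen the epoch window")
        masks.append(m)
    return masks


def bootstrap_baseline_z(
    data: np.ndarray,
    baseline_values: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """z-score ``data`` against ``n_boot`` values resampled with replacement
    from the pooled baseline. The bootstrap mean/SD converge on the pooled
    sample statistics, so the transform is scale-invariant by construction."""
    draw = baseline_values[rng.integers(0, baseline_values.size, size=n_boot)]
    mu, sd = draw.mean(), draw.std()
    if sd <= 0:
        sd = 1.0
    return (data - mu) / sd


def extract_hfa(
    epochs: Epochs,
    baseline: tuple = (-0.2, -0.01),
    n_boot: int = 1000,
    seed: int = 0,
    band_edges: tuple = HFA_BAND_EDGES,
) -> HfaEpochs:
    """Band-binned Hilbert envelopes, bootstrap-baseline z, averaged bins.

    ``baseline`` is relative to cue onset regardless of the epoch lock;
    baseline envelope values are pooled across trials per channel and bin.
    """
    if epochs.fs < 300:
        raise ValueError("sampling rate too low for the 70-150 Hz band")
    rng = np.random.default_rng(seed)
    masks = _baseline_masks(epochs, baseline)
    nfft = sfft.next_fast_len(epochs.data.shape[-1])

    acc = np.zeros_like(epochs.data)
    n_bands = len(band_edges) - 1
    for b in range(n_bands):
        lo, hi = band_edges[b], band_edges[b + 1]
        filt = bandpass_fir(epochs.data, epochs.fs, lo, hi, axis=-1)
        env = np.abs(sps.hilbert(filt, N=nfft, axis=-1)[..., : epochs.data.shape[-1]])
        for ch in range(epochs.n_channels):
            pool = np.concatenate(
                [env[i, ch, m] for i, m in enumerate(masks)]
            )
            acc[:, ch] += bootstrap_baseline_z(env[:, ch], pool, n_boot, rng)
    acc /= n_bands
    return HfaEpochs(
        data=acc,
        fs=epochs.fs,
        t0_event=epochs.t0_event,
        times=epochs.times,
        trial_meta=epochs.trial_meta,
        roi_labels=epochs.roi_labels,
        ch_names=epochs.ch_names,
        band_edges=tuple(band_edges),
        baseline_window=tuple(baseline),
    )


# ---------------------------------------------------------------------------
# peaks


def detect_hfa_peaks(
    hfa: Epochs,
    min_prominence_z: float = 0.5,
    min_separation_s: float = 0.05,
    tmin: float | None = None,
    tmax: float | None = None,
) -> PeakSet:
    """Local maxima above a prominence threshold and minimum separation.

    When two candidate peaks fall within the separation window the higher
    one is retained. An empty peak set is a valid result.
    """
    if not np.all(np.isfinite(hfa.data)):
        raise ValueError("HFA contains non-finite values")
    distance = max(1, int(round(min_separation_s * hfa.fs)))
    lo = -np.inf if tmin is None else tmin
    hi = np.inf if tmax is None else tmax
    sel = (hfa.times >= lo) & (hfa.times <= hi)
    t_sel = hfa.times[sel]
    rows = []
    for i in range(hfa.n_trials):
        for ch in range(hfa.n_channels):
            x = hfa.data[i, ch, sel]
            idx, _ = sps.find_peaks(x, prominence=min_prominence_z, distance=distance)
            for k in idx:
                rows.append((i, ch, t_sel[k], x[k]))
    table = pd.DataFrame(rows, columns=["trial", "channel", "time", "amplitude"])
    return PeakSet(
        table=table,
        fs=hfa.fs,
        min_prominence_z=min_prominence_z,
        min_separation_s=min_separation_s,
    )


def peak_metrics(
    peaks: PeakSet, trim: tuple = (2.5, 97.5)
) -> tuple[pd.DataFrame, list]:
    """Per-trial maximum peak, then per-channel percentile outlier trimming.

    Amplitude and latency are trimmed independently at the given percentile
    bounds (inclusive, so a constant column is never trimmed). Channels left
    with fewer than 3 trials are flagged unusable.
    """
    tab = peaks.table
    if tab.empty:
        return tab.rename(columns={"time": "latency"}), []
    best = tab.loc[tab.groupby(["trial", "channel"])["amplitude"].idxmax()]
    best = best.rename(columns={"time": "latency"})
    kept, unusable = [], []
    for ch, grp in best.groupby("channel"):
        ok = np.ones(len(grp), bool)
        for colname in ("amplitude", "latency"):
            v = grp[colname].to_numpy()
            lo, hi = np.percentile(v, trim)
            ok &= (v >= lo) & (v <= hi)
        surv = grp[ok]
        if len(surv) < 3:
            unusable.append(ch)
        kept.append(surv)
    return pd.concat(kept).reset_index(drop=True), unusable


# ---------------------------------------------------------------------------
# ramping


def huber_slope(
    t: np.ndarray,
    y: np.ndarray,
    c: float = 1.345,
    n_iter: int = 50,
    tol: float = 1e-8,
) -> float:
    """Huber-weighted IRLS slope of y on t.

    Residual scale is the normalized median absolute deviation; when every
    standardized residual is within the Huber constant all weights are one
    and the estimate equals ordinary least squares.
    """
    if t.size < 3:
        raise ValueError("window shorter than 3 samples")
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    for _ in range(n_iter):
        r = y - X @ beta
        scale = np.median(np.abs(r - np.median(r))) / 0.6745
        if scale < 1e-12:
            break
        u = np.abs(r) / scale
        w = np.where(u <= c, 1.0, c / u)
        Xw = X * w[:, None]
        new, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ y, rcond=None)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return float(beta[1])


def ramping_slope(
    hfa: Epochs, t_start: float | None = None, t_end: float = 0.0
) -> np.ndarray:
    """Robust single-trial HFA slope (z/s) from trial start to the HLL.

    With ``t_start=None`` each trial's own press time (relative to the
    epoch lock) is used. Returns trials x channels.
    """
    col = _EVENT_COLUMN[hfa.t0_event]
    slopes = np.empty((hfa.n_trials, hfa.n_channels))
    for i, row in enumerate(hfa.trial_meta.itertuples()):
        if t_start is None:
            start = row.t_press - getattr(row, col)
        else:
            start = t_start
        m = (hfa.times >= start) & (hfa.times <= t_end)
        if m.sum() < 3:
            raise ValueError("regression window shorter than 3 samples")
        tt = hfa.times[m]
        for ch in range(hfa.n_channels):
            slopes[i, ch] = huber_slope(tt, hfa.data[i, ch, m])
    return slopes


# ---------------------------------------------------------------------------
# peak-triggered average and inter-peak interval


def _sine(t, amp, freq, phase, offset):
    return amp * np.cos(2 * np.pi * freq * t + phase) + offset


def peak_triggered_average(
    raw_epochs: Epochs, peaks: PeakSet, half_width: float = 0.5
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Average unfiltered traces around HFA peaks, plus a 4-parameter sine fit.

    Returns ``(lags, pta, fit)`` where ``fit`` holds amplitude, frequency,
    phase, offset and a ``converged`` flag; frequency is initialized at the
    PTA's FFT peak and reported from the FFT if the fit fails.
    """
    fs = raw_epochs.fs
    hw = int(round(half_width * fs))
    segs = []
    it0 = -raw_epochs.times[0]  # seconds from epoch start to t=0
    for row in peaks.table.itertuples():
        center = int(round((row.time + it0) * fs))
        if center - hw < 0 or center + hw >= raw_epochs.data.shape[-1]:
            continue
        segs.append(raw_epochs.data[int(row.trial), int(row.channel), center - hw : center + hw + 1])
    if len(segs) < 10:
        raise ValueError("need at least 10 in-bounds peaks for a PTA")
    pta = np.mean(segs, axis=0)
    lags = np.arange(-hw, hw + 1) / fs

    spec = np.abs(np.fft.rfft(pta * np.hanning(pta.size), n=8 * pta.size))
    freqs = np.fft.rfftfreq(8 * pta.size, 1 / fs)
    f0 = float(freqs[1 + np.argmax(spec[1:])])
    # initial amplitude/phase from the projection onto the f0 carrier
    z = np.mean(pta * np.exp(-2j * np.pi * f0 * lags)) * 2
    p0 = [np.abs(z), f0, np.angle(z), float(pta.mean())]
    try:
        popt, _ = curve_fit(_sine, lags, pta, p0=p0, maxfev=5000)
        if popt[0] < 0:
            popt[0], popt[2] = -popt[0], popt[2] + np.pi
        popt[1] = abs(popt[1])
        popt[2] = (popt[2] + np.pi) % (2 * np.pi) - np.pi
        fit = dict(
            amplitude=popt[0], frequency=popt[1], phase=popt[2], offset=popt[3],
            converged=True,
        )
    except RuntimeError:
        fit = dict(amplitude=np.nan, frequency=f0, phase=np.nan, offset=np.nan,
                   converged=False)
    return lags, pta, fit


def inter_peak_interval(peaks: PeakSet) -> tuple[np.ndarray, float]:
    """Adjacent-peak intervals converted to instantaneous frequencies (Hz).

    Pooled across trials and channels; the distribution mean is the
    instantaneous frequency of the HFA amplitude modulation.
    """
    freqs = []
    for (_, _), grp in peaks.table.groupby(["trial", "channel"]):
        tt = np.sort(grp["time"].to_numpy())
        if tt.size >= 2:
            freqs.append(1.0 / np.diff(tt))
    if not freqs:
        raise UndefinedResultError("no trial contains two or more peaks")
    freqs = np.concatenate(freqs)
    return freqs, float(freqs.mean())
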