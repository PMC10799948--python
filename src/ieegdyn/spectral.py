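"""Spectral decomposition: multitaper TFR, IRASA, slopes, sample entropy.

The aperiodic ("1/f") and periodic components of iEEG spectra are separated
with irregular-resampling auto-spectral analysis (IRASA): resampling a time
series by a non-integer factor h leaves scale-free 1/f activity unchanged
but shifts any oscillatory peak, so the geometric mean of spectra resampled
by h and 1/h, aggregated over a set of factors, converges on the aperiodic
component. The spectral slope is then a log-log linear fit between
30 and 45 Hz, a band free of prominent oscillations.

Sample entropy quantifies signal irregularity as the negative log
conditional probability that template sequences matching for m points still
match for m+1 (Chebyshev distance, tolerance r x SD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import InvalidConfigError, UndefinedResultError
from .sigproc import Epochs, _baseline_masks, bootstrap_baseline_z

__all__ = [
    "Spectrum",
    "fft_spectrum",
    "irasa",
    "spectral_slope",
    "sample_entropy",
    "time_resolved_entropy",
    "multitaper_tfr",
    "TFR",
]

DEFAULT_HSET = tuple(np.round(np.arange(1.1, 1.91, 0.05), 10))
TFR_FREQS = tuple(np.geomspace(0.5, 128.0, 33))


@dataclass
class Spectrum:
    """Power spectrum; ``aperiodic``/``oscillatory`` filled by IRASA.

    Pointwise, oscillatory = power - aperiodic wherever both are present.
    """

    freqs: np.ndarray
    power: np.ndarray
    resolution: float
    aperiodic: np.ndarray | None = None
    oscillatory: np.ndarray | None = None


@dataclass
class TFR:
    """Baseline-z time-frequency representation: trials x channels x freqs x times."""

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    fs: float
    baseline_window: tuple


def _hann_psd(x: np.ndarray, fs: float, nfft: int, nperseg: int | None = None) -> np.ndarray:
    """Hanning Welch PSD normalized by the window energy (relative units).

    Segment averaging (50% overlap) tames the chi-square noise of single
    periodograms; without it the geometric mean of two noisy spectra is
    biased low by E[sqrt(P)]^2 < E[P], which inflates the oscillatory
    residual of a pure power law.
    """
    if nperseg is None or nperseg >= x.size:
        nperseg = x.size
    w = np.hanning(nperseg)
    hop = max(1, nperseg // 2)
    acc = np.zeros(nfft // 2 + 1)
    n_seg = 0
    for start in range(0, x.size - nperseg + 1, hop):
        X = np.fft.rfft(x[start : start + nperseg] * w, n=nfft)
        acc += np.abs(X) ** 2
        n_seg += 1
    acc /= n_seg
    acc[1:] *= 2.0
    if nfft % 2 == 0:
        acc[-1] /= 2.0
    return acc / (nfft * np.sum(w**2))


def fft_spectrum(segment: np.ndarray, fs: float, resolution: float = 0.25) -> Spectrum:
    """Hanning-tapered, zero-padded periodogram on a fixed frequency grid.

    Power is energy-scaled: the sum across the returned bins equals the
    energy of the windowed signal (Parseval).
    """
    x = np.asarray(segment, float)
    if x.size < 2:
        raise ValueError("segment too short")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    base = int(round(fs / resolution))
    nfft = base * int(np.ceil(x.size / base))
    w = np.hanning(x.size)
    X = np.fft.rfft(x * w, n=nfft)
    power = np.abs(X) ** 2
    power[1:] *= 2.0
    if nfft % 2 == 0:
        power[-1] /= 2.0
    power /= nfft
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    return Spectrum(freqs=freqs, power=power, resolution=fs / nfft)


def irasa(
    segment: np.ndarray,
    fs: float,
    hset: tuple = DEFAULT_HSET,
    resolution: float = 0.25,
) -> Spectrum:
    """Separate a spectrum into aperiodic and oscillatory components.

    For every resampling factor h the signal is resampled by h and 1/h
    (rational polyphase with anti-aliasing) and the geometric mean of the
    two spectra taken; the median across factors is the aperiodic
    component, and the oscillatory residual is total minus aperiodic.
    """
    hset = tuple(float(h) for h in hset)
    if any(abs(h - 1.0) < 1e-9 for h in hset):
        raise InvalidConfigError("hset must not contain 1.0")
    x = np.asarray(segment, float)
    h_max = max(hset)
    if x.size < 64 or x.size * (1.0 / h_max) < 8:
        raise ValueError("segment too short for the largest resampling pair")

    base = int(round(fs / resolution))
    n_longest = int(np.ceil(x.size * h_max))
    nfft = base * int(np.ceil(max(x.size, n_longest) / base))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    nperseg = min(x.size, int(round(4.0 * fs)))  # Welch segments up to 4 s
    total = _hann_psd(x, fs, nfft, nperseg)

    geo = np.empty((len(hset), freqs.size))
    for i, h in enumerate(hset):
        frac = Fraction(h).limit_denominator(100)
        up = sps.resample_poly(x, frac.numerator, frac.denominator)
        down = sps.resample_poly(x, frac.denominator, frac.numerator)
        geo[i] = np.sqrt(
            _hann_psd(up, fs, nfft, nperseg) * _hann_psd(down, fs, nfft, nperseg)
        )
    aperiodic = np.median(geo, axis=0)
    return Spectrum(
        freqs=freqs,
        power=total,
        resolution=fs / nfft,
        aperiodic=aperiodic,
        oscillatory=total - aperiodic,
    )


def spectral_slope(spectrum: Spectrum, band: tuple = (30.0, 45.0)) -> float:
    """OLS slope of log10(power) on log10(frequency) inside ``band``.

    Uses the aperiodic component when available, the total power otherwise.
    """
    y = spectrum.aperiodic if spectrum.aperiodic is not None else spectrum.power
    m = (spectrum.freqs >= band[0]) & (spectrum.freqs <= band[1]) & (y > 0)
    if m.sum() < 3:
        raise ValueError("fewer than 3 spectral points in band")
    lf = np.log10(spectrum.freqs[m])
    lp = np.log10(y[m])
    return float(np.polyfit(lf, lp, 1)[0])


# ---------------------------------------------------------------------------
# sample entropy


def sample_entropy(
    series: np.ndarray, m: int = 2, r: float = 0.2, tol: float | None = None
) -> float:
    """SampEn(m, r, N) = -log(A/B): A, B = template-pair match counts at
    lengths m+1 and m (Chebyshev distance, tolerance ``r x SD`` unless an
    absolute ``tol`` is given, self-matches excluded).

    A constant series returns 0; if no length-m pair matches the quantity is
    undefined and an error is raised.
    """
    x = np.asarray(series, float)
    n = x.size
    if n <= m + 1:
        raise ValueError("series shorter than m+2 samples")
    if tol is None:
        tol = r * x.std()
    n_templates = n - m
    d = np.abs(x[:, None] - x[None, :])
    # running Chebyshev distance over template offsets
    dm = np.zeros((n_templates, n_templates))
    for k in range(m):
        dm = np.maximum(dm, d[k : k + n_templates, k : k + n_templates])
    dm1 = np.maximum(dm, d[m : m + n_templates, m : m + n_templates])
    iu = np.triu_indices(n_templates, k=1)
    b = np.count_nonzero(dm[iu] <= tol)
    a = np.count_nonzero(dm1[iu] <= tol)
    if b == 0:
        raise UndefinedResultError("no template pair matches at length m")
    if a == 0:
        return float("inf")
    return float(-np.log(a / b))


def time_resolved_entropy(
    epochs: Epochs,
    m: int = 2,
    r: float = 0.2,
    win: float = 0.100,
    step: float = 0.020,
    smooth: float = 0.005,
    r_scope: str = "window",
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window sample entropy per trial and channel.

    ``r_scope='window'`` scales the tolerance to each window's own SD (the
    series under analysis); ``'global'`` fixes it to the whole-trial SD.
    A terminal boxcar of ``smooth`` seconds (at least one sample on the
    window grid) is applied. Undefined windows propagate as NaN.

    Returns ``(centers, ent)`` with ent trials x channels x windows.
    """
    if r_scope not in ("window", "global"):
        raise InvalidConfigError("r_scope must be 'window' or 'global'")
    nw = int(round(win * epochs.fs))
    if nw < m + 2:
        raise ValueError("window shorter than m+2 samples")
    hop = max(1, int(round(step * epochs.fs)))
    starts = np.arange(0, epochs.data.shape[-1] - nw + 1, hop)
    centers = epochs.times[starts] + (nw - 1) / (2 * epochs.fs)
    ent = np.full((epochs.n_trials, epochs.n_channels, starts.size), np.nan)
    for i in range(epochs.n_trials):
        for ch in range(epochs.n_channels):
            trace = epochs.data[i, ch]
            g_tol = r * trace.std() if r_scope == "global" else None
            for k, s in enumerate(starts):
                seg = trace[s : s + nw]
                try:
                    val = sample_entropy(seg, m=m, r=r, tol=g_tol)
                    # no length-(m+1) match (inf) propagates as missing too
                    ent[i, ch, k] = val if np.isfinite(val) else np.nan
                except UndefinedResultError:
                    pass
    width = max(1, int(round(smooth / step)))
    if width > 1:
        kernel = np.ones(width) / width
        ent = np.apply_along_axis(
            lambda v: np.convolve(v, kernel, mode="same"), -1, ent
        )
    return centers, ent


# ---------------------------------------------------------------------------
# multitaper time-frequency decomposition


def _taper_bank(f: float, fs: float, taper: str) -> np.ndarray:
    """Window(s) for one frequency: >=200 ms or 2 cycles; DPSS count from
    half-bandwidth max(f/8, 1/window) via K = floor(2*T*W) - 1."""
    win_len = max(0.2, 2.0 / f)
    n = int(round(win_len * fs))
    if taper == "hann":
        w = np.hanning(n)
        return w[None, :] / np.linalg.norm(w)
    half_bw = max(f / 8.0, 1.0 / win_len)
    tw = win_len * half_bw
    k = max(1, int(np.floor(2 * tw)) - 1)
    tapers = sps.windows.dpss(n, max(tw, 1.0), Kmax=k)
    return np.atleast_2d(tapers)


def multitaper_tfr(
    epochs: Epochs,
    freqs: tuple = TFR_FREQS,
    baseline: tuple = (-0.4, -0.1),
    n_boot: int = 1000,
    seed: int = 0,
    t_step: float = 0.010,
    taper: str = "dpss",
    zscore: bool = True,
) -> TFR:
    """Slepian multitaper power, z-normalized per frequency bin against a
    bootstrapped pre-cue baseline distribution (pooled across trials).

    Smoothing approximates a 200 ms time window with quarter-octave
    frequency smoothing; frequencies at or above Nyquist are dropped with a
    warning. ``taper='hann'`` gives the single-taper special case.
    """
    freqs = np.asarray(freqs, float)
    ok = freqs < epochs.fs / 2
    if not ok.all():
        warnings.warn("dropping frequencies at or above Nyquist")
        freqs = freqs[ok]
    fs = epochs.fs
    hop = max(1, int(round(t_step * fs)))
    sel = np.arange(0, epochs.data.shape[-1], hop)
    times = epochs.times[sel]
    flat = epochs.data.reshape(-1, epochs.data.shape[-1])

    values = np.empty(
        (epochs.n_trials, epochs.n_channels, freqs.size, sel.size), dtype=np.float32
    )
    t_full = np.empty((flat.shape[0], epochs.data.shape[-1]))
    for fi, f in enumerate(freqs):
        tapers = _taper_bank(f, fs, taper)
        n = tapers.shape[1]
        carrier = np.exp(-2j * np.pi * f * np.arange(n) / fs)
        t_full[:] = 0.0
        for tp in tapers:
            kern = (tp * carrier)[::-1].conj()
            conv = sps.fftconvolve(flat, kern[None, :], mode="same", axes=1)
            t_full += np.abs(conv) ** 2
        t_full /= tapers.shape[0]
        values[:, :, fi, :] = t_full[:, sel].reshape(
            epochs.n_trials, epochs.n_channels, -1
        )

    if zscore:
        rng = np.random.default_rng(seed)
        masks = [m[sel] for m in _baseline_masks(epochs, baseline)]
        for ch in range(epochs.n_channels):
            for fi in range(freqs.size):
                pool = np.concatenate(
                    [values[i, ch, fi, m] for i, m in enumerate(masks)]
                ).astype(float)
                values[:, ch, fi, :] = bootstrap_baseline_z(
                    values[:, ch, fi, :].astype(float), pool, n_boot, rng
                )
    return TFR(values=values, freqs=freqs, times=times, fs=fs, baseline_window=tuple(baseline))
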