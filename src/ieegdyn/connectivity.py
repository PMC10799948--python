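"""Prefrontal-motor coupling: imaginary PLV, phase-slope index, PC power
correlations.

The imaginary phase-locking value

    iPLV_f = | imag( n^-1 sum_t exp(i (phi_x(t) - phi_y(t))) ) |

discards zero-phase-lag coupling (volume conduction). Directionality uses
the phase-slope index (PSI): the imaginary part of sum_f conj(C(f)) C(f+df)
of the complex coherency C over a band around the pair's iPLV peak; a
positive value means the first channel leads. Both statistics are
z-normalized against permutation nulls (trial shuffling for iPLV,
frequency shuffling for PSI), with the permutation values resampled with
replacement to smooth the null before taking its mean and SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .sigproc import bandpass_fir

__all__ = [
    "iplv_spectrum",
    "find_iplv_peak",
    "select_behavioral_electrode",
    "psi",
    "DirectedEstimate",
    "pc_power_correlation",
]

IPLV_FREQS = tuple(3.0 * 2 ** (np.arange(28) / 8.0))  # 3-32 Hz, 2^(1/8) steps


def _trial_phases(x: np.ndarray, fs: float, f: float) -> np.ndarray:
    lo, hi = f - f / 4.0, f + f / 4.0
    filt = bandpass_fir(x, fs, lo, hi, axis=-1)
    return np.angle(sps.hilbert(filt, axis=-1))


def _iplv(phix: np.ndarray, phiy: np.ndarray) -> np.ndarray:
    """Per-trial |imag(mean_t e^{i dphi})|; inputs trials x time."""
    return np.abs(np.imag(np.mean(np.exp(1j * (phix - phiy)), axis=-1)))


def iplv_spectrum(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    freqs: tuple = IPLV_FREQS,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Permutation-z-normalized iPLV per center frequency.

    ``x``/``y``: trials x time for the two channels. The null mismatches
    trial pairings (x from trial i, y from a shuffled trial), and the
    permutation values are bootstrap-resampled before z-normalization.
    Returns ``(freqs, z_iplv, raw_iplv)``.
    """
    if x.shape[0] < 10:
        raise ValueError("need at least 10 trials")
    rng = np.random.default_rng(seed)
    freqs = np.asarray([f for f in freqs if f * 1.25 < fs / 2])
    if freqs.size < len(tuple(IPLV_FREQS)) and freqs.size == 0:
        raise ValueError("all frequencies above Nyquist")
    z = np.empty(freqs.size)
    raw = np.empty(freqs.size)
    n_trials = x.shape[0]
    for i, f in enumerate(freqs):
        phix = _trial_phases(x, fs, f)
        phiy = _trial_phases(y, fs, f)
        raw[i] = _iplv(phix, phiy).mean()
        null = np.empty(n_perm)
        for p in range(n_perm):
            perm = rng.permutation(n_trials)
            null[p] = _iplv(phix, phiy[perm]).mean()
        draws = null[rng.integers(0, n_perm, size=n_boot)]
        sd = draws.std()
        z[i] = (raw[i] - draws.mean()) / (sd if sd > 0 else 1.0)
    return freqs, z, raw


def find_iplv_peak(
    freqs: np.ndarray, spectrum: np.ndarray, frange: tuple = (2.0, 13.0)
) -> float | None:
    """Distinct iPLV peak: a local maximum exceeding both neighbors and the
    spectrum median, within ``frange``. ``None`` means the pair is discarded."""
    med = np.median(spectrum)
    best_f, best_v = None, -np.inf
    for i in range(1, freqs.size - 1):
        if not (frange[0] <= freqs[i] <= frange[1]):
            continue
        v = spectrum[i]
        if v > spectrum[i - 1] and v > spectrum[i + 1] and v > med and v > best_v:
            best_f, best_v = float(freqs[i]), v
    return best_f


def select_behavioral_electrode(
    latency_table, rt: np.ndarray
) -> tuple[int, dict]:
    """Motor channel whose HFA peak latency explains most RT variance.

    ``latency_table``: DataFrame with trial/channel/latency columns (from
    peak metrics). R^2 is the squared Pearson correlation of the
    single-regressor model; ties resolve to the lowest channel index.
    """
    rt = np.asarray(rt, float)
    r2 = {}
    for ch, grp in latency_table.groupby("channel"):
        idx = grp["trial"].to_numpy().astype(int)
        lat = grp["latency"].to_numpy()
        ok = np.isfinite(rt[idx])
        if ok.sum() < 10:
            continue
        r = np.corrcoef(lat[ok], rt[idx][ok])[0, 1]
        r2[int(ch)] = 0.0 if np.isnan(r) else float(r**2)
    if not r2:
        raise ValueError("no channel with >=10 complete trials")
    best = max(sorted(r2), key=lambda c: r2[c])  # sorted => ties to lowest index
    return best, r2


@dataclass
class DirectedEstimate:
    pair: tuple
    peak_freq: float
    psi_raw: float
    z_psi: float  # positive = first channel leads


def _coherency(
    x: np.ndarray, y: np.ndarray, fs: float, pad: float = 2.0, nw: float = 2.5, kmax: int = 4
):
    """Complex coherency from trial- and taper-averaged cross-spectra.

    Slepian tapers keep sidelobe leakage from a strong narrowband peak out
    of the neighboring bins; with a single Hanning taper that leakage
    systematically distorts the cross-spectral phase at the band edges,
    which the phase-slope index is directly sensitive to.
    """
    n = x.shape[1]
    tapers = sps.windows.dpss(n, nw, Kmax=kmax)
    nfft = n + 2 * int(round(pad * fs))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    sxy = np.zeros(freqs.size, complex)
    sxx = np.zeros(freqs.size)
    syy = np.zeros(freqs.size)
    for tp in tapers:
        X = np.fft.rfft(x * tp, n=nfft, axis=1)
        Y = np.fft.rfft(y * tp, n=nfft, axis=1)
        sxy += np.mean(X * np.conj(Y), axis=0)
        sxx += np.mean(np.abs(X) ** 2, axis=0)
        syy += np.mean(np.abs(Y) ** 2, axis=0)
    return freqs, sxy / np.sqrt(sxx * syy + 1e-300)


def psi(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    peak_freq: float,
    half_band: float = 3.0,
    n_perm: int = 1000,
    seed: int = 0,
    pair: tuple = (0, 0),
) -> DirectedEstimate:
    """Phase-slope index over ``peak_freq`` +- ``half_band`` Hz.

    PSI = imag( sum_f conj(C(f)) C(f + df) ) with df one frequency bin;
    the null shuffles the within-band frequency ordering of the coherency
    and recomputes. Swapping the channel order exactly negates psi_raw.
    """
    rng = np.random.default_rng(seed)
    freqs, C = _coherency(x, y, fs)
    lo, hi = peak_freq - half_band, peak_freq + half_band
    if lo < freqs[1] or hi > freqs[-2]:
        warnings.warn("PSI band clipped at spectrum edge")
        lo, hi = max(lo, freqs[1]), min(hi, freqs[-2])
    band = np.flatnonzero((freqs >= lo) & (freqs <= hi))
    Cb = C[band]

    def _psi(cvals):
        return float(np.imag(np.sum(np.conj(cvals[:-1]) * cvals[1:])))

    raw = _psi(Cb)
    null = np.array([_psi(Cb[rng.permutation(Cb.size)]) for _ in range(n_perm)])
    sd = null.std()
    z = (raw - null.mean()) / (sd if sd > 0 else 1.0)
    return DirectedEstimate(pair=pair, peak_freq=peak_freq, psi_raw=raw, z_psi=z)


def pc_power_correlation(
    trace_a: np.ndarray,
    trace_b: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Trial-wise correlation between two component traces, z-normalized by
    a circular trial-block-swap null.

    ``trace_a``/``trace_b``: trials x time, already cropped to the analysis
    window. Returns ``(raw_mean_corr, z)``.
    """
    if trace_a.shape != trace_b.shape:
        raise ValueError("traces must be trial-aligned")
    n = trace_a.shape[0]
    if n < 10:
        raise ValueError("need at least 10 trials")
    rng = np.random.default_rng(seed)

    a = trace_a - trace_a.mean(axis=1, keepdims=True)
    b = trace_b - trace_b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    a /= na[:, None]
    b /= nb[:, None]
    corr = np.sum(a * b, axis=1)
    obs = float(corr.mean())

    null = np.empty(n_perm)
    for i in range(n_perm):
        shift = rng.integers(1, n)
        null[i] = np.mean(np.sum(a * np.roll(b, shift, axis=0), axis=1))
    sd = null.std()
    z = (obs - null.mean()) / (sd if sd > 0 else 1.0)
    return obs, float(z)
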