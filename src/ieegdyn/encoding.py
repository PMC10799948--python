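"""Context-dependent neural information (omega squared) and electrode selection.

A sliding one-way ANOVA quantifies, per channel and time window, the
fraction of trial-to-trial HFA variance explained by the predictive
context, using the bias-corrected effect size

    omega^2 = (SS_between - df * MSE) / (SS_total + MSE),  df = G - 1,

which may be negative under the null and is reported as-is. Channels become
stage-1 candidates when a sufficiently long consecutive run of windows
shows a significant context effect; stage 2 applies PCA to the candidates'
F-value time series and keeps channels loading strongly on components whose
explained variance beats a temporal-shuffle null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from .sigproc import Epochs

__all__ = [
    "InfoTimeSeries",
    "anova_effect",
    "sliding_anova",
    "consecutive_criterion",
    "pca_context_selection",
    "PcaSelection",
]


@dataclass
class InfoTimeSeries:
    """Per-channel omega^2 / F / p time courses on a uniform window grid."""

    centers: np.ndarray  # window centers, s relative to the epoch lock
    omega2: np.ndarray  # channels x windows
    F: np.ndarray
    p: np.ndarray
    labels: np.ndarray  # per-trial context labels used


def anova_effect(values: np.ndarray, labels: np.ndarray) -> tuple:
    """One-way ANOVA along axis 0 of ``values`` (trials x ...).

    Returns ``(F, p, omega2)`` broadcast over the trailing axes. Requires at
    least two groups with two or more trials each.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least two groups")
    n = values.shape[0]
    counts = np.array([(labels == g).sum() for g in groups])
    if (counts < 2).any():
        raise ValueError("every group needs at least two trials")
    grand = values.mean(axis=0)
    ss_total = ((values - grand) ** 2).sum(axis=0)
    ss_between = np.zeros_like(grand)
    for g, ng in zip(groups, counts):
        gm = values[labels == g].mean(axis=0)
        ss_between = ss_between + ng * (gm - grand) ** 2
    df = groups.size - 1
    df_err = n - groups.size
    mse = (ss_total - ss_between) / df_err
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df) / mse
        omega2 = (ss_between - df * mse) / (ss_total + mse)
    p = spstats.f.sf(F, df, df_err)
    return F, p, omega2


def sliding_anova(
    hfa: Epochs,
    labels: np.ndarray | None = None,
    win: float = 0.050,
    step: float = 0.002,
    tmin: float | None = None,
    tmax: float | None = None,
) -> InfoTimeSeries:
    """omega^2 / F / p per channel on a sliding-window grid.

    One observation per trial per window (the window mean). Both correct
    and incorrect go trials enter; ``labels`` defaults to the trial table's
    context column.
    """
    if labels is None:
        labels = hfa.trial_meta["context"].to_numpy()
    nw = max(2, int(round(win * hfa.fs)))
    hop = max(1, int(round(step * hfa.fs)))
    t = hfa.times
    lo = t[0] if tmin is None else tmin
    hi = t[-1] if tmax is None else tmax
    starts = np.arange(np.searchsorted(t, lo), np.searchsorted(t, hi, "right") - nw + 1, hop)
    if starts.size == 0:
        raise ValueError("analysis segment shorter than one window")
    centers = t[starts] + (nw - 1) / (2 * hfa.fs)
    cs = np.concatenate(
        [np.zeros(hfa.data.shape[:2] + (1,)), np.cumsum(hfa.data, axis=-1)], axis=-1
    )
    means = (cs[..., starts + nw] - cs[..., starts]) / nw  # trials x ch x windows
    F, p, om = anova_effect(means, labels)
    return InfoTimeSeries(centers=centers, omega2=om, F=F, p=p, labels=np.asarray(labels))


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def consecutive_criterion(
    info: InfoTimeSeries, alpha: float = 0.05, frac: float = 0.10
) -> np.ndarray:
    """Stage-1 mask: a run of >= ``frac`` x windows with p < alpha."""
    n_win = info.p.shape[1]
    need = int(np.ceil(frac * n_win))
    return np.array([_longest_run(row < alpha) >= need for row in info.p])


@dataclass
class PcaSelection:
    encoding_mask: np.ndarray
    surviving_pcs: np.ndarray
    loadings: np.ndarray  # channels x components (scores on temporal PCs)
    explained_variance: np.ndarray
    null_95: np.ndarray


def _ev_spectrum(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Explained-variance fractions and channel scores of a channels x time
    matrix, time features centered across channels."""
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    ev = S**2 / np.sum(S**2)
    return ev, U * S  # channel scores on each PC


def pca_context_selection(
    F_matrix: np.ndarray,
    n_perm: int = 1000,
    weight_pct: float = 75.0,
    var_pct: float = 95.0,
    seed: int = 0,
) -> PcaSelection:
    """Stage-2 mask from PCA of candidate channels' F time series.

    The null shuffles each channel's F series independently across time and
    records the explained-variance spectrum; a PC survives when its
    variance fraction exceeds the null's ``var_pct`` percentile at the same
    rank. A channel is context-encoding when its |loading| reaches the
    ``weight_pct`` percentile on any surviving PC. An empty mask (no PC
    survives) is a valid outcome.
    """
    F_matrix = np.asarray(F_matrix, float)
    if F_matrix.shape[0] < 2:
        raise ValueError("need at least two candidate channels")
    rng = np.random.default_rng(seed)
    ev, scores = _ev_spectrum(F_matrix)
    null = np.empty((n_perm, ev.size))
    shuffled = F_matrix.copy()
    for i in range(n_perm):
        for ch in range(shuffled.shape[0]):
            rng.shuffle(shuffled[ch])
        null[i] = _ev_spectrum(shuffled)[0]
    null_95 = np.percentile(null, var_pct, axis=0)
    # sequential acceptance (as in parallel analysis): stop at the first
    # rank that fails its null, which keeps the no-structure false-alarm
    # rate at the per-rank alpha instead of compounding across ranks
    k = 0
    while k < ev.size and ev[k] > null_95[k]:
        k += 1
    surviving = np.arange(k)
    mask = np.zeros(F_matrix.shape[0], bool)
    for pc in surviving:
        w = np.abs(scores[:, pc])
        mask |= w >= np.percentile(w, weight_pct)
    return PcaSelection(
        encoding_mask=mask,
        surviving_pcs=surviving,
        loadings=scores,
        explained_variance=ev,
        null_95=null_95,
    )
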