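"""Population state-space analyses: PCA trajectories, distances, decoding.

Population HFA at each time point is a point in channel space; PCA over
all (trial, time) observations yields a low-dimensional manifold (the
components cumulatively explaining 99% of variance are kept). Linear
discriminant classifiers applied per principal component and time point
identify the coding dimensions for predictive context and for action (RT
terciles); the winning component maximizes the largest supra-chance
cluster of decoding accuracy and is validated against a label-permutation
null. Cross-regional generalization trains at prefrontal time points and
tests at motor time points; trial-wise cross-correlation gives the
temporal lag between regional subspaces (negative = motor lags prefrontal
cortex).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import UndefinedResultError
from .sigproc import Epochs
from .spectral import irasa

__all__ = [
    "StateSpace",
    "CodingDimension",
    "build_state_space",
    "trajectory_distance",
    "state_transitions",
    "decode_timecourse",
    "find_coding_dimension",
    "cross_region_generalization",
    "trajectory_lag",
    "find_theta_pc",
    "rt_terciles",
]


@dataclass
class StateSpace:
    scores: np.ndarray  # trials x components x time
    loadings: np.ndarray  # channels x components, orthonormal columns
    explained_variance: np.ndarray  # fractions, descending
    kept: int  # components cumulating 99% variance
    times: np.ndarray
    fs: float
    alignment: str


@dataclass
class CodingDimension:
    target: str
    pc_index: int
    accuracy: np.ndarray  # winning PC's smoothed decoding time series
    accuracy_by_pc: np.ndarray  # kept PCs x time, smoothed, unthresholded
    cluster_mass: float
    null_95: float
    valid: bool
    chance: float


def build_state_space(hfa: Epochs, var_keep: float = 0.99) -> StateSpace:
    """Channel-centered PCA over all (time, trial) observations."""
    data = hfa.data
    n_trials, n_ch, n_t = data.shape
    if n_trials * n_t < n_ch:
        raise ValueError("fewer observations than channels")
    X = data.transpose(1, 0, 2).reshape(n_ch, -1)
    Xc = X - X.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T / (Xc.shape[1] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    ev = evals / evals.sum() if evals.sum() > 0 else evals
    kept = int(np.searchsorted(np.cumsum(ev), var_keep) + 1)
    kept = min(kept, n_ch)
    scores = (evecs.T @ Xc).reshape(n_ch, n_trials, n_t).transpose(1, 0, 2)
    return StateSpace(
        scores=scores,
        loadings=evecs,
        explained_variance=ev,
        kept=kept,
        times=hfa.times,
        fs=hfa.fs,
        alignment=hfa.t0_event,
    )


def _window_means(data: np.ndarray, fs: float, times: np.ndarray, win: float, hop: float):
    nw = max(1, int(round(win * fs)))
    nh = max(1, int(round(hop * fs)))
    starts = np.arange(0, data.shape[-1] - nw + 1, nh)
    cs = np.concatenate(
        [np.zeros(data.shape[:-1] + (1,)), np.cumsum(data, axis=-1)], axis=-1
    )
    means = (cs[..., starts + nw] - cs[..., starts]) / nw
    centers = times[starts] + (nw - 1) / (2 * fs)
    return means, centers


def _boxcar(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    return np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), -1, x)


def trajectory_distance(
    hfa: Epochs,
    labels: np.ndarray | None = None,
    win: float = 0.050,
    step: float = 0.020,
    smooth: float = 0.025,
) -> tuple[np.ndarray, np.ndarray]:
    """Summed pairwise Euclidean distance between condition-mean trajectories.

    Euclidean norms over channels make the result invariant to channel
    permutation and rotation of the channel basis.
    """
    if labels is None:
        labels = hfa.trial_meta["context"].to_numpy()
    labels = np.asarray(labels)
    conds = np.unique(labels)
    if conds.size < 2:
        raise ValueError("need at least two conditions")
    means, centers = _window_means(hfa.data, hfa.fs, hfa.times, win, step)
    cond_means = np.stack([means[labels == c].mean(axis=0) for c in conds])  # C x ch x W
    dist = np.zeros(cond_means.shape[-1])
    for i in range(conds.size):
        for j in range(i + 1, conds.size):
            dist += np.linalg.norm(cond_means[i] - cond_means[j], axis=0)
    width = max(1, int(round(smooth / step)))
    return centers, _boxcar(dist[None, :], width)[0]


def state_transitions(
    hfa: Epochs, win: float = 0.050, overlap: float = 0.020
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial Euclidean distance between adjacent overlapping windows."""
    hop = win - overlap
    means, centers = _window_means(hfa.data, hfa.fs, hfa.times, win, hop)
    if means.shape[-1] < 2:
        raise ValueError("need at least two windows")
    trans = np.linalg.norm(np.diff(means, axis=-1), axis=1)  # trials x (W-1)
    return centers[1:], trans


# ---------------------------------------------------------------------------
# decoding


def rt_terciles(rt: np.ndarray) -> np.ndarray:
    """Split RTs into terciles; ties fall toward the lower tercile."""
    rt = np.asarray(rt, float)
    q1, q2 = np.quantile(rt, [1 / 3, 2 / 3])
    return (rt > q1).astype(int) + (rt > q2).astype(int)


def _lda1d_predict(
    train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray, classes: np.ndarray,
    ridge: float,
) -> np.ndarray:
    """Gaussian LDA with a single feature per time point, vectorized over time.

    train_x/test_x: trials x time. Returns predicted class per test trial
    and time. Pooled within-class variance gets a small ridge for stability.
    """
    n_t = train_x.shape[1]
    mus = np.stack([train_x[train_y == c].mean(axis=0) for c in classes])  # C x T
    resid = train_x - mus[np.searchsorted(classes, train_y)]
    var = (resid**2).sum(axis=0) / max(1, train_x.shape[0] - classes.size) + ridge
    # uniform priors: decoding chance stays 1/n_classes under trial imbalance
    disc = test_x[:, None, :] * (mus / var)[None] - (mus**2 / (2 * var))[None]
    return classes[np.argmax(disc, axis=1)]  # trials x T


def decode_timecourse(
    scores: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    repeats: int = 5,
    ridge: float = 1e-4,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Time-resolved k-fold cross-validated LDA accuracy on one component.

    ``scores``: trials x time. Folds are re-drawn ``repeats`` times and the
    accuracy time courses averaged.
    """
    if rng is None:
        rng = np.random.default_rng()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    n = scores.shape[0]
    acc = np.zeros(scores.shape[1])
    for _ in range(repeats):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        hits = np.zeros(scores.shape[1])
        for f in folds:
            train = np.setdiff1d(perm, f, assume_unique=False)
            pred = _lda1d_predict(
                scores[train], labels[train], scores[f], classes, ridge
            )
            hits += (pred == labels[f][:, None]).sum(axis=0)
        acc += hits / n
    return acc / repeats


def _largest_cluster_mass(trace: np.ndarray, chance: float) -> tuple[float, slice]:
    """Sum of accuracies in the largest supra-chance run (earlier run wins ties)."""
    above = trace > chance
    best, best_span, cur, start = 0.0, slice(0, 0), 0.0, None
    for i, flag in enumerate(above):
        if flag:
            if start is None:
                start, cur = i, 0.0
            cur += trace[i]
        elif start is not None:
            if cur > best:
                best, best_span = cur, slice(start, i)
            start = None
    if start is not None and cur > best:
        best, best_span = cur, slice(start, above.size)
    return best, best_span


def find_coding_dimension(
    space: StateSpace,
    labels: np.ndarray,
    target: str = "context",
    k: int = 10,
    repeats: int = 5,
    n_perm: int = 50,
    smooth: float = 0.025,
    ridge: float = 1e-4,
    seed: int = 0,
) -> CodingDimension:
    """Identify the principal component coding for ``labels``.

    Per kept PC: time-resolved CV accuracy, boxcar-smoothed, thresholded at
    chance with below-chance values zeroed; the PC with the largest
    supra-chance cluster mass wins (ties to the lower PC index). Validity:
    the winning mass must exceed the 95th percentile of ``n_perm``
    label-shuffle recomputations on the winning PC.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    chance = 1.0 / np.unique(labels).size
    width = max(1, int(round(smooth * space.fs)))
    acc_by_pc = np.stack(
        [
            _boxcar(
                decode_timecourse(space.scores[:, pc, :], labels, k, repeats, ridge, rng)[None],
                width,
            )[0]
            for pc in range(space.kept)
        ]
    )
    masses, spans = zip(
        *[_largest_cluster_mass(acc_by_pc[pc], chance) for pc in range(space.kept)]
    )
    winner = int(np.argmax(masses))
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = rng.permutation(labels)
        trace = _boxcar(
            decode_timecourse(space.scores[:, winner, :], shuffled, k, repeats, ridge, rng)[None],
            width,
        )[0]
        null[i] = _largest_cluster_mass(trace, chance)[0]
    null_95 = float(np.percentile(null, 95))
    mass = float(masses[winner])
    return CodingDimension(
        target=target,
        pc_index=winner,
        accuracy=acc_by_pc[winner],
        accuracy_by_pc=acc_by_pc,
        cluster_mass=mass,
        null_95=null_95,
        valid=bool(mass > null_95),
        chance=chance,
    )


def cross_region_generalization(
    scores_train: np.ndarray,
    scores_test: np.ndarray,
    labels: np.ndarray,
    ridge: float = 1e-4,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Train at every source time point, test at every target time point.

    Both inputs are trials x time single-component scores for the same
    trials (no cross-validation: the datasets are independent). Returns the
    time x time accuracy matrix plus a cluster-corrected significance mask
    versus chance (label-permutation maximum-cluster-mass null,
    4-connectivity).
    """
    from scipy import ndimage

    labels = np.asarray(labels)
    if scores_train.shape[0] != labels.size or scores_test.shape[0] != labels.size:
        raise ValueError("label/trial mismatch between regions")
    classes = np.unique(labels)
    chance = 1.0 / classes.size

    def _matrix(lab):
        mus = np.stack([scores_train[lab == c].mean(axis=0) for c in classes])
        resid = scores_train - mus[np.searchsorted(classes, lab)]
        var = (resid**2).sum(axis=0) / max(1, lab.size - classes.size) + ridge
        out = np.empty((scores_train.shape[1], scores_test.shape[1]))
        for t in range(scores_train.shape[1]):
            disc = (
                scores_test[:, None, :] * (mus[:, t] / var[t])[None, :, None]
                - (mus[:, t] ** 2 / (2 * var[t]))[None, :, None]
            )
            pred = classes[np.argmax(disc, axis=1)]
            out[t] = (pred == lab[:, None]).mean(axis=0)
        return out

    def _max_mass(mat):
        lab_img, n = ndimage.label(mat > chance)
        if n == 0:
            return 0.0, None
        sums = ndimage.sum_labels(mat, lab_img, index=np.arange(1, n + 1))
        return float(sums.max()), lab_img == (1 + int(np.argmax(sums)))

    acc = _matrix(labels)
    obs_mass, _ = _max_mass(acc)
    rng = np.random.default_rng(seed)
    null = np.array([_max_mass(_matrix(rng.permutation(labels)))[0] for _ in range(n_perm)])
    thresh = np.percentile(null, 100 * (1 - alpha))
    lab_img, n = ndimage.label(acc > chance)
    sig = np.zeros_like(acc, bool)
    pvals = []
    for c in range(1, n + 1):
        mass = float(acc[lab_img == c].sum())
        p = (1 + np.sum(null >= mass)) / (n_perm + 1)
        pvals.append(p)
        if mass > thresh:
            sig |= lab_img == c
    return {"accuracy": acc, "significant": sig, "cluster_p": pvals, "chance": chance,
            "max_mass": obs_mass}


def trajectory_lag(
    pc_a: np.ndarray, pc_b: np.ndarray, fs: float
) -> tuple[float, np.ndarray]:
    """Mean trial-wise cross-correlation lag between two component traces.

    Negative lags mean the second trace (e.g. the motor subspace) lags the
    first (prefrontal). Zero-variance trials are skipped.
    """
    if pc_a.shape != pc_b.shape:
        raise ValueError("traces must be equal-length and trial-aligned")
    n_t = pc_a.shape[1]
    lags = []
    for a, b in zip(pc_a, pc_b):
        if a.std() < 1e-12 or b.std() < 1e-12:
            continue
        an = (a - a.mean()) / (a.std() * np.sqrt(n_t))
        bn = (b - b.mean()) / (b.std() * np.sqrt(n_t))
        c = np.correlate(an, bn, mode="full")
        lags.append((np.argmax(c) - (n_t - 1)) / fs)
    if not lags:
        raise UndefinedResultError("all trials flat; lag undefined")
    lags = np.asarray(lags)
    return float(lags.mean()), lags


def find_theta_pc(
    space: StateSpace,
    band: tuple = (2.0, 13.0),
    max_trials: int | None = None,
) -> tuple[int, np.ndarray]:
    """Component with the strongest oscillatory power in ``band``.

    Per kept PC, IRASA is run on every single-trial score trace, the
    oscillatory residual averaged across trials and integrated over the
    band; the argmax component is returned along with the per-PC band
    powers.
    """
    n_trials = space.scores.shape[0]
    take = range(n_trials) if max_trials is None else range(min(max_trials, n_trials))
    powers = np.zeros(space.kept)
    for pc in range(space.kept):
        acc = None
        for i in take:
            spec = irasa(space.scores[i, pc], space.fs)
            osc = np.clip(spec.oscillatory, 0, None)
            m = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
            val = np.trapezoid(osc[m], spec.freqs[m])
            acc = val if acc is None else acc + val
        powers[pc] = acc / len(list(take))
    if np.allclose(powers, 0):
        raise UndefinedResultError("no oscillatory residual in any component")
    return int(np.argmax(powers)), powers
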