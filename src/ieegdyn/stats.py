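"""Cross-cutting inference: cluster permutation, bootstrap balancing,
binomial and signal-detection statistics, behavioral summaries.

The cluster-based permutation test controls family-wise error over time
(or frequency, or time x frequency) maps: sample-wise dependent t tests
(or repeated-measures F for three conditions) are thresholded at alpha,
supra-threshold neighbors form clusters whose mass is the summed
statistic, and the observed masses are ranked against the maximum-mass
distribution under sign flipping (t) or within-unit label permutation (F).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage
from scipy import stats as spstats

__all__ = [
    "ClusterResult",
    "cluster_permutation",
    "bootstrap_balance",
    "binomial_two_sided",
    "sdt",
    "SdtResult",
    "behavior_summary",
    "neuro_behavior_regression",
]


@dataclass
class ClusterResult:
    clusters: list = field(default_factory=list)  # dicts: mask, mass, p
    stat: np.ndarray | None = None
    threshold: float = np.nan
    n_perm: int = 0
    exact: bool = False

    @property
    def min_p(self) -> float:
        return min((c["p"] for c in self.clusters), default=1.0)


def _paired_t(diff: np.ndarray) -> np.ndarray:
    """Dependent t over axis 0 (units)."""
    n = diff.shape[0]
    m = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return m / (sd / np.sqrt(n))


def _rm_f(data: np.ndarray) -> np.ndarray:
    """One-way repeated-measures F; data: conditions x units x ..."""
    c, n = data.shape[0], data.shape[1]
    grand = data.mean(axis=(0, 1))
    cond_m = data.mean(axis=1)
    unit_m = data.mean(axis=0)
    ss_cond = n * ((cond_m - grand) ** 2).sum(axis=0)
    resid = data - cond_m[:, None] - unit_m[None] + grand
    ss_err = (resid**2).sum(axis=(0, 1))
    df1, df2 = c - 1, (c - 1) * (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ss_cond / df1) / (ss_err / df2)


def _clusters_from_stat(stat: np.ndarray, thresh: float, signed: bool):
    """Label supra-threshold clusters (4-connectivity in 2D); returns
    (mask, mass) pairs with mass = summed statistic."""
    out = []
    stat = np.atleast_1d(stat)
    sides = [(stat >= thresh, 1.0)]
    if signed:
        sides.append((stat <= -thresh, -1.0))
    for mask, sign in sides:
        lab, n = ndimage.label(mask)
        for k in range(1, n + 1):
            m = lab == k
            out.append((m, float(stat[m].sum()) * 1.0))
    return out


def _max_mass(stat: np.ndarray, thresh: float, signed: bool) -> float:
    masses = [abs(m) for _, m in _clusters_from_stat(stat, thresh, signed)]
    return max(masses, default=0.0)


def cluster_permutation(
    conditions: list,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-based permutation test over 2 (paired t) or 3+ (RM F)
    conditions; each condition array is units x map-dims.

    Two conditions use sign flipping of unit-wise differences (exhaustive
    enumeration when 2^units <= n_perm, so small samples degenerate to the
    exact permutation t test); three or more permute condition labels
    within units. Cluster p values are exceedance proportions of the
    maximum-mass null, two-tailed for t.
    """
    data = np.stack([np.asarray(c, float) for c in conditions])
    n_cond, n_units = data.shape[0], data.shape[1]
    if n_units < 5:
        raise ValueError("need at least 5 paired units")
    rng = np.random.default_rng(seed)

    if n_cond == 2:
        diff = data[0] - data[1]
        stat = _paired_t(diff)
        thresh = spstats.t.ppf(1 - alpha / 2, n_units - 1)
        signed = True
        exact = 2**n_units <= n_perm
        if exact:
            flips = np.array(
                [[1 if (i >> b) & 1 else -1 for b in range(n_units)] for i in range(2**n_units)]
            )
        else:
            flips = rng.choice([-1.0, 1.0], size=(n_perm, n_units))
        null = np.empty(flips.shape[0])
        for i, s in enumerate(flips):
            null[i] = _max_mass(_paired_t(diff * s.reshape((-1,) + (1,) * (diff.ndim - 1))),
                                thresh, signed)
    else:
        stat = _rm_f(data)
        thresh = spstats.f.ppf(1 - alpha, n_cond - 1, (n_cond - 1) * (n_units - 1))
        signed = False
        exact = False
        null = np.empty(n_perm)
        shuffled = data.copy()
        for i in range(n_perm):
            for u in range(n_units):
                shuffled[:, u] = data[rng.permutation(n_cond), u]
            null[i] = _max_mass(_rm_f(shuffled), thresh, signed)

    clusters = []
    for mask, mass in _clusters_from_stat(stat, thresh, signed):
        if exact:
            p = float(np.mean(null >= abs(mass)))
        else:
            p = float((1 + np.sum(null >= abs(mass))) / (null.size + 1))
        clusters.append({"mask": mask, "mass": mass, "p": p})
    clusters.sort(key=lambda c: -abs(c["mass"]))
    return ClusterResult(
        clusters=clusters, stat=stat, threshold=float(thresh),
        n_perm=int(null.size), exact=exact,
    )


def bootstrap_balance(
    samples: dict,
    reference: object,
    statistic=np.mean,
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """Equalize trial counts by resampling down to the reference condition.

    Conditions with more trials than the reference are resampled (with
    replacement) to the reference count ``n_boot`` times and the statistic
    averaged; the reference condition is evaluated directly.
    """
    if reference not in samples or len(samples[reference]) == 0:
        raise ValueError("reference condition empty")
    rng = np.random.default_rng(seed)
    n_ref = len(samples[reference])
    out = {}
    for cond, vals in samples.items():
        vals = np.asarray(vals)
        if cond == reference or len(vals) <= n_ref:
            out[cond] = float(statistic(vals))
        else:
            reps = [
                statistic(vals[rng.integers(0, len(vals), size=n_ref)])
                for _ in range(n_boot)
            ]
            out[cond] = float(np.mean(reps))
    return out


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p by doubling the smaller tail (capped at 1)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k outside [0, n]")
    lower = spstats.binom.cdf(k, n, p0)
    upper = spstats.binom.sf(k - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass
class SdtResult:
    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion_c: float


def sdt(hits: int, misses: int, fas: int, crs: int) -> SdtResult:
    """d' and criterion c from hit/false-alarm counts.

    Extreme rates are adjusted by the 1/(2N) rule before the quantile
    transform.
    """
    n_sig, n_noise = hits + misses, fas + crs
    if n_sig == 0 or n_noise == 0:
        raise ValueError("both signal and noise trials required")
    hr = np.clip(hits / n_sig, 1 / (2 * n_sig), 1 - 1 / (2 * n_sig))
    fr = np.clip(fas / n_noise, 1 / (2 * n_noise), 1 - 1 / (2 * n_noise))
    zh, zf = spstats.norm.ppf(hr), spstats.norm.ppf(fr)
    return SdtResult(
        hit_rate=float(hr),
        fa_rate=float(fr),
        d_prime=float(zh - zf),
        criterion_c=float(-(zh + zf) / 2),
    )


def behavior_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-context RT mean, RT IQR and go-trial accuracy.

    RT uses all go trials with a release (correct and incorrect); the IQR
    uses linear quantile interpolation. Accuracy is the fraction of go
    trials released inside the response window.
    """
    rows = []
    for ctx, grp in trials.groupby("context"):
        go = grp[~grp.is_stop.astype(bool)]
        if len(go) == 0:
            raise ValueError(f"context {ctx} has no go trials")
        rt = go["rt"].dropna().to_numpy()
        q75, q25 = np.percentile(rt, [75, 25])
        rows.append(
            {
                "context": ctx,
                "rt_mean": rt.mean(),
                "rt_iqr": q75 - q25,
                "accuracy": go["correct"].mean(),
                "n_go": len(go),
            }
        )
    return pd.DataFrame(rows).sort_values("context").reset_index(drop=True)


def neuro_behavior_regression(
    amplitude: np.ndarray, latency: np.ndarray, rt: np.ndarray
) -> dict:
    """Full (amplitude + latency ~ RT) and partial single-regressor OLS.

    Returns per model: R^2, F, p and coefficients.
    """
    amplitude, latency, rt = (np.asarray(v, float) for v in (amplitude, latency, rt))
    ok = np.isfinite(amplitude) & np.isfinite(latency) & np.isfinite(rt)
    if ok.sum() < 10:
        raise ValueError("need at least 10 complete trials")
    a, l, y = amplitude[ok], latency[ok], rt[ok]

    def _fit(X):
        model = sm.OLS(y, sm.add_constant(np.column_stack(X))).fit()
        return {
            "r2": float(model.rsquared),
            "F": float(model.fvalue),
            "p": float(model.f_pvalue),
            "coef": model.params.tolist(),
        }

    return {
        "full": _fit([a, l]),
        "amplitude": _fit([a]),
        "latency": _fit([l]),
    }
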