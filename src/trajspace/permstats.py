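"""Inferential machinery: cluster-based permutation tests with pluggable
time-resolved statistics, plus the supporting univariate tests.

Cluster tests form temporal clusters of contiguous suprathreshold
(pointwise p < 0.05 by default) time points, sum the statistic within each
cluster, and compare that mass with the permutation distribution of the
maximal cluster mass. For signed statistics (t), a cluster additionally
requires a constant sign. Permutation p-values follow the
``(1 + #{null >= observed}) / (1 + n_perm)`` convention so p is never 0;
the percentile-threshold decision (95th for one-tailed, 97.5th for
two-tailed) is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Cluster",
    "ClusterTestResult",
    "PermScheme",
    "cluster_permutation",
    "stat_one_sample_t",
    "stat_rm_anova_2x2",
    "stat_signed_rank",
    "rm_anova_2x2_timecourse",
    "wilcoxon_signed_rank",
    "circ_median",
    "circ_median_test",
    "binomial_proportion_test",
    "bh_fdr",
    "within_subject_sem",
    "permute_condition_labels",
    "permute_time_labels",
]


@dataclass
class Cluster:
    start: float
    stop: float
    start_idx: int
    stop_idx: int  # inclusive
    stat_sum: float
    sign: int
    p_value: float = np.nan
    significant: bool = False


@dataclass
class ClusterTestResult:
    clusters: list
    null_max: np.ndarray
    n_perm: int
    alpha: float
    tail: str
    stat: np.ndarray
    pointwise_p: np.ndarray
    times: np.ndarray

    @property
    def significant_clusters(self):
        return [c for c in self.clusters if c.significant]


@dataclass
class PermScheme:
    """Permutation scheme descriptor.

    kind: ``condition_labels_within_subject`` (shuffle the condition axis
    independently per subject), ``trial_labels_within_subject`` (shuffle
    trial labels), or ``poststim_vs_baseline_labels`` (shuffle time-point
    labels between the baseline and analysis windows, per subject).
    """

    kind: str = "condition_labels_within_subject"
    n_perm: int = 1000
    rng_seed: int | None = None

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


# -- time-resolved statistics (vectorized over the time axis) ---------------

def stat_one_sample_t(values: np.ndarray, mu: float = 0.0):
    """One-sample t vs ``mu`` per time point; values (n_subjects, n_times).

    Returns (t, two-sided p). Signed statistic.
    """
    values = np.asarray(values, float)
    n = values.shape[0]
    d = values - mu
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = d.mean(axis=0) / (sd / np.sqrt(n))
    p = 2 * st.t.sf(np.abs(t), df=n - 1)
    return t, p


def stat_rm_anova_2x2(values: np.ndarray, effect: str = "A"):
    """2x2 repeated-measures ANOVA F per time point.

    ``values`` has shape (n_subjects, 2, 2, n_times) with axes
    (subject, factor A level, factor B level, time). Effects have 1
    numerator df and n_subjects-1 denominator df; the error term is the
    effect-by-subject interaction. With 1-df effects each F equals the
    squared paired t on the per-subject contrast scores.

    ``effect`` is "A", "B" or "AB". Returns (F, p). Unsigned statistic.
    If a contrast has exactly zero within-subject variation, F is NaN.
    """
    v = np.asarray(values, float)
    if v.ndim != 4 or v.shape[1:3] != (2, 2):
        raise ValueError("values must be (n_subjects, 2, 2, n_times)")
    n = v.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if effect == "A":
        c = v[:, 0].mean(axis=1) - v[:, 1].mean(axis=1)
    elif effect == "B":
        c = v[:, :, 0].mean(axis=1) - v[:, :, 1].mean(axis=1)
    elif effect == "AB":
        c = v[:, 0, 0] - v[:, 0, 1] - v[:, 1, 0] + v[:, 1, 1]
    else:
        raise ValueError(f"unknown effect {effect!r}")
    sd = c.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = c.mean(axis=0) / (sd / np.sqrt(n))
        f = np.where(sd > 0, t**2, np.nan)
    p = st.f.sf(f, 1, n - 1)
    return f, p


def rm_anova_2x2_timecourse(values: np.ndarray):
    """All three effects of the 2x2 repeated-measures ANOVA per time point.

    Returns a dict ``{"A": (F, p), "B": (F, p), "AB": (F, p)}``.
    """
    return {e: stat_rm_anova_2x2(values, e) for e in ("A", "B", "AB")}


@lru_cache(maxsize=64)
def _signed_rank_null_sf(n: int) -> np.ndarray:
    """Exact null survival function of the W+ statistic for sample size n.

    ``sf[w] = P(W+ >= w)`` under the null, from the standard
    polynomial-product recursion over sign assignments (no ties).
    """
    counts = np.zeros(n * (n + 1) // 2 + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        new = counts.copy()
        new[r:] += counts[:-r]
        counts = new
    probs = counts / counts.sum()
    return np.cumsum(probs[::-1])[::-1]


def stat_signed_rank(values: np.ndarray, mu: float = 0.5, tail: str = "greater"):
    """Vectorized one-sample Wilcoxon signed-rank vs ``mu`` per time point.

    values: (n_subjects, n_times). Returns (W+, p) with the exact null
    distribution for n <= 25 and a normal approximation above. The raw W+
    is returned (cluster masses sum W over the cluster's time points).
    """
    v = np.asarray(values, float) - mu
    n, n_times = v.shape
    ranks = st.rankdata(np.abs(v), axis=0)
    w_pos = np.where(v > 0, ranks, 0.0).sum(axis=0)
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    if n <= 25:
        sf = _signed_rank_null_sf(n)
        idx = np.round(w_pos).astype(int)
        p_greater = sf[np.clip(idx, 0, len(sf) - 1)]
        total = n * (n + 1) / 2
        p_less = sf[np.clip(total - idx, 0, len(sf) - 1).astype(int)]
    else:
        mean = n * (n + 1) / 4
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
        z = (w_pos - mean) / sd
        p_greater = st.norm.sf(z)
        p_less = st.norm.cdf(z)
    if tail == "greater":
        p = p_greater
    elif tail == "less":
        p = p_less
    else:
        p = np.minimum(1.0, 2 * np.minimum(p_greater, p_less))
    return w_pos, p


# -- cluster machinery ------------------------------------------------------

def _find_clusters(stat, pointwise_p, times, cluster_alpha, signed):
    supra = pointwise_p < cluster_alpha
    clusters = []
    i, n = 0, len(stat)
    while i < n:
        if not supra[i] or not np.isfinite(stat[i]):
            i += 1
            continue
        sign = int(np.sign(stat[i])) if signed else 1
        j = i
        while (
            j + 1 < n
            and supra[j + 1]
            and np.isfinite(stat[j + 1])
            and (not signed or int(np.sign(stat[j + 1])) == sign)
        ):
            j += 1
        mass = float(np.abs(stat[i : j + 1]).sum()) if signed else float(stat[i : j + 1].sum())
        clusters.append(
            Cluster(
                start=float(times[i]),
                stop=float(times[j]),
                start_idx=i,
                stop_idx=j,
                stat_sum=mass,
                sign=sign,
            )
        )
        i = j + 1
    return clusters


def cluster_permutation(
    data,
    statistic_fn,
    permute_fn,
    scheme: PermScheme | None = None,
    tail: str = "one",
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    times: np.ndarray | None = None,
    signed: bool = False,
    rng: np.random.Generator | None = None,
) -> ClusterTestResult:
    """Cluster-based permutation test with a pluggable statistic.

    ``statistic_fn(data) -> (stat_per_time, pointwise_p)``;
    ``permute_fn(data, rng) -> permuted data``. The null distribution is
    the maximal cluster mass over ``scheme.n_perm`` permutations; observed
    clusters are significant when their mass exceeds the 95th (one-tailed)
    or 97.5th (two-tailed) percentile of that distribution. Permutation
    p-values use ``(1 + count) / (1 + n_perm)``.
    """
    scheme = scheme or PermScheme()
    if rng is None:
        rng = np.random.default_rng(scheme.rng_seed)
    if scheme.n_perm < int(round(1 / alpha)):
        import warnings

        warnings.warn(
            f"n_perm={scheme.n_perm} is small for alpha={alpha}; p-values are coarse"
        )
    stat, p = statistic_fn(data)
    stat, p = np.asarray(stat, float), np.asarray(p, float)
    if times is None:
        times = np.arange(len(stat), dtype=float)
    clusters = _find_clusters(stat, p, times, cluster_alpha, signed)
    null_max = np.zeros(scheme.n_perm)
    for b in range(scheme.n_perm):
        pstat, pp = statistic_fn(permute_fn(data, rng))
        pcl = _find_clusters(np.asarray(pstat, float), np.asarray(pp, float), times, cluster_alpha, signed)
        if pcl:
            null_max[b] = max(c.stat_sum for c in pcl)
    pct = 95.0 if tail == "one" else 97.5
    thresh = np.percentile(null_max, pct) if scheme.n_perm else np.inf
    for c in clusters:
        c.p_value = (1 + np.sum(null_max >= c.stat_sum)) / (1 + scheme.n_perm)
        c.significant = bool(c.stat_sum > thresh)
    return ClusterTestResult(
        clusters=clusters,
        null_max=null_max,
        n_perm=scheme.n_perm,
        alpha=alpha,
        tail=tail,
        stat=stat,
        pointwise_p=p,
        times=np.asarray(times, float),
    )


def permute_condition_labels(axis: int = 1):
    """Permute the condition axis independently per subject (axis 0)."""

    def _permute(data, rng):
        data = np.asarray(data)
        out = np.empty_like(data)
        n_subj = data.shape[0]
        n_cond = data.shape[axis]
        for s in range(n_subj):
            perm = rng.permutation(n_cond)
            out[s] = np.take(data[s], perm, axis=axis - 1)
        return out

    return _permute


def permute_cell_labels_2x2():
    """Shuffle the four cell labels of a (subject, 2, 2, time) array,
    independently per subject."""

    def _permute(data, rng):
        data = np.asarray(data)
        n_subj, _, _, n_times = data.shape
        flat = data.reshape(n_subj, 4, n_times)
        out = np.empty_like(flat)
        for s in range(n_subj):
            out[s] = flat[s, rng.permutation(4)]
        return out.reshape(data.shape)

    return _permute


def permute_time_labels(baseline_mask: np.ndarray):
    """Shuffle time-point labels between baseline and analysis windows,
    independently per subject, for (subject, time) data.

    The permuted data has the same time axis but with values drawn (per
    subject) from a random relabelling of which points are "baseline".
    """
    baseline_mask = np.asarray(baseline_mask, bool)

    def _permute(data, rng):
        data = np.asarray(data)
        out = np.empty_like(data)
        n_times = data.shape[1]
        for s in range(data.shape[0]):
            out[s] = data[s, rng.permutation(n_times)]
        return out

    return _permute


def permute_circular_shift():
    """Circularly shift each subject's time course by a random offset.

    Preserves each series' autocorrelation (unlike a full time shuffle),
    which keeps the null calibrated for smooth time courses; destroys the
    time-locking of any real effect. For (subject, time) data.
    """

    def _permute(data, rng):
        data = np.asarray(data)
        out = np.empty_like(data)
        n_times = data.shape[1]
        for s in range(data.shape[0]):
            out[s] = np.roll(data[s], int(rng.integers(n_times)))
        return out

    return _permute


__all__ += ["permute_cell_labels_2x2", "back_to_baseline_stat", "permute_circular_shift"]


def back_to_baseline_stat(baseline_mask: np.ndarray, statistic_fn=stat_one_sample_t):
    """Wrap a one-sample statistic to test analysis-window values against
    each subject's own baseline mean (values minus per-subject baseline)."""
    baseline_mask = np.asarray(baseline_mask, bool)

    def _stat(data):
        data = np.asarray(data, float)
        centered = data - data[:, baseline_mask].mean(axis=1, keepdims=True)
        return statistic_fn(centered, 0.0)

    return _stat


# -- supporting tests -------------------------------------------------------

def wilcoxon_signed_rank(x, mu0: float = 0.0, tail: str = "greater"):
    """One-sample Wilcoxon signed-rank test against ``mu0``.

    Exact null distribution for n <= 25, normal approximation above.
    Returns (W+, p). All-zero differences give p = 1.
    """
    x = np.asarray(x, float)
    d = x - mu0
    if np.all(d == 0):
        return 0.0, 1.0
    alt = {"greater": "greater", "less": "less", "two": "two-sided", "two-sided": "two-sided"}[tail]
    method = "exact" if (len(d) <= 25 and np.all(d != 0)) else "approx"
    res = st.wilcoxon(d, alternative=alt, method=method)
    return float(res.statistic), float(res.pvalue)


def circ_median(angles: np.ndarray) -> float:
    """Circular median: the direction minimizing the mean absolute circular
    deviation, chosen among the sample points (and their antipodes)."""
    a = np.mod(np.asarray(angles, float), 2 * np.pi)
    cands = np.concatenate([a, np.mod(a + np.pi, 2 * np.pi)])
    dev = np.pi - np.abs(np.pi - np.abs(a[None, :] - cands[:, None]))
    means = dev.mean(axis=1)
    best = means.min()
    chosen = cands[np.isclose(means, best, atol=1e-12)]
    # average ties on the circle
    return float(np.mod(np.arctan2(np.sin(chosen).mean(), np.cos(chosen).mean()), 2 * np.pi))


def _circ_dist(a, b):
    return np.angle(np.exp(1j * (np.asarray(a) - np.asarray(b))))


def circ_median_test(a, b):
    """Fisher's nonparametric common-median test for two circular samples.

    The combined circular median is computed; the counts of each sample
    falling on one side of it form a chi-square statistic with 1 df.
    Identical constant samples give (0, 1). Points exactly at the median
    count with the "lower" side.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    allv = np.concatenate([a, b])
    if np.allclose(allv, allv[0]):
        return 0.0, 1.0
    md = circ_median(allv)
    m = np.array(
        [np.sum(_circ_dist(a, md) < 0), np.sum(_circ_dist(b, md) < 0)], dtype=float
    )
    n = np.array([len(a), len(b)], dtype=float)
    N, M = n.sum(), m.sum()
    if M == 0 or M == N:
        return 0.0, 1.0
    stat = (N**2 / (M * (N - M))) * np.sum(m**2 / n) - N * M / (N - M)
    p = float(st.chi2.sf(stat, df=1))
    return float(stat), p


def binomial_proportion_test(k: int, n: int, p0: float = 0.5, tail: str = "greater") -> float:
    """Exact one-sample binomial proportion test: P(X >= k | p0) for the
    default 'greater' tail."""
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    return float(st.binomtest(k, n, p0, alternative=tail).pvalue)


def bh_fdr(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up at level ``q``.

    Returns (reject flags, adjusted p-values); empty input gives empty
    arrays.
    """
    pvals = np.asarray(pvals, float)
    if pvals.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, p_adj


def within_subject_sem(values: np.ndarray) -> np.ndarray:
    """Per-condition s.e.m. appropriate to a within-subject design.

    Cousineau normalization (subtract each subject's mean, add the grand
    mean) followed by the Morey correction factor sqrt(M/(M-1)) for M
    conditions. ``values``: (n_subjects, n_conditions[, n_times]).
    """
    v = np.asarray(values, float)
    if v.ndim < 2 or v.shape[1] < 2:
        raise ValueError("need at least 2 conditions")
    n_subj, m = v.shape[0], v.shape[1]
    centered = v - v.mean(axis=1, keepdims=True) + v.mean(axis=(0, 1), keepdims=True)
    sem = centered.std(axis=0, ddof=1) / np.sqrt(n_subj)
    return sem * np.sqrt(m / (m - 1))
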