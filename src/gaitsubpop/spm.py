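"""One-dimensional waveform inference over the stance phase.

Pointwise two-sample (pooled-variance) or paired t statistics are computed at
each of the 101 stance-phase timepoints, and family-wise inference over the
whole trajectory uses the non-parametric max-statistic permutation approach:
the null distribution of the maximum absolute t over the trajectory is built
by permuting group labels (unpaired design) or randomly sign-flipping paired
differences (paired design), and the critical value is its (1 - alpha)
empirical quantile.  Supra-threshold timepoints form significant regions and
are summarized as a percentage of the stance phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

__all__ = [
    "SpmResult",
    "t_trajectory_unpaired",
    "t_trajectory_paired",
    "permutation_critical_value",
    "null_max_distribution",
    "summarize",
    "compare_unpaired",
    "compare_paired",
]


@dataclass
class SpmResult:
    """Trajectory-level inference summary for one waveform channel."""

    channel: str
    t_trajectory: np.ndarray  # [T]
    critical_value: float
    significant_mask: np.ndarray  # [T] bool
    significant_fraction: float  # % of timepoints supra-threshold
    regions: tuple[tuple[int, int], ...]  # half-open [start, end) index runs


# --------------------------------------------------------------------------
# t trajectories
# --------------------------------------------------------------------------


def _unpaired_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column; a, b are [n, T]."""
    n1, n2 = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return (a.mean(axis=0) - b.mean(axis=0)) / denom


def t_trajectory_unpaired(group_a: np.ndarray, group_b: np.ndarray) -> np.ndarray:
    """Two-sample pooled-variance t statistic at each timepoint."""
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs >= 2 subjects")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups disagree on the number of timepoints")
    n1, n2 = a.shape[0], b.shape[0]
    sp2 = ((n1 - 1) * a.var(axis=0, ddof=1) + (n2 - 1) * b.var(axis=0, ddof=1)) / (
        n1 + n2 - 2
    )
    zero = np.flatnonzero(sp2 == 0)
    if zero.size:
        raise ValueError(f"zero pooled variance at timepoint {int(zero[0])}")
    return _unpaired_t(a, b)


def t_trajectory_paired(pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    """One-sample t of the paired differences (post - pre) at each timepoint."""
    pre = np.atleast_2d(np.asarray(pre, dtype=float))
    post = np.atleast_2d(np.asarray(post, dtype=float))
    if pre.shape != post.shape:
        raise ValueError(f"paired shapes differ: {pre.shape} vs {post.shape}")
    if pre.shape[0] < 2:
        raise ValueError("paired design needs >= 2 subjects")
    d = post - pre
    n = d.shape[0]
    sd = d.std(axis=0, ddof=1)
    mean = d.mean(axis=0)
    zero = sd == 0
    bad = np.flatnonzero(zero & (mean != 0))
    if bad.size:
        raise ValueError(
            f"zero difference variance with nonzero shift at timepoint {int(bad[0])}; "
            "degenerate paired data"
        )
    t = np.zeros_like(mean)
    nz = ~zero  # identical pre/post at a timepoint gives t = 0 there
    t[nz] = mean[nz] / (sd[nz] / np.sqrt(n))
    return t


# --------------------------------------------------------------------------
# Max-statistic permutation inference
# --------------------------------------------------------------------------


def _unpaired_null(
    a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null distribution of max |t| under group-label permutation.

    Exhaustive over all label assignments when their count is <= n_perm;
    otherwise Monte-Carlo with the observed labelling always included.
    """
    x = np.vstack([a, b])  # [n, T]
    n, n1 = x.shape[0], a.shape[0]
    total = comb(n, n1)
    if total <= n_perm:
        sel = np.zeros((total, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), n1)):
            sel[i, list(idx)] = True
    else:
        sel = np.zeros((n_perm, n), dtype=bool)
        sel[0, :n1] = True  # observed labelling
        for i in range(1, n_perm):
            sel[i, rng.permutation(n)[:n1]] = True
    n2 = n - n1
    x2 = x**2
    sum_all = x.sum(axis=0)
    sumsq_all = x2.sum(axis=0)
    s1 = sel.astype(float) @ x  # [M, T]
    q1 = sel.astype(float) @ x2
    m1 = s1 / n1
    m2 = (sum_all - s1) / n2
    v1 = (q1 - n1 * m1**2) / (n1 - 1)
    v2 = (sumsq_all - q1 - n2 * m2**2) / (n2 - 1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return np.nanmax(np.abs(t), axis=1)


def _paired_null(
    d: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null distribution of max |t| under random sign flips of the differences."""
    n = d.shape[0]
    if n <= 30 and 2**n <= n_perm:
        bits = np.arange(2**n)
        signs = 1.0 - 2.0 * ((bits[:, None] >> np.arange(n)[None, :]) & 1)
    else:
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        signs[0] = 1.0  # observed signs
    sd_flip = signs @ d  # [M, T] sums of flipped differences
    # per-perm mean and sd: flipping signs leaves d_i^2 unchanged
    m = sd_flip / n
    sumsq = (d**2).sum(axis=0)
    var = (sumsq[None, :] - n * m**2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / n)
    return np.nanmax(np.abs(t), axis=1)


def null_max_distribution(
    data: tuple[np.ndarray, np.ndarray] | np.ndarray,
    design: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """The permutation null distribution of the trajectory maximum |t|.

    ``data`` is (group_a, group_b) for the unpaired design or the paired
    difference matrix [n, T] for the paired design.  Enumeration is
    exhaustive when the number of distinct permutations does not exceed
    n_perm.
    """
    rng = np.random.default_rng(seed)
    if design == "unpaired":
        a, b = data
        a = np.atleast_2d(np.asarray(a, dtype=float))
        b = np.atleast_2d(np.asarray(b, dtype=float))
        if comb(a.shape[0] + b.shape[0], a.shape[0]) < 10:
            raise ValueError("too few subjects: fewer than 10 distinct permutations")
        return _unpaired_null(a, b, n_perm, rng)
    if design == "paired":
        d = np.atleast_2d(np.asarray(data, dtype=float))
        if 2 ** d.shape[0] < 10:
            raise ValueError("too few pairs: fewer than 10 distinct sign flips")
        return _paired_null(d, n_perm, rng)
    raise ValueError(f"unknown design {design!r}")


def permutation_critical_value(
    data: tuple[np.ndarray, np.ndarray] | np.ndarray,
    design: str,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """(1 - alpha) empirical quantile of the max-|t| permutation null."""
    if not 0.0 < alpha <= 0.5:
        raise ValueError("alpha must lie in (0, 0.5]")
    dist = null_max_distribution(data, design, n_perm=n_perm, seed=seed)
    return float(np.quantile(dist, 1.0 - alpha, method="higher"))


# --------------------------------------------------------------------------
# Summaries
# --------------------------------------------------------------------------


def _runs(mask: np.ndarray) -> tuple[tuple[int, int], ...]:
    """Maximal runs of True as half-open [start, end) intervals."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return tuple((int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2))


def summarize(channel: str, t_trajectory: np.ndarray, critical_value: float) -> SpmResult:
    """Threshold the trajectory and report mask, regions, % stance significant."""
    t = np.asarray(t_trajectory, dtype=float)
    mask = np.abs(t) >= critical_value
    fraction = 100.0 * mask.sum() / t.shape[0]
    return SpmResult(
        channel=channel,
        t_trajectory=t,
        critical_value=float(critical_value),
        significant_mask=mask,
        significant_fraction=float(fraction),
        regions=_runs(mask),
    )


def compare_unpaired(
    channel: str,
    group_a: np.ndarray,
    group_b: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> SpmResult:
    """Full unpaired trajectory comparison of two cohorts on one channel."""
    t = t_trajectory_unpaired(group_a, group_b)
    crit = permutation_critical_value(
        (group_a, group_b), "unpaired", alpha=alpha, n_perm=n_perm, seed=seed
    )
    return summarize(channel, t, crit)


def compare_paired(
    channel: str,
    pre: np.ndarray,
    post: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> SpmResult:
    """Full paired pre/post trajectory comparison on one channel."""
    t = t_trajectory_paired(pre, post)
    crit = permutation_critical_value(
        np.asarray(post, dtype=float) - np.asarray(pre, dtype=float),
        "paired",
        alpha=alpha,
        n_perm=n_perm,
        seed=seed,
    )
    return summarize(channel, t, crit)
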