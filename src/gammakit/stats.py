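"""Nonparametric paired/unpaired comparisons and time-course normalization.

The comparison machinery used throughout the analyses: one-tailed Wilcoxon
matched-pairs (paired before/after designs) and Mann-Whitney U (unpaired),
both with *exact* small-sample null distributions.  Exactness matters: with
n pairs all changing in one direction the one-tailed Wilcoxon p is exactly
2^(-n) (0.03125 at n=5, 0.015625 at n=6, 0.00390625 at n=8), the minimal
attainable value, and approximations would mangle precisely the sample sizes
these experiments use.

Also provides control-window normalization of 1-min-binned time courses and
the percent-change reporting convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import norm, rankdata

SIGNIFICANCE = 0.05
EXACT_WILCOXON_MAX_N = 25
EXACT_MW_MAX_N = 20


class StatsError(ValueError):
    pass


def _signed_rank_cdf_counts(ranks2: np.ndarray) -> np.ndarray:
    """Distribution of W+ over all 2^n sign assignments, via the generating
    polynomial prod(1 + z^r).  ``ranks2`` are ranks doubled to integers so
    mid-ranks (ties) stay exact."""
    total = int(np.sum(ranks2))
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts  # sums to 2^n


def wilcoxon_one_tailed(before, after, direction: str = "less") -> tuple[float, float]:
    """One-tailed Wilcoxon matched-pairs signed-rank test.

    ``direction='less'`` tests H1: after < before (a reduction);
    ``'greater'`` the opposite.  Zero differences are dropped.  The null
    distribution is exact (full enumeration over sign assignments) for
    n <= 25, normal approximation with continuity correction above.

    Returns (W+, p) with W+ the positive-rank sum of after - before.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise StatsError("before/after must have equal length")
    if direction not in ("less", "greater"):
        raise StatsError(f"direction must be 'less' or 'greater', got {direction!r}")
    d = after - before
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise StatsError("degenerate pairs: all differences zero")
    if n < 5:
        raise StatsError(f"need at least 5 non-zero differences, got {n}")
    ranks = rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    total = float(np.sum(ranks))
    # 'less' -> small W+ is evidence; 'greater' -> large W+.
    if n <= EXACT_WILCOXON_MAX_N:
        ranks2 = np.round(2 * ranks).astype(int)
        counts = _signed_rank_cdf_counts(ranks2)
        w2 = int(round(2 * w_plus))
        if direction == "less":
            p = counts[: w2 + 1].sum() / counts.sum()
        else:
            p = counts[w2:].sum() / counts.sum()
    else:
        mean = total / 2.0
        sd = np.sqrt(np.sum(ranks**2) / 4.0)
        if direction == "less":
            p = norm.cdf((w_plus - mean + 0.5) / sd)
        else:
            p = norm.sf((w_plus - mean - 0.5) / sd)
    return w_plus, float(min(p, 1.0))


def mann_whitney_one_tailed(x, y, direction: str = "less") -> tuple[float, float]:
    """One-tailed Mann-Whitney U test.

    ``direction='less'`` tests H1: x tends to be smaller than y.  For
    n + m <= 20 the p-value is the exact permutation tail over all
    C(n+m, n) group assignments of the (mid-)ranks, which handles ties;
    larger samples use the normal approximation with tie correction.

    Returns (U, p) with U the U-statistic of x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise StatsError("empty group")
    if n < 3 or m < 3:
        raise StatsError(f"need at least 3 per group, got {n} and {m}")
    if direction not in ("less", "greater"):
        raise StatsError(f"direction must be 'less' or 'greater', got {direction!r}")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    rx = float(np.sum(ranks[:n]))
    u = rx - n * (n + 1) / 2.0
    if n + m <= EXACT_MW_MAX_N:
        sums = np.fromiter(
            (sum(c) for c in combinations(ranks, n)), dtype=float
        )
        if direction == "less":
            p = float(np.mean(sums <= rx + 1e-9))
        else:
            p = float(np.mean(sums >= rx - 1e-9))
    else:
        N = n + m
        mean = n * m / 2.0
        _, t = np.unique(pooled, return_counts=True)
        tie = np.sum(t**3 - t) / (N * (N - 1))
        sd = np.sqrt(n * m / 12.0 * (N + 1 - tie))
        if direction == "less":
            p = float(norm.cdf((u - mean + 0.5) / sd))
        else:
            p = float(norm.sf((u - mean - 0.5) / sd))
    return u, min(p, 1.0)


def normalize_timecourse(bins, control_window: int = 5) -> np.ndarray:
    """Divide every bin by the mean of the first ``control_window`` bins.

    The normalized control-window mean is exactly 1; normalization is
    idempotent.
    """
    bins = np.asarray(bins, dtype=float)
    if bins.size < control_window:
        raise StatsError(
            f"need at least {control_window} control bins, got {bins.size}"
        )
    ref = float(np.mean(bins[:control_window]))
    if ref <= 0:
        raise StatsError(f"control-window mean must be positive, got {ref}")
    return bins / ref


def percent_change(before_mean: float, after_mean: float) -> float:
    """Percent reduction 100*(before - after)/before (positive = decrease)."""
    if before_mean <= 0:
        raise StatsError(f"before_mean must be positive, got {before_mean}")
    return 100.0 * (before_mean - after_mean) / before_mean


@dataclass
class PairedComparison:
    """Before/after comparison of per-recording values (means of 5 one-min
    bins per epoch) with a one-tailed exact Wilcoxon test."""

    before: np.ndarray
    after: np.ndarray
    direction: str
    statistic: float
    p_one_tailed: float
    pct_change_per_recording: np.ndarray  # per-recording reductions
    pct_change_mean: float
    pct_change_sem: float
    pct_change_pooled: float  # from ratio of group means
    significant: bool


def paired_comparison(before, after, direction: str = "less") -> PairedComparison:
    """Package a paired contrast the way the figures report it: per-recording
    percent change (mean +- SEM), the pooled ratio, and the one-tailed
    Wilcoxon p."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    w, p = wilcoxon_one_tailed(before, after, direction=direction)
    pct = np.array([percent_change(b, a) for b, a in zip(before, after)])
    sem = float(np.std(pct, ddof=1) / np.sqrt(pct.size)) if pct.size > 1 else float("nan")
    return PairedComparison(
        before=before, after=after, direction=direction, statistic=w,
        p_one_tailed=p, pct_change_per_recording=pct,
        pct_change_mean=float(np.mean(pct)), pct_change_sem=sem,
        pct_change_pooled=percent_change(float(np.mean(before)), float(np.mean(after))),
        significant=bool(p < SIGNIFICANCE),
    )
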