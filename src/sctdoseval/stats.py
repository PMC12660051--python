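"""Cohort statistics: paired Wilcoxon signed-rank, Pearson correlation, and
median/IQR summaries.

The Wilcoxon test follows the classical treatment: zero differences are
dropped before ranking, tied absolute differences receive midranks, the test
statistic is the smaller of the two signed-rank sums, and two-sided p-values
come from exact enumeration of the sign-assignment distribution for small
samples (n <= 25 by default) or from a tie- and continuity-corrected normal
approximation otherwise.  The exact distribution is computed by dynamic
programming over the generating polynomial of the (doubled) ranks, which is
equivalent to enumerating all 2^n sign patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "StatsError",
    "wilcoxon_signed_rank",
    "pearson",
    "summarize",
]

ALPHA = 0.05  # conventional two-sided significance level
EXACT_N_MAX = 25


class StatsError(ValueError):
    pass


@dataclass
class PairedSample:
    """Two equal-length paired numeric vectors with case labels."""

    x: np.ndarray
    y: np.ndarray
    labels: Sequence[str] = ()

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise StatsError("x and y must be equal-length 1-D vectors")
        if self.x.size < 2:
            raise StatsError("need at least 2 pairs")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise StatsError("non-finite values in paired sample")


def _exact_wilcoxon_p(ranks2: np.ndarray, w2: float) -> float:
    """Two-sided exact p for W+ on the doubled-rank integer scale.

    ``ranks2`` are 2x the midranks (integers); ``w2`` the observed smaller
    signed-rank sum on the same scale.  DP over the generating polynomial
    prod(1 + z^r) counts sign assignments by their rank sum.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        counts[r:] += counts[: total + 1 - r]
    n = len(ranks2)
    cdf_low = counts[: int(np.floor(w2 + 1e-9)) + 1].sum() / 2.0**n
    return float(min(1.0, 2.0 * cdf_low))


def wilcoxon_signed_rank(
    s: PairedSample, mode: str = "auto"
) -> Tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test.

    Returns ``(W, p)`` where W is the smaller of the positive- and
    negative-difference rank sums (midranks over |differences|, zeros
    dropped).  ``mode`` selects 'exact' (sign-assignment enumeration),
    'approx' (normal with tie and continuity corrections) or 'auto'
    (exact for n <= 25).
    """
    if mode not in ("exact", "approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    d = s.x - s.y
    d = d[d != 0.0]
    n = d.size
    if n < 2:
        raise StatsError("all differences are zero (degenerate sample)")
    ranks = sps.rankdata(np.abs(d))  # midranks
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    if mode == "auto":
        mode = "exact" if n <= EXACT_N_MAX else "approx"
    if mode == "exact":
        ranks2 = np.rint(2 * ranks).astype(int)
        p = _exact_wilcoxon_p(ranks2, 2 * w)
    else:
        mu = n * (n + 1) / 4.0
        # variance with midrank tie correction
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var <= 0:
            raise StatsError("zero variance in normal approximation")
        z = (w - mu + 0.5) / np.sqrt(var)  # continuity correction toward the mean
        p = float(min(1.0, 2.0 * sps.norm.cdf(z)))
    return w, p


def pearson(s: PairedSample) -> Tuple[float, float]:
    """Sample Pearson correlation with two-sided p from the t-transform
    t = r sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom."""
    if s.x.size < 3:
        raise StatsError("Pearson correlation needs n >= 3")
    if np.ptp(s.x) == 0 or np.ptp(s.y) == 0:
        raise StatsError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(s.x, s.y)
    return float(r), float(p)


def summarize(values) -> Tuple[float, float, float, float, float]:
    """(median, q1, q3, min, max) with linearly interpolated quartiles
    (quartile q at position (n-1) q)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise StatsError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q1), float(q3), float(v.min()), float(v.max())
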