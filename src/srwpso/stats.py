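"""Nonparametric comparison harness for stochastic optimizers.

Algorithms are compared over a grid of problems with multiple independent
runs per (method, problem) cell: per-cell mean/SD summaries, paired
Wilcoxon signed-rank tests, significance-gated win/tie/loss (+/=/-)
counts against a reference method, and Friedman-style mean ranks.

The Wilcoxon variant implemented here drops zero differences, mid-ranks
ties, enumerates the exact null for up to 12 nonzero pairs (via a
rank-sum counting recursion) and falls back to the tie-corrected normal
approximation with continuity correction beyond that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "ComparisonTable",
    "wilcoxon_signed_rank",
    "friedman_mean_ranks",
    "win_tie_loss",
    "summarize_avg_std",
]

_EXACT_LIMIT = 12


@dataclass
class ComparisonTable:
    """Complete methods x problems x runs result array."""

    methods: list[str]
    problems: list[str]
    results: np.ndarray

    def __post_init__(self) -> None:
        self.results = np.asarray(self.results, dtype=float)
        if self.results.shape[:2] != (len(self.methods), len(self.problems)):
            raise ValueError(
                "results must have shape (n_methods, n_problems, n_runs), got "
                f"{self.results.shape}"
            )
        if not np.all(np.isfinite(self.results)):
            raise ValueError("comparison table has missing cells")

    def cell(self, method: str, problem: str) -> np.ndarray:
        return self.results[self.methods.index(method), self.problems.index(problem)]


def _exact_two_sided_p(doubled_ranks: np.ndarray, doubled_stat: int) -> float:
    """P(two-sided) by counting rank-sum distributions over all sign flips.

    Works on doubled ranks so mid-ranks stay integral.  The null
    distribution of W+ is symmetric (each rank enters with probability
    1/2), so the two-sided p is 2 * P(W+ <= min(W+, W-)).
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    tail = counts[: doubled_stat + 1].sum() / counts.sum()
    return min(1.0, 2.0 * tail)


def wilcoxon_signed_rank(a, b) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Returns (statistic, p_value) where the statistic is min(W+, W-) over
    the signed ranks of the nonzero differences.  All differences zero
    gives the defined degenerate p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-d arrays of equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    stat = min(w_plus, w_minus)

    if n <= _EXACT_LIMIT:
        doubled = np.rint(2.0 * ranks).astype(int)
        p = _exact_two_sided_p(doubled, int(round(2.0 * stat)))
        return stat, p

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return stat, 1.0
    z = (stat - mu + 0.5) / np.sqrt(var)  # continuity correction toward the mean
    return stat, float(min(1.0, 2.0 * norm.cdf(z)))


def friedman_mean_ranks(
    table: ComparisonTable, maximize: bool = False
) -> dict[str, float]:
    """Per-method mean rank across problems (1 = best, average ranks on ties).

    Cells are summarized by their mean over runs; ranking is ascending for
    minimization scores and descending when ``maximize`` (accuracy-like
    metrics).
    """
    if len(table.methods) < 2 or len(table.problems) < 2:
        raise ValueError("need at least 2 methods and 2 problems")
    means = table.results.mean(axis=2)  # (methods, problems)
    scores = -means if maximize else means
    ranks = np.apply_along_axis(rankdata, 0, scores)
    mean_ranks = ranks.mean(axis=1)
    return dict(zip(table.methods, mean_ranks.tolist()))


def win_tie_loss(
    table: ComparisonTable,
    reference_method: str,
    alpha: float = 0.05,
    maximize: bool = False,
) -> dict[str, tuple[int, int, int]]:
    """Significance-gated (+, =, -) counts of the reference vs each competitor.

    Per problem: '+' when the reference's mean is better and the paired
    Wilcoxon p is below alpha, '-' when worse and significant, '='
    otherwise; counts are summed over problems.
    """
    if reference_method not in table.methods:
        raise ValueError(f"unknown reference method {reference_method!r}")
    out: dict[str, tuple[int, int, int]] = {}
    for method in table.methods:
        if method == reference_method:
            continue
        plus = tie = minus = 0
        for problem in table.problems:
            ref = table.cell(reference_method, problem)
            comp = table.cell(method, problem)
            _, p = wilcoxon_signed_rank(ref, comp)
            diff = ref.mean() - comp.mean()
            better = diff > 0 if maximize else diff < 0
            worse = diff < 0 if maximize else diff > 0
            if p < alpha and better:
                plus += 1
            elif p < alpha and worse:
                minus += 1
            else:
                tie += 1
        out[method] = (plus, tie, minus)
    return out


def summarize_avg_std(table: ComparisonTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell sample mean and sample standard deviation (n-1 denominator)."""
    avg = table.results.mean(axis=2)
    std = table.results.std(axis=2, ddof=1)
    return avg, std
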