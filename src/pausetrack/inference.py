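"""Nonparametric significance machinery.

Per-recording permutation nulls: envelope-EEG pairings are deliberately
mismatched (derangements of the segment pairing, so no envelope keeps its
own EEG), the full cross-validation — including lambda selection — is re-run
under each mismatch, and the observed mean correlation is compared with the
empirical (1 - alpha) quantile of the null.  Cohort-level comparisons use
Friedman and Wilcoxon signed-rank tests with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .evaluation import CVPlan, run_cv
from .decoder import build_lagged_design

__all__ = [
    "PermutationNull", "permutation_test", "friedman_test",
    "wilcoxon_signed_rank", "bonferroni",
]


@dataclass
class PermutationNull:
    """Null distribution of CV reconstruction accuracies for one recording."""

    null_r: np.ndarray
    critical_r: float
    observed_r: float
    significant: bool
    alpha: float
    n_perm: int
    seed: int


def _derangements(n: int) -> List[Tuple[int, ...]]:
    """All permutations of range(n) with no fixed point."""
    return [p for p in permutations(range(n))
            if all(p[i] != i for i in range(n))]


def _mismatched_pairings(n: int) -> List[Tuple[int, ...]]:
    """Pairings to sample the null from.

    Derangements (no envelope keeps its own EEG) are preferred, but with few
    segments there are too few of them to resolve a 95th-percentile critical
    value (9 for n = 4, so the critical value is the null maximum and the
    test rejects at a 10% floor).  Below 20 derangements all non-identity
    permutations are enumerated instead, which widens the support (23 for
    n = 4) while keeping every pairing mismatched in at least two segments.
    """
    der = _derangements(n)
    if len(der) >= 20:
        return der
    ident = tuple(range(n))
    return [p for p in permutations(range(n)) if p != ident]


def permutation_test(plan: CVPlan, n_perm: int = 500, seed: int = 0,
                     alpha: float = 0.05,
                     observed: Optional[float] = None) -> PermutationNull:
    """Permutation null for one (subject, condition, band) recording.

    Each of the ``n_perm`` draws picks a mismatched envelope-EEG pairing
    uniformly from the derangements of the segments and re-runs the entire
    cross-validation (lambda re-selected under the mismatch).  With few
    segments the pairing space is small, so CV values are computed once per
    distinct pairing and re-used across draws; the sampled null is identical
    in distribution to the naive loop.  The critical value is the empirical
    (1 - alpha) quantile of type "higher" (conservative for a 500-draw null).

    All segments are first truncated to their common minimum length: a
    mismatched pair of unequal durations would otherwise be evaluated on
    less data than the matched pairing, which breaks the exchangeability of
    the observed score with its null and makes the test anti-conservative.
    The observed score is therefore the CV score on the length-matched
    segments.
    """
    if n_perm < 100:
        import warnings
        warnings.warn("n_perm < 100: permutation quantile will be unstable",
                      stacklevel=2)
    from .evaluation import truncate_for_duration_match
    n_min = min(s.n_samples for s in plan.segments)
    if len({s.n_samples for s in plan.segments}) > 1:
        plan = truncate_for_duration_match(plan, n_min / plan.segments[0].envelope.fs)
        observed = None  # recompute on the length-matched data
    n_seg = len(plan.segments)
    designs = [build_lagged_design(s.eeg, plan.lag_spec) for s in plan.segments]
    cache: dict = {}
    if observed is None:
        observed = run_cv(plan, designs=designs, cross_cache=cache).mean_r

    pairings = _mismatched_pairings(n_seg)
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(pairings), size=n_perm)
    values: dict = {}
    null_r = np.empty(n_perm)
    for k, d in enumerate(draws):
        if d not in values:
            values[d] = run_cv(plan, pairing=pairings[d], designs=designs,
                               cross_cache=cache).mean_r
        null_r[k] = values[d]

    critical = float(np.quantile(null_r, 1.0 - alpha, method="higher"))
    return PermutationNull(null_r=null_r, critical_r=critical,
                           observed_r=float(observed),
                           significant=bool(observed > critical),
                           alpha=alpha, n_perm=n_perm, seed=seed)


def friedman_test(matrix: np.ndarray) -> Tuple[float, float]:
    """Friedman rank test across conditions (columns) within subjects (rows).

    Returns the chi-square statistic ((k-1) degrees of freedom) and its
    asymptotic p-value.  All cells must be present.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need a subjects x conditions matrix, both >= 2")
    if np.any(np.isnan(matrix)):
        raise ValueError("missing cells are not allowed")
    if np.allclose(matrix, matrix[:, [0]]):
        return 0.0, 1.0  # identical conditions: no evidence, by convention
    n, k = matrix.shape
    if k >= 3:
        stat, p = stats.friedmanchisquare(*[matrix[:, j] for j in range(k)])
        return float(stat), float(p)
    # two-condition case: same rank formula (with tie correction), which the
    # scipy entry point does not accept
    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)
    ties = 0.0
    for row in matrix:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts ** 3 - counts))
    correction = 1.0 - ties / (n * k * (k ** 2 - 1))
    R = ranks.sum(axis=0)
    stat = (12.0 / (n * k * (k + 1)) * np.sum(R ** 2) - 3 * n * (k + 1)) / correction
    return float(stat), float(stats.chi2.sf(stat, k - 1))


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float],
                         alternative: str = "two-sided") -> Tuple[float, float]:
    """Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (Wilcoxon's original rule), ties are
    mid-ranked, the p-value is exact for n <= 25 (without ties) and a
    continuity-corrected normal approximation otherwise.  The statistic
    returned is min(W+, W-).  All-zero differences are degenerate and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero: test is degenerate")
    method = "exact" if (d.size <= 25 and np.unique(np.abs(d)).size == d.size) \
        else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"),
                         alternative=alternative, method=method)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    return min(w_plus, w_minus), float(res.pvalue)


def bonferroni(alpha: float, n_tests: int) -> float:
    """Bonferroni-adjusted significance level alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    return alpha / n_tests
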