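"""Permutation nulls and rank-based tests against enumeration oracles."""

import dataclasses
from itertools import permutations, product

import numpy as np
import pytest
from scipy import stats

from pausetrack import (CVPlan, LagSpec, SimConfig, bonferroni, friedman_test,
                        permutation_test, run_cv, segments_from_records,
                        simulate_segment, wilcoxon_signed_rank)
from pausetrack.inference import _derangements, _mismatched_pairings

FS = 128.0


class TestBonferroni:
    @pytest.mark.parametrize("n,printed", [(3, 0.0167), (27, 0.00185), (9, 0.0056)])
    def test_printed_adjusted_levels(self, n, printed):
        val = bonferroni(0.05, n)
        assert float(f"{val:.3g}") == pytest.approx(printed, rel=1e-2)

    def test_identity_and_errors(self):
        assert bonferroni(0.05, 1) == 0.05
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni(1.5, 3)


class TestFriedman:
    def test_identical_conditions_no_evidence(self):
        m = np.tile([[0.3], [0.5], [0.2]], (1, 3))
        stat, p = friedman_test(m)
        assert stat == 0.0 and p == 1.0

    def test_consistent_ordering_statistic_matches_enumeration(self):
        m = np.array([[1, 2, 3], [1, 2, 3], [1, 2, 3]], dtype=float)
        stat, p = friedman_test(m)
        assert stat == pytest.approx(6.0)
        # exact enumeration oracle: distribution of the statistic over all
        # within-subject rank orderings, n=3 subjects, k=3 conditions
        def chi2_of(ranks):
            R = np.sum(ranks, axis=0)
            n, k = ranks.shape
            return 12.0 / (n * k * (k + 1)) * np.sum(R ** 2) - 3 * n * (k + 1)
        perms = [np.array(p) + 1 for p in permutations(range(3))]
        stats_all = [chi2_of(np.stack(combo))
                     for combo in product(perms, repeat=3)]
        assert max(stats_all) == pytest.approx(6.0)
        p_exact = np.mean(np.array(stats_all) >= stat - 1e-12)
        # the asymptotic p is of the same order as the exact one
        assert 0 < p < 0.2 and 0 < p_exact < 0.2

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(0)
        m = rng.standard_normal((6, 3))
        stat1, _ = friedman_test(m)
        stat2, _ = friedman_test(m[:, [2, 0, 1]])
        assert stat1 == pytest.approx(stat2)

    def test_missing_cells_rejected(self):
        m = np.ones((3, 3))
        m[0, 0] = np.nan
        with pytest.raises(ValueError):
            friedman_test(m)


def _wilcoxon_exact_two_sided(d):
    """Enumeration oracle over all 2^n sign patterns (no ties)."""
    d = np.asarray(d, float)
    ranks = stats.rankdata(np.abs(d))
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    n = d.size
    ws = []
    for bits in product([0, 1], repeat=n):
        signs = np.array(bits)
        wp = ranks[signs == 1].sum()
        ws.append(min(wp, ranks.sum() - wp))
    return np.mean(np.array(ws) <= w_obs + 1e-12)


class TestWilcoxon:
    def test_all_positive_differences(self):
        x = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([1.0, 1.0, 1.0, 1.0, 1.0])
        stat, p = wilcoxon_signed_rank(x, y, alternative="greater")
        assert stat == 0.0  # sum of negative ranks
        assert p == pytest.approx(1 / 32)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        s1, p1 = wilcoxon_signed_rank(x, y)
        s2, p2 = wilcoxon_signed_rank(y, x)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_all_zero_differences(self):
        x = np.arange(6.0)
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(x, x)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exact_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(6)
        y = rng.standard_normal(6)
        _, p = wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(_wilcoxon_exact_two_sided(x - y))


class TestPairings:
    def test_derangements_of_four(self):
        der = _derangements(4)
        assert len(der) == 9
        for d in der:
            assert all(d[i] != i for i in range(4))

    def test_few_segments_widen_to_all_non_identity(self):
        # 9 derangements cannot resolve a 95th-percentile critical value;
        # for n=4 all 23 non-identity permutations are used instead
        pairings = _mismatched_pairings(4)
        assert len(pairings) == 23
        assert tuple(range(4)) not in pairings

    def test_enough_segments_use_derangements_only(self):
        pairings = _mismatched_pairings(5)
        assert len(pairings) == 44
        assert all(all(p[i] != i for i in range(5)) for p in pairings)

    def test_fallback_for_two_segments(self):
        pairings = _mismatched_pairings(2)
        assert pairings == [(1, 0)]


@pytest.fixture(scope="module")
def noisy_plan():
    cfg = SimConfig(n_subjects=1, n_channels=2, fs_eeg=FS, fs_env=FS,
                    n_words_per_segment=40, snr_db=0.0, seed=31)
    records = [simulate_segment(cfg, "short", 0, s) for s in range(4)]
    segments = segments_from_records(records, "delta")
    return CVPlan(segments=segments, lag_spec=LagSpec(0, 300, FS),
                  lambda_grid=np.logspace(-2, 12, 15),
                  condition="short", band="delta")


class TestPermutation:
    def test_deterministic_given_seed(self, noisy_plan):
        p1 = permutation_test(noisy_plan, n_perm=120, seed=5)
        p2 = permutation_test(noisy_plan, n_perm=120, seed=5)
        assert np.array_equal(p1.null_r, p2.null_r)
        assert p1.critical_r == p2.critical_r

    def test_strong_signal_is_significant(self, noisy_plan):
        perm = permutation_test(noisy_plan, n_perm=150, seed=6)
        assert perm.observed_r > perm.critical_r
        assert perm.significant
        assert perm.null_r.size == 150
        assert perm.null_r.min() <= perm.critical_r <= perm.null_r.max()

    def test_small_n_perm_warns(self, noisy_plan):
        with pytest.warns(UserWarning, match="unstable"):
            permutation_test(noisy_plan, n_perm=50, seed=7)

    def test_critical_value_grows_for_shorter_recordings(self):
        """Shorter segments give noisier null correlations, hence larger
        critical values (stochastically).  Checked on noise-only recordings,
        averaged over a few datasets, where the 1/sqrt(n) dispersion of the
        null correlation is the only effect in play."""
        from pausetrack import truncate_for_duration_match
        diffs = []
        for seed in (60, 61, 62):
            cfg = SimConfig(n_subjects=1, n_channels=2, fs_eeg=FS, fs_env=FS,
                            n_words_per_segment=40, onset_gain=0.0,
                            sustained_gain=0.0, snr_db=0.0, seed=seed)
            records = [simulate_segment(cfg, "short", 0, s) for s in range(4)]
            segments = segments_from_records(records, "delta")
            plan = CVPlan(segments=segments, lag_spec=LagSpec(0, 300, FS),
                          lambda_grid=np.logspace(-2, 12, 15),
                          condition="short", band="delta")
            full = permutation_test(plan, n_perm=150, seed=8)
            short = permutation_test(
                truncate_for_duration_match(plan, 8.0), n_perm=150, seed=8)
            diffs.append(short.critical_r - full.critical_r)
        assert np.mean(diffs) > 0
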