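"""Statistical machinery: normality gate, Friedman omnibus, pairwise Wilcoxon."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mrinorm.errors import (
    DegenerateSampleError,
    IncompleteBlockError,
    SampleSizeError,
)
from mrinorm import stats as mstats
from mrinorm.stats import friedman_compare, pairwise_wilcoxon, wilcoxon_pair

# shapiro.test(1:12) computed with R 4.3.3 (independent reference)
R_SHAPIRO_P_1_TO_12 = 0.8757314434


class TestNormality:
    def test_matches_R_reference(self):
        assert mstats.test_normality(np.arange(1, 13)) == pytest.approx(
            R_SHAPIRO_P_1_TO_12, abs=1e-4
        )

    def test_degenerate_and_size_guards(self):
        with pytest.raises(DegenerateSampleError):
            mstats.test_normality([4.0, 4.0, 4.0])
        with pytest.raises(SampleSizeError):
            mstats.test_normality([1.0, 2.0])

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = mstats.test_normality(rng.normal(size=rng.integers(3, 40)))
            assert 0.0 <= p <= 1.0


def friedman_exact_p(observed_q, n_blocks, k):
    """Exact null P(Q >= q) by enumerating all within-block rank orders."""
    perms = list(itertools.permutations(range(1, k + 1)))
    count = total = 0
    for combo in itertools.product(perms, repeat=n_blocks):
        ranks = np.asarray(combo, dtype=float)
        rbar = ranks.mean(axis=0)
        q = 12.0 * n_blocks / (k * (k + 1)) * np.sum((rbar - (k + 1) / 2) ** 2)
        total += 1
        if q >= observed_q - 1e-12:
            count += 1
    return count / total


class TestFriedman:
    def test_worked_example_q_equals_six(self):
        """3 blocks each ranking the 3 methods (1, 2, 3) gives Q = 6."""
        table = pd.DataFrame(
            [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]],
            columns=["a", "b", "c"],
        )
        q, p = friedman_compare(table)
        assert q == pytest.approx(6.0)
        assert p == pytest.approx(float(sps.chi2.sf(6.0, 2)))

    def test_identical_columns_give_q_zero_p_one(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        q, p = friedman_compare(table)
        assert q == 0.0 and p == 1.0

    def test_chi2_p_close_to_exact_permutation_p(self):
        table = pd.DataFrame(
            [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]],
            columns=["a", "b", "c"],
        )
        q, p = friedman_compare(table)
        exact = friedman_exact_p(q, n_blocks=3, k=3)
        assert abs(p - exact) < 0.05

    def test_matches_scipy_on_tie_free_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            table = pd.DataFrame(rng.normal(size=(10, 4)))
            q, p = friedman_compare(table)
            ref = sps.friedmanchisquare(*[table[c] for c in table])
            assert q == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame(rng.uniform(0.01, 1, size=(12, 6)))
        q1, _ = friedman_compare(table)
        q2, _ = friedman_compare(np.log(table))
        assert q1 == pytest.approx(q2, rel=1e-12)

    def test_incomplete_block_rejected(self):
        table = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        with pytest.raises(IncompleteBlockError):
            friedman_compare(table)


def wilcoxon_exact_enumeration(d):
    """Two-sided exact p via full 2^n sign-flip enumeration of T+."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    t_obs = ranks[d > 0].sum()
    stats = [
        np.sum(ranks[np.array(signs, dtype=bool)])
        for signs in itertools.product([0, 1], repeat=n)
    ]
    stats = np.asarray(stats)
    cdf = np.mean(stats <= t_obs + 1e-12)
    sf = np.mean(stats >= t_obs - 1e-12)
    return min(1.0, 2.0 * min(cdf, sf))


class TestWilcoxon:
    def test_twelve_uniform_signs_exact_p(self):
        """12 all-positive differences: two-sided exact p = 2 / 2^12."""
        a = np.arange(1.0, 13.0)
        b = np.zeros(12)
        p = wilcoxon_pair(a, b)
        assert p == pytest.approx(2.0 / 4096.0, rel=1e-12)
        assert min(1.0, p * 15) == pytest.approx(0.00732421875, rel=1e-12)

    def test_identical_columns_report_p_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert wilcoxon_pair(np.ones(8), np.ones(8)) == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exact_p_matches_sign_flip_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        d = rng.normal(size=n)
        d[d == 0] = 0.1
        p = wilcoxon_pair(d, np.zeros(n))
        assert p == pytest.approx(wilcoxon_exact_enumeration(d), rel=1e-9)


class TestPairwiseMatrix:
    @staticmethod
    def strong_table(k=6, n=12, seed=5):
        """Blocks-by-methods table with a consistently ordered method effect."""
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.1, 0.2, size=(n, 1))
        effect = np.arange(k) * 0.05
        return pd.DataFrame(
            base + effect + rng.uniform(0, 0.005, size=(n, k)),
            columns=[f"m{j}" for j in range(k)],
        )

    def test_gate_blocks_matrix_when_friedman_not_significant(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        cm = pairwise_wilcoxon(table)
        assert not cm.computed and cm.corrected_p is None
        assert cm.friedman_p == 1.0

    def test_bonferroni_capped_and_symmetric(self):
        table = self.strong_table()
        cm = pairwise_wilcoxon(table)
        assert cm.computed and cm.m == 15
        vals = cm.corrected_p.to_numpy()
        off_diag = vals[~np.eye(len(vals), dtype=bool)]
        assert np.nanmax(off_diag) <= 1.0
        pd.testing.assert_frame_equal(cm.corrected_p, cm.corrected_p.T)
        # corrected = min(1, raw * m)
        a, b = cm.methods[0], cm.methods[1]
        assert cm.corrected_p.loc[a, b] == pytest.approx(
            min(1.0, cm.raw_p.loc[a, b] * 15)
        )

    def test_long_form_has_all_unordered_pairs(self):
        cm = pairwise_wilcoxon(self.strong_table())
        long = cm.to_long()
        assert len(long) == 15
        assert set(long.columns) == {
            "method_a", "method_b", "raw_p", "corrected_p", "significant",
        }
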