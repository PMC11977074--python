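import numpy as np
import pytest
from scipy import stats
from scipy.special import betainc

from likertcomp import paired_t, unpaired_t
from likertcomp.ttests import paired_pvalues, unpaired_pvalues


def t_cdf_tail_by_incomplete_beta(t, df):
    """Independent two-sided p-value: 2*P(T >= |t|) via the regularized
    incomplete beta function, P(T >= t) = I_{df/(df+t^2)}(df/2, 1/2) / 2."""
    return betainc(df / 2.0, 0.5, df / (df + t * t))


class TestUnpaired:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = unpaired_t(x, x)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert not res.reject

    def test_hand_computed_student_example(self):
        res = unpaired_t([1, 2, 3, 4, 5], [2, 3, 4, 5, 6], welch=False)
        assert res.statistic == pytest.approx(-1.0)
        assert res.df == 8

    def test_student_and_welch_agree_for_balanced_equal_variance(self, rng):
        x = rng.normal(0, 1, 30)
        y = np.sort(rng.normal(0.5, 1, 30))
        # force equal sample variances by standardizing both samples
        x = (x - x.mean()) / x.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1) + 0.4
        student = unpaired_t(x, y, welch=False)
        welch = unpaired_t(x, y, welch=True)
        assert student.statistic == pytest.approx(welch.statistic, rel=1e-12)
        assert student.df == pytest.approx(welch.df, rel=1e-12)

    @pytest.mark.parametrize("welch", [False, True])
    def test_matches_scipy_on_random_samples(self, welch, rng):
        for _ in range(200):
            n1, n2 = rng.integers(3, 40, size=2)
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.3, 1.5, n2)
            res = unpaired_t(x, y, welch=welch)
            ref = stats.ttest_ind(x, y, equal_var=not welch)
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_pvalue_matches_incomplete_beta_oracle(self, rng):
        for _ in range(300):
            x = rng.normal(0, 1, 25)
            y = rng.normal(0.2, 1, 25)
            res = unpaired_t(x, y)
            assert res.p_value == pytest.approx(
                t_cdf_tail_by_incomplete_beta(res.statistic, res.df), abs=1e-10
            )

    def test_degenerate_constant_samples(self):
        same = unpaired_t([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert same.p_value == 1.0
        apart = unpaired_t([2.0, 2.0, 2.0], [3.0, 3.0, 3.0])
        assert apart.p_value == 0.0
        assert apart.statistic == -np.inf

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValueError):
            unpaired_t([1.0], [1.0, 2.0])


class TestPaired:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        res = paired_t(x, x)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_constant_nonzero_differences(self):
        res = paired_t([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])
        assert res.statistic == np.inf
        assert res.p_value == 0.0

    def test_alternating_differences_match_oracle(self):
        x = np.array([3.0, 1.0, 3.0, 1.0])
        y = np.array([1.0, 1.0, 1.0, 1.0])
        res = paired_t(x, y)
        ref = stats.ttest_rel(x, y)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.statistic == pytest.approx(np.sqrt(3.0))
        assert res.df == 3
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_matches_scipy_on_random_samples(self, rng):
        for _ in range(200):
            n = rng.integers(3, 50)
            x = rng.normal(0, 1, n)
            y = x + rng.normal(0.2, 0.5, n)
            res = paired_t(x, y)
            ref = stats.ttest_rel(x, y)
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0], [1.0, 2.0, 3.0])


class TestBatchedInterfaces:
    def test_batched_rows_equal_scalar_calls(self, rng):
        x = rng.normal(0, 1, (20, 15))
        y = rng.normal(0.3, 2, (20, 12))
        t, df, p = unpaired_pvalues(x, y, welch=True)
        for i in range(20):
            res = unpaired_t(x[i], y[i], welch=True)
            assert t[i] == pytest.approx(res.statistic)
            assert p[i] == pytest.approx(res.p_value)

    def test_batched_paired_rows_equal_scalar_calls(self, rng):
        x = rng.normal(0, 1, (10, 25))
        y = rng.normal(0, 1, (10, 25))
        t, df, p = paired_pvalues(x, y)
        for i in range(10):
            res = paired_t(x[i], y[i])
            assert t[i] == pytest.approx(res.statistic)
            assert p[i] == pytest.approx(res.p_value)

    def test_reject_flag_tracks_alpha(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(1.0, 1, 40)
        res = unpaired_t(x, y, alpha=0.05)
        assert res.reject == (res.p_value < 0.05)
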