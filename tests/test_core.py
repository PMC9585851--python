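"""Unit and property tests for the RI core: quantiles, Tukey fences,
normality, Box-Cox machinery, and the two reference-interval estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from risize import (
    BoxCoxTransform,
    boxcox_apply,
    boxcox_fit,
    boxcox_invert,
    ks_normality,
    nonparametric_ri,
    parametric_ri,
    quantile,
    tukey_filter,
)
from risize.errors import DomainError, InputError

from .oracles import boxcox_lambda_grid, quantile_oracle


class TestQuantile:
    @given(
        st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=50),
        st.sampled_from([0.025, 0.05, 0.5, 0.95, 0.975]),
    )
    @settings(derandomize=True, max_examples=200)
    def test_matches_sort_and_interpolate_oracle(self, values, p):
        assert quantile(values, p) == pytest.approx(quantile_oracle(values, p), abs=1e-12)

    def test_clips_to_extreme_order_statistics(self):
        # rank p(n+1) < 1 for tiny p: must return the minimum, not extrapolate
        vals = [1.0, 2.0, 3.0, 4.0]
        assert quantile(vals, 0.001) == 1.0
        assert quantile(vals, 0.999) == 4.0


class TestTukeyFilter:
    def test_constant_values_all_kept(self):
        res = tukey_filter([5, 5, 5, 5, 5])
        assert res.removed.size == 0
        assert res.lower_fence == res.upper_fence == 5.0

    def test_gross_outlier_removed(self):
        vals = list(range(1, 11)) + [1000]
        res = tukey_filter(vals)
        assert 1000 in res.removed
        assert sorted(res.kept) == list(range(1, 11))
        # fences from the quantile-convention quartiles
        q1, q3 = quantile_oracle(vals, 0.25), quantile_oracle(vals, 0.75)
        assert res.lower_fence == pytest.approx(q1 - 1.5 * (q3 - q1))
        assert res.upper_fence == pytest.approx(q3 + 1.5 * (q3 - q1))

    def test_kept_preserves_input_order(self):
        vals = [7.0, 1.0, 9.0, 3.0, 5.0]
        res = tukey_filter(vals)
        assert list(res.kept) == vals

    def test_too_few_values_errors(self):
        with pytest.raises(InputError, match="4"):
            tukey_filter([1, 2, 3])

    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=60),
           st.randoms(use_true_random=False))
    @settings(derandomize=True, max_examples=100)
    def test_partition_and_fence_invariants(self, values, rnd):
        res = tukey_filter(values)
        assert sorted(np.concatenate([res.kept, res.removed])) == pytest.approx(sorted(values))
        assert all(res.lower_fence <= v <= res.upper_fence for v in res.kept)
        assert all(v < res.lower_fence or v > res.upper_fence for v in res.removed)
        # permutation invariance of the kept multiset
        shuffled = list(values)
        rnd.shuffle(shuffled)
        assert sorted(tukey_filter(shuffled).kept) == pytest.approx(sorted(res.kept))


class TestKSNormality:
    def test_normal_samples_usually_pass(self):
        rejections = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=5000)
            if not ks_normality(x, alpha=0.05).is_normal:
                rejections += 1
        assert rejections <= 2

    def test_lognormal_samples_fail(self):
        x = np.random.default_rng(7).lognormal(0.0, 0.5, 5000)
        assert not ks_normality(x, alpha=0.05).is_normal

    def test_constant_input_reports_non_normal_without_crash(self):
        rep = ks_normality([3.0] * 50)
        assert not rep.is_normal
        assert rep.note
        assert 0 <= rep.statistic <= 1 and 0 <= rep.p_value <= 1

    def test_too_few_values_errors(self):
        with pytest.raises(InputError):
            ks_normality([1.0, 2.0, 3.0])


class TestBoxCox:
    def test_lambda_near_zero_for_lognormal(self):
        x = np.exp(np.random.default_rng(3).normal(0, 1, 4000))
        t = boxcox_fit(x)
        assert abs(t.lmbda) < 0.15
        assert t.lmbda == pytest.approx(boxcox_lambda_grid(x), abs=0.01)

    def test_lambda_near_one_for_normal(self):
        x = np.random.default_rng(0).normal(100, 5, 4000)
        t = boxcox_fit(x)
        assert abs(t.lmbda - 1.0) < 0.5
        assert t.lmbda == pytest.approx(boxcox_lambda_grid(x), abs=0.01)

    def test_shift_rule_for_nonpositive_data(self):
        t = boxcox_fit([0.0, 1.0, 2.0, 5.0, 9.0, 12.0])
        assert t.shift == 1.0
        t2 = boxcox_fit([-3.0, 1.0, 2.0, 5.0, 9.0])
        assert t2.shift == 4.0

    def test_constant_input_errors(self):
        with pytest.raises(InputError):
            boxcox_fit([2.0] * 30)

    def test_log_and_affine_special_cases(self):
        assert boxcox_apply([np.e], BoxCoxTransform(0.0))[0] == pytest.approx(1.0)
        assert boxcox_apply([10.0], BoxCoxTransform(1.0))[0] == pytest.approx(9.0)

    def test_invert_out_of_range_errors(self):
        with pytest.raises(DomainError):
            boxcox_invert([-3.0], BoxCoxTransform(0.5))

    @given(
        st.floats(-2.0, 2.0),
        st.lists(st.floats(1e-3, 1e2), min_size=1, max_size=50),
    )
    @settings(derandomize=True, max_examples=150)
    def test_round_trip_identity(self, lmbda, values):
        # x <= 100: at larger magnitudes with strongly negative lambda the
        # transformed value no longer carries 1e-9 absolute precision in float64
        t = BoxCoxTransform(lmbda=lmbda)
        x = np.asarray(values)
        back = boxcox_invert(boxcox_apply(x, t), t)
        assert np.max(np.abs(x - back)) < 1e-9


class TestParametricRI:
    def test_identity_transform_reduces_to_mean_pm_z_sd(self):
        # normal data forced through lambda = 1: limits are m ± z s exactly
        x = np.random.default_rng(0).normal(10, 1, 500)
        t = BoxCoxTransform(lmbda=1.0)
        y = boxcox_apply(x, t)
        m, s = y.mean(), y.std(ddof=1)
        lo, hi = boxcox_invert(np.array([m - 1.96 * s, m + 1.96 * s]), t)
        assert lo == pytest.approx(x.mean() - 1.96 * x.std(ddof=1), abs=1e-9)
        assert hi == pytest.approx(x.mean() + 1.96 * x.std(ddof=1), abs=1e-9)

    def test_recovers_normal_limits(self):
        x = np.random.default_rng(12).normal(10, 1, 100_000)
        ri = parametric_ri(x)
        assert ri.lower == pytest.approx(10 - 1.959964, abs=0.02)
        assert ri.upper == pytest.approx(10 + 1.959964, abs=0.02)
        assert ri.method == "transformed_parametric"
        assert ri.transform is not None

    def test_recovers_lognormal_limits(self):
        x = np.random.default_rng(13).lognormal(0.0, 0.5, 100_000)
        ri = parametric_ri(x)
        assert ri.lower == pytest.approx(np.exp(-0.97998), abs=0.03)
        assert ri.upper == pytest.approx(np.exp(0.97998), abs=0.03)

    def test_constant_input_errors(self):
        with pytest.raises(InputError):
            parametric_ri([5.0] * 30)


class TestNonparametricRI:
    def test_matches_oracle_on_1_to_40(self):
        vals = np.arange(1.0, 41.0)
        ri = nonparametric_ri(vals)
        assert ri.lower == pytest.approx(quantile_oracle(vals, 0.025), abs=1e-12)
        assert ri.upper == pytest.approx(quantile_oracle(vals, 0.975), abs=1e-12)

    def test_constant_values_give_zero_width(self):
        ri = nonparametric_ri([4.2] * 25)
        assert ri.lower == ri.upper == 4.2

    def test_order_invariance(self, rng):
        x = rng.normal(size=200)
        a, b = nonparametric_ri(x), nonparametric_ri(x[::-1])
        assert (a.lower, a.upper) == (b.lower, b.upper)


@pytest.mark.parametrize("estimator", [parametric_ri, nonparametric_ri])
def test_ri_nesting_90_inside_95(estimator, rng):
    x = rng.lognormal(0.0, 0.4, 2000)
    narrow = estimator(x, level=0.90)
    wide = estimator(x, level=0.95)
    assert wide.lower <= narrow.lower <= narrow.upper <= wide.upper


def test_parametric_and_nonparametric_agree_on_large_normal_sample():
    from .oracles import normal_quantile_se

    x = np.random.default_rng(99).normal(0, 1, 100_000)
    p, np_ = parametric_ri(x), nonparametric_ri(x)
    tol = 3 * normal_quantile_se(0.975, 100_000)
    assert abs(p.lower - np_.lower) < tol
    assert abs(p.upper - np_.upper) < tol
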