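"""Survival and association statistics against independent oracles.

The Kaplan–Meier estimator is checked against a brute-force product-limit
recomputation and against lifelines; the log-rank test against lifelines
and a label-permutation null; Pearson and the t-test against
scipy.stats / textbook formulas.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

from nkp44var.stats import km_estimate, logrank_test, pairwise_logrank, pearson, unpaired_t


def km_oracle(times, events):
    """Brute-force product-limit: independent double-loop recomputation."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    out = {}
    s = 1.0
    for t in sorted(set(times[events])):
        n_at_risk = sum(1 for x in times if x >= t)
        d = sum(1 for x, e in zip(times, events) if e and x == t)
        s = s * (1 - d / n_at_risk)
        out[t] = s
    return out


class TestKaplanMeier:
    def test_all_events_closed_form(self):
        curve = km_estimate([1, 2, 3])
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        assert list(curve.at_risk) == [3, 2, 1]

    def test_censoring_semantics(self):
        # one event at t=1, one censored at t=2: S(1)=0.5 and never drops after
        curve = km_estimate([1, 2], [True, False])
        assert list(curve.times) == [1]
        assert curve.survival[0] == pytest.approx(0.5)
        assert curve.survival_at(100.0) == pytest.approx(0.5)

    def test_matches_brute_force_oracle_on_random_records(self, rng):
        times = np.round(rng.exponential(300, size=200), 0)
        events = rng.uniform(size=200) < 0.7
        events[0] = True
        curve = km_estimate(times, events)
        expected = km_oracle(times, events)
        assert len(curve.times) == len(expected)
        for t, s in zip(curve.times, curve.survival):
            assert abs(s - expected[t]) <= 1e-12

    def test_matches_lifelines(self, rng):
        times = rng.exponential(200, size=150)
        events = rng.uniform(size=150) < 0.6
        events[0] = True
        curve = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.times, curve.survival):
            assert kmf.predict(t) == pytest.approx(s, abs=1e-10)

    def test_no_censoring_equals_one_minus_ecdf(self, rng):
        times = rng.integers(1, 50, size=80).astype(float)
        curve = km_estimate(times)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(np.mean(times > t), abs=1e-12)

    def test_product_limit_identity(self, rng):
        times = rng.integers(1, 30, size=60).astype(float)
        events = rng.uniform(size=60) < 0.8
        events[0] = True
        c = km_estimate(times, events)
        prev = 1.0
        for k in range(len(c.times)):
            expected = prev * (1 - c.n_events[k] / c.at_risk[k])
            assert c.survival[k] == pytest.approx(expected, abs=1e-15)
            prev = c.survival[k]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([])


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        t = [3, 5, 8, 13]
        res = logrank_test([t, t])
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_df_is_k_minus_1_and_obs_expected_balance(self, rng):
        groups = [rng.exponential(100, size=20) for _ in range(3)]
        res = logrank_test(groups)
        assert res.df == 2
        assert sum(res.group_observed.values()) == pytest.approx(
            sum(res.group_expected.values()), abs=1e-9
        )

    def test_matches_lifelines_with_ties_and_censoring(self, rng):
        times = np.concatenate([rng.integers(1, 40, 35), rng.integers(1, 25, 30),
                                rng.integers(5, 60, 25)]).astype(float)
        events = rng.uniform(size=90) < 0.75
        groups = np.repeat([0, 1, 2], [35, 30, 25])
        res = logrank_test(
            [times[groups == g] for g in range(3)],
            [events[groups == g] for g in range(3)],
        )
        ll = multivariate_logrank_test(times, groups, events)
        assert res.chi_square == pytest.approx(ll.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ll.p_value, rel=1e-9)

    def test_relabeling_and_monotone_time_transform_invariance(self, rng):
        a = rng.exponential(50, 20)
        b = rng.exponential(90, 25)
        base = logrank_test([a, b])
        swapped = logrank_test([b, a])
        assert swapped.chi_square == pytest.approx(base.chi_square, rel=1e-12)
        warped = logrank_test([np.sqrt(a), np.sqrt(b)])
        assert warped.chi_square == pytest.approx(base.chi_square, rel=1e-12)

    def test_permutation_oracle_agreement(self, rng):
        # two groups of 8 with crossing hazards; modest permutation null here,
        # the full 50k-permutation check runs in the acceptance suite
        a = np.array([2.0, 4, 6, 8, 40, 45, 50, 55])
        b = np.array([15.0, 18, 20, 22, 25, 28, 30, 90])
        res = logrank_test([a, b])
        times = np.concatenate([a, b])
        stats_null = []
        for _ in range(4000):
            perm = rng.permutation(16)
            stats_null.append(
                logrank_test([times[perm[:8]], times[perm[8:]]]).chi_square
            )
        p_perm = np.mean(np.asarray(stats_null) >= res.chi_square - 1e-12)
        assert res.p_value == pytest.approx(p_perm, abs=0.02)

    def test_error_cases(self):
        with pytest.raises(ValueError):
            logrank_test([[1.0, 2.0]])  # one group
        with pytest.raises(ValueError):
            logrank_test([[1.0], []])  # empty group
        with pytest.raises(ValueError, match="censored"):
            logrank_test([[1.0, 2.0], [3.0]], [[False, False], [False]])

    def test_pairwise_holm_adjustment_monotone(self, rng):
        groups = {k: rng.exponential(s, 15)
                  for k, s in zip("abc", (30, 60, 120))}
        tab = pairwise_logrank(groups, holm=True)
        assert len(tab) == 3
        assert (tab["p_holm"] >= tab["p_value"] - 1e-15).all()
        assert (tab["p_holm"] <= 1.0).all()


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_t_transform_p_for_r009_n27(self):
        # construct vectors with exact r = 0.09 via orthogonal decomposition
        rng = np.random.default_rng(5)
        x = rng.normal(size=27)
        z = rng.normal(size=27)
        xc = (x - x.mean()) / np.std(x - x.mean())
        zc = z - z.mean()
        zc -= xc * (zc @ xc) / (xc @ xc)
        zc /= np.std(zc)
        r = 0.09
        y = r * xc + np.sqrt(1 - r**2) * zc
        res = pearson(x, y)
        assert res.r == pytest.approx(0.09, abs=1e-12)
        tstat = r * np.sqrt((27 - 2) / (1 - r**2))
        assert res.p_value == pytest.approx(2 * sps.t.sf(tstat, 25), abs=1e-12)
        assert res.p_value == pytest.approx(0.655, abs=0.001)

    def test_matches_scipy_on_random_data(self, rng):
        x = rng.normal(size=40)
        y = 0.3 * x + rng.normal(size=40)
        res = pearson(x, y)
        ref_r, ref_p = sps.pearsonr(x, y)
        assert res.r == pytest.approx(ref_r, abs=1e-12)
        assert res.p_value == pytest.approx(ref_p, abs=1e-12)

    @given(st.floats(0.01, 100), st.floats(-50, 50))
    def test_invariant_under_positive_affine_transform(self, a, b):
        x = np.array([1.0, 2, 4, 8, 9, 12])
        y = np.array([3.0, 1, 4, 1, 5, 9])
        base = pearson(x, y).r
        assert pearson(a * x + b, y).r == pytest.approx(base, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [1.0, 2.0])  # n < 3
        with pytest.raises(ValueError, match="variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestUnpairedT:
    def test_identical_samples_t0_p1(self):
        x = [1.0, 2.0, 3.0]
        res = unpaired_t(x, x)
        assert res.t == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(1, 2, 15)
        a = unpaired_t(x, y)
        b = unpaired_t(y, x)
        assert a.t == pytest.approx(-b.t, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_textbook_formula_oracle(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.5, 1, 14)
        res = unpaired_t(x, y)
        # independent recomputation, pooled variance
        sp2 = ((9 * x.var(ddof=1)) + 13 * y.var(ddof=1)) / 22
        t_ref = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 10 + 1 / 14))
        assert res.t == pytest.approx(t_ref, abs=1e-10)
        ref = sps.ttest_ind(x, y)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_welch_matches_scipy(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.5, 3, 25)
        res = unpaired_t(x, y, pooled=False)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert res.t == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)
        assert res.df == pytest.approx(ref.df, abs=1e-8)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            unpaired_t([1.0], [1.0, 2.0])
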