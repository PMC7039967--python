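import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import statsmodels.api as sm

from hemangiomics import (
    ExpressionMatrix,
    SimConfig,
    SplineTestConfig,
    bh_adjust,
    moderate_variances,
    natural_spline_basis,
    simulate_tox_timecourse,
    spline_timecourse_test,
    two_group_ttest,
)


def _matrix(rows, samples):
    return ExpressionMatrix(pd.DataFrame(
        np.atleast_2d(np.asarray(rows, dtype=float)),
        index=[f"g{i}" for i in range(np.atleast_2d(rows).shape[0])],
        columns=samples))


def bh_stepup_oracle(p):
    """Exhaustive step-up oracle: for each feature, the smallest candidate
    threshold t in {p_i} at which it is rejected under the step-up rule."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    q = np.ones(m)
    for i, pi in enumerate(p):
        qs = []
        for t in sorted(p):
            k = (p <= t).sum()
            if pi <= t:
                qs.append(m * t / k)
        q[i] = min(1.0, min(qs))
    return q


class TestTwoGroupTTest:
    def test_pooled_closed_form(self, two_group_matrix):
        """(1,2,3) vs (4,5,6): t = -3.674, df = 4, p ~ 0.0213."""
        m, groups = two_group_matrix
        res = two_group_ttest(m, groups, ("A", "B"), variant="pooled")
        assert res["stat"].iloc[0] == pytest.approx(-3.6742346, abs=1e-6)
        assert res["df"].iloc[0] == 4
        assert res["p"].iloc[0] == pytest.approx(0.021312, abs=1e-5)
        assert res["effect"].iloc[0] == pytest.approx(-3.0)

    def test_identical_groups_give_t0_p1(self):
        m = _matrix([[1.0, 2, 3, 1, 2, 3]], ["a1", "a2", "a3", "b1", "b2", "b3"])
        groups = dict(a1="A", a2="A", a3="A", b1="B", b2="B", b3="B")
        res = two_group_ttest(m, groups, ("A", "B"))
        assert res["stat"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_zero_variance_nonzero_diff_clamped_and_flagged(self):
        m = _matrix([[5.0, 5, 7, 7]], ["a1", "a2", "b1", "b2"])
        res = two_group_ttest(m, dict(a1="A", a2="A", b1="B", b2="B"), ("A", "B"))
        assert res["p"].iloc[0] > 0
        assert res["p"].iloc[0] < 1e-300
        assert bool(res["degenerate"].iloc[0])

    def test_small_group_rejected(self):
        m = _matrix([[1.0, 2, 3]], ["a1", "b1", "b2"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            two_group_ttest(m, dict(a1="A", b1="B", b2="B"), ("A", "B"))

    @pytest.mark.parametrize("variant", ["pooled", "welch"])
    def test_antisymmetric_in_contrast_order(self, rng, variant):
        m = _matrix(rng.normal(size=(20, 8)),
                    [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)])
        groups = {s: s[0].upper() for s in m.sample_ids}
        ab = two_group_ttest(m, groups, ("A", "B"), variant=variant)
        ba = two_group_ttest(m, groups, ("B", "A"), variant=variant)
        np.testing.assert_allclose(ab["stat"], -ba["stat"], rtol=1e-10)
        np.testing.assert_allclose(ab["p"], ba["p"], rtol=1e-10)

    def test_welch_matches_scipy(self, rng):
        from scipy import stats

        xa = rng.normal(size=(10, 5))
        xb = rng.normal(size=(10, 7)) * 2
        m = _matrix(np.hstack([xa, xb]),
                    [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(7)])
        groups = {s: s[0].upper() for s in m.sample_ids}
        res = two_group_ttest(m, groups, ("A", "B"), variant="welch")
        t, p = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
        np.testing.assert_allclose(res["stat"], t)
        np.testing.assert_allclose(res["p"], p)


class TestModerateVariances:
    def test_common_variance_collapses_to_prior(self):
        post, df_aug, d0, s0, flat = moderate_variances(np.full(50, 2.5), df=4)
        assert flat
        assert np.isinf(d0)
        np.testing.assert_allclose(post, 2.5, rtol=1e-6)

    def test_posterior_between_sample_and_prior(self, rng):
        # true per-feature variances from a scaled inverse-chi-square prior,
        # so the hierarchical spread is real and d0 is finite
        true_var = 4.0 / rng.chisquare(4, size=500)
        s2 = true_var * rng.chisquare(4, size=500) / 4
        post, df_aug, d0, s0, flat = moderate_variances(s2, df=4)
        assert not flat
        assert np.isfinite(d0) and d0 > 0
        assert df_aug == pytest.approx(4 + d0)
        lo = np.minimum(s2, s0)
        hi = np.maximum(s2, s0)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()

    def test_recovers_unit_variance_on_average(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, size=(2000, 5))
        s2 = x.var(axis=1, ddof=1)
        post, *_ = moderate_variances(s2, df=4)
        assert 0.9 <= post.mean() <= 1.1

    def test_needs_ensemble(self):
        with pytest.raises(ValueError, match=">= 10"):
            moderate_variances(np.ones(5), df=4)


class TestBHAdjust:
    def test_hand_stepup_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust(np.ones(5)), np.ones(5))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_q_at_least_p_and_rank_monotone(self, rng):
        p = rng.random(100)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    def test_matches_exhaustive_stepup_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_stepup_oracle(p), atol=1e-12)


class TestNaturalSplineBasis:
    def test_dimension_and_linearity_beyond_boundary(self):
        x = np.linspace(0, 10, 50)
        b = natural_spline_basis(x, df=3)
        assert b.shape == (50, 3)
        # linear extrapolation: second differences vanish outside the knots
        xx = np.array([-5.0, -4.0, -3.0, 13.0, 14.0, 15.0])
        bb = natural_spline_basis(xx, df=3, boundary=(0.0, 10.0),
                                  interior_knots=np.quantile(x, [1 / 3, 2 / 3]))
        for col in bb.T:
            assert abs(np.diff(col[:3], 2)).max() < 1e-8
            assert abs(np.diff(col[3:], 2)).max() < 1e-8

    def test_full_rank_with_intercept(self):
        x = np.repeat([1.0, 3, 7, 14], 5)
        b = natural_spline_basis(x, df=3)
        X = np.column_stack([np.ones(len(x)), b])
        assert np.linalg.matrix_rank(X) == 4


class TestSplineTimecourse:
    def _sim(self, **kw):
        cfg = SimConfig(**kw)
        m, sheet, truth = simulate_tox_timecourse(cfg)
        time = sheet.table.set_index("sample")["time"]
        arm = sheet.table.set_index("sample")["arm"]
        return m, time, arm, truth

    def test_reports_three_interaction_df(self):
        m, time, arm, _ = self._sim(n_genes=5, seed=1)
        res = spline_timecourse_test(m, time, arm)
        assert (res["df"] == 3.0).all()

    def test_null_pvalues_approximately_uniform(self):
        from scipy import stats

        m, time, arm, _ = self._sim(n_genes=2000, frac_divergent=0.0,
                                    noise_sd=1.0, seed=7)
        res = spline_timecourse_test(m, time, arm)
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_noise_free_divergent_feature_is_extreme(self):
        m, time, arm, truth = self._sim(n_genes=20, frac_divergent=1.0,
                                        noise_sd=0.0, effect_size=3, seed=3)
        res = spline_timecourse_test(m, time, arm)
        assert (res["p"] < 1e-12).all()

    def test_constant_feature_degenerate_p1(self):
        samples = [f"s{i}" for i in range(16)]
        m = ExpressionMatrix(pd.DataFrame(np.full((1, 16), 5.0),
                                          index=["g0"], columns=samples))
        time = pd.Series(np.tile([1.0, 3, 7, 14], 4), index=samples)
        arm = pd.Series(["a"] * 8 + ["b"] * 8, index=samples)
        res = spline_timecourse_test(m, time, arm)
        assert res["p"].iloc[0] == 1.0
        assert bool(res["degenerate"].iloc[0])

    def test_too_few_times_rejected(self):
        samples = [f"s{i}" for i in range(12)]
        m = ExpressionMatrix(pd.DataFrame(np.random.default_rng(0).normal(size=(2, 12)),
                                          index=["g0", "g1"], columns=samples))
        time = pd.Series(np.tile([1.0, 3, 7], 4), index=samples)
        arm = pd.Series(["a"] * 6 + ["b"] * 6, index=samples)
        with pytest.raises(ValueError, match="distinct time"):
            spline_timecourse_test(m, time, arm)

    def test_matches_statsmodels_nested_f(self, rng):
        """Moderation off on a single feature equals the classical
        nested-model F test computed from residual sums of squares."""
        times = np.tile(np.repeat([0.0, 2, 5, 9, 14], 2), 2)
        arms = np.array(["c"] * 10 + ["p"] * 10)
        samples = [f"s{i}" for i in range(20)]
        y = rng.normal(size=20) + (arms == "p") * rng.normal(size=20)
        m = ExpressionMatrix(pd.DataFrame(y[None, :], index=["g0"], columns=samples))
        res = spline_timecourse_test(m, pd.Series(times, index=samples),
                                     pd.Series(arms, index=samples))
        basis = natural_spline_basis(times, df=3)
        ind = (arms == "p").astype(float)
        x_null = sm.add_constant(np.column_stack([ind, basis]))
        x_full = np.column_stack([x_null, basis * ind[:, None]])
        fit_null = sm.OLS(y, x_null).fit()
        fit_full = sm.OLS(y, x_full).fit()
        f, p, df_diff = fit_full.compare_f_test(fit_null)
        assert res["stat"].iloc[0] == pytest.approx(f, rel=1e-10)
        assert res["p"].iloc[0] == pytest.approx(p, rel=1e-10)
        assert df_diff == 3

    def test_moderated_variant_runs_and_orders_like_classical(self):
        m, time, arm, truth = self._sim(n_genes=300, frac_divergent=0.2,
                                        noise_sd=0.3, seed=9)
        classical = spline_timecourse_test(m, time, arm)
        moderated = spline_timecourse_test(
            m, time, arm, SplineTestConfig(n_knots=3, moderation=True))
        # moderated df exceeds residual df; calls broadly agree
        called_c = set(classical.loc[classical["q"] <= 0.05, "feature"])
        called_m = set(moderated.loc[moderated["q"] <= 0.05, "feature"])
        divergent = set(truth.divergent.index[truth.divergent])
        assert len(called_m & divergent) / len(divergent) > 0.9
        assert len(called_c ^ called_m) <= 0.1 * len(called_c | called_m) + 5
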