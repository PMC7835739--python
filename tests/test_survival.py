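import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
from sklearn.base import clone

from splice_prognosis import (
    CutoffSurvivalScanner,
    cox_fit,
    cox_score_test,
    km_estimate,
    logrank_test,
    prognostic_direction,
    scan_optimal_cutoff,
)
from splice_prognosis.survival import _logrank_arrays, nearest_rank_percentile


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = km_estimate([1, 2, 3], [1, 1, 0])
        np.testing.assert_allclose(km.event_times, [1, 2])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3])
        assert km.survival_at(3.5) == pytest.approx(1 / 3)

    def test_all_censored_is_constant_one(self):
        km = km_estimate([5, 8, 2], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.survival_at(100) == 1.0

    def test_single_subject_event(self):
        km = km_estimate([5], [1])
        assert km.survival_at(5) == 0.0

    def test_matches_lifelines(self, rng):
        t = rng.exponential(10, 60)
        e = rng.integers(0, 2, 60)
        e[0] = 1
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for u in km.event_times:
            assert km.survival_at(u) == pytest.approx(
                float(kmf.survival_function_at_times(u).iloc[0]), abs=1e-10
            )

    def test_monotone_and_bounded(self, rng):
        t = rng.exponential(5, 80)
        e = rng.integers(0, 2, 80)
        e[:3] = 1
        km = km_estimate(t, e)
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all((km.survival >= 0) & (km.survival <= 1))
        assert np.all(np.diff(km.at_risk) < 0)


class TestLogRank:
    def test_hand_risk_set_arithmetic(self):
        r = logrank_test([1, 2, 3], [1, 1, 1], [4, 5, 6], [1, 1, 1])
        assert r.observed[0] == 3
        assert r.expected[0] == pytest.approx(1.15)
        assert r.variance == pytest.approx(0.6775)
        assert r.statistic == pytest.approx(5.0517, abs=1e-3)
        assert r.p_value == pytest.approx(0.0246, abs=1e-3)
        assert r.sign == 1  # group A dies earlier than expected

    def test_identical_groups_give_null(self):
        r = logrank_test([1, 2, 3], [1, 1, 0], [1, 2, 3], [1, 1, 0])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_lifelines_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        ta = np.ceil(rng.exponential(10, 40))  # integer times force ties
        tb = np.ceil(rng.exponential(14, 35))
        ea = rng.integers(0, 2, 40)
        eb = rng.integers(0, 2, 35)
        ea[0] = 1
        r = logrank_test(ta, ea, tb, eb)
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert r.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert r.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_censoring_time_beyond_last_event_is_irrelevant(self):
        # a subject censored after the last event stays in every risk set
        # either way, so pushing the censoring time out changes nothing
        r1 = logrank_test([1, 2, 3, 4.5], [1, 1, 1, 0], [2, 4], [1, 1])
        r2 = logrank_test([1, 2, 3, 99], [1, 1, 1, 0], [2, 4], [1, 1])
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        assert r1.expected[0] == pytest.approx(r2.expected[0], abs=1e-12)

    def test_swapping_groups_flips_sign(self):
        args = ([1, 2, 3], [1, 1, 1], [4, 5, 6], [1, 1, 1])
        r = logrank_test(*args)
        r_swapped = logrank_test(args[2], args[3], args[0], args[1])
        assert r.sign == -r_swapped.sign
        assert r.statistic == pytest.approx(r_swapped.statistic)

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            logrank_test([], [], [1], [1])
        with pytest.raises(ValueError, match="at least one event"):
            logrank_test([1, 2], [0, 0], [3], [0])


class TestCutoffScan:
    @staticmethod
    def _latent_groups(n=100, hr=4.0, seed=5):
        """Two latent expression clusters with a built-in hazard gap."""
        rng = np.random.default_rng(seed)
        group = rng.integers(0, 2, n)
        expr = np.where(group == 1, rng.normal(10, 0.5, n), rng.normal(4, 0.5, n))
        t = rng.exponential(1.0 / (0.01 * hr**group))
        return expr, t, np.ones(n, int), group

    def test_recovers_separating_gap(self):
        expr, t, e, group = self._latent_groups()
        scan = scan_optimal_cutoff(expr, times=t, events=e)
        # the selected split essentially reproduces the latent bipartition
        # (min-p may trade a boundary sample or two for a lower p-value)
        assert np.sum((expr > scan.cutoff) != (group == 1)) <= 2
        assert 4 < scan.cutoff < 10  # between the cluster centers
        ref = logrank_test(t[group == 1], e[group == 1], t[group == 0], e[group == 0])
        assert scan.p_value <= ref.p_value * (1 + 1e-9)
        assert scan.direction == "unfavorable"
        assert prognostic_direction(scan) == "unfavorable"

    def test_constant_expression_rejected(self):
        t = np.arange(1, 21, dtype=float)
        with pytest.raises(ValueError, match="no valid cutoff"):
            scan_optimal_cutoff(np.ones(20), times=t, events=np.ones(20, int))

    @pytest.mark.parametrize("seed", range(5))
    def test_min_p_not_above_median_cutoff_p(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        x = rng.lognormal(2, 1, n)
        t = rng.exponential(100, n)
        e = rng.integers(0, 2, n)
        e[:5] = 1
        scan = scan_optimal_cutoff(x, times=t, events=e)
        med = nearest_rank_percentile(x, 50)
        high = x > med
        ref = logrank_test(t[high], e[high], t[~high], e[~high])
        assert scan.p_value <= ref.p_value + 1e-12
        assert nearest_rank_percentile(x, 10) <= scan.cutoff <= nearest_rank_percentile(x, 90)

    def test_scan_engine_agrees_with_direct_logrank(self, rng):
        n = 80
        x = rng.lognormal(1, 1, n)
        t = np.ceil(rng.exponential(50, n))
        e = rng.integers(0, 2, n)
        e[:4] = 1
        scan = scan_optimal_cutoff(x, times=t, events=e)
        for i in [0, len(scan.candidate_cutoffs) // 2, len(scan.candidate_cutoffs) - 1]:
            v = scan.candidate_cutoffs[i]
            high = x > v
            if high.sum() in (0, n) or np.isnan(scan.candidate_pvalues[i]):
                continue
            ref = logrank_test(t[high], e[high], t[~high], e[~high])
            assert scan.candidate_pvalues[i] == pytest.approx(ref.p_value, rel=1e-9)

    def test_estimator_interface(self):
        expr, t, e, _ = self._latent_groups(seed=7)
        est = CutoffSurvivalScanner()
        assert clone(est).get_params() == est.get_params()
        est.fit(expr.reshape(-1, 1), np.c_[t, e])
        labels = est.predict(expr)
        assert set(labels) == {"high", "low"}
        assert ((expr > est.cutoff_) == (labels == "high")).all()


class TestCox:
    def test_null_binary_covariate_is_small(self):
        hits = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 2, 500).astype(float)
            t = rng.exponential(10, 500)
            fit = cox_fit(x, times=t, events=np.ones(500, int))
            hits += abs(fit.coef[0]) < 0.2  # ~2.2 asymptotic SEs
        assert hits >= 57  # >= 95% of seeds

    def test_recovers_log2_rate_ratio(self):
        hits = 0
        for seed in range(60):
            rng = np.random.default_rng(1000 + seed)
            x = rng.integers(0, 2, 1000).astype(float)
            t = rng.exponential(1.0 / np.exp(np.log(2) * x))
            fit = cox_fit(x, times=t, events=np.ones(1000, int))
            assert fit.converged
            hits += abs(fit.coef[0] - np.log(2)) < 0.15  # ~2.4 asymptotic SEs
        assert hits >= 57

    def test_matches_lifelines_multivariate(self):
        # continuous times: no ties, where Breslow and Efron coincide
        rng = np.random.default_rng(3)
        n = 300
        x1 = rng.normal(size=n)
        x2 = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / np.exp(0.5 * x1 - 0.3 * x2)) * 30
        e = rng.integers(0, 2, n)
        e[:10] = 1
        fit = cox_fit(np.c_[x1, x2], times=t, events=e)
        df = pd.DataFrame({"t": t, "e": e, "x1": x1, "x2": x2})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        np.testing.assert_allclose(fit.coef, cph.params_[["x1", "x2"]], atol=1e-4)
        np.testing.assert_allclose(fit.se, cph.standard_errors_[["x1", "x2"]], atol=1e-4)
        assert np.allclose(fit.hazard_ratio, np.exp(fit.coef))

    def test_score_test_equals_logrank_without_ties(self, rng):
        x = rng.integers(0, 2, 80).astype(float)
        t = rng.exponential(5, 80)  # continuous: no ties a.s.
        e = np.ones(80, int)
        chi2, _ = cox_score_test(x, t, e)
        r = logrank_test(t[x == 1], e[x == 1], t[x == 0], e[x == 0])
        assert chi2 == pytest.approx(r.statistic, abs=1e-8)

    def test_wald_score_lrt_agree_asymptotically(self):
        rng = np.random.default_rng(9)
        n = 1000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / np.exp(0.3 * x))
        e = np.ones(n, int)
        fit = cox_fit(x, times=t, events=e)
        wald = fit.coef[0] ** 2 / fit.se[0] ** 2
        score, _ = cox_score_test(x, t, e)
        from splice_prognosis.survival import _cox_quantities

        ll0, _, _ = _cox_quantities(x[:, None], t, e, np.zeros(1))
        lrt = 2 * (fit.log_likelihood - ll0)
        assert wald == pytest.approx(score, rel=0.15)
        assert lrt == pytest.approx(score, rel=0.15)

    def test_missing_covariates_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            cox_fit(np.array([1.0, np.nan, 0.0]), times=[1, 2, 3], events=[1, 1, 1])


def test_logrank_arrays_matches_public_api(rng):
    t = np.ceil(rng.exponential(10, 50))
    e = rng.integers(0, 2, 50)
    e[:3] = 1
    g = rng.integers(0, 2, 50).astype(bool)
    if g.all() or not g.any():
        g[0] = ~g[0]
    o, exp, var, _ = _logrank_arrays(t, e, g)
    r = logrank_test(t[g], e[g], t[~g], e[~g])
    assert o == pytest.approx(r.observed[0])
    assert exp == pytest.approx(r.expected[0])
    assert var == pytest.approx(r.variance)
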