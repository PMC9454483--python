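import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from crcpanel.survival import (
    cox_fit,
    km_fit,
    km_survival_at,
    logrank_test,
    schoenfeld_test,
    vif,
)


class TestKaplanMeier:
    def test_all_censored_gives_unit_survival(self):
        curve = km_fit([3, 8, 12, 20, 30], [0, 0, 0, 0, 0])
        np.testing.assert_array_equal(curve.survival, 1.0)

    def test_five_event_worked_example(self):
        """Times 1..5 all events: S just after t=3 is (4/5)(3/4)(2/3) = 0.4."""
        curve = km_fit([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        np.testing.assert_allclose(curve.survival, [0.8, 0.6, 0.4, 0.2, 0.0])
        assert km_survival_at(curve, 3.5) == pytest.approx(0.4)

    def test_step_evaluation_conventions(self):
        curve = km_fit([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        assert km_survival_at(curve, 0.5) == 1.0          # before first event
        assert km_survival_at(curve, 3.0) == pytest.approx(0.4)  # right-continuous
        assert km_survival_at(curve, 1e6) == 0.0          # beyond last follow-up
        with pytest.raises(ValueError):
            km_survival_at(curve, -1.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, 60)
        curve = km_fit(t, np.ones(60, dtype=bool))
        for q in [2.0, 5.0, 15.0]:
            assert km_survival_at(curve, q) == pytest.approx((t > q).mean())

    def test_matches_lifelines_under_censoring(self, censored_sample):
        time, event = censored_sample
        curve = km_fit(time, event)
        kmf = KaplanMeierFitter().fit(time, event)
        for q in [5.0, 10.0, 25.0, 39.0]:
            assert km_survival_at(curve, q) == pytest.approx(float(kmf.predict(q)))

    def test_survival_non_increasing_and_empty_rejected(self, censored_sample):
        curve = km_fit(*censored_sample)
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert (np.diff(curve.at_risk) < 0).all()
        with pytest.raises(ValueError):
            km_fit([], [])


class TestLogRank:
    def test_matches_lifelines_three_groups(self, rng, censored_sample):
        time, event = censored_sample
        g = rng.integers(0, 3, time.size)
        mine = logrank_test(time, event, g)
        ref = multivariate_logrank_test(time, g, event)
        assert mine.chi2 == pytest.approx(ref.test_statistic)
        assert mine.p == pytest.approx(ref.p_value)
        assert mine.df == 2

    def test_invariant_to_relabeling_and_time_zero_censoring(self, rng, censored_sample):
        time, event = censored_sample
        g = rng.integers(0, 2, time.size)
        base = logrank_test(time, event, g)
        relabel = logrank_test(time, event, np.where(g == 0, "B", "A"))
        assert relabel.chi2 == pytest.approx(base.chi2)
        padded = logrank_test(
            np.r_[time, 0.0], np.r_[event, False], np.r_[g, 0]
        )
        assert padded.chi2 == pytest.approx(base.chi2)

    def test_duplicate_group_merging_preserves_statistic(self, rng):
        """With group C an exact copy of group B, the 3-group statistic equals
        the 2-group statistic on B and C merged."""
        tA = rng.exponential(10, 15)
        eA = rng.random(15) < 0.8
        tB = rng.exponential(20, 12)
        eB = rng.random(12) < 0.8
        time = np.r_[tA, tB, tB]
        event = np.r_[eA, eB, eB]
        g3 = np.r_[np.zeros(15), np.ones(12), 2 * np.ones(12)]
        g2 = np.r_[np.zeros(15), np.ones(24)]
        assert logrank_test(time, event, g3).chi2 == pytest.approx(
            logrank_test(time, event, g2).chi2
        )

    def test_power_against_hazard_ratio_four(self):
        """HR=4 at n=50/50 with ~30% censoring: p < 0.05 in >= 90% of reps."""
        hits = 0
        reps = 50
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            lam = np.r_[np.full(50, 0.01), np.full(50, 0.04)]
            t = rng.exponential(1 / lam)
            c = rng.uniform(0, 150, 100)
            time, event = np.minimum(t, c), t <= c
            g = np.r_[np.zeros(50), np.ones(50)]
            hits += logrank_test(time, event, g).p < 0.05
        assert hits >= 0.9 * reps

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2, 3], [1, 1, 0], [0, 0, 0])   # one group
        with pytest.raises(ValueError):
            logrank_test([1, 2], [0, 0], [0, 1])             # no events


class TestCox:
    def simulate_cox(self, rng, n, beta):
        x = rng.normal(0, 1, n)
        t = rng.exponential(1 / (0.02 * np.exp(beta * x)))
        c = rng.uniform(0, 120, n)
        return pd.DataFrame({"x": x}), np.minimum(t, c), t <= c

    def test_recovers_log_hazard_ratio(self):
        """True log-HR 0.9 at n=500: mean estimate within 0.15 over 50 seeds."""
        est = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            cov, time, event = self.simulate_cox(rng, 500, 0.9)
            est.append(cox_fit(cov, time, event).coefficients["x"])
        assert abs(np.mean(est) - 0.9) < 0.15

    def test_null_covariate_p_uniform(self):
        pvals = []
        for seed in range(60):
            rng = np.random.default_rng(1000 + seed)
            cov, time, event = self.simulate_cox(rng, 120, 0.0)
            pvals.append(cox_fit(cov, time, event).summary.loc["x", "p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_summary_contract(self, rng):
        cov, time, event = self.simulate_cox(rng, 200, 0.5)
        cov["z"] = rng.normal(0, 1, 200)
        res = cox_fit(cov, time, event)
        np.testing.assert_allclose(
            res.hazard_ratios, np.exp(res.coefficients), rtol=1e-10
        )
        assert (res.summary["ci_lower"] <= res.summary["ci_upper"]).all()
        assert res.ties == "efron"

    def test_constant_covariate_rejected(self, rng):
        cov, time, event = self.simulate_cox(rng, 50, 0.0)
        cov["const"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cox_fit(cov, time, event)


class TestVIF:
    def test_orthogonal_covariates_have_unit_vif(self):
        n = 40
        x = np.arange(n) % 2 - 0.5
        y = np.where(np.arange(n) % 4 < 2, -0.5, 0.5)
        df = pd.DataFrame({"a": x, "b": y})
        np.testing.assert_allclose(vif(df), 1.0, atol=1e-6)

    def test_near_duplicate_covariate_flagged(self, rng):
        x = rng.normal(0, 1, 100)
        df = pd.DataFrame({"a": x, "b": x + rng.normal(0, 1e-4, 100)})
        assert (vif(df) > 10).all()

    def test_vif_at_least_one(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (50, 4)), columns=list("abcd"))
        assert (vif(df) >= 1 - 1e-9).all()


class TestSchoenfeld:
    def test_null_rejection_rate_near_nominal(self):
        rejections = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 120)
            t = rng.exponential(1 / (0.02 * np.exp(0.5 * x)))
            c = rng.uniform(0, 120, 120)
            time, event = np.minimum(t, c), t <= c
            cov = pd.DataFrame({"x": x})
            fit = cox_fit(cov, time, event)
            p = schoenfeld_test(fit, cov, time, event)["x"]
            rejections += p < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) <= 2 * se + 1e-12

    def test_detects_reversing_hazard_effect(self):
        """Effect flips sign at the median time: flagged in >= 80% of seeds."""
        hits = 0
        reps = 20
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            n = 300
            x = rng.normal(0, 1, n)
            # piecewise exponential: hazard exp(+x) before t0, exp(-x) after
            t0 = 20.0
            lam1 = 0.03 * np.exp(0.8 * x)
            lam2 = 0.03 * np.exp(-0.8 * x)
            t_first = rng.exponential(1 / lam1)
            t = np.where(
                t_first < t0, t_first, t0 + rng.exponential(1 / lam2)
            )
            c = rng.uniform(0, 80, n)
            time, event = np.minimum(t, c), t <= c
            cov = pd.DataFrame({"x": x})
            fit = cox_fit(cov, time, event)
            hits += schoenfeld_test(fit, cov, time, event)["x"] < 0.05
        assert hits >= 0.8 * reps

    def test_one_p_per_covariate(self, rng):
        x = rng.normal(0, 1, (100, 3))
        t = rng.exponential(20, 100)
        c = rng.uniform(0, 40, 100)
        time, event = np.minimum(t, c), t <= c
        cov = pd.DataFrame(x, columns=["a", "b", "c"])
        fit = cox_fit(cov, time, event)
        p = schoenfeld_test(fit, cov, time, event)
        assert len(p) == 3 and set(p.index) == {"a", "b", "c"}
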