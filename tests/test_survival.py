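import numpy as np
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

import pandas as pd

from m6apattern.survival import (
    _two_group_logrank_z,
    cox_fit,
    km_estimate,
    logrank_test,
    median_survival,
    surv_cutpoint,
)


class TestKaplanMeier:
    def test_all_censored(self):
        curve = km_estimate([1, 2, 3], [0, 0, 0])
        assert curve.times.size == 0
        assert np.isnan(median_survival(curve))

    def test_all_events_product(self):
        curve = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        # first time S(t) <= 0.5 is t=2 (S=1/3)
        assert median_survival(curve) == 2.0

    def test_hand_computed_mixed_fixture(self):
        # subjects: (1,event) (2,cens) (3,event) (4,event) (5,cens) (6,event)
        curve = km_estimate([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1])
        np.testing.assert_allclose(curve.times, [1, 3, 4, 6])
        # S: 5/6, 5/6*3/4=0.625, 0.625*2/3=0.41667, 0
        np.testing.assert_allclose(
            curve.survival, [5 / 6, 0.625, 5 / 12, 0.0], atol=1e-12
        )
        np.testing.assert_array_equal(curve.at_risk, [6, 4, 3, 1])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10.0, size=50)
        curve = km_estimate(t, np.ones(50))
        for ti, si in zip(curve.times, curve.survival):
            assert si == pytest.approx((t > ti).mean(), abs=1e-12)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10.0, size=80)
        e = rng.integers(0, 2, size=80)
        curve = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ours = pd.Series(curve.survival, index=curve.times)
        theirs = kmf.survival_function_["KM_estimate"]
        for ti in curve.times:
            assert ours[ti] == pytest.approx(theirs.loc[ti], abs=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        chi2, df, p = logrank_test(t, e, [0, 0, 0, 0, 1, 1, 1, 1])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(5.0, 40)
        e = rng.integers(0, 2, 40)
        g = rng.integers(0, 2, 40)
        chi2a, _, _ = logrank_test(t, e, g)
        chi2b, _, _ = logrank_test(t, e, 1 - g)
        assert chi2a == pytest.approx(chi2b, abs=1e-12)

    def test_hand_table_oracle_two_groups(self):
        # 8 subjects, group 0: (1,1) (3,1) (5,0) (7,1); group 1: (2,1) (4,0) (6,1) (8,0)
        t = np.array([1.0, 3, 5, 7, 2, 4, 6, 8])
        e = np.array([1, 1, 0, 1, 1, 0, 1, 0])
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        # brute-force O-E and V accumulated at each distinct event time
        o = ex = v = 0.0
        for ti in np.unique(t[e == 1]):
            at = t >= ti
            n, d = at.sum(), ((t == ti) & (e == 1)).sum()
            n0 = (at & (g == 0)).sum()
            d0 = ((t == ti) & (e == 1) & (g == 0)).sum()
            o += d0
            ex += d * n0 / n
            if n > 1:
                v += d * (n - d) / (n - 1) * (n0 / n) * (1 - n0 / n)
        chi2_oracle = (o - ex) ** 2 / v
        chi2, df, p = logrank_test(t, e, g)
        assert df == 1
        assert chi2 == pytest.approx(chi2_oracle, abs=1e-8)

    def test_matches_lifelines_three_groups(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5.0, 60)
        e = rng.integers(0, 2, 60)
        g = rng.integers(0, 3, 60)
        chi2, df, p = logrank_test(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_invariant_under_monotone_time_transform(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(5.0, 50) + 0.1
        e = rng.integers(0, 2, 50)
        g = rng.integers(0, 2, 50)
        chi2a, _, _ = logrank_test(t, e, g)
        chi2b, _, _ = logrank_test(np.sqrt(t), e, g)
        assert chi2a == pytest.approx(chi2b, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])


class TestCoxFit:
    def test_null_covariate_small_beta(self):
        rng = np.random.default_rng(5)
        n = 500
        x = rng.normal(size=n)
        t = rng.exponential(10.0, n)
        c = rng.uniform(0, 20, n)
        fit = cox_fit(np.minimum(t, c), (t <= c).astype(int), x, ["x"])
        assert abs(fit.terms[0].beta) < 0.2
        assert fit.converged

    def test_planted_log_hr_recovery(self):
        rng = np.random.default_rng(6)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        lam = 0.02 * np.exp(0.7 * x)
        t = rng.exponential(1.0 / lam)
        c = rng.uniform(0, 70, n)
        fit = cox_fit(np.minimum(t, c), (t <= c).astype(int), x, ["x"])
        assert fit.terms[0].beta == pytest.approx(0.7, abs=0.15)
        assert fit.terms[0].ci_low < fit.terms[0].hr < fit.terms[0].ci_high

    def test_duplicate_columns_rejected(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        X = np.column_stack([x, x])
        t = rng.exponential(5.0, 30)
        with pytest.raises(ValueError, match="rank"):
            cox_fit(t, np.ones(30), X, ["a", "b"])

    def test_constant_column_rejected(self):
        t = np.arange(1.0, 11.0)
        with pytest.raises(ValueError, match="constant"):
            cox_fit(t, np.ones(10), np.ones(10), ["c"])

    def test_matches_lifelines_untied(self):
        rng = np.random.default_rng(8)
        n = 120
        X = rng.normal(size=(n, 2))
        lam = 0.05 * np.exp(0.5 * X[:, 0] - 0.3 * X[:, 1])
        t = rng.exponential(1.0 / lam)  # continuous -> no ties
        c = rng.uniform(0, 40, n)
        times, events = np.minimum(t, c), (t <= c).astype(int)
        fit = cox_fit(times, events, X, ["a", "b"])
        df = pd.DataFrame({"t": times, "e": events, "a": X[:, 0], "b": X[:, 1]})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert fit["a"].beta == pytest.approx(cph.params_["a"], abs=1e-5)
        assert fit["b"].beta == pytest.approx(cph.params_["b"], abs=1e-5)
        assert fit["a"].se == pytest.approx(cph.standard_errors_["a"], abs=1e-5)

    def test_efron_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(9)
        n = 100
        x = rng.normal(size=n)
        t = rng.integers(1, 15, size=n).astype(float)  # heavy ties
        e = rng.integers(0, 2, size=n)
        e[0] = 1
        fit = cox_fit(t, e, x, ["x"], ties="efron")
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert fit["x"].beta == pytest.approx(cph.params_["x"], abs=1e-5)

    def test_binary_covariate_no_censoring_closed_form_direction(self):
        rng = np.random.default_rng(10)
        n = 4000
        x = rng.integers(0, 2, n).astype(float)
        lam = 0.05 * np.exp(0.9 * x)
        t = rng.exponential(1.0 / lam)
        fit = cox_fit(t, np.ones(n), x, ["x"])
        assert fit.terms[0].beta == pytest.approx(0.9, abs=0.12)


class TestSurvCutpoint:
    @staticmethod
    def exhaustive_oracle(score, times, events, minprop):
        """Scan every feasible midpoint with an independent per-event-time
        log-rank accumulation."""
        n = len(score)
        distinct = np.unique(score)
        best = None
        for cut in (distinct[:-1] + distinct[1:]) / 2.0:
            high = score > cut
            if min(high.sum(), n - high.sum()) < minprop * n:
                continue
            o = ex = v = 0.0
            for ti in np.unique(times[events == 1]):
                at = times >= ti
                nt, dt = at.sum(), ((times == ti) & (events == 1)).sum()
                n1 = (at & high).sum()
                d1 = ((times == ti) & (events == 1) & high).sum()
                o += d1
                ex += dt * n1 / nt
                if nt > 1:
                    v += dt * (nt - dt) / (nt - 1) * (n1 / nt) * (1 - n1 / nt)
            z = (o - ex) / np.sqrt(v) if v > 0 else 0.0
            if best is None or abs(z) > abs(best[1]) + 1e-12:
                best = (cut, z)
        return best

    def test_equals_exhaustive_scan(self):
        rng = np.random.default_rng(11)
        for rep in range(8):
            n = rng.integers(20, 61)
            score = rng.normal(size=n)
            t = rng.exponential(5.0, n)
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                e[0] = 1
            res = surv_cutpoint(score, t, e, minprop=0.15)
            cut, z = self.exhaustive_oracle(score, t, e, 0.15)
            assert res.cutpoint == pytest.approx(cut, abs=1e-8)
            assert res.statistic == pytest.approx(z, abs=1e-8)

    def test_planted_separation_recovered(self):
        # two constant-hazard halves (HR 4): the maximally selected split
        # recovers the planted partition almost entirely (the exact cut can
        # drift off the gap by noise optima of the correlated z-process)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 200
            score = np.concatenate([rng.normal(0, 0.3, n // 2),
                                    rng.normal(3, 0.3, n // 2)])
            truth = score > 1.5
            lam = np.where(truth, 0.02, 0.08)  # high score protective
            t = rng.exponential(1.0 / lam)
            c = rng.uniform(0, 60, n)
            res = surv_cutpoint(score, np.minimum(t, c), (t <= c).astype(int))
            high = score > res.cutpoint
            agreement = max((high == truth).mean(), (high != truth).mean())
            hits += agreement >= 0.85
        assert hits >= 9

    def test_minprop_counting(self):
        score = np.arange(10.0)
        t = np.arange(1.0, 11.0)
        res = surv_cutpoint(score, t, np.ones(10), minprop=0.49)
        assert len(res.scanned) == 1
        assert res.cutpoint == pytest.approx(4.5)

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError):
            surv_cutpoint(np.ones(20), np.arange(1.0, 21.0), np.ones(20))

    def test_group_sizes_respect_minprop(self):
        rng = np.random.default_rng(12)
        score = rng.normal(size=100)
        t = rng.exponential(5.0, 100)
        e = rng.integers(0, 2, 100)
        e[0] = 1
        res = surv_cutpoint(score, t, e, minprop=0.2)
        assert min(res.group_sizes) >= 20
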