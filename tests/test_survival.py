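"""Survival statistics against brute-force and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmenet import (
    dl_meta, fit_cox_univariate, kaplan_meier, logrank_test, maxstat_cutpoint,
)
from tmenet.survival import cox_score_residual, _logrank_z_thresholds

from conftest import exp_survival


def _surv(times, events):
    return pd.DataFrame({"time": times, "event": events},
                        index=[f"s{i}" for i in range(len(times))])


def naive_logrank_two_group(time, event, group):
    """Independent O-E / hypergeometric-variance log-rank implementation."""
    time, event, group = map(np.asarray, (time, event, group))
    O = E = V = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        r, r1 = at_risk.sum(), (at_risk & group).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & group).sum()
        O += d1
        E += d * r1 / r
        if r > 1:
            V += d * (r1 / r) * (1 - r1 / r) * (r - d) / (r - 1)
    return O - E, V


class TestCox:
    def test_constant_covariate_rejected(self):
        surv = _surv([1, 2, 3, 4], [1, 1, 1, 0])
        with pytest.raises(ValueError, match="variance"):
            fit_cox_univariate([1.0, 1.0, 1.0, 1.0], surv)

    def test_no_events_rejected(self):
        surv = _surv([1, 2, 3], [0, 0, 0])
        with pytest.raises(ValueError):
            fit_cox_univariate([0.0, 1.0, 2.0], surv)

    def test_toy_matches_grid_search_of_partial_likelihood(self):
        # 4 subjects, binary covariate, no ties: brute-force Breslow=Efron here
        surv = _surv([2.0, 5.0, 7.0, 11.0], [1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])

        def loglik(beta):
            t = surv["time"].to_numpy()
            ll = 0.0
            for i in np.argsort(t):
                risk = t >= t[i]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return ll

        grid = np.arange(-5, 5, 1e-4)
        best = grid[np.argmax([loglik(b) for b in grid])]
        fit = fit_cox_univariate(x, surv)
        assert fit.beta == pytest.approx(best, abs=1e-3)
        assert fit.converged

    def test_matches_lifelines_with_ties(self, rng):
        from lifelines import CoxPHFitter

        x = rng.normal(size=80)
        surv = exp_survival(rng, x, beta=0.5)
        surv["time"] = np.ceil(surv["time"])  # force ties
        fit = fit_cox_univariate(x, surv)
        df = surv.copy()
        df["x"] = x
        ll = CoxPHFitter().fit(df, duration_col="time", event_col="event")
        # tolerance reflects lifelines' own stopping rule (its score residual
        # is ~2e-4 where ours is ~1e-15)
        assert fit.beta == pytest.approx(ll.params_["x"], abs=1e-4)
        assert fit.se == pytest.approx(ll.standard_errors_["x"], rel=1e-4)

    def test_score_residual_vanishes_at_mle(self, rng):
        x = rng.normal(size=60)
        surv = exp_survival(rng, x, beta=0.8)
        fit = fit_cox_univariate(x, surv)
        assert abs(cox_score_residual(fit, x, surv)) < 1e-6

    def test_recovers_true_hazard_ratio_two_groups(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = np.repeat([0.0, 1.0], 500)
            surv = exp_survival(rng, x, beta=np.log(2), censor_frac=0.2)
            fit = fit_cox_univariate(x, surv)
            hits += abs(fit.beta - np.log(2)) < 3 * fit.se
        assert hits >= 95

    def test_ci_definition(self, rng):
        x = rng.normal(size=50)
        surv = exp_survival(rng, x, beta=0.5)
        fit = fit_cox_univariate(x, surv)
        assert fit.ci_low == pytest.approx(np.exp(fit.beta - 1.959964 * fit.se))
        assert fit.hr > 0


class TestKaplanMeier:
    def test_three_deaths_no_censoring(self):
        curves = kaplan_meier(_surv([1, 2, 3], [1, 1, 1]))["all"]
        lookup = dict(zip(curves["time"], curves["survival"]))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        curves = kaplan_meier(_surv([1, 2, 3], [0, 0, 0]))["all"]
        np.testing.assert_allclose(curves["survival"], 1.0)

    def test_no_censoring_equals_empirical_fraction(self, rng):
        t = rng.exponential(10, size=40).round(1) + 0.1
        curves = kaplan_meier(_surv(t, np.ones(40, dtype=int)))["all"]
        for time, s in zip(curves["time"], curves["survival"]):
            if time > 0:
                assert s == pytest.approx((t > time).mean(), abs=1e-12)

    def test_monotone_right_continuous(self, rng):
        t = rng.exponential(10, size=30) + 0.1
        e = rng.integers(0, 2, size=30)
        e[0] = 1
        curves = kaplan_meier(_surv(t, e))["all"]
        assert (np.diff(curves["survival"]) <= 1e-12).all()
        assert curves["survival"].iloc[0] == 1.0  # S(0) = 1


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 1]
        surv = _surv(t + t, e + e)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=surv.index)
        chi2, df, p = logrank_test(surv, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_six_subject_toy_matches_hand_computation(self):
        surv = _surv([1, 3, 4, 2, 5, 6], [1, 1, 0, 1, 1, 1])
        groups = pd.Series([True] * 3 + [False] * 3, index=surv.index)
        ome, v = naive_logrank_two_group(surv["time"], surv["event"], groups)
        chi2, df, p = logrank_test(surv, groups.map({True: "a", False: "b"}))
        assert chi2 == pytest.approx(ome**2 / v, rel=1e-9)
        assert p == pytest.approx(stats.chi2.sf(ome**2 / v, 1), rel=1e-9)

    def test_single_group_rejected(self):
        surv = _surv([1, 2], [1, 1])
        with pytest.raises(ValueError):
            logrank_test(surv, pd.Series(["a", "a"], index=surv.index))

    def test_vectorized_z_matches_naive_implementation(self, rng):
        x = rng.normal(size=30)
        surv = exp_survival(rng, x, beta=1.0)
        surv["time"] = np.ceil(surv["time"] * 3)  # ties
        cuts = np.quantile(x, [0.3, 0.5, 0.7])
        zs = _logrank_z_thresholds(surv["time"].to_numpy(),
                                   surv["event"].to_numpy(),
                                   x[:, None], cuts)[:, 0]
        for c, z in zip(cuts, zs):
            ome, v = naive_logrank_two_group(surv["time"], surv["event"], x <= c)
            assert z == pytest.approx(ome / np.sqrt(v), rel=1e-9)


class TestMaxstat:
    def test_matches_exhaustive_brute_force(self, rng):
        for _ in range(10):
            x = rng.normal(size=40)
            surv = exp_survival(rng, x, beta=0.7)
            res = maxstat_cutpoint(x, surv, n_perm=25, seed=1)
            n = len(x)
            best_cut, best_stat = None, -1.0
            for c in np.unique(x):
                n_low = (x <= c).sum()
                if n_low < np.ceil(0.1 * n) or n - n_low < np.ceil(0.1 * n):
                    continue
                ome, v = naive_logrank_two_group(surv["time"], surv["event"], x <= c)
                z = abs(ome / np.sqrt(v))
                if z > best_stat + 1e-12:
                    best_stat, best_cut = z, c
            assert res.cutpoint == pytest.approx(best_cut)
            assert res.statistic == pytest.approx(best_stat, rel=1e-9)

    def test_planted_binary_boundary_recovered(self, rng):
        x = np.repeat([0.0, 1.0], 30)
        surv = exp_survival(rng, x, beta=np.log(3), censor_frac=0.0)
        res = maxstat_cutpoint(x, surv, n_perm=50, seed=2)
        assert res.cutpoint == 0.0
        assert res.n_low == 30 and res.n_high == 30

    def test_null_covariate_rarely_significant(self):
        signif = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            x = rng.normal(size=40)
            surv = exp_survival(rng, np.zeros(40), beta=0.0)
            res = maxstat_cutpoint(x, surv, n_perm=99, seed=seed)
            signif += res.p <= 0.05
        assert signif <= 2  # >=90% non-significant

    def test_minprop_respected_and_errors(self, rng):
        x = rng.normal(size=30)
        surv = exp_survival(rng, x, beta=0.0)
        res = maxstat_cutpoint(x, surv, minprop=0.2, n_perm=10, seed=0)
        assert res.n_low >= 6 and res.n_high >= 6
        with pytest.raises(ValueError):
            maxstat_cutpoint(x[:5], surv.iloc[:5], n_perm=10)


class TestDlMeta:
    def test_single_study_passthrough(self):
        res = dl_meta([0.4], [0.1])
        assert res.pooled_log_hr == pytest.approx(0.4)
        assert res.pooled_se == pytest.approx(0.1)
        assert res.tau2 == 0.0

    def test_two_equal_studies_closed_form(self):
        res = dl_meta([0.5, 0.5], [0.2, 0.2])
        assert res.q == pytest.approx(0.0, abs=1e-12)
        assert res.tau2 == 0.0
        assert res.pooled_log_hr == pytest.approx(0.5)
        assert res.pooled_se == pytest.approx(0.2 / np.sqrt(2))

    def test_matches_statsmodels_dl(self, rng):
        from statsmodels.stats.meta_analysis import combine_effects

        y = rng.normal(0.5, 1.0, size=8)  # heterogeneous: tau2 > 0
        se = rng.uniform(0.1, 0.4, size=8)
        res = dl_meta(y, se)
        sm = combine_effects(y, se**2, method_re="dl")
        assert sm.tau2 > 0
        assert res.tau2 == pytest.approx(sm.tau2, rel=1e-8)
        assert res.pooled_log_hr == pytest.approx(sm.mean_effect_re, rel=1e-8)

    def test_reduces_to_fixed_effect_when_homogeneous(self):
        y = [0.5, 0.52, 0.48]
        se = [0.3, 0.3, 0.3]
        res = dl_meta(y, se)
        assert res.tau2 == 0.0
        w = 1 / np.array(se) ** 2
        assert res.pooled_log_hr == pytest.approx(np.sum(w * y) / np.sum(w))

    def test_homogeneous_effect_recovery(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            se = rng.uniform(0.15, 0.3, size=10)
            y = rng.normal(0.7, se)
            res = dl_meta(y, se)
            hits += abs(res.pooled_log_hr - 0.7) < 3 * res.pooled_se
        assert hits >= 47  # >=95% of 50 seeds (integer floor)
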