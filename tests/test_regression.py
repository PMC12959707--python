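"""Cox and Fine-Gray fitters and Gray's test: brute-force partial-likelihood
oracles on tiny datasets, library cross-checks, reductions and power."""

import numpy as np
import pandas as pd
import pytest

import lymphrisk as lr
from lymphrisk.cohort import CohortTable
from lymphrisk.regression import bootstrap_se

from conftest import competing_exponential, make_cohort


# --- independent oracles (deliberately naive; loops over definitions) ----


def naive_cox_loglik(beta, times, causes, x, cause=1):
    """Breslow log partial likelihood computed by direct summation."""
    ll = 0.0
    times = np.asarray(times, float)
    x = np.asarray(x, float)
    for i in range(len(times)):
        if causes[i] == cause:
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def naive_censoring_km(times, causes):
    """Censoring-distribution KM; deaths leave the risk set first at ties."""
    times = np.asarray(times, float)
    causes = np.asarray(causes, int)
    uts = np.unique(times)
    surv, out_t, out_s = 1.0, [], []
    for t in uts:
        n = np.sum(times >= t)
        d = np.sum((times == t) & (causes > 0))
        c = np.sum((times == t) & (causes == 0))
        if c > 0:
            surv *= 1 - c / (n - d)
        out_t.append(t)
        out_s.append(surv)
    return np.array(out_t), np.array(out_s)


def naive_fine_gray_loglik(beta, times, causes, x, cause=1):
    """Weighted Breslow log-likelihood with the subdistribution risk set,
    w_i(t) = G(t)/G(min(T_i, t)), computed by direct summation."""
    times = np.asarray(times, float)
    causes = np.asarray(causes, int)
    x = np.asarray(x, float)
    other = 2 if cause == 1 else 1
    gt, gs = naive_censoring_km(times, causes)

    def G(t):
        idx = np.searchsorted(gt, t, side="right") - 1
        return 1.0 if idx < 0 else gs[idx]

    ll = 0.0
    for i in range(len(times)):
        if causes[i] != cause:
            continue
        t = times[i]
        denom = 0.0
        for j in range(len(times)):
            if times[j] >= t:
                w = 1.0
            elif causes[j] == other:
                w = G(t) / G(times[j])
            else:
                continue
            denom += w * np.exp(beta * x[j])
        ll += beta * x[i] - np.log(denom)
    return ll


def grid_argmax(fun, lo=-5.0, hi=5.0, step=1e-4):
    grid = np.arange(lo, hi + step, step)
    vals = np.array([fun(b) for b in grid])
    return grid[np.argmax(vals)]


def to_cohort(times, causes, x):
    return make_cohort(times, causes, x=np.asarray(x, float))


# ------------------------------ Cox --------------------------------------


class TestCox:
    def test_six_subject_matches_grid_search_oracle(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        causes = [1, 0, 1, 1, 0, 1]
        x = [1, 1, 0, 1, 0, 0]
        fit = lr.fit_cox(to_cohort(times, causes, x), ["x"], cause=1)
        best = grid_argmax(lambda b: naive_cox_loglik(b, times, causes, x))
        assert fit.coef[0] == pytest.approx(best, abs=1e-4)

    def test_null_covariate_within_3se_of_zero(self):
        t, c, _ = competing_exponential(3000, seed=10)
        rng = np.random.default_rng(11)
        x = rng.integers(0, 2, 3000).astype(float)  # independent of outcome
        fit = lr.fit_cox(to_cohort(t, c, x), ["x"], cause=1)
        assert abs(fit.coef[0]) < 3 * fit.se[0]

    def test_recovers_true_hazard_ratio_two(self):
        t, c, x = competing_exponential(2000, seed=1, beta1=np.log(2.0))
        fit = lr.fit_cox(to_cohort(t, c, x), ["x"], cause=1)
        assert 1.7 < fit.hazard_ratios[0] < 2.35
        assert abs(fit.coef[0] - np.log(2.0)) < 3 * fit.se[0]

    def test_matches_lifelines_coefficients_and_se(self):
        from lifelines import CoxPHFitter

        t, c, x = competing_exponential(400, seed=12, beta1=0.5, beta2=-0.3)
        df = pd.DataFrame({"T": t, "E": (c == 1).astype(int), "x": x})
        ll = CoxPHFitter().fit(df, "T", "E")
        fit = lr.fit_cox(to_cohort(t, c, x), ["x"], cause=1)
        assert fit.coef[0] == pytest.approx(ll.params_.iloc[0], abs=2e-5)
        assert fit.se[0] == pytest.approx(ll.standard_errors_.iloc[0], rel=1e-4)

    def test_time_updated_exposure_matches_lifelines_tv(self):
        from lifelines import CoxTimeVaryingFitter

        cfg = lr.SimulationConfig(n_subjects=600, seed=13)
        cohort = lr.simulate_cohort(cfg)
        cp = lr.expand_counting_process(cohort, ["sm"])
        fit = lr.fit_cox(cp, ["age_gt60", "sm"], cause=2)
        df = cp.data[["subject_id", "start", "stop", "status", "age_gt60", "sm"]].copy()
        df["event"] = (df["status"] == 2).astype(int)
        ctv = CoxTimeVaryingFitter().fit(
            df.drop(columns="status"), id_col="subject_id",
            start_col="start", stop_col="stop", event_col="event",
        )
        np.testing.assert_allclose(fit.coef, ctv.params_.to_numpy(), atol=5e-5)

    def test_score_at_solution_is_small(self):
        from lymphrisk.regression import _RiskSums, _fail_groups, _partial_likelihood

        t, c, x = competing_exponential(500, seed=14, beta1=0.7)
        X = np.asarray(x, float)[:, None]
        ev, fail_X, fail_counts, _ = _fail_groups(t, c, X, 1)
        engine = _RiskSums(np.zeros_like(t), t, X, ev)
        fit = lr.fit_cox(to_cohort(t, c, x), ["x"], cause=1)
        _, score, _ = _partial_likelihood(fit.coef, engine, fail_X, fail_counts)
        assert np.max(np.abs(score)) < 1e-6

    def test_complete_separation_flagged(self):
        times = [1, 2, 3, 4, 9, 10, 11, 12]
        causes = [1] * 8
        x = [1, 1, 1, 1, 0, 0, 0, 0]
        with pytest.warns(UserWarning, match="separation"):
            fit = lr.fit_cox(to_cohort(times, causes, x), ["x"], cause=1)
        assert not fit.converged
        assert abs(fit.coef[0]) <= 15.0

    def test_no_events_is_an_error(self):
        with pytest.raises(lr.FitError, match="no events"):
            lr.fit_cox(to_cohort([1, 2], [0, 0], [0, 1]), ["x"], cause=1)


# ----------------------------- Fine-Gray ----------------------------------


class TestFineGray:
    def test_reduces_to_cox_without_competing_events(self):
        t, c, x = competing_exponential(300, seed=20, lam2=0.0, beta1=0.4)
        fg = lr.fit_fine_gray(to_cohort(t, c, x), ["x"], cause=1)
        cox = lr.fit_cox(to_cohort(t, c, x), ["x"], cause=1)
        assert abs(fg.coef[0] - cox.coef[0]) < 1e-8

    def test_eight_subject_toy_matches_grid_search_oracle(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        causes = [1, 2, 1, 0, 1, 0, 1, 0]  # one competing event at t=2
        x = [1, 1, 0, 1, 1, 0, 0, 0]
        fit = lr.fit_fine_gray(to_cohort(times, causes, x), ["x"], cause=1)
        best = grid_argmax(lambda b: naive_fine_gray_loglik(b, times, causes, x))
        assert fit.coef[0] == pytest.approx(best, abs=1e-4)

    def test_recovers_true_subdistribution_hr(self):
        times, causes, x = lr.simulate_fine_gray(4000, np.log(2.0), seed=2)
        fit = lr.fit_fine_gray(to_cohort(times, causes, x), ["x"], cause=1)
        assert abs(fit.coef[0] - np.log(2.0)) < 3 * fit.se[0]

    def test_matches_published_crr_fit(self):
        # frozen oracle: cmprsk::crr on the same 150-subject draw returns
        # coef 0.5432376, se 0.2356211
        times, causes, x = lr.simulate_fine_gray(150, 0.8, seed=5)
        fit = lr.fit_fine_gray(to_cohort(times, causes, x), ["x"], cause=1)
        assert fit.coef[0] == pytest.approx(0.5432376, abs=5e-5)
        assert fit.se[0] == pytest.approx(0.2356211, rel=0.02)

    def test_sandwich_se_consistent_with_bootstrap(self):
        times, causes, x = lr.simulate_fine_gray(400, 0.5, seed=6)
        cohort = to_cohort(times, causes, x)
        fit = lr.fit_fine_gray(cohort, ["x"], cause=1)
        se_boot = bootstrap_se(cohort, ["x"], cause=1, n_boot=200, seed=7)
        assert fit.se[0] == pytest.approx(se_boot[0], rel=0.25)


# ----------------------------- Gray test ----------------------------------


class TestGrayTest:
    def test_agrees_with_logrank_without_competing_events(self):
        from lifelines.statistics import logrank_test

        diffs = []
        for s in range(100):
            t, c, x = competing_exponential(150, seed=100 + s, lam2=0.0, beta1=0.3)
            p_gray = lr.gray_test(t, c, x.astype(int), cause=1).p
            p_lr = logrank_test(t[x == 0], t[x == 1], c[x == 0] > 0, c[x == 1] > 0).p_value
            diffs.append(abs(p_gray - p_lr))
        assert max(diffs) < 0.02

    def test_strong_separation_is_significant(self):
        times, causes, x = lr.simulate_fine_gray(500, np.log(5.0), seed=8)
        assert lr.gray_test(times, causes, x.astype(int), cause=1).p < 0.001

    def test_agrees_with_permutation_reference(self):
        t, c, x = competing_exponential(120, seed=9, beta1=0.5)
        asym = lr.gray_test(t, c, x.astype(int), cause=1)
        perm = lr.gray_test_permutation(t, c, x.astype(int), cause=1, n_perm=2000, seed=1)
        assert perm.statistic == asym.statistic
        assert abs(perm.p - asym.p) < 0.05

    def test_three_groups_have_two_df(self):
        rng = np.random.default_rng(10)
        t, c, _ = competing_exponential(300, seed=10)
        g = rng.integers(0, 3, 300)
        res = lr.gray_test(t, c, g, cause=1)
        assert res.df == 2 and 0 <= res.p <= 1

    def test_empty_group_rejected(self):
        t, c, _ = competing_exponential(50, seed=11)
        with pytest.raises(ValueError, match="2 groups"):
            lr.gray_test(t, c, np.zeros(50, dtype=int), cause=1)
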