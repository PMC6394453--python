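from datetime import date

import numpy as np
import pytest

from petstrat.survival import (
    DataError,
    assign_groups,
    build_endpoints,
    cox_fit,
    cox_loglik,
    doubling_time,
    km_estimate,
    logrank_test,
    median_followup_reverse_km,
    roc_auc,
    youden_cutoff,
)
from petstrat.synthetic import CohortSpec, generate_cohort, survival_to_frame

import oracles


class TestEndpoints:
    def test_death_event(self):
        r = build_endpoints(date(2010, 1, 1), None, date(2014, 1, 1), date(2016, 6, 1))
        assert r["os_years"] == pytest.approx(4.0, abs=0.01)
        assert r["os_event"] is True
        assert r["pfs_event"] is False  # censored at censor date

    def test_censored_pfs(self):
        r = build_endpoints(date(2010, 1, 1), None, None, date(2016, 5, 26))
        assert r["pfs_years"] == pytest.approx(6.4, abs=0.01)
        assert r["pfs_event"] is False

    def test_death_before_start_errors(self):
        with pytest.raises(DataError):
            build_endpoints(date(2010, 1, 1), None, date(2009, 1, 1), date(2016, 1, 1))


class TestRocAuc:
    def test_perfect_separation(self):
        curve = roc_auc([1, 2, 3, 4], [0, 0, 1, 1])
        assert curve.auc == 1.0

    def test_hand_counted_auc(self):
        # pairs: (2,1) (2,3) (4,1) (4,3) -> 3 concordant of 4
        curve = roc_auc([1, 3, 2, 4], [0, 0, 1, 1])
        assert curve.auc == 0.75

    def test_null_limit(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=4000)
        y = rng.binomial(1, 0.5, size=4000)
        assert roc_auc(v, y).auc == pytest.approx(0.5, abs=0.03)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_pairwise_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.integers(0, 6, size=40).astype(float)  # heavy ties
        y = rng.binomial(1, 0.5, size=40)
        if y.sum() in (0, 40):
            y[0] = 1 - y[0]
        assert roc_auc(v, y).auc == pytest.approx(
            oracles.auc_pairwise_oracle(v, y), abs=1e-12
        )


class TestYouden:
    def test_simple_cutoff(self):
        cut = youden_cutoff(roc_auc([1, 2, 3, 4], [0, 0, 1, 1]))
        assert cut.cutoff == 2.5
        assert cut.youden_j == pytest.approx(1.0)
        assert cut.sensitivity == 100.0 and cut.specificity == 100.0
        assert cut.n_above == 2 and cut.n_below == 2

    def test_all_equal_degenerate(self):
        cut = youden_cutoff(roc_auc([5, 5, 5, 5], [0, 1, 0, 1]))
        assert cut.degenerate
        assert cut.youden_j == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        v = np.round(rng.normal(size=n), 1)  # induce occasional ties
        y = rng.binomial(1, 0.5, size=n)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        cut = youden_cutoff(roc_auc(v, y))
        j_ref, cut_ref = oracles.youden_exhaustive_oracle(v, y)
        assert cut.youden_j == pytest.approx(j_ref, abs=1e-12)
        assert cut.cutoff == pytest.approx(cut_ref) or (
            np.isinf(cut.cutoff) and np.isinf(cut_ref)
        )

    def test_assign_groups_strict_greater(self):
        groups = assign_groups([1.0, 2.5, 2.5, 4.0], 2.5)
        np.testing.assert_array_equal(groups, [False, False, False, True])  # ties go low


class TestKaplanMeier:
    def test_all_events_product_limit(self):
        est = km_estimate([1, 2, 3], [1, 1, 1])
        lookup = dict(zip(est.times, est.survival))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == pytest.approx(0.0)
        assert est.median == 2.0

    def test_censoring_hand_computation(self):
        est = km_estimate([1, 2, 3], [0, 1, 1])
        lookup = dict(zip(est.times, est.survival))
        assert lookup[2.0] == pytest.approx(0.5)
        assert lookup[3.0] == pytest.approx(0.0)
        assert est.median == 2.0

    def test_no_events_median_undefined(self):
        est = km_estimate([1, 2, 3], [0, 0, 0])
        assert np.all(est.survival == 1.0)
        assert not est.median_defined

    def test_matches_oracle_and_is_nonincreasing(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(2.0, size=60)
        e = rng.binomial(1, 0.7, size=60).astype(bool)
        est = km_estimate(t, e)
        assert np.all(np.diff(est.survival) <= 1e-12)
        lookup = {tt: ss for tt, ss in zip(est.times, est.survival)}
        for ut, s_ref in oracles.km_oracle(t, e):
            assert lookup[ut] == pytest.approx(s_ref, rel=1e-9)

    def test_reverse_km_median_followup(self):
        # with no events, reverse KM median is the plain median of times
        m = median_followup_reverse_km([1.0, 2.0, 3.0, 4.0, 5.0], [0, 0, 0, 0, 0])
        assert m == 3.0


class TestLogrank:
    def test_identical_groups(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 1]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_power_under_strong_effect(self):
        hits = 0
        for seed in range(40):
            _, surv = generate_cohort(CohortSpec(n_patients=500, hazard_ratio=6.0, seed=seed))
            df = survival_to_frame(surv)
            g = df["group"].to_numpy().astype(bool)
            t, e = df["os_years"].to_numpy(), df["os_event"].to_numpy().astype(bool)
            _, p = logrank_test(t[g], e[g], t[~g], e[~g])
            hits += p < 0.001
        assert hits >= 38  # >= 95% of seeds


class TestCox:
    def test_symmetric_groups_give_hr_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        e = np.ones(8, dtype=bool)
        x = np.array([0.0] * 4 + [1.0] * 4)
        res = cox_fit(x[:, None], t, e)
        assert res.hazard_ratio[0] == pytest.approx(1.0, abs=1e-6)

    def test_bruteforce_likelihood_oracle_on_tied_fixture(self):
        # 8 patients with tied event times; Breslow beta-hat must match the
        # grid maximizer of the directly-summed partial likelihood
        t = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 5.0])
        e = np.array([1, 1, 1, 0, 1, 1, 0, 1], dtype=bool)
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0, 0.0])
        res = cox_fit(x[:, None], t, e, ties="breslow")
        grid = np.arange(-3.0, 3.0, 1e-4)
        lls = [oracles.breslow_loglik_oracle(b, x, t, e) for b in grid]
        beta_ref = grid[int(np.argmax(lls))]
        assert res.coef[0] == pytest.approx(beta_ref, abs=1e-4)

    def test_matches_lifelines_on_tie_free_data(self):
        from lifelines import CoxPHFitter
        import pandas as pd

        _, surv = generate_cohort(CohortSpec(n_patients=400, hazard_ratio=3.0, seed=11))
        df = survival_to_frame(surv)
        res = cox_fit(df[["group", "age"]].to_numpy(), df["os_years"].to_numpy(),
                      df["os_event"].to_numpy().astype(bool), terms=["group", "age"])
        cph = CoxPHFitter().fit(df[["os_years", "os_event", "group", "age"]],
                                "os_years", "os_event")
        np.testing.assert_allclose(res.coef, cph.params_.values, rtol=1e-5, atol=1e-7)
        np.testing.assert_allclose(res.se, cph.standard_errors_.values, rtol=1e-4)

    def test_efron_matches_breslow_without_ties(self):
        _, surv = generate_cohort(CohortSpec(n_patients=150, hazard_ratio=2.0, seed=3))
        df = survival_to_frame(surv)
        args = (df["group"].to_numpy()[:, None], df["os_years"].to_numpy(),
                df["os_event"].to_numpy().astype(bool))
        a = cox_fit(*args, ties="breslow")
        b = cox_fit(*args, ties="efron")
        assert a.coef[0] == pytest.approx(b.coef[0], rel=1e-8)

    def test_separation_is_flagged(self):
        # group 1 all early events, group 0 all late: monotone likelihood
        t = np.array([1, 2, 3, 4, 10, 11, 12, 13], dtype=float)
        e = np.ones(8, dtype=bool)
        x = np.array([1.0] * 4 + [0.0] * 4)
        res = cox_fit(x[:, None], t, e)
        assert not res.converged
        assert res.flags

    def test_ci_contains_hr_and_exp_relation(self):
        _, surv = generate_cohort(CohortSpec(n_patients=200, hazard_ratio=4.0, seed=21))
        df = survival_to_frame(surv)
        res = cox_fit(df["group"].to_numpy()[:, None], df["os_years"].to_numpy(),
                      df["os_event"].to_numpy().astype(bool))
        hr = res.hazard_ratio[0]
        assert res.ci95[0, 0] < hr < res.ci95[0, 1]
        assert hr == pytest.approx(np.exp(res.coef[0]))

    def test_no_events_errors(self):
        with pytest.raises(ValueError):
            cox_fit(np.zeros((4, 1)), [1, 2, 3, 4], [0, 0, 0, 0])


class TestDoublingTime:
    def test_exact_doubling(self):
        assert doubling_time([0.0, 1.0], [100.0, 200.0]).doubling_time_years == pytest.approx(1.0)

    def test_exact_log_linear_fit(self):
        r = doubling_time([0.0, 1.0, 2.0], [100.0, 200.0, 400.0])
        assert r.doubling_time_years == pytest.approx(1.0, rel=1e-12)

    def test_flat_marker_flagged(self):
        r = doubling_time([0.0, 1.0, 2.0], [100.0, 100.0, 100.0])
        assert r.flat and np.isinf(r.doubling_time_years)

    def test_declining_marker(self):
        r = doubling_time([0.0, 1.0], [200.0, 100.0])
        assert r.declining and r.doubling_time_years == pytest.approx(-1.0)

    def test_non_positive_marker_errors(self):
        with pytest.raises(ValueError):
            doubling_time([0.0, 1.0], [0.0, 100.0])


class TestCoxLoglikInternals:
    def test_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(8)
        n = 40
        X = rng.normal(size=(n, 2))
        t = rng.exponential(1.0, size=n)
        e = rng.binomial(1, 0.8, size=n).astype(bool)
        beta = np.array([0.3, -0.2])
        ll, grad, hess = cox_loglik(beta, X, t, e)
        eps = 1e-6
        for k in range(2):
            db = np.zeros(2)
            db[k] = eps
            ll_hi, _, _ = cox_loglik(beta + db, X, t, e)
            ll_lo, _, _ = cox_loglik(beta - db, X, t, e)
            assert grad[k] == pytest.approx((ll_hi - ll_lo) / (2 * eps), rel=1e-4, abs=1e-6)
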