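import numpy as np
import pandas as pd
import pytest

from tespipe.errors import DegenerateCovariateError
from tespipe.survival import (
    cox_fit,
    cox_univariate,
    km_estimate,
    logrank_test,
    restricted_mean_survival,
)

from conftest import make_survival


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        """times (1,2,3), events (1,0,1): S = 2/3 on [1,3), 0 at 3."""
        table = make_survival([1, 2, 3], [1, 0, 1])
        sf = km_estimate(table)["all"]
        s = dict(zip(sf["time"], sf["survival"]))
        assert s[1.0] == pytest.approx(2 / 3)
        assert s[3.0] == pytest.approx(0.0)

    def test_all_censored_flat_one(self):
        sf = km_estimate(make_survival([1, 2, 3], [0, 0, 0]))["all"]
        np.testing.assert_allclose(sf["survival"], 1.0)

    def test_tied_events_pooled_into_one_step(self):
        sf = km_estimate(make_survival([2, 2, 5], [1, 1, 1]))["all"]
        s = dict(zip(sf["time"], sf["survival"]))
        assert s[2.0] == pytest.approx(1 / 3)

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(10, size=40)
        table = make_survival(times, np.ones(40))
        sf = km_estimate(table)["all"]
        for t, s in zip(sf["time"], sf["survival"]):
            if t > 0:
                assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_survival_nonincreasing(self):
        rng = np.random.default_rng(3)
        table = make_survival(rng.exponential(5, 50), rng.integers(0, 2, 50))
        sf = km_estimate(table)["all"]
        assert (np.diff(sf["survival"]) <= 1e-12).all()


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        table = make_survival([1, 2, 3, 1, 2, 3], [1, 0, 1, 1, 0, 1])
        groups = pd.Series([0, 0, 0, 1, 1, 1], index=table.sample_ids)
        stat, p = logrank_test(table, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_hypergeometric_sum(self):
        """A:(1,1),(3,1); B:(2,1),(4,1): chi2 = (2 - 4/3)^2 / (13/18)."""
        table = make_survival([1, 3, 2, 4], [1, 1, 1, 1])
        groups = pd.Series(["A", "A", "B", "B"], index=table.sample_ids)
        stat, p = logrank_test(table, groups)
        assert stat == pytest.approx(0.6153846153846155, abs=1e-9)
        assert p == pytest.approx(0.43276758066778453, abs=1e-9)

    def test_time_transform_invariance(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(5, 30)
        events = rng.integers(0, 2, 30)
        groups = pd.Series(rng.integers(0, 2, 30), index=[f"S{i}" for i in range(30)])
        s1 = logrank_test(make_survival(times, events), groups)
        s2 = logrank_test(make_survival(np.exp(times / 10), events), groups)
        assert s1[0] == pytest.approx(s2[0], abs=1e-9)

    def test_single_group_rejected(self):
        table = make_survival([1, 2], [1, 1])
        with pytest.raises(ValueError):
            logrank_test(table, pd.Series([1, 1], index=table.sample_ids))

    def test_null_type_one_error_calibrated(self):
        """Random splits of exponential data reject at ~5%."""
        rng = np.random.default_rng(10)
        n, reps = 60, 500
        rejections = 0
        for _ in range(reps):
            table = make_survival(rng.exponential(10, n), np.ones(n))
            groups = pd.Series(rng.integers(0, 2, n), index=table.sample_ids)
            if groups.nunique() < 2:
                continue
            _, p = logrank_test(table, groups)
            rejections += p < 0.05
        rate = rejections / reps
        sd = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * sd


class TestCox:
    def test_two_group_hr_recovered(self):
        """Exponential data with true HR 3: exp(beta) within 20%."""
        rng = np.random.default_rng(20)
        n = 500
        group = rng.integers(0, 2, n)
        times = rng.exponential(1.0 / (0.01 * 3.0**group))
        table = make_survival(times, np.ones(n))
        res = cox_univariate(table, pd.Series(group.astype(float),
                                              index=table.sample_ids, name="g"))
        assert res.hazard_ratio == pytest.approx(3.0, rel=0.2)
        assert res.direction == "risk"
        # closed-form two-group exponential MLE as an independent check
        hr_mle = (group.sum() / times[group == 1].sum()) / \
                 ((n - group.sum()) / times[group == 0].sum())
        assert res.hazard_ratio == pytest.approx(hr_mle, rel=0.05)

    def test_sign_equivariance(self):
        rng = np.random.default_rng(21)
        n = 80
        x = pd.Series(rng.normal(size=n), index=[f"S{i}" for i in range(n)], name="x")
        times = rng.exponential(np.exp(-0.5 * x.to_numpy()))
        table = make_survival(times, np.ones(n), ids=list(x.index))
        r1 = cox_univariate(table, x)
        r2 = cox_univariate(table, -x)
        assert r1.beta == pytest.approx(-r2.beta, abs=1e-6)
        assert abs(r1.z) == pytest.approx(abs(r2.z), abs=1e-6)

    def test_zero_variance_covariate_rejected(self):
        table = make_survival([1, 2, 3], [1, 1, 0])
        with pytest.raises(DegenerateCovariateError):
            cox_univariate(table, pd.Series([1.0, 1.0, 1.0], index=table.sample_ids))

    def test_matches_lifelines_on_tie_free_data(self):
        """Without tied event times Breslow and Efron coincide, so the
        solver must agree with lifelines' Cox fit."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(22)
        n = 120
        x = rng.normal(size=n)
        times = rng.exponential(np.exp(-0.7 * x))
        events = rng.integers(0, 2, n)
        events[:5] = 1
        table = make_survival(times, events)
        res = cox_univariate(table, pd.Series(x, index=table.sample_ids, name="x"))

        df = pd.DataFrame({"t": times, "e": events, "x": x})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert res.beta == pytest.approx(float(cph.params_["x"]), abs=1e-5)
        assert res.p_value == pytest.approx(float(cph.summary.loc["x", "p"]), abs=1e-5)

    def test_breslow_tie_handling_frozen_oracle(self):
        """Tied-event fixture with coefficients frozen from an independent
        reference fit using Breslow tie handling."""
        t = [5, 5, 8, 2, 2, 2, 11, 3, 7, 5, 1, 9]
        e = [1, 1, 1, 1, 0, 1, 0, 1, 1, 1, 1, 1]
        x = [0.3, -1.2, 0.5, 2.1, -0.4, 1.7, -2.0, 0.9, -0.6, 1.1, 0.2, -1.5]
        table = make_survival(t, e)
        res = cox_univariate(table, pd.Series(x, index=table.sample_ids, name="x"))
        assert res.beta == pytest.approx(0.891749263270, abs=1e-8)
        assert res.se == pytest.approx(0.384305933918, abs=1e-8)
        assert res.p_value == pytest.approx(0.0203184368667, abs=1e-8)

    def test_partial_likelihood_beats_null_and_grid(self):
        rng = np.random.default_rng(23)
        n = 25
        x = rng.normal(size=n)
        times = rng.exponential(np.exp(-x))
        table = make_survival(times, np.ones(n))
        res = cox_univariate(table, pd.Series(x, index=table.sample_ids, name="x"))
        from tespipe.survival import _cox_negloglik_parts

        order = np.argsort(-times)
        xs, ts, es = x[order, None], times[order], np.ones(n)[order]
        ll_hat = _cox_negloglik_parts(np.array([res.beta]), xs, ts, es)[0]
        ll_null = _cox_negloglik_parts(np.array([0.0]), xs, ts, es)[0]
        assert ll_hat >= ll_null
        grid = np.linspace(res.beta - 2, res.beta + 2, 4001)
        lls = [_cox_negloglik_parts(np.array([b]), xs, ts, es)[0] for b in grid]
        assert abs(grid[int(np.argmax(lls))] - res.beta) < 1e-3

    def test_null_covariate_calibrated(self):
        """Permuted covariate: ~5% of Wald p-values below 0.05."""
        rng = np.random.default_rng(24)
        n, reps = 80, 500
        rejections = 0
        for _ in range(reps):
            times = rng.exponential(10, n)
            x = pd.Series(rng.normal(size=n), index=[f"S{i}" for i in range(n)],
                          name="x")
            table = make_survival(times, np.ones(n), ids=list(x.index))
            rejections += cox_univariate(table, x).p_value < 0.05
        rate = rejections / reps
        sd = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * sd

    def test_multivariate_signature(self):
        rng = np.random.default_rng(25)
        n = 100
        x = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"],
                         index=[f"S{i}" for i in range(n)])
        times = rng.exponential(np.exp(-x["a"].to_numpy()))
        table = make_survival(times, np.ones(n), ids=list(x.index))
        results = cox_fit(table, x)
        assert [r.covariate for r in results] == ["a", "b"]
        assert results[0].p_value < 0.01


def test_restricted_mean_no_censoring_is_capped_mean():
    table = make_survival([1.0, 2.0, 3.0], [1, 1, 1])
    assert restricted_mean_survival(table) == pytest.approx(2.0)
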