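"""Survival statistics: KM, log-rank, Cox, cutpoint, time-ROC, C-index."""

import numpy as np
import pandas as pd
import pytest

from tics import (
    concordance_index,
    cox_fit,
    cox_score_test,
    dichotomize_median,
    km_estimate,
    logrank_test,
    optimal_cutoff,
    time_dependent_auc,
)
from tics.survival import _logrank_z

from conftest import make_survival
from oracles import cox_grid_search


def _sim_cohort(rng, n, beta=0.0, censor=0.3):
    x = rng.normal(size=n)
    t = rng.exponential(1.0 / np.exp(beta * x))
    c = rng.exponential(1.0 / censor, size=n)
    return make_survival(np.minimum(t, c), (t <= c).astype(int)), x


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        surv = make_survival([1, 2, 3, 4], [1, 1, 1, 1])
        km = km_estimate(surv)
        np.testing.assert_allclose(km.survival, [0.75, 0.5, 0.25, 0.0])

    def test_censored_subject_leaves_risk_set(self):
        # times {1,2,3}, events {1,0,1}: S(1)=2/3; at t=3 only one subject
        # remains at risk, so the product-limit drops to 0
        km = km_estimate(make_survival([1, 2, 3], [1, 0, 1]))
        np.testing.assert_allclose(km.times, [1, 3])
        assert km.survival[0] == pytest.approx(2 / 3)
        assert km.survival[-1] == pytest.approx((2 / 3) * (1 - 1 / 1))

    def test_all_censored_flat_with_warning(self):
        with pytest.warns(UserWarning, match="no events"):
            km = km_estimate(make_survival([1, 2, 3], [0, 0, 0]))
        assert km.times.size == 0
        assert km.survival_at(2.5) == 1.0

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(1)
        surv, _ = _sim_cohort(rng, 60)
        km = km_estimate(surv)
        assert np.all(np.diff(km.survival) <= 1e-15)
        assert np.all((km.survival >= 0) & (km.survival <= 1))


class TestLogrank:
    def test_mirror_data_statistic_zero(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        d = [1, 0, 1, 1, 1, 0, 1, 1]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        chi2, p = logrank_test(make_survival(t, d), g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_lifelines(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(2)
        for _ in range(5):
            surv, x = _sim_cohort(rng, 80, beta=0.4)
            g = (x > 0).astype(int)
            chi2, p = logrank_test(surv, g)
            ref = lifelines_stats.logrank_test(
                surv.data["time"][g == 0], surv.data["time"][g == 1],
                surv.data["event"][g == 0], surv.data["event"][g == 1],
            )
            assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
            assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(make_survival([1, 2], [1, 1]), [1, 1])

    def test_null_calibration(self):
        """Rejection rate under permuted labels is close to nominal."""
        rng = np.random.default_rng(3)
        n_reject = 0
        reps = 400
        for _ in range(reps):
            surv, _ = _sim_cohort(rng, 100)
            g = rng.permutation(np.repeat([0, 1], 50))
            _, p = logrank_test(surv, g)
            n_reject += p < 0.05
        assert n_reject / reps == pytest.approx(0.05, abs=0.025)


class TestCox:
    def test_symmetric_groups_beta_zero(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        d = [1, 1, 0, 1, 1, 1, 0, 1]
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        res = cox_fit(make_survival(t, d), x[:, None])[0]
        assert res.beta == pytest.approx(0.0, abs=1e-8)

    def test_grid_search_oracle_six_observations(self):
        t = [2.0, 5.0, 1.0, 7.0, 4.0, 9.0]
        d = [1, 1, 1, 1, 1, 0]
        x = [0.2, 1.0, -0.5, 0.7, -1.2, 0.4]
        res = cox_fit(make_survival(t, d), np.array(x)[:, None])[0]
        oracle = cox_grid_search(t, d, x)
        assert res.beta == pytest.approx(oracle, abs=1e-3)

    def test_matches_lifelines_multivariate(self):
        CoxPHFitter = pytest.importorskip("lifelines").CoxPHFitter
        rng = np.random.default_rng(4)
        n = 120
        X = rng.normal(size=(n, 2))
        t = rng.exponential(1 / np.exp(0.4 * X[:, 0] - 0.6 * X[:, 1]))
        d = (rng.random(n) < 0.75).astype(int)
        surv = make_survival(t, d)
        mine = cox_fit(surv, X, feature_names=["a", "b"])
        frame = pd.DataFrame({"T": t, "E": d, "a": X[:, 0], "b": X[:, 1]})
        ref = CoxPHFitter().fit(frame, "T", "E")
        for r in mine:
            assert r.beta == pytest.approx(ref.params_[r.feature], abs=1e-5)
            assert r.se_beta == pytest.approx(ref.standard_errors_[r.feature], abs=1e-5)

    def test_score_test_equals_logrank(self):
        rng = np.random.default_rng(5)
        surv, x = _sim_cohort(rng, 90, beta=0.5)
        g = (x > 0).astype(int)
        chi_score, _ = cox_score_test(surv, g)
        chi_lr, _ = logrank_test(surv, g)
        assert chi_score == pytest.approx(chi_lr, abs=1e-6)

    def test_consistency_true_hr_2(self):
        """Mean estimated HR near 2 under an exponential PH model."""
        rng = np.random.default_rng(6)
        hrs = []
        for _ in range(40):
            n = 300
            g = rng.integers(0, 2, size=n).astype(float)
            t = rng.exponential(1 / np.exp(np.log(2) * g))
            surv = make_survival(t, np.ones(n))
            hrs.append(cox_fit(surv, g[:, None])[0].hr)
        assert np.mean(hrs) == pytest.approx(2.0, abs=0.15)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(make_survival([1, 2, 3], [1, 1, 1]), np.ones((3, 1)))

    def test_separation_flagged_and_capped(self):
        # group 1 all fails first: monotone likelihood
        t = [1, 2, 3, 4, 10, 11, 12, 13]
        d = [1] * 8
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        with pytest.warns(UserWarning, match="separation"):
            res = cox_fit(make_survival(t, d), x[:, None])[0]
        assert res.separation
        assert abs(res.beta) <= 15.0


class TestDichotomize:
    def test_even_split(self):
        np.testing.assert_array_equal(dichotomize_median([1, 2, 3, 4]), [0, 0, 1, 1])

    def test_median_ties_go_low(self):
        np.testing.assert_array_equal(dichotomize_median([1, 2, 2, 3]), [0, 0, 0, 1])

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=25)
        np.testing.assert_array_equal(
            dichotomize_median(v), dichotomize_median(np.exp(v))
        )

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_median([1.0, 1.0, 1.0])


class TestOptimalCutoff:
    def test_recovers_planted_threshold(self):
        rng = np.random.default_rng(8)
        n = 60
        scores = np.concatenate([rng.uniform(0, 1, n // 2), rng.uniform(2, 3, n // 2)])
        hazard = np.where(scores < 1.5, 3.0, 1.0)
        t = rng.exponential(1 / hazard)
        surv = make_survival(t, np.ones(n))
        cut = optimal_cutoff(scores, surv)
        assert 1.0 < cut.threshold < 2.0

    def test_statistic_dominates_all_candidates(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=50)
        surv, _ = _sim_cohort(rng, 50)
        cut = optimal_cutoff(scores, surv, minprop=0.1)
        t = surv.data["time"].to_numpy()
        d = surv.data["event"].to_numpy()
        uniq = np.unique(scores)
        for c in (uniq[:-1] + uniq[1:]) / 2:
            g = (scores > c).astype(int)
            if min(g.sum(), (1 - g).sum()) < 5:
                continue
            assert abs(_logrank_z(t, d, g)) <= cut.statistic + 1e-12

    def test_minprop_half_forces_median_split(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=40)
        surv, _ = _sim_cohort(rng, 40)
        cut = optimal_cutoff(scores, surv, minprop=0.5)
        np.testing.assert_array_equal(cut.labels, dichotomize_median(scores))

    def test_permutation_p_null_uniformish(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(30):
            surv, _ = _sim_cohort(rng, 40)
            scores = rng.normal(size=40)
            cut = optimal_cutoff(scores, surv, n_permutations=99, rng=rng)
            ps.append(cut.permutation_p)
        assert np.mean(np.array(ps) < 0.5) == pytest.approx(0.5, abs=0.25)

    def test_no_admissible_threshold_raises(self):
        surv, _ = _sim_cohort(np.random.default_rng(12), 20)
        with pytest.raises(ValueError, match="minprop"):
            optimal_cutoff(np.repeat([0.0, 1.0], [19, 1]), surv, minprop=0.4)


class TestTimeDependentAuc:
    def test_perfect_ordering_gives_one(self):
        t = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        d = np.ones(6, dtype=int)
        scores = -t  # higher score = earlier event
        surv = make_survival(t, d)
        assert time_dependent_auc(scores, surv, horizon=5.0) == pytest.approx(1.0)

    def test_no_censoring_equals_plain_auc(self):
        from oracles import mann_whitney_auc

        rng = np.random.default_rng(13)
        n = 40
        t = rng.exponential(2, n)
        scores = -t + rng.normal(0, 0.5, n)
        surv = make_survival(t, np.ones(n))
        horizon = float(np.median(t))
        label = (t <= horizon).astype(int)
        assert time_dependent_auc(scores, surv, horizon) == pytest.approx(
            mann_whitney_auc(scores, label), abs=1e-12
        )

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(14)
        aucs = []
        for _ in range(40):
            surv, _ = _sim_cohort(rng, 100, censor=0.2)
            aucs.append(time_dependent_auc(rng.normal(size=100), surv,
                                           float(np.median(surv.data["time"]))))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_matches_sksurv(self):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        rng = np.random.default_rng(15)
        surv, x = _sim_cohort(rng, 120, beta=0.8, censor=0.2)
        t = surv.data["time"].to_numpy()
        d = surv.data["event"].to_numpy().astype(bool)
        y = np.empty(120, dtype=[("e", bool), ("t", float)])
        y["e"], y["t"] = d, t
        horizon = float(np.quantile(t, 0.5))
        ref, _ = sksurv_metrics.cumulative_dynamic_auc(y, y, x, [horizon])
        mine = time_dependent_auc(x, surv, horizon)
        assert mine == pytest.approx(float(ref[0]), abs=0.02)

    def test_degenerate_horizon_raises(self):
        surv = make_survival([5, 6, 7], [1, 1, 1])
        with pytest.raises(ValueError):
            time_dependent_auc([1, 2, 3], surv, horizon=1.0)


class TestConcordance:
    def test_matches_lifelines(self):
        lifelines_utils = pytest.importorskip("lifelines.utils")
        rng = np.random.default_rng(16)
        surv, x = _sim_cohort(rng, 100, beta=0.6)
        mine = concordance_index(surv, -x)  # higher score = longer survival
        ref = lifelines_utils.concordance_index(
            surv.data["time"], -x, surv.data["event"]
        )
        assert mine == pytest.approx(ref, abs=1e-12)
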