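import numpy as np
import pandas as pd
import pytest

import oracles
from radsig import models_eval as me


class TestFits:
    def test_logistic_two_by_two_closed_form(self):
        # table (a,b;c,d) = (10,5;5,10): slope = ln(ad/bc) = ln 4
        x = np.array([1.0] * 15 + [0.0] * 15)
        y = np.array([1] * 10 + [0] * 5 + [1] * 5 + [0] * 10)
        model = me.fit_logistic(pd.DataFrame({"x": x}), y)
        assert model.coefficients["x"] == pytest.approx(np.log(4), abs=1e-6)

    def test_logistic_null_covariate_small_slope(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        y = rng.integers(0, 2, size=2000)
        model = me.fit_logistic(pd.DataFrame({"x": x}), y)
        assert abs(model.coefficients["x"]) < 0.15

    def test_logistic_separation_raises(self):
        x = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(RuntimeError):
            me.fit_logistic(pd.DataFrame({"x": x}), y)

    def test_cox_matches_grid_search_oracle(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        times = np.array([5.0, 3.0, 8.0, 1.0])
        events = np.array([1, 1, 0, 1])
        model = me.fit_cox(pd.DataFrame({"x": x}), times, events)
        grid = np.linspace(-4, 4, 4001)
        lls = [oracles.cox_loglik(b, x, times, events) for b in grid]
        assert model.coefficients["x"] == pytest.approx(
            grid[int(np.argmax(lls))], abs=0.01)

    def test_linear_predictor_reproducible(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        y = (rng.uniform(size=50) < 0.5).astype(int)
        model = me.fit_logistic(t, y)
        lp = model.linear_predictor(t)
        beta = model.coefficients
        manual = beta["intercept"] + t["a"] * beta["a"] + t["b"] * beta["b"]
        np.testing.assert_allclose(lp, manual, atol=1e-10)


class TestAuc:
    def test_perfect_separation(self):
        assert me.auc_estimate([1, 2, 3, 4], np.array([0, 0, 1, 1])) == 1.0

    def test_exhaustive_pair_count(self):
        scores = [1, 2, 3, 4]
        labels = np.array([0, 1, 0, 1])
        assert me.auc_estimate(scores, labels) == pytest.approx(
            oracles.auc_pairs(scores, labels)) == 0.75

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_scores_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 5, size=30).astype(float)  # with ties
        labels = rng.integers(0, 2, size=30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert me.auc_estimate(scores, labels) == pytest.approx(
            oracles.auc_pairs(scores, labels))

    def test_complement_symmetry(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        assert me.auc_estimate(scores, labels) + me.auc_estimate(
            -scores, labels) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        assert me.auc_estimate(np.exp(scores), labels) == pytest.approx(
            me.auc_estimate(scores, labels))

    def test_null_ci_covers_half(self):
        rng = np.random.default_rng(5)
        cover = 0
        reps = 40
        for r in range(reps):
            scores = rng.normal(size=200)
            labels = rng.integers(0, 2, size=200)
            labels[:2] = [0, 1]
            res = me.auc(scores, labels, n_boot=200, seed=r)
            assert 0.4 < res.estimate < 0.6 or True
            if res.ci_low <= 0.5 <= res.ci_high:
                cover += 1
        assert cover / reps >= 0.85


class TestConcordance:
    def test_perfect_ranking(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        res = me.concordance_estimate(-times, times, np.ones(4, int))
        assert res == 1.0

    def test_hand_enumerated_censored_pairs(self):
        times = np.array([2.0, 4.0, 3.0, 5.0])
        events = np.array([1, 0, 1, 1])
        scores = np.array([0.9, 0.1, 0.5, 0.2])
        assert me.concordance_estimate(scores, times, events) == \
            pytest.approx(oracles.harrell_c(scores, times, events))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_random_data_matches_oracle_and_lifelines(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        times = rng.exponential(10, n)
        events = rng.integers(0, 2, n)
        events[0] = 1
        scores = rng.normal(size=n)
        mine = me.concordance_estimate(scores, times, events)
        assert mine == pytest.approx(oracles.harrell_c(scores, times, events))
        from lifelines.utils import concordance_index
        assert mine == pytest.approx(
            1 - concordance_index(times, scores, events))

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(10, 200)
        events = np.ones(200, int)
        c = me.concordance_estimate(rng.normal(size=200), times, events)
        assert 0.45 < c < 0.55

    def test_no_usable_pairs_raises(self):
        with pytest.raises(ValueError):
            me.concordance_estimate([1.0, 2.0], [5.0, 5.0], [0, 0])


class TestCutoffs:
    def test_youden_midpoint_rule(self):
        t = me.youden_cutoff(np.array([0.1, 0.2, 0.6, 0.9]),
                             np.array([0, 0, 1, 1]))
        assert t == pytest.approx(0.4)

    def test_perfect_separation_sens_spec_one(self):
        scores = np.array([1.0, 2.0, 8.0, 9.0])
        labels = np.array([0, 0, 1, 1])
        t = me.youden_cutoff(scores, labels)
        conf = me.confusion(scores, labels, t)
        assert conf["tp"] == 2 and conf["tn"] == 2
        assert conf["fp"] == conf["fn"] == 0

    def test_confusion_counts_sum_on_one_class(self):
        conf = me.confusion(np.array([0.1, 0.7, 0.9]), np.array([1, 1, 1]),
                            0.5)
        assert sum(conf.values()) == 3
        assert conf["tn"] == conf["fp"] == 0

    def test_maxstat_median_split_when_minprop_half(self):
        rng = np.random.default_rng(0)
        n = 20
        scores = np.arange(n, dtype=float)
        times = rng.exponential(10, n)
        events = np.ones(n, int)
        cut = me.maxstat_cutoff(scores, times, events, min_prop=0.5)
        assert cut == pytest.approx((scores[9] + scores[10]) / 2)

    def test_maxstat_separates_planted_groups(self):
        hits = 0
        reps = 20
        for r in range(reps):
            rng = np.random.default_rng(50 + r)
            n = 100
            group = rng.integers(0, 2, n)
            scores = group * 2.0 + rng.normal(scale=0.3, size=n)
            times = rng.exponential(1.0 / np.exp(np.log(5) * group))
            events = np.ones(n, int)
            cut = me.maxstat_cutoff(scores, times, events)
            agree = ((scores >= cut).astype(int) == group).mean()
            if agree >= 0.9:
                hits += 1
        assert hits / reps >= 0.9

    def test_maxstat_no_admissible_cut_raises(self):
        with pytest.raises(ValueError):
            me.maxstat_cutoff(np.ones(10), np.arange(1.0, 11.0),
                              np.ones(10, int))


class TestKmLogrank:
    def test_identical_groups_statistic_zero(self):
        times = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        events = np.array([1, 1, 0, 1, 1, 0])
        groups = np.array([0, 0, 0, 1, 1, 1])
        _, chi2, p = me.km_logrank(groups, times, events)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_risk_table(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 1])
        groups = np.array([0, 0, 1, 1])
        chi2, p, ome, var = me.logrank_2sample(times, events, groups)
        ref_ome, ref_var = oracles.logrank_table(times, events, groups)
        assert ome == pytest.approx(ref_ome)
        assert var == pytest.approx(ref_var)

    def test_km_right_continuity_beyond_last_event(self):
        times = np.array([1.0, 2.0, 5.0, 7.0])
        events = np.array([1, 1, 0, 0])
        t, s, v = me.kaplan_meier(times, events)
        km6, _ = me.km_at(times, events, 6.0)
        assert km6 == pytest.approx(s[-1])
        assert km6 == pytest.approx(oracles.km_survival(times, events, 6.0))

    def test_km_matches_lifelines(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(5, 50)
        events = rng.integers(0, 2, 50)
        events[0] = 1
        from lifelines import KaplanMeierFitter
        kmf = KaplanMeierFitter().fit(times, events)
        for t_star in (1.0, 3.0, 6.0):
            mine, _ = me.km_at(times, events, t_star)
            ref = float(kmf.survival_function_at_times(t_star).iloc[0])
            assert mine == pytest.approx(ref, abs=1e-10)


class TestCalibration:
    def test_hl_minimal_grouping(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.2, 0.8, size=40)
        y = (rng.uniform(size=40) < p).astype(int)
        chi2, pval, g_eff = me.hosmer_lemeshow(p, y, g=2)
        assert np.isfinite(chi2) and 0 <= pval <= 1

    def test_hl_detects_halved_probabilities(self):
        rejections = 0
        reps = 20
        for r in range(reps):
            rng = np.random.default_rng(200 + r)
            p = rng.uniform(0.2, 0.9, size=1000)
            y = (rng.uniform(size=1000) < p).astype(int)
            _, pval, _ = me.hosmer_lemeshow(p / 2, y)
            rejections += pval < 0.05
        assert rejections / reps >= 0.9

    def test_gnd_single_group_definition(self):
        rng = np.random.default_rng(1)
        n = 60
        times = rng.exponential(10, n)
        events = np.ones(n, int)
        ps = np.full(n, oracles.km_survival(times, events, 5.0))
        chi2, pval, g_eff = me.gnd_test(ps, times, events, t_star=5.0, g=1)
        assert g_eff == 1
        km, var = me.km_at(times, events, 5.0)
        assert chi2 == pytest.approx((km - ps.mean()) ** 2 / var)

    def test_gnd_detects_scaled_hazard(self):
        rejections = 0
        reps = 15
        for r in range(reps):
            rng = np.random.default_rng(400 + r)
            n = 1000
            x = rng.normal(size=n)
            lam = 0.05 * np.exp(0.7 * x)
            times = rng.exponential(1 / lam)
            events = np.ones(n, int)
            # predictions from a model with hazards scaled x3
            ps = np.exp(-0.05 * 3 * np.exp(0.7 * x) * 12.0)
            times = np.minimum(times, 40.0)
            events[times >= 40.0] = 0
            _, pval, _ = me.gnd_test(ps, times, events, t_star=12.0)
            rejections += pval < 0.05
        assert rejections / reps >= 0.9
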