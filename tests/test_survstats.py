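import numpy as np
import pandas as pd
import pytest

from erss_pipeline.survstats import (
    clinical_association,
    cox_fit,
    km_estimate,
    logrank_test,
    logrank_z,
    optimal_cutpoint,
    time_dependent_auc,
)


def brute_force_cutpoint(score, times, status, minprop):
    """Exhaustive-scan oracle: hand-computed log-rank at every threshold."""
    score = np.asarray(score, dtype=float)
    n = len(score)
    best = None
    for thr in np.unique(score)[:-1]:
        high = score > thr
        k = high.sum()
        if k < np.ceil(minprop * n) or n - k < np.ceil(minprop * n):
            continue
        u = v = 0.0
        for t in np.unique(np.asarray(times)[np.asarray(status) == 1]):
            at_risk = np.asarray(times) >= t
            n_r = at_risk.sum()
            n1 = (at_risk & high).sum()
            d = ((np.asarray(times) == t) & (np.asarray(status) == 1)).sum()
            d1 = ((np.asarray(times) == t) & (np.asarray(status) == 1) & high).sum()
            u += d1 - d * n1 / n_r
            if n_r > 1:
                v += d * (n1 / n_r) * (1 - n1 / n_r) * (n_r - d) / (n_r - 1)
        z = abs(u / np.sqrt(v)) if v > 0 else 0.0
        if best is None or z > best[1]:
            best = (thr, z)
    return best


class TestKaplanMeier:
    def test_all_censored_flat_curve(self):
        curves = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert (curves["all"].survival == 1.0).all()

    def test_hand_product_limit(self):
        curves = km_estimate([1.0, 2.0, 3.0], [1, 1, 0])
        c = curves["all"]
        assert c.survival_at(1.0) == pytest.approx(2 / 3)
        assert c.survival_at(2.0) == pytest.approx(1 / 3)

    def test_replication_invariance(self):
        t = np.array([1.0, 3.0, 4.0, 7.0])
        s = np.array([1, 0, 1, 1])
        single = km_estimate(t, s)["all"]
        double = km_estimate(np.tile(t, 2), np.tile(s, 2))["all"]
        np.testing.assert_allclose(single.survival, double.survival, atol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            km_estimate([-1.0, 2.0], [1, 1])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        s = np.array([1, 1, 0, 1, 1, 0])
        chi2, df, p = logrank_test(t, s, ["a"] * 3 + ["b"] * 3)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_eight_subject_toy(self):
        """Observed-minus-expected over explicit risk sets."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        s = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        g = np.array(["a", "a", "b", "a", "b", "b", "a", "b"])
        u = v = 0.0
        for et in t[s == 1]:
            risk = t >= et
            n_r, n_b = risk.sum(), (risk & (g == "b")).sum()
            d = 1
            d_b = int(((t == et) & (s == 1) & (g == "b")).sum())
            u += d_b - d * n_b / n_r
            if n_r > 1:
                v += (n_b / n_r) * (1 - n_b / n_r) * (n_r - d) / (n_r - 1)
        chi2, df, p = logrank_test(t, s, g)
        assert df == 1
        assert chi2 == pytest.approx(u**2 / v, rel=1e-10)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(0)
        t = rng.exponential(size=60)
        s = rng.binomial(1, 0.7, size=60)
        g = rng.choice(["a", "b"], size=60)
        chi2, _, p = logrank_test(t, s, g)
        ref = ll_logrank(t[g == "a"], t[g == "b"], s[g == "a"], s[g == "b"])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-8)
        assert p == pytest.approx(ref.p_value, rel=1e-8)

    def test_monotone_time_transform_invariance(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(size=40) + 0.1
        s = rng.binomial(1, 0.8, size=40)
        g = rng.choice(["a", "b"], size=40)
        chi2_a, _, _ = logrank_test(t, s, g)
        chi2_b, _, _ = logrank_test(np.log(t), s, g)
        assert chi2_a == pytest.approx(chi2_b, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test([1.0, 2.0], [1, 1], ["a", "a"])

    def test_null_type_one_rate(self):
        """Rejection rate at alpha=0.05 under the null, 2000 replicates."""
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            t = rng.exponential(size=200)
            s = rng.binomial(1, 0.8, size=200)
            g = np.repeat(["a", "b"], 100)
            _, _, p = logrank_test(t, s, g)
            rejections += p < 0.05
        assert 0.035 < rejections / reps < 0.065


class TestOptimalCutpoint:
    def test_oracle_agreement_uncensored_toy(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(size=40)
        status = np.ones(40, dtype=int)
        score = -times + rng.normal(0, 0.2, size=40)  # high score = short survival
        res = optimal_cutpoint(score, times, status, minprop=0.1)
        thr, z = brute_force_cutpoint(score, times, status, 0.1)
        assert res.threshold == pytest.approx(thr)
        assert res.statistic == pytest.approx(z, rel=1e-9)

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_agreement_random_instances(self, seed):
        """Maximally selected statistic equals the exhaustive scan, n <= 200."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        times = rng.exponential(size=n)
        status = rng.binomial(1, 0.7, size=n)
        if status.sum() == 0:
            status[0] = 1
        score = rng.normal(size=n)
        minprop = float(rng.choice([0.1, 0.2]))
        res = optimal_cutpoint(score, times, status, minprop=minprop)
        thr, z = brute_force_cutpoint(score, times, status, minprop)
        assert res.statistic == pytest.approx(z, rel=1e-9)
        assert res.threshold == pytest.approx(thr)

    def test_median_split_only_at_half_minprop(self):
        rng = np.random.default_rng(4)
        score = np.arange(10.0)
        times = rng.exponential(size=10)
        status = np.ones(10, dtype=int)
        res = optimal_cutpoint(score, times, status, minprop=0.5)
        assert res.n_low == res.n_high == 5

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            optimal_cutpoint(np.ones(20), np.arange(1.0, 21.0), np.ones(20, dtype=int))


class TestCoxFit:
    def test_binary_toy_matches_grid_oracle(self):
        from tests.test_erss import efron_partial_loglik
        from scipy.optimize import minimize_scalar

        x = np.array([1.0, 0, 1, 0, 1, 0])
        t = np.array([1.0, 3, 4, 6, 8, 9])
        s = np.array([1, 1, 1, 1, 0, 1])
        model = cox_fit(pd.DataFrame({"x": x}), t, s)
        opt = minimize_scalar(lambda b: -efron_partial_loglik(b, x, t, s),
                              bounds=(-5, 5), method="bounded", options={"xatol": 1e-8})
        assert model.params["x"] == pytest.approx(opt.x, abs=1e-4)

    def test_duplicated_covariate_dropped(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        t = rng.exponential(np.exp(-0.3 * x))
        s = np.ones(50, dtype=int)
        with pytest.warns(UserWarning, match="aliased"):
            model = cox_fit(pd.DataFrame({"x": x, "x2": x}), t, s)
        ref = cox_fit(pd.DataFrame({"x": x}), t, s)
        assert model.params["x"] == pytest.approx(ref.params["x"], abs=1e-10)

    def test_planted_beta_recovery(self):
        betas = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=400)
            t = rng.exponential(np.exp(-0.7 * x))
            c = rng.exponential(np.quantile(t, 0.8), size=400)
            s = (t <= c).astype(int)
            betas.append(cox_fit(pd.DataFrame({"x": x}), np.minimum(t, c), s).params["x"])
        assert abs(np.mean(betas) - 0.7) < 0.07

    def test_baseline_cumhaz_monotone(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=100)
        t = rng.exponential(np.exp(-0.5 * x))
        model = cox_fit(pd.DataFrame({"x": x}), t, np.ones(100, dtype=int))
        ch = model.baseline_cumhaz.iloc[:, 0].to_numpy()
        assert (np.diff(ch) >= -1e-12).all()


class TestTimeDependentAuc:
    def test_perfect_ranking(self):
        times = np.linspace(1, 10, 30)
        auc = time_dependent_auc(-times, times, np.ones(30, dtype=int), horizon=5.0)
        assert auc == pytest.approx(1.0)

    def test_uncensored_equals_pair_counting(self):
        rng = np.random.default_rng(7)
        n = 60
        times = rng.exponential(size=n)
        score = -times + rng.normal(0, 0.5, size=n)
        status = np.ones(n, dtype=int)
        h = float(np.median(times))
        auc = time_dependent_auc(score, times, status, h)
        cases = times <= h
        num = den = 0
        for i in np.where(cases)[0]:
            for j in np.where(~cases)[0]:
                den += 1
                num += score[i] > score[j]
                num += 0.5 * (score[i] == score[j])
        assert auc == pytest.approx(num / den, abs=1e-10)

    def test_null_score_auc_half(self):
        rng = np.random.default_rng(8)
        aucs = []
        for _ in range(200):
            times = rng.exponential(size=80)
            score = rng.normal(size=80)
            aucs.append(time_dependent_auc(score, times, np.ones(80, dtype=int),
                                           float(np.median(times))))
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_no_events_by_horizon_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            time_dependent_auc([1.0, 2.0], [5.0, 6.0], [1, 1], horizon=1.0)


class TestClinicalAssociation:
    def test_balanced_table_chi_square_zero(self):
        x = ["hi"] * 20 + ["lo"] * 20
        y = (["m"] * 10 + ["f"] * 10) * 2
        out = clinical_association(x, y)
        assert out["test"] == "chi-square"
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_fisher_fallback_small_expected(self):
        """2x2 (1,9; 9,1): exact two-sided p = 202/184756."""
        x = ["hi"] * 10 + ["lo"] * 10
        y = ["m"] * 1 + ["f"] * 9 + ["m"] * 9 + ["f"] * 1
        out = clinical_association(x, y)
        assert out["test"] == "fisher-exact"
        assert out["p"] == pytest.approx(202 / 184756, rel=1e-9)
        assert out["p"] == pytest.approx(0.00115, abs=1e-4)

    def test_two_level_wilcoxon(self):
        rng = np.random.default_rng(9)
        score = np.concatenate([rng.normal(size=30), rng.normal(2, 1, size=30)])
        y = ["a"] * 30 + ["b"] * 30
        out = clinical_association(score, y)
        assert out["test"] == "wilcoxon" and out["p"] < 1e-4

    def test_three_identical_groups_kruskal(self):
        rng = np.random.default_rng(10)
        ps = []
        for _ in range(50):
            score = rng.normal(size=90)
            y = np.repeat(["a", "b", "c"], 30)
            out = clinical_association(score, y)
            assert out["test"] == "kruskal-wallis"
            ps.append(out["p"])
        assert np.mean(ps) > 0.4

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            clinical_association([1.0, 2.0, 3.0], ["a", "a", "a"])
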