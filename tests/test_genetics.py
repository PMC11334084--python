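import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from erss_pipeline.genetics import (
    GenotypeCounts,
    additive_interaction,
    crossover_analysis,
    expand_counts_to_subjects,
    hwe_test,
    logistic_fit,
    multiplicative_interaction,
    odds_ratio,
)
from erss_pipeline.synthdata import CaseControlSpec, simulate_case_control

# the printed case-control genotype distribution used as a worked input:
# cases 433 CC / 34 CT+TT, controls 349 CC / 46 CT+TT
PRINTED = GenotypeCounts(case_cc=433, case_carrier=34, control_cc=349, control_carrier=46)


class TestHwe:
    def test_exact_hwe_zero(self):
        chi2, df, p = hwe_test(25, 50, 25)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_hand_computed_chi_square(self):
        """(30, 40, 30) vs expected (25, 50, 25): chi2 = 1 + 2 + 1 = 4."""
        chi2, _, _ = hwe_test(30, 40, 30)
        assert chi2 == pytest.approx(4.0, abs=1e-12)

    def test_monomorphic_degenerate(self):
        with pytest.warns(UserWarning, match="monomorphic"):
            chi2, _, p = hwe_test(100, 0, 0)
        assert chi2 == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)


class TestOddsRatio:
    def test_printed_counts(self):
        est = odds_ratio(PRINTED)
        assert est.odds_ratio == pytest.approx(0.596, abs=5e-4)
        assert est.ci_low == pytest.approx(0.374, abs=5e-4)
        assert est.ci_high == pytest.approx(0.949, abs=5e-4)
        assert est.p < 0.05

    def test_unit_table_symmetric_ci(self):
        est = odds_ratio(np.array([[10, 10], [10, 10]]))
        assert est.odds_ratio == pytest.approx(1.0)
        assert np.log(est.ci_low) == pytest.approx(-np.log(est.ci_high), abs=1e-12)

    def test_cross_product(self):
        est = odds_ratio(np.array([[2, 1], [1, 2]]))
        assert est.odds_ratio == pytest.approx(4.0)

    def test_zero_cell_haldane(self):
        est = odds_ratio(np.array([[0, 10], [5, 5]]))
        assert est.corrected
        assert est.odds_ratio == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero row/column"):
            odds_ratio(np.array([[0, 0], [5, 5]]))

    @given(
        a=st.integers(1, 200), b=st.integers(1, 200),
        c=st.integers(1, 200), d=st.integers(1, 200),
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_case_control_swap_inverts(self, a, b, c, d):
        est = odds_ratio(np.array([[a, b], [c, d]]))
        inv = odds_ratio(np.array([[c, d], [a, b]]))
        assert est.odds_ratio == pytest.approx(1 / inv.odds_ratio, rel=1e-10)
        assert est.ci_low == pytest.approx(1 / inv.ci_high, rel=1e-10)


class TestLogisticFit:
    def test_saturated_equivalence_with_woolf(self):
        """Single binary predictor reproduces the 2x2 OR and Woolf CI."""
        subjects = expand_counts_to_subjects(PRINTED)
        fit = logistic_fit(subjects, "case", ["carrier"])
        direct = odds_ratio(PRINTED)
        row = fit.table.loc["carrier"]
        assert row["or"] == pytest.approx(direct.odds_ratio, abs=1e-6)
        assert row["ci_low"] == pytest.approx(direct.ci_low, abs=1e-6)
        assert row["ci_high"] == pytest.approx(direct.ci_high, abs=1e-6)

    @given(
        a=st.integers(5, 80), b=st.integers(5, 80),
        c=st.integers(5, 80), d=st.integers(5, 80),
    )
    @settings(max_examples=10, derandomize=True, deadline=None)
    def test_saturated_equivalence_property(self, a, b, c, d):
        counts = GenotypeCounts(case_cc=b, case_carrier=a, control_cc=d, control_carrier=c)
        fit = logistic_fit(expand_counts_to_subjects(counts), "case", ["carrier"])
        direct = odds_ratio(counts)
        assert fit.table.loc["carrier", "or"] == pytest.approx(direct.odds_ratio, rel=1e-6)
        assert fit.table.loc["carrier", "ci_low"] == pytest.approx(direct.ci_low, rel=1e-5)

    def test_wald_type_one_rate(self):
        rng = np.random.default_rng(0)
        reps, n = 1000, 2000
        rej = 0
        for _ in range(reps):
            x = rng.binomial(1, 0.3, size=n)
            y = rng.binomial(1, 0.5, size=n)
            fit = logistic_fit(pd.DataFrame({"x": x, "y": y}), "y", ["x"])
            rej += fit.table.loc["x", "p"] < 0.05
        assert 0.035 < rej / reps < 0.065

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"x": [0, 1, 0, 1], "z": [1, 1, 1, 1], "y": [0, 1, 1, 0]})
        with pytest.raises(ValueError, match="aliased"):
            logistic_fit(df, "y", ["x", "z"])

    def test_separation_detected(self):
        df = pd.DataFrame({"x": [0] * 20 + [1] * 20, "y": [0] * 20 + [1] * 20})
        with pytest.raises(RuntimeError):
            logistic_fit(df, "y", ["x"])


class TestCrossover:
    def test_flat_case_fractions_all_unit(self):
        rows = []
        for g in (0, 1):
            for e in (0, 1):
                rows += [(g, e, 1)] * 30 + [(g, e, 0)] * 30
        df = pd.DataFrame(rows, columns=["carrier", "exposure", "case"])
        out = crossover_analysis(df, protective_genotype=1)
        for key in ("genotype_only", "exposure_only", "both"):
            assert out[key].odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_planted_joint_ors_recovered(self):
        """Joint ORs from the generator land inside their 95% CIs."""
        hits = {"genotype_only": 0, "exposure_only": 0, "both": 0}
        n_seeds = 50
        for seed in range(n_seeds):
            spec = CaseControlSpec(
                n_cases=10000, n_controls=10000, q=0.3, or_genotype=2.0,
                or_exposure=1.5, or_interaction=1.0, seed=seed,
            )
            subjects, _ = simulate_case_control(spec)
            out = crossover_analysis(subjects, protective_genotype=0)
            for key, target in (
                ("genotype_only", 2.0), ("exposure_only", 1.5), ("both", 3.0)
            ):
                est = out[key]
                hits[key] += est.ci_low <= target <= est.ci_high
        for key in hits:
            assert hits[key] >= 0.9 * n_seeds

    def test_collapsing_reproduces_marginal_or(self):
        """Without exposure effect or interaction, the exposure-collapsed OR
        matches the marginal 2x2 odds ratio."""
        spec = CaseControlSpec(n_cases=8000, n_controls=8000, q=0.3,
                               or_genotype=1.8, or_exposure=1.0, or_interaction=1.0, seed=3)
        subjects, _ = simulate_case_control(spec)
        counts = GenotypeCounts(
            case_cc=int(((subjects.case == 1) & (subjects.carrier == 0)).sum()),
            case_carrier=int(((subjects.case == 1) & (subjects.carrier == 1)).sum()),
            control_cc=int(((subjects.case == 0) & (subjects.carrier == 0)).sum()),
            control_carrier=int(((subjects.case == 0) & (subjects.carrier == 1)).sum()),
        )
        marginal = odds_ratio(counts)
        fit = logistic_fit(subjects, "case", ["carrier"])
        assert fit.table.loc["carrier", "or"] == pytest.approx(marginal.odds_ratio, rel=1e-6)

    def test_empty_reference_rejected(self):
        df = pd.DataFrame({"carrier": [1, 1], "exposure": [1, 1], "case": [0, 1]})
        with pytest.raises(ValueError, match="reference cell"):
            crossover_analysis(df, protective_genotype=0)


def _fit_with_coefs(bg, be, bge, cov_scale=0.01, seed=0):
    """LogisticFit stub with fixed coefficients and a small random PSD covariance."""
    from erss_pipeline.genetics import LogisticFit

    rng = np.random.default_rng(seed)
    names = ["intercept", "g", "e", "ge"]
    coef = pd.Series([-1.0, bg, be, bge], index=names)
    M = rng.normal(size=(4, 4))
    cov = pd.DataFrame(cov_scale * (M @ M.T + 4 * np.eye(4)), index=names, columns=names)
    se = pd.Series(np.sqrt(np.diag(cov)), index=names)
    from scipy import stats as sps

    table = pd.DataFrame({
        "coef": coef, "se": se, "or": np.exp(coef),
        "ci_low": np.exp(coef - 1.96 * se), "ci_high": np.exp(coef + 1.96 * se),
        "p": 2 * sps.norm.sf(np.abs(coef / se)),
    })
    return LogisticFit(table, cov, n=1000, log_likelihood=0.0)


class TestAdditiveInteraction:
    def test_exact_additivity_identity(self):
        """OR10=2, OR01=3, OR11=4: RERI=0, AP=0, S=1."""
        fit = _fit_with_coefs(np.log(2), np.log(3), np.log(4 / 6))
        est = additive_interaction(fit, "g", "e", "ge")
        assert est.reri == pytest.approx(0.0, abs=1e-12)
        assert est.ap == pytest.approx(0.0, abs=1e-12)
        assert est.s == pytest.approx(1.0, abs=1e-12)

    def test_direct_formula_values(self):
        """OR10=2, OR01=2, OR11=6: RERI=3, AP=0.5, S=2.5."""
        fit = _fit_with_coefs(np.log(2), np.log(2), np.log(6 / 4))
        est = additive_interaction(fit, "g", "e", "ge")
        assert est.reri == pytest.approx(3.0, abs=1e-10)
        assert est.ap == pytest.approx(0.5, abs=1e-10)
        assert est.s == pytest.approx(2.5, abs=1e-10)

    def test_delta_ci_matches_parametric_bootstrap(self):
        """Delta-method RERI interval vs 10,000 draws from the same covariance."""
        fit = _fit_with_coefs(np.log(1.5), np.log(1.8), np.log(1.4), cov_scale=0.002, seed=1)
        est = additive_interaction(fit, "g", "e", "ge")
        rng = np.random.default_rng(2)
        theta = fit.table.loc[["g", "e", "ge"], "coef"].to_numpy()
        cov = fit.cov.loc[["g", "e", "ge"], ["g", "e", "ge"]].to_numpy()
        draws = rng.multivariate_normal(theta, cov, size=10000)
        reri = np.exp(draws.sum(axis=1)) - np.exp(draws[:, 0]) - np.exp(draws[:, 1]) + 1
        sd_boot = reri.std()
        sd_delta = (est.reri_ci[1] - est.reri) / 1.959963984540054
        assert abs(sd_delta - sd_boot) / sd_boot < 0.05

    def test_s_undefined_reported(self):
        fit = _fit_with_coefs(np.log(0.7), np.log(0.8), np.log(1.0))
        est = additive_interaction(fit, "g", "e", "ge")
        assert est.s is None and "undefined" in est.note

    def test_reri_zero_iff_s_one(self):
        """Whenever S is defined, RERI = 0 exactly when S = 1."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            bg, be = rng.uniform(0.1, 1.0, size=2)
            bge = rng.uniform(-0.5, 0.5)
            fit = _fit_with_coefs(bg, be, bge)
            est = additive_interaction(fit, "g", "e", "ge")
            if est.s is None:
                continue
            if abs(est.reri) < 1e-10:
                assert est.s == pytest.approx(1.0, abs=1e-8)
            else:
                assert abs(est.s - 1.0) > 1e-12


class TestMultiplicativeInteraction:
    def test_multiplicative_null_recovered(self):
        spec = CaseControlSpec(n_cases=25000, n_controls=25000, q=0.3,
                               or_genotype=1.5, or_exposure=1.5, or_interaction=1.0, seed=4)
        subjects, _ = simulate_case_control(spec)
        subjects = subjects.assign(gxe=subjects.carrier * subjects.exposure)
        fit = logistic_fit(subjects, "case", ["carrier", "exposure", "gxe"])
        est = multiplicative_interaction(fit, "gxe")
        assert est.ci_low <= 1.0 <= est.ci_high

    def test_planted_interaction_recovered(self):
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            spec = CaseControlSpec(n_cases=10000, n_controls=10000, q=0.3,
                                   or_genotype=1.2, or_exposure=1.2, or_interaction=2.0, seed=seed)
            subjects, _ = simulate_case_control(spec)
            subjects = subjects.assign(gxe=subjects.carrier * subjects.exposure)
            fit = logistic_fit(subjects, "case", ["carrier", "exposure", "gxe"])
            est = multiplicative_interaction(fit, "gxe")
            hits += est.ci_low <= 2.0 <= est.ci_high
        assert hits >= 0.9 * n_seeds

    def test_aliased_product_rejected(self):
        df = pd.DataFrame(
            {"g": [0, 1, 0, 1, 0, 1], "e": [1, 1, 1, 1, 1, 1], "y": [0, 1, 1, 0, 1, 0]}
        )
        df["ge"] = df.g * df.e  # equals g when e is constant
        with pytest.raises(ValueError, match="aliased"):
            logistic_fit(df, "y", ["g", "e", "ge"])

    def test_missing_term_rejected(self):
        fit = _fit_with_coefs(0.1, 0.1, 0.1)
        with pytest.raises(ValueError, match="absent"):
            multiplicative_interaction(fit, "nope")
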