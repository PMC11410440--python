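"""Statistics layer against independent oracles (scipy/statsmodels/quadrature)."""

import numpy as np
import pytest
from scipy import integrate, stats as sps

from octmorph.errors import DegenerateInput, EmptyGroup, ZeroMarginal
from octmorph.stats import (
    build_cohort_report,
    chi_square_2x2,
    multivariate_regression_backward,
    pearson_correlation,
    simple_regression,
    two_sample_t,
    two_sample_t_from_summary,
)
from octmorph.synthetic import default_cohort_spec, generate_cohort


class TestTwoSampleT:
    def test_pooled_matches_scipy_from_stats(self):
        cmp = two_sample_t_from_summary(104.88, 15.68, 75, 128.80, 36.00, 65,
                                        mode="pooled")
        t_sp, p_sp = sps.ttest_ind_from_stats(
            104.88, 15.68, 75, 128.80, 36.00, 65, equal_var=True
        )
        assert cmp.statistic == pytest.approx(t_sp, rel=1e-12)
        assert cmp.p == pytest.approx(p_sp, rel=1e-12)
        assert cmp.df == 138

    def test_welch_matches_scipy_from_stats(self):
        cmp = two_sample_t_from_summary(133.66, 21.07, 75, 146.17, 34.42, 65,
                                        mode="welch")
        t_sp, p_sp = sps.ttest_ind_from_stats(
            133.66, 21.07, 75, 146.17, 34.42, 65, equal_var=False
        )
        assert cmp.statistic == pytest.approx(t_sp, rel=1e-12)
        assert cmp.p == pytest.approx(p_sp, rel=1e-12)

    def test_identical_summaries(self):
        cmp = two_sample_t_from_summary(10, 2, 30, 10, 2, 30, mode="pooled")
        assert cmp.statistic == 0
        assert cmp.p == pytest.approx(1.0)

    def test_antisymmetry_under_group_swap(self):
        a = two_sample_t_from_summary(10, 2, 30, 12, 3, 40, mode="welch")
        b = two_sample_t_from_summary(12, 3, 40, 10, 2, 30, mode="welch")
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_welch_df_never_exceeds_pooled_df(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n1, n2 = rng.integers(3, 40, 2)
            s1, s2 = rng.uniform(0.5, 5.0, 2)
            w = two_sample_t_from_summary(0, s1, n1, 1, s2, n2, mode="welch")
            p = two_sample_t_from_summary(0, s1, n1, 1, s2, n2, mode="pooled")
            assert w.df <= p.df + 1e-9

    def test_pooled_equals_welch_for_balanced_equal_sd(self):
        w = two_sample_t_from_summary(3, 2.5, 20, 5, 2.5, 20, mode="welch")
        p = two_sample_t_from_summary(3, 2.5, 20, 5, 2.5, 20, mode="pooled")
        assert w.statistic == pytest.approx(p.statistic, rel=1e-12)
        assert w.df == pytest.approx(p.df, rel=1e-12)

    def test_auto_mode_on_samples_uses_levene(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 80)
        y = rng.normal(0.5, 6, 80)
        assert two_sample_t(x, y, mode="auto").test == "welch_t"
        y2 = rng.normal(0.5, 1, 80)
        assert two_sample_t(x, y2, mode="auto").test == "pooled_t"

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInput):
            two_sample_t_from_summary(1, 0.0, 10, 2, 1.0, 10)
        with pytest.raises(DegenerateInput):
            two_sample_t([1.0], [1.0, 2.0])


class TestChiSquare:
    def test_reference_sex_table(self):
        assert chi_square_2x2(39, 36, 43, 22).statistic == pytest.approx(
            2.875, abs=5e-4
        )

    def test_matches_scipy_without_correction(self):
        ours = chi_square_2x2(12, 7, 5, 19)
        chi2, p, df, _ = sps.chi2_contingency(
            [[12, 7], [5, 19]], correction=False
        )
        assert ours.statistic == pytest.approx(chi2, rel=1e-12)
        assert ours.p == pytest.approx(p, rel=1e-12)

    def test_no_association_and_perfect_association(self):
        assert chi_square_2x2(10, 10, 10, 10).statistic == 0
        assert chi_square_2x2(20, 0, 0, 20).statistic == pytest.approx(40.0)

    def test_invariance_under_permutation(self):
        a = chi_square_2x2(12, 7, 5, 19)
        assert chi_square_2x2(5, 19, 12, 7).statistic == pytest.approx(a.statistic)
        assert chi_square_2x2(7, 12, 19, 5).statistic == pytest.approx(a.statistic)

    def test_zero_marginal(self):
        with pytest.raises(ZeroMarginal):
            chi_square_2x2(0, 0, 5, 5)


class TestPearson:
    def test_reported_r_gives_reported_p(self):
        from octmorph.stats import correlation_t_p

        t, p = correlation_t_p(0.271, 65)
        assert p == pytest.approx(0.029, abs=0.002)
        t, p = correlation_t_p(0.480, 65)
        assert t == pytest.approx(4.34, abs=0.02)
        assert p < 0.001

    def test_perfect_correlation(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, x).r == pytest.approx(1.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=50), rng.normal(size=50)
        cr = pearson_correlation(x, y)
        r_sp, p_sp = sps.pearsonr(x, y)
        assert cr.r == pytest.approx(r_sp, rel=1e-10)
        assert cr.p == pytest.approx(p_sp, rel=1e-6)

    def test_degenerate(self):
        with pytest.raises(DegenerateInput):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestPValueQuadratureOracle:
    """Tail probabilities agree with direct numerical integration to 1e-6."""

    def test_t_tail(self):
        df, tval = 63, 2.234
        pdf = lambda u: sps.t.pdf(u, df)
        tail, _ = integrate.quad(pdf, tval, np.inf)
        cmp = two_sample_t_from_summary(0, 1, 33, 0.55, 1, 32, mode="pooled")
        expect, _ = integrate.quad(pdf, abs(cmp.statistic), np.inf)
        assert cmp.p == pytest.approx(2 * expect, abs=1e-6)
        assert 2 * tail == pytest.approx(2 * sps.t.sf(tval, df), abs=1e-9)

    def test_chi2_tail(self):
        cmp = chi_square_2x2(12, 7, 5, 19)
        tail, _ = integrate.quad(lambda u: sps.chi2.pdf(u, 1), cmp.statistic, np.inf)
        assert cmp.p == pytest.approx(tail, abs=1e-6)

    def test_f_tail(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = 1 + 0.4 * x + rng.normal(size=40)
        rr = simple_regression(y, x)
        tail, _ = integrate.quad(
            lambda u: sps.f.pdf(u, 1, 38), rr.f_statistic, np.inf
        )
        assert rr.p_values["x"] == pytest.approx(tail, abs=1e-6)


class TestRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        rr = simple_regression(2 * x + 1, x)
        assert rr.intercept == pytest.approx(1.0)
        assert rr.coefficients["x"] == pytest.approx(2.0)
        assert rr.r_squared == pytest.approx(1.0)

    def test_f_equals_r2_identity(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=65)
        y = 0.6 * x + rng.normal(size=65)
        rr = simple_regression(y, x)
        r2 = rr.r_squared
        assert rr.f_statistic == pytest.approx(r2 * 63 / (1 - r2), rel=1e-9)
        r = pearson_correlation(x, y).r
        assert r2 == pytest.approx(r * r, rel=1e-9)

    def test_constant_predictor(self):
        with pytest.raises(DegenerateInput):
            simple_regression(np.arange(10.0), np.ones(10))

    def test_backward_elimination_recovers_single_link(self):
        rng = np.random.default_rng(5)
        stage = rng.integers(1, 6, 65).astype(float)
        duration = rng.normal(10, 5, 65)
        age = rng.normal(65, 9, 65)
        y = 3.0 + 2.0 * stage + rng.normal(0, 0.8, 65)
        rr = multivariate_regression_backward(
            y, {"stage": stage, "duration": duration, "age": age}
        )
        assert set(rr.coefficients) == {"stage"}
        assert rr.coefficients["stage"] == pytest.approx(2.0, abs=0.2)

    def test_pure_noise_gives_intercept_only(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=60)
        rr = multivariate_regression_backward(
            y,
            {
                "stage": rng.integers(1, 6, 60).astype(float),
                "age": rng.normal(65, 9, 60),
            },
        )
        assert rr.coefficients == {}
        assert rr.r_squared == 0.0

    def test_exact_multipredictor(self):
        rng = np.random.default_rng(7)
        age = rng.normal(65, 9, 50)
        stage = rng.integers(1, 6, 50).astype(float)
        rr = multivariate_regression_backward(
            5.0 * age, {"stage": stage, "age": age}
        )
        assert set(rr.coefficients) == {"age"}
        assert rr.coefficients["age"] == pytest.approx(5.0, rel=1e-9)
        assert rr.r_squared == pytest.approx(1.0)


class TestCohortReport:
    def test_report_structure_and_group_sizes(self):
        cohort = generate_cohort(default_cohort_spec("table_matched"), seed=11)
        report = build_cohort_report(cohort)
        comp = report["artery_comparison"]
        assert set(comp.n_ndr) == {75} and set(comp.n_dr) == {65}
        assert list(comp.parameter) == ["ld", "od", "wlr", "wt", "wcsa"]
        corr = report["vein_correlations"]
        assert set(corr.n) == {65}  # within-DR analyses
        assert len(report["vein_regressions"]) == 5

    def test_identical_groups_yield_null_results(self):
        from dataclasses import replace

        cohort = generate_cohort(default_cohort_spec("table_matched"), seed=12)
        ndr = [p for p in cohort if p.group == "NDR"]
        # mirror NDR patients into a fake DR group (stage drawn arbitrarily)
        fake_dr = [
            replace(p, id=f"fake{i}", group="DR", dr_stage=1 + i % 5)
            for i, p in enumerate(ndr)
        ]
        report = build_cohort_report(ndr + fake_dr)
        for vessel in ("artery", "vein"):
            comp = report[f"{vessel}_comparison"]
            assert np.allclose(comp.t.abs(), 0.0, atol=1e-9)

    def test_single_group_rejected(self):
        cohort = generate_cohort(default_cohort_spec("table_matched"), seed=13)
        ndr = [p for p in cohort if p.group == "NDR"]
        with pytest.raises(EmptyGroup):
            build_cohort_report(ndr)
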