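"""Onset residuals, selection model, and association machinery."""

import numpy as np
import pytest
from scipy import integrate, stats

from qtronset.onset import (
    LangbehnModel,
    SelectionModel,
    bonferroni_adjust,
    compare_statistics,
    conditional_association,
    dichotomize_and_logistic,
    expected_onset,
    fit_regression_with_selection,
    fit_selection_model,
    ols_association,
    repeat_statistics,
    residual,
    selected_density,
    selection_function,
    selection_loglik,
    selection_normalizer,
)
from qtronset.simulate import CohortSimConfig, simulate_cohort, simulate_selected_residuals

MODEL = SelectionModel(7.02, 17.6, 3.30)


class TestExpectedOnset:
    def test_matches_independent_formula(self):
        # oracle: direct evaluation of the published parametric relation
        for cag in (40, 43, 50):
            assert expected_onset(cag) == pytest.approx(
                21.54 + np.exp(9.556 - 0.146 * cag), rel=1e-12
            )

    def test_inverse_relation_with_cag(self):
        assert expected_onset(42) > expected_onset(45)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            expected_onset(30)
        # but a widened model accepts it
        assert expected_onset(30, LangbehnModel(cag_min=20)) > 0

    def test_residual_sign_convention(self):
        cag = 43
        assert residual(expected_onset(cag), cag) == pytest.approx(0.0)
        assert residual(expected_onset(cag) + 10, cag) == pytest.approx(10.0)


class TestRepeatStatistics:
    def test_reference_het_pair(self):
        out = repeat_statistics(38, 35)
        assert out == {"sum": 73, "diff": 3, "min": 35, "max": 38, "n3rep": 1}

    def test_hom_reference(self):
        out = repeat_statistics(38, 38)
        assert out["diff"] == 0 and out["n3rep"] == 0

    def test_three_repeat_dosage_two(self):
        assert repeat_statistics(35, 35)["n3rep"] == 2

    def test_n3rep_uses_str_when_available(self):
        # 35-unit QTR but a non-3 STR would not count
        assert repeat_statistics(35, 38, str_a=4, str_b=6)["n3rep"] == 0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            repeat_statistics(0, 38)


class TestSelectionFunction:
    def test_half_at_threshold(self):
        assert selection_function(17.6, MODEL) == pytest.approx(0.5)
        assert selection_function(-17.6, MODEL) == pytest.approx(0.5)

    def test_centre_value(self):
        assert selection_function(0.0, MODEL) == pytest.approx(
            1 / (1 + np.exp(17.6 / 3.3))
        )

    def test_zero_width_limit_is_indicator(self):
        d0 = SelectionModel(7.02, 17.6, 0.0)
        assert selection_function(20.0, d0) == 1.0
        assert selection_function(10.0, d0) == 0.0
        assert selection_function(17.6, d0) == 0.5

    def test_model_validation(self):
        with pytest.raises(ValueError):
            SelectionModel(-1.0, 17.6, 3.3)
        with pytest.raises(ValueError):
            SelectionModel(7.0, 17.6, -0.1)


class TestSelectedDensity:
    def test_unit_integral(self):
        val, _ = integrate.quad(
            lambda r: selected_density(r, MODEL), -90, 90,
            points=[-17.6, 0, 17.6], limit=300,
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_no_selection_limit_reduces_to_normal(self):
        free = SelectionModel(7.02, -1e6, 1.0)  # S == 1 everywhere
        r = np.linspace(-20, 20, 41)
        np.testing.assert_allclose(
            selected_density(r, free), stats.norm.pdf(r, scale=7.02), rtol=1e-9
        )

    def test_symmetry(self):
        assert selected_density(12.3, MODEL) == pytest.approx(
            selected_density(-12.3, MODEL)
        )


class TestNormalizer:
    @pytest.mark.parametrize("mu", [-8.0, 0.0, 1.7, 12.0])
    def test_against_adaptive_quadrature(self, mu):
        want, _ = integrate.quad(
            lambda r: stats.norm.pdf(r, loc=mu, scale=MODEL.sigma)
            * selection_function(r, MODEL),
            mu - 90, mu + 90, points=[-17.6, 0, 17.6], limit=300,
        )
        assert selection_normalizer(mu, MODEL.sigma, MODEL) == pytest.approx(
            want, rel=1e-10
        )

    def test_against_monte_carlo(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(3.0, MODEL.sigma, size=1_000_000)
        mc = float(np.mean(selection_function(draws, MODEL)))
        assert selection_normalizer(3.0, MODEL.sigma, MODEL) == pytest.approx(
            mc, abs=3e-3
        )

    def test_zero_width_closed_form_matches_tiny_width(self):
        sharp = SelectionModel(7.02, 17.6, 0.0)
        near = SelectionModel(7.02, 17.6, 1e-6)
        for mu in (0.0, 5.0, -11.0):
            assert selection_normalizer(mu, 7.02, sharp) == pytest.approx(
                selection_normalizer(mu, 7.02, near), abs=1e-6
            )


class TestSelectionLoglik:
    def test_reduces_to_ols_term_without_selection(self):
        term = selection_loglik(4.0, 76.0, 1.0, -0.5, 7.0, None)
        eps = 4.0 - (1.0 - 0.5 * 76.0)
        assert term == pytest.approx(stats.norm.logpdf(eps, scale=7.0), rel=1e-12)

    def test_selection_term_structure(self):
        term = selection_loglik(20.0, 76.0, 0.0, 0.0, 7.02, MODEL)
        eps = 20.0
        want = (
            stats.norm.logpdf(eps, scale=7.02)
            + np.log(selection_function(20.0, MODEL))
            - np.log(selection_normalizer(0.0, 7.02, MODEL))
        )
        assert term == pytest.approx(want, rel=1e-12)


class TestFitSelectionModel:
    def test_small_sample_warns(self):
        rng = np.random.default_rng(1)
        with pytest.warns(UserWarning, match="unreliable"):
            fit_selection_model(rng.normal(0, 5, size=10))

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            fit_selection_model(np.full(100, 3.0))

    def test_unselected_normal_residuals(self):
        """Without real selection the fitted S stays ~1 over the data and D
        approaches the plain KS distance to the normal."""
        rng = np.random.default_rng(5)
        r = rng.normal(0, 7.0, size=2000)
        fit = fit_selection_model(r)
        plain = stats.kstest(np.abs(r), "foldnorm", args=(1e-9, 0, fit.model.sigma))
        assert fit.D <= plain.statistic + 0.01
        # selection must be inactive where the data live
        s_vals = selection_function(r, fit.model)
        assert np.median(s_vals) > 0.5


class TestOlsAssociation:
    def test_noiseless_line_recovered_exactly(self):
        x = np.array([70.0, 72, 74, 76, 78, 80])
        r = 2.0 - 1.0 * x
        fit = ols_association((x, r))
        assert fit.beta0 == pytest.approx(2.0, abs=1e-9)
        assert fit.beta1 == pytest.approx(-1.0, abs=1e-12)

    def test_constant_statistic_rejected(self):
        with pytest.raises(ValueError):
            ols_association((np.full(10, 76.0), np.arange(10.0)))

    def test_null_p_uniformity(self):
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(300):
            x = rng.integers(70, 80, size=60).astype(float)
            r = rng.normal(0, 7, size=60)
            ps.append(ols_association((x, r)).lrt_p)
        assert stats.kstest(ps, "uniform").pvalue > 1e-3
        assert np.mean(np.asarray(ps) < 0.05) < 0.11


class TestLogistic:
    def test_negative_effect_detected(self):
        cfg = CohortSimConfig(n=600, selection=None, seed=3)
        coh = simulate_cohort(cfg)
        fit = dichotomize_and_logistic(coh, "sum", 0.0)
        assert fit.beta1 < 0 and fit.lrt_p < 0.05

    def test_all_excluded_raises(self):
        cfg = CohortSimConfig(n=100, selection=None, seed=4)
        coh = simulate_cohort(cfg)
        with pytest.raises(ValueError):
            dichotomize_and_logistic(coh, "sum", 1e6)


class TestRegressionWithSelection:
    def test_matches_ols_mle_without_selection(self):
        rng = np.random.default_rng(6)
        x = rng.integers(68, 82, size=200).astype(float)
        r = -1.0 * (x - x.mean()) + rng.normal(0, 7, size=200)
        free = fit_regression_with_selection((x, r), model=None, compute_ci=False)
        ols = ols_association((x, r))
        assert free.beta1 == pytest.approx(ols.beta1, abs=1e-4)
        assert free.beta0 == pytest.approx(ols.beta0, abs=1e-2)

    def test_corrects_selection_bias_single_cohort(self):
        coh = simulate_cohort(CohortSimConfig(n=610, seed=8))
        sel = fit_regression_with_selection(coh, "sum", MODEL, compute_ci=True)
        ols = ols_association(coh, "sum")
        assert abs(ols.beta1) > 1.5          # inflated on the selected sample
        assert abs(sel.beta1 + 1.0) < 0.45   # near the generating effect
        lo, hi = sel.ci95_beta1
        assert lo < -1.0 < hi

    def test_loglik_is_sum_of_terms(self):
        coh = simulate_cohort(CohortSimConfig(n=120, seed=9))
        fit = fit_regression_with_selection(coh, "sum", MODEL, compute_ci=False)
        x = (coh["qtr_a"] + coh["qtr_b"]).to_numpy(dtype=float)
        r = coh["residual"].to_numpy()
        total = sum(
            selection_loglik(ri, xi, fit.beta0, fit.beta1, fit.sigma, MODEL)
            for ri, xi in zip(r, x)
        )
        assert fit.loglik == pytest.approx(total, rel=1e-8)


class TestCompareStatistics:
    def test_duplicate_statistic_reports_no_improvement(self):
        coh = simulate_cohort(CohortSimConfig(n=300, selection=None, seed=10))
        import pandas as pd

        from qtronset.onset import cohort_statistics

        stats_df = cohort_statistics(coh)
        stats_df["sum2"] = stats_df["sum"]
        df = pd.concat([coh[["residual"]], stats_df], axis=1)
        pmat, _ = compare_statistics(df, ("sum", "sum2"))
        assert pmat.loc["sum", "sum2"] == 1.0

    def test_sum_best_when_sum_generates(self):
        wins = 0
        for seed in range(5):
            coh = simulate_cohort(CohortSimConfig(n=610, seed=40 + seed))
            _, best = compare_statistics(coh)
            wins += best == ["sum"]
        assert wins >= 3


class TestConditional:
    def test_identical_covariate_flagged(self):
        coh = simulate_cohort(CohortSimConfig(n=200, selection=None, seed=12))
        res = conditional_association(coh, "sum", "sum")
        assert "collinear" in res.flags

    def test_independent_covariate_preserves_primary(self):
        rng = np.random.default_rng(13)
        coh = simulate_cohort(CohortSimConfig(n=500, selection=None, seed=13))
        coh["noise_cov"] = rng.normal(size=len(coh))
        res = conditional_association(coh, "sum", "noise_cov")
        assert res.partial_primary_p == pytest.approx(
            res.marginal_primary.lrt_p, rel=0.6
        )


class TestBonferroni:
    def test_published_pair(self):
        assert bonferroni_adjust(5.0e-9, 4) == pytest.approx(2.0e-8)

    def test_capped_at_one(self):
        assert bonferroni_adjust(0.5, 4) == 1.0

    def test_identity_for_single_test(self):
        assert bonferroni_adjust(0.123, 1) == 0.123

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(0.1, 0)
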