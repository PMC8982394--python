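"""Inheritance-model fitting: design construction, IRLS, nested tests."""

import numpy as np
import pytest

from conidiokit import (
    ADDITIVE,
    ENVIRONMENTAL,
    FULL_EPISTATIC,
    PARAM_NAMES,
    CrossCountsTable,
    GeneticDesign,
    ModelSpec,
    ParameterVector,
    compare_nested,
    default_design,
    fit_environmental,
    fit_model,
    heritability,
    hierarchy_table,
    pearson_chisq,
    standard_errors,
)
from conidiokit.inheritance import MODEL_HIERARCHY, SingularDesignError
from conidiokit.simulate import simulate_cross_counts

from _oracles import simplex_ml_fit


class TestDefaultDesign:
    def test_columns_sum_to_zero_and_full_rank(self, design):
        assert np.allclose(design.per_cross.sum(axis=1), 0.0)
        assert np.linalg.matrix_rank(design.stacked) == 6

    def test_zero_effects_give_uniform_probabilities(self, design):
        probs = design.probabilities(ParameterVector())
        assert np.allclose(probs, 1.0 / 3.0)

    def test_any_theta_keeps_rows_stochastic(self, design, rng):
        for _ in range(50):
            theta = rng.uniform(-0.2, 0.2, size=6)
            probs = design.probabilities(theta)
            assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_column_sum_violation_rejected(self, design):
        broken = design.per_cross.copy()
        broken[0, 0, 0] += 0.5
        with pytest.raises(ValueError, match="sum to zero"):
            GeneticDesign(per_cross=broken)


class TestPearsonChisq:
    def test_identity_gives_zero(self):
        table = np.arange(1.0, 10.0).reshape(3, 3)
        assert pearson_chisq(table, table) == 0.0

    def test_table5_against_uniform_expectation(self, f2_counts):
        expected = np.repeat(f2_counts.row_totals[:, None] / 3.0, 3, axis=1)
        assert pearson_chisq(f2_counts.counts, expected) == pytest.approx(
            84.269, abs=5e-4)

    def test_hand_computed_sum(self):
        observed = np.array([[4, 1, 1], [1, 4, 1], [1, 1, 4]], float)
        assert pearson_chisq(observed, np.full((3, 3), 2.0)) == pytest.approx(9.0)

    def test_shape_and_positivity_contracts(self):
        with pytest.raises(ValueError, match="3x3"):
            pearson_chisq(np.ones((2, 3)), np.ones((2, 3)))
        with pytest.raises(ValueError, match="> 0"):
            pearson_chisq(np.ones((3, 3)), np.zeros((3, 3)))


class TestEnvironmentalFit:
    def test_no_genetic_effects_model_on_f2_counts(self, f2_counts):
        fit = fit_environmental(f2_counts)
        assert fit.chisq == pytest.approx(84.269, abs=5e-4)
        assert fit.df == 6
        assert fit.iterations == 0
        assert np.allclose(fit.fitted_probs, 1.0 / 3.0)
        assert np.allclose(fit.expected_counts.sum(axis=1),
                           f2_counts.row_totals)

    def test_uniform_rows_fit_perfectly(self):
        table = CrossCountsTable(counts=np.full((3, 3), 7.0))
        assert fit_environmental(table).chisq == 0.0

    def test_independent_of_design_matrix(self, f2_counts, design, rng):
        # uses only the 1/3 baseline, so a scrambled full-rank design
        # must give the identical statistic
        other = GeneticDesign(per_cross=design.per_cross[:, :, ::-1] * 2.0)
        a = fit_model(f2_counts, design, ENVIRONMENTAL).chisq
        b = fit_model(f2_counts, other, ENVIRONMENTAL).chisq
        assert a == b


class TestFullEpistaticFit:
    def test_saturated_on_f2_counts(self, f2_counts):
        fit = fit_model(f2_counts)
        assert fit.converged and fit.iterations <= 20
        assert fit.chisq == pytest.approx(0.0, abs=1e-8)
        assert fit.df == 0
        assert np.allclose(fit.fitted_probs, f2_counts.proportions,
                           atol=1e-9)
        assert np.allclose(fit.fitted_probs.sum(axis=1), 1.0, atol=1e-9)

    def test_uniform_counts_give_zero_effects(self):
        table = CrossCountsTable(counts=np.full((3, 3), 50.0))
        fit = fit_model(table)
        assert np.allclose(fit.theta_hat.as_array(), 0.0, atol=1e-12)
        assert fit.chisq == pytest.approx(0.0, abs=1e-12)

    def test_recovers_generating_parameters_from_rounded_expectations(
            self, design):
        theta_star = ParameterVector(0.06, -0.03, 0.03, 0.03, -0.03, 0.0)
        n_i = 6000
        expected = np.rint(n_i * design.probabilities(theta_star))
        fit = fit_model(CrossCountsTable(counts=expected), design)
        assert np.all(np.abs(fit.theta_hat.as_array()
                             - theta_star.as_array()) < 0.01)
        # agreement with the derivative-free oracle on the same table
        oracle = simplex_ml_fit(CrossCountsTable(counts=expected), design,
                                FULL_EPISTATIC)
        assert np.all(np.abs(fit.theta_hat.as_array() - oracle) < 1e-5)

    def test_saturated_on_random_attainable_tables(self, design, rng):
        for _ in range(20):
            theta = np.concatenate([rng.uniform(-0.08, 0.08, 3),
                                    rng.uniform(-0.05, 0.05, 3)])
            table = simulate_cross_counts(ParameterVector(*theta), design,
                                          (500, 500, 500), rng)
            fit = fit_model(table, design)
            assert fit.chisq < 1e-6

    def test_irls_matches_simplex_oracle_on_f2_counts(self, f2_counts,
                                                      design):
        fit = fit_model(f2_counts, design, FULL_EPISTATIC)
        oracle = simplex_ml_fit(f2_counts, design, FULL_EPISTATIC)
        assert np.all(np.abs(fit.theta_hat.as_array() - oracle) < 1e-5)

    def test_collinear_free_columns_are_named(self, f2_counts, design):
        duplicated = design.per_cross.copy()
        duplicated[:, :, 3] = duplicated[:, :, 0]  # alpha_beta := alpha
        with pytest.raises(SingularDesignError, match="alpha_beta"):
            fit_model(f2_counts, GeneticDesign(per_cross=duplicated))


class TestNestedComparison:
    def test_environmental_vs_additive_arithmetic(self, f2_counts):
        h0 = fit_environmental(f2_counts)
        ha = fit_model(f2_counts, spec=ADDITIVE)
        result = compare_nested(h0, ha)
        assert result.delta_chisq == pytest.approx(h0.chisq - ha.chisq)
        assert result.delta_df == 3
        assert result.p_value < 1e-4

    def test_identical_fit_quality_gives_zero_and_p_one(self, f2_counts):
        import dataclasses
        ha = fit_model(f2_counts, spec=ModelSpec("ab", frozenset({"alpha_beta"})))
        h0 = fit_model(f2_counts, spec=ModelSpec(
            "ab+a", frozenset({"alpha_beta", "alpha"})))
        result = compare_nested(dataclasses.replace(h0, chisq=ha.chisq), ha)
        assert result.delta_chisq == 0.0
        assert result.p_value == pytest.approx(1.0)

    def test_single_df_difference_is_highly_significant(self):
        # a 13.37 chi-squared improvement on 1 df: upper tail 2.557e-4
        from scipy.stats import chi2
        assert chi2.sf(13.37, 1) == pytest.approx(2.5568e-4, rel=1e-3)

    def test_non_nested_specs_rejected(self, f2_counts):
        ab = fit_model(f2_counts, spec=ModelSpec("ab", frozenset({"alpha_beta"})))
        bc = fit_model(f2_counts, spec=ModelSpec("bc", frozenset({"beta_gamma"})))
        with pytest.raises(ValueError, match="nested"):
            compare_nested(ab, bc)

    def test_negative_difference_clamped_with_warning(self, f2_counts):
        import dataclasses
        h0 = fit_model(f2_counts, spec=ModelSpec(
            "ab+a", frozenset({"alpha_beta", "alpha"})))
        ha = fit_model(f2_counts, spec=ModelSpec("ab", frozenset({"alpha_beta"})))
        inflated = dataclasses.replace(ha, chisq=h0.chisq + 0.5)
        with pytest.warns(RuntimeWarning, match="clamped"):
            result = compare_nested(h0, inflated)
        assert result.delta_chisq == 0.0
        assert result.p_value == 1.0
        assert result.raw_delta_chisq == pytest.approx(-0.5)


class TestHeritability:
    def test_published_statistics_give_047(self):
        assert heritability(84.27, 44.61, ndigits=2).h_squared == 0.47

    def test_no_additive_improvement_gives_zero(self):
        assert heritability(30.0, 30.0).h_squared == 0.0

    def test_saturating_additive_model_gives_one(self):
        assert heritability(30.0, 0.0).h_squared == 1.0

    def test_rejects_non_positive_total(self):
        with pytest.raises(ValueError):
            heritability(0.0, 0.0)


class TestStandardErrors:
    def test_positive_finite_for_saturated_fit(self, f2_counts):
        ses = standard_errors(fit_model(f2_counts))
        assert set(ses) == set(PARAM_NAMES)
        assert all(0 < se < 1 for se in ses.values())

    def test_doubling_counts_shrinks_ses_by_sqrt2(self, f2_counts):
        base = standard_errors(fit_model(f2_counts))
        doubled = CrossCountsTable(counts=2 * f2_counts.counts)
        scaled = standard_errors(fit_model(doubled))
        for name in PARAM_NAMES:
            assert scaled[name] == pytest.approx(base[name] / np.sqrt(2),
                                                 abs=1e-9)

    def test_agree_with_parametric_bootstrap(self, f2_counts, design):
        # 20000 resamples keep the Monte-Carlo error of the bootstrap sd
        # (~1/sqrt(2B) = 0.5%) well below the 2% agreement band
        fit = fit_model(f2_counts, design)
        probs = fit.fitted_probs
        n = f2_counts.row_totals.astype(int)
        rng = np.random.default_rng(0)
        draws = []
        for _ in range(20_000):
            counts = np.stack([rng.multinomial(n[i], probs[i])
                               for i in range(3)])
            draws.append(fit_model(CrossCountsTable(counts=counts),
                                   design).theta_hat.as_array())
        boot_sd = np.array(draws).std(axis=0, ddof=1)
        ses = np.array([fit.standard_errors[p] for p in PARAM_NAMES])
        assert np.all(np.abs(ses / boot_sd - 1) < 0.02)


class TestHierarchyTable:
    def test_df_accounting_across_the_hierarchy(self, f2_counts):
        frame = hierarchy_table(f2_counts).to_frame()
        assert list(frame["df"]) == [0, 1, 2, 1, 2, 2, 1, 2, 3, 6]

    def test_extreme_rows_match_the_design_independent_statistics(
            self, f2_counts):
        report = hierarchy_table(f2_counts)
        assert report.fits["environmental"].chisq == pytest.approx(84.269,
                                                                   abs=5e-4)
        assert report.fits["full_epistatic"].chisq == pytest.approx(0.0,
                                                                    abs=1e-8)

    def test_nesting_monotonicity(self, f2_counts):
        report = hierarchy_table(f2_counts)
        by_name = {spec.name: spec for spec in MODEL_HIERARCHY}
        for child_name, parent_name in (
                ("ab_zero", "full_epistatic"),
                ("ab_alpha_zero", "ab_zero"),
                ("bc_zero", "full_epistatic"),
                ("bc_beta_zero", "bc_zero"),
                ("ab_beta_zero", "ab_zero"),
                ("ac_zero", "full_epistatic"),
                ("ac_alpha_zero", "ac_zero"),
                ("additive", "ab_zero"),
                ("environmental", "additive")):
            assert by_name[child_name].is_nested_in(by_name[parent_name])
            assert (report.fits[child_name].chisq
                    >= report.fits[parent_name].chisq - 1e-6)

    def test_uniform_counts_leave_heritability_undefined(self):
        table = CrossCountsTable(counts=np.full((3, 3), 40.0))
        report = hierarchy_table(table)
        assert report.heritability is None
        assert all(fit.chisq == pytest.approx(0.0, abs=1e-10)
                   for fit in report.fits.values())
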