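"""Continuum approach: scaled-beta distribution and interval-censored fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from shm import (
    BetaParams,
    BoundarySet,
    FrequencyTable,
    ResponseScale,
    ValidationError,
    beta_cdf,
    beta_mean_sd,
    beta_pdf,
    beta_quantile,
    expected_frequencies,
    fit_beta,
    numeric_equal_width_boundaries,
    solve_three_option,
)
from shm.continuum import FitCriterion

CRITERIA = ["chi2", "ml", "cdf_lsq"]


def make_bounds(uppers, kind="verbal"):
    k = len(uppers)
    scale = ResponseScale("x", kind, tuple(f"o{i}" for i in range(k)))
    return BoundarySet(scale, tuple(uppers), "judges")


def table_from_probs(bounds, probs, year=1, survey_id="s"):
    return FrequencyTable(scale=bounds.scale, weights=tuple(probs), year=year, survey_id=survey_id)


class TestDistribution:
    def test_uniform_cdf_midpoint(self):
        assert beta_cdf(5.0, BetaParams(1, 1)) == pytest.approx(0.5)

    def test_cdf_at_support_end(self):
        assert beta_cdf(10.0, BetaParams(3.7, 0.4)) == 1.0

    def test_symmetric_closed_form(self):
        # Beta(2,2): F(t) = 3t^2 - 2t^3, at t = 0.25
        assert beta_cdf(2.5, BetaParams(2, 2)) == pytest.approx(0.15625)
        assert beta_quantile(0.15625, BetaParams(2, 2)) == pytest.approx(2.5)

    def test_cdf_domain_checked(self):
        with pytest.raises(ValidationError):
            beta_cdf(10.5, BetaParams(1, 1))
        with pytest.raises(ValidationError):
            beta_quantile(1.5, BetaParams(1, 1))

    def test_quantile_endpoints(self):
        p = BetaParams(2.5, 1.5)
        assert beta_quantile(0.0, p) == 0.0
        assert beta_quantile(1.0, p) == 10.0

    def test_pdf_integrates_to_one(self):
        # the 0-10 rescaling must carry the 1/10 Jacobian
        x = np.linspace(0, 10, 20001)
        for params in [BetaParams(1, 1), BetaParams(2, 3), BetaParams(8, 2.8)]:
            assert np.trapezoid(beta_pdf(x, params), x) == pytest.approx(1.0, abs=1e-6)

    @given(
        st.floats(min_value=0.001, max_value=0.999),
        st.floats(min_value=0.2, max_value=50),
        st.floats(min_value=0.2, max_value=50),
    )
    @settings(derandomize=True, max_examples=200)
    def test_cdf_quantile_mutually_inverse(self, p, a, b):
        params = BetaParams(a, b)
        assert beta_cdf(beta_quantile(p, params), params) == pytest.approx(p, abs=1e-10)

    @pytest.mark.parametrize(
        "a, b, mean, sd",
        [
            (1.0, 1.0, 5.0, 10 / np.sqrt(12)),
            (3.0, 1.0, 7.5, None),
            (2.0, 2.0, 5.0, None),
        ],
    )
    def test_mean_sd(self, a, b, mean, sd):
        m, s = beta_mean_sd(BetaParams(a, b))
        assert m == pytest.approx(mean)
        if sd is not None:
            assert s == pytest.approx(sd)


class TestEqualWidthBoundaries:
    @pytest.mark.parametrize("k", [2, 5, 11])
    def test_equal_fifths_and_elevenths(self, k):
        scale = ResponseScale("num", "numeric", tuple(range(k)))
        bounds = numeric_equal_width_boundaries(scale)
        np.testing.assert_allclose(bounds.uppers(), [(i + 1) * 10 / k for i in range(k)])
        assert bounds.source.value == "numeric_equal_width"

    def test_verbal_scale_rejected(self, scale4):
        with pytest.raises(ValidationError, match="verbal"):
            numeric_equal_width_boundaries(scale4)


class TestFitBeta:
    def test_two_options_undetermined(self):
        bounds = make_bounds([5.0, 10.0])
        table = table_from_probs(bounds, (0.4, 0.6))
        with pytest.raises(ValidationError, match="undetermined"):
            fit_beta(bounds, table)

    @pytest.mark.parametrize("criterion", CRITERIA)
    def test_parameter_recovery_from_exact_frequencies(self, criterion):
        """Frequencies that are exact CDF differences identify the generator."""
        truth = BetaParams(2.0, 3.0)
        bounds = make_bounds([2.0, 4.5, 6.0, 8.0, 10.0])
        probs = expected_frequencies(truth, bounds)
        fit = fit_beta(bounds, table_from_probs(bounds, probs), criterion=criterion)
        assert fit.params.alpha == pytest.approx(2.0, abs=1e-3)
        assert fit.params.beta == pytest.approx(3.0, abs=1e-3)
        assert fit.objective_value < 1e-9

    def test_mirror_equivariance(self):
        """Reflecting bounds and reversing frequencies swaps (alpha, beta)."""
        truth = BetaParams(2.4, 1.3)
        bounds = make_bounds([3.0, 5.5, 7.0, 10.0])
        probs = expected_frequencies(truth, bounds)
        mirrored = make_bounds([3.0, 4.5, 7.0, 10.0])  # 10 - b reversed
        fit = fit_beta(bounds, table_from_probs(bounds, probs))
        fit_m = fit_beta(mirrored, table_from_probs(mirrored, probs[::-1]))
        assert fit_m.params.alpha == pytest.approx(fit.params.beta, abs=1e-4)
        assert fit_m.params.beta == pytest.approx(fit.params.alpha, abs=1e-4)
        m, m_m = beta_mean_sd(fit.params)[0], beta_mean_sd(fit_m.params)[0]
        assert m_m == pytest.approx(10.0 - m, abs=1e-3)

    def test_symmetric_input_gives_symmetric_fit(self):
        bounds = make_bounds([2.5, 5.0, 7.5, 10.0])
        table = table_from_probs(bounds, (0.15625, 0.34375, 0.34375, 0.15625))
        fit = fit_beta(bounds, table)
        assert fit.params.alpha == pytest.approx(fit.params.beta, abs=1e-6)

    def test_zero_frequency_interior_category(self):
        bounds = make_bounds([2.0, 4.0, 6.0, 10.0])
        table = table_from_probs(bounds, (0.2, 0.0, 0.3, 0.5))
        for criterion in CRITERIA:
            fit = fit_beta(bounds, table, criterion=criterion)
            assert np.isfinite(fit.objective_value)
            assert fit.params.alpha > 0 and fit.params.beta > 0

    def test_residuals_are_cdf_misfit(self, eb2008, eb_judges):
        fit = fit_beta(eb_judges, eb2008)
        P = np.cumsum(eb2008.rel())[:-1]
        F = beta_cdf(eb_judges.uppers()[:-1], fit.params)
        np.testing.assert_allclose(fit.residuals, F - P, atol=1e-12)

    def test_cdf_lsq_matches_grid_search_oracle(self, eb2008, eb_judges):
        """Two-stage dense grid over (log a, log b) as an independent optimum check."""
        P = np.cumsum(eb2008.rel())[:-1]
        b01 = eb_judges.uppers()[:-1] / 10.0

        def obj(la, lb):
            F = stats.beta.cdf(b01[:, None, None], np.exp(la), np.exp(lb))
            return ((F - P[:, None, None]) ** 2).sum(axis=0)

        la = np.linspace(-3, 3, 121)
        grid = obj(la[None, :], la[:, None])
        i, j = np.unravel_index(np.argmin(grid), grid.shape)
        fine_a = np.linspace(la[j] - 0.1, la[j] + 0.1, 81)
        fine_b = np.linspace(la[i] - 0.1, la[i] + 0.1, 81)
        fine = obj(fine_a[None, :], fine_b[:, None])
        i2, j2 = np.unravel_index(np.argmin(fine), fine.shape)
        a, b = np.exp(fine_a[j2]), np.exp(fine_b[i2])
        grid_mean = 10 * a / (a + b)
        fit = fit_beta(eb_judges, eb2008, criterion="cdf_lsq")
        assert beta_mean_sd(fit.params)[0] == pytest.approx(grid_mean, abs=0.01)

    def test_criteria_agree_on_well_specified_data(self):
        truth = BetaParams(5.0, 2.0)
        bounds = make_bounds([3.0, 5.0, 6.5, 8.0, 10.0])
        probs = expected_frequencies(truth, bounds)
        means = [
            beta_mean_sd(fit_beta(bounds, table_from_probs(bounds, probs), criterion=c).params)[0]
            for c in CRITERIA
        ]
        assert max(means) - min(means) < 1e-3


class TestThreeOptionExactFit:
    def test_forward_generate_then_invert(self):
        truth = BetaParams(2.0, 2.0)
        bounds = make_bounds([10 / 3, 20 / 3, 10.0])
        probs = expected_frequencies(truth, bounds)
        params = solve_three_option(bounds, table_from_probs(bounds, probs))
        assert params.alpha == pytest.approx(2.0, abs=1e-6)
        assert params.beta == pytest.approx(2.0, abs=1e-6)

    def test_uniform_thirds(self):
        bounds = make_bounds([10 / 3, 20 / 3, 10.0])
        params = solve_three_option(bounds, table_from_probs(bounds, (1 / 3, 1 / 3, 1 / 3)))
        assert params.alpha == pytest.approx(1.0, abs=1e-6)
        assert params.beta == pytest.approx(1.0, abs=1e-6)

    def test_mirrored_frequencies_swap_shapes(self):
        bounds = make_bounds([10 / 3, 20 / 3, 10.0])
        p = solve_three_option(bounds, table_from_probs(bounds, (0.5, 0.3, 0.2)))
        q = solve_three_option(bounds, table_from_probs(bounds, (0.2, 0.3, 0.5)))
        assert q.alpha == pytest.approx(p.beta, abs=1e-6)
        assert q.beta == pytest.approx(p.alpha, abs=1e-6)

    def test_degenerate_cumulatives_rejected(self):
        bounds = make_bounds([3.0, 7.0, 10.0])
        with pytest.raises(ValidationError, match="P1"):
            solve_three_option(bounds, table_from_probs(bounds, (0.0, 0.4, 0.6)))

    @pytest.mark.parametrize(
        "probs", [(0.1, 0.3, 0.6), (0.6, 0.3, 0.1), (0.05, 0.9, 0.05), (0.4, 0.2, 0.4)]
    )
    def test_exact_fit_guarantee_via_fit_beta(self, probs):
        """Every 3-option instance with interior cumulatives fits with ~zero objective."""
        bounds = make_bounds([3.0, 6.5, 10.0])
        for criterion in CRITERIA:
            fit = fit_beta(bounds, table_from_probs(bounds, probs), criterion=criterion)
            assert fit.objective_value <= 1e-9
            assert max(abs(r) for r in fit.residuals) <= 1e-9
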