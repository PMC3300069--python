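"""Poisson spline fits, the constrained IRLS, and null-parameter extraction."""

import numpy as np
import pytest
from scipy import optimize, stats

from gelfdr import (bin_z, build_design, cme_quadratic, extract_null_params,
                    fit_cme, fit_constrained, fit_poisson_spline, mle_null,
                    poisson_deviance, select_df_aic)


class TestPoissonDeviance:
    def test_saturated_fit_is_zero(self):
        assert poisson_deviance([3, 5, 7], [3, 5, 7]) == pytest.approx(0.0)

    def test_hand_value(self):
        # 2(2 ln 2 - 2 - (0 - 1)) = 4 ln 2 - 2
        assert poisson_deviance([2], [1]) == pytest.approx(4 * np.log(2) - 2)

    def test_zero_count_convention(self):
        # 0*log(0) = 0: dev = 2(0 - 0 - (0 - 1)) = 2
        assert poisson_deviance([0], [1]) == pytest.approx(2.0)

    def test_rejects_nonpositive_means(self):
        with pytest.raises(ValueError):
            poisson_deviance([1], [0.0])


def _poisson_loglik(theta, gamma, m):
    eta = gamma @ theta
    return float(np.sum(m * eta - np.exp(eta)))


class TestUnconstrainedFit:
    def test_irls_matches_generic_convex_optimizer(self):
        """Oracle equivalence on 20 random small instances (J=50, D=5)."""
        rng = np.random.default_rng(12)
        for trial in range(20):
            z = rng.normal(rng.uniform(-1, 1), rng.uniform(0.8, 1.5), 2000)
            hist = bin_z(z, bins=50)
            design = build_design(hist, 5, (-1.0, 1.0))
            fit = fit_poisson_spline(hist, design, tolerance=1e-12)
            m = hist.counts.astype(float)
            res = optimize.minimize(
                lambda t: -_poisson_loglik(t, design.gamma, m),
                np.zeros(5),
                jac=lambda t: -(design.gamma.T @ (m - np.exp(design.gamma @ t))),
                method="BFGS", options={"gtol": 1e-10, "maxiter": 500})
            np.testing.assert_allclose(fit.theta, res.x, atol=1e-6,
                                       err_msg=f"instance {trial}")

    def test_matches_statsmodels_poisson_glm(self, fitted_hist_design):
        sm = pytest.importorskip("statsmodels.api")
        hist, design = fitted_hist_design
        fit = fit_poisson_spline(hist, design, tolerance=1e-12)
        glm = sm.GLM(hist.counts, design.gamma,
                     family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.theta, glm.params, atol=1e-6)
        assert fit.deviance == pytest.approx(glm.deviance, rel=1e-6)

    def test_recovers_exponential_linear_truth(self):
        # counts exactly exp(c1 + c2 x): a df-3 fit reproduces (c1, c2, 0)
        x = np.linspace(0, 1, 30)
        from gelfdr.design import Histogram
        counts = np.round(np.exp(5.0 + 1.2 * x)).astype(int)
        hist = Histogram(counts=counts, midpoints=x, width=x[1] - x[0],
                         total=int(counts.sum()))
        design = build_design(hist, 3, (0.0, 1.0))
        fit = fit_poisson_spline(hist, design, tolerance=1e-12)
        assert fit.theta[0] == pytest.approx(5.0, abs=5e-3)
        assert fit.theta[1] == pytest.approx(1.2, abs=1e-2)

    def test_improves_on_initialization(self, fitted_hist_design):
        hist, design = fitted_hist_design
        fit = fit_poisson_spline(hist, design)
        m = hist.counts.astype(float)
        init_dev = poisson_deviance(m, (m + m.mean()) / 2.0)
        assert fit.deviance <= init_dev
        assert fit.converged


class TestConstrainedFit:
    def test_equals_unconstrained_when_constraint_inactive(self):
        """When the unconstrained optimum is feasible, the constrained fit
        coincides with it.

        Feasibility demands the spline be exactly quadratic over the null
        bins (least-squares residuals there sum to zero, so nonnegative
        slack forces zero slack), so the test instance is built with counts
        lying exactly on a log-linear curve: the unconstrained GLM
        reproduces it exactly and sits on the constraint boundary.
        """
        from gelfdr.design import Histogram
        x = np.linspace(-2, 2, 40)
        counts = np.exp(3.0 - 0.7 * x)
        hist = Histogram(counts=counts, midpoints=x, width=x[1] - x[0],
                         total=int(round(counts.sum())))
        design = build_design(hist, 6, (-1.0, 1.0))
        unc = fit_poisson_spline(hist, design, tolerance=1e-12)
        assert (design.constraint @ unc.theta).min() >= -1e-9  # feasible
        con = fit_constrained(hist, design, tolerance=1e-12)
        np.testing.assert_allclose(con.theta, unc.theta, atol=1e-6)

    def test_close_to_unconstrained_on_pure_null_sample(
            self, pure_null_hist_design):
        """On a pure-null sample the mixture is its own null: constraining
        barely moves the fit (null parameters agree closely)."""
        from gelfdr import extract_null_params, cme_quadratic
        hist, design = pure_null_hist_design
        unc = fit_poisson_spline(hist, design, tolerance=1e-12)
        con = fit_constrained(hist, design, tolerance=1e-12)
        pu = extract_null_params(cme_quadratic(unc, design),
                                 hist.total, hist.width)
        pc = con.null_params()
        assert pc.delta == pytest.approx(pu.delta, abs=0.05)
        assert pc.sigma == pytest.approx(pu.sigma, abs=0.05)
        assert pc.p0 == pytest.approx(pu.p0, abs=0.05)

    def test_constraint_satisfied_across_replicates(self, two_normal_config):
        from gelfdr import simulate_z
        for seed in range(1, 11):
            z, _ = simulate_z(two_normal_config, seed)
            hist = bin_z(z, bins=100)
            design = build_design(hist, 7, two_normal_config.null_interval)
            fit = fit_constrained(hist, design)
            assert (design.constraint @ fit.theta).min() >= -1e-8
            assert fit.converged

    def test_fdr_at_midpoints_never_exceeds_one(self, fitted_hist_design):
        hist, design = fitted_hist_design
        fit = fit_constrained(hist, design)
        fdr = np.exp(fit.log_null(hist.midpoints)
                     - fit.log_mixture(hist.midpoints))
        assert fdr.max() <= 1.0 + 1e-8

    def test_likelihood_no_better_than_unconstrained(self, fitted_hist_design):
        hist, design = fitted_hist_design
        unc = fit_poisson_spline(hist, design)
        con = fit_constrained(hist, design)
        assert con.deviance >= unc.deviance - 1e-6


class TestCMEQuadratic:
    def test_matches_polyfit_on_null_bins(self, fitted_hist_design):
        hist, design = fitted_hist_design
        fit = fit_poisson_spline(hist, design)
        beta = cme_quadratic(fit, design)
        xs = design.omega0[:, 1]
        s_vals = design.gamma0 @ fit.theta
        oracle = np.polyfit(xs, s_vals, 2)[::-1]
        np.testing.assert_allclose(beta, oracle, rtol=1e-7, atol=1e-9)

    def test_fit_cme_attaches_beta(self, fitted_hist_design):
        hist, design = fitted_hist_design
        fit = fit_cme(hist, design)
        assert fit.method == "cme"
        np.testing.assert_allclose(fit.beta, cme_quadratic(fit, design))


class TestExtractNullParams:
    def test_standard_normal_round_trip(self):
        # delta=0, sigma=1, p0=1, N*Delta=100
        beta = [np.log(100) - 0.5 * np.log(2 * np.pi), 0.0, -0.5]
        p = extract_null_params(beta, total=100, width=1.0)
        assert p.delta == pytest.approx(0.0, abs=1e-12)
        assert p.sigma == pytest.approx(1.0, rel=1e-12)
        assert p.p0 == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("delta,sigma,p0", [
        (-1.0, 0.9, 0.9), (0.3, 1.2, 0.5), (-1.5, 1.07, 0.84)])
    def test_closed_form_round_trip(self, delta, sigma, p0):
        N, width = 550, 0.11
        scale = np.log(N * width)
        beta = [scale + np.log(p0)
                - 0.5 * (delta ** 2 / sigma ** 2 + np.log(2 * np.pi * sigma ** 2)),
                delta / sigma ** 2, -0.5 / sigma ** 2]
        p = extract_null_params(beta, total=N, width=width)
        assert p.delta == pytest.approx(delta, abs=1e-12)
        assert p.sigma == pytest.approx(sigma, abs=1e-12)
        assert p.p0 == pytest.approx(p0, abs=1e-12)

    def test_p0_capped_with_raw_value_recorded(self):
        beta = [np.log(100) - 0.5 * np.log(2 * np.pi) + 0.3, 0.0, -0.5]
        p = extract_null_params(beta, total=100, width=1.0)
        assert p.p0 == 1.0
        assert p.p0_raw == pytest.approx(np.exp(0.3), rel=1e-10)

    def test_nonnegative_curvature_rejected(self):
        with pytest.raises(ValueError, match="curvature"):
            extract_null_params([0.0, 0.0, 0.1], total=100, width=1.0)


class TestMLENull:
    def test_recovers_wide_normal(self):
        rng = np.random.default_rng(21)
        z = rng.normal(0.3, 1.2, 50_000)
        p = mle_null(z, (-4.0, 4.6))
        assert p.delta == pytest.approx(0.3, abs=0.03)
        assert p.sigma == pytest.approx(1.2, abs=0.03)
        assert p.p0 > 0.97

    def test_symmetric_data_centered_estimate(self):
        rng = np.random.default_rng(22)
        half = rng.normal(0, 1, 10_000)
        z = np.concatenate([half, -half]) + 2.0  # exactly symmetric about 2
        p = mle_null(z, (0.0, 4.0))
        assert p.delta == pytest.approx(2.0, abs=0.02)

    def test_plugin_mode_close_to_joint(self, two_normal_config):
        from gelfdr import simulate_z
        z, _ = simulate_z(two_normal_config, 3)
        joint = mle_null(z, (-2.0, 0.0))
        plugin = mle_null(z, (-2.0, 0.0), p0_mode="plugin")
        assert joint.delta == pytest.approx(plugin.delta, abs=0.05)
        assert joint.sigma == pytest.approx(plugin.sigma, abs=0.05)
        assert joint.p0 == pytest.approx(plugin.p0, abs=0.05)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            mle_null(np.linspace(-10, 10, 30), (-0.1, 0.1))


class TestSelectDfAic:
    def test_singleton_range_returned(self, fitted_hist_design):
        hist, _ = fitted_hist_design
        fit, table = select_df_aic(hist, (-2, 0), df_range=[5])
        assert fit.design.df == 5
        assert list(table["df"]) == [5]

    def test_unconstrained_deviance_improves_coarse_to_fine(
            self, fitted_hist_design):
        # uniform knot sets at different df are not nested, so the deviance
        # need not fall at every single step — but a rich basis must beat a
        # coarse one decisively on this clearly non-quadratic histogram
        hist, _ = fitted_hist_design
        _, table = select_df_aic(hist, (-2, 0), df_range=range(4, 11),
                                 constrained=False)
        dev = table["deviance"].to_numpy()
        assert dev[-1] < dev[0]
        assert dev.min() == pytest.approx(dev[-3:].min())

    def test_aic_is_deviance_plus_2df(self, fitted_hist_design):
        hist, _ = fitted_hist_design
        _, table = select_df_aic(hist, (-2, 0), df_range=range(4, 8))
        np.testing.assert_allclose(table["aic"],
                                   table["deviance"] + 2 * table["df"])

    def test_winner_minimises_aic(self, fitted_hist_design):
        hist, _ = fitted_hist_design
        fit, table = select_df_aic(hist, (-2, 0), df_range=range(4, 11))
        ok = table[table["converged"]]
        assert fit.design.df == int(ok.loc[ok["aic"].idxmin(), "df"])
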