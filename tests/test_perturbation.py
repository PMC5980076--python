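"""Linearized hazard: weights, targets, closed-form effect, loss."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from sklearn.linear_model import LinearRegression

from locoage.gompertz import fit_gompertz
from locoage.perturbation import (
    compute_weights,
    effect_closed_form,
    linearized_vs_full_fit,
    transform_targets,
    weighted_regression_loss,
)

from conftest import simulate_feature_cohort


@pytest.fixture(scope="module")
def cohort_and_weights():
    df, xi = simulate_feature_cohort(6000, 0.1, seed=77)
    fit = fit_gompertz(df, covariate_cols=["gender"], fix_Gamma=0.085)
    lin = compute_weights(df, fit)
    return df, xi, fit, lin


class TestWeights:
    def test_algebraic_identities(self, cohort_and_weights):
        _, _, _, lin = cohort_and_weights
        assert np.isclose(lin.rho.sum(), 1.0, rtol=1e-12)
        assert abs(np.sum(lin.rho * lin.R)) < 1e-10
        assert abs(np.sum(lin.delta - lin.N_d * lin.rho)) < 1e-8

    def test_identical_subjects_share_weight(self):
        n = 10
        df = pd.DataFrame({"t1": 60.0, "t2": 65.0,
                           "delta": [1, 0, 0, 0, 1, 0, 0, 0, 0, 0],
                           "gender": 1}, index=range(n))
        fit = fit_gompertz(df, covariate_cols=["gender"], fix_Gamma=0.085)
        lin = compute_weights(df, fit)
        assert np.allclose(lin.rho, 1.0 / n)
        assert np.allclose(lin.R, df["delta"] * n / lin.N_d - 1.0)

    def test_zero_exposure_subject_dropped(self):
        df = pd.DataFrame({
            "t1": [60.0, 60.0, 62.0], "t2": [65.0, 64.0, 62.0],
            "delta": [1, 0, 0], "gender": [0, 1, 1]})
        fit = fit_gompertz(df, covariate_cols=["gender"], fix_Gamma=0.085)
        lin = compute_weights(df, fit)
        assert lin.n_dropped == 1
        assert len(lin) == 2
        assert np.isclose(lin.rho.sum(), 1.0)

    def test_zero_exposure_death_is_degenerate(self):
        df = pd.DataFrame({
            "t1": [60.0, 62.0], "t2": [65.0, 62.0],
            "delta": [0, 1], "gender": [0, 1]})
        fit = fit_gompertz(df, covariate_cols=["gender"], fix_Gamma=0.085,
                           fix_M0=1e-4)
        with pytest.raises(ValueError, match="zero exposure"):
            compute_weights(df, fit)

    def test_no_events_errors(self):
        df = pd.DataFrame({"t1": [60.0], "t2": [65.0], "delta": [0],
                           "gender": [1]})
        fit = fit_gompertz(df, covariate_cols=["gender"], fix_Gamma=0.085,
                           fix_M0=1e-4)
        with pytest.raises(ValueError, match="no death events"):
            compute_weights(df, fit)

    def test_nd_rho_is_integrated_hazard(self, cohort_and_weights):
        df, _, fit, lin = cohort_and_weights
        beta = fit.beta["gender"]
        rng = np.random.default_rng(0)
        kept = df.reset_index(drop=True)
        for i in rng.integers(0, len(kept), size=5):
            row = kept.iloc[int(i)]
            integral, _ = quad(
                lambda t: fit.M0 * np.exp(fit.Gamma * t
                                          + beta * row["gender"]),
                row["t1"], row["t2"])
            assert np.isclose(lin.N_d * lin.rho[int(i)], integral,
                              rtol=1e-6)


class TestClosedFormEffect:
    def test_planted_effect_recovered_within_3_sigma(self,
                                                     cohort_and_weights):
        _, xi, _, lin = cohort_and_weights
        eff = effect_closed_form(lin, xi)
        assert abs(eff.beta_xi[0] - 0.1) < 3 * eff.sigma[0]
        assert eff.sigma[0] > 0
        assert 0 <= eff.p_value[0] <= 1

    def test_constant_feature_is_singular(self, cohort_and_weights):
        _, _, _, lin = cohort_and_weights
        with pytest.raises(ValueError, match="variance|singular"):
            effect_closed_form(lin, np.ones(len(lin)))

    def test_mirrored_cohort_gives_zero_effect(self):
        # two exact copies of the same survival data, labelled 0 and 1:
        # by symmetry the death excess cancels and beta = 0
        half, _ = simulate_feature_cohort(400, 0.0, seed=5)
        df = pd.concat([half, half], ignore_index=True)
        xi = np.r_[np.zeros(len(half)), np.ones(len(half))]
        fit = fit_gompertz(df, covariate_cols=["gender"], fix_Gamma=0.085)
        lin = compute_weights(df, fit)
        eff = effect_closed_form(lin, xi)
        assert abs(eff.beta_xi[0]) < 1e-10

    def test_scalar_sigma_matches_information_diagonal(self,
                                                       cohort_and_weights):
        _, xi, _, lin = cohort_and_weights
        eff = effect_closed_form(lin, xi)
        # single-feature formula: sigma^2 = 1 / (N_d * rho-weighted var)
        m = lin.rho @ xi
        var = lin.rho @ (xi - m) ** 2
        assert np.isclose(eff.sigma[0], 1.0 / np.sqrt(lin.N_d * var))


class TestWeightedLoss:
    def test_zero_beta_loss_is_weighted_target_norm(self,
                                                    cohort_and_weights):
        _, xi, _, lin = cohort_and_weights
        L = weighted_regression_loss(np.zeros(1), xi[:, None], lin)
        assert np.isclose(L, np.sum(lin.rho * lin.R ** 2))

    def test_perfect_fit_has_zero_loss(self, cohort_and_weights):
        _, _, _, lin = cohort_and_weights
        beta_star = 0.7
        xi = lin.R / beta_star
        assert weighted_regression_loss([beta_star], xi[:, None], lin) < 1e-20

    def test_minimizer_equals_closed_form(self, cohort_and_weights):
        # independent route: weighted least squares on rho-centred features
        _, _, _, lin = cohort_and_weights
        rng = np.random.default_rng(1)
        xi = rng.standard_normal((len(lin), 3))
        eff = effect_closed_form(lin, xi)
        xc = xi - lin.rho @ xi
        wls = LinearRegression(fit_intercept=False).fit(
            xc, lin.R, sample_weight=lin.rho)
        assert np.allclose(wls.coef_, eff.beta_xi, atol=1e-8)
        # and the loss at the minimizer is no larger than nearby points
        L0 = weighted_regression_loss(eff.beta_xi, xc, lin)
        for bump in np.eye(3) * 1e-3:
            assert L0 <= weighted_regression_loss(eff.beta_xi + bump, xc,
                                                  lin)


class TestTransformTargets:
    def test_mean_zero_unit_sd(self, cohort_and_weights):
        _, _, _, lin = cohort_and_weights
        z = transform_targets(lin.R)
        assert abs(z.mean()) < 1e-12
        assert np.isclose(z.std(), 1.0)

    def test_rank_preserved(self):
        rng = np.random.default_rng(2)
        R = rng.gamma(2.0, size=500)
        z = transform_targets(R)
        assert np.array_equal(np.argsort(R), np.argsort(z))

    def test_near_identity_on_standard_normal(self):
        # deviations concentrate in the extreme order statistics, so the
        # identity holds in the bulk: small RMS and small 95th-percentile
        # absolute deviation
        rng = np.random.default_rng(3)
        R = rng.standard_normal(10_000)
        z = transform_targets(R)
        dev = np.abs(z - (R - R.mean()) / R.std())
        assert np.sqrt(np.mean(dev ** 2)) < 0.05
        assert np.quantile(dev, 0.95) < 0.05

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            transform_targets(np.ones(10))


class TestLinearizedVsFull:
    def test_null_effect_agrees(self):
        df, xi = simulate_feature_cohort(4000, 0.0, seed=404)
        cmp = linearized_vs_full_fit(df, xi, covariate_cols=["gender"])
        s = cmp["sigma_analytic"][0]
        assert abs(cmp["beta_linearized"][0]) < 3 * s
        assert abs(cmp["beta_full"][0]) < 3 * s

    def test_small_effect_first_order_agreement(self):
        ratios = []
        for s in range(20):
            df, xi = simulate_feature_cohort(6000, 0.05, seed=500 + s)
            cmp = linearized_vs_full_fit(df, xi, covariate_cols=["gender"])
            ratios.append(abs(cmp["discrepancy"][0])
                          / cmp["sigma_analytic"][0])
        assert np.median(ratios) < 0.2

    def test_large_effect_leaves_linear_regime(self):
        small_d, large_d = [], []
        for s in range(5):
            df, xi = simulate_feature_cohort(6000, 0.05, seed=600 + s)
            cmp = linearized_vs_full_fit(df, xi, covariate_cols=["gender"])
            small_d.append(abs(cmp["discrepancy"][0])
                           / cmp["sigma_analytic"][0])
            df, xi = simulate_feature_cohort(6000, 1.0, seed=600 + s)
            cmp = linearized_vs_full_fit(df, xi, covariate_cols=["gender"])
            large_d.append(abs(cmp["discrepancy"][0])
                           / cmp["sigma_analytic"][0])
        assert np.median(large_d) > np.median(small_d)
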