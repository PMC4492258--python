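"""Fitting, prediction, cross-validation and trend surrogacy of the
simplified single-trend exposure model."""

import numpy as np
import pytest

from monitorharm import (
    Network,
    PanelMatrix,
    Scale,
    TrendFunction,
    fit_simplified,
    loso_cv,
    predict_long_term,
    trend_surrogacy_check,
)
from monitorharm.model import SimplifiedModelFit
from monitorharm.records import SiteRecord

from conftest import make_sites


def seasonal_trend(grid, period=26.0):
    f = np.sin(2 * np.pi * np.arange(grid.n_periods) / period)
    return TrendFunction.from_values(grid, f)


def model_panel(grid, sites, trend, gamma0, theta=None, gamma1=None,
                resid_sd=0.0, mask=None, seed=0):
    """Panel generated exactly from the simplified model's equation."""
    rng = np.random.default_rng(seed)
    names = sorted(sites[0].covariates)
    X = np.array([[s.covariates[c] for c in names] for s in sites])
    amp = np.full(len(sites), theta) if gamma1 is None else X @ np.asarray(
        gamma1)
    vals = (X @ np.asarray(gamma0))[:, None] + np.outer(amp, trend.values)
    if resid_sd > 0:
        vals = vals + rng.normal(0, resid_sd, vals.shape)
    if mask is None:
        mask = np.ones_like(vals, dtype=bool)
    return PanelMatrix([s.site_id for s in sites], grid,
                       np.where(mask, vals, np.nan), mask, scale=Scale.LOG)


def unbalanced_mask(n_fixed, n_home, n_periods, seed=0):
    """Fixed sites fully observed; home sites observed 1-3 periods."""
    rng = np.random.default_rng(seed)
    mask = np.zeros((n_fixed + n_home, n_periods), dtype=bool)
    mask[:n_fixed] = True
    for i in range(n_fixed, n_fixed + n_home):
        ks = rng.choice(n_periods, size=rng.choice([1, 2, 3],
                                                   p=[0.35, 0.5, 0.15]),
                        replace=False)
        mask[i, ks] = True
    return mask


def test_zero_noise_coefficients_recovered_exactly(grid20):
    sites = make_sites(30, n_cov=2, seed=1)
    trend = seasonal_trend(grid20)
    panel = model_panel(grid20, sites, trend, gamma0=[1.0, -0.5], theta=0.8)
    fit = fit_simplified(panel, sites, trend, amplitude_mode="constant")
    np.testing.assert_allclose(fit.gamma0_hat, [1.0, -0.5], atol=1e-10)
    assert fit.theta_hat == pytest.approx(0.8, abs=1e-10)
    assert fit.sigma2_hat == pytest.approx(0.0, abs=1e-18)
    assert fit.r2 == pytest.approx(1.0)

    panel_c = model_panel(grid20, sites, trend, gamma0=[1.0, -0.5],
                          gamma1=[0.6, 0.2])
    fit_c = fit_simplified(panel_c, sites, trend, amplitude_mode="covariate")
    np.testing.assert_allclose(fit_c.gamma1_hat, [0.6, 0.2], atol=1e-10)


def test_parameter_recovery_on_unbalanced_design(grid20):
    """Estimates are unbiased within Monte-Carlo error on a 7+113 design."""
    trend = seasonal_trend(grid20)
    n_rep = 20
    est = []
    for rep in range(n_rep):
        sites = make_sites(120, n_cov=2, seed=1000 + rep)
        mask = unbalanced_mask(7, 113, 20, seed=rep)
        panel = model_panel(grid20, sites, trend, gamma0=[1.0, 0.5],
                            theta=0.8, resid_sd=0.2, mask=mask, seed=rep)
        fit = fit_simplified(panel, sites, trend)
        est.append([*fit.gamma0_hat, fit.theta_hat])
    est = np.asarray(est)
    truth = np.array([1.0, 0.5, 0.8])
    mc_se = est.std(axis=0, ddof=1) / np.sqrt(n_rep)
    assert np.all(np.abs(est.mean(axis=0) - truth) < 3 * mc_se + 1e-12)


def test_sampling_variance_shrinks_with_sample_size(grid20):
    """Doubling the number of observations roughly halves the variance."""
    trend = seasonal_trend(grid20)
    var = {}
    for n_home in (50, 113):
        thetas = []
        for rep in range(120):
            sites = make_sites(7 + n_home, n_cov=2, seed=5000 + rep)
            mask = unbalanced_mask(7, n_home, 20, seed=rep)
            panel = model_panel(grid20, sites, trend, gamma0=[1.0, 0.5],
                                theta=0.8, resid_sd=0.3, mask=mask,
                                seed=rep)
            thetas.append(
                fit_simplified(panel, sites, trend).gamma0_hat[0])
        var[n_home] = np.var(thetas, ddof=1)
    # observation counts differ by ~ the home-site ratio, not exactly 2x;
    # check the 1/n trend rather than an exact halving
    assert var[113] < 0.75 * var[50]


def test_rank_deficient_design_names_columns(grid20):
    sites = []
    rng = np.random.default_rng(2)
    for i in range(10):
        c0 = float(rng.standard_normal())
        sites.append(SiteRecord(f"s{i:02d}", Network.NPACT_FIXED,
                                float(i), 0.0,
                                covariates={"c0": c0, "c1": 2.0 * c0}))
    trend = seasonal_trend(grid20)
    panel = model_panel(grid20, sites, trend, gamma0=[1.0, 0.0], theta=0.5)
    with pytest.raises(ValueError, match="collinear"):
        fit_simplified(panel, sites, trend)


def test_more_parameters_than_observations_rejected(grid20):
    sites = make_sites(2, n_cov=2, seed=3)
    trend = seasonal_trend(grid20)
    mask = np.zeros((2, 20), dtype=bool)
    mask[0, 0] = mask[1, 1] = True
    panel = model_panel(grid20, sites, trend, gamma0=[1.0, 0.0], theta=0.5,
                        mask=mask)
    with pytest.raises(ValueError, match="observations"):
        fit_simplified(panel, sites, trend)


def test_constant_mode_misfit_raises_residual_variance(grid20):
    """If the true amplitude varies with covariates, the constant-amplitude
    fit leaves more residual variance than the covariate-amplitude fit."""
    sites = make_sites(60, n_cov=2, seed=4)
    trend = seasonal_trend(grid20)
    panel = model_panel(grid20, sites, trend, gamma0=[1.0, -0.5],
                        gamma1=[1.0, 0.8], resid_sd=0.1, seed=4)
    f_const = fit_simplified(panel, sites, trend, amplitude_mode="constant")
    f_cov = fit_simplified(panel, sites, trend, amplitude_mode="covariate")
    assert f_const.sigma2_hat > f_cov.sigma2_hat


def test_prediction_at_training_site_zero_noise(grid20):
    sites = make_sites(20, n_cov=2, seed=5)
    trend = seasonal_trend(grid20)
    panel = model_panel(grid20, sites, trend, gamma0=[0.7, 0.2], theta=0.5)
    fit = fit_simplified(panel, sites, trend)
    pred = predict_long_term(fit, sites[:1])
    assert pred["prediction"].iloc[0] == pytest.approx(
        panel.values[0].mean(), abs=1e-10)
    # degenerate single-period window
    pred_t0 = predict_long_term(fit, sites[:1], averaging_window=(3, 3))
    assert pred_t0["prediction"].iloc[0] == pytest.approx(
        panel.values[0, 3], abs=1e-10)


def test_covariate_name_mismatch_rejected(grid20):
    sites = make_sites(10, n_cov=2, seed=6)
    trend = seasonal_trend(grid20)
    panel = model_panel(grid20, sites, trend, gamma0=[0.7, 0.2], theta=0.5)
    fit = fit_simplified(panel, sites, trend)
    alien = SiteRecord("new", Network.NPACT_HOME, 0.0, 0.0,
                       covariates={"zz": 1.0, "c0": 0.0})
    with pytest.raises(ValueError, match="covariates"):
        predict_long_term(fit, [alien])


def test_plugin_se_calibrated_against_simulation(grid20):
    """Prediction RMSE at held-out sites matches the plug-in SE."""
    trend = seasonal_trend(grid20)
    errs, ses = [], []
    for rep in range(60):
        sites = make_sites(90, n_cov=2, seed=7000 + rep)
        train, held = sites[:40], sites[40:]
        panel = model_panel(grid20, train, trend, gamma0=[1.0, 0.5],
                            theta=0.8, resid_sd=0.25, seed=rep)
        fit = fit_simplified(panel, train, trend)
        pred = predict_long_term(fit, held)
        X = np.array([[s.covariates["c0"], s.covariates["c1"]]
                      for s in held])
        true_mean = X @ np.array([1.0, 0.5]) + 0.8 * trend.values.mean()
        errs.extend(pred["prediction"].to_numpy() - true_mean)
        ses.extend(pred["se"].to_numpy())
    rmse = float(np.sqrt(np.mean(np.square(errs))))
    analytic = float(np.sqrt(np.mean(np.square(ses))))
    assert rmse == pytest.approx(analytic, rel=0.2)


def test_loso_cv_perfect_model(grid20):
    sites = make_sites(25, n_cov=2, seed=8)
    trend = seasonal_trend(grid20)
    panel = model_panel(grid20, sites, trend, gamma0=[1.0, -0.3], theta=0.6)
    res = loso_cv(panel, sites, trend)
    assert res.cv_r2 == pytest.approx(1.0, abs=1e-6)
    assert res.failed_sites == []
    assert len(res.per_site) == 25


def test_loso_cv_strong_signal_and_null(grid20):
    trend = seasonal_trend(grid20)
    sites = make_sites(60, n_cov=2, seed=9)
    mask = unbalanced_mask(10, 50, 20, seed=9)
    strong = model_panel(grid20, sites, trend, gamma0=[1.0, 0.5],
                         theta=0.8, resid_sd=0.2, mask=mask, seed=9)
    assert loso_cv(strong, sites, trend).cv_r2 >= 0.8
    # covariates carry no information about the nearly-flat truth
    null = model_panel(grid20, sites, trend, gamma0=[0.0, 0.0], theta=0.1,
                       resid_sd=0.2, mask=mask, seed=10)
    assert loso_cv(null, sites, trend).cv_r2 <= 0.1


def test_loso_needs_five_sites(grid20):
    sites = make_sites(4, n_cov=2, seed=11)
    trend = seasonal_trend(grid20)
    panel = model_panel(grid20, sites, trend, gamma0=[1.0, 0.0], theta=0.5)
    with pytest.raises(ValueError, match=">= 5 sites"):
        loso_cv(panel, sites, trend)


def test_fit_serialization_round_trip(grid20, tmp_path):
    sites = make_sites(30, n_cov=2, seed=12)
    trend = seasonal_trend(grid20)
    panel = model_panel(grid20, sites, trend, gamma0=[1.0, -0.5],
                        theta=0.8, resid_sd=0.1, seed=12)
    fit = fit_simplified(panel, sites, trend)
    path = tmp_path / "fit.json"
    fit.to_json(path)
    back = SimplifiedModelFit.from_json(path)
    p1 = predict_long_term(fit, sites[:5])
    p2 = predict_long_term(back, sites[:5])
    np.testing.assert_array_equal(p1["prediction"], p2["prediction"])
    np.testing.assert_array_equal(p1["se"], p2["se"])


def test_trend_surrogacy_verdicts(grid100):
    f = np.sin(2 * np.pi * np.arange(100) / 26.0)
    shared = TrendFunction.from_values(grid100, f)
    assert trend_surrogacy_check(shared, shared).adequate
    # 90-degree phase shift: nearly orthogonal seasonal cycles
    shifted = TrendFunction.from_values(
        grid100, np.sin(2 * np.pi * np.arange(100) / 26.0 + np.pi / 2))
    check = trend_surrogacy_check(shared, shifted)
    assert abs(check.pearson_r) < 0.3
    assert not check.adequate
    # a noisy copy of the same seasonal cycle stays adequate
    rng = np.random.default_rng(13)
    noisy = TrendFunction.from_values(
        grid100, f + rng.normal(0, 0.05 * f.std(), 100))
    assert trend_surrogacy_check(shared, noisy).adequate
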