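"""Conditional-expectation scores, reconstruction and confidence bands."""

import numpy as np
import pytest
from scipy.optimize import brentq

from gwtraj import SubjectRecord, generate_cohort, make_kl_truth
from gwtraj.fpca import CovarianceModel, EigenSystem, FPCAModel
from gwtraj.scores import (
    confidence_bands,
    model_from_truth,
    predict_scores,
    reconstruct_trajectory,
)
from gwtraj.smoothing import Smoother1DResult
from gwtraj.synthetic import gram_schmidt

GRID = np.linspace(0.0, 42.0, 201)


def _single_component_model(lam=2.0, sigma2=1.0, mean_value=60.0):
    """Hand-built K=1 model with a bump eigenfunction peaking above 0.5."""
    f = np.exp(-0.5 * ((GRID - 20.0) / 2.0) ** 2)
    phi = gram_schmidt(f[None, :], GRID)
    surface = lam * np.outer(phi[0], phi[0])
    mean = Smoother1DResult(grid=GRID, values=np.full_like(GRID, mean_value), bandwidth=1.0)
    cov = CovarianceModel(grid=GRID, surface=surface, diag_smooth=np.diag(surface).copy(),
                          v_hat=np.diag(surface) + sigma2, sigma2=sigma2)
    eig = EigenSystem(eigenvalues=np.array([lam]), eigenfunctions=phi,
                      fve=np.array([1.0]), grid=GRID)
    return FPCAModel(mean=mean, covariance=cov, eigen=eig, K=1)


def test_zero_residual_gives_zero_scores_and_mean_trajectory(kl_truth):
    model = model_from_truth(kl_truth)
    t = np.array([0.0, 10.0, 25.0, 39.0])
    subj = SubjectRecord("z", t, model.mean(t), ("W0", "WA", "WB", "WH"),
                         ga_birth=39.0, bmi_p=23.0)
    sc = predict_scores(subj, model)
    np.testing.assert_allclose(sc.scores, 0.0, atol=1e-10)
    tr = reconstruct_trajectory(sc, model)
    np.testing.assert_allclose(tr.values, model.mean(tr.grid), atol=1e-10)


def test_single_observation_scalar_formula():
    """K=1, one observation with residual r: score = lam*phi*r / (lam*phi^2
    + sigma^2); with lam=2, phi=0.5, sigma^2=1, r=3 the score is exactly 2."""
    model = _single_component_model(lam=2.0, sigma2=1.0)
    phi_interp = lambda x: np.interp(x, GRID, model.eigen.eigenfunctions[0])
    t_star = brentq(lambda x: phi_interp(x) - 0.5, 10.0, 20.0)
    subj = SubjectRecord("one", [t_star], [60.0 + 3.0], ("WB",),
                         ga_birth=40.0, bmi_p=23.0)
    sc = predict_scores(subj, model)
    assert abs(sc.scores[0] - 2.0) < 1e-6


def test_reconstruction_is_linear_in_score():
    model = _single_component_model()
    subj = SubjectRecord("lin", [20.0], [65.0], ("WB",), ga_birth=40.0, bmi_p=23.0)
    sc = predict_scores(subj, model)
    tr = reconstruct_trajectory(sc, model)
    np.testing.assert_allclose(
        tr.values - model.mean(tr.grid),
        sc.scores[0] * model.eigen.eigenfunctions[0],
        atol=1e-10,
    )


def test_monte_carlo_conditional_expectation_oracle():
    """Predicted scores match the conditional mean estimated from simulated
    joint draws via empirical moments, within 3 MC standard errors."""
    truth = make_kl_truth(eigenvalues=(20.0, 5.0), noise_sd=1.0)
    model = model_from_truth(truth)
    times = np.array([0.0, 20.0, 35.0])
    mu = truth.mean_at(times)
    y0 = mu + np.array([2.0, -1.0, 1.5])
    subj = SubjectRecord("mc", times, y0, ("W0", "WB", "WC"), ga_birth=40.0, bmi_p=23.0)
    sc = predict_scores(subj, model)
    phi = truth.phi_at(times)
    rng = np.random.default_rng(123)
    blocks = []
    for _ in range(10):
        n = 100_000
        xi = rng.normal(0, 1, size=(n, 2)) * np.sqrt(truth.eigenvalues)
        Y = mu + xi @ phi + rng.normal(0, 1.0, size=(n, 3))
        Ym = Y.mean(0)
        Cxy = (xi - xi.mean(0)).T @ (Y - Ym) / (n - 1)
        Cyy = np.cov(Y.T)
        blocks.append(Cxy @ np.linalg.solve(Cyy, y0 - Ym) + xi.mean(0))
    blocks = np.array(blocks)
    mc = blocks.mean(0)
    se = blocks.std(0, ddof=1) / np.sqrt(10)
    assert np.all(np.abs(sc.scores - mc) <= 3 * se)


def test_k1_simultaneous_equals_pointwise():
    """chi2 with one degree of freedom is the squared normal quantile."""
    model = _single_component_model()
    subj = SubjectRecord("b", [20.0], [63.0], ("WB",), ga_birth=40.0, bmi_p=23.0)
    sc = predict_scores(subj, model)
    lo_p, hi_p = confidence_bands(sc, model, simultaneous=False)
    lo_s, hi_s = confidence_bands(sc, model, simultaneous=True)
    np.testing.assert_allclose(hi_p, hi_s, rtol=1e-10)


def test_zero_omega_gives_zero_width_bands(kl_truth):
    model = model_from_truth(kl_truth)
    t = np.linspace(0.0, 42.0, 60)
    subj = SubjectRecord("dense", t, model.mean(t), ("W0",) + ("WB",) * 59,
                         ga_birth=42.0, bmi_p=23.0)
    model.covariance.sigma2 = 1e-10
    sc = predict_scores(subj, model)
    lo, hi = confidence_bands(sc, model, simultaneous=True)
    assert np.max(hi) < 0.05


def test_simultaneous_band_contains_pointwise(kl_truth, full_design):
    model = model_from_truth(kl_truth)
    c = generate_cohort(kl_truth, full_design, 20, seed=21)
    for s in c:
        tr = reconstruct_trajectory(predict_scores(s, model), model)
        assert np.all(tr.simultaneous_hi >= tr.pointwise_hi - 1e-12)
        assert np.all(tr.simultaneous_lo <= tr.pointwise_lo + 1e-12)


def test_dense_noiseless_reconstruction_error(full_design):
    """Noiseless densely observed subjects are reconstructed to well under
    0.5 kg RMSE under the true-model plug-in."""
    truth = make_kl_truth(noise_sd=0.0)
    model = model_from_truth(truth)
    model.covariance.sigma2 = 1e-8
    c = generate_cohort(truth, full_design, 100, seed=31)
    grid = np.linspace(0, 42, 51)
    errs = []
    for i, s in enumerate(c):
        dense = SubjectRecord(s.subject_id, grid, np.maximum(c.true_curve(i, grid), 1.0),
                              ("W0",) + ("WB",) * 49 + ("WH",),
                              ga_birth=42.0, bmi_p=s.bmi_p)
        tr = reconstruct_trajectory(predict_scores(dense, model), model, grid)
        errs.append(np.sqrt(np.mean((tr.values - c.true_curve(i, grid)) ** 2)))
    assert np.mean(errs) <= 0.5


def test_shrinkage_pulls_gain_toward_mean(full_design):
    """Regression slope of reconstructed gain on true gain lies strictly in
    (0, 1): large gains are pulled down, small gains up."""
    truth = make_kl_truth()
    model = model_from_truth(truth)
    c = generate_cohort(truth, full_design, 400, seed=41)
    rec, true = [], []
    for i, s in enumerate(c):
        tr = reconstruct_trajectory(predict_scores(s, model), model)
        rec.append(tr(s.ga_birth) - tr(0.0))
        x = c.true_curve(i, np.array([0.0, s.ga_birth]))
        true.append(x[1] - x[0])
    slope = np.polyfit(true, rec, 1)[0]
    assert 0.0 < slope < 1.0


def test_more_observations_never_increase_score_uncertainty():
    """trace(Omega_K) is non-increasing along nested observation designs."""
    truth = make_kl_truth()
    model = model_from_truth(truth)
    times = [0.0, 9.0, 18.0, 27.0, 36.0]
    prev = np.inf
    for n_obs in range(1, 6):
        t = np.array(times[:n_obs])
        subj = SubjectRecord("n", t, model.mean(t) + 1.0,
                             tuple(["W0"] + ["WB"] * (n_obs - 1)),
                             ga_birth=40.0, bmi_p=23.0)
        tr = float(np.trace(predict_scores(subj, model).Omega_K))
        assert tr <= prev + 1e-10
        prev = tr


def test_predicted_score_variance_contracts(full_design):
    """var(xi_hat) <= lambda componentwise (conditional expectations are
    shrunken towards zero)."""
    truth = make_kl_truth()
    model = model_from_truth(truth)
    c = generate_cohort(truth, full_design, 1500, seed=51)
    S = np.array([predict_scores(s, model).scores for s in c])
    assert np.all(S.var(axis=0) <= truth.eigenvalues * 1.05)


def test_alpha_validation(kl_truth):
    model = model_from_truth(kl_truth)
    subj = SubjectRecord("a", [20.0], [63.0], ("WB",), ga_birth=40.0, bmi_p=23.0)
    sc = predict_scores(subj, model)
    with pytest.raises(ValueError):
        confidence_bands(sc, model, alpha=1.5)
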