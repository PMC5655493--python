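"""Covariance estimation and eigendecomposition against exact oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gwtraj import (
    SubjectRecord,
    Cohort,
    generate_cohort,
    make_kl_truth,
)
from gwtraj.fpca import (
    CovarianceModel,
    compute_raw_covariances,
    eigendecompose,
    estimate_covariance_model,
    estimate_sigma2,
    fit_fpca,
    select_K_fve,
)
from gwtraj.smoothing import Smoother1DResult
from gwtraj.synthetic import gram_schmidt, trapezoid_weights

GRID = np.linspace(0.0, 42.0, 51)


def _flat_mean(value=0.0):
    return Smoother1DResult(grid=GRID, values=np.full_like(GRID, value), bandwidth=1.0)


def _subject(times, weights):
    labels = ["W0" if t == 0.0 else "WB" for t in times]
    return SubjectRecord("s0", times, weights, tuple(labels), ga_birth=40.0, bmi_p=23.0)


class TestRawCovariances:
    def test_observations_on_mean_give_zero(self):
        mean = _flat_mean(60.0)
        c = Cohort(subjects=[_subject([0.0, 10.0, 20.0], [60.0, 60.0, 60.0])])
        raw = compute_raw_covariances(c, mean)
        assert np.allclose(raw.triples[:, 2], 0.0)
        assert np.allclose(raw.diagonal_inputs[:, 1], 0.0)

    def test_counts_for_three_observations(self):
        c = Cohort(subjects=[_subject([0.0, 10.0, 20.0], [61.0, 59.0, 63.0])])
        raw = compute_raw_covariances(c, _flat_mean(60.0))
        assert raw.triples.shape[0] == 6          # N_i (N_i - 1) ordered pairs
        assert raw.diagonal_inputs.shape[0] == 3

    def test_product_of_residuals(self):
        c = Cohort(subjects=[_subject([5.0, 15.0], [62.0, 59.0])])  # residuals +2, -1
        raw = compute_raw_covariances(c, _flat_mean(60.0))
        assert raw.triples.shape[0] == 2
        assert np.allclose(sorted(raw.triples[:, 2]), [-2.0, -2.0])
        pairs = {tuple(r[:2]) for r in raw.triples}
        assert pairs == {(5.0, 15.0), (15.0, 5.0)}

    def test_single_observation_subject_allowed(self):
        c = Cohort(subjects=[_subject([7.0], [61.0])])
        raw = compute_raw_covariances(c, _flat_mean(60.0))
        assert raw.triples.shape[0] == 0
        assert raw.diagonal_inputs.shape[0] == 1


class TestSigma2:
    def test_equal_inputs_give_zero(self):
        v = np.full_like(GRID, 3.0)
        assert estimate_sigma2(v, v, GRID) == 0.0

    @pytest.mark.parametrize("c", [0.5, 2.5])
    def test_constant_offset_recovered(self, c):
        g = np.sin(GRID / 6.0) + 2.0
        assert abs(estimate_sigma2(g + c, g, GRID) - c) < 1e-12

    def test_negative_average_clamps_to_zero(self):
        g = np.full_like(GRID, 2.0)
        with pytest.warns(UserWarning):
            assert estimate_sigma2(g - 1.0, g, GRID) == 0.0


class TestEigendecompose:
    def test_rank_one_surface(self):
        phi = gram_schmidt(np.sin(GRID / 7.0)[None, :], GRID)[0]
        cov = CovarianceModel(
            grid=GRID, surface=4.0 * np.outer(phi, phi),
            diag_smooth=4.0 * phi**2, v_hat=4.0 * phi**2, sigma2=0.0,
        )
        es = eigendecompose(cov)
        assert abs(es.eigenvalues[0] - 4.0) < 1e-8
        assert np.all(es.eigenvalues[1:] <= 1e-8)
        err = min(np.max(np.abs(es.eigenfunctions[0] - s * phi)) for s in (1, -1))
        assert err < 1e-8

    def test_brownian_motion_mercer_expansion(self):
        """min(s,t) on [0,1]: eigenvalues 4/((2k-1)^2 pi^2), eigenfunctions
        sqrt(2) sin((k - 1/2) pi t)."""
        grid = np.linspace(0, 1, 201)
        S = np.minimum.outer(grid, grid)
        cov = CovarianceModel(grid=grid, surface=S, diag_smooth=np.diag(S).copy(),
                              v_hat=np.diag(S).copy(), sigma2=0.0)
        es = eigendecompose(cov)
        for k in (1, 2, 3):
            exact = 4.0 / ((2 * k - 1) ** 2 * np.pi**2)
            assert abs(es.eigenvalues[k - 1] - exact) / exact < 0.01
            target = np.sqrt(2) * np.sin((k - 0.5) * np.pi * grid)
            l2 = min(
                np.sqrt(np.trapezoid((es.eigenfunctions[k - 1] - s * target) ** 2, grid))
                for s in (1, -1)
            )
            assert l2 < 0.02

    def test_orthonormality_contract(self, small_cohort):
        model = fit_fpca(small_cohort)
        w = trapezoid_weights(model.grid)
        gram = (model.eigen.eigenfunctions * w) @ model.eigen.eigenfunctions.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-8)

    def test_asymmetric_surface_rejected(self):
        S = np.outer(GRID, GRID + 1.0)
        cov = CovarianceModel.__new__(CovarianceModel)
        cov.grid, cov.surface, cov.sigma2 = GRID, S, 0.0
        with pytest.raises(ValueError):
            eigendecompose(cov)

    def test_dense_data_matches_matrix_pca(self):
        """Noiseless fully observed cohort: bypassing smoothing, the
        quadrature eigenproblem agrees with direct matrix PCA to 1e-8."""
        truth = make_kl_truth(noise_sd=0.0)
        rng = np.random.default_rng(0)
        xi = rng.normal(0, 1, size=(400, 3)) * np.sqrt(truth.eigenvalues)
        X = truth.mean_at(GRID) + xi @ truth.phi_at(GRID)
        S = np.cov(X.T)
        cov = CovarianceModel(grid=GRID, surface=S, diag_smooth=np.diag(S).copy(),
                              v_hat=np.diag(S).copy(), sigma2=0.0)
        es = eigendecompose(cov)
        w = trapezoid_weights(GRID)
        sw = np.sqrt(w)
        ref = np.sort(np.linalg.eigvalsh(sw[:, None] * S * sw[None, :]))[::-1]
        np.testing.assert_allclose(es.eigenvalues, ref[: len(es.eigenvalues)], atol=1e-8)


class TestSelectK:
    def test_printed_variance_fractions(self):
        assert select_K_fve([0.957, 0.028, 0.011, 0.004], 0.99) == 3

    def test_single_eigenvalue(self):
        assert select_K_fve([7.3], 0.999) == 1

    def test_equal_eigenvalues(self):
        assert select_K_fve([1.0, 1.0, 1.0, 1.0], 0.99) == 4

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            select_K_fve([0.0, 0.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        lam=st.lists(st.floats(0.01, 100.0), min_size=1, max_size=8),
        thr=st.floats(0.05, 1.0),
    )
    def test_k_is_minimal_cover(self, lam, thr):
        lam = sorted(lam, reverse=True)
        k = select_K_fve(lam, thr)
        fve = np.cumsum(lam) / np.sum(lam)
        assert fve[k - 1] >= thr - 1e-9
        if k > 1:
            assert fve[k - 2] < thr


class TestCovarianceModelEstimation:
    def test_too_few_triples_rejected(self):
        raw_cohort = Cohort(subjects=[_subject([0.0, 10.0], [61.0, 59.0])])
        raw = compute_raw_covariances(raw_cohort, _flat_mean(60.0))
        with pytest.raises(ValueError, match="larger cohort"):
            estimate_covariance_model(raw, GRID)

    def test_rank_one_surface_recovered(self, full_design):
        """Noiseless single-component data: smoothed surface within 10%
        relative error of lambda phi(s) phi(t) on interior nodes."""
        truth = make_kl_truth(eigenvalues=(40.0,), noise_sd=0.0)
        c = generate_cohort(truth, full_design, 2000, seed=8)
        model = fit_fpca(c)
        phi = truth.phi_at(model.grid)[0]
        target = 40.0 * np.outer(phi, phi)
        inner = (model.grid >= 8) & (model.grid <= 36)
        rel = np.abs(model.covariance.surface - target)[np.ix_(inner, inner)] / np.abs(
            target[np.ix_(inner, inner)]
        )
        assert np.median(rel) < 0.10

    def test_total_variance_bound(self, small_cohort):
        """Sum of eigenvalues cannot exceed the integrated V-hat (total
        variance including noise), within tolerance."""
        model = fit_fpca(small_cohort)
        total = np.trapezoid(model.covariance.v_hat, model.grid)
        assert model.eigen.eigenvalues.sum() <= 1.1 * total
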