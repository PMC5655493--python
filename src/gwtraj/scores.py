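"""Conditional-expectation FPC scores, trajectory reconstruction and bands.

With few, noisy, irregular observations per subject, numerical integration
of score integrals is hopeless; instead, under joint Gaussianity of scores
and errors the best predictor of subject i's k-th score given her
observation vector Y_i is the conditional expectation

    xi_ik = lambda_k phi_ik' Sigma_Yi^{-1} (Y_i - mu_i),

where Sigma_Yi has entries G(T_ij, T_il) + sigma^2 delta_jl.  The
reconstruction X_iK(t) = mu(t) + sum_k xi_ik phi_k(t) then borrows the mean
and eigensystem from the whole cohort while the scores are driven by the
subject's own data.  The score-prediction error has covariance

    Omega_K = Lambda - H Sigma_Yi^{-1} H',   H = (lambda_1 phi_i1, ...)',

giving pointwise normal bands with multiplier Phi^{-1}(1 - alpha/2) and
simultaneous (whole-curve) bands with multiplier sqrt(chi^2_{K, 1-alpha}).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg, stats

from .fpca import FPCAModel, CovarianceModel, EigenSystem
from .smoothing import Smoother1DResult
from .synthetic import SubjectRecord, TrueModel, gram_schmidt

__all__ = [
    "SubjectScores",
    "TrajectoryEstimate",
    "predict_scores",
    "reconstruct_trajectory",
    "confidence_bands",
    "model_from_truth",
]


@dataclass
class SubjectScores:
    subject_id: str
    scores: np.ndarray         # (K,)
    Sigma_Yi: np.ndarray       # (N_i, N_i)
    H: np.ndarray              # (K, N_i)
    Omega_K: np.ndarray        # (K, K) score-error covariance
    times: np.ndarray


@dataclass
class TrajectoryEstimate:
    subject_id: str
    grid: np.ndarray
    values: np.ndarray
    pointwise_lo: np.ndarray
    pointwise_hi: np.ndarray
    simultaneous_lo: np.ndarray
    simultaneous_hi: np.ndarray
    alpha: float

    def __call__(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.grid, self.values)


def model_from_truth(truth: TrueModel, grid: Optional[np.ndarray] = None) -> FPCAModel:
    """Plug-in model built from known generative quantities.

    Bypasses all estimation: the mean, eigensystem, covariance surface
    (sum_k lambda_k phi_k(s) phi_k(t)) and noise variance come straight from
    the truth.  Used for oracle checks of the score/band machinery.
    """
    if grid is None:
        grid = truth.grid
    grid = np.asarray(grid, dtype=float)
    mean = Smoother1DResult(grid=grid, values=truth.mean_at(grid), bandwidth=np.nan)
    # re-orthonormalise on the working grid: quadrature orthonormality on the
    # truth's dense grid does not survive interpolation exactly
    phi = gram_schmidt(truth.phi_at(grid), grid)
    lam = truth.eigenvalues
    surface = (phi.T * lam) @ phi
    diag = np.diag(surface).copy()
    cov = CovarianceModel(
        grid=grid, surface=surface, diag_smooth=diag,
        v_hat=diag + truth.noise_sd**2, sigma2=float(truth.noise_sd**2),
    )
    fve = np.cumsum(lam) / np.sum(lam)
    fve[-1] = 1.0
    eigen = EigenSystem(eigenvalues=lam.copy(), eigenfunctions=phi, fve=fve, grid=grid)
    return FPCAModel(mean=mean, covariance=cov, eigen=eigen, K=len(lam), fve_threshold=0.99)


def _solve_spd(S: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve S X = B for symmetric positive definite S with a ridge-jitter
    ladder: 1e-8 * mean(diag), escalating tenfold up to 1e-4."""
    base = float(np.mean(np.diag(S)))
    try:
        cf = linalg.cho_factor(S, lower=True)
        return linalg.cho_solve(cf, B)
    except linalg.LinAlgError:
        pass
    jitter = 1e-8
    while jitter <= 1e-4 + 1e-15:
        try:
            cf = linalg.cho_factor(S + jitter * base * np.eye(len(S)), lower=True)
            warnings.warn(f"Sigma_Yi required ridge jitter {jitter:g}", stacklevel=3)
            return linalg.cho_solve(cf, B)
        except linalg.LinAlgError:
            jitter *= 10.0
    # estimated covariance surfaces can be indefinite beyond any small ridge;
    # project onto the nearest positive definite matrix by eigenvalue clipping
    if not np.all(np.isfinite(S)):
        raise np.linalg.LinAlgError("Sigma_Yi contains non-finite entries")
    evals, evecs = np.linalg.eigh(S)
    floor = max(1e-6 * base, 1e-10)
    warnings.warn(
        f"Sigma_Yi indefinite (min eigenvalue {evals.min():.3g}); "
        "clipped to nearest positive definite matrix", stacklevel=3,
    )
    evals = np.maximum(evals, floor)
    return evecs @ ((evecs.T @ B) / evals[:, None])


def predict_scores(subject: SubjectRecord, model: FPCAModel, K: Optional[int] = None) -> SubjectScores:
    """Conditional-expectation scores of one subject under a fitted model.

    Mean and eigenfunctions are linearly interpolated to the observation
    times; the observation covariance is assembled from the positive-part
    eigenexpansion of the smoothed surface plus sigma^2 on the diagonal.
    """
    K = model.K if K is None else K
    t = subject.times
    y = subject.weights
    mu_i = model.mean(t)
    phi_i = model.phi_at(t, K=K)                      # (K, N)
    lam = model.eigen.eigenvalues[:K]
    # Sigma_Yi from the positive-part eigenexpansion of the smoothed surface:
    # the raw smoothed G can be indefinite, and an indefinite Sigma_Yi turns
    # the conditional-expectation weights into noise amplifiers
    lam_all = model.eigen.eigenvalues
    phi_all = model.phi_at(t, K=len(lam_all))
    Sigma = (phi_all.T * lam_all) @ phi_all + model.covariance.sigma2 * np.eye(t.size)
    Sigma = 0.5 * (Sigma + Sigma.T)
    H = lam[:, None] * phi_i                          # (K, N)
    resid = y - mu_i
    SinvH_r = _solve_spd(Sigma, np.column_stack([H.T, resid]))
    Sinv_Ht = SinvH_r[:, :K]                          # Sigma^{-1} H'
    Sinv_r = SinvH_r[:, K]
    scores = H @ Sinv_r
    Omega = np.diag(lam) - H @ Sinv_Ht
    Omega = 0.5 * (Omega + Omega.T)
    return SubjectScores(
        subject_id=subject.subject_id, scores=scores, Sigma_Yi=Sigma,
        H=H, Omega_K=Omega, times=t.copy(),
    )


def confidence_bands(
    scores: SubjectScores,
    model: FPCAModel,
    grid: Optional[np.ndarray] = None,
    alpha: float = 0.05,
    simultaneous: bool = False,
) -> tuple:
    """Half-band pair (lo_offset, hi_offset) around the reconstruction.

    The variance at t is phi_{K,t}' Omega_K phi_{K,t}; indefinite Omega
    estimates can push it slightly negative, in which case it is clamped at
    zero with a warning.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if grid is None:
        grid = model.grid
    K = scores.scores.size
    phi_t = model.phi_at(grid, K=K)                   # (K, m)
    var = np.einsum("km,kl,lm->m", phi_t, scores.Omega_K, phi_t)
    if np.any(var < -1e-10 * max(1.0, float(np.max(np.abs(var))))):
        warnings.warn("negative band variance clamped to 0", stacklevel=2)
    var = np.maximum(var, 0.0)
    if simultaneous:
        q = float(np.sqrt(stats.chi2.ppf(1.0 - alpha, df=K)))
    else:
        q = float(stats.norm.ppf(1.0 - alpha / 2.0))
    half = q * np.sqrt(var)
    return -half, half


def reconstruct_trajectory(
    scores: SubjectScores,
    model: FPCAModel,
    grid: Optional[np.ndarray] = None,
    alpha: float = 0.05,
) -> TrajectoryEstimate:
    """Karhunen-Loeve reconstruction with pointwise and simultaneous bands."""
    if grid is None:
        grid = model.grid
    grid = np.asarray(grid, dtype=float)
    K = scores.scores.size
    values = model.mean(grid) + scores.scores @ model.phi_at(grid, K=K)
    pw_lo, pw_hi = confidence_bands(scores, model, grid, alpha, simultaneous=False)
    sm_lo, sm_hi = confidence_bands(scores, model, grid, alpha, simultaneous=True)
    return TrajectoryEstimate(
        subject_id=scores.subject_id, grid=grid, values=values,
        pointwise_lo=values + pw_lo, pointwise_hi=values + pw_hi,
        simultaneous_lo=values + sm_lo, simultaneous_hi=values + sm_hi,
        alpha=alpha,
    )
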