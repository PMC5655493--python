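"""Logistic-growth mixed-effects comparator and the model-fit comparison.

The parametric benchmark for the trajectory reconstruction is

    W_i(t) = L_i / (1 + exp(-k (t - t0))) + c_i + e_ij,

with subject-specific magnitude L_i and baseline c_i treated as correlated
Gaussian random effects, a common steepness k estimated as a fixed effect,
and the inflection t0 pinned at 30 weeks (the observed inflection of the
mean gestational weight curve).  For fixed k the model is *linear* in
(L_i, c_i), so the marginal likelihood is an exact linear-mixed-model
likelihood: we profile the population means (mu_L, mu_c) by generalised
least squares and maximise over k, the random-effect Cholesky factor and
the residual variance.  Per-subject effects are empirical-Bayes posterior
modes.  Model fit is summarised by the mean squared error of fitted versus
observed weights pooled over all visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy import linalg, optimize
from scipy.special import expit

from .synthetic import Cohort

__all__ = [
    "LogisticNLMEFit",
    "FitComparison",
    "logistic_mean",
    "fit_nlme",
    "compare_models",
    "pct_reduction",
]


def logistic_mean(t, L, k, t0, c):
    """Logistic growth curve L / (1 + exp(-k (t - t0))) + c, overflow-safe."""
    return L * expit(k * (np.asarray(t, dtype=float) - t0)) + c


@dataclass
class LogisticNLMEFit:
    k: float
    t0: float
    mu_L: float
    mu_c: float
    var_L: float
    var_c: float
    cov_Lc: float
    sigma2_resid: float
    subject_effects: dict = field(default_factory=dict)   # id -> (L_i, c_i)
    loglik: float = np.nan
    n_subjects: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("steepness k must be positive")
        D = np.array([[self.var_L, self.cov_Lc], [self.cov_Lc, self.var_c]])
        if np.min(np.linalg.eigvalsh(D)) < -1e-8 * max(1.0, np.max(np.abs(D))):
            raise ValueError("random-effect covariance must be positive semidefinite")

    def fitted(self, subject_id: str, t) -> np.ndarray:
        L_i, c_i = self.subject_effects[subject_id]
        return logistic_mean(t, L_i, self.k, self.t0, c_i)


def _unpack(theta: np.ndarray):
    # log-Cholesky with the off-diagonal scaled by the second diagonal:
    # chol = [[e^a, 0], [r e^c, e^c]].  When the variance floors pull a and c
    # down, every entry of D collapses with them, so degenerate (zero
    # variance) fits are reachable without a flat log-singular direction in r.
    k = np.exp(theta[0])
    ea, r, ec = np.exp(theta[1]), theta[2], np.exp(theta[3])
    chol = np.array([[ea, 0.0], [r * ec, ec]])
    D = chol @ chol.T
    s2 = np.exp(2.0 * theta[4])
    return k, D, s2


def _neg2_profile_loglik(theta, times, ys, t0):
    """-2 profile log-likelihood over (k, chol D, log sigma); (mu_L, mu_c)
    are concentrated out by GLS."""
    k, D, s2 = _unpack(theta)
    XtVX = np.zeros((2, 2))
    XtVy = np.zeros(2)
    parts = []
    ld = 0.0
    for t, y in zip(times, ys):
        Z = np.column_stack([expit(k * (t - t0)), np.ones_like(t)])
        V = Z @ D @ Z.T + s2 * np.eye(t.size)
        try:
            cf = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            return 1e12
        ld += 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        ViZ = linalg.cho_solve(cf, Z)
        Viy = linalg.cho_solve(cf, y)
        XtVX += Z.T @ ViZ
        XtVy += Z.T @ Viy
        parts.append((Z, y, cf))
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return 1e12
    quad = 0.0
    for Z, y, cf in parts:
        r = y - Z @ beta
        quad += float(r @ linalg.cho_solve(cf, r))
    val = ld + quad
    return val if np.isfinite(val) else 1e12


def fit_nlme(cohort: Cohort, t0: float = 30.0, max_iter: int = 500, tol: float = 1e-12) -> LogisticNLMEFit:
    """Exact marginal maximum likelihood for the logistic growth model.

    Requires at least 20 subjects with two or more observations.  The fit is
    deterministic for identical data and starting values (k0 = 0.15/week,
    baseline from the earliest weights, magnitude from the mean gain).
    """
    usable = [s for s in cohort if s.n_obs >= 2]
    if len(usable) < 20:
        raise ValueError("need >= 20 subjects with >= 2 observations")
    times = [s.times for s in usable]
    ys = [s.weights for s in usable]

    L0 = max(float(np.mean([y[-1] - y[0] for y in ys])), 1.0)
    sdL0 = max(0.3 * L0, 1.0)
    sdc0 = max(float(np.std([y[0] for y in ys])), 1.0)
    theta0 = np.array([np.log(0.15), np.log(sdL0), 0.0, np.log(sdc0), np.log(1.0)])

    # variance floors keep V well conditioned so the objective stays smooth
    bounds = [
        (np.log(0.01), np.log(2.0)),
        (np.log(1e-4), np.log(1e3)),
        (-50.0, 50.0),
        (np.log(1e-4), np.log(1e3)),
        (np.log(1e-4), np.log(1e3)),
    ]
    res = optimize.minimize(
        _neg2_profile_loglik, theta0, args=(times, ys, t0),
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
    )
    # accept maxiter (status 1) and line-search stalls at a variance floor,
    # provided the objective actually improved; anything else is an error
    improved = np.isfinite(res.fun) and res.fun < _neg2_profile_loglik(theta0, times, ys, t0)
    if not res.success and res.status != 1 and not improved:
        raise RuntimeError(
            f"NLME did not converge: {res.message}; last iterate {res.x}, "
            f"|grad| = {np.max(np.abs(res.jac)):.3g}"
        )
    best = res
    k, D, s2 = _unpack(best.x)

    # GLS means and empirical-Bayes subject effects at the optimum
    XtVX = np.zeros((2, 2))
    XtVy = np.zeros(2)
    cache = []
    for t, y in zip(times, ys):
        Z = np.column_stack([expit(k * (t - t0)), np.ones_like(t)])
        V = Z @ D @ Z.T + s2 * np.eye(t.size)
        cf = linalg.cho_factor(V, lower=True)
        XtVX += Z.T @ linalg.cho_solve(cf, Z)
        XtVy += Z.T @ linalg.cho_solve(cf, y)
        cache.append((Z, cf))
    beta = np.linalg.solve(XtVX, XtVy)
    effects = {}
    for subj, t, y, (Z, cf) in zip(usable, times, ys, cache):
        b = D @ Z.T @ linalg.cho_solve(cf, y - Z @ beta)
        effects[subj.subject_id] = (float(beta[0] + b[0]), float(beta[1] + b[1]))
    return LogisticNLMEFit(
        k=float(k), t0=float(t0), mu_L=float(beta[0]), mu_c=float(beta[1]),
        var_L=float(D[0, 0]), var_c=float(D[1, 1]), cov_Lc=float(D[0, 1]),
        sigma2_resid=float(s2), subject_effects=effects,
        loglik=-0.5 * float(best.fun), n_subjects=len(usable),
    )


@dataclass
class FitComparison:
    mse_fpca: float
    mse_nlme: float
    rmse_fpca: float
    rmse_nlme: float
    resid_var_fpca: float
    resid_var_nlme: float
    pct_reduction: float
    n_obs: int
    n_subjects: int
    n_excluded: int = 0


def pct_reduction(resid_var_fpca: float, resid_var_nlme: float) -> float:
    """Percent reduction in residual variance of FPCA relative to NLME:
    100 * (1 - var_fpca / var_nlme)."""
    if resid_var_nlme == 0.0:
        return 0.0 if resid_var_fpca == 0.0 else -np.inf
    return 100.0 * (1.0 - resid_var_fpca / resid_var_nlme)


def compare_models(cohort: Cohort, fpca_trajectories: dict, nlme_fit: LogisticNLMEFit) -> FitComparison:
    """Pooled MSE/RMSE of both models against the observed weights.

    ``fpca_trajectories`` maps subject id to a TrajectoryEstimate.  Subjects
    missing from either fit are excluded (and counted); MSE averages the
    squared residuals over all remaining observations.
    """
    sq_f, sq_n, n_obs, n_sub, excluded = 0.0, 0.0, 0, 0, 0
    for subj in cohort:
        if subj.subject_id not in fpca_trajectories or subj.subject_id not in nlme_fit.subject_effects:
            excluded += 1
            continue
        yhat_f = fpca_trajectories[subj.subject_id](subj.times)
        yhat_n = nlme_fit.fitted(subj.subject_id, subj.times)
        sq_f += float(np.sum((yhat_f - subj.weights) ** 2))
        sq_n += float(np.sum((yhat_n - subj.weights) ** 2))
        n_obs += subj.n_obs
        n_sub += 1
    if n_obs == 0:
        raise ValueError("no overlapping subjects between the two fits")
    mse_f = sq_f / n_obs
    mse_n = sq_n / n_obs
    return FitComparison(
        mse_fpca=mse_f, mse_nlme=mse_n,
        rmse_fpca=float(np.sqrt(mse_f)), rmse_nlme=float(np.sqrt(mse_n)),
        resid_var_fpca=mse_f, resid_var_nlme=mse_n,
        pct_reduction=pct_reduction(mse_f, mse_n),
        n_obs=n_obs, n_subjects=n_sub, n_excluded=excluded,
    )
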