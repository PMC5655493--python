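"""Sparse functional PCA: covariance estimation and eigendecomposition.

Pipeline (all estimates pooled across subjects):

1. mean function mu(t) by a 1-D local linear smoother of all observations;
2. raw covariances G_i(T_ij, T_il) = (Y_ij - mu(T_ij))(Y_il - mu(T_il));
   off-diagonal pairs (j != l) feed a 2-D local planar smoother for the
   covariance surface G(s, t), because same-index products are inflated by
   the measurement-error variance sigma^2;
3. the diagonal G(t, t) is re-estimated by a rotated smoother (linear along
   the diagonal, quadratic across it), and a 1-D smoother V(t) of the
   same-index products targets G(t, t) + sigma^2, so sigma^2 is read off as
   the average gap over the middle half of the domain;
4. eigenfunctions/eigenvalues solve the trapezoid-discretised integral
   eigenproblem; the number of components K is the smallest one whose
   cumulative fraction of variance explained reaches the threshold (0.99).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .smoothing import (
    Smoother1DResult,
    Smoother2DResult,
    _kernel,
    local_linear_1d,
    local_linear_2d,
    select_bandwidth_gcv,
)
from .synthetic import Cohort, DOMAIN, trapezoid_weights

__all__ = [
    "RawCovariances",
    "CovarianceModel",
    "EigenSystem",
    "FPCAModel",
    "compute_raw_covariances",
    "estimate_covariance_model",
    "estimate_sigma2",
    "eigendecompose",
    "select_K_fve",
    "fit_fpca",
    "default_grid",
]


def default_grid(n_points: int = 51) -> np.ndarray:
    return np.linspace(DOMAIN[0], DOMAIN[1], n_points)


@dataclass
class RawCovariances:
    """Raw covariance inputs split by index equality.

    ``triples`` holds ordered off-diagonal products (s, t, value), exactly
    N_i (N_i - 1) of them per subject; ``diagonal_inputs`` holds the
    same-index products (t, value) that estimate G(t,t) + sigma^2.
    """

    triples: np.ndarray            # (M, 3): s, t, G_i(s, t), j != l
    diagonal_inputs: np.ndarray    # (D, 2): t, G_i(t, t)


@dataclass
class CovarianceModel:
    grid: np.ndarray
    surface: np.ndarray            # smoothed G(s, t), kg^2
    diag_smooth: np.ndarray        # rotated-smoother diagonal G~(t), kg^2
    v_hat: np.ndarray              # V(t) targeting G(t,t) + sigma^2, kg^2
    sigma2: float
    bandwidths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        if np.max(np.abs(self.surface - self.surface.T)) > 1e-8 * max(
            1.0, np.max(np.abs(self.surface))
        ):
            raise ValueError("covariance surface must be symmetric")

    def interp(self, s, t) -> np.ndarray:
        """Bilinear interpolation of the surface at arbitrary (s, t)."""
        from scipy.interpolate import RegularGridInterpolator

        f = RegularGridInterpolator(
            (self.grid, self.grid), self.surface, bounds_error=False, fill_value=None
        )
        pts = np.column_stack([np.atleast_1d(s), np.atleast_1d(t)])
        return f(pts)


@dataclass
class EigenSystem:
    eigenvalues: np.ndarray        # descending, positive
    eigenfunctions: np.ndarray     # (K, len(grid)), orthonormal rows
    fve: np.ndarray                # cumulative fraction of variance explained
    grid: np.ndarray

    def __post_init__(self) -> None:
        w = trapezoid_weights(self.grid)
        gram = (self.eigenfunctions * w) @ self.eigenfunctions.T
        if np.max(np.abs(gram - np.eye(len(gram)))) > 1e-8:
            raise ValueError("eigenfunctions fail quadrature orthonormality")
        if np.any(np.diff(self.fve) < -1e-12) or abs(self.fve[-1] - 1.0) > 1e-9:
            raise ValueError("fve must be non-decreasing and end at 1")


@dataclass
class FPCAModel:
    """Everything needed to reconstruct individual trajectories."""

    mean: Smoother1DResult
    covariance: CovarianceModel
    eigen: EigenSystem
    K: int
    fve_threshold: float = 0.99

    def __post_init__(self) -> None:
        if not 1 <= self.K <= len(self.eigen.eigenvalues):
            raise ValueError("K out of range")

    @property
    def grid(self) -> np.ndarray:
        return self.covariance.grid

    def phi_at(self, t, K: Optional[int] = None) -> np.ndarray:
        K = self.K if K is None else K
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.vstack(
            [np.interp(t, self.eigen.grid, f) for f in self.eigen.eigenfunctions[:K]]
        )


def compute_raw_covariances(cohort: Cohort, mean: Smoother1DResult) -> RawCovariances:
    """Products of mean-removed observations, split off-/on-diagonal.

    Subjects with a single observation contribute only a diagonal input.
    """
    trip, diag = [], []
    for subj in cohort:
        r = subj.weights - mean(subj.times)
        t = subj.times
        n = t.size
        diag.append(np.column_stack([t, r * r]))
        if n >= 2:
            jj, ll = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
            off = jj != ll
            trip.append(np.column_stack([t[jj[off]], t[ll[off]], r[jj[off]] * r[ll[off]]]))
    triples = np.vstack(trip) if trip else np.empty((0, 3))
    diagonal = np.vstack(diag) if diag else np.empty((0, 2))
    return RawCovariances(triples=triples, diagonal_inputs=diagonal)


def _rotated_diagonal(
    raw: RawCovariances,
    grid: np.ndarray,
    bandwidth: float,
    kernel: str = "gaussian",
    perp_bandwidth: float = 6.0,
) -> np.ndarray:
    """Diagonal of the covariance surface via the rotated local smoother.

    In rotated coordinates u = (s+t)/sqrt(2), v = (t-s)/sqrt(2) a local fit
    linear in u and quadratic in v is evaluated at v = 0 for each grid
    point; off-diagonal raw covariances are the inputs.  The perpendicular
    bandwidth is deliberately wider than a near-diagonal strip: visit
    schedules that place at most one measurement per trimester leave the
    near-diagonal region empty in mid-domain, so the curvature across the
    diagonal has to be borrowed from pairs further out.  Returns NaN at
    nodes where the local design is rank deficient (caller falls back to
    the plain surface diagonal there).
    """
    s, t, val = raw.triples.T
    u = (s + t) / np.sqrt(2.0)
    v = (t - s) / np.sqrt(2.0)
    out = np.full(grid.size, np.nan)
    for i, t0 in enumerate(grid):
        u0 = np.sqrt(2.0) * t0
        h = bandwidth
        for _ in range(6):
            du = u - u0
            w = _kernel(du / h, kernel) * _kernel(v / perp_bandwidth, kernel)
            X = np.column_stack([np.ones_like(du), du, v * v])
            Xw = X * w[:, None]
            A = Xw.T @ X
            if np.linalg.cond(A) < 1e10:
                out[i] = np.linalg.solve(A, Xw.T @ val)[0]
                break
            h *= 1.5
    return out


def estimate_sigma2(v_hat: np.ndarray, diag_smooth: np.ndarray, grid: np.ndarray) -> float:
    """Measurement-error variance: trapezoid-weighted mean of V(t) - G~(t)
    over the middle half of the domain, clamped at zero."""
    lo = grid[0] + 0.25 * (grid[-1] - grid[0])
    hi = grid[-1] - 0.25 * (grid[-1] - grid[0])
    mask = (grid >= lo) & (grid <= hi)
    w = trapezoid_weights(grid[mask])
    s2 = float(np.sum(w * (v_hat[mask] - diag_smooth[mask])) / np.sum(w))
    if s2 < 0:
        warnings.warn("negative sigma^2 estimate clamped to 0", stacklevel=2)
        return 0.0
    return s2


def estimate_covariance_model(
    raw: RawCovariances,
    grid: np.ndarray,
    bandwidths: float | tuple = 4.0,
    diag_bandwidth: Optional[float] = None,
    diag_rot_bandwidth: float = 8.0,
    perp_bandwidth: float = 6.0,
    kernel: str = "gaussian",
) -> CovarianceModel:
    """Smoothed covariance surface, diagonal, V(t) and sigma^2."""
    if raw.triples.shape[0] < 10:
        raise ValueError(
            "fewer than 10 off-diagonal raw covariances; a larger cohort "
            "(or more observations per subject) is required"
        )
    hs, ht = (bandwidths, bandwidths) if np.isscalar(bandwidths) else bandwidths
    surf = local_linear_2d(
        raw.triples[:, 0], raw.triples[:, 1], raw.triples[:, 2],
        (hs, ht), grid, kernel=kernel, assume_symmetric=True,
    )
    diag = _rotated_diagonal(
        raw, grid, bandwidth=diag_rot_bandwidth, kernel=kernel,
        perp_bandwidth=perp_bandwidth,
    )
    fallback = ~np.isfinite(diag)
    if np.any(fallback):
        diag[fallback] = np.diag(surf.surface)[fallback]

    if diag_bandwidth is None:
        cands = np.geomspace(1.5, 12.0, 6)
        diag_bandwidth = select_bandwidth_gcv(
            raw.diagonal_inputs[:, 0], raw.diagonal_inputs[:, 1], cands, kernel=kernel
        )
    v_hat = local_linear_1d(
        raw.diagonal_inputs[:, 0], raw.diagonal_inputs[:, 1],
        diag_bandwidth, grid, kernel=kernel,
    )
    sigma2 = estimate_sigma2(v_hat.values, diag, grid)
    return CovarianceModel(
        grid=np.asarray(grid, dtype=float),
        surface=surf.surface,
        diag_smooth=diag,
        v_hat=v_hat.values,
        sigma2=sigma2,
        bandwidths={"surface": (float(hs), float(ht)), "v_hat": float(diag_bandwidth)},
    )


def eigendecompose(cov: CovarianceModel, tol: float = 1e-12) -> EigenSystem:
    """Solve the quadrature-discretised eigenproblem of the covariance
    operator.

    With W the diagonal trapezoid-weight matrix, the symmetric matrix
    W^{1/2} G W^{1/2} is diagonalised; eigenvectors are mapped back through
    W^{-1/2}, which makes them orthonormal in the quadrature inner product.
    Negative eigenvalues (smoothing artefacts) are truncated and excluded
    from the FVE denominator.  Signs follow a fixed convention: integral of
    each eigenfunction >= 0, ties broken by the value at the last node.
    """
    G = cov.surface
    scale = max(1.0, float(np.max(np.abs(G))))
    if np.max(np.abs(G - G.T)) > 1e-8 * scale:
        raise ValueError("covariance surface is not symmetric")
    grid = cov.grid
    w = trapezoid_weights(grid)
    sw = np.sqrt(w)
    A = sw[:, None] * G * sw[None, :]
    A = 0.5 * (A + A.T)
    evals, evecs = np.linalg.eigh(A)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    keep = evals > max(tol, 1e-12 * max(evals.max(), 0.0))
    evals = evals[keep]
    if evals.size == 0:
        raise ValueError("covariance surface has no positive eigenvalues")
    phi = (evecs[:, keep] / sw[:, None]).T          # rows orthonormal under quadrature
    # sign convention for reproducible score signs
    integrals = phi @ w
    for k in range(phi.shape[0]):
        sgn = np.sign(integrals[k])
        if abs(integrals[k]) < 1e-10 * np.sqrt(np.sum(w)):
            sgn = np.sign(phi[k, -1]) or 1.0
        phi[k] *= sgn if sgn != 0 else 1.0
    fve = np.cumsum(evals) / np.sum(evals)
    fve[-1] = 1.0
    return EigenSystem(eigenvalues=evals, eigenfunctions=phi, fve=fve, grid=grid)


def select_K_fve(eigenvalues, threshold: float = 0.99) -> int:
    """Smallest K whose cumulative eigenvalue share reaches ``threshold``."""
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("no positive eigenvalues")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    fve = np.cumsum(lam) / np.sum(lam)
    return int(np.searchsorted(fve, threshold - 1e-12) + 1)


def fit_fpca(
    cohort: Cohort,
    grid: Optional[np.ndarray] = None,
    mean_bandwidth: Optional[float] = None,
    cov_bandwidth: float = 4.0,
    diag_bandwidth: Optional[float] = None,
    fve_threshold: float = 0.99,
    kernel: str = "gaussian",
    bandwidth_candidates: Optional[Sequence[float]] = None,
) -> FPCAModel:
    """End-to-end sparse FPCA fit of a cohort.

    The mean bandwidth defaults to a GCV choice over a log-spaced candidate
    grid.  The covariance-surface bandwidth defaults to 4 weeks — wide
    enough to bridge the gaps the trimester visit schedule leaves in the
    design while retaining small-variance-fraction components; on cohorts
    whose covariance magnitude is only a few kg^2 the sampling noise of raw
    covariances is relatively larger and a wider setting (6-7 weeks)
    stabilises the eigenvalue tail.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    all_t = np.concatenate([s.times for s in cohort])
    all_y = np.concatenate([s.weights for s in cohort])
    if mean_bandwidth is None:
        cands = bandwidth_candidates if bandwidth_candidates is not None else np.geomspace(1.0, 10.0, 6)
        mean_bandwidth = select_bandwidth_gcv(all_t, all_y, cands, kernel=kernel)
    mean = local_linear_1d(all_t, all_y, mean_bandwidth, grid, kernel=kernel)
    raw = compute_raw_covariances(cohort, mean)
    cov = estimate_covariance_model(
        raw, grid, bandwidths=cov_bandwidth, diag_bandwidth=diag_bandwidth, kernel=kernel
    )
    eigen = eigendecompose(cov)
    K = select_K_fve(eigen.eigenvalues, fve_threshold)
    return FPCAModel(mean=mean, covariance=cov, eigen=eigen, K=K, fve_threshold=fve_threshold)
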