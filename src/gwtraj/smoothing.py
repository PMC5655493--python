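"""Local linear kernel smoothers in one and two dimensions.

These are the nonparametric building blocks of the sparse-FPCA pipeline: the
mean function, the diagonal variance function and the off-diagonal covariance
surface are all estimated by locally weighted least squares (a line in 1D, a
plane in 2D) evaluated at each target point.  A Gaussian kernel is the
default; an Epanechnikov kernel is available.  Near the boundary of the
design, or wherever the local weighted design is rank deficient, the
bandwidth at that evaluation point is widened geometrically (factor 1.5, at
most 5 times) until the local fit is identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Smoother1DResult",
    "Smoother2DResult",
    "local_linear_1d",
    "local_linear_2d",
    "select_bandwidth_gcv",
]

_WIDEN_FACTOR = 1.5
_WIDEN_MAX = 5


def _kernel(u: np.ndarray, name: str) -> np.ndarray:
    if name == "gaussian":
        return np.exp(-0.5 * u * u)
    if name == "epanechnikov":
        return np.maximum(0.0, 0.75 * (1.0 - u * u))
    raise ValueError(f"unknown kernel {name!r}; use 'gaussian' or 'epanechnikov'")


@dataclass
class Smoother1DResult:
    """A smoothed curve on an evaluation grid."""

    grid: np.ndarray
    values: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be one-dimensional and strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("smoothed values must be finite")

    def __call__(self, t) -> np.ndarray:
        """Evaluate by linear interpolation between grid nodes."""
        return np.interp(np.asarray(t, dtype=float), self.grid, self.values)


@dataclass
class Smoother2DResult:
    """A smoothed symmetric surface on ``grid x grid``."""

    grid: np.ndarray
    surface: np.ndarray
    bandwidths: tuple = field(default=(1.0, 1.0))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.surface = np.asarray(self.surface, dtype=float)
        if self.surface.shape != (self.grid.size, self.grid.size):
            raise ValueError("surface must be square on grid x grid")
        if not np.all(np.isfinite(self.surface)):
            raise ValueError("surface must be finite everywhere")


def _local_linear_at(
    t: np.ndarray, y: np.ndarray, x0: float, h: float, kernel: str
) -> float:
    """Intercept of the weighted linear fit centred at ``x0``.

    Widens the bandwidth when fewer than two distinct times carry positive
    weight or the local design is numerically singular.
    """
    h_eff = h
    scale = max(np.ptp(t), 1.0)
    for _ in range(_WIDEN_MAX + 1):
        d = t - x0
        w = _kernel(d / h_eff, kernel)
        support = w > 1e-12
        if np.unique(t[support]).size >= 2:
            s0 = w.sum()
            s1 = (w * d).sum()
            s2 = (w * d * d).sum()
            det = s0 * s2 - s1 * s1
            if det > 1e-12 * max(s0 * s2, 1e-300):
                t0 = (w * y).sum()
                t1 = (w * d * y).sum()
                return (s2 * t0 - s1 * t1) / det
        h_eff *= _WIDEN_FACTOR
        if h_eff > _WIDEN_FACTOR**_WIDEN_MAX * h and h_eff > 10 * scale:
            break
    raise ValueError(
        f"singular local design at t={x0:g}: fewer than 2 distinct support "
        "points even after bandwidth widening"
    )


def local_linear_1d(times, values, bandwidth: float, grid, kernel: str = "gaussian") -> Smoother1DResult:
    """Local linear kernel smoother of scattered ``(times, values)`` data.

    At each grid point the intercept of the kernel-weighted least-squares
    line centred there is returned, which reproduces globally linear data
    exactly for any bandwidth.
    """
    t = np.asarray(times, dtype=float).ravel()
    y = np.asarray(values, dtype=float).ravel()
    g = np.asarray(grid, dtype=float).ravel()
    if t.size != y.size:
        raise ValueError("times and values must have equal length")
    if np.unique(t).size < 2:
        raise ValueError("need at least 2 distinct times")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    out = np.array([_local_linear_at(t, y, x0, bandwidth, kernel) for x0 in g])
    return Smoother1DResult(grid=g, values=out, bandwidth=float(bandwidth))


def _fit_at_data(t: np.ndarray, y: np.ndarray, h: float, kernel: str):
    """Fitted values and hat-diagonal of the smoother at the data points.

    Used by GCV.  Vectorised over evaluation points in chunks.
    """
    n = t.size
    fitted = np.empty(n)
    hat = np.empty(n)
    chunk = max(1, int(2e6 / max(n, 1)))
    for start in range(0, n, chunk):
        x0 = t[start : start + chunk, None]
        d = t[None, :] - x0
        w = _kernel(d / h, kernel)
        s0 = w.sum(axis=1)
        s1 = (w * d).sum(axis=1)
        s2 = (w * d * d).sum(axis=1)
        det = s0 * s2 - s1 * s1
        bad = det <= 1e-300
        det = np.where(bad, np.nan, det)
        # weight of y_j in the intercept at x0_i: w_ij (s2_i - d_ij s1_i)/det_i
        coef = w * (s2[:, None] - d * s1[:, None]) / det[:, None]
        fitted[start : start + chunk] = coef @ y
        idx = np.arange(start, min(start + chunk, n))
        hat[start : start + chunk] = coef[np.arange(idx.size), idx]
    return fitted, hat


def select_bandwidth_gcv(times, values, candidates, kernel: str = "gaussian") -> float:
    """Pick the bandwidth minimising the generalized cross-validation score.

    GCV(h) = n * RSS(h) / (n - tr(S_h))^2 with S_h the local linear smoother
    matrix evaluated at the data points.  Ties break to the smaller
    bandwidth; candidates for which the smoother is ill-posed are skipped.
    """
    t = np.asarray(times, dtype=float).ravel()
    y = np.asarray(values, dtype=float).ravel()
    cands = sorted(float(c) for c in np.atleast_1d(candidates))
    if not cands:
        raise ValueError("candidate list must be non-empty")
    n = t.size
    best_h, best_score = None, np.inf
    for h in cands:
        if h <= 0:
            continue
        try:
            fitted, hat = _fit_at_data(t, y, h, kernel)
        except (ValueError, FloatingPointError):
            continue
        if not np.all(np.isfinite(fitted)):
            continue
        tr = float(np.sum(hat))
        if tr >= n:
            continue
        rss = float(np.sum((y - fitted) ** 2))
        score = n * rss / (n - tr) ** 2
        if best_h is None or score < best_score - 1e-12 * max(abs(best_score), 1.0):
            best_h, best_score = h, score
    if best_h is None:
        raise ValueError("no candidate bandwidth produced a valid smoother")
    return best_h


def _local_planar_chunk(
    s: np.ndarray, t: np.ndarray, v: np.ndarray,
    s0: np.ndarray, t0: np.ndarray, hs: float, ht: float, kernel: str,
) -> np.ndarray:
    """Planar-fit intercepts at the points (s0, t0); NaN where singular."""
    ds = s[None, :] - s0[:, None]
    dt = t[None, :] - t0[:, None]
    w = _kernel(ds / hs, kernel) * _kernel(dt / ht, kernel)
    # normal equations of [1, ds, dt] with weights w, solved per point
    a00 = w.sum(axis=1)
    a01 = (w * ds).sum(axis=1)
    a02 = (w * dt).sum(axis=1)
    a11 = (w * ds * ds).sum(axis=1)
    a12 = (w * ds * dt).sum(axis=1)
    a22 = (w * dt * dt).sum(axis=1)
    b0 = (w * v).sum(axis=1)
    b1 = (w * ds * v).sum(axis=1)
    b2 = (w * dt * v).sum(axis=1)
    m = len(s0)
    A = np.empty((m, 3, 3))
    A[:, 0, 0] = a00; A[:, 0, 1] = a01; A[:, 0, 2] = a02
    A[:, 1, 0] = a01; A[:, 1, 1] = a11; A[:, 1, 2] = a12
    A[:, 2, 0] = a02; A[:, 2, 1] = a12; A[:, 2, 2] = a22
    b = np.stack([b0, b1, b2], axis=1)
    out = np.full(m, np.nan)
    # scale-aware singularity guard per point
    dets = np.linalg.det(A)
    ok = np.isfinite(dets) & (dets > 1e-12 * np.maximum(a00 * a11 * a22, 1e-300))
    if np.any(ok):
        sol = np.linalg.solve(A[ok], b[ok][..., None])[..., 0]
        out[ok] = sol[:, 0]
        out[~np.isfinite(out)] = np.nan
    return out


def local_linear_2d(
    s, t, v, bandwidths, grid, kernel: str = "gaussian",
    assume_symmetric: bool = False,
) -> Smoother2DResult:
    """Local planar kernel smoother of scattered surface samples.

    Fits, at each node of ``grid x grid``, a weighted least-squares plane in
    ``(s, t)`` and keeps its intercept; the result is symmetrised as
    ``(S + S.T) / 2``.  Rank-deficient nodes fall back to geometrically
    widened bandwidths.  With ``assume_symmetric=True`` (valid when the input
    triples contain both orderings of every pair, as raw covariances do, and
    the two bandwidths are equal) only the upper triangle of the grid is
    evaluated and mirrored, halving the work without changing the result.
    """
    s = np.asarray(s, dtype=float).ravel()
    t = np.asarray(t, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if not (s.size == t.size == v.size):
        raise ValueError("s, t, v must have equal length")
    pts = np.column_stack([s, t])
    if np.unique(pts, axis=0).shape[0] < 3:
        raise ValueError("need at least 3 distinct (s, t) locations")
    hs, ht = (float(bandwidths), float(bandwidths)) if np.isscalar(bandwidths) else map(float, bandwidths)
    if hs <= 0 or ht <= 0:
        raise ValueError("bandwidths must be positive")
    g = np.asarray(grid, dtype=float).ravel()
    m = g.size
    if assume_symmetric and hs == ht:
        iu, ju = np.triu_indices(m)
    else:
        iu, ju = map(np.ravel, np.meshgrid(np.arange(m), np.arange(m), indexing="ij"))
    s0 = g[iu]
    t0 = g[ju]
    vals = np.full(iu.size, np.nan)
    chunk = max(1, int(4e6 / max(s.size, 1)))
    for start in range(0, iu.size, chunk):
        sl = slice(start, start + chunk)
        vals[sl] = _local_planar_chunk(s, t, v, s0[sl], t0[sl], hs, ht, kernel)
    # widen bandwidths at unresolved nodes
    bad = np.flatnonzero(~np.isfinite(vals))
    for k in range(1, _WIDEN_MAX + 1):
        if bad.size == 0:
            break
        f = _WIDEN_FACTOR**k
        vals[bad] = _local_planar_chunk(s, t, v, s0[bad], t0[bad], hs * f, ht * f, kernel)
        bad = np.flatnonzero(~np.isfinite(vals))
    if bad.size:
        raise ValueError(
            f"rank-deficient local design at {bad.size} grid nodes even after "
            "bandwidth widening; data too sparse"
        )
    surf = np.empty((m, m))
    if assume_symmetric and hs == ht:
        surf[iu, ju] = vals
        surf[ju, iu] = vals
    else:
        surf = vals.reshape(m, m)
    surf = 0.5 * (surf + surf.T)
    return Smoother2DResult(grid=g, surface=surf, bandwidths=(hs, ht))
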