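"""Synthetic cohorts under the pregnancy-study sampling design.

Each woman's latent weight curve on gestational weeks [0, 42] follows a
Karhunen-Loeve model

    X_i(t) = mu(t) + sum_k xi_ik phi_k(t),        Y_ij = X_i(T_ij) + eps_ij,

with orthonormal eigenfunctions phi_k, eigenvalues lambda_k = var(xi_k) and
i.i.d. Gaussian measurement error eps.  The observation design mimics the
cohort the method was built for: a self-reported prepregnancy weight W0 at
t = 0, up to three measured weights in trimester windows A/B/C, and a
self-reported highest weight WH placed at the gestational age at birth
(>= 37 weeks).  The two self-reported weights carry additive recall bias;
visits can be missed, and late-recruited women have no A visit.

An optional BMI link makes the log relative weight change linear in
prepregnancy BMI, LG_i = b0 + b1 BMI_i + eta_i, so regression stages have a
known generative coefficient to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import truncnorm

DOMAIN = (0.0, 42.0)

__all__ = [
    "DOMAIN",
    "TrueModel",
    "VisitDesign",
    "SubjectRecord",
    "Cohort",
    "gram_schmidt",
    "generate_cohort",
    "make_kl_truth",
    "make_paper_like_truth",
    "make_early_loss_truth",
    "simulate_logistic_cohort",
    "combine_cohorts",
]


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Trapezoid quadrature weights for an increasing grid."""
    g = np.asarray(grid, dtype=float)
    w = np.empty_like(g)
    w[1:-1] = 0.5 * (g[2:] - g[:-2])
    w[0] = 0.5 * (g[1] - g[0])
    w[-1] = 0.5 * (g[-1] - g[-2])
    return w


def gram_schmidt(shapes: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Orthonormalise row-wise shapes under trapezoid quadrature on ``grid``."""
    w = trapezoid_weights(grid)
    out = np.array(shapes, dtype=float, copy=True)
    for k in range(out.shape[0]):
        for j in range(k):
            out[k] -= np.sum(w * out[k] * out[j]) * out[j]
        nrm = np.sqrt(np.sum(w * out[k] ** 2))
        if nrm < 1e-10:
            raise ValueError(f"shape {k} is linearly dependent on earlier shapes")
        out[k] /= nrm
    return out


@dataclass
class TrueModel:
    """Generative truth: mean, eigensystem, noise and reporting model.

    ``bmi_link`` is ``(b0, b1, eta_sd)`` for LG = b0 + b1*BMI + eta, or
    ``None`` for scores drawn independently N(0, lambda_k).  ``report_bias``
    maps label W0/WH to (bias mean, bias sd) in kg.
    """

    grid: np.ndarray
    mean: np.ndarray
    eigenfunctions: np.ndarray          # (K, len(grid)), orthonormal rows
    eigenvalues: np.ndarray             # kg^2 * weeks, descending
    noise_sd: float = 0.5
    bmi_link: Optional[tuple] = None
    report_bias: dict = field(
        default_factory=lambda: {"W0": (-1.0, 1.0), "WH": (1.0, 1.0)}
    )
    bmi_median: float = 23.0
    bmi_log_sd: float = 0.17
    height_mean: float = 1.64
    height_sd: float = 0.065
    ga_birth_mean: float = 39.5
    ga_birth_sd: float = 1.1

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.eigenfunctions = np.atleast_2d(np.asarray(self.eigenfunctions, dtype=float))
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.eigenvalues.size == 0:
            raise ValueError("eigenvalue list must be non-empty")
        if np.any(self.eigenvalues < 0):
            raise ValueError("eigenvalues must be non-negative")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        w = trapezoid_weights(self.grid)
        gram = (self.eigenfunctions * w) @ self.eigenfunctions.T
        if np.max(np.abs(gram - np.eye(len(gram)))) > 1e-6:
            raise ValueError("eigenfunctions are not orthonormal under trapezoid quadrature")

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def mean_at(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.grid, self.mean)

    def phi_at(self, t) -> np.ndarray:
        """Eigenfunctions evaluated at times ``t``; shape (K, len(t))."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.vstack([np.interp(t, self.grid, f) for f in self.eigenfunctions])

    def trajectory(self, scores: np.ndarray, t) -> np.ndarray:
        return self.mean_at(t) + np.asarray(scores, dtype=float) @ self.phi_at(t)

    def to_json(self) -> str:
        d = {
            "grid": self.grid.tolist(),
            "mean": self.mean.tolist(),
            "eigenfunctions": self.eigenfunctions.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "noise_sd": self.noise_sd,
            "bmi_link": list(self.bmi_link) if self.bmi_link else None,
            "report_bias": {k: list(v) for k, v in self.report_bias.items()},
            "bmi_median": self.bmi_median,
            "bmi_log_sd": self.bmi_log_sd,
            "height_mean": self.height_mean,
            "height_sd": self.height_sd,
            "ga_birth_mean": self.ga_birth_mean,
            "ga_birth_sd": self.ga_birth_sd,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "TrueModel":
        d = json.loads(text)
        d["bmi_link"] = tuple(d["bmi_link"]) if d["bmi_link"] else None
        d["report_bias"] = {k: tuple(v) for k, v in d["report_bias"].items()}
        return cls(**d)


@dataclass
class VisitDesign:
    """Trimester visit windows, birth-age range and missingness rates."""

    window_A: tuple = (8.0, 13.0)
    window_B: tuple = (14.0, 27.0)
    window_C: tuple = (28.0, 36.0)
    ga_birth_range: tuple = (37.0, 42.0)
    p_miss_A: float = 0.15
    p_miss_B: float = 0.10
    p_miss_C: float = 0.10
    p_late_recruit: float = 0.25

    def __post_init__(self) -> None:
        wins = [self.window_A, self.window_B, self.window_C]
        flat = [x for w in wins for x in w]
        if any(a >= b for a, b in wins) or flat != sorted(flat) or len(set(flat)) < 6:
            raise ValueError("visit windows must be disjoint and increasing")
        for p in (self.p_miss_A, self.p_miss_B, self.p_miss_C, self.p_late_recruit):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not (self.window_C[1] < self.ga_birth_range[0] < self.ga_birth_range[1]):
            raise ValueError("ga_birth_range must follow window_C and be increasing")


@dataclass
class SubjectRecord:
    """One woman's sparse weight observations and subject-level covariates."""

    subject_id: str
    times: np.ndarray                   # gestational weeks, strictly increasing
    weights: np.ndarray                 # kg
    labels: tuple                       # per observation: W0/WA/WB/WC/WH
    ga_birth: float
    bmi_p: float
    mean_caloric: float = np.nan
    mean_pa_index: float = np.nan
    instrument: str = "interviewer"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.labels = tuple(self.labels)
        if self.times.size < 1:
            raise ValueError(f"{self.subject_id}: at least one observation required")
        if not (len(self.times) == len(self.weights) == len(self.labels)):
            raise ValueError(f"{self.subject_id}: times/weights/labels length mismatch")
        if np.any(self.times < DOMAIN[0]) or np.any(self.times > DOMAIN[1]):
            raise ValueError(f"{self.subject_id}: observation time outside [0, 42]")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.subject_id}: times must be strictly increasing")
        if np.any(self.weights <= 0):
            raise ValueError(f"{self.subject_id}: weights must be positive")
        for t, lab in zip(self.times, self.labels):
            if lab == "W0" and t != 0.0:
                raise ValueError(f"{self.subject_id}: W0 must sit at t = 0")
            if lab == "WH" and t != self.ga_birth:
                raise ValueError(f"{self.subject_id}: WH must sit at GA at birth")

    @property
    def n_obs(self) -> int:
        return len(self.times)

    def weight_by_label(self, label: str) -> Optional[float]:
        for t, y, lab in zip(self.times, self.weights, self.labels):
            if lab == label:
                return float(y)
        return None

    def time_by_label(self, label: str) -> Optional[float]:
        for t, y, lab in zip(self.times, self.weights, self.labels):
            if lab == label:
                return float(t)
        return None


@dataclass
class Cohort:
    subjects: list
    domain: tuple = DOMAIN
    truth: Optional[TrueModel] = None
    true_scores: Optional[np.ndarray] = None   # (n, K), rows follow subjects

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        if self.truth is not None and self.true_scores is not None:
            if self.true_scores.shape != (len(self.subjects), self.truth.n_components):
                raise ValueError("true_scores must be (n_subjects, n_eigenfunctions)")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def true_curve(self, i: int, t) -> np.ndarray:
        """Noiseless latent trajectory of subject ``i`` (synthetic data only)."""
        if self.truth is None or self.true_scores is None:
            raise ValueError("cohort carries no generative truth")
        return self.truth.trajectory(self.true_scores[i], t)


def _logistic_shape(t: np.ndarray, k: float = 0.2, t0: float = 30.0) -> np.ndarray:
    """Normalised logistic gain shape: 0 at week 0, 1 at week 42."""
    lo = expit(-k * t0)
    hi = expit(k * (DOMAIN[1] - t0))
    return (expit(k * (t - t0)) - lo) / (hi - lo)


def make_kl_truth(
    eigenvalues: Sequence[float] = (40.0, 12.0, 6.0),
    noise_sd: float = 1.0,
    gain_kg: float = 14.7,
) -> TrueModel:
    """Generic Karhunen-Loeve truth for recovery experiments.

    Logistic-shaped mean, up to three smooth orthonormal eigenfunctions and
    caller-chosen eigenvalues; scores independent N(0, lambda_k), no BMI
    link and no reporting bias.  The default eigenvalues give clearly
    separated variance fractions (69 / 21 / 10 %), so component-number
    selection is well posed, and a pointwise weight variance of a few kg^2,
    so the measurement-error variance is identifiable at moderate cohort
    sizes: the sampling noise of raw covariances scales with the square of
    the covariance magnitude, and at cohort-realistic weight variances the
    noise variance is only weakly identifiable under a one-visit-per-
    trimester design.
    """
    grid = np.linspace(DOMAIN[0], DOMAIN[1], 421)
    s = _logistic_shape(grid)
    mean = 62.0 + gain_kg * s
    shapes = np.vstack([1.0 - 0.25 * s, s, s * (1.0 - s)])
    lam = np.asarray(eigenvalues, dtype=float)
    phi = gram_schmidt(shapes[: len(lam)], grid)
    return TrueModel(
        grid=grid, mean=mean, eigenfunctions=phi, eigenvalues=lam,
        noise_sd=noise_sd, bmi_link=None,
        report_bias={"W0": (0.0, 0.0), "WH": (0.0, 0.0)},
    )


def make_paper_like_truth(
    noise_sd: float = 0.5,
    with_bmi_link: bool = True,
    with_report_bias: bool = True,
    slope: float = -0.012,
    lg_sd: Optional[float] = None,
) -> TrueModel:
    """Default truth shaped like the gestational-weight application.

    Logistic-shaped mean with inflection near week 30; three orthonormal
    eigenfunctions (overall level, early-vs-late gain contrast, mid-vs-late
    contrast) whose variance fractions are 95.7 / 2.8 / 1.1 % of the total;
    eigenvalue scale chosen so the implied prepregnancy-weight spread is
    realistic (sd ~ 12 kg).  The BMI link carries a negative slope: heavier
    prepregnancy BMI, smaller relative gain.

    ``lg_sd`` optionally sets the population sd of the log relative weight
    change directly, re-deriving the gain-contrast eigenvalue from it
    (instead of deriving the LG spread from the variance fractions).  Use
    this for regression experiments where the weight-change signal must
    dominate the per-subject measurement noise of the change; a value near
    0.095 corresponds to a realistic total-gain sd of ~ 6.5 kg.
    """
    grid = np.linspace(DOMAIN[0], DOMAIN[1], 421)
    s = _logistic_shape(grid)
    mean = 62.0 + 14.7 * s

    shapes = np.vstack([1.0 - 0.25 * s, s, s * (1.0 - s)])
    phi = gram_schmidt(shapes, grid)

    fractions = np.array([0.957, 0.028, 0.011])
    fractions = fractions / fractions.sum()

    # scale so that component 1 reproduces the spread of prepregnancy weight
    bmi_median, bmi_log_sd = 23.0, 0.17
    h_mean, h_sd = 1.64, 0.065
    bmi_mean = bmi_median * np.exp(bmi_log_sd**2 / 2)
    bmi_var = bmi_mean**2 * (np.exp(bmi_log_sd**2) - 1.0)
    h2_mean = h_mean**2 + h_sd**2
    h2_var = (2 * h_mean * h_sd) ** 2 + 2 * h_sd**4
    w0_mean = bmi_mean * h2_mean
    w0_var = bmi_var * h2_var + bmi_var * h2_mean**2 + h2_var * bmi_mean**2
    lam1 = w0_var / phi[0, 0] ** 2
    lam = lam1 * fractions / fractions[0]

    bmi_link = None
    if with_bmi_link:
        ga_ref = 39.5
        c2 = float(np.interp(ga_ref, grid, phi[1]) - phi[1, 0])
        c3 = float(np.interp(ga_ref, grid, phi[2]) - phi[2, 0])
        mean_lg = float(np.log(np.interp(ga_ref, grid, mean) / mean[0]))
        # var(gain) ~ W0^2 e^{2 LG} var(LG) + (e^LG - 1)^2 var(W0)
        if lg_sd is None:
            # derive the LG spread so the induced gain-contrast score
            # variance matches lambda_2 (delta-method, to first order)
            gain_var_target = lam[1] * c2**2
            resid = gain_var_target - (np.expm1(mean_lg)) ** 2 * w0_var - lam[2] * c3**2
            var_lg = max(resid, 1e-6) / (w0_mean**2 * np.exp(2 * mean_lg))
        else:
            # inverse direction: re-derive lambda_2 from the requested LG sd
            var_lg = float(lg_sd) ** 2
            gain_var = (
                var_lg * w0_mean**2 * np.exp(2 * mean_lg)
                + (np.expm1(mean_lg)) ** 2 * w0_var
                + lam[2] * c3**2
            )
            lam[1] = gain_var / c2**2
            lam = np.sort(lam)[::-1]
        eta_sd = float(np.sqrt(max(var_lg - slope**2 * bmi_var, 1e-8)))
        b0 = float(mean_lg - slope * bmi_mean)
        bmi_link = (b0, float(slope), eta_sd)

    bias = {"W0": (-1.0, 1.0), "WH": (1.0, 1.0)} if with_report_bias else {
        "W0": (0.0, 0.0), "WH": (0.0, 0.0)
    }
    return TrueModel(
        grid=grid, mean=mean, eigenfunctions=phi, eigenvalues=lam,
        noise_sd=noise_sd, bmi_link=bmi_link, report_bias=bias,
        bmi_median=bmi_median, bmi_log_sd=bmi_log_sd,
        height_mean=h_mean, height_sd=h_sd,
    )


def make_early_loss_truth(noise_sd: float = 0.5, dip_kg: float = 8.0) -> TrueModel:
    """Truth for a shape-deviant subpopulation: weight loss in early
    pregnancy with late partial regain — a pattern no single logistic curve
    can produce.  Used to probe adaptability of trajectory estimators."""
    grid = np.linspace(DOMAIN[0], DOMAIN[1], 421)
    s = _logistic_shape(grid)
    # broad loss centred mid-pregnancy with only partial late regain
    dip = np.exp(-0.5 * ((grid - 16.0) / 9.0) ** 2)
    mean = 62.0 - dip_kg * dip + 10.0 * s
    shapes = np.vstack([1.0 - 0.25 * s, s, s * (1.0 - s)])
    phi = gram_schmidt(shapes, grid)
    lam = 0.5 * np.array([40.0, 12.0, 6.0])
    return TrueModel(
        grid=grid, mean=mean, eigenfunctions=phi, eigenvalues=lam,
        noise_sd=noise_sd, bmi_link=None,
        report_bias={"W0": (0.0, 0.0), "WH": (0.0, 0.0)},
    )


def _draw_visits(design: VisitDesign, rng: np.random.Generator, n: int):
    """Visit times (NaN = missed) for the three measured windows."""
    def window_draws(window, p_miss):
        t = rng.uniform(window[0], window[1], size=n)
        t[rng.random(n) < p_miss] = np.nan
        return t

    tA = window_draws(design.window_A, design.p_miss_A)
    tA[rng.random(n) < design.p_late_recruit] = np.nan   # recruited in weeks 14-27
    tB = window_draws(design.window_B, design.p_miss_B)
    tC = window_draws(design.window_C, design.p_miss_C)
    return tA, tB, tC


def generate_cohort(
    truth: TrueModel, design: VisitDesign, n: int, seed: int,
    id_prefix: str = "S",
) -> Cohort:
    """Draw ``n`` subjects from ``truth`` under the visit design.

    Deterministic in ``(truth, design, n, seed)``.  Every subject receives a
    W0 record at t = 0 and a WH record at her GA at birth (both subject to
    the truth's report bias), plus 0-3 measured visits.  When the truth has
    a BMI link, the first two scores are solved per subject so that
    X(0) = BMI * height^2 and log(X(ga)/X(0)) = b0 + b1*BMI + eta hold
    exactly; remaining scores are independent N(0, lambda_k).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    K = truth.n_components

    bmi = truth.bmi_median * np.exp(rng.normal(0.0, truth.bmi_log_sd, size=n))
    height = np.clip(rng.normal(truth.height_mean, truth.height_sd, size=n), 1.4, 1.95)
    lo, hi = design.ga_birth_range
    a = (lo - truth.ga_birth_mean) / truth.ga_birth_sd
    b = (hi - truth.ga_birth_mean) / truth.ga_birth_sd
    ga = truncnorm.rvs(a, b, loc=truth.ga_birth_mean, scale=truth.ga_birth_sd,
                       size=n, random_state=rng)

    scores = rng.normal(0.0, 1.0, size=(n, K)) * np.sqrt(truth.eigenvalues)
    if truth.bmi_link is not None:
        if K < 2:
            raise ValueError("BMI link requires at least two eigenfunctions")
        b0, b1, eta_sd = truth.bmi_link
        lg = b0 + b1 * bmi + rng.normal(0.0, eta_sd, size=n)
        w0_target = bmi * height**2
        phi0 = truth.phi_at(0.0)[:, 0]                  # (K,)
        phig = truth.phi_at(ga)                         # (K, n)
        rest0 = scores[:, 2:] @ phi0[2:] if K > 2 else 0.0
        restg = np.einsum("ik,ki->i", scores[:, 2:], phig[2:]) if K > 2 else 0.0
        r1 = w0_target - truth.mean_at(0.0) - rest0
        r2 = w0_target * np.exp(lg) - truth.mean_at(ga) - restg
        det = phi0[0] * phig[1] - phi0[1] * phig[0]
        if np.any(np.abs(det) < 1e-10):
            raise ValueError("degenerate eigenfunction pair for the BMI link")
        scores[:, 0] = (phig[1] * r1 - phi0[1] * r2) / det
        scores[:, 1] = (phi0[0] * r2 - phig[0] * r1) / det

    tA, tB, tC = _draw_visits(design, rng, n)

    caloric = rng.normal(2200.0, 350.0, size=n)
    pa = rng.normal(7.5, 1.2, size=n)
    instrument = np.where(rng.random(n) < 0.48, "interviewer", "web")

    subjects = []
    for i in range(n):
        times = [0.0]
        labels = ["W0"]
        for t_visit, lab in ((tA[i], "WA"), (tB[i], "WB"), (tC[i], "WC")):
            if np.isfinite(t_visit):
                times.append(float(t_visit))
                labels.append(lab)
        times.append(float(ga[i]))
        labels.append("WH")
        times = np.array(times)
        y = truth.trajectory(scores[i], times)
        if truth.noise_sd > 0:
            y = y + rng.normal(0.0, truth.noise_sd, size=times.size)
        for j, lab in enumerate(labels):
            if lab in truth.report_bias:
                bm, bs = truth.report_bias[lab]
                y[j] += bm + (rng.normal(0.0, bs) if bs > 0 else 0.0)
        subjects.append(SubjectRecord(
            subject_id=f"{id_prefix}{i:05d}",
            times=times, weights=y, labels=tuple(labels),
            ga_birth=float(ga[i]), bmi_p=float(bmi[i]),
            mean_caloric=float(caloric[i]), mean_pa_index=float(pa[i]),
            instrument=str(instrument[i]),
        ))
    return Cohort(subjects=subjects, truth=truth, true_scores=scores)


def simulate_logistic_cohort(
    n: int, seed: int, k: float = 0.15, t0: float = 30.0,
    mu_L: float = 16.0, mu_c: float = 62.0, sd_L: float = 2.0, sd_c: float = 8.0,
    noise_sd: float = 1.0, design: Optional[VisitDesign] = None,
    id_prefix: str = "L",
) -> Cohort:
    """Cohort whose latent curves are exactly subject-specific logistic
    growth curves W(t) = L_i / (1 + exp(-k (t - t0))) + c_i.

    All five records are observed (no missingness, no report bias) unless a
    design is supplied.  Used as generative ground truth for the nonlinear
    mixed-effects comparator.
    """
    if design is None:
        design = VisitDesign(p_miss_A=0.0, p_miss_B=0.0, p_miss_C=0.0, p_late_recruit=0.0)
    rng = np.random.default_rng(seed)
    L = rng.normal(mu_L, sd_L, size=n)
    c = rng.normal(mu_c, sd_c, size=n)
    lo, hi = design.ga_birth_range
    ga = truncnorm.rvs((lo - 39.5) / 1.1, (hi - 39.5) / 1.1, loc=39.5, scale=1.1,
                       size=n, random_state=rng)
    tA, tB, tC = _draw_visits(design, rng, n)
    bmi = 23.0 * np.exp(rng.normal(0.0, 0.17, size=n))
    caloric = rng.normal(2200.0, 350.0, size=n)
    pa = rng.normal(7.5, 1.2, size=n)
    instrument = np.where(rng.random(n) < 0.48, "interviewer", "web")

    subjects = []
    for i in range(n):
        times = [0.0]
        labels = ["W0"]
        for t_visit, lab in ((tA[i], "WA"), (tB[i], "WB"), (tC[i], "WC")):
            if np.isfinite(t_visit):
                times.append(float(t_visit))
                labels.append(lab)
        times.append(float(ga[i]))
        labels.append("WH")
        times = np.array(times)
        y = L[i] * expit(k * (times - t0)) + c[i]
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=times.size)
        subjects.append(SubjectRecord(
            subject_id=f"{id_prefix}{i:05d}",
            times=times, weights=y, labels=tuple(labels),
            ga_birth=float(ga[i]), bmi_p=float(bmi[i]),
            mean_caloric=float(caloric[i]), mean_pa_index=float(pa[i]),
            instrument=str(instrument[i]),
        ))
    return Cohort(subjects=subjects)


def combine_cohorts(*cohorts: Cohort) -> Cohort:
    """Pool subjects from several cohorts (generative truth is dropped,
    since a mixture no longer has a single Karhunen-Loeve truth)."""
    subjects = [s for c in cohorts for s in c.subjects]
    return Cohort(subjects=subjects)
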