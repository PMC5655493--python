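"""Inclusion filters, gestational weight-change outcomes and regression.

Four responses quantify weight change over pregnancy:

* G   = max{W_H, W_C} - W_0            (absolute, from raw records)
* LG  = log(max{W_H, W_C} / W_0)       (relative, from raw records)
* G'  = X(ga_birth) - X(0)             (absolute, from the reconstructed curve)
* LG' = log(X(ga_birth) / X(0))        (relative, from the reconstructed curve)

The raw versions inherit recall bias from the two self-reported weights and
the substitution of W_C for the weight at delivery; the primed versions read
both endpoints off the fitted trajectory.  Each response is regressed on
prepregnancy BMI alone or together with averaged caloric intake and
physical-activity index, stratified by food-recall instrument (the two
instruments are never pooled).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic import Cohort, SubjectRecord
from .scores import TrajectoryEstimate

__all__ = [
    "WeightChangeOutcomes",
    "RegressionRow",
    "apply_inclusion_criteria",
    "compute_weight_change",
    "outcomes_table",
    "regress_outcomes",
]

FULL_TERM_WEEKS = 37.0


@dataclass
class WeightChangeOutcomes:
    subject_id: str
    G: float
    LG: float
    G_prime: float
    LG_prime: float

    @property
    def usable_raw(self) -> bool:
        return np.isfinite(self.G)

    @property
    def usable_trajectory(self) -> bool:
        return np.isfinite(self.G_prime)


def apply_inclusion_criteria(cohort: Cohort) -> tuple:
    """Retain analysable subjects; return (cohort, exclusion log).

    Rules: full term (GA at birth >= 37 weeks); a W0 record; at least one
    measured weight (WA/WB/WC); at least one diet or physical-activity
    record; a prepregnancy BMI (requires the height measurement); and
    internal consistency, GA at birth strictly greater than the GA of W_C.
    The log counts every rule each excluded subject fails.
    """
    kept = []
    log = {
        "preterm": 0,
        "missing_W0": 0,
        "no_measured_weight": 0,
        "no_diet_or_pa_record": 0,
        "missing_bmi": 0,
        "inconsistent_ga": 0,
    }
    details = []
    for s in cohort:
        reasons = []
        if s.ga_birth < FULL_TERM_WEEKS:
            reasons.append("preterm")
        if s.weight_by_label("W0") is None:
            reasons.append("missing_W0")
        if not any(s.weight_by_label(lab) is not None for lab in ("WA", "WB", "WC")):
            reasons.append("no_measured_weight")
        if not (np.isfinite(s.mean_caloric) or np.isfinite(s.mean_pa_index)):
            reasons.append("no_diet_or_pa_record")
        if not np.isfinite(s.bmi_p):
            reasons.append("missing_bmi")
        t_c = s.time_by_label("WC")
        if t_c is not None and s.ga_birth <= t_c:
            reasons.append("inconsistent_ga")
        if reasons:
            for r in reasons:
                log[r] += 1
            details.append((s.subject_id, reasons))
        else:
            kept.append(s)
    if not kept:
        raise ValueError("inclusion criteria removed every subject")
    log["n_input"] = len(cohort)
    log["n_retained"] = len(kept)
    log["excluded_subjects"] = details
    return Cohort(subjects=kept), log


def compute_weight_change(
    subject: SubjectRecord, trajectory: Optional[TrajectoryEstimate] = None
) -> WeightChangeOutcomes:
    """Per-subject weight-change outcomes.

    When one of W_H / W_C is missing the other stands in for the weight at
    delivery; when both are missing, G and LG are flagged NaN rather than
    raising.  G'/LG' require a trajectory covering t = 0 and the GA at
    birth and are NaN otherwise.
    """
    w0 = subject.weight_by_label("W0")
    wh = subject.weight_by_label("WH")
    wc = subject.weight_by_label("WC")
    if w0 is not None and w0 <= 0:
        raise ValueError("W0 must be positive")
    candidates = [w for w in (wh, wc) if w is not None]
    G = LG = np.nan
    if w0 is not None and candidates:
        w_top = max(candidates)
        G = w_top - w0
        LG = float(np.log(w_top / w0))
    Gp = LGp = np.nan
    if trajectory is not None:
        g = trajectory.grid
        if g[0] <= 0.0 and g[-1] >= subject.ga_birth:
            x0 = float(trajectory(0.0))
            xd = float(trajectory(subject.ga_birth))
            Gp = xd - x0
            LGp = float(np.log(xd / x0)) if x0 > 0 and xd > 0 else np.nan
    return WeightChangeOutcomes(
        subject_id=subject.subject_id, G=float(G), LG=float(LG),
        G_prime=float(Gp), LG_prime=float(LGp),
    )


def outcomes_table(cohort: Cohort, trajectories: Optional[dict] = None) -> pd.DataFrame:
    """Assemble outcomes and covariates for the regression stage."""
    rows = []
    for s in cohort:
        traj = (trajectories or {}).get(s.subject_id)
        o = compute_weight_change(s, traj)
        rows.append({
            "subject_id": s.subject_id,
            "G": o.G, "LG": o.LG, "G_prime": o.G_prime, "LG_prime": o.LG_prime,
            "bmi_p": s.bmi_p, "mean_caloric": s.mean_caloric,
            "mean_pa_index": s.mean_pa_index, "instrument": s.instrument,
            "ga_birth": s.ga_birth,
        })
    return pd.DataFrame(rows)


@dataclass
class RegressionRow:
    response: str
    covariates: tuple
    stratum: Optional[str]
    coef: dict            # name -> estimate (includes "const")
    bse: dict             # name -> standard error
    r2: float
    rmse: float
    n: int


def regress_outcomes(
    table: pd.DataFrame,
    response: str,
    covariates: Sequence[str] = ("bmi_p",),
    stratum: Optional[str] = None,
) -> RegressionRow:
    """OLS of one weight-change response on subject-level covariates.

    ``stratum`` restricts to one food-recall instrument; strata are always
    fitted separately, never pooled.  RMSE uses n in the denominator and R^2
    is unadjusted.  A collinear design raises with the offending columns.
    """
    df = table if stratum is None else table[table["instrument"] == stratum]
    cols = [response, *covariates]
    df = df[cols].dropna()
    if len(df) < 10:
        raise ValueError(f"fewer than 10 complete cases for {response} ~ {covariates}")
    X = df[list(covariates)].to_numpy(dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        bad = [c for c in covariates if df[c].nunique() <= 1]
        raise ValueError(f"collinear design; offending covariates: {bad or list(covariates)}")
    y = df[response].to_numpy(dtype=float)
    fit = sm.OLS(y, Xc).fit()
    names = ["const", *covariates]
    return RegressionRow(
        response=response,
        covariates=tuple(covariates),
        stratum=stratum,
        coef=dict(zip(names, fit.params)),
        bse=dict(zip(names, fit.bse)),
        r2=float(fit.rsquared),
        rmse=float(np.sqrt(np.mean(fit.resid**2))),
        n=int(fit.nobs),
    )
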