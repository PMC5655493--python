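"""Cohort CSV readers/writers, run configuration and the full pipeline.

File formats (UTF-8, comma-separated, header row, times in decimal weeks):

* observations.csv: subject_id, t_weeks, weight_kg, label
* subjects.csv: subject_id, ga_birth_weeks, bmi_p, mean_caloric,
  mean_pa_index, instrument
* truth.json sidecar (synthetic cohorts only)

``run_full_analysis`` chains simulate/read -> FPCA fit -> per-subject
trajectories with bands -> logistic NLME -> model comparison -> inclusion
filters -> weight-change regression, and writes every table plus a
machine-readable run log.  All randomness flows from the single seed in the
configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic import (
    Cohort, SubjectRecord, VisitDesign, DOMAIN,
    generate_cohort, make_paper_like_truth,
)
from .fpca import fit_fpca, default_grid
from .scores import predict_scores, reconstruct_trajectory
from .nlme import fit_nlme, compare_models
from .gwg import apply_inclusion_criteria, outcomes_table, regress_outcomes

__all__ = [
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "run_full_analysis",
]

OBS_COLUMNS = ["subject_id", "t_weeks", "weight_kg", "label"]
SUBJ_COLUMNS = ["subject_id", "ga_birth_weeks", "bmi_p", "mean_caloric",
                "mean_pa_index", "instrument"]


@dataclass
class RunConfig:
    seed: int = 0
    n_subjects: int = 500
    grid_points: int = 51
    fve_threshold: float = 0.99
    cov_bandwidth: float = 4.0
    bandwidth_candidates: tuple = (1.0, 1.8, 3.2, 5.6, 10.0)
    alpha: float = 0.05
    t0: float = 30.0
    stratum: Optional[str] = None
    out_dir: str = "results/run"
    observations_csv: Optional[str] = None   # read instead of simulate
    subjects_csv: Optional[str] = None
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.fve_threshold <= 1:
            raise ValueError("fve_threshold must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.bandwidth_candidates, list):
            cfg.bandwidth_candidates = tuple(cfg.bandwidth_candidates)
        return cfg


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write observations.csv, subjects.csv and (if present) truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    obs = pd.DataFrame(
        [
            (s.subject_id, t, y, lab)
            for s in cohort
            for t, y, lab in zip(s.times, s.weights, s.labels)
        ],
        columns=OBS_COLUMNS,
    )
    subj = pd.DataFrame(
        [
            (s.subject_id, s.ga_birth, s.bmi_p, s.mean_caloric, s.mean_pa_index, s.instrument)
            for s in cohort
        ],
        columns=SUBJ_COLUMNS,
    )
    paths = {"observations": out / "observations.csv", "subjects": out / "subjects.csv"}
    obs.to_csv(paths["observations"], index=False)
    subj.to_csv(paths["subjects"], index=False)
    if cohort.truth is not None:
        paths["truth"] = out / "truth.json"
        paths["truth"].write_text(cohort.truth.to_json())
    return {k: str(v) for k, v in paths.items()}


def read_cohort(observations_csv, subjects_csv) -> tuple:
    """Parse and validate a cohort; returns (Cohort, rejects DataFrame).

    Malformed observation rows (time outside [0, 42], non-positive or
    unparseable weight) are collected into the rejects report rather than
    silently dropped.  Duplicate (subject, time) pairs are an error listing
    the offenders.
    """
    obs = pd.read_csv(observations_csv)
    subj = pd.read_csv(subjects_csv)
    for cols, df, name in ((OBS_COLUMNS, obs, "observations"), (SUBJ_COLUMNS, subj, "subjects")):
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(f"{name} file missing columns {sorted(missing)}")

    rejects = []
    t = pd.to_numeric(obs["t_weeks"], errors="coerce")
    y = pd.to_numeric(obs["weight_kg"], errors="coerce")
    bad_t = t.isna() | (t < DOMAIN[0]) | (t > DOMAIN[1])
    bad_y = y.isna() | (y <= 0)
    for idx in obs.index[bad_t]:
        rejects.append({"row": int(idx), "subject_id": obs.at[idx, "subject_id"],
                        "reason": "time outside [0, 42]"})
    for idx in obs.index[bad_y & ~bad_t]:
        rejects.append({"row": int(idx), "subject_id": obs.at[idx, "subject_id"],
                        "reason": "non-positive or unparseable weight"})
    ok = obs[~(bad_t | bad_y)].assign(t_weeks=t[~(bad_t | bad_y)], weight_kg=y[~(bad_t | bad_y)])

    dup = ok.duplicated(subset=["subject_id", "t_weeks"], keep=False)
    if dup.any():
        offenders = ok.loc[dup, ["subject_id", "t_weeks"]].drop_duplicates()
        raise ValueError(
            "duplicate (subject, time) pairs: "
            + "; ".join(f"{r.subject_id}@{r.t_weeks:g}" for r in offenders.itertuples())
        )

    subj = subj.set_index("subject_id")
    subjects = []
    for sid, g in ok.groupby("subject_id", sort=True):
        if sid not in subj.index:
            rejects.append({"row": -1, "subject_id": sid, "reason": "no subject-level row"})
            continue
        g = g.sort_values("t_weeks")
        meta = subj.loc[sid]
        subjects.append(SubjectRecord(
            subject_id=str(sid),
            times=g["t_weeks"].to_numpy(),
            weights=g["weight_kg"].to_numpy(),
            labels=tuple(g["label"]),
            ga_birth=float(meta["ga_birth_weeks"]),
            bmi_p=float(meta["bmi_p"]),
            mean_caloric=float(meta["mean_caloric"]),
            mean_pa_index=float(meta["mean_pa_index"]),
            instrument=str(meta["instrument"]),
        ))
    return Cohort(subjects=subjects), pd.DataFrame(rejects, columns=["row", "subject_id", "reason"])


def run_full_analysis(config: RunConfig) -> dict:
    """Simulate (or read) a cohort and run every pipeline stage.

    Returns the result bundle and writes model.json, trajectories.csv,
    comparison.csv, regression_report.csv and run_log.json to the output
    directory.  Identical configuration and seed give identical numbers.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate/read"
    try:
        if config.observations_csv:
            cohort, rejects = read_cohort(config.observations_csv, config.subjects_csv)
        else:
            truth = make_paper_like_truth(noise_sd=config.noise_sd)
            cohort = generate_cohort(truth, VisitDesign(), config.n_subjects, seed=config.seed)
            rejects = pd.DataFrame()

        stage = "inclusion"
        included, exclusion_log = apply_inclusion_criteria(cohort)

        stage = "fit-fpca"
        grid = default_grid(config.grid_points)
        model = fit_fpca(
            included, grid=grid, cov_bandwidth=config.cov_bandwidth,
            fve_threshold=config.fve_threshold,
            bandwidth_candidates=config.bandwidth_candidates,
        )

        stage = "trajectories"
        trajectories = {}
        traj_rows = []
        for s in included:
            sc = predict_scores(s, model)
            tr = reconstruct_trajectory(sc, model, alpha=config.alpha)
            trajectories[s.subject_id] = tr
            for j in range(grid.size):
                traj_rows.append((s.subject_id, grid[j], tr.values[j],
                                  tr.pointwise_lo[j], tr.pointwise_hi[j],
                                  tr.simultaneous_lo[j], tr.simultaneous_hi[j]))
        traj_df = pd.DataFrame(
            traj_rows,
            columns=["subject_id", "t_weeks", "est_kg", "pw_lo", "pw_hi", "sim_lo", "sim_hi"],
        )

        stage = "fit-nlme"
        nlme = fit_nlme(included, t0=config.t0)

        stage = "compare"
        comparison = compare_models(included, trajectories, nlme)
        comp_df = pd.DataFrame([{
            "mse_fpca": comparison.mse_fpca, "mse_nlme": comparison.mse_nlme,
            "rmse_fpca": comparison.rmse_fpca, "rmse_nlme": comparison.rmse_nlme,
            "resid_var_fpca": comparison.resid_var_fpca,
            "resid_var_nlme": comparison.resid_var_nlme,
            "pct_reduction": comparison.pct_reduction,
            "n_obs": comparison.n_obs, "n_subjects": comparison.n_subjects,
        }])

        stage = "gwg-regress"
        table = outcomes_table(included, trajectories)
        strata = [config.stratum] if config.stratum else sorted(table["instrument"].unique())
        reg_rows = []
        for stratum in strata:
            for response in ("G", "LG", "G_prime", "LG_prime"):
                for covs in (("bmi_p",), ("bmi_p", "mean_caloric", "mean_pa_index")):
                    row = regress_outcomes(table, response, covs, stratum=stratum)
                    reg_rows.append({
                        "stratum": stratum, "response": response,
                        "covariates": "+".join(covs), "r2": row.r2, "rmse": row.rmse,
                        "n": row.n,
                        **{f"coef_{k}": v for k, v in row.coef.items()},
                        **{f"se_{k}": v for k, v in row.bse.items()},
                    })
        reg_df = pd.DataFrame(reg_rows)

        stage = "write"
        model_summary = {
            "eigenvalues": model.eigen.eigenvalues.tolist(),
            "fve": model.eigen.fve.tolist(),
            "K": model.K,
            "sigma2": model.covariance.sigma2,
            "mean_bandwidth": model.mean.bandwidth,
            "cov_bandwidths": model.covariance.bandwidths,
            "grid": model.grid.tolist(),
            "mean": model.mean.values.tolist(),
            "eigenfunctions": model.eigen.eigenfunctions.tolist(),
        }
        (out / "model.json").write_text(json.dumps(model_summary))
        traj_df.to_csv(out / "trajectories.csv", index=False)
        comp_df.to_csv(out / "comparison.csv", index=False)
        reg_df.to_csv(out / "regression_report.csv", index=False)
        if not rejects.empty:
            rejects.to_csv(out / "rejects.csv", index=False)
        run_log = {
            "seed": config.seed,
            "config": {k: v for k, v in asdict(config).items()},
            "versions": {"gwtraj": __version__, "numpy": np.__version__,
                         "pandas": pd.__version__},
            "n_input": exclusion_log["n_input"],
            "n_retained": exclusion_log["n_retained"],
            "exclusions": {k: v for k, v in exclusion_log.items()
                           if isinstance(v, int) and k not in ("n_input", "n_retained")},
            "excluded_subjects": [
                {"subject_id": sid, "reasons": rs}
                for sid, rs in exclusion_log["excluded_subjects"]
            ],
        }
        (out / "run_log.json").write_text(json.dumps(run_log, indent=1))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    return {
        "cohort": included,
        "model": model,
        "trajectories": trajectories,
        "nlme": nlme,
        "comparison": comparison,
        "regression": reg_df,
        "exclusions": exclusion_log,
        "paths": {p.name: str(p) for p in out.iterdir()},
    }
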