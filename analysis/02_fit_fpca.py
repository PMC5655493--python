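"""Fit sparse FPCA to the simulated cohort and reconstruct trajectories.

Reads the cohort written by 01_simulate_cohort.py (or simulates one when it
is absent), applies the inclusion filters, fits the mean, covariance
surface, noise variance and eigensystem, selects the number of components
at 99% variance explained, and writes the model summary plus per-subject
trajectories with pointwise and simultaneous 95% bands under results/fpca/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from gwtraj import (
    RunConfig,
    VisitDesign,
    apply_inclusion_criteria,
    fit_fpca,
    generate_cohort,
    make_paper_like_truth,
    read_cohort,
)
from gwtraj.scores import predict_scores, reconstruct_trajectory


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/fpca")
    args = ap.parse_args()

    cdir = Path(args.cohort)
    if (cdir / "observations.csv").exists():
        cohort, _ = read_cohort(cdir / "observations.csv", cdir / "subjects.csv")
    else:
        cohort = generate_cohort(make_paper_like_truth(), VisitDesign(), 600, seed=args.seed)
    included, log = apply_inclusion_criteria(cohort)
    print(f"{log['n_retained']}/{log['n_input']} subjects pass inclusion")

    model = fit_fpca(included)
    fve_pct = 100 * np.diff(np.concatenate([[0.0], model.eigen.fve]))
    print(f"selected K = {model.K} components at 99% FVE")
    print("variance fractions (%):", np.round(fve_pct[: model.K + 1], 1))
    print(f"measurement-error variance sigma^2 = {model.covariance.sigma2:.2f} kg^2")

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in included:
        tr = reconstruct_trajectory(predict_scores(s, model), model)
        for j, t in enumerate(tr.grid):
            rows.append((s.subject_id, t, tr.values[j], tr.pointwise_lo[j],
                         tr.pointwise_hi[j], tr.simultaneous_lo[j], tr.simultaneous_hi[j]))
    import pandas as pd

    pd.DataFrame(rows, columns=["subject_id", "t_weeks", "est_kg", "pw_lo", "pw_hi",
                                "sim_lo", "sim_hi"]).to_csv(out / "trajectories.csv", index=False)
    (out / "model.json").write_text(json.dumps({
        "K": model.K,
        "eigenvalues": model.eigen.eigenvalues.tolist(),
        "fve": model.eigen.fve.tolist(),
        "sigma2": model.covariance.sigma2,
        "grid": model.grid.tolist(),
        "mean": model.mean.values.tolist(),
        "eigenfunctions": model.eigen.eigenfunctions.tolist(),
    }))
    print(f"wrote {out/'model.json'} and {out/'trajectories.csv'}")


if __name__ == "__main__":
    main()
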