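"""Discrimination and stability of the selected final model.

Refits the final model chosen under the all-covariates strategy and checks
that its apparent concordance survives 10-fold cross-validation and that
model-based standard errors agree with case-resampling bootstrap ones.
"""

import json
from pathlib import Path

import numpy as np

from lifecourse import (bootstrap_se, build_design, c_statistic,
                        cv_c_statistic, fit_logistic, read_cohort, select_all)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1

if __name__ == "__main__":
    cohort = read_cohort(OUT / "cohort.csv")
    table = select_all(cohort, "all")
    outcome = cohort["no_graduation"].to_numpy(float)
    design = build_design(cohort, table.chosen)
    fit = fit_logistic(design, outcome)
    apparent = c_statistic(fit.fitted, outcome).c
    cv = cv_c_statistic(design, outcome, k=10, seed=SEED)

    boot_n = 20_000  # resampling on a subset keeps 200 refits quick
    sub = cohort.iloc[:boot_n].reset_index(drop=True)
    sub_design = build_design(sub, table.chosen)
    sub_fit = fit_logistic(sub_design, sub["no_graduation"])
    boot = bootstrap_se(sub_design, sub["no_graduation"], n_boot=200,
                        seed=SEED)
    ratio = np.median(boot["se_boot"].to_numpy() / sub_fit.se.to_numpy())

    report = {
        "apparent_c": apparent,
        "cv_c_mean": cv.mean_c,
        "cv_c_per_fold": cv.per_fold,
        "bootstrap_to_model_se_ratio_median": float(ratio),
        "bootstrap_n": boot_n,
    }
    (OUT / "discrimination.json").write_text(json.dumps(report, indent=2))
    print(f"apparent c {apparent:.3f}; 10-fold CV c {cv.mean_c:.3f}")
    print(f"median bootstrap/model SE ratio at n={boot_n}: {ratio:.3f}")
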