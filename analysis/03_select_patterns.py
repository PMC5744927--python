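"""Trim the full model: pick the temporal pattern for each exposure.

Runs the likelihood-ratio trimming under three covariate strategies (all
time-invariant covariates, birth covariates only, none) and writes a
side-by-side comparison of the selected hypotheses, plus the long-format
candidate diagnostics (LRT statistic, df, p, AIC for every exposure and
hypothesis) behind each choice.
"""

from pathlib import Path

import pandas as pd

from lifecourse import read_cohort, select_all

OUT = Path(__file__).resolve().parents[1] / "results"
STRATEGIES = ("all", "birth_only", "none")

if __name__ == "__main__":
    cohort = read_cohort(OUT / "cohort.csv")
    chosen = {}
    diagnostics = []
    for strategy in STRATEGIES:
        table = select_all(cohort, strategy)
        chosen[strategy] = {e: h.value for e, h in table.chosen.items()}
        diag = table.candidates_frame()
        diag.insert(0, "strategy", strategy)
        diagnostics.append(diag)
        print(f"strategy {strategy!r}: c-statistic {table.final_c:.3f}")
        for e, h in table.chosen.items():
            print(f"  {e:>14}: {h.value}")
    comparison = pd.DataFrame(chosen)
    comparison.index.name = "exposure"
    comparison.to_csv(OUT / "selection_comparison.csv", lineterminator="\n")
    pd.concat(diagnostics).to_csv(OUT / "selection_candidates.csv",
                                  index=False, float_format="%.6g",
                                  lineterminator="\n")
    print(f"\nwrote {OUT / 'selection_comparison.csv'}")
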