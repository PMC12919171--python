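"""Trajectory modeling of the module composites.

For each module PC1 score the male-vs-female contrast is tested at every
timepoint with a two-sided Mann-Whitney U test; the per-timepoint
p-values are combined into Fisher's psi (chi-square with 2k df) and
cross-checked against a within-timepoint permutation null; directional
consistency records how stably one sex exceeds the other across the
trajectory.  The contrast is run separately within injured and within
sham animals: shams carry no injury effect, so their consistency curves
should hover near the mixed-direction regime while injured modules with
sex-specific templates should approach 1.0.

Reads results/cohort_with_modules.csv; writes results/trajectory_injured
.{json,csv}, results/trajectory_sham.{json,csv} and
results/consistency_curves.csv.
"""

from pathlib import Path

import pandas as pd

from bbbtraj.cohort import CohortTable
from bbbtraj.trajectory import (
    Contrast,
    reports_to_csv,
    reports_to_json,
    trajectory_suite,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20260921
N_PERM = 500


def main() -> None:
    table = CohortTable.from_csv(RESULTS / "cohort_with_modules.csv")
    score_cols = [f for f in table.feature_names if f.startswith("module_")]

    curve_rows = []
    for group in ["injured", "sham"]:
        contrast = Contrast(within={"group": group})
        reports = trajectory_suite(
            table, score_cols, contrast, n_perm=N_PERM, seed=SEED
        )
        reports_to_json(reports, RESULTS / f"trajectory_{group}.json")
        reports_to_csv(reports, RESULTS / f"trajectory_{group}.csv")

        print(f"\n=== male vs female within {group} ===")
        for rep in reports:
            print(
                f"{rep.feature:<28} k={rep.k}  psi={rep.psi:7.2f}  "
                f"p_combined={rep.p_combined:.4g}  "
                f"p_perm={rep.permutation.p_perm:.4g}  "
                f"majority={rep.majority_sign}  consistency={rep.consistency:.2f}"
            )
            for tp, c in rep.cumulative_consistency:
                curve_rows.append(
                    {"group": group, "module": rep.feature,
                     "timepoint": tp, "cumulative_consistency": c}
                )

    pd.DataFrame(curve_rows).to_csv(RESULTS / "consistency_curves.csv", index=False)


if __name__ == "__main__":
    main()
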