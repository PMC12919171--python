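"""Summarize each feature module by its PC1 composite score.

Members are standardized and the first principal component, oriented to
correlate positively with the members' common direction, becomes the
module's per-animal score.  Animals missing a member after subgroup
imputation are rescued by the global-mean fallback so every animal gets
a score.

Reads results/cohort_imputed.csv + results/modules_def.json; writes
results/cohort_with_modules.csv and results/modules.csv.
"""

import json
from pathlib import Path

import pandas as pd

from bbbtraj.cohort import CohortTable
from bbbtraj.composites import append_module_scores, module_pc1

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = CohortTable.from_csv(RESULTS / "cohort_imputed.csv")
    modules_def = json.loads((RESULTS / "modules_def.json").read_text())

    fitted = [
        module_pc1(table, name, members, fallback_impute=True)
        for name, members in modules_def.items()
    ]
    table = append_module_scores(table, fitted)
    table.to_csv(RESULTS / "cohort_with_modules.csv")

    summary = pd.DataFrame(
        [
            {
                "module": m.name,
                "n_members": len(m.members),
                "members": ";".join(m.members),
                "explained_variance_fraction": round(m.explained_variance_fraction, 4),
                "n_animals_scored": m.n_animals,
            }
            for m in fitted
        ]
    )
    summary.to_csv(RESULTS / "modules.csv", index=False)
    print(summary.drop(columns="members").to_string(index=False))


if __name__ == "__main__":
    main()
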