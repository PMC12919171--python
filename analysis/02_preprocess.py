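"""Exclude extremely sparse features and impute the rest hierarchically.

Features missing in more than 70% of animals are dropped.  Remaining
missing cells get the mean of their group x sex x timepoint subset when
at least two values are observed there; sparser subsets are left missing
for the trajectory tests (which handle missingness per timepoint) and
only rescued by the global mean where PCA or the embedding require
complete data.

Reads results/cohort_raw.csv; writes results/cohort_imputed.csv and
results/imputation_log.json.
"""

from pathlib import Path

from bbbtraj.cohort import CohortTable
from bbbtraj.preprocess import drop_sparse_features, impute_hierarchical

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = CohortTable.from_csv(RESULTS / "cohort_raw.csv")
    table, dropped = drop_sparse_features(table, 0.70)
    print(f"dropped {len(dropped)} features over the 70% threshold: {dropped}")

    table, log = impute_hierarchical(table)
    table.to_csv(RESULTS / "cohort_imputed.csv")
    log.to_json(RESULTS / "imputation_log.json")

    actions = log.actions()
    total_missing = sum(actions.values())
    print(f"missing cells: {total_missing}")
    for action, count in sorted(actions.items()):
        print(f"  {action:<14} {count}")
    remaining = table.df[table.feature_names].isna().sum().sum()
    print(f"cells still missing after subgroup imputation: {remaining}")


if __name__ == "__main__":
    main()
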