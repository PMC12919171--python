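"""Discover the feature correlation structure.

Pairwise Spearman correlations over all animals (pairwise-complete),
average-linkage clustering on the Euclidean distances between correlation
rows, a dendrogram-ordered heatmap, and a proposed module cut.  The cut
is advisory: the module definitions consumed downstream live in
results/modules_def.json and may be curated by hand.

Reads results/cohort_imputed.csv; writes results/spearman_rho.csv,
results/linkage.json, results/heatmap.png and results/modules_def.json.
"""

import json
from pathlib import Path

from bbbtraj.cohort import CohortTable
from bbbtraj.correlation import (
    cluster_features,
    plot_heatmap,
    propose_modules,
    spearman_matrix,
)
from bbbtraj.preprocess import impute_hierarchical

RESULTS = Path(__file__).resolve().parents[1] / "results"
N_CLUSTERS = 5


def main() -> None:
    table = CohortTable.from_csv(RESULTS / "cohort_imputed.csv")
    # the global-mean fallback keeps every correlation defined for the
    # clustering step without touching the analysis table on disk
    filled, _ = impute_hierarchical(table, allow_global_fallback=True)
    structure = cluster_features(spearman_matrix(filled))
    structure.rho_to_csv(RESULTS / "spearman_rho.csv")
    structure.linkage_to_json(RESULTS / "linkage.json")
    plot_heatmap(structure, RESULTS / "heatmap.png")

    modules = propose_modules(structure, N_CLUSTERS)
    usable = {name: members for name, members in modules if len(members) >= 2}
    (RESULTS / "modules_def.json").write_text(json.dumps(usable, indent=2))

    print(f"features clustered: {len(structure.features)}")
    print(f"leaf order: {structure.leaf_order}")
    for name, members in modules:
        tag = "" if len(members) >= 2 else "  (singleton, no composite)"
        print(f"  {name}: {members}{tag}")


if __name__ == "__main__":
    main()
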