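"""Correlation-structure discovery over cohort features.

Pairwise Spearman correlations (pairwise-complete over animals, average
tied ranks) feed an agglomerative average-linkage (UPGMA) clustering whose
distance between two features is the Euclidean distance between their rows
of the correlation matrix.  The resulting dendrogram supplies the heatmap
leaf order, and a flat cut proposes feature modules.  Proposed modules are
advisory: final module membership is a curation decision supplied through
configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from .cohort import CohortTable


class CorrelationError(ValueError):
    pass


@dataclass
class CorrelationStructure:
    features: list[str]
    rho: pd.DataFrame  # symmetric, unit diagonal; NaN where undefined
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)
    linkage_matrix: np.ndarray | None = None  # scipy (n-1, 4) merge tree
    leaf_order: list[str] | None = None
    cluster_labels: dict[str, int] | None = None

    def rho_to_csv(self, path: str | Path) -> None:
        self.rho.to_csv(path)

    def linkage_to_json(self, path: str | Path) -> None:
        if self.linkage_matrix is None:
            raise CorrelationError("linkage not computed")
        merges = [
            {"left": int(a), "right": int(b), "height": float(h), "size": int(s)}
            for a, b, h, s in self.linkage_matrix
        ]
        Path(path).write_text(
            json.dumps({"features": self.features, "merges": merges,
                        "leaf_order": self.leaf_order}, indent=2)
        )


def spearman_matrix(table: CohortTable, min_pairs: int = 3) -> CorrelationStructure:
    """Pairwise-complete Spearman correlation across all animals.

    An entry is undefined (NaN, and listed in ``undefined_pairs``) when
    fewer than ``min_pairs`` animals have both features observed or a
    variable is constant on the overlap.  The diagonal is fixed at 1.
    """
    feats = table.feature_names
    if len(feats) < 2:
        raise CorrelationError("need at least two features")
    X = table.features_frame()
    rho = X.corr(method="spearman", min_periods=min_pairs)
    np.fill_diagonal(rho.values, 1.0)
    undefined = [
        (feats[i], feats[j])
        for i in range(len(feats))
        for j in range(i + 1, len(feats))
        if np.isnan(rho.iat[i, j])
    ]
    return CorrelationStructure(features=feats, rho=rho, undefined_pairs=undefined)


def cluster_features(
    structure: CorrelationStructure, metric: str = "euclidean_rows"
) -> CorrelationStructure:
    """Average-linkage clustering of features on the correlation matrix.

    The default distance between features i and j is the Euclidean
    distance between rows i and j of the Spearman matrix; ``metric`` may
    instead be ``one_minus_rho`` for the conventional 1 - rho dissimilarity.
    Requires a fully defined matrix — resolve undefined entries first
    (e.g. re-run after global-mean fallback imputation).
    """
    if structure.undefined_pairs:
        raise CorrelationError(
            "correlation matrix has undefined entries "
            f"({len(structure.undefined_pairs)} pairs); re-run after "
            "global-mean fallback imputation or drop the affected features"
        )
    R = structure.rho.to_numpy(dtype=float)
    if metric == "euclidean_rows":
        condensed = pdist(R, metric="euclidean")
    elif metric == "one_minus_rho":
        iu = np.triu_indices(len(R), k=1)
        condensed = 1.0 - R[iu]
    else:
        raise CorrelationError(f"unknown metric {metric!r}")
    Z = linkage(condensed, method="average")
    order = leaves_list(Z)
    out = CorrelationStructure(
        features=structure.features,
        rho=structure.rho,
        undefined_pairs=[],
        linkage_matrix=Z,
        leaf_order=[structure.features[i] for i in order],
    )
    return out


def propose_modules(
    structure: CorrelationStructure, n_clusters: int
) -> list[tuple[str, list[str]]]:
    """Flat cut of the dendrogram into ``n_clusters`` feature groups.

    Returns ``(module_name, member_features)`` pairs named cluster_1..k
    in leaf order.  Singleton groups are still returned (callers needing
    a PC1 composite must check for >= 2 members).
    """
    if structure.linkage_matrix is None:
        raise CorrelationError("linkage not computed; call cluster_features first")
    n = len(structure.features)
    if not 1 < n_clusters < n:
        raise CorrelationError("n_clusters must satisfy 1 < n_clusters < n_features")
    labels = fcluster(structure.linkage_matrix, t=n_clusters, criterion="maxclust")
    structure.cluster_labels = dict(zip(structure.features, map(int, labels)))
    # order clusters by first appearance along the dendrogram leaf order
    order = structure.leaf_order or structure.features
    label_of = structure.cluster_labels
    seen: list[int] = []
    for f in order:
        if label_of[f] not in seen:
            seen.append(label_of[f])
    modules: list[tuple[str, list[str]]] = []
    for idx, lab in enumerate(seen, start=1):
        members = [f for f in structure.features if label_of[f] == lab]
        modules.append((f"cluster_{idx}", members))
    return modules


def plot_heatmap(structure: CorrelationStructure, path: str | Path) -> None:
    """Dendrogram-ordered correlation heatmap figure (PNG/SVG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = structure.leaf_order or structure.features
    R = structure.rho.loc[order, order]
    fig, ax = plt.subplots(figsize=(0.4 * len(order) + 2, 0.4 * len(order) + 2))
    im = ax.imshow(R.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(order)), order, fontsize=7)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
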