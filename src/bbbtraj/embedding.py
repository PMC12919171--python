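"""Complete-case t-SNE embedding of curated features.

Animals with any missing value among the selected features are excluded
before embedding (complete-case rule), features are standardized, and the
2-D t-SNE map is made reproducible by seeding and by initializing from
the first two principal components instead of a random layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .cohort import CohortTable
from .composites import standardize


class EmbeddingError(ValueError):
    pass


@dataclass
class EmbeddingResult:
    animal_ids: list[str]
    coords: np.ndarray  # (n, 2)
    perplexity: float
    n_iter: int
    seed: int
    init: str
    annotations: pd.DataFrame  # sex, group, timepoint per animal

    def to_csv(self, path: str | Path) -> None:
        out = self.annotations.copy()
        out.insert(0, "animal_id", self.animal_ids)
        out["tsne_1"] = self.coords[:, 0]
        out["tsne_2"] = self.coords[:, 1]
        out.to_csv(path, index=False)


def select_complete(table: CohortTable, features: list[str]) -> CohortTable:
    """Keep exactly the animals with no missing value among ``features``."""
    absent = [f for f in features if f not in table.feature_names]
    if absent:
        raise EmbeddingError(f"features not in table: {absent}")
    mask = table.df[features].notna().all(axis=1)
    if not mask.any():
        raise EmbeddingError("no animal has complete data for the selected features")
    return table.subset(mask.to_numpy())


def tsne_embed(
    table: CohortTable,
    features: list[str],
    perplexity: float | None = None,
    seed: int = 0,
    n_iter: int = 1000,
) -> EmbeddingResult:
    """Standardize the selected features and embed to two dimensions.

    Requires a complete-case table (run ``select_complete`` first).  The
    default perplexity is min(30, floor((n - 1) / 3)); an explicit
    perplexity must satisfy n >= 3 * perplexity + 1.
    """
    complete = select_complete(table, features)
    if complete.n_animals != table.n_animals:
        raise EmbeddingError(
            "table contains incomplete animals; apply select_complete first"
        )
    n = complete.n_animals
    if perplexity is None:
        perplexity = float(min(30, (n - 1) // 3))
        if perplexity < 1:
            raise EmbeddingError(f"too few animals (n={n}) for t-SNE")
    if n < 3 * perplexity + 1:
        raise EmbeddingError(
            f"perplexity {perplexity} too large: need n >= {3 * perplexity + 1}, "
            f"have {n}"
        )
    std = standardize(complete, features)
    X = std.df[features].to_numpy(dtype=float)
    # seeded PCA initialization: deterministic and reproducible figures
    pca = PCA(n_components=2, random_state=seed)
    init = pca.fit_transform(X)
    init = init / np.std(init[:, 0]) * 1e-4  # t-SNE convention: tiny spread
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init=init,
        random_state=seed,
        max_iter=n_iter,
    )
    coords = tsne.fit_transform(X)
    return EmbeddingResult(
        animal_ids=list(std.df["animal_id"]),
        coords=np.asarray(coords, dtype=float),
        perplexity=perplexity,
        n_iter=n_iter,
        seed=seed,
        init="pca",
        annotations=std.df[["sex", "group", "timepoint"]].reset_index(drop=True),
    )


def plot_embedding(result: EmbeddingResult, path: str | Path) -> None:
    """Scatter with color = sex, marker = group, numeric timepoint labels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"male": "tab:blue", "female": "tab:red"}
    markers = {"sham": "o", "injured": "^"}
    fig, ax = plt.subplots(figsize=(6, 6))
    ann = result.annotations
    for group, marker in markers.items():
        for sex, color in colors.items():
            sel = (ann["group"] == group) & (ann["sex"] == sex)
            ax.scatter(
                result.coords[sel, 0], result.coords[sel, 1],
                c=color, marker=marker, s=30, alpha=0.8,
                label=f"{group} {sex}",
            )
    for i, tp in enumerate(ann["timepoint"]):
        ax.annotate(str(tp), result.coords[i], fontsize=5, alpha=0.6)
    ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
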