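"""Module composite scores: PC1 of standardized member features.

A feature module is a curated set of >= 2 correlated features.  Members
are standardized (mean 0, sample SD 1 with the n-1 denominator) and the
module's composite score per animal is the projection onto the first
principal component.  Because a principal axis has no intrinsic sign, the
orientation is fixed by convention: scores must correlate positively with
the row-mean of the standardized members, so "higher composite" always
means "members jointly higher".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .preprocess import impute_hierarchical


class CompositeError(ValueError):
    pass


@dataclass
class FeatureModule:
    name: str
    members: list[str]
    loadings: np.ndarray  # unit vector over members
    explained_variance_fraction: float
    orientation: int  # +1 if PC1 kept as computed, -1 if flipped
    scores: pd.Series = field(repr=False)  # animal_id -> composite
    n_animals: int = 0


def standardize(table: CohortTable, features: list[str] | None = None) -> CohortTable:
    """Center each feature to mean 0 and scale to sample SD 1.

    Statistics are computed over observed values only; missing cells stay
    missing.  A zero-variance feature is an error naming the feature.
    """
    features = list(features) if features is not None else table.feature_names
    absent = [f for f in features if f not in table.feature_names]
    if absent:
        raise CompositeError(f"features not in table: {absent}")
    X = table.df[features].to_numpy(dtype=float)
    out = table.df.copy()
    for j, feat in enumerate(features):
        col = X[:, j]
        obs = col[np.isfinite(col)]
        if obs.size < 2:
            raise CompositeError(f"feature {feat!r} has fewer than 2 observed values")
        sd = obs.std(ddof=1)
        if sd == 0:
            raise CompositeError(f"feature {feat!r} has zero variance")
        out[feat] = (col - obs.mean()) / sd
    return CohortTable(out, list(table.timepoint_order), dict(table.timepoint_hours))


def module_pc1(
    table: CohortTable,
    name: str,
    members: list[str],
    fallback_impute: bool = False,
) -> FeatureModule:
    """PC1 composite of a module over complete-member animals.

    With ``fallback_impute`` the global-mean fallback rescues animals
    still missing a member after subgroup imputation; otherwise those
    animals are dropped from the score map.  Requires >= 3 animals with
    complete members.
    """
    members = list(members)
    if len(members) < 2:
        raise CompositeError(f"module {name!r} needs >= 2 members")
    work = table.select_features(members)
    if fallback_impute:
        work, _ = impute_hierarchical(work, allow_global_fallback=True)
    std = standardize(work, members)
    X = std.df[members].to_numpy(dtype=float)
    complete = np.isfinite(X).all(axis=1)
    if complete.sum() < 3:
        raise CompositeError(
            f"module {name!r}: only {int(complete.sum())} animals with complete "
            "members (>= 3 required)"
        )
    ids = std.df.loc[complete, "animal_id"].to_numpy()
    Xc = X[complete]
    Xc = Xc - Xc.mean(axis=0)  # re-center on the complete-case subset

    cov = np.cov(Xc, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    lead = np.argmax(eigvals)
    v = eigvecs[:, lead]
    evf = float(eigvals[lead] / eigvals.sum())
    scores = Xc @ v

    orientation = 1
    row_mean = Xc.mean(axis=1)
    if np.dot(scores, row_mean) < 0:
        v = -v
        scores = -scores
        orientation = -1

    return FeatureModule(
        name=name,
        members=members,
        loadings=v,
        explained_variance_fraction=evf,
        orientation=orientation,
        scores=pd.Series(scores, index=pd.Index(ids, name="animal_id")),
        n_animals=int(complete.sum()),
    )


def append_module_scores(
    table: CohortTable, modules: list[FeatureModule]
) -> CohortTable:
    """Attach each module's composite as a new ``module_<name>`` column.

    Animals without a score (incomplete members) get a missing value.
    """
    out = table.df.copy()
    for mod in modules:
        out[f"module_{mod.name}"] = (
            out["animal_id"].map(mod.scores).astype(float)
        )
    return CohortTable(out, list(table.timepoint_order), dict(table.timepoint_hours))
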