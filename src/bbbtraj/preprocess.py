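"""Feature exclusion and hierarchical subgroup-mean imputation.

Features missing in more than a threshold fraction of animals (default
70%, strict inequality) are dropped outright.  Remaining missing cells
are filled per variable within each group x sex x timepoint subset: with
at least two observed values in the subset the missing cells receive the
subset's arithmetic mean; with fewer than two they stay missing, unless a
global-mean fallback is explicitly requested by a downstream consumer
(PCA, embedding) that needs complete columns.  Observed values are never
altered, so subgroup means are invariant under imputation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable

SUBSET_KEYS = ["group", "sex", "timepoint"]  # canonical logging order


class PreprocessError(ValueError):
    pass


@dataclass
class ImputationEntry:
    animal_id: str
    feature: str
    action: str  # subgroup_mean | left_missing | global_mean
    subset_n: int  # observed values in the subset


@dataclass
class ImputationLog:
    entries: list[ImputationEntry] = field(default_factory=list)
    n_observed_cells: int = 0

    def actions(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries:
            out[e.action] = out.get(e.action, 0) + 1
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_observed_cells": self.n_observed_cells,
            "action_counts": self.actions(),
            "entries": [vars(e) for e in self.entries],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def drop_sparse_features(
    table: CohortTable, max_missing_fraction: float = 0.70
) -> tuple[CohortTable, list[str]]:
    """Remove features missing in strictly more than the threshold
    fraction of animals.  A feature missing in exactly the threshold
    fraction is kept."""
    if not 0.0 < max_missing_fraction <= 1.0:
        raise PreprocessError("max_missing_fraction must be in (0, 1]")
    feats = table.feature_names
    frac = table.df[feats].isna().mean()
    dropped = [f for f in feats if frac[f] > max_missing_fraction]
    kept = [f for f in feats if f not in dropped]
    if not kept:
        raise PreprocessError("every feature exceeds the missingness threshold")
    return table.select_features(kept), dropped


def impute_hierarchical(
    table: CohortTable, allow_global_fallback: bool = False
) -> tuple[CohortTable, ImputationLog]:
    """Fill missing feature cells with subgroup means where possible.

    For each variable and each group x sex x timepoint subset, missing
    cells become the subset mean when >= 2 values are observed there;
    otherwise they stay missing, or — only with ``allow_global_fallback``
    — receive the variable's global mean over all observed values.
    Imputing an already-imputed table is a no-op.
    """
    if not table.feature_names:
        raise PreprocessError("table has no features to impute")
    df = table.df
    feats = table.feature_names
    values = df[feats].to_numpy(dtype=float).copy()
    log = ImputationLog(n_observed_cells=int(np.isfinite(values).sum()))

    cell_codes = df[SUBSET_KEYS].astype(str).agg("|".join, axis=1).to_numpy()
    animal_ids = df["animal_id"].to_numpy()

    for j, feat in enumerate(feats):
        col = values[:, j]
        missing = np.isnan(col)
        if not missing.any():
            continue
        observed = ~missing
        global_mean = col[observed].mean() if observed.any() else np.nan
        for code in sorted(set(cell_codes[missing])):
            in_cell = cell_codes == code
            obs_cell = in_cell & observed
            n_obs = int(obs_cell.sum())
            targets = np.flatnonzero(in_cell & missing)
            if n_obs >= 2:
                col[targets] = col[obs_cell].mean()
                action = "subgroup_mean"
            elif allow_global_fallback and np.isfinite(global_mean):
                col[targets] = global_mean
                action = "global_mean"
            else:
                action = "left_missing"
            for i in targets:
                log.entries.append(
                    ImputationEntry(str(animal_ids[i]), feat, action, n_obs)
                )
        values[:, j] = col

    out = df.copy()
    out[feats] = values
    return (
        CohortTable(out, list(table.timepoint_order), dict(table.timepoint_hours)),
        log,
    )
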