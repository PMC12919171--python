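"""Trajectory testing: per-timepoint Mann-Whitney tests combined by
Fisher's method, a within-timepoint permutation null, and a directional
consistency index.

The trajectory statistic for a feature under a binary contrast (canonical
example: male vs female within injured animals) is

    psi = -2 * sum_i ln p_i,       df = 2k,

where p_i is the two-sided Mann-Whitney p-value at timepoint i and k the
number of usable timepoints.  Under independent null p-values psi follows
a chi-square distribution with 2k degrees of freedom, giving the analytic
combined p.  The permutation variant shuffles contrast labels within each
timepoint stratum and recomputes the whole pipeline, so it stays valid
when the per-timepoint p-values are discrete or the samples small.

Fisher's method ignores direction, so the directional-consistency index
records, per timepoint, the sign of (mean_A - mean_B) and reports the
fraction of timepoints agreeing with the majority direction: values near
1.0 mean a stable effect direction, values near 0.5 a fluctuating one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from . import mwu
from .cohort import CohortTable

P_CLAMP = 1e-15  # floor applied before the log so psi stays finite
SIGN_TOL = 1e-12


class TrajectoryError(ValueError):
    pass


@dataclass(frozen=True)
class Contrast:
    """A binary split of a metadata column, optionally within a filter.

    ``within`` restricts the analysis, e.g. ``{"group": "injured"}`` for
    the male-vs-female comparison among injured animals only.
    """

    column: str = "sex"
    label_a: str = "male"
    label_b: str = "female"
    within: Mapping[str, str] | None = None

    def describe(self) -> str:
        base = f"{self.label_a} vs {self.label_b} on {self.column}"
        if self.within:
            base += " within " + ",".join(f"{k}={v}" for k, v in self.within.items())
        return base


@dataclass
class TimepointTest:
    timepoint: str
    n_a: int
    n_b: int
    u: float | None
    p: float | None
    sign: int
    skipped: bool


@dataclass
class FisherResult:
    psi: float
    df: int
    p_combined: float
    n_clamped: int = 0


@dataclass
class PermutationResult:
    n_perm: int
    seed: int
    p_perm: float
    null_psi: np.ndarray = field(repr=False)


@dataclass
class TrajectoryReport:
    feature: str
    contrast: str
    per_timepoint: list[TimepointTest]
    k: int
    psi: float
    df: int
    p_combined: float
    majority_sign: int | None
    consistency: float
    cumulative_consistency: list[tuple[str, float]]
    permutation: PermutationResult | None = None
    #: the headline consistency is the full-window fraction; the
    #: cumulative curve is an interpretation choice for trajectory plots
    consistency_variant: str = "cumulative-over-ordered-timepoints"

    def to_dict(self) -> dict:
        d = {
            "feature": self.feature,
            "contrast": self.contrast,
            "k": self.k,
            "psi": self.psi,
            "df": self.df,
            "p_combined": self.p_combined,
            "majority_sign": self.majority_sign,
            "consistency": self.consistency,
            "consistency_variant": self.consistency_variant,
            "cumulative_consistency": [
                {"timepoint": tp, "consistency": c}
                for tp, c in self.cumulative_consistency
            ],
            "per_timepoint": [asdict(t) for t in self.per_timepoint],
        }
        if self.permutation is not None:
            d["permutation"] = {
                "n_perm": self.permutation.n_perm,
                "seed": self.permutation.seed,
                "p_perm": self.permutation.p_perm,
            }
        return d


# ----------------------------------------------------------------------
def _apply_within(df: pd.DataFrame, contrast: Contrast) -> pd.DataFrame:
    if contrast.within:
        for col, val in contrast.within.items():
            df = df[df[col] == val]
    return df


def mann_whitney_per_timepoint(
    table: CohortTable,
    feature: str,
    contrast: Contrast,
    min_n: int = 2,
) -> list[TimepointTest]:
    """Two-sided Mann-Whitney U at each timepoint, on observed values.

    Timepoints where either arm has fewer than ``min_n`` observed values
    are marked skipped and excluded from k.  The sign is
    sign(mean_A - mean_B), zero when the means differ by < 1e-12.
    """
    if feature not in table.feature_names:
        raise TrajectoryError(f"feature {feature!r} not in table")
    df = _apply_within(table.df, contrast)
    results: list[TimepointTest] = []
    for tp in table.timepoint_order:
        sub = df[df["timepoint"] == tp]
        a = sub.loc[sub[contrast.column] == contrast.label_a, feature].dropna().to_numpy()
        b = sub.loc[sub[contrast.column] == contrast.label_b, feature].dropna().to_numpy()
        if len(a) < min_n or len(b) < min_n:
            results.append(TimepointTest(tp, len(a), len(b), None, None, 0, True))
            continue
        u, p = mwu.mwu_two_sided(a, b)
        diff = a.mean() - b.mean()
        sign = 0 if abs(diff) < SIGN_TOL else (1 if diff > 0 else -1)
        results.append(TimepointTest(tp, len(a), len(b), u, p, sign, False))
    if all(t.skipped for t in results):
        raise TrajectoryError(
            f"all timepoints skipped for {feature!r} under {contrast.describe()}"
        )
    return results


def fisher_combine(p_list: Sequence[float]) -> FisherResult:
    """Fisher's combined probability: psi = -2 sum ln p_i ~ chi2(2k).

    p-values below 1e-15 are clamped to 1e-15 before the log (the clamp
    count is reported) so psi stays finite.
    """
    if len(p_list) == 0:
        raise TrajectoryError("fisher_combine requires at least one p-value")
    ps = np.asarray(p_list, dtype=float)
    if np.any(ps <= 0) or np.any(ps > 1):
        raise TrajectoryError("p-values must lie in (0, 1]")
    n_clamped = int(np.sum(ps < P_CLAMP))
    ps = np.maximum(ps, P_CLAMP)
    psi = float(-2.0 * np.log(ps).sum())
    df = 2 * len(ps)
    return FisherResult(psi, df, float(chi2.sf(psi, df)), n_clamped)


def directional_consistency(
    per_timepoint: Sequence[TimepointTest],
) -> tuple[int | None, float]:
    """Majority direction and the fraction of timepoints matching it.

    Zero signs never match the majority; on a +/- tie (or all zeros)
    there is no majority and consistency is the tied count over k.
    """
    usable = [t for t in per_timepoint if not t.skipped]
    if not usable:
        raise TrajectoryError("no usable timepoints")
    k = len(usable)
    pos = sum(1 for t in usable if t.sign > 0)
    neg = sum(1 for t in usable if t.sign < 0)
    if pos > neg:
        return 1, pos / k
    if neg > pos:
        return -1, neg / k
    return None, pos / k  # tie (pos == neg), including the all-zero case


def cumulative_consistency(
    per_timepoint: Sequence[TimepointTest],
) -> list[tuple[str, float]]:
    """Consistency over timepoints 1..t for each usable t, in order."""
    usable = [t for t in per_timepoint if not t.skipped]
    curve = []
    for t in range(1, len(usable) + 1):
        _, c = directional_consistency(usable[:t])
        curve.append((usable[t - 1].timepoint, c))
    return curve


# ----------------------------------------------------------------------
def permutation_combined_p(
    table: CohortTable,
    feature: str,
    contrast: Contrast,
    n_perm: int,
    seed: int,
    min_n: int = 2,
) -> PermutationResult:
    """Permutation null for psi: contrast labels are shuffled
    independently within each timepoint stratum (group and timepoint
    fixed), the per-timepoint tests and Fisher statistic recomputed, and

        p_perm = (1 + #{psi_perm >= psi_obs}) / (1 + n_perm).

    The add-one estimator keeps p_perm strictly positive.
    """
    if n_perm < 100:
        raise TrajectoryError("n_perm must be >= 100")
    observed = mann_whitney_per_timepoint(table, feature, contrast, min_n)
    psi_obs = fisher_combine([t.p for t in observed if not t.skipped]).psi

    rng = np.random.default_rng(seed)
    df = _apply_within(table.df, contrast)
    lnp_cols: list[np.ndarray] = []
    any_variation = False
    for tp in table.timepoint_order:
        sub = df[df["timepoint"] == tp]
        sub = sub[sub[contrast.column].isin([contrast.label_a, contrast.label_b])]
        labels = (sub[contrast.column] == contrast.label_a).to_numpy()
        values = sub[feature].to_numpy(dtype=float)
        col = _permuted_lnp_column(values, labels, n_perm, rng, min_n)
        if col is None:
            continue
        any_variation = True
        lnp_cols.append(col)
    if not any_variation:
        raise TrajectoryError(
            "every timepoint stratum is degenerate; permutation null undefined"
        )
    psi_perm = -2.0 * np.sum(lnp_cols, axis=0)
    p_perm = (1 + int(np.sum(psi_perm >= psi_obs - 1e-12))) / (1 + n_perm)
    return PermutationResult(n_perm=n_perm, seed=seed, p_perm=p_perm,
                             null_psi=psi_perm)


def _permuted_lnp_column(
    values: np.ndarray,
    labels: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    min_n: int,
) -> np.ndarray | None:
    """ln p per permutation for one timepoint stratum, or None if the
    stratum never yields a usable test (insufficient n in either arm).

    With complete observations the per-permutation test reduces to a
    rank-sum over a re-labelled pooled sample, so the ranks and tie
    structure are computed once and only label assignments vary — exactly
    the test ``mann_whitney_per_timepoint`` would run on the shuffled
    table, evaluated in vector form.
    """
    n = len(values)
    n_a = int(labels.sum())
    n_b = n - n_a
    if n_a < min_n or n_b < min_n or n_a == 0 or n_b == 0:
        return None
    observed_mask = np.isfinite(values)
    if observed_mask.all():
        ranks = rankdata(values)
        tie_term = mwu.tie_correction_term(values)
        # permuted label matrix: each row an independent shuffle
        keys = rng.random((n_perm, n))
        order = np.argsort(keys, axis=1)
        perm_is_a = labels[order]
        r_a = (ranks[None, :] * perm_is_a).sum(axis=1)
        u1 = r_a - n_a * (n_a + 1) / 2.0
        if n <= mwu.EXACT_MAX_N and tie_term == 0:
            ps = mwu.exact_two_sided_p(np.round(u1).astype(int), n_a, n_b)
        else:
            ps = mwu.asymptotic_two_sided_p(u1, n_a, n_b, tie_term)
        return np.log(np.maximum(ps, P_CLAMP))
    # missing values present: label shuffles change the observed arms'
    # sizes, so fall back to per-permutation evaluation
    out = np.zeros(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        lab = labels[perm]
        a = values[lab & observed_mask]
        b = values[~lab & observed_mask]
        if len(a) < min_n or len(b) < min_n:
            out[i] = 0.0  # skipped timepoint contributes ln 1 = 0
            continue
        _, p = mwu.mwu_two_sided(a, b)
        out[i] = math.log(max(p, P_CLAMP))
    return out


# ----------------------------------------------------------------------
def trajectory_report(
    table: CohortTable,
    feature: str,
    contrast: Contrast,
    min_n: int = 2,
    n_perm: int | None = None,
    seed: int = 0,
) -> TrajectoryReport:
    """Full trajectory analysis of one feature (or module score) column."""
    per_tp = mann_whitney_per_timepoint(table, feature, contrast, min_n)
    usable = [t for t in per_tp if not t.skipped]
    fisher = fisher_combine([t.p for t in usable])
    majority, consistency = directional_consistency(per_tp)
    perm = None
    if n_perm is not None:
        perm = permutation_combined_p(table, feature, contrast, n_perm, seed, min_n)
    return TrajectoryReport(
        feature=feature,
        contrast=contrast.describe(),
        per_timepoint=per_tp,
        k=len(usable),
        psi=fisher.psi,
        df=fisher.df,
        p_combined=fisher.p_combined,
        majority_sign=majority,
        consistency=consistency,
        cumulative_consistency=cumulative_consistency(per_tp),
        permutation=perm,
    )


def trajectory_suite(
    table: CohortTable,
    features: Sequence[str],
    contrast: Contrast,
    min_n: int = 2,
    n_perm: int | None = None,
    seed: int = 0,
) -> list[TrajectoryReport]:
    """One TrajectoryReport per feature; module score columns are treated
    exactly like raw features."""
    reports = []
    for i, feature in enumerate(features):
        reports.append(
            trajectory_report(
                table, feature, contrast, min_n=min_n, n_perm=n_perm,
                seed=seed + i,
            )
        )
    return reports


def reports_to_json(reports: Sequence[TrajectoryReport], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([r.to_dict() for r in reports], indent=2)
    )


def reports_to_csv(reports: Sequence[TrajectoryReport], path: str | Path) -> None:
    """Flat CSV: one row per feature x timepoint plus one summary row."""
    rows = []
    for r in reports:
        for t in r.per_timepoint:
            rows.append(
                {
                    "feature": r.feature, "contrast": r.contrast,
                    "row_type": "timepoint", "timepoint": t.timepoint,
                    "n_a": t.n_a, "n_b": t.n_b, "U": t.u, "p": t.p,
                    "sign": t.sign, "skipped": t.skipped,
                }
            )
        rows.append(
            {
                "feature": r.feature, "contrast": r.contrast,
                "row_type": "summary", "timepoint": "",
                "k": r.k, "psi": r.psi, "df": r.df,
                "p_combined": r.p_combined,
                "p_perm": r.permutation.p_perm if r.permutation else None,
                "majority_sign": r.majority_sign,
                "consistency": r.consistency,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
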