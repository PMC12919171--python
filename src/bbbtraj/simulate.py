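"""Synthetic longitudinal injury cohorts with block-correlated features.

The generator emulates a two-group (sham / injured), two-sex, five-timepoint
(1h, 6h, 1d, 3d, 7d post-injury) study design.  Features come in named
blocks sharing one latent factor each

    x_j = sqrt(rho) * z + sqrt(1 - rho) * eps_j + effect_shift

with ``z`` and ``eps_j`` standard normal, giving exchangeable within-block
correlation ``rho`` and zero correlation between blocks.  Effect shifts are
expressed in marginal-SD units and keyed by (group, sex, timepoint), so
sex-by-injury-by-time patterns can be injected per cell; sham cells are
unshifted under every default template.  Missingness is applied last,
missing-completely-at-random over feature cells only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    DEFAULT_TIMEPOINTS,
    GROUPS,
    META_COLUMNS,
    SEXES,
    CohortTable,
)

EffectKey = tuple[str, str, str]  # (group, sex, timepoint)


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class BlockSpec:
    """One correlated feature block.

    ``loading`` is the exchangeable within-block correlation rho in [0, 1).
    ``noise_sd`` scales the idiosyncratic part; at the default 1.0 each
    feature has unit marginal SD so effect shifts are in SD units.  A
    ``noise_sd`` of 0 together with ``loading`` 0 yields noiseless features
    equal to their configured shift, which is useful for exact directional
    checks.
    """

    name: str
    m: int
    loading: float = 0.0
    effect: Mapping[EffectKey, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    member_names: Sequence[str] | None = None

    def members(self) -> list[str]:
        if self.member_names is not None:
            return list(self.member_names)
        return [f"{self.name}_{j + 1}" for j in range(self.m)]

    def validate(self) -> None:
        if self.m < 1:
            raise SimConfigError(f"block {self.name!r}: m must be >= 1")
        if not 0.0 <= self.loading < 1.0:
            raise SimConfigError(f"block {self.name!r}: loading must be in [0, 1)")
        if self.noise_sd < 0:
            raise SimConfigError(f"block {self.name!r}: noise_sd must be >= 0")
        if self.member_names is not None and len(self.member_names) != self.m:
            raise SimConfigError(f"block {self.name!r}: member_names length != m")
        for key in self.effect:
            g, s, _tp = key
            if g not in GROUPS or s not in SEXES:
                raise SimConfigError(f"block {self.name!r}: bad effect key {key}")


@dataclass
class PhysioSpec:
    """A singleton physiological scalar (apnea duration, righting time, ...).

    All physiological features share one weak latent factor (``loading``
    small by default) so they correlate with each other only loosely and
    with the feature blocks not at all — reproducing the reduced clustering
    such scalars show relative to imaging-derived blocks.
    """

    name: str
    loading: float = 0.1
    effect: Mapping[EffectKey, float] = field(default_factory=dict)
    noise_sd: float = 1.0


@dataclass
class SimConfig:
    """Full statistical specification of a synthetic cohort."""

    n_per_cell: int
    timepoints: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TIMEPOINTS)
    )
    blocks: Sequence[BlockSpec] = field(default_factory=list)
    physio_features: Sequence[PhysioSpec] = field(default_factory=list)
    missing_rate: float = 0.17
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_cell < 1:
            raise SimConfigError("n_per_cell must be a positive integer")
        if not self.timepoints:
            raise SimConfigError("at least one timepoint required")
        if not 0.0 <= self.missing_rate <= 0.5:
            raise SimConfigError("missing_rate must be in [0, 0.5]")
        names = [b.name for b in self.blocks]
        if len(set(names)) != len(names):
            raise SimConfigError("block names must be disjoint")
        for b in self.blocks:
            b.validate()
        feature_names: list[str] = []
        for b in self.blocks:
            feature_names.extend(b.members())
        feature_names.extend(p.name for p in self.physio_features)
        if len(set(feature_names)) != len(feature_names):
            raise SimConfigError("feature names collide across blocks/physio")
        if not feature_names:
            raise SimConfigError("configuration defines no features")

    @property
    def timepoint_order(self) -> list[str]:
        return sorted(self.timepoints, key=lambda tp: self.timepoints[tp])

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        def effect_out(eff: Mapping[EffectKey, float]) -> dict[str, float]:
            return {"/".join(k): float(v) for k, v in eff.items()}

        return {
            "n_per_cell": self.n_per_cell,
            "timepoints": {k: float(v) for k, v in self.timepoints.items()},
            "blocks": [
                {
                    "name": b.name,
                    "m": b.m,
                    "loading": b.loading,
                    "noise_sd": b.noise_sd,
                    "effect": effect_out(b.effect),
                    **(
                        {"member_names": list(b.member_names)}
                        if b.member_names is not None
                        else {}
                    ),
                }
                for b in self.blocks
            ],
            "physio_features": [
                {
                    "name": p.name,
                    "loading": p.loading,
                    "noise_sd": p.noise_sd,
                    "effect": effect_out(p.effect),
                }
                for p in self.physio_features
            ],
            "missing_rate": self.missing_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        def effect_in(eff: Mapping[str, float]) -> dict[EffectKey, float]:
            out: dict[EffectKey, float] = {}
            for k, v in eff.items():
                parts = tuple(k.split("/"))
                if len(parts) != 3:
                    raise SimConfigError(f"effect key {k!r} is not group/sex/timepoint")
                out[parts] = float(v)  # type: ignore[index]
            return out

        blocks = [
            BlockSpec(
                name=b["name"],
                m=int(b["m"]),
                loading=float(b.get("loading", 0.0)),
                noise_sd=float(b.get("noise_sd", 1.0)),
                effect=effect_in(b.get("effect", {})),
                member_names=b.get("member_names"),
            )
            for b in d.get("blocks", [])
        ]
        physio = [
            PhysioSpec(
                name=p["name"],
                loading=float(p.get("loading", 0.1)),
                noise_sd=float(p.get("noise_sd", 1.0)),
                effect=effect_in(p.get("effect", {})),
            )
            for p in d.get("physio_features", [])
        ]
        return cls(
            n_per_cell=int(d["n_per_cell"]),
            timepoints=dict(d.get("timepoints", DEFAULT_TIMEPOINTS)),
            blocks=blocks,
            physio_features=physio,
            missing_rate=float(d.get("missing_rate", 0.17)),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yml", ".yaml"}:
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in {".yml", ".yaml"}:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))


# ----------------------------------------------------------------------
def generate_cohort(
    config: SimConfig, return_latent: bool = False
) -> CohortTable | tuple[CohortTable, pd.DataFrame]:
    """Draw one cohort from ``config``.

    Records are laid out cell by cell (group, sex, timepoint in canonical
    order) with ``n_per_cell`` animals each.  Identical config and seed
    yield an identical table.  With ``return_latent`` the per-animal block
    latent factors are returned alongside (pre-missingness truth, useful
    for validating composite scores).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tps = config.timepoint_order
    cells = [(g, s, tp) for g in GROUPS for s in SEXES for tp in tps]
    n_total = config.n_per_cell * len(cells)

    meta = {
        "animal_id": [f"a{i + 1:04d}" for i in range(n_total)],
        "group": [],
        "sex": [],
        "timepoint": [],
    }
    for g, s, tp in cells:
        meta["group"].extend([g] * config.n_per_cell)
        meta["sex"].extend([s] * config.n_per_cell)
        meta["timepoint"].extend([tp] * config.n_per_cell)

    columns: dict[str, np.ndarray] = {}
    latents: dict[str, np.ndarray] = {}

    shift_vec = _shift_vector(meta, n_total)

    for block in config.blocks:
        z = rng.standard_normal(n_total)
        latents[block.name] = z
        shifts = shift_vec(block.effect)
        root_rho = np.sqrt(block.loading)
        root_eps = np.sqrt(1.0 - block.loading)
        for member in block.members():
            eps = rng.standard_normal(n_total) * block.noise_sd
            columns[member] = root_rho * z + root_eps * eps + shifts

    if config.physio_features:
        w = rng.standard_normal(n_total)  # shared weak physio factor
        for spec in config.physio_features:
            eps = rng.standard_normal(n_total) * spec.noise_sd
            shifts = shift_vec(spec.effect)
            columns[spec.name] = (
                np.sqrt(spec.loading) * w
                + np.sqrt(1.0 - spec.loading) * eps
                + shifts
            )

    df = pd.DataFrame({**meta, **columns})
    table = CohortTable(df, tps, dict(config.timepoints))
    if config.missing_rate > 0:
        # sub-seed derived from the config seed keeps the whole draw
        # reproducible from one integer
        miss_seed = int(np.random.SeedSequence(config.seed).spawn(1)[0].generate_state(1)[0] % (2**31))
        table = inject_missingness(table, config.missing_rate, seed=miss_seed)
    if return_latent:
        lat = pd.DataFrame(latents)
        lat.insert(0, "animal_id", meta["animal_id"])
        return table, lat
    return table


def _shift_vector(meta: Mapping[str, list], n_total: int):
    group = np.asarray(meta["group"])
    sex = np.asarray(meta["sex"])
    tp = np.asarray(meta["timepoint"])

    def apply(effect: Mapping[EffectKey, float]) -> np.ndarray:
        shifts = np.zeros(n_total)
        for (g, s, t), delta in effect.items():
            shifts[(group == g) & (sex == s) & (tp == t)] += delta
        return shifts

    return apply


def inject_missingness(table: CohortTable, rate: float, seed: int) -> CohortTable:
    """Blank each feature cell independently with probability ``rate``.

    Metadata columns are never masked.  ``rate`` must lie in [0, 0.5]; the
    cap guards against degenerate cohorts that no imputation could rescue.
    """
    if not 0.0 <= rate <= 0.5:
        raise SimConfigError("missing rate must be in [0, 0.5]")
    if rate == 0:
        return table.copy()
    rng = np.random.default_rng(seed)
    feats = table.feature_names
    values = table.df[feats].to_numpy(dtype=float).copy()
    mask = rng.random(values.shape) < rate
    values[mask] = np.nan
    out = table.df.copy()
    out[feats] = values
    return CohortTable(out, list(table.timepoint_order), dict(table.timepoint_hours))


# ----------------------------------------------------------------------
# Canonical study templates
# ----------------------------------------------------------------------
def _injured_effect(
    male: Mapping[str, float], female: Mapping[str, float]
) -> dict[EffectKey, float]:
    eff: dict[EffectKey, float] = {}
    for tp, v in male.items():
        eff[("injured", "male", tp)] = v
    for tp, v in female.items():
        eff[("injured", "female", tp)] = v
    return eff


def default_sim_config(seed: int = 0, n_per_cell: int = 8) -> SimConfig:
    """The default synthetic study.

    8 animals per group x sex x timepoint (16 per group per timepoint),
    four correlated blocks mirroring the four feature families (coronal
    vascular, axial vascular, Evans-Blue leakage, local fractal
    dimension), three weakly correlated physiological scalars, and 17%
    missing-completely-at-random cells.  The injury template encodes the
    qualitative pattern the downstream analysis is meant to resolve:
    vascular metrics depressed acutely in injured males and recovering by
    7d, leakage elevated early in both sexes with a faster female decay,
    and shams unshifted throughout.
    """
    vascular_male = {"1h": -1.5, "6h": -1.2, "1d": -0.9, "3d": -0.5, "7d": -0.2}
    leak_male = {"1h": 1.5, "6h": 1.3, "1d": 1.0, "3d": 0.6, "7d": 0.2}
    leak_female = {"1h": 1.6, "6h": 1.0, "1d": 0.4, "3d": 0.2, "7d": 0.1}
    lfd_male = {"1h": 0.8, "6h": 0.6, "1d": 0.4, "3d": 0.2, "7d": 0.1}
    injured_both = {"1h": 1.0, "6h": 1.0, "1d": 1.0, "3d": 1.0, "7d": 1.0}

    blocks = [
        BlockSpec("vascular_coronal", m=5, loading=0.7,
                  effect=_injured_effect(vascular_male, {})),
        BlockSpec("vascular_axial", m=4, loading=0.7,
                  effect=_injured_effect(vascular_male, {})),
        BlockSpec(
            "leakage_evans_blue", m=3, loading=0.6,
            effect=_injured_effect(leak_male, leak_female),
            member_names=["eb_coronal_intdens", "eb_axial_area", "eb_leak_fraction"],
        ),
        BlockSpec("lfd", m=4, loading=0.6, effect=_injured_effect(lfd_male, {})),
    ]
    physio = [
        PhysioSpec("apnea_duration", effect=_injured_effect(injured_both, injured_both)),
        PhysioSpec("righting_time", effect=_injured_effect(injured_both, injured_both)),
        PhysioSpec("weight_change",
                   effect=_injured_effect({k: -0.5 for k in injured_both},
                                          {k: -0.5 for k in injured_both})),
    ]
    return SimConfig(
        n_per_cell=n_per_cell,
        blocks=blocks,
        physio_features=physio,
        missing_rate=0.17,
        seed=seed,
    )


def null_config(seed: int = 0, n_per_cell: int = 8, m: int = 1) -> SimConfig:
    """A cohort with no sex or injury effect anywhere: one independent
    feature block, no missingness.  Used for type-I-error calibration."""
    return SimConfig(
        n_per_cell=n_per_cell,
        blocks=[BlockSpec("null_feature", m=m, loading=0.0)],
        missing_rate=0.0,
        seed=seed,
    )


def constant_direction_config(
    seed: int = 0, shift: float = 1.5, n_per_cell: int = 8
) -> SimConfig:
    """Injured males shifted by ``shift`` SD above females at every
    timepoint on a single feature; sham unshifted; no missingness."""
    eff = {("injured", "male", tp): shift for tp in DEFAULT_TIMEPOINTS}
    return SimConfig(
        n_per_cell=n_per_cell,
        blocks=[BlockSpec("sexdiff", m=1, loading=0.0, effect=eff)],
        missing_rate=0.0,
        seed=seed,
    )


def alternating_direction_config(
    seed: int = 0, shift: float = 1.5, n_per_cell: int = 8, noiseless: bool = True
) -> SimConfig:
    """Sex effect whose sign alternates across the five timepoints.

    With ``noiseless`` the feature is exactly its configured shift
    (loading 0, noise_sd 0), so per-timepoint signs are deterministic:
    +, -, +, -, + in chronological order.
    """
    order = sorted(DEFAULT_TIMEPOINTS, key=DEFAULT_TIMEPOINTS.__getitem__)
    eff = {
        ("injured", "male", tp): (shift if i % 2 == 0 else -shift)
        for i, tp in enumerate(order)
    }
    return SimConfig(
        n_per_cell=n_per_cell,
        blocks=[
            BlockSpec(
                "sexflip", m=1, loading=0.0,
                noise_sd=0.0 if noiseless else 1.0, effect=eff,
            )
        ],
        missing_rate=0.0,
        seed=seed,
    )


def two_block_config(
    seed: int = 0,
    n_per_cell: int = 25,
    m: int = 4,
    rho: float = 0.8,
) -> SimConfig:
    """Two equally sized exchangeable blocks, uncorrelated with each other,
    no effects, no missingness.  25 animals per cell x 20 cells = 500
    animals.  Used for cluster- and composite-recovery checks."""
    return SimConfig(
        n_per_cell=n_per_cell,
        blocks=[
            BlockSpec("block_a", m=m, loading=rho),
            BlockSpec("block_b", m=m, loading=rho),
        ],
        missing_rate=0.0,
        seed=seed,
    )


def strong_separation_config(seed: int = 0, n_per_cell: int = 8) -> SimConfig:
    """Module shifts separating the injured sexes by 3 SD, for embedding
    checks: vascular blocks depressed in injured males only, leakage
    elevated in injured females only, fractal dimension split +/-1.5 SD
    between the injured sexes.  Shams remain unshifted (and hence the two
    sham sexes overlap, as no injury means no effect)."""
    all_tp = {tp: 1.0 for tp in DEFAULT_TIMEPOINTS}

    def scaled(c: float) -> dict[str, float]:
        return {tp: c for tp in all_tp}

    blocks = [
        BlockSpec("vascular_coronal", m=4, loading=0.7,
                  effect=_injured_effect(scaled(-3.0), {})),
        BlockSpec("vascular_axial", m=4, loading=0.7,
                  effect=_injured_effect(scaled(-3.0), {})),
        BlockSpec("leakage_evans_blue", m=3, loading=0.6,
                  effect=_injured_effect({}, scaled(3.0))),
        BlockSpec("lfd", m=4, loading=0.6,
                  effect=_injured_effect(scaled(1.5), scaled(-1.5))),
    ]
    return SimConfig(n_per_cell=n_per_cell, blocks=blocks,
                     missing_rate=0.0, seed=seed)
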