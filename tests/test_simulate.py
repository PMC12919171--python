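"""Synthetic cohort generator: determinism, correlation structure,
effect injection and MCAR missingness."""

import numpy as np
import pytest

from bbbtraj.cohort import GROUPS, SEXES
from bbbtraj.simulate import (
    BlockSpec,
    SimConfig,
    SimConfigError,
    default_sim_config,
    generate_cohort,
    inject_missingness,
    null_config,
)


def _flat_config(n_per_cell, m=1, rho=0.0, missing=0.0, seed=0, effect=None):
    return SimConfig(
        n_per_cell=n_per_cell,
        blocks=[BlockSpec("b", m=m, loading=rho, effect=effect or {})],
        missing_rate=missing,
        seed=seed,
    )


class TestGenerateCohort:
    def test_same_seed_identical_tables(self):
        cfg = default_sim_config(seed=7)
        t1 = generate_cohort(cfg)
        t2 = generate_cohort(cfg)
        assert t1.equals(t2)

    def test_cell_layout(self):
        cfg = _flat_config(n_per_cell=3)
        t = generate_cohort(cfg)
        assert t.n_animals == 3 * 2 * 2 * 5
        counts = t.df.groupby(["group", "sex", "timepoint"]).size()
        assert (counts == 3).all()
        assert set(t.df["group"]) == set(GROUPS)
        assert set(t.df["sex"]) == set(SEXES)

    def test_null_config_mean_within_clt_bound(self):
        # no effects, rho=0: per-feature mean within 4 SE of 0
        cfg = _flat_config(n_per_cell=50, m=3, seed=11)
        t = generate_cohort(cfg)
        n = t.n_animals
        for f in t.feature_names:
            assert abs(t.df[f].mean()) < 4.0 / np.sqrt(n)

    def test_within_block_correlation_near_rho(self):
        cfg = _flat_config(n_per_cell=25, m=4, rho=0.8, seed=3)  # 500 animals
        t = generate_cohort(cfg)
        corr = t.df[t.feature_names].corr().to_numpy()
        off = corr[np.triu_indices(4, k=1)]
        assert 0.72 <= off.mean() <= 0.88

    def test_between_block_correlation_near_zero(self):
        # the between-block correlations share the two block latents, so a
        # single cohort's mean rho-hat has SE ~ 0.8/sqrt(500); averaging
        # over independent cohorts tests the zero-correlation invariant at
        # the 0.05 tolerance with adequate power
        means = []
        for seed in range(10):
            cfg = SimConfig(
                n_per_cell=25,
                blocks=[BlockSpec("a", m=3, loading=0.8),
                        BlockSpec("c", m=3, loading=0.8)],
                missing_rate=0.0,
                seed=seed,
            )
            t = generate_cohort(cfg)
            corr = t.df[t.feature_names].corr()
            means.append(
                corr.loc[["a_1", "a_2", "a_3"], ["c_1", "c_2", "c_3"]].to_numpy().mean()
            )
        assert abs(np.mean(means)) < 0.05

    def test_effect_shift_recovered_in_cell_means(self):
        shift = 1.2
        eff = {("injured", "male", "1h"): shift}
        cfg = _flat_config(n_per_cell=200, effect=eff, seed=9)
        t = generate_cohort(cfg)
        df = t.df
        cell = lambda g, s: df[
            (df.group == g) & (df.sex == s) & (df.timepoint == "1h")
        ]["b_1"]
        diff = cell("injured", "male").mean() - cell("sham", "male").mean()
        se = np.sqrt(2.0 / 200)
        assert abs(diff - shift) < 4 * se
        # shams never shifted
        assert abs(cell("sham", "male").mean()) < 4 / np.sqrt(200)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_per_cell=0),
            dict(n_per_cell=2, rho=1.0),
            dict(n_per_cell=2, missing=0.9),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        missing = kwargs.pop("missing", 0.0)
        rho = kwargs.pop("rho", 0.0)
        cfg = _flat_config(kwargs["n_per_cell"], rho=rho, missing=missing)
        with pytest.raises(SimConfigError):
            generate_cohort(cfg)

    def test_latent_factor_alignment(self):
        cfg = _flat_config(n_per_cell=25, m=4, rho=0.8, seed=2)
        t, lat = generate_cohort(cfg, return_latent=True)
        x = t.df[t.feature_names].mean(axis=1)
        r = np.corrcoef(x, lat["b"])[0, 1]
        assert r > 0.9


class TestInjectMissingness:
    def test_rate_zero_is_identity(self):
        t = generate_cohort(_flat_config(4, m=2, seed=1))
        assert inject_missingness(t, 0.0, seed=3).equals(t)

    def test_observed_rate_within_binomial_band(self):
        # 10,000 cells at rate 0.17: +/- 4 binomial SE
        cfg = _flat_config(n_per_cell=25, m=20, seed=8)  # 500 x 20 = 10,000
        t = generate_cohort(cfg)
        masked = inject_missingness(t, 0.17, seed=4)
        frac = masked.df[masked.feature_names].isna().to_numpy().mean()
        assert 0.155 <= frac <= 0.185

    def test_metadata_never_masked(self):
        t = generate_cohort(_flat_config(10, m=3, seed=1))
        masked = inject_missingness(t, 0.5, seed=2)
        assert not masked.df[["animal_id", "group", "sex", "timepoint"]].isna().any().any()

    def test_rate_above_cap_rejected(self):
        t = generate_cohort(_flat_config(2, seed=0))
        with pytest.raises(SimConfigError):
            inject_missingness(t, 1.0, seed=0)


def test_csv_round_trip(tmp_path):
    t = generate_cohort(default_sim_config(seed=3, n_per_cell=2))
    path = tmp_path / "cohort.csv"
    t.to_csv(path)
    back = type(t).from_csv(path)
    assert back.timepoint_order == t.timepoint_order
    assert np.allclose(
        back.df[t.feature_names].to_numpy(),
        t.df[t.feature_names].to_numpy(),
        equal_nan=True,
    )


def test_null_config_has_no_effects():
    t = generate_cohort(null_config(seed=0, n_per_cell=40))
    inj = t.df[t.df.group == "injured"]
    m = inj[inj.sex == "male"]["null_feature_1"]
    f = inj[inj.sex == "female"]["null_feature_1"]
    se = np.sqrt(1 / len(m) + 1 / len(f))
    assert abs(m.mean() - f.mean()) < 4 * se
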