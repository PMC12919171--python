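"""Per-timepoint Mann-Whitney tests, Fisher's combined statistic,
permutation null and directional consistency."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.special import gamma

from bbbtraj.simulate import (
    constant_direction_config,
    generate_cohort,
    null_config,
)
from bbbtraj.trajectory import (
    Contrast,
    TimepointTest,
    TrajectoryError,
    directional_consistency,
    fisher_combine,
    mann_whitney_per_timepoint,
    permutation_combined_p,
    trajectory_report,
    trajectory_suite,
)

from conftest import make_table

INJ_SEX = Contrast(within={"group": "injured"})


def _two_sample_table(a_by_tp, b_by_tp):
    rows = []
    i = 0
    for tp, vals in a_by_tp.items():
        for v in vals:
            rows.append((f"m{i}", "injured", "male", tp, {"x": float(v)}))
            i += 1
    for tp, vals in b_by_tp.items():
        for v in vals:
            rows.append((f"f{i}", "injured", "female", tp, {"x": float(v)}))
            i += 1
    return make_table(rows)


def exhaustive_mwu_p(a, b):
    """Oracle: exact two-sided p by enumerating every rank assignment."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(combo)].sum() - n1 * (n1 + 1) / 2)
    us = np.array(us)
    lower = np.mean(us <= u_obs)
    upper = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lower, upper))


def chi2_sf_quadrature(x, df):
    """Oracle: upper-tail chi-square probability by numerical integration."""
    dens = lambda t: t ** (df / 2 - 1) * math.exp(-t / 2) / (
        2 ** (df / 2) * gamma(df / 2)
    )
    # integrate the finite lower interval and complement: tighter
    # quadrature error than an infinite upper limit
    val, err = quad(dens, 0.0, x, limit=200)
    assert err < 1e-11  # well inside the 1e-10 comparison tolerance
    return 1.0 - val


class TestMannWhitneyPerTimepoint:
    def test_separated_samples_match_enumeration(self, tiny_table):
        (res,) = mann_whitney_per_timepoint(tiny_table, "x", INJ_SEX)
        assert res.u == 0.0
        assert res.p == pytest.approx(0.1)
        assert res.p == pytest.approx(
            exhaustive_mwu_p(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        )
        assert res.sign == -1  # males lower

    def test_identical_multisets_give_p_one(self):
        t = _two_sample_table({"1h": [1, 2, 2, 3]}, {"1h": [1, 2, 2, 3]})
        (res,) = mann_whitney_per_timepoint(t, "x", INJ_SEX)
        assert res.p == pytest.approx(1.0)
        assert res.sign == 0

    def test_small_arm_skipped_and_excluded_from_k(self):
        t = _two_sample_table(
            {"1h": [1, 2, 3], "6h": [1, 2, 3]}, {"1h": [4, 5], "6h": [4]}
        )
        res = mann_whitney_per_timepoint(t, "x", INJ_SEX, min_n=2)
        by_tp = {r.timepoint: r for r in res}
        assert not by_tp["1h"].skipped
        assert by_tp["6h"].skipped
        rep = trajectory_report(t, "x", INJ_SEX)
        assert rep.k == 1 and rep.df == 2

    def test_missing_feature_is_error(self, tiny_table):
        with pytest.raises(TrajectoryError):
            mann_whitney_per_timepoint(tiny_table, "nope", INJ_SEX)

    def test_random_cases_match_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 6))
            b = rng.normal(size=rng.integers(2, 6))
            t = _two_sample_table({"1h": a}, {"1h": b})
            (res,) = mann_whitney_per_timepoint(t, "x", INJ_SEX)
            assert res.p == pytest.approx(exhaustive_mwu_p(a, b))


class TestFisherCombine:
    def test_all_ones_gives_zero_statistic(self):
        res = fisher_combine([1.0] * 5)
        assert res.psi == 0.0
        assert res.df == 10
        assert res.p_combined == pytest.approx(1.0)

    def test_closed_form_two_pvalues(self):
        res = fisher_combine([0.05, 0.05])
        assert res.psi == pytest.approx(11.9829, abs=5e-5)
        assert res.df == 4

    def test_agrees_with_quadrature_oracle(self):
        res = fisher_combine([0.05] * 5)
        assert res.psi == pytest.approx(29.9573, abs=5e-5)
        assert res.p_combined == pytest.approx(
            chi2_sf_quadrature(res.psi, 10), abs=1e-10
        )

    def test_tiny_pvalues_clamped(self):
        res = fisher_combine([1e-300, 0.5])
        assert math.isfinite(res.psi)
        assert res.n_clamped == 1

    @pytest.mark.parametrize("bad", [[], [0.0], [-0.1], [1.5]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(TrajectoryError):
            fisher_combine(bad)

    @settings(derandomize=True, max_examples=40)
    @given(
        st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=6),
        st.integers(0, 5),
    )
    def test_psi_monotone_decreasing_in_each_p(self, ps, idx):
        idx = idx % len(ps)
        res = fisher_combine(ps)
        smaller = list(ps)
        smaller[idx] = smaller[idx] / 2
        assert fisher_combine(smaller).psi >= res.psi

    def test_removing_unit_pvalue_keeps_psi_but_raises_significance_never(self):
        with_one = fisher_combine([0.05, 0.05, 1.0])
        without = fisher_combine([0.05, 0.05])
        assert with_one.psi == pytest.approx(without.psi)
        assert with_one.df == without.df + 2
        assert without.p_combined <= with_one.p_combined


def _tp(sign, skipped=False):
    return TimepointTest("1h", 3, 3, 0.0, 0.5, sign, skipped)


class TestDirectionalConsistency:
    @pytest.mark.parametrize(
        "signs, majority, consistency",
        [
            ([1, 1, 1, 1, 1], 1, 1.0),
            ([1, 1, 1, -1, -1], 1, 0.6),
            ([1, -1, 1, -1], None, 0.5),
            ([0, 0, 0], None, 0.0),
            ([1, 1, 0, -1], 1, 0.5),
        ],
    )
    def test_majority_and_fraction(self, signs, majority, consistency):
        tests = [_tp(s) for s in signs]
        got_majority, got_c = directional_consistency(tests)
        assert got_majority == majority
        assert got_c == pytest.approx(consistency)

    def test_skipped_timepoints_ignored(self):
        tests = [_tp(1), _tp(1), _tp(-1, skipped=True)]
        majority, c = directional_consistency(tests)
        assert majority == 1 and c == 1.0

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.sampled_from([-1, 0, 1]), min_size=1, max_size=8))
    def test_consistency_on_grid_and_unity_iff_unanimous_nonzero(self, signs):
        tests = [_tp(s) for s in signs]
        _, c = directional_consistency(tests)
        k = len(signs)
        assert any(c == pytest.approx(j / k) for j in range(k + 1))
        unanimous = len(set(signs)) == 1 and signs[0] != 0
        assert (c == pytest.approx(1.0)) == unanimous


class TestPermutation:
    def test_constant_values_give_p_one(self):
        t = _two_sample_table(
            {"1h": [2, 2, 2], "6h": [2, 2, 2]}, {"1h": [2, 2, 2], "6h": [2, 2, 2]}
        )
        res = permutation_combined_p(t, "x", INJ_SEX, n_perm=100, seed=0)
        assert res.p_perm == pytest.approx(1.0)

    def test_fixed_seed_reproducible(self):
        t = generate_cohort(null_config(seed=3))
        a = permutation_combined_p(t, "null_feature_1", INJ_SEX, 200, seed=9)
        b = permutation_combined_p(t, "null_feature_1", INJ_SEX, 200, seed=9)
        assert a.p_perm == b.p_perm
        assert np.array_equal(a.null_psi, b.null_psi)

    def test_add_one_estimator_strictly_positive(self):
        t = generate_cohort(constant_direction_config(seed=2, shift=3.0))
        res = permutation_combined_p(t, "sexdiff_1", INJ_SEX, 100, seed=1)
        assert res.p_perm == pytest.approx(1 / 101)

    def test_degenerate_strata_rejected(self):
        rows = [(f"m{i}", "injured", "male", "1h", {"x": float(i)}) for i in range(4)]
        with pytest.raises(TrajectoryError):
            permutation_combined_p(make_table(rows), "x", INJ_SEX, 100, seed=0)

    def test_small_nperm_rejected(self, tiny_table):
        with pytest.raises(TrajectoryError):
            permutation_combined_p(tiny_table, "x", INJ_SEX, 50, seed=0)

    def test_null_agreement_with_analytic_p(self):
        # on exchangeable data the permutation and analytic combined
        # p-values estimate the same quantity
        ps_perm, ps_ana = [], []
        for seed in range(30):
            t = generate_cohort(null_config(seed=100 + seed))
            rep = trajectory_report(t, "null_feature_1", INJ_SEX, n_perm=300,
                                    seed=seed)
            ps_perm.append(rep.permutation.p_perm)
            ps_ana.append(rep.p_combined)
        r = np.corrcoef(ps_perm, ps_ana)[0, 1]
        assert r > 0.9


class TestSuite:
    def test_empty_feature_list(self, tiny_table):
        assert trajectory_suite(tiny_table, [], INJ_SEX) == []

    def test_module_scores_treated_like_features(self):
        t = generate_cohort(constant_direction_config(seed=5))
        t.df["module_fake"] = t.df["sexdiff_1"]
        raw = trajectory_report(t, "sexdiff_1", INJ_SEX)
        mod = trajectory_report(t, "module_fake", INJ_SEX)
        assert raw.psi == pytest.approx(mod.psi)

    def test_cumulative_consistency_curve_is_prefix_consistency(self):
        t = generate_cohort(constant_direction_config(seed=6, shift=3.0))
        rep = trajectory_report(t, "sexdiff_1", INJ_SEX)
        assert [tp for tp, _ in rep.cumulative_consistency] == t.timepoint_order
        assert rep.cumulative_consistency[-1][1] == pytest.approx(rep.consistency)

    def test_report_round_trip(self, tmp_path):
        from bbbtraj.trajectory import reports_to_csv, reports_to_json

        t = generate_cohort(null_config(seed=4))
        reps = trajectory_suite(t, ["null_feature_1"], INJ_SEX, n_perm=100, seed=0)
        reports_to_json(reps, tmp_path / "r.json")
        reports_to_csv(reps, tmp_path / "r.csv")
        assert (tmp_path / "r.json").stat().st_size > 0
        assert (tmp_path / "r.csv").stat().st_size > 0
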