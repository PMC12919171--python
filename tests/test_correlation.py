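"""Spearman matrix, UPGMA clustering on correlation rows, module cut."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bbbtraj.correlation import (
    CorrelationError,
    CorrelationStructure,
    cluster_features,
    propose_modules,
    spearman_matrix,
)
from bbbtraj.simulate import generate_cohort, two_block_config

from conftest import make_table


def _paired_table(x, y):
    rows = [
        (f"a{i}", "injured", "male", "1h", {"x": float(xi), "y": float(yi)})
        for i, (xi, yi) in enumerate(zip(x, y))
    ]
    return make_table(rows)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.arange(10, dtype=float)
        s = spearman_matrix(_paired_table(x, 2 * x + 1))
        assert s.rho.loc["x", "y"] == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.arange(10, dtype=float)
        s = spearman_matrix(_paired_table(x, -x))
        assert s.rho.loc["x", "y"] == pytest.approx(-1.0)

    def test_equals_pearson_of_ranks(self):
        # hand oracle: ranks of y=(1,3,2,5,4) against x=(1..5), Pearson of
        # rank vectors = 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 6*4/120 = 0.8
        s = spearman_matrix(_paired_table([1, 2, 3, 4, 5], [1, 3, 2, 5, 4]))
        assert s.rho.loc["x", "y"] == pytest.approx(0.8)

    def test_pairwise_complete_and_min_pairs(self):
        rows = [
            ("a1", "sham", "male", "1h", {"x": 1.0, "y": 2.0}),
            ("a2", "sham", "male", "1h", {"x": 2.0, "y": 1.0}),
            ("a3", "sham", "male", "1h", {"x": 3.0}),
            ("a4", "sham", "male", "1h", {"x": 4.0}),
        ]
        s = spearman_matrix(make_table(rows), min_pairs=3)
        assert np.isnan(s.rho.loc["x", "y"])
        assert s.undefined_pairs == [("x", "y")]

    @settings(derandomize=True, max_examples=25)
    @given(st.permutations(list(range(8))))
    def test_invariant_under_strictly_monotone_transform(self, perm):
        x = np.array(perm, dtype=float)
        y = np.arange(8, dtype=float)
        base = spearman_matrix(_paired_table(x, y)).rho.loc["x", "y"]
        warped = spearman_matrix(_paired_table(np.exp(x / 3), y)).rho.loc["x", "y"]
        assert warped == pytest.approx(base)


def _structure_from_rows(rows: np.ndarray, names) -> CorrelationStructure:
    # cluster_features only consumes the row vectors of the matrix, so a
    # fixture may pin arbitrary row geometry to force known distances
    rho = pd.DataFrame(np.asarray(rows, dtype=float), index=names)
    return CorrelationStructure(features=list(names), rho=rho)


class TestClusterFeatures:
    def test_identical_rows_merge_at_zero(self):
        rows = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        s = _structure_from_rows(rows, ["A", "B", "C"])
        out = cluster_features(s)
        assert out.linkage_matrix[0, 2] == pytest.approx(0.0)
        assert set(out.linkage_matrix[0, :2].astype(int)) == {0, 1}

    def test_manual_upgma_heights(self):
        # rows chosen so d(AB)=1, d(AC)=4, d(BC)=5; UPGMA merges (A,B) at
        # height 1 then joins C at (4+5)/2 = 4.5 (hand computation)
        rows = np.array([[0.0, 0.0], [1.0, 0.0], [-4.0, 0.0]])
        s = _structure_from_rows(rows, ["A", "B", "C"])
        out = cluster_features(s)
        assert out.linkage_matrix[0, 2] == pytest.approx(1.0)
        assert out.linkage_matrix[1, 2] == pytest.approx(4.5)

    def test_undefined_entries_rejected(self):
        rho = pd.DataFrame(
            [[1.0, np.nan], [np.nan, 1.0]], index=["x", "y"], columns=["x", "y"]
        )
        s = CorrelationStructure(["x", "y"], rho, undefined_pairs=[("x", "y")])
        with pytest.raises(CorrelationError, match="undefined"):
            cluster_features(s)

    def test_two_block_membership_recovered(self):
        t = generate_cohort(two_block_config(seed=13))
        s = cluster_features(spearman_matrix(t))
        modules = propose_modules(s, 2)
        got = [set(m) for _, m in modules]
        want = [
            {f"block_a_{i}" for i in range(1, 5)},
            {f"block_b_{i}" for i in range(1, 5)},
        ]
        assert got == want or got == want[::-1]


class TestProposeModules:
    def test_cut_just_below_n_features_pairs_one_merge(self):
        t = generate_cohort(two_block_config(seed=1, n_per_cell=5))
        s = cluster_features(spearman_matrix(t))
        n = len(s.features)
        modules = propose_modules(s, n - 1)
        sizes = sorted(len(m) for _, m in modules)
        assert sizes == [1] * (n - 2) + [2]

    @pytest.mark.parametrize("k", [1, 99])
    def test_degenerate_cut_rejected(self, k):
        t = generate_cohort(two_block_config(seed=1, n_per_cell=5))
        s = cluster_features(spearman_matrix(t))
        with pytest.raises(CorrelationError):
            propose_modules(s, k)


def test_leaf_order_places_blocks_contiguously():
    t = generate_cohort(two_block_config(seed=3))
    s = cluster_features(spearman_matrix(t))
    R = s.rho.loc[s.leaf_order, s.leaf_order].to_numpy()
    half = len(s.leaf_order) // 2
    within = np.concatenate(
        [R[:half, :half][np.triu_indices(half, 1)],
         R[half:, half:][np.triu_indices(half, 1)]]
    )
    between = R[:half, half:].ravel()
    assert within.mean() > between.mean()
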