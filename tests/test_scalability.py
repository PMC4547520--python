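"""Guttman-error counting, scalability coefficients, and their identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nartscale import (
    ItemResponseMatrix,
    ScaleStrength,
    classify_strength,
    guttman,
    guttman_errors,
    item_scalability,
    pair_scalability,
    scale_scalability,
)
from nartscale.scalability import DegenerateItemError, pair_error_matrices

from conftest import matrix_from_rows


def covariance_ratio(m: ItemResponseMatrix, i: int, j: int) -> float:
    """Independent oracle: H_ij as cov / cov_max with cov_max computed
    from the (easier, harder) ordering by sample proportion."""
    x, y = m.values[:, i].astype(float), m.values[:, j].astype(float)
    p = m.proportions()
    if p[i] > p[j] or (p[i] == p[j] and i < j):
        pe, ph = p[i], p[j]
    else:
        pe, ph = p[j], p[i]
    cov = np.mean(x * y) - x.mean() * y.mean()
    cov_max = ph * (1.0 - pe)
    return cov / cov_max


class TestGuttmanErrors:
    @pytest.mark.parametrize(
        "col_i, col_j, observed, expected",
        [
            ((1, 1, 1, 0), (1, 1, 0, 0), 0, 0.5),
            ((1, 1, 1, 1, 0), (1, 1, 0, 0, 1), 1, 0.6),
        ],
    )
    def test_counts_match_direct_enumeration(
        self, col_i, col_j, observed, expected
    ):
        m = matrix_from_rows(np.column_stack([col_i, col_j]))
        g = guttman_errors(m, 0, 1)
        assert g.observed == observed
        assert g.expected == pytest.approx(expected)

    def test_nested_pair_has_zero_observed_errors(self, staircase):
        for j in range(1, staircase.n_items):
            assert guttman_errors(staircase, 0, j).observed == 0

    def test_degenerate_item_rejected(self):
        m = matrix_from_rows([[1, 1], [1, 0], [1, 1]])
        with pytest.raises(DegenerateItemError):
            guttman_errors(m, 0, 1)


class TestPairScalability:
    @pytest.mark.parametrize(
        "col_i, col_j, expected",
        [
            ((1, 1, 1, 0), (1, 1, 0, 0), 1.0),
            ((1, 1, 0, 0), (0, 0, 1, 1), -1.0),
            ((1, 1, 1, 1, 0), (1, 1, 0, 0, 1), -2.0 / 3.0),
        ],
    )
    def test_error_ratio_values(self, col_i, col_j, expected):
        m = matrix_from_rows(np.column_stack([col_i, col_j]))
        h = pair_scalability(m, 0, 1)
        assert h == pytest.approx(expected, abs=1e-12)
        assert h == pytest.approx(covariance_ratio(m, 0, 1), abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**60 - 1))
    def test_error_ratio_equals_covariance_ratio(self, seed):
        rng = np.random.default_rng(seed)
        values = (rng.random((10, 6)) < rng.uniform(0.2, 0.8, 6)).astype(int)
        p = values.mean(axis=0)
        ok = (p > 0) & (p < 1)
        if ok.sum() < 2:
            return
        m = ItemResponseMatrix(
            values[:, ok], tuple(f"i{k}" for k in range(int(ok.sum())))
        )
        for i in range(m.n_items):
            for j in range(i + 1, m.n_items):
                assert pair_scalability(m, i, j) == pytest.approx(
                    covariance_ratio(m, i, j), abs=1e-10
                )


class TestItemAndScale:
    def test_perfect_scalogram_yields_unit_coefficients(self, staircase):
        coefs = scale_scalability(staircase, se=None)
        assert coefs.h_scale == pytest.approx(1.0)
        assert coefs.h_item == pytest.approx(np.ones(staircase.n_items))
        off_diag = coefs.h_pair[~np.isnan(coefs.h_pair)]
        assert off_diag == pytest.approx(np.ones_like(off_diag))

    def test_item_scalability_ratio_of_sums(self):
        # brute force over the two pairs involving item 1
        m = matrix_from_rows([(1, 1, 1), (1, 1, 0), (1, 0, 0), (0, 0, 0)])
        assert item_scalability(m, 1) == pytest.approx(1.0)

    def test_independent_item_scalability_near_zero(self):
        rng = np.random.default_rng(11)
        n = 5000
        theta = rng.standard_normal(n)
        related = (
            rng.random((n, 3))
            < 1 / (1 + np.exp(-2 * (theta[:, None] - [[-0.5, 0.0, 0.5]])))
        ).astype(int)
        noise = (rng.random(n) < 0.5).astype(int)
        m = ItemResponseMatrix(
            np.column_stack([related, noise]), ("a", "b", "c", "noise")
        )
        # 3 MC standard errors for an H_i built from ~n/4 expected errors
        assert abs(item_scalability(m, 3)) < 0.06

    def test_independent_pair_scale_h_within_3_se(self):
        rng = np.random.default_rng(5)
        values = (rng.random((5000, 2)) < 0.5).astype(int)
        m = ItemResponseMatrix(values, ("x", "y"))
        coefs = scale_scalability(m, n_boot=300, seed=0)
        assert coefs.se_scale is not None and coefs.se_scale > 0
        assert abs(coefs.h_scale) < 3 * coefs.se_scale

    def test_single_pair_reduction(self):
        m = matrix_from_rows(np.column_stack([(1, 1, 1, 0), (1, 1, 0, 0)]))
        assert scale_scalability(m, se=None).h_scale == pytest.approx(1.0)

    def test_degenerate_items_reported_not_silently_dropped(self):
        m = matrix_from_rows([(1, 1, 0), (1, 0, 1), (1, 1, 0), (1, 0, 1)])
        coefs = scale_scalability(m, se=None)
        assert coefs.degenerate == (0,)
        assert np.isnan(coefs.h_item[0])

    def test_row_permutation_invariance_and_column_consistency(self):
        rng = np.random.default_rng(3)
        values = (rng.random((60, 5)) < [0.3, 0.45, 0.6, 0.7, 0.8]).astype(int)
        m = ItemResponseMatrix(values, tuple("abcde"))
        base = scale_scalability(m, se=None)
        perm_rows = ItemResponseMatrix(
            values[rng.permutation(60)], m.item_labels
        )
        shuffled = scale_scalability(perm_rows, se=None)
        assert shuffled.h_scale == pytest.approx(base.h_scale)
        assert shuffled.h_item == pytest.approx(base.h_item)
        cols = rng.permutation(5)
        perm_cols = m.select(list(cols))
        permuted = scale_scalability(perm_cols, se=None)
        assert permuted.h_scale == pytest.approx(base.h_scale)
        assert permuted.h_item == pytest.approx(base.h_item[cols])
        assert permuted.h_pair == pytest.approx(
            base.h_pair[np.ix_(cols, cols)], nan_ok=True
        )

    def test_pair_error_matrices_symmetry(self):
        rng = np.random.default_rng(4)
        values = (rng.random((40, 4)) < 0.5).astype(int)
        m = ItemResponseMatrix(values, tuple("abcd"))
        F, E, _ = pair_error_matrices(m)
        assert np.allclose(F, F.T, equal_nan=True)
        assert np.allclose(E, E.T, equal_nan=True)


class TestClassifyStrength:
    @pytest.mark.parametrize(
        "h, expected",
        [
            (0.534, ScaleStrength.STRONG),
            (0.471, ScaleStrength.MEDIUM),
            (0.3, ScaleStrength.WEAK),
            (0.29, ScaleStrength.UNSCALABLE),
            (0.5, ScaleStrength.STRONG),
            (0.4, ScaleStrength.MEDIUM),
        ],
    )
    def test_bands(self, h, expected):
        assert classify_strength(h) is expected

    def test_h_above_one_rejected(self):
        with pytest.raises(ValueError):
            classify_strength(1.2)


def test_guttman_generator_rows():
    m = guttman(4, 3)
    assert m.values.tolist() == [[1, 1, 1], [1, 1, 0], [1, 0, 0], [0, 0, 0]]
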