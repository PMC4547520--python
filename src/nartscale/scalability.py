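"""Loevinger-type scalability coefficients for dichotomous items.

For an item pair ordered by sample difficulty (the item with the higher
proportion correct is the *easier* one), a Guttman error is the response
pattern "harder item passed, easier item failed".  With observed error
count F_ij and the count E_ij = N * P(easier = 0) * P(harder = 1) expected
under marginal independence, the pair scalability coefficient is

    H_ij = 1 - F_ij / E_ij,

algebraically equal to cov(X_i, X_j) / cov_max where
cov_max = P(harder = 1) * (1 - P(easier = 1)).  Item and scale coefficients
aggregate error counts as ratios of sums:

    H_i = 1 - sum_j F_ij / sum_j E_ij,      H = 1 - sum sum F / sum sum E.

H_i expresses item discrimination (akin to an item-test correlation or a
factor loading); H the strength of the scale as a whole, with the usual
rule of thumb: < 0.3 unscalable, 0.3-0.4 weak, 0.4-0.5 medium, >= 0.5
strong.  H = 1 exactly when the data form a perfect Guttman scalogram.

Standard errors are obtained by a seeded nonparametric bootstrap over
respondents.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats as sps

from .data_io import ItemResponseMatrix

__all__ = [
    "GuttmanErrorCount",
    "ScalabilityCoefficients",
    "ScaleStrength",
    "guttman_errors",
    "pair_scalability",
    "item_scalability",
    "scale_scalability",
    "classify_strength",
    "pair_error_matrices",
    "pair_z_positive",
]


class DegenerateItemError(ValueError):
    """An operation required an item with nonzero variance."""


@dataclass(frozen=True)
class GuttmanErrorCount:
    """Observed and independence-expected Guttman error counts for a pair."""

    observed: int
    expected: float
    easier: int
    harder: int


class ScaleStrength(str, Enum):
    UNSCALABLE = "unscalable"
    WEAK = "weak"
    MEDIUM = "medium"
    STRONG = "strong"


@dataclass(frozen=True)
class ScalabilityCoefficients:
    """H_ij matrix, H_i vector and scale H with bootstrap standard error.

    ``h_pair`` is symmetric with NaN on the diagonal and on any pair
    involving a degenerate (zero-variance) item; degenerate items also get
    NaN in ``h_item`` and are excluded from all error sums.
    """

    h_pair: np.ndarray
    h_item: np.ndarray
    h_scale: float
    se_scale: float | None
    n_persons: int
    item_labels: tuple[str, ...]
    degenerate: tuple[int, ...] = ()

    @property
    def strength(self) -> ScaleStrength:
        return classify_strength(self.h_scale)

    def to_dict(self) -> dict:
        return {
            "item_labels": list(self.item_labels),
            "h_pair": self.h_pair,
            "h_item": self.h_item,
            "h_scale": self.h_scale,
            "se_scale": self.se_scale,
            "n_persons": self.n_persons,
            "degenerate_items": list(self.degenerate),
            "strength": self.strength.value,
        }


def _order_pair(p: np.ndarray, i: int, j: int) -> tuple[int, int]:
    """Return (easier, harder) for a pair; difficulty ties break by column
    order, the lower index counting as easier (a fixed administration-order
    convention; H_ij itself is unchanged under the symmetric tie)."""
    if p[i] > p[j] or (p[i] == p[j] and i < j):
        return i, j
    return j, i


def guttman_errors(m: ItemResponseMatrix, i: int, j: int) -> GuttmanErrorCount:
    """Observed and expected Guttman error counts for item pair (i, j)."""
    if i == j:
        raise ValueError("a pair needs two distinct items")
    X = m.values
    p = m.proportions()
    for k in (i, j):
        if p[k] in (0.0, 1.0):
            raise DegenerateItemError(
                f"item {m.item_labels[k]!r} has zero variance"
            )
    e, h = _order_pair(p, i, j)
    observed = int(np.sum((X[:, e] == 0) & (X[:, h] == 1)))
    expected = m.n_persons * (1.0 - p[e]) * p[h]
    return GuttmanErrorCount(observed, expected, e, h)


def pair_scalability(m: ItemResponseMatrix, i: int, j: int) -> float:
    """H_ij = 1 - observed/expected Guttman errors for the ordered pair."""
    g = guttman_errors(m, i, j)
    if g.expected == 0.0:
        raise DegenerateItemError("expected error count is zero")
    return 1.0 - g.observed / g.expected


def pair_error_matrices(
    m: ItemResponseMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (F, E, degenerate-mask) over all ordered pairs.

    ``F[i, j]`` and ``E[i, j]`` are the observed/expected error counts for
    the unordered pair {i, j} (symmetric); entries involving a degenerate
    item are NaN.  The ordering inside each pair follows sample difficulty
    with the column-order tie rule.
    """
    X = m.values.astype(np.float64)
    n, J = X.shape
    p = X.mean(axis=0)
    both = X.T @ X                      # count(i=1 & j=1)
    n1 = X.sum(axis=0)
    # count(row: a=0, b=1) = n1[b] - both[a, b]
    f_ab = n1[None, :] - both           # f_ab[a, b] = #(a=0, b=1)
    idx = np.arange(J)
    # easier[i, j] = True where i is the easier of the pair
    i_easier = (p[:, None] > p[None, :]) | (
        (p[:, None] == p[None, :]) & (idx[:, None] < idx[None, :])
    )
    F = np.where(i_easier, f_ab, f_ab.T)
    E = np.where(
        i_easier,
        n * (1.0 - p[:, None]) * p[None, :],
        n * (1.0 - p[None, :]) * p[:, None],
    )
    degenerate = (p == 0.0) | (p == 1.0)
    bad = degenerate[:, None] | degenerate[None, :]
    F = np.where(bad, np.nan, F)
    E = np.where(bad, np.nan, E)
    np.fill_diagonal(F, np.nan)
    np.fill_diagonal(E, np.nan)
    return F, E, degenerate


def item_scalability(m: ItemResponseMatrix, i: int) -> float:
    """H_i: 1 minus the ratio of summed observed to summed expected errors
    over all non-degenerate pairs involving item i."""
    F, E, degenerate = pair_error_matrices(m)
    if degenerate[i]:
        raise DegenerateItemError(
            f"item {m.item_labels[i]!r} has zero variance"
        )
    f_sum = np.nansum(F[i])
    e_sum = np.nansum(E[i])
    if e_sum == 0.0:
        raise DegenerateItemError("all pairs for this item are degenerate")
    return 1.0 - f_sum / e_sum


def _h_from_matrix(X: np.ndarray) -> float:
    n, J = X.shape
    p = X.mean(axis=0)
    keep = (p > 0.0) & (p < 1.0)
    Xk = X[:, keep]
    pk = p[keep]
    Jk = Xk.shape[1]
    if Jk < 2:
        return np.nan
    both = Xk.T @ Xk
    n1 = Xk.sum(axis=0)
    f_ab = n1[None, :] - both
    idx = np.arange(Jk)
    i_easier = (pk[:, None] > pk[None, :]) | (
        (pk[:, None] == pk[None, :]) & (idx[:, None] < idx[None, :])
    )
    iu = np.triu_indices(Jk, k=1)
    F = np.where(i_easier, f_ab, f_ab.T)[iu]
    E = np.where(
        i_easier,
        n * (1.0 - pk[:, None]) * pk[None, :],
        n * (1.0 - pk[None, :]) * pk[:, None],
    )[iu]
    return 1.0 - F.sum() / E.sum()


def scale_scalability(
    m: ItemResponseMatrix,
    se: str | None = "bootstrap",
    n_boot: int = 1000,
    seed: int | None = 0,
) -> ScalabilityCoefficients:
    """All scalability coefficients for the matrix.

    ``se="bootstrap"`` attaches a respondent-resampling standard error of
    the scale H (``n_boot`` seeded resamples); ``se=None`` skips it.
    """
    F, E, degenerate = pair_error_matrices(m)
    if int((~degenerate).sum()) < 2:
        raise DegenerateItemError("need at least 2 non-degenerate items")
    with np.errstate(invalid="ignore", divide="ignore"):
        h_pair = 1.0 - F / E
        h_item = 1.0 - np.nansum(F, axis=1) / np.nansum(E, axis=1)
    h_item[degenerate] = np.nan
    iu = np.triu_indices(m.n_items, k=1)
    h_scale = 1.0 - np.nansum(F[iu]) / np.nansum(E[iu])

    se_scale = None
    if se == "bootstrap":
        rng = np.random.default_rng(seed)
        n = m.n_persons
        hs = np.empty(n_boot)
        for b in range(n_boot):
            rows = rng.integers(0, n, size=n)
            hs[b] = _h_from_matrix(m.values[rows].astype(np.float64))
        se_scale = float(np.nanstd(hs, ddof=1))
    elif se is not None:
        raise ValueError(f"unknown se method {se!r}")

    return ScalabilityCoefficients(
        h_pair=h_pair,
        h_item=h_item,
        h_scale=float(h_scale),
        se_scale=se_scale,
        n_persons=m.n_persons,
        item_labels=m.item_labels,
        degenerate=tuple(int(k) for k in np.flatnonzero(degenerate)),
    )


def classify_strength(h: float) -> ScaleStrength:
    """Rule-of-thumb band for a scale H."""
    if h > 1.0 + 1e-12:
        raise ValueError("H cannot exceed 1")
    if h < 0.3:
        return ScaleStrength.UNSCALABLE
    if h < 0.4:
        return ScaleStrength.WEAK
    if h < 0.5:
        return ScaleStrength.MEDIUM
    return ScaleStrength.STRONG


def pair_z_positive(F: np.ndarray, E: np.ndarray, n: int) -> np.ndarray:
    """One-sided Z statistics for H_ij > 0 under the independence null.

    Under independence the observed error count of a pair is approximately
    Binomial(n, q) with q = E/n, so Z = (E - F) / sqrt(E (1 - E/n)); large
    positive Z favours positive scalability.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        var0 = E * (1.0 - E / n)
        z = (E - F) / np.sqrt(var0)
    return z


def z_critical(alpha: float, n_tests: int = 1) -> float:
    """One-sided normal critical value with Bonferroni correction."""
    return float(sps.norm.isf(alpha / max(n_tests, 1)))
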