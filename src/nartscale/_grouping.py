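"""Rest-score grouping shared by the monotonicity and item-ordering checks.

Manifest checks of nonparametric IRT assumptions condition on the rest
score (the total over the items not under evaluation).  Adjacent rest-score
values are merged from the low end upward until each group reaches a
minimum size, so that conditional proportions are estimated with usable
precision.  The default minimum follows the sample-size-dependent
convention of the standard procedure: n/10 for n >= 500, n/5 for
250 <= n < 500, otherwise max(n/3, 50).
"""

from __future__ import annotations

import numpy as np

__all__ = ["default_minsize", "group_rest_scores", "two_proportion_z"]


def default_minsize(n: int) -> int:
    if n >= 500:
        return n // 10
    if n >= 250:
        return n // 5
    return max(n // 3, 50)


def group_rest_scores(
    rest: np.ndarray, minsize: int
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Merge adjacent rest-score values into ordered groups of >= minsize.

    Returns ``(assignment, boundaries)`` where ``assignment[k]`` is the
    group index (ascending in rest score) of person k and ``boundaries``
    lists each group's inclusive (low, high) rest-score range.  A trailing
    undersized group is merged into its predecessor.  With too few persons
    to form two groups, a single group covering everyone is returned.
    """
    rest = np.asarray(rest)
    values, counts = np.unique(rest, return_counts=True)
    bins: list[list[int]] = []
    current: list[int] = []
    size = 0
    for v, c in zip(values, counts):
        current.append(int(v))
        size += int(c)
        if size >= minsize:
            bins.append(current)
            current, size = [], 0
    if current:
        if bins:
            bins[-1].extend(current)
        else:
            bins.append(current)
    boundaries = [(b[0], b[-1]) for b in bins]
    edges = np.array([b[-1] for b in bins])
    assignment = np.searchsorted(edges, rest, side="left")
    return assignment, boundaries


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> float:
    """One-sided pooled two-proportion z statistic for p1 > p2."""
    if n1 == 0 or n2 == 0:
        return np.nan
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    if var == 0.0:
        return np.nan
    return (p1 - p2) / np.sqrt(var)
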