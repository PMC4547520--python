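"""Manifest monotonicity checks against rest-score groups.

Under the monotone homogeneity model every item response function is
non-decreasing in the latent trait, so the conditional proportion correct
P(X_i = 1 | rest-score group) must be non-decreasing across ordered
rest-score groups.  A decrease larger than ``minvi`` (default 0.03, the
conventional floor below which violations are treated as trivial) between
ANY ordered pair of groups counts as a violation; each flagged decrease
carries a one-sided pooled two-proportion z statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from ._grouping import default_minsize, group_rest_scores, two_proportion_z
from .data_io import ItemResponseMatrix

__all__ = ["ItemMonotonicity", "MonotonicityReport", "check_monotonicity"]

DEFAULT_MINVI = 0.03
Z_ONE_SIDED_05 = 1.6448536269514722


@dataclass(frozen=True)
class ItemMonotonicity:
    """Monotonicity evidence for one item."""

    label: str
    group_boundaries: tuple[tuple[int, int], ...]
    group_sizes: tuple[int, ...]
    conditional_proportions: tuple[float, ...]
    active_comparisons: int
    violations: int
    max_violation: float
    z_statistics: tuple[float, ...]  # one per flagged decrease
    z_crit: float = Z_ONE_SIDED_05   # family-wise critical value
    skipped: bool = False

    @property
    def significant_violations(self) -> int:
        return sum(1 for z in self.z_statistics if z > self.z_crit)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "group_boundaries": [list(b) for b in self.group_boundaries],
            "group_sizes": list(self.group_sizes),
            "conditional_proportions": list(self.conditional_proportions),
            "active_comparisons": self.active_comparisons,
            "violations": self.violations,
            "max_violation": self.max_violation,
            "z_statistics": list(self.z_statistics),
            "significant_violations": self.significant_violations,
            "skipped": self.skipped,
        }


@dataclass(frozen=True)
class MonotonicityReport:
    items: tuple[ItemMonotonicity, ...]
    minvi: float
    minsize: int
    alpha: float = 0.05
    z_crit: float = Z_ONE_SIDED_05

    @property
    def total_violations(self) -> int:
        return sum(it.violations for it in self.items)

    @property
    def total_significant(self) -> int:
        return sum(it.significant_violations for it in self.items)

    def to_dict(self) -> dict:
        return {
            "minvi": self.minvi,
            "minsize": self.minsize,
            "alpha": self.alpha,
            "z_crit": self.z_crit,
            "total_violations": self.total_violations,
            "total_significant": self.total_significant,
            "items": [it.to_dict() for it in self.items],
        }


def check_monotonicity(
    m: ItemResponseMatrix,
    minvi: float = DEFAULT_MINVI,
    minsize: int | None = None,
    alpha: float = 0.05,
) -> MonotonicityReport:
    """Check every item's conditional proportions across rest-score groups.

    The rest score for item i is the total over the other items.  All
    ordered group pairs are compared; the reported ``max_violation`` is
    the largest decrease found (0.0 if none exceed ``minvi``).  Flagged
    decreases are significant when their z exceeds the Bonferroni-
    corrected critical value for ``alpha`` over the comparisons scanned.
    Items whose rest scores cannot form two groups of ``minsize`` are
    reported as skipped.
    """
    if m.n_items < 3:
        raise ValueError("monotonicity check needs at least 3 items")
    if minsize is None:
        minsize = default_minsize(m.n_persons)
    X = m.values
    totals = m.total_scores()
    per_item = []
    n_comparisons = 0
    for i in range(m.n_items):
        rest = totals - X[:, i]
        assignment, boundaries = group_rest_scores(rest, minsize)
        n_groups = len(boundaries)
        if n_groups < 2:
            per_item.append((i, boundaries, None, None, None))
            continue
        sizes = np.bincount(assignment, minlength=n_groups)
        successes = np.bincount(
            assignment, weights=X[:, i].astype(float), minlength=n_groups
        ).astype(int)
        n_comparisons += n_groups * (n_groups - 1) // 2
        per_item.append((i, boundaries, sizes, successes, n_groups))
    z_crit = float(sps.norm.isf(alpha / max(n_comparisons, 1)))

    items = []
    for i, boundaries, sizes, successes, n_groups in per_item:
        if n_groups is None:
            items.append(
                ItemMonotonicity(
                    m.item_labels[i], tuple(boundaries),
                    (m.n_persons,), (float(X[:, i].mean()),),
                    0, 0, 0.0, (), z_crit=z_crit, skipped=True,
                )
            )
            continue
        props = successes / sizes
        violations = 0
        max_vi = 0.0
        zs = []
        active = 0
        for g in range(n_groups):
            for h in range(g + 1, n_groups):
                active += 1
                decrease = props[g] - props[h]
                if decrease > minvi:
                    violations += 1
                    max_vi = max(max_vi, float(decrease))
                    zs.append(
                        float(
                            two_proportion_z(
                                int(successes[g]), int(sizes[g]),
                                int(successes[h]), int(sizes[h]),
                            )
                        )
                    )
        items.append(
            ItemMonotonicity(
                m.item_labels[i],
                tuple(boundaries),
                tuple(int(s) for s in sizes),
                tuple(float(p) for p in props),
                active,
                violations,
                max_vi,
                tuple(zs),
                z_crit=z_crit,
            )
        )
    return MonotonicityReport(tuple(items), minvi, minsize, alpha, z_crit)
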