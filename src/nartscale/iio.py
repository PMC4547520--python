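"""Invariant item ordering: manifest checks, backward selection, and H^T.

A set of dichotomous items is invariantly ordered when the item response
functions do not intersect: the difficulty ordering observed in the whole
sample holds at every trait level.  The manifest check conditions on the
rest score over the other J - 2 items: for a pair (i easier than j in the
full sample) a reversal is a rest-score group in which the harder item is
endorsed more often than the easier one by more than ``minvi``.

Backward selection iteratively removes the item carrying the largest
significant reversal (ties: larger significant-violation count, then lower
column index) and re-checks the reduced set, until no significant
reversals remain.

H^T quantifies the accuracy of the ordering: it is the scale scalability
coefficient of the *transposed* matrix (persons as items), computed after
excluding persons with all-0 or all-1 response vectors, and shares the
rule-of-thumb interpretation bands of H.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._grouping import default_minsize, group_rest_scores, two_proportion_z
from .data_io import ItemResponseMatrix
from scipy import stats as sps

from .monotonicity import DEFAULT_MINVI
from .scalability import DegenerateItemError, scale_scalability

__all__ = [
    "PairViolation",
    "IIOResult",
    "check_iio",
    "backward_select_iio",
    "ht_coefficient",
]


@dataclass(frozen=True)
class PairViolation:
    """One reversal of the sample difficulty ordering within a group."""

    easier: int           # column index of the easier item (full-sample)
    harder: int
    group: int            # rest-score group index (ascending)
    magnitude: float      # P(harder | group) - P(easier | group) > minvi
    z: float
    significant: bool     # z above the family-wise critical value


def check_iio(
    m: ItemResponseMatrix,
    minvi: float = DEFAULT_MINVI,
    minsize: int | None = None,
    alpha: float = 0.05,
) -> list[PairViolation]:
    """Scan all ordered item pairs for manifest IIO reversals.

    Items are ordered by full-sample proportion correct (ties by column
    index); the rest score for a pair excludes both of its items.
    Degenerate (zero-variance) items cannot reverse and are skipped.

    A reversal is *significant* when its one-sided z exceeds the
    Bonferroni-corrected critical value for ``alpha`` over the number of
    group comparisons scanned in this call, so that a clean item set
    yields a significant flag with probability about ``alpha`` in total.
    """
    if m.n_items < 3:
        raise ValueError("IIO check needs at least 3 items")
    if minsize is None:
        minsize = default_minsize(m.n_persons)
    X = m.values
    p = m.proportions()
    totals = m.total_scores()
    usable = [i for i in range(m.n_items) if 0.0 < p[i] < 1.0]
    order = sorted(usable, key=lambda i: (-p[i], i))
    raw: list[tuple[int, int, int, float, float]] = []
    n_comparisons = 0
    for a in range(len(order)):
        for b in range(a + 1, len(order)):
            e, h = order[a], order[b]
            rest = totals - X[:, e] - X[:, h]
            assignment, boundaries = group_rest_scores(rest, minsize)
            n_groups = len(boundaries)
            if n_groups < 1:
                continue
            n_comparisons += n_groups
            sizes = np.bincount(assignment, minlength=n_groups)
            succ_e = np.bincount(
                assignment, weights=X[:, e].astype(float), minlength=n_groups
            ).astype(int)
            succ_h = np.bincount(
                assignment, weights=X[:, h].astype(float), minlength=n_groups
            ).astype(int)
            pe = succ_e / sizes
            ph = succ_h / sizes
            for g in range(n_groups):
                reversal = ph[g] - pe[g]
                if reversal > minvi:
                    z = two_proportion_z(
                        int(succ_h[g]), int(sizes[g]),
                        int(succ_e[g]), int(sizes[g]),
                    )
                    raw.append((e, h, g, float(reversal), float(z)))
    z_crit = float(sps.norm.isf(alpha / max(n_comparisons, 1)))
    return [
        PairViolation(e, h, g, mag, z, bool(z > z_crit))
        for e, h, g, mag, z in raw
    ]


@dataclass(frozen=True)
class IIOResult:
    """Outcome of backward IIO selection on a matrix."""

    pair_violations: tuple[PairViolation, ...]   # on the initial item set
    item_violation_counts: tuple[int, ...]       # significant, initial set
    removal_trace: tuple[tuple[str, float], ...]  # (label, max violation)
    retained: tuple[int, ...]                    # column indices, original
    retained_labels: tuple[str, ...]
    ht: float | None
    minvi: float

    def to_dict(self) -> dict:
        return {
            "minvi": self.minvi,
            "initial_significant_violations": [
                {
                    "easier": v.easier,
                    "harder": v.harder,
                    "group": v.group,
                    "magnitude": v.magnitude,
                    "z": v.z,
                }
                for v in self.pair_violations
                if v.significant
            ],
            "item_violation_counts": list(self.item_violation_counts),
            "removal_trace": [
                {"label": lab, "max_violation": vi}
                for lab, vi in self.removal_trace
            ],
            "retained_labels": list(self.retained_labels),
            "ht": self.ht,
        }


def _worst_item(
    violations: list[PairViolation], n_items: int
) -> tuple[int | None, float]:
    """Item with the largest significant reversal.

    Ties on the largest magnitude (shared by the two members of the
    flagged pair) are broken by the larger total violation count — all
    reversals above minvi, significant or not, since the count measures
    how pervasively an item disturbs the ordering — and a remaining tie
    by the lower column index.
    """
    max_mag = np.zeros(n_items)
    counts = np.zeros(n_items, dtype=int)
    any_sig = False
    for v in violations:
        for k in (v.easier, v.harder):
            counts[k] += 1
        if not v.significant:
            continue
        any_sig = True
        for k in (v.easier, v.harder):
            max_mag[k] = max(max_mag[k], v.magnitude)
    if not any_sig:
        return None, 0.0
    best = max(range(n_items), key=lambda k: (max_mag[k], counts[k], -k))
    return best, float(max_mag[best])


def backward_select_iio(
    m: ItemResponseMatrix,
    minvi: float = DEFAULT_MINVI,
    minsize: int | None = None,
    alpha: float = 0.05,
) -> IIOResult:
    """Iteratively remove the worst IIO violator until none remain.

    Only significant reversals (family-wise one-sided z at level
    ``alpha``) trigger removal; the retained set therefore re-checks
    clean.  H^T is computed on the retained set.
    """
    initial = check_iio(m, minvi=minvi, minsize=minsize, alpha=alpha)
    counts = np.zeros(m.n_items, dtype=int)
    for v in initial:
        if v.significant:
            counts[v.easier] += 1
            counts[v.harder] += 1

    active = list(range(m.n_items))
    trace: list[tuple[str, float]] = []
    violations = initial
    current = m
    while True:
        worst_local, mag = _worst_item(violations, current.n_items)
        if worst_local is None:
            break
        removed_original = active.pop(worst_local)
        trace.append((m.item_labels[removed_original], mag))
        if len(active) < 3:
            break
        current = m.select(active)
        violations = check_iio(current, minvi=minvi, minsize=minsize,
                               alpha=alpha)

    retained = tuple(active)
    try:
        ht = ht_coefficient(m.select(active)) if len(active) >= 2 else None
    except DegenerateItemError:
        ht = None
    return IIOResult(
        pair_violations=tuple(initial),
        item_violation_counts=tuple(int(c) for c in counts),
        removal_trace=tuple(trace),
        retained=retained,
        retained_labels=tuple(m.item_labels[i] for i in retained),
        ht=ht,
        minvi=minvi,
    )


def ht_coefficient(m: ItemResponseMatrix) -> float:
    """Scale H of the transposed matrix over non-extreme persons.

    Persons scoring 0 or the maximum on the given items carry no ordering
    information (zero variance after transposition) and are excluded.
    """
    if m.n_items < 2:
        raise ValueError("H^T needs at least 2 items")
    totals = m.total_scores()
    keep = (totals > 0) & (totals < m.n_items)
    if int(keep.sum()) < 2:
        raise DegenerateItemError("fewer than 2 non-extreme persons")
    transposed = ItemResponseMatrix(
        m.values[keep].T,
        tuple(f"person_{k}" for k in np.flatnonzero(keep)),
    )
    return scale_scalability(transposed, se=None).h_scale
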