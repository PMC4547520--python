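"""Molenaar-Sijtsma (MS) reliability of total scores.

The MS statistic estimates the reliability of the total score directly
from the joint distribution of item pairs.  With items ordered by
popularity (proportion correct, descending; ties by column index), the
unobservable "replication" diagonal P(X_i = 1 on two independent
administrations) of the joint-proportion matrix is approximated from
adjacent off-diagonal entries:

    interior:  pi_ii ~ pi[i-1,i] * pi[i,i+1] / pi[i-1,i+1]
    edges:     pi_11 ~ pi_1 * pi[1,2] / pi_2   (and mirrored for the last)

and the reliability is

    MS = 1 - sum_i (pi_i - pi_ii) / var(total score).

Under marginal independence the approximation returns pi_i^2, giving
MS ~ 0; for a perfectly coherent matrix (every person all-0 or all-1) it
returns pi_i exactly, giving MS = 1.  Values above 0.7 are conventionally
taken to indicate a reliable scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ItemResponseMatrix
from .scalability import DegenerateItemError

__all__ = ["ReliabilityEstimate", "ms_reliability"]

RELIABILITY_THRESHOLD = 0.7


@dataclass(frozen=True)
class ReliabilityEstimate:
    ms: float
    n_persons: int
    n_items: int
    excluded_items: tuple[str, ...] = ()

    @property
    def reliable_flag(self) -> bool:
        return self.ms > RELIABILITY_THRESHOLD

    @property
    def degenerate(self) -> bool:
        """MS outside [0, 1]; reported raw, never clamped."""
        return not 0.0 <= self.ms <= 1.0

    def to_dict(self) -> dict:
        return {
            "ms": self.ms,
            "reliable_flag": self.reliable_flag,
            "degenerate": self.degenerate,
            "n_persons": self.n_persons,
            "n_items": self.n_items,
            "excluded_items": list(self.excluded_items),
        }


def ms_reliability(m: ItemResponseMatrix) -> ReliabilityEstimate:
    """MS reliability of the total score on the given items.

    Zero-variance items are excluded (their joint proportions are
    uninformative); at least 3 usable items are required for the diagonal
    interpolation.
    """
    X = m.values.astype(np.float64)
    p = X.mean(axis=0)
    usable = np.flatnonzero((p > 0.0) & (p < 1.0))
    excluded = tuple(
        m.item_labels[i] for i in range(m.n_items) if i not in set(usable)
    )
    if usable.size < 3:
        raise DegenerateItemError(
            "MS reliability needs at least 3 non-degenerate items"
        )
    order = sorted(usable, key=lambda i: (-p[i], i))
    Xo = X[:, order]
    po = p[order]
    n, J = Xo.shape
    pi = (Xo.T @ Xo) / n  # joint proportions, popularity-ordered

    diag = np.empty(J)
    with np.errstate(invalid="ignore", divide="ignore"):
        for i in range(J):
            if i == 0:
                est = po[0] * pi[0, 1] / po[1]
            elif i == J - 1:
                est = po[-1] * pi[J - 2, J - 1] / po[J - 2]
            else:
                denom = pi[i - 1, i + 1]
                est = (
                    pi[i - 1, i] * pi[i, i + 1] / denom if denom > 0 else 0.0
                )
            diag[i] = est

    total = Xo.sum(axis=1)
    var_total = float(np.var(total))
    if var_total == 0.0:
        raise DegenerateItemError("total score has zero variance")
    ms = 1.0 - float(np.sum(po - diag)) / var_total
    return ReliabilityEstimate(
        ms=float(ms),
        n_persons=m.n_persons,
        n_items=int(usable.size),
        excluded_items=excluded,
    )
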