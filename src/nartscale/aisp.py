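"""Automated item selection: bottom-up partitioning into Mokken scales.

The greedy procedure seeds a scale with the pair of items having the
highest H_ij among pairs whose scalability is at least the lower bound c
and significantly positive; it then repeatedly admits the candidate item
that (a) has a positive H_ij point estimate with every selected item,
(b) has an item scalability H_i with respect to the selected set of at
least c and significantly above zero, and (c) maximizes the resulting
scale H.  When no candidate qualifies the scale is closed and the
procedure restarts on the remaining items; whatever is left over at the
end is unscalable.

Significance uses the one-sided null-variance Z statistic of the classical
procedure with a Bonferroni correction across the candidate tests of each
selection step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ItemResponseMatrix
from .scalability import (
    ScalabilityCoefficients,
    pair_error_matrices,
    pair_z_positive,
    scale_scalability,
    z_critical,
)

__all__ = ["ScalePartition", "aisp", "scale_membership_table"]

DEFAULT_LOWERBOUND = 0.3
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ScalePartition:
    """Partition of items into Mokken scales plus an unscalable remainder."""

    scales: tuple[tuple[int, ...], ...]
    unscalable: tuple[int, ...]
    coefficients: tuple[ScalabilityCoefficients, ...]
    lowerbound: float
    alpha: float
    item_labels: tuple[str, ...]

    def scale_of(self, item: int) -> int | None:
        """1-based scale id of an item, or None if unscalable."""
        for s, members in enumerate(self.scales, start=1):
            if item in members:
                return s
        return None

    def to_dict(self) -> dict:
        return {
            "lowerbound": self.lowerbound,
            "alpha": self.alpha,
            "scales": [
                {
                    "items": [self.item_labels[i] for i in members],
                    "h_scale": coef.h_scale,
                    "strength": coef.strength.value,
                }
                for members, coef in zip(self.scales, self.coefficients)
            ],
            "unscalable": [self.item_labels[i] for i in self.unscalable],
        }


def _h_of_subset(F: np.ndarray, E: np.ndarray, items: list[int]) -> float:
    idx = np.array(items)
    sub_f = F[np.ix_(idx, idx)]
    sub_e = E[np.ix_(idx, idx)]
    iu = np.triu_indices(len(items), k=1)
    return 1.0 - np.nansum(sub_f[iu]) / np.nansum(sub_e[iu])


def _item_h_vs_set(
    F: np.ndarray, E: np.ndarray, item: int, selected: list[int]
) -> tuple[float, float, float]:
    """(H_i, sum F, sum E) of ``item`` with respect to ``selected``."""
    idx = np.array(selected)
    f_sum = np.nansum(F[item, idx])
    e_sum = np.nansum(E[item, idx])
    if e_sum == 0.0 or np.isnan(e_sum):
        return np.nan, f_sum, e_sum
    return 1.0 - f_sum / e_sum, f_sum, e_sum


def aisp(
    m: ItemResponseMatrix,
    c: float = DEFAULT_LOWERBOUND,
    alpha: float = DEFAULT_ALPHA,
) -> ScalePartition:
    """Partition the items of ``m`` into Mokken scales.

    ``c`` is the scalability lower bound (items with H_i below c are not
    admitted; scales with all H below c never form); ``alpha`` the
    one-sided significance level of the positivity screens.
    """
    F, E, degenerate = pair_error_matrices(m)
    n = m.n_persons
    with np.errstate(invalid="ignore", divide="ignore"):
        H = 1.0 - F / E
    Z = pair_z_positive(F, E, n)

    remaining = [i for i in range(m.n_items) if not degenerate[i]]
    leftovers = [i for i in range(m.n_items) if degenerate[i]]
    scales: list[list[int]] = []

    while len(remaining) >= 2:
        # --- seed: best significantly positive pair with H_ij >= c
        pairs = [
            (i, j)
            for a, i in enumerate(remaining)
            for j in remaining[a + 1:]
        ]
        zc = z_critical(alpha, len(pairs))
        best_pair = None
        best_key = None
        for i, j in pairs:
            if np.isnan(H[i, j]) or H[i, j] < c or not Z[i, j] > zc:
                continue
            key = (H[i, j], Z[i, j], -i, -j)
            if best_key is None or key > best_key:
                best_key, best_pair = key, (i, j)
        if best_pair is None:
            break
        selected = list(best_pair)
        remaining = [k for k in remaining if k not in selected]

        # --- grow greedily
        while remaining:
            candidates = []
            zc = z_critical(alpha, len(remaining))
            for k in remaining:
                # veto only significantly negative pair coefficients: a
                # point-negative H_ij indistinguishable from zero (tiny
                # expected-error counts for near-ceiling items) is not
                # evidence against the candidate
                if np.nanmin(Z[k, np.array(selected)]) < -zc:
                    continue
                h_i, f_sum, e_sum = _item_h_vs_set(F, E, k, selected)
                if np.isnan(h_i) or h_i < c:
                    continue
                var0 = np.nansum(
                    E[k, np.array(selected)]
                    * (1.0 - E[k, np.array(selected)] / n)
                )
                z_i = (e_sum - f_sum) / np.sqrt(var0) if var0 > 0 else np.nan
                if not z_i > zc:
                    continue
                candidates.append((k, _h_of_subset(F, E, selected + [k])))
            if not candidates:
                break
            # maximize resulting scale H; ties -> lower column index
            best = max(candidates, key=lambda t: (t[1], -t[0]))[0]
            selected.append(best)
            remaining.remove(best)
        scales.append(sorted(selected))

    unscalable = sorted(remaining + leftovers)
    coefs = tuple(
        scale_scalability(m.select(members), se=None) for members in scales
    )
    return ScalePartition(
        scales=tuple(tuple(s) for s in scales),
        unscalable=tuple(unscalable),
        coefficients=coefs,
        lowerbound=c,
        alpha=alpha,
        item_labels=m.item_labels,
    )


def scale_membership_table(
    p: ScalePartition, labels: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Human-readable item assignment, ordered by scale then difficulty
    position (original column order within a scale)."""
    labels = tuple(labels) if labels is not None else p.item_labels
    rows = []
    for s, members in enumerate(p.scales, start=1):
        for i in members:
            rows.append({"item": labels[i], "scale": str(s)})
    for i in p.unscalable:
        rows.append({"item": labels[i], "scale": "unscalable"})
    return pd.DataFrame(rows, columns=["item", "scale"])
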