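"""Adaptive administration of an invariantly ordered scale.

When the items of a scale are invariantly ordered, a respondent's standing
can be established from a partial administration: someone who pronounces
the hardest words correctly would almost surely manage all the easier
ones, and someone failing the easiest words would almost surely fail the
harder ones.  This module administers items in difficulty order, stops
after a run of confirming responses, and completes the record with the
Guttman pattern those responses imply.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .data_io import ItemStats

__all__ = ["AdaptiveSession", "order_by_difficulty", "run_session"]


@dataclass(frozen=True)
class AdaptiveSession:
    """Record of one adaptive administration."""

    ordered_items: tuple[str, ...]   # easiest -> hardest
    direction: str                   # "ascending" | "descending"
    stop_after: int
    responses: tuple[tuple[str, int], ...]  # administered (item, 0/1)
    imputed_score: int

    @property
    def n_administered(self) -> int:
        return len(self.responses)

    def to_dict(self) -> dict:
        return {
            "ordered_items": list(self.ordered_items),
            "direction": self.direction,
            "stop_after": self.stop_after,
            "responses": [list(r) for r in self.responses],
            "imputed_score": self.imputed_score,
            "n_administered": self.n_administered,
        }


def order_by_difficulty(stats: Sequence[ItemStats]) -> tuple[str, ...]:
    """Labels ordered easiest first (percent correct descending, ties by
    administration order)."""
    for s in stats:
        if s.pct_correct is None:
            raise ValueError(f"{s.label}: missing percent correct")
    return tuple(
        s.label
        for s in sorted(stats, key=lambda s: (-s.pct_correct, s.test_order))
    )


def run_session(
    ordered_items: Sequence[str],
    responder: Callable[[str], int],
    direction: str = "ascending",
    stop_after: int = 2,
) -> AdaptiveSession:
    """Administer items adaptively and impute the total score.

    Ascending: present easiest to hardest and stop after ``stop_after``
    consecutive failures; unadministered (harder) items are imputed as
    failed.  Descending: present hardest to easiest and stop after
    ``stop_after`` consecutive successes; unadministered (easier) items
    are imputed as passed.  The imputed score is the number of passes,
    observed plus imputed, and for a respondent whose responses follow a
    perfect Guttman pattern it equals the full-administration total in
    either direction.
    """
    if direction not in ("ascending", "descending"):
        raise ValueError(f"unknown direction {direction!r}")
    if stop_after < 1:
        raise ValueError("stop_after must be >= 1")
    items = list(ordered_items)
    sequence = items if direction == "ascending" else items[::-1]
    confirming = 0 if direction == "ascending" else 1

    responses: list[tuple[str, int]] = []
    streak = 0
    administered = 0
    for label in sequence:
        r = int(responder(label))
        if r not in (0, 1):
            raise ValueError(f"responder returned non-binary value {r!r}")
        responses.append((label, r))
        administered += 1
        streak = streak + 1 if r == confirming else 0
        if streak >= stop_after:
            break

    observed_passes = sum(r for _, r in responses)
    if direction == "ascending":
        imputed = 0  # remaining harder items imputed failed
    else:
        imputed = len(items) - administered  # remaining easier items passed
    return AdaptiveSession(
        ordered_items=tuple(items),
        direction=direction,
        stop_after=stop_after,
        responses=tuple(responses),
        imputed_score=observed_passes + imputed,
    )
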