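"""Input/output for dichotomous response matrices and packaged item tables.

The universal input of every analysis in this package is a persons x items
matrix of 0/1 scores (1 = correct).  This module validates and ingests such
matrices from delimited text, ships the published NART item statistics
(administration order, percent correct in the validation cohort, and the
item scalability coefficients of the 23-item invariantly ordered subset)
as a packaged fixture, and persists assembled analysis results as JSON.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ItemResponseMatrix",
    "ItemStats",
    "NARTFixture",
    "MINI_NART_SCALE_H",
    "read_responses",
    "write_responses",
    "load_nart_fixture",
    "write_report",
    "read_report",
]

#: Scale scalability coefficient of the 23-item mini-NART in the validation
#: cohort (reference value; classified "strong").
MINI_NART_SCALE_H = 0.534


class DataError(ValueError):
    """Malformed or invalid response data."""


@dataclass(frozen=True)
class ItemResponseMatrix:
    """Binary persons x items response matrix with item labels.

    Parameters
    ----------
    values
        Integer array of shape ``(n_persons, n_items)`` with entries 0/1.
    item_labels
        Unique column labels, one per item.
    """

    values: np.ndarray
    item_labels: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise DataError("response matrix must be two-dimensional")
        if not np.isin(v, (0, 1)).all():
            raise DataError("response matrix entries must all be 0 or 1")
        v = v.astype(np.int8)
        object.__setattr__(self, "values", v)
        labels = tuple(str(x) for x in self.item_labels)
        if len(labels) != v.shape[1]:
            raise DataError(
                f"{len(labels)} labels for {v.shape[1]} item columns"
            )
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise DataError(f"duplicate item labels: {dupes}")
        if v.shape[1] < 2:
            raise DataError("need at least 2 items")
        if v.shape[0] < 2:
            raise DataError("need at least 2 respondents")
        object.__setattr__(self, "item_labels", labels)

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def proportions(self) -> np.ndarray:
        """Per-item proportion correct (the sample difficulty ordering)."""
        return self.values.mean(axis=0)

    def total_scores(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def select(self, items: Sequence[int]) -> "ItemResponseMatrix":
        """Column subset, preserving the given order."""
        idx = list(items)
        return ItemResponseMatrix(
            self.values[:, idx], tuple(self.item_labels[i] for i in idx)
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.item_labels))


@dataclass(frozen=True)
class ItemStats:
    """Published per-item statistics.

    ``test_order`` is the item's position in the standard administration
    order; ``pct_correct`` is the percentage of respondents pronouncing the
    word correctly (higher percentage = easier item); ``h_i`` is the item
    scalability coefficient where published (the 23 hierarchical items).
    """

    label: str
    test_order: int
    pct_correct: float
    h_i: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.pct_correct <= 100.0:
            raise DataError(
                f"{self.label}: pct_correct {self.pct_correct} not in [0, 100]"
            )


@dataclass(frozen=True)
class NARTFixture:
    """The packaged published item tables.

    ``all_items`` holds the 50 items ordered from least to most difficult
    (sample percent correct); ``mini_items`` the 23-item invariantly ordered
    subset with item scalabilities; ``scale_h`` its scale coefficient.
    """

    all_items: tuple[ItemStats, ...]
    mini_items: tuple[ItemStats, ...]
    scale_h: float = MINI_NART_SCALE_H
    _by_label: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if len(self.all_items) != 50:
            raise DataError("expected 50 items in the full table")
        if len(self.mini_items) != 23:
            raise DataError("expected 23 items in the mini table")
        all_labels = {s.label for s in self.all_items}
        if not {s.label for s in self.mini_items} <= all_labels:
            raise DataError("mini item labels must be a subset of the full set")
        object.__setattr__(
            self, "_by_label", {s.label: s for s in self.all_items}
        )

    def lookup(self, label: str) -> ItemStats:
        """Full-table stats for ``label``, with ``h_i`` attached when the
        item belongs to the 23-item subset."""
        stats = self._by_label[label.upper()]
        for m in self.mini_items:
            if m.label == stats.label:
                return m
        return stats

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.all_items)

    @property
    def mini_labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.mini_items)


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return "\t" if "\t" in sample else ","


def read_responses(path, missing_policy: str = "listwise") -> ItemResponseMatrix:
    """Read a delimited 0/1 response matrix.

    The file must have a header row of item labels and one respondent per
    body row; comma or tab delimiters are auto-detected.  A non-numeric
    first column is treated as respondent identifiers and dropped.

    ``missing_policy`` controls rows containing anything other than 0/1:
    ``"listwise"`` drops such rows (complete-case analysis) and logs the
    count; ``"error"`` raises.
    """
    if missing_policy not in ("error", "listwise"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    path = Path(path)
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        rows = list(csv.reader(fh, delimiter=_sniff_delimiter(sample)))
    if len(rows) < 2:
        raise DataError(f"{path}: no data rows")
    header, body = rows[0], rows[1:]
    widths = {len(r) for r in body}
    if widths != {len(header)}:
        raise DataError(f"{path}: ragged rows (widths {sorted(widths)})")

    def parse_cell(cell: str) -> float:
        cell = cell.strip()
        if cell in ("0", "1"):
            return float(cell)
        try:
            return float(cell)  # non-binary numerics fall to the policy
        except ValueError:
            return np.nan

    # optional identifier column: every body cell below it is a non-empty,
    # non-numeric string (a blank cell is missing data, not an identifier)
    id_column = all(
        r[0].strip() != "" and np.isnan(parse_cell(r[0])) for r in body if r
    )
    if id_column and len(header) > 1:
        header = header[1:]
        body = [r[1:] for r in body]

    labels = [h.strip() for h in header]
    parsed = np.array([[parse_cell(c) for c in r] for r in body])
    ok = np.isin(parsed, (0.0, 1.0)).all(axis=1) & ~np.isnan(parsed).any(axis=1)
    if not ok.all():
        n_bad = int((~ok).sum())
        if missing_policy == "error":
            raise DataError(
                f"{path}: {n_bad} row(s) with missing or non-binary entries"
            )
        logger.warning(
            "%s: dropped %d respondent row(s) with missing or non-binary "
            "entries (listwise deletion)", path, n_bad,
        )
        parsed = parsed[ok]
    if parsed.shape[0] < 2:
        raise DataError(f"{path}: fewer than 2 usable respondent rows")
    return ItemResponseMatrix(parsed.astype(np.int8), tuple(labels))


def write_responses(m: ItemResponseMatrix, path) -> None:
    """Write a matrix in the package's standard CSV dialect."""
    m.to_dataframe().to_csv(path, index=False)


def load_nart_fixture() -> NARTFixture:
    """Load the packaged 50-item table and its 23-item hierarchical subset."""
    ref = resources.files("nartscale.data").joinpath("nart_items.csv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p)
    df = df.sort_values("difficulty_rank")
    all_items = tuple(
        ItemStats(r.label, int(r.test_order), float(r.pct_correct))
        for r in df.itertuples()
    )
    mini = df[df.mini == 1].sort_values(
        ["pct_correct", "test_order"], ascending=[False, True]
    )
    mini_items = tuple(
        ItemStats(r.label, int(r.test_order), float(r.pct_correct), float(r.h_i))
        for r in mini.itertuples()
    )
    return NARTFixture(all_items, mini_items)


def _jsonable(obj):
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj


REPORT_SECTIONS = (
    "scalability",
    "partition",
    "monotonicity",
    "iio",
    "reliability",
    "regression",
)


def write_report(results: dict, path) -> None:
    """Persist assembled analysis outputs as a JSON report.

    Every standard section is present in the output; sections absent from
    ``results`` are written as explicit nulls so that an empty analysis is
    distinguishable from an unwritten one.  Result objects with a
    ``to_dict`` method are serialized through it.
    """
    report = {sec: None for sec in REPORT_SECTIONS}
    for key, val in results.items():
        report[str(key)] = _jsonable(val)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
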