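"""Deterministic table-lens operations over a :class:`~paramlens.core.ResultTable`.

These are the batch equivalents of the interactive gestures a parameter-
exploration GUI offers: clicking column headers to build up a nested sort,
a one-click "smart sort" that ranks parameters by aggregate correlation with
the output measures, cursor-context selection of runs of equal values,
interval filters, and per-column domain-coverage summaries.  Every operation
is pure: it returns a new table (or a derived value) and never mutates its
input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .core import ResultTable

__all__ = [
    "CoverageStrip",
    "multi_sort",
    "clear_sort",
    "smart_sort",
    "aggregate_correlations",
    "context_selection",
    "filter_interval",
    "clear_filters",
    "domain_coverage",
]


@dataclass(frozen=True)
class CoverageStrip:
    """Which sub-intervals of a column's domain a set of rows occupies.

    ``domain`` is the column's ``(min, max)`` over all records; ``covered``
    is a list of disjoint ``(lo, hi)`` sub-intervals, each at least one
    display bin wide.
    """

    column: str
    domain: tuple[float, float]
    covered: tuple[tuple[float, float], ...]


def _sorted_ordering(table: ResultTable, keys: Sequence[str]) -> tuple[int, ...]:
    # lexicographic ascending over keys (first key outermost), record_id tiebreak
    cols = {k: table.column_values(k) for k in keys}
    return tuple(
        sorted(
            range(len(table.records)),
            key=lambda i: tuple(cols[k][i] for k in keys) + (table.records[i].record_id,),
        )
    )


def multi_sort(table: ResultTable, new_key: str) -> ResultTable:
    """Add *new_key* as the innermost sort key, keeping earlier sorts.

    Records that agree on all previously applied keys form contiguous bins;
    the new key reorders records only within each bin (the nested step-like
    pattern).  Ties on the full key tuple fall back to ``record_id``.
    """
    if new_key not in table.columns:
        raise KeyError(f"unknown column {new_key!r}")
    if new_key in table.sort_keys:
        raise ValueError(f"column {new_key!r} is already a sort key")
    keys = table.sort_keys + (new_key,)
    return replace(table, sort_keys=keys, ordering=_sorted_ordering(table, keys))


def clear_sort(table: ResultTable) -> ResultTable:
    """Reset to canonical record order with no sort keys."""
    return replace(table, sort_keys=(), ordering=tuple(range(len(table.records))))


def _abs_pearson(x: np.ndarray, y: np.ndarray) -> float:
    # correlation with a constant column is undefined; treat as no association
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(abs(np.corrcoef(x, y)[0, 1]))


def aggregate_correlations(
    table: ResultTable, method: Literal["mean_abs_r", "variance_weighted"] = "mean_abs_r"
) -> dict[str, float]:
    """Score each parameter by its aggregate correlation with the measures.

    Scores are computed over the visible records only.  ``mean_abs_r`` is the
    unweighted mean of ``|Pearson r(parameter, measure)|`` over all measure
    columns; ``variance_weighted`` weights each measure's ``|r|`` by that
    measure's variance share, emphasising the measures that actually vary.
    """
    vis = sorted(table.visible)
    if len(vis) < 2:
        raise ValueError("aggregate correlation requires at least 2 visible records")
    if not table.param_columns or not table.measure_columns:
        raise ValueError("need at least one parameter and one measure column")
    mvals = {m: table.column_values(m)[vis] for m in table.measure_columns}
    if method == "variance_weighted":
        variances = np.array([mvals[m].var() for m in table.measure_columns])
        total = variances.sum()
        weights = variances / total if total > 0 else np.full(len(variances), 1.0 / len(variances))
    elif method == "mean_abs_r":
        weights = np.full(len(table.measure_columns), 1.0 / len(table.measure_columns))
    else:
        raise ValueError(f"unknown method {method!r}")
    scores = {}
    for p in table.param_columns:
        pv = table.column_values(p)[vis]
        rs = np.array([_abs_pearson(pv, mvals[m]) for m in table.measure_columns])
        scores[p] = float(rs @ weights)
    return scores


def smart_sort(
    table: ResultTable, method: Literal["mean_abs_r", "variance_weighted"] = "mean_abs_r"
) -> tuple[str, ResultTable]:
    """Sort by the single parameter with the highest aggregate correlation.

    Ties break toward the leftmost parameter column.  Any existing sort keys
    are replaced by the chosen parameter (automated sorting is a fresh sort,
    not a refinement).
    """
    scores = aggregate_correlations(table, method=method)
    chosen = max(table.param_columns, key=lambda p: (scores[p], -table.param_columns.index(p)))
    sorted_table = multi_sort(replace(table, sort_keys=()), chosen)
    return chosen, sorted_table


def context_selection(table: ResultTable, row: int, column: str) -> tuple[int, ...]:
    """Maximal contiguous run of visible rows sharing *row*'s value in *column*.

    *row* is a record index (position in ``table.records``); the run is taken
    over the current visible ordering and returned top-to-bottom.  This is the
    batch form of cursor focus: directly adjacent rows with the same value for
    the cursor column join the focus set.
    """
    if column not in table.columns:
        raise KeyError(f"unknown column {column!r}")
    if row not in table.visible:
        raise ValueError(f"record {row} is not visible")
    order = table.visible_ordering()
    pos = order.index(row)
    target = table.records[row].value(column)
    lo = pos
    while lo > 0 and table.records[order[lo - 1]].value(column) == target:
        lo -= 1
    hi = pos
    while hi + 1 < len(order) and table.records[order[hi + 1]].value(column) == target:
        hi += 1
    return order[lo : hi + 1]


def select(table: ResultTable, rows: Sequence[int], extend: bool = False) -> ResultTable:
    """Set (or extend) the table selection, preserving order of *rows*."""
    rows = tuple(rows)
    if extend:
        rows = table.selection + tuple(r for r in rows if r not in table.selection)
    return replace(table, selection=rows)


def filter_interval(table: ResultTable, column: str, lo: float, hi: float) -> ResultTable:
    """Hide records whose *column* value falls outside ``[lo, hi]`` (inclusive).

    Filters compose by intersection with the current visible set; ordering is
    untouched and the selection is pruned to the surviving records.
    """
    if column not in table.columns:
        raise KeyError(f"unknown column {column!r}")
    if lo > hi:
        raise ValueError(f"invalid interval: lo={lo} > hi={hi}")
    values = table.column_values(column)
    passing = {i for i in table.visible if lo <= values[i] <= hi}
    return replace(
        table,
        visible=frozenset(passing),
        selection=tuple(i for i in table.selection if i in passing),
    )


def clear_filters(table: ResultTable) -> ResultTable:
    """Make every record visible again (selection is preserved)."""
    return replace(table, visible=frozenset(range(len(table.records))))


def domain_coverage(
    table: ResultTable, rows: Sequence[int], n_bins: int = 100
) -> list[CoverageStrip]:
    """Per-column strips showing which parts of each domain *rows* occupy.

    Each column's full domain ``[min, max]`` (over all records) is divided
    into *n_bins* display bins; a bin is covered when any of *rows* takes a
    value inside it, and adjacent covered bins merge into one sub-interval.
    Point values therefore widen to one display bin, and a degenerate
    (constant) domain is either fully covered or empty.
    """
    if not table.records:
        raise ValueError("empty table")
    rows = tuple(rows)
    if not set(rows) <= table.visible:
        raise ValueError("coverage rows must be visible")
    strips = []
    for column in table.columns:
        values = table.column_values(column)
        cmin, cmax = float(values.min()), float(values.max())
        if not rows:
            strips.append(CoverageStrip(column, (cmin, cmax), ()))
            continue
        selected = values[list(rows)]
        if cmax == cmin:
            strips.append(CoverageStrip(column, (cmin, cmax), ((cmin, cmax),)))
            continue
        width = (cmax - cmin) / n_bins
        bins = np.clip(((selected - cmin) / width).astype(int), 0, n_bins - 1)
        covered_bins = np.zeros(n_bins, dtype=bool)
        covered_bins[bins] = True
        intervals = []
        start = None
        for b in range(n_bins + 1):
            on = b < n_bins and covered_bins[b]
            if on and start is None:
                start = b
            elif not on and start is not None:
                intervals.append((cmin + start * width, cmin + b * width))
                start = None
        strips.append(CoverageStrip(column, (cmin, cmax), tuple(intervals)))
    return strips
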