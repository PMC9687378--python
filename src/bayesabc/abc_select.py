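"""Computed ABC analysis: find "the important few" items of a value vector.

Items are sorted by value descending and summarized by the cumulative
contribution curve (x_i = i/n, y_i = fraction of the total carried by
the top i items), a discrete Lorenz-type curve.  Set A ends at the
curve point closest to the ideal point (0, 1) — maximal yield for
minimal effort; set B extends to the last item whose curve segment is
steeper than the uniform share (slope > 1), i.e., items that still
contribute more than average; the remainder is set C ("the trivial
many").  Applying the analysis recursively to the surviving set three
times and taking the smallest surviving value yields a data-driven
selection threshold for differential-expression statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ABCCurve",
    "ABCPartition",
    "SelectionThreshold",
    "abc_curve",
    "abc_partition",
    "recursive_abc",
    "select_genes",
]


@dataclass(frozen=True)
class ABCCurve:
    """Items sorted descending with cumulative-contribution curve points."""

    order: np.ndarray  # original indices, sorted by value desc (ties: index asc)
    sorted_values: np.ndarray
    x: np.ndarray  # i/n for i = 1..n
    y: np.ndarray  # cumulative value fraction
    total: float


@dataclass(frozen=True)
class ABCPartition:
    """A/B/C membership by original index plus the boundary positions.

    ``ab_index`` and ``bc_index`` are 1-based inclusive ends of A and of
    B on the sorted order; B may be empty (bc_index == ab_index).
    """

    a_indices: np.ndarray
    b_indices: np.ndarray
    c_indices: np.ndarray
    ab_index: int
    bc_index: int
    curve: ABCCurve


@dataclass(frozen=True)
class SelectionThreshold:
    """Outcome of the recursive analysis: the smallest still-important value."""

    threshold: float
    keep: str  # "A" or "AB" at the final iteration
    iterations: int
    completed_iterations: int
    kept_indices: np.ndarray  # original indices of the final kept set
    degenerate: bool = False


def abc_curve(values) -> ABCCurve:
    """Build the cumulative-contribution curve over non-negative values."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot build an ABC curve from an empty vector")
    if np.any(v < 0):
        raise ValueError("ABC analysis requires non-negative values")
    total = float(v.sum())
    if total == 0.0:
        raise ValueError("all values are zero; nothing to rank")
    # stable sort descending with ties broken by original index ascending
    order = np.lexsort((np.arange(v.size), -v))
    sv = v[order]
    n = v.size
    x = np.arange(1, n + 1) / n
    y = np.cumsum(sv) / total
    return ABCCurve(order=order, sorted_values=sv, x=x, y=y, total=total)


def abc_partition(curve: ABCCurve) -> ABCPartition:
    """Place the A|B and B|C boundaries on a curve.

    A|B: the curve point with the smallest Euclidean distance to the
    ideal point (0, 1), ties toward the smaller index (smaller A).
    B|C: the largest index whose segment slope exceeds 1 (an item
    contributing more than a uniform share), floored at the A|B index.
    """
    d2 = curve.x**2 + (curve.y - 1.0) ** 2
    # ties (within float noise) break toward the smaller index / smaller A
    ab = int(np.argmax(d2 <= d2.min() + 1e-12)) + 1
    n = curve.x.size
    slopes = curve.sorted_values * n / curve.total
    above = np.nonzero(slopes > 1.0)[0]
    bc = max(ab, int(above[-1]) + 1) if above.size else ab
    return ABCPartition(
        a_indices=curve.order[:ab],
        b_indices=curve.order[ab:bc],
        c_indices=curve.order[bc:],
        ab_index=ab,
        bc_index=bc,
        curve=curve,
    )


def recursive_abc(values, iterations: int = 3, keep: str = "A") -> SelectionThreshold:
    """Apply ABC analysis recursively and return the selection threshold.

    Rounds 1..iterations-1 retain set A; the final round retains A or
    A-union-B according to ``keep``.  The threshold is the smallest
    value of the final kept set.  Kept sets are nested across rounds.
    Recursion stops early (with a warning) when fewer than 3 items
    survive; an all-equal input is degenerate and returns the common
    value.
    """
    if iterations < 1:
        raise ValueError("need at least one iteration")
    if keep not in ("A", "AB"):
        raise ValueError("keep mode must be 'A' or 'AB'")
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot run ABC analysis on an empty vector")
    if np.all(v == v[0]):
        warnings.warn("all values equal; ABC selection is degenerate")
        return SelectionThreshold(
            threshold=float(v[0]),
            keep=keep,
            iterations=iterations,
            completed_iterations=0,
            kept_indices=np.arange(v.size),
            degenerate=True,
        )
    kept = np.arange(v.size)
    completed = 0
    for it in range(1, iterations + 1):
        if kept.size < 3:
            warnings.warn(
                f"only {kept.size} items survive before iteration {it}; "
                "stopping the recursion early"
            )
            break
        part = abc_partition(abc_curve(v[kept]))
        final = it == iterations
        local = (
            np.concatenate([part.a_indices, part.b_indices])
            if (final and keep == "AB")
            else part.a_indices
        )
        kept = kept[np.sort(local)]
        completed = it
    return SelectionThreshold(
        threshold=float(v[kept].min()),
        keep=keep,
        iterations=iterations,
        completed_iterations=completed,
        kept_indices=kept,
    )


def select_genes(
    table: pd.DataFrame,
    threshold: SelectionThreshold | float,
    stat: str = "pdeg",
    display_threshold: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Select genes whose |statistic| reaches the threshold; zero small effects.

    Returns ``(selected, reported)``: ``selected`` is the sub-table of
    genes with |stat| >= threshold (boundary inclusive), sorted by
    |stat| descending; ``reported`` is a copy of the full table whose
    Cohen's D entries with |D| below the display threshold (default:
    the selection threshold) are set to 0, matching how published
    effect-size tables blank the unimportant many.
    """
    t = threshold.threshold if isinstance(threshold, SelectionThreshold) else float(threshold)
    if stat not in table.columns:
        raise KeyError(f"statistic column {stat!r} not in table")
    magnitude = table[stat].abs()
    selected = table.loc[magnitude >= t].copy()
    selected = selected.loc[selected[stat].abs().sort_values(ascending=False).index]
    display = t if display_threshold is None else float(display_threshold)
    reported = table.copy()
    if "cohen_d" in reported.columns:
        reported.loc[reported["cohen_d"].abs() < display, "cohen_d"] = 0.0
    return selected, reported
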