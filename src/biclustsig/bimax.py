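"""Enumeration of inclusion-maximal all-ones submatrices (biclusters).

The binary-inclusion model treats a bicluster as a pair (rows, cols)
whose cells are all 1 and to which no further row or column can be
added without breaking that property.  These are exactly the closed
patterns of the column-set lattice: a column set C with row support
R(C) is maximal iff C is precisely the set of columns that are 1 on
all of R(C).

The search is a depth-first closure-based enumeration with an explicit
stack.  Each node carries a closed column set and its row support;
children extend by one column and take the closure.  A child whose
closure acquires a column earlier in the fixed column order than the
extension column is a duplicate of a branch explored elsewhere and is
pruned (prefix-preserving closure extension), so every closed set with
enough rows is emitted exactly once.  Row support only shrinks and the
closure only grows along a branch, which makes the minimum-row and
maximum-column constraints sound pruning rules.

Size constraints (minimum rows, minimum/maximum columns) act as
filters on the maximal set; maximality itself is judged without them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binarize import BinaryMatrix


@dataclass(frozen=True)
class Bicluster:
    """An inclusion-maximal all-ones submatrix of a binary matrix."""

    rows: frozenset[str]
    cols: frozenset[str]
    direction: str = "up"

    @property
    def area(self) -> int:
        return len(self.rows) * len(self.cols)

    def sort_key(self) -> tuple:
        return (-self.area, tuple(sorted(self.rows)), tuple(sorted(self.cols)))

    def jaccard(self, other: "Bicluster") -> tuple[float, float]:
        """Row-set and column-set Jaccard similarity with another bicluster."""
        jr = len(self.rows & other.rows) / len(self.rows | other.rows)
        jc = len(self.cols & other.cols) / len(self.cols | other.cols)
        return jr, jc


@dataclass(frozen=True)
class BimaxParams:
    """Size constraints for the enumeration (defaults: >= 15 genes,
    5-15 conditions)."""

    min_rows: int = 15
    min_cols: int = 5
    max_cols: int = 15

    def __post_init__(self) -> None:
        if self.min_rows < 1:
            raise ValueError("min_rows must be >= 1")
        if not (1 <= self.min_cols <= self.max_cols):
            raise ValueError("need 1 <= min_cols <= max_cols")


class BiclusterLimitError(RuntimeError):
    """Raised when the enumeration exceeds the configured output cap."""


def bimax(
    matrix: BinaryMatrix,
    params: BimaxParams = BimaxParams(),
    max_biclusters: int = 100_000,
) -> list[Bicluster]:
    """Enumerate every inclusion-maximal all-ones submatrix satisfying
    the size constraints.

    Output is deterministic: sorted by area (|rows|*|cols|) descending,
    ties broken lexicographically on sorted row labels then column
    labels.  Exceeding ``max_biclusters`` raises
    :class:`BiclusterLimitError` rather than truncating silently.
    """
    values = matrix.values
    m, n = values.shape
    if m == 0 or n == 0:
        return []
    arr = values.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("matrix contains a non-binary cell")
    M = arr.astype(bool)
    row_labels = np.asarray(values.index, dtype=object)
    col_labels = np.asarray(values.columns, dtype=object)

    def closure(rows: np.ndarray) -> np.ndarray:
        # columns that are all-ones on the given row support
        return M[rows].all(axis=0)

    out: list[Bicluster] = []

    def emit(rows: np.ndarray, closed: np.ndarray) -> None:
        ncols = int(closed.sum())
        if params.min_cols <= ncols <= params.max_cols and int(rows.sum()) >= params.min_rows:
            if len(out) >= max_biclusters:
                raise BiclusterLimitError(
                    f"more than {max_biclusters} biclusters; raise the cap "
                    "or tighten the size constraints"
                )
            out.append(
                Bicluster(
                    rows=frozenset(row_labels[rows]),
                    cols=frozenset(col_labels[closed]),
                    direction=matrix.direction,
                )
            )

    all_rows = np.ones(m, dtype=bool)
    root_closed = closure(all_rows)
    if root_closed.any():
        emit(all_rows, root_closed)
    # explicit DFS stack: (row support, closed column set, next column to try)
    stack: list[tuple[np.ndarray, np.ndarray, int]] = []
    if int(root_closed.sum()) < params.max_cols:
        stack.append((all_rows, root_closed, 0))
    while stack:
        rows, closed, start = stack.pop()
        for j in range(start, n):
            if closed[j]:
                continue
            new_rows = rows & M[:, j]
            if int(new_rows.sum()) < params.min_rows:
                continue
            new_closed = closure(new_rows)
            # prefix-preserving check: closure may not add columns before j
            if (new_closed[:j] & ~closed[:j]).any():
                continue
            emit(new_rows, new_closed)
            if int(new_closed.sum()) < params.max_cols:
                stack.append((new_rows, new_closed, j + 1))

    out.sort(key=Bicluster.sort_key)
    return out


def run_discovery(
    fc,
    params: BimaxParams = BimaxParams(),
    threshold_log2: float = 1.0,
    max_biclusters: int = 100_000,
) -> list[Bicluster]:
    """Binarize a fold-change matrix in both directions and enumerate
    biclusters in each, independently.

    Returns up-matrix biclusters followed by down-matrix biclusters,
    each tagged with its source direction.
    """
    from .binarize import binarize

    results: list[Bicluster] = []
    for direction in ("up", "down"):
        bm = binarize(fc, direction, threshold_log2)
        results.extend(bimax(bm, params, max_biclusters))
    return results
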