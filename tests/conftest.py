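import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from biclustsig.binarize import BinaryMatrix

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def brute_force_biclusters(df: pd.DataFrame, min_rows: int, min_cols: int, max_cols: int):
    """Independent oracle: enumerate every nonempty column subset, take
    its all-ones row support, keep the pair when the subset is closed
    (equals the columns all-ones on that support), then size-filter."""
    M = df.to_numpy().astype(bool)
    m, n = M.shape
    out = set()
    for r in range(1, n + 1):
        for C in itertools.combinations(range(n), r):
            rows = M[:, C].all(axis=1)
            if not rows.any():
                continue
            closed = M[rows].all(axis=0)
            if set(np.where(closed)[0]) != set(C):
                continue
            if rows.sum() >= min_rows and min_cols <= len(C) <= max_cols:
                out.add(
                    (
                        frozenset(df.index[rows]),
                        frozenset(df.columns[list(C)]),
                    )
                )
    return out


def random_binary_frame(rng: np.random.Generator, max_rows: int = 12, max_cols: int = 10):
    m = int(rng.integers(1, max_rows + 1))
    n = int(rng.integers(1, max_cols + 1))
    p = rng.uniform(0.1, 0.9)
    arr = (rng.random((m, n)) < p).astype("int8")
    return pd.DataFrame(
        arr,
        index=[f"r{i:02d}" for i in range(m)],
        columns=[f"c{j:02d}" for j in range(n)],
    )


def as_binary(df: pd.DataFrame, direction: str = "up") -> BinaryMatrix:
    return BinaryMatrix(values=df, direction=direction, threshold_log2=1.0)


def is_maximal_all_ones(df: pd.DataFrame, rows: frozenset, cols: frozenset) -> bool:
    """Direct check: the block is all ones and extending by any single
    row or column breaks that."""
    sub = df.loc[sorted(rows), sorted(cols)]
    if not (sub.to_numpy() == 1).all():
        return False
    for r in df.index.difference(list(rows)):
        if (df.loc[r, sorted(cols)].to_numpy() == 1).all():
            return False
    for c in df.columns.difference(list(cols)):
        if (df.loc[sorted(rows), c].to_numpy() == 1).all():
            return False
    return True


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
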