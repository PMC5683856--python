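"""Fold-change binarization.

A fold-change compendium is turned into two binary matrices analyzed
independently: the *up* matrix marks cells at or above a log2 threshold
(default 1.0, i.e. 2-fold up), the *down* matrix marks cells at or
below the negated threshold.  The boundary is inclusive, so for any
positive threshold the two matrices never share a 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import FoldChangeMatrix

DIRECTIONS = ("up", "down")


@dataclass
class BinaryMatrix:
    values: pd.DataFrame  # int8 over {0, 1}
    direction: str
    threshold_log2: float

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if not self.values.isin([0, 1]).to_numpy().all():
            raise ValueError("binary matrix contains a non-binary cell")
        self.values = self.values.astype("int8")


def binarize(
    fc: FoldChangeMatrix, direction: str, threshold_log2: float = 1.0
) -> BinaryMatrix:
    """Threshold log2 fold changes into a 0/1 matrix.

    up: cell = 1 iff log2FC >= threshold; down: cell = 1 iff
    log2FC <= -threshold.  Non-finite fold changes are a hard error.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if not threshold_log2 > 0:
        raise ValueError("threshold_log2 must be positive")
    arr = fc.values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite fold-change value; clean the matrix upstream")
    if direction == "up":
        mask = arr >= threshold_log2
    else:
        mask = arr <= -threshold_log2
    values = pd.DataFrame(
        mask.astype("int8"), index=fc.values.index, columns=fc.values.columns
    )
    return BinaryMatrix(values=values, direction=direction, threshold_log2=threshold_log2)
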