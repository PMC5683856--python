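"""Heatmap-style ordering of a gene set across exposure groups.

The presentation procedure: collapse biological replicates to per-group
medians, then cluster with average (UPGMA) linkage on the
1 - Spearman-correlation dissimilarity.  The tested artifact is the
linkage and the induced leaf order; pixel rendering is a thin optional
layer.  Spearman uses midranks for ties, so the whole result is
invariant under any strictly increasing transform of a single item.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .enrichment import DoseExperiment


@dataclass
class LinkageResult:
    """An agglomerative clustering of row or column items.

    ``labels`` lists the leaf items in the (lexicographic) order used
    for the computation; ``merge_history`` holds one (a, b, height,
    size) tuple per merge, where a and b index leaves (< n) or earlier
    merges (>= n); ``leaf_order`` is the dendrogram's left-to-right
    label permutation.
    """

    labels: list[str]
    merge_history: list[tuple[int, int, float, int]]
    leaf_order: list[str]
    linkage_matrix: np.ndarray

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h, _ in self.merge_history]


def group_medians(exp: DoseExperiment, grouping: pd.Series | dict) -> pd.DataFrame:
    """Per-gene median within each sample group (one column per group)."""
    grouping = pd.Series(grouping, dtype=str)
    unknown = sorted(set(grouping.index) - set(exp.values.columns))
    if unknown:
        raise ValueError(f"grouping names unknown sample(s): {unknown}")
    ungrouped = sorted(set(exp.values.columns) - set(grouping.index))
    if ungrouped:
        raise ValueError(f"sample(s) without a group: {ungrouped}")
    return exp.values.T.groupby(grouping, sort=True).median().T


def spearman_dissimilarity(matrix: pd.DataFrame, axis: str = "cols") -> pd.DataFrame:
    """Pairwise 1 - Spearman rho between columns (or rows).

    A constant item has no rank variance and an undefined correlation;
    it is a hard error naming the item.
    """
    if axis not in {"rows", "cols"}:
        raise ValueError("axis must be 'rows' or 'cols'")
    data = matrix if axis == "cols" else matrix.T
    if data.shape[1] < 2:
        raise ValueError("need at least 2 items to cluster")
    for label in data.columns:
        col = data[label].to_numpy(dtype=float)
        if np.allclose(col, col[0]):
            raise ValueError(
                f"item {label!r} is constant; Spearman correlation undefined"
            )
    rho = data.corr(method="spearman")
    d = (1.0 - rho).clip(lower=0.0, upper=2.0)
    np.fill_diagonal(d.to_numpy(), 0.0)
    return d


def spearman_average_linkage(matrix: pd.DataFrame, axis: str = "cols") -> LinkageResult:
    """Average-linkage clustering on the 1 - Spearman dissimilarity.

    Items are processed in lexicographic label order, which fixes the
    tie-breaking and makes the result a pure function of the values.
    """
    data = matrix if axis == "cols" else matrix.T
    labels = sorted(data.columns.astype(str))
    data = data[labels]
    d = spearman_dissimilarity(data, axis="cols")
    condensed = squareform(d.to_numpy(), checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    leaf_order = [labels[i] for i in hierarchy.leaves_list(Z)]
    merges = [
        (int(a), int(b), float(h), int(size)) for a, b, h, size in Z
    ]
    return LinkageResult(
        labels=labels,
        merge_history=merges,
        leaf_order=leaf_order,
        linkage_matrix=Z,
    )


def ordered_matrix(
    matrix: pd.DataFrame,
    col_linkage: LinkageResult | None = None,
    row_linkage: LinkageResult | None = None,
) -> pd.DataFrame:
    """Reorder a matrix by dendrogram leaf order on either axis."""
    out = matrix
    if col_linkage is not None:
        out = out[col_linkage.leaf_order]
    if row_linkage is not None:
        out = out.loc[row_linkage.leaf_order]
    return out


def plot_heatmap(matrix: pd.DataFrame, path: str, cmap: str = "RdBu_r"):
    """Optional rendering of an (already ordered) matrix to an image
    file.  Imports matplotlib lazily; everything testable lives in the
    linkage and ordering functions above."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * matrix.shape[1]), max(4, 0.12 * matrix.shape[0]))
    )
    vmax = float(np.nanmax(np.abs(matrix.to_numpy()))) or 1.0
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="log2 expression")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
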