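"""Normalized-intensity preprocessing: replicate collapsing, control
standardization, and cross-study merging.

The pipeline starts from log2 signal intensities that have already been
platform-normalized.  From there: technical replicates (repeated probe
rows) collapse by median; probes map to gene symbols and each gene's
probes collapse by median; biological replicates of a condition collapse
by median; each condition is expressed as log2 fold change against its
matched control, and control columns are dropped; finally studies merge
on gene symbol into one fold-change compendium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ExpressionStudy:
    """A single study's log2 intensity matrix plus sample metadata.

    ``values`` is probe-by-sample (gene-by-sample once collapsed);
    ``probe_to_gene`` is a two-column frame (probe, gene) — a probe
    annotated with several symbols appears on several rows; ``samples``
    is metadata indexed by sample id with columns study, condition,
    dose, timepoint, is_control, replicate.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    probe_to_gene: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        in_meta = set(self.samples.index)
        in_matrix = set(self.values.columns)
        if in_meta != in_matrix:
            only_meta = sorted(in_meta - in_matrix)[:5]
            only_matrix = sorted(in_matrix - in_meta)[:5]
            raise ValueError(
                "sample metadata and matrix columns disagree "
                f"(metadata-only: {only_meta}, matrix-only: {only_matrix})"
            )
        if not bool(self.samples["is_control"].any()):
            raise ValueError("study has no control sample")
        if self.values.isna().to_numpy().any():
            raise ValueError("missing values in expression matrix; impute or drop upstream")
        # align column order to metadata order for determinism
        self.values = self.values.loc[:, list(self.samples.index)]

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.samples["condition"]))


@dataclass
class FoldChangeMatrix:
    """Gene-by-condition log2 fold changes with study provenance.

    ``condition_study`` maps each column label to the study it came
    from.  Control columns are gone by construction.
    """

    values: pd.DataFrame
    condition_study: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene symbols in fold-change matrix")
        if set(self.condition_study.index) != set(self.values.columns):
            raise ValueError("condition_study labels do not match matrix columns")
        self.condition_study = self.condition_study.loc[list(self.values.columns)]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)


def collapse_technical_replicates(study: ExpressionStudy) -> ExpressionStudy:
    """Collapse repeated probe rows, map probes to gene symbols, and
    collapse each gene's probes — all by median.

    Probes with no gene symbol are dropped (count logged).  A probe
    annotated with several symbols contributes its value to each of
    them before the per-gene median.
    """
    values = study.values
    if values.index.duplicated().any():
        values = values.groupby(level=0, sort=True).median()

    if study.probe_to_gene is None:
        # rows are already gene symbols; still collapse duplicates
        return replace(study, values=values, probe_to_gene=None)

    pm = study.probe_to_gene.dropna()
    pm = pm[pm["gene"].astype(str).str.len() > 0]
    mapped_probes = set(pm["probe"])
    dropped = [p for p in values.index if p not in mapped_probes]
    if dropped:
        logger.info("dropping %d probe(s) with no gene symbol", len(dropped))
    multi = pm["probe"].value_counts()
    n_multi = int((multi > 1).sum())
    if n_multi:
        logger.info("%d probe(s) map to multiple gene symbols", n_multi)

    pm = pm[pm["probe"].isin(values.index)]
    expanded = values.loc[pm["probe"]].set_axis(pm["gene"].to_numpy(), axis=0)
    by_gene = expanded.groupby(level=0, sort=True).median()
    return replace(study, values=by_gene, probe_to_gene=None)


def collapse_biological_replicates(study: ExpressionStudy) -> ExpressionStudy:
    """One column per condition: the per-gene median across that
    condition's samples.  Metadata collapses alongside."""
    meta = study.samples
    cond_of = meta["condition"]
    collapsed = study.values.T.groupby(cond_of, sort=True).median().T

    rows = []
    for cond, grp in meta.groupby("condition", sort=True):
        flags = set(grp["is_control"])
        if len(flags) != 1:
            raise ValueError(f"condition {cond!r} mixes control and non-control samples")
        rows.append(
            {
                "sample": cond,
                "study": grp["study"].iloc[0],
                "condition": cond,
                "dose": grp["dose"].iloc[0],
                "timepoint": grp["timepoint"].iloc[0],
                "is_control": flags.pop(),
                "replicate": "",
            }
        )
    new_meta = pd.DataFrame(rows).set_index("sample")
    return ExpressionStudy(values=collapsed, samples=new_meta, probe_to_gene=study.probe_to_gene)


def infer_control_map(samples: pd.DataFrame) -> dict[str, str]:
    """Map every treated condition to its study's control condition.

    Works only when each study has exactly one control condition;
    otherwise an explicit map must be supplied.
    """
    control_map: dict[str, str] = {}
    for study_id, grp in samples.groupby("study", sort=True):
        ctrls = sorted(set(grp.loc[grp["is_control"], "condition"]))
        if len(ctrls) != 1:
            raise ValueError(
                f"study {study_id!r} has {len(ctrls)} control conditions "
                f"({ctrls}); supply an explicit control map"
            )
        for cond in set(grp.loc[~grp["is_control"], "condition"]):
            control_map[cond] = ctrls[0]
    return control_map


def fold_change_vs_control(
    study: ExpressionStudy,
    control_map: Mapping[str, str] | None = None,
) -> FoldChangeMatrix:
    """Express each treated condition as log2 fold change against its
    matched control, then drop control columns.

    ``control_map`` maps treated condition label -> control condition
    label; if omitted it is inferred (one control per study).  A treated
    condition without a mapped, present control is a hard error naming
    the condition.
    """
    collapsed = collapse_biological_replicates(study)
    meta = collapsed.samples
    if control_map is None:
        control_map = infer_control_map(meta)

    treated = [c for c in collapsed.values.columns if not meta.loc[c, "is_control"]]
    fc = {}
    for cond in treated:
        if cond not in control_map:
            raise ValueError(f"condition {cond!r} has no control mapping")
        ctrl = control_map[cond]
        if ctrl not in collapsed.values.columns:
            raise ValueError(f"condition {cond!r}: control condition {ctrl!r} not present")
        fc[cond] = collapsed.values[cond] - collapsed.values[ctrl]
    values = pd.DataFrame(fc, index=collapsed.values.index)
    values = values[treated]
    condition_study = pd.Series(
        {c: meta.loc[c, "study"] for c in treated}, name="study", dtype=object
    )
    return FoldChangeMatrix(values=values, condition_study=condition_study)


def merge_studies(
    studies: Sequence[FoldChangeMatrix], how: str = "intersection"
) -> FoldChangeMatrix:
    """Merge per-study fold-change matrices on gene symbol.

    The gene universe is the intersection of the studies' symbols (a
    union is available with ``how='union'``; genes missing from a study
    then carry NaN, which downstream binarization rejects — union output
    is for inspection, not the discovery pipeline).  Columns become
    ``study::condition`` and sort lexicographically by (study,
    condition), so the merge is order-independent.
    """
    if len(studies) == 0:
        raise ValueError("merge_studies needs at least one study")
    if how not in {"intersection", "union"}:
        raise ValueError(f"unknown merge mode {how!r}")

    gene_sets = [set(s.values.index) for s in studies]
    if how == "intersection":
        genes = set.intersection(*gene_sets)
        if not genes:
            raise ValueError("gene-symbol intersection across studies is empty")
    else:
        genes = set.union(*gene_sets)
    gene_index = sorted(genes)
    logger.info("merged gene universe: %d gene symbols", len(gene_index))

    pieces = []
    provenance = {}
    seen: dict[str, int] = {}
    for s in studies:
        block = s.values.reindex(gene_index)
        renames = {}
        for cond in block.columns:
            study_id = s.condition_study[cond]
            label = f"{study_id}::{cond}"
            seen[label] = seen.get(label, 0) + 1
            if seen[label] > 1:
                label = f"{label}#{seen[label]}"
            renames[cond] = label
            provenance[label] = study_id
        pieces.append(block.rename(columns=renames))
    values = pd.concat(pieces, axis=1)
    values = values[sorted(values.columns)]
    condition_study = pd.Series(provenance, name="study", dtype=object)
    return FoldChangeMatrix(values=values, condition_study=condition_study)


def preprocess_study(
    study: ExpressionStudy, control_map: Mapping[str, str] | None = None
) -> FoldChangeMatrix:
    """Full single-study pipeline: probe/gene collapse -> biological
    replicate collapse -> control standardization."""
    return fold_change_vs_control(collapse_technical_replicates(study), control_map)
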