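"""Readers and writers for the package's plain-text interchange formats.

All matrices travel as TSV with genes (or probes) in rows, the first
column named ``gene``, and sample/condition labels in the header.
Sample metadata is a TSV with the columns ``sample, study, condition,
dose, timepoint, is_control, replicate``.  Gene sets use the standard
GMT dialect (name, description, member genes, tab-separated).  Gene
symbols are treated case-sensitively; an opt-in uppercase fold is
available on the GMT reader for cross-platform merges.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

METADATA_COLUMNS = [
    "sample",
    "study",
    "condition",
    "dose",
    "timepoint",
    "is_control",
    "replicate",
]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols (one GMT line)."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set needs a non-empty name")
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


def read_gmt(path: str | Path, uppercase: bool = False) -> list[GeneSet]:
    """Parse a GMT file into gene sets.

    Duplicate genes within a line are dropped (first occurrence wins)
    with a warning; a line with fewer than three tab-separated fields
    is a hard error reported with its line number.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line "
                    f"({len(fields)} tab-separated fields, need >= 3)"
                )
            name, description, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            if uppercase:
                genes = [g.upper() for g in genes]
            seen: dict[str, None] = {}
            dupes = 0
            for g in genes:
                if g in seen:
                    dupes += 1
                else:
                    seen[g] = None
            if dupes:
                logger.warning(
                    "gene set %r: %d duplicate gene(s) dropped", name, dupes
                )
            if not seen:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name, description, tuple(seen)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample (or -condition) TSV into a float DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_matrix_tsv(values: pd.DataFrame, path: str | Path, index_label: str = "gene") -> None:
    values.to_csv(path, sep="\t", index_label=index_label)


def read_binary_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    bad = ~df.isin([0, 1]).to_numpy()
    if bad.any():
        raise ValueError(f"{path}: non-binary cell(s) in binary matrix")
    return df.astype("int8")


def _parse_bool(x: object) -> bool:
    if isinstance(x, bool):
        return x
    s = str(x).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise ValueError(f"cannot interpret {x!r} as a boolean control flag")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read sample metadata, indexed by sample id."""
    meta = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: metadata is missing column(s) {missing}")
    meta["is_control"] = meta["is_control"].map(_parse_bool)
    meta = meta.set_index("sample")
    if meta.index.duplicated().any():
        dupes = sorted(meta.index[meta.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate sample id(s) {dupes}")
    return meta[[c for c in METADATA_COLUMNS if c != "sample"]]


def write_metadata_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


def read_probe_map_tsv(path: str | Path) -> pd.DataFrame:
    """Two-column probe -> gene symbol map; repeated probe rows encode
    probes annotated with multiple gene symbols."""
    pm = pd.read_csv(path, sep="\t", dtype=str)
    if list(pm.columns[:2]) != ["probe", "gene"]:
        raise ValueError(f"{path}: probe map must have columns 'probe' and 'gene'")
    return pm[["probe", "gene"]]


def write_probe_map_tsv(pm: pd.DataFrame, path: str | Path) -> None:
    pm[["probe", "gene"]].to_csv(path, sep="\t", index=False)


def write_biclusters_json(biclusters: Sequence, path: str | Path) -> None:
    payload = [
        {
            "direction": b.direction,
            "rows": sorted(b.rows),
            "cols": sorted(b.cols),
        }
        for b in biclusters
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_gene_lists(biclusters: Sequence, outdir: str | Path) -> list[Path]:
    """One plain gene list per bicluster, one symbol per line — the
    format functional-annotation web tools accept by paste."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, b in enumerate(biclusters, start=1):
        p = outdir / f"bicluster_{i:02d}_{b.direction}.txt"
        p.write_text("\n".join(sorted(b.rows)) + "\n", encoding="utf-8")
        paths.append(p)
    return paths


def biclusters_to_gene_sets(biclusters: Sequence) -> list[GeneSet]:
    return [
        GeneSet(
            name=f"bicluster_{i:02d}_{b.direction}",
            description=f"{len(b.rows)} genes x {len(b.cols)} conditions ({b.direction})",
            genes=tuple(sorted(b.rows)),
        )
        for i, b in enumerate(biclusters, start=1)
    ]
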