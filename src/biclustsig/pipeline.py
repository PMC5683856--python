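"""End-to-end orchestration: discovery (preprocess -> binarize ->
bicluster) and application (dose-effect enrichment -> heatmap order),
driven by a YAML config, with a provenance sidecar per artifact.

Reruns with an identical config and seed are byte-identical: no
timestamps enter any artifact, float formatting is pandas' default
repr, and JSON is written with sorted keys.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Any

import yaml

from . import io as bio
from .bimax import Bicluster, BimaxParams, run_discovery
from .binarize import binarize
from .clusterviz import group_medians, spearman_average_linkage, ordered_matrix
from .enrichment import DoseExperiment, enrichment_report
from .preprocess import ExpressionStudy, preprocess_study
from .simulate import (
    DoseDesign,
    PlantedBicluster,
    SimulationConfig,
    condition_labels,
    dose_metadata,
    gene_universe,
    generate_dose_experiment,
    generate_raw_study,
)

logger = logging.getLogger(__name__)


def _package_version() -> str:
    try:
        return version("biclustsig")
    except PackageNotFoundError:
        return "unknown"


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration (see ``from_yaml``)."""

    raw: dict[str, Any]
    out_dir: Path
    seed: int = 0
    threshold_log2: float = 1.0
    bimax_params: BimaxParams = field(default_factory=BimaxParams)
    alternative: str = "greater"
    background: str = "all"
    bh: bool = False

    @classmethod
    def from_yaml(
        cls, path: str | Path, out_dir: str | Path, seed: int | None = None
    ) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, out_dir, seed)

    @classmethod
    def from_dict(
        cls, raw: dict[str, Any], out_dir: str | Path, seed: int | None = None
    ) -> "PipelineConfig":
        if seed is not None:
            raw = {**raw, "seed": int(seed)}
        bim = raw.get("bimax", {})
        enr = raw.get("enrichment", {})
        return cls(
            raw=raw,
            out_dir=Path(out_dir),
            seed=int(raw.get("seed", 0)),
            threshold_log2=float(raw.get("threshold_log2", 1.0)),
            bimax_params=BimaxParams(
                min_rows=int(bim.get("min_rows", 15)),
                min_cols=int(bim.get("min_cols", 5)),
                max_cols=int(bim.get("max_cols", 15)),
            ),
            alternative=enr.get("alternative", "greater"),
            background=enr.get("background", "all"),
            bh=bool(enr.get("bh", False)),
        )

    def config_sha256(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode("utf-8")).hexdigest()


def simulation_config_from_dict(d: dict[str, Any], seed: int) -> SimulationConfig:
    """Build a compendium config from a YAML block.  Planted entries
    give block sizes (``genes``, ``conditions``) allocated as
    consecutive disjoint blocks, or explicit ``gene_ids`` /
    ``condition_ids`` lists."""
    n_genes = int(d.get("n_genes", 300))
    n_conditions = int(d.get("n_conditions", 24))
    genes = gene_universe(n_genes)
    conds = condition_labels(n_conditions)
    planted = []
    g_off = c_off = 0
    for entry in d.get("planted", []):
        if "gene_ids" in entry:
            gene_ids = tuple(entry["gene_ids"])
            condition_ids = tuple(entry["condition_ids"])
        else:
            ng, nc = int(entry["genes"]), int(entry["conditions"])
            gene_ids = tuple(genes[g_off : g_off + ng])
            condition_ids = tuple(conds[c_off : c_off + nc])
            if len(gene_ids) < ng or len(condition_ids) < nc:
                raise ValueError("planted blocks exceed the matrix universe")
            g_off += ng
            c_off += nc
        planted.append(
            PlantedBicluster(
                gene_ids=gene_ids,
                condition_ids=condition_ids,
                direction=entry.get("direction", "up"),
                effect_mean=float(entry.get("effect_mean", 2.0)),
                effect_sd=float(entry.get("effect_sd", 0.1)),
            )
        )
    return SimulationConfig(
        n_genes=n_genes,
        n_conditions=n_conditions,
        noise_sd=float(d.get("noise_sd", 0.1)),
        planted=tuple(planted),
        seed=int(d.get("seed", seed)),
    )


def dose_design_from_dict(d: dict[str, Any], seed: int) -> DoseDesign:
    return DoseDesign(
        dose_levels=tuple(str(x) for x in d.get("dose_levels", ["0", "18", "54", "162"])),
        replicates_per_dose=int(d.get("replicates_per_dose", 3)),
        responsive_set=d.get("responsive_set", "responsive"),
        responsive_genes=tuple(d.get("responsive_genes", ())),
        per_dose_shift=tuple(float(x) for x in d.get("per_dose_shift", [0, 1, 2, 3])),
        residual_sd=float(d.get("residual_sd", 0.5)),
        seed=int(d.get("seed", seed)),
    )


class _ArtifactWriter:
    def __init__(self, config: PipelineConfig):
        self.config = config
        self.paths: dict[str, Path] = {}
        config.out_dir.mkdir(parents=True, exist_ok=True)

    def register(self, name: str, path: Path) -> Path:
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        payload = {
            "artifact": path.name,
            "config_sha256": self.config.config_sha256(),
            "seed": self.config.seed,
            "package_version": _package_version(),
        }
        sidecar.write_text(
            json.dumps(payload, sort_keys=True, indent=1) + "\n", encoding="utf-8"
        )
        self.paths[name] = path
        return path


def _load_study(d: dict[str, Any]) -> ExpressionStudy:
    values = bio.read_matrix_tsv(d["expr"])
    samples = bio.read_metadata_tsv(d["meta"])
    probe_map = bio.read_probe_map_tsv(d["probe_map"]) if d.get("probe_map") else None
    return ExpressionStudy(values=values, samples=samples, probe_to_gene=probe_map)


def _load_dose_experiment(d: dict[str, Any]) -> DoseExperiment:
    values = bio.read_matrix_tsv(d["expr"])
    meta = bio.read_metadata_tsv(d["meta"])
    dose_of = meta["dose"].astype(str)
    return DoseExperiment(values=values, dose_of=dose_of)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run discovery and/or application per the config; returns the
    map of artifact names to paths.  Any stage error propagates after
    a ``FAILED`` marker is written next to the partial artifacts."""
    w = _ArtifactWriter(config)
    try:
        return _run_pipeline_inner(config, w)
    except Exception as exc:
        (config.out_dir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise


def _run_pipeline_inner(config: PipelineConfig, w: _ArtifactWriter) -> dict[str, Path]:
    raw = config.raw
    out = config.out_dir
    discovered: list[Bicluster] = []
    sim_config = None

    disc = raw.get("discovery")
    if disc:
        if "synthetic" in disc:
            s = disc["synthetic"]
            sim_config = simulation_config_from_dict(s, config.seed)
            study = generate_raw_study(
                sim_config,
                replicates=int(s.get("replicates", 3)),
                controls=int(s.get("controls", 2)),
                probes_per_gene=int(s.get("probes_per_gene", 1)),
            )
            bio.write_matrix_tsv(study.values, out / "discovery_expr.tsv", index_label="gene")
            w.register("discovery_expr", out / "discovery_expr.tsv")
            bio.write_metadata_tsv(study.samples, out / "discovery_meta.tsv")
            w.register("discovery_meta", out / "discovery_meta.tsv")
            truth = [
                {
                    "direction": p.direction,
                    "rows": sorted(p.gene_ids),
                    "cols": sorted(p.condition_ids),
                }
                for p in sim_config.planted
            ]
            (out / "planted_truth.json").write_text(
                json.dumps(truth, sort_keys=True, indent=1) + "\n", encoding="utf-8"
            )
            w.register("planted_truth", out / "planted_truth.json")
        else:
            study = _load_study(disc)

        fc = preprocess_study(study, disc.get("control_map"))
        logger.info("fold-change matrix: %d genes x %d conditions", *fc.values.shape)
        bio.write_matrix_tsv(fc.values, out / "fold_changes.tsv")
        w.register("fold_changes", out / "fold_changes.tsv")

        for direction in ("up", "down"):
            bm = binarize(fc, direction, config.threshold_log2)
            bio.write_matrix_tsv(bm.values, out / f"binary_{direction}.tsv")
            w.register(f"binary_{direction}", out / f"binary_{direction}.tsv")

        discovered = run_discovery(fc, config.bimax_params, config.threshold_log2)
        logger.info(
            "discovery: %d bicluster(s) (%d up, %d down)",
            len(discovered),
            sum(b.direction == "up" for b in discovered),
            sum(b.direction == "down" for b in discovered),
        )
        bio.write_biclusters_json(discovered, out / "biclusters.json")
        w.register("biclusters", out / "biclusters.json")
        bio.write_gene_lists(discovered, out / "gene_lists")
        sets = bio.biclusters_to_gene_sets(discovered)
        if sets:
            bio.write_gmt(sets, out / "biclusters.gmt")
            w.register("biclusters_gmt", out / "biclusters.gmt")

    app = raw.get("application")
    if app:
        if "synthetic" in app:
            a = app["synthetic"]
            design = dose_design_from_dict(a, config.seed)
            n_genes = int(a.get("n_genes", sim_config.n_genes if sim_config else 300))
            if not design.responsive_genes and sim_config and sim_config.planted:
                # default: the first planted bicluster is the responsive set
                design = DoseDesign(
                    **{
                        **design.__dict__,
                        "responsive_genes": sim_config.planted[0].gene_ids,
                        "responsive_set": "planted_bicluster_1",
                    }
                )
            exp, truth_set = generate_dose_experiment(n_genes, design)
            bio.write_matrix_tsv(exp.values, out / "dose_expr.tsv")
            w.register("dose_expr", out / "dose_expr.tsv")
            bio.write_metadata_tsv(dose_metadata(exp), out / "dose_meta.tsv")
            w.register("dose_meta", out / "dose_meta.tsv")
            bio.write_gmt([truth_set], out / "responsive_truth.gmt")
            w.register("responsive_truth", out / "responsive_truth.gmt")
        else:
            exp = _load_dose_experiment(app)

        gene_sets = bio.biclusters_to_gene_sets(discovered) if discovered else []
        if app.get("sets"):
            gene_sets = gene_sets + bio.read_gmt(app["sets"])
        report = enrichment_report(
            exp, gene_sets, config.alternative, config.background, config.bh
        )
        report.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        w.register("enrichment", out / "enrichment.tsv")

        if len(report):
            top = report.iloc[0]["set_name"]
            top_set = next(s for s in gene_sets if s.name == top)
            members = [g for g in top_set.genes if g in exp.values.index]
            sub = DoseExperiment(
                values=exp.values.loc[members], dose_of=exp.dose_of
            )
            med = group_medians(sub, exp.dose_of)
            link = spearman_average_linkage(med, axis="cols")
            ordered = ordered_matrix(med, col_linkage=link)
            bio.write_matrix_tsv(ordered, out / "top_set_group_medians.tsv")
            w.register("top_set_group_medians", out / "top_set_group_medians.tsv")
            (out / "top_set_linkage.json").write_text(
                json.dumps(
                    {
                        "set_name": str(top),
                        "labels": link.labels,
                        "merges": link.merge_history,
                        "leaf_order": link.leaf_order,
                    },
                    sort_keys=True,
                    indent=1,
                )
                + "\n",
                encoding="utf-8",
            )
            w.register("top_set_linkage", out / "top_set_linkage.json")

    return w.paths
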