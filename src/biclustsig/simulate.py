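"""Synthetic fixtures for the whole pipeline.

Two families of generators:

* multi-study fold-change compendia with *planted* up/down-regulated
  biclusters on a Gaussian noise background, plus a raw-intensity
  variant (probes, technical and biological replicates, control
  samples) whose preprocessing reproduces the compendium;
* multi-dose exposure experiments in which a chosen gene set carries a
  per-dose mean shift, for power and null calibration of the
  enrichment test.

All randomness flows through a single seeded generator per call, so a
fixed seed gives bit-identical output and parallel callers never
interact.  Noise is Gaussian on the log2 scale — the standard model
for log-intensity data.  Overlapping planted biclusters are allowed;
cells are written in planted-list order, so the last writer wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import DoseExperiment
from .io import GeneSet
from .preprocess import ExpressionStudy, FoldChangeMatrix

SYNTHETIC_STUDY = "synthetic"


def gene_universe(n_genes: int) -> list[str]:
    return [f"g{i:05d}" for i in range(1, n_genes + 1)]


def condition_labels(n_conditions: int) -> list[str]:
    return [f"c{i:03d}" for i in range(1, n_conditions + 1)]


@dataclass(frozen=True)
class PlantedBicluster:
    """Ground truth for one planted all-up or all-down block.

    Planted cells draw from Normal(effect_mean, effect_sd^2) in log2
    fold-change units.  A bicluster is *recoverable* when
    |effect_mean| - 2 * effect_sd >= 1, i.e. planted cells clear the
    2-fold threshold with high probability.
    """

    gene_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]
    direction: str
    effect_mean: float
    effect_sd: float

    def __post_init__(self) -> None:
        if self.direction not in {"up", "down"}:
            raise ValueError("direction must be 'up' or 'down'")
        if not self.gene_ids or len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be non-empty and unique")
        if not self.condition_ids or len(set(self.condition_ids)) != len(self.condition_ids):
            raise ValueError("condition_ids must be non-empty and unique")
        if self.direction == "up" and not self.effect_mean > 0:
            raise ValueError("up bicluster needs effect_mean > 0")
        if self.direction == "down" and not self.effect_mean < 0:
            raise ValueError("down bicluster needs effect_mean < 0")
        if self.effect_sd < 0:
            raise ValueError("effect_sd must be >= 0")

    @property
    def recoverable(self) -> bool:
        return abs(self.effect_mean) - 2.0 * self.effect_sd >= 1.0


@dataclass(frozen=True)
class SimulationConfig:
    """Shape, noise level, planted structure and seed of a compendium."""

    n_genes: int
    n_conditions: int
    noise_sd: float = 0.2
    planted: tuple[PlantedBicluster, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_conditions < 1:
            raise ValueError("need at least one gene and one condition")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        genes = set(gene_universe(self.n_genes))
        conds = set(condition_labels(self.n_conditions))
        for p in self.planted:
            bad_g = set(p.gene_ids) - genes
            bad_c = set(p.condition_ids) - conds
            if bad_g or bad_c:
                raise ValueError(
                    f"planted bicluster references labels outside the matrix "
                    f"universe (genes: {sorted(bad_g)[:3]}, conditions: {sorted(bad_c)[:3]})"
                )


def planted_block(
    n_genes: int,
    n_conditions: int,
    gene_offset: int,
    n_block_genes: int,
    cond_offset: int,
    n_block_conds: int,
    direction: str = "up",
    effect_mean: float = 2.0,
    effect_sd: float = 0.1,
) -> PlantedBicluster:
    """Convenience: a planted bicluster occupying a contiguous block of
    the label universe (offsets are 0-based)."""
    genes = gene_universe(n_genes)[gene_offset : gene_offset + n_block_genes]
    conds = condition_labels(n_conditions)[cond_offset : cond_offset + n_block_conds]
    if len(genes) < n_block_genes or len(conds) < n_block_conds:
        raise ValueError("planted block exceeds the matrix universe")
    return PlantedBicluster(
        gene_ids=tuple(genes),
        condition_ids=tuple(conds),
        direction=direction,
        effect_mean=effect_mean,
        effect_sd=effect_sd,
    )


def generate_compendium(
    config: SimulationConfig,
) -> tuple[FoldChangeMatrix, list[PlantedBicluster]]:
    """Fold-change matrix with planted biclusters on Gaussian noise.

    Background cells ~ Normal(0, noise_sd^2); planted cells
    ~ Normal(effect_mean, effect_sd^2), written in planted order
    (last writer wins on overlap).  Returns the ground truth alongside.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    genes = gene_universe(config.n_genes)
    conds = condition_labels(config.n_conditions)
    gidx = {g: i for i, g in enumerate(genes)}
    cidx = {c: j for j, c in enumerate(conds)}

    if config.noise_sd > 0:
        arr = rng.normal(0.0, config.noise_sd, size=(config.n_genes, config.n_conditions))
    else:
        arr = np.zeros((config.n_genes, config.n_conditions))
    for p in config.planted:
        block = rng.normal(p.effect_mean, p.effect_sd, size=(len(p.gene_ids), len(p.condition_ids)))
        rows = [gidx[g] for g in p.gene_ids]
        cols = [cidx[c] for c in p.condition_ids]
        arr[np.ix_(rows, cols)] = block

    values = pd.DataFrame(arr, index=genes, columns=conds)
    condition_study = pd.Series(
        {c: SYNTHETIC_STUDY for c in conds}, name="study", dtype=object
    )
    return FoldChangeMatrix(values=values, condition_study=condition_study), list(config.planted)


def generate_raw_study(
    config: SimulationConfig,
    replicates: int = 3,
    controls: int = 2,
    probes_per_gene: int = 1,
    baseline_log2: float = 8.0,
) -> ExpressionStudy:
    """Raw-intensity study whose preprocessing reproduces the
    compendium of the same config up to noise (exactly at noise_sd=0).

    Each condition gets ``replicates`` biological replicate samples;
    ``controls`` control samples sit at the baseline; each gene is
    measured by ``probes_per_gene`` probes sharing its symbol.  Every
    probe/sample cell carries independent Normal(0, noise_sd^2)
    measurement noise on top of baseline + planted fold change.
    """
    if replicates < 1 or controls < 1:
        raise ValueError("need at least 1 replicate and 1 control sample")
    if probes_per_gene < 1:
        raise ValueError("need at least 1 probe per gene")
    fc, _ = generate_compendium(config)
    # independent noise stream so the signal draws match the compendium
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 911)))

    genes = list(fc.values.index)
    conds = list(fc.values.columns)
    probe_rows = []
    probe_map_rows = []
    for g in genes:
        for j in range(1, probes_per_gene + 1):
            probe = f"{g}_p{j}"
            probe_rows.append(probe)
            probe_map_rows.append({"probe": probe, "gene": g})

    sample_ids = []
    meta_rows = []
    signal_cols = []
    M = fc.values.to_numpy()
    for ci, cond in enumerate(conds):
        for r in range(1, replicates + 1):
            sid = f"{cond}_r{r}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample": sid,
                    "study": SYNTHETIC_STUDY,
                    "condition": cond,
                    "dose": "",
                    "timepoint": "",
                    "is_control": False,
                    "replicate": str(r),
                }
            )
            signal_cols.append(M[:, ci])
    for r in range(1, controls + 1):
        sid = f"control_r{r}"
        sample_ids.append(sid)
        meta_rows.append(
            {
                "sample": sid,
                "study": SYNTHETIC_STUDY,
                "condition": "control",
                "dose": "0",
                "timepoint": "",
                "is_control": True,
                "replicate": str(r),
            }
        )
        signal_cols.append(np.zeros(len(genes)))

    signal = np.stack(signal_cols, axis=1)  # gene x sample
    signal = np.repeat(signal, probes_per_gene, axis=0)  # probe x sample
    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=signal.shape)
    else:
        noise = np.zeros_like(signal)
    values = pd.DataFrame(
        baseline_log2 + signal + noise, index=probe_rows, columns=sample_ids
    )
    samples = pd.DataFrame(meta_rows).set_index("sample")
    probe_to_gene = pd.DataFrame(probe_map_rows)
    return ExpressionStudy(values=values, samples=samples, probe_to_gene=probe_to_gene)


@dataclass(frozen=True)
class DoseDesign:
    """Design of a simulated multi-dose exposure experiment.

    ``per_dose_shift`` gives the mean log2 shift of responsive genes at
    each dose level (first entry 0: the lowest level is the reference).
    Dose levels are treated as categorical groups, so the shifts need
    not be monotone.
    """

    dose_levels: tuple[str, ...] = ("0", "18", "54", "162")
    replicates_per_dose: int = 3
    responsive_set: str = "responsive"
    responsive_genes: tuple[str, ...] = ()
    per_dose_shift: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    residual_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.dose_levels) < 2:
            raise ValueError("need at least 2 dose levels")
        if len(set(self.dose_levels)) != len(self.dose_levels):
            raise ValueError("dose levels must be unique")
        if self.replicates_per_dose < 2:
            raise ValueError(
                "need at least 2 replicates per dose (within-group variance undefined otherwise)"
            )
        if len(self.per_dose_shift) != len(self.dose_levels):
            raise ValueError("per_dose_shift needs one entry per dose level")
        if self.per_dose_shift[0] != 0.0:
            raise ValueError("first per_dose_shift entry must be 0 (reference level)")
        if not self.residual_sd > 0:
            raise ValueError("residual_sd must be > 0")


def generate_dose_experiment(
    n_genes: int,
    design: DoseDesign,
    universe: Sequence[str] | None = None,
) -> tuple[DoseExperiment, GeneSet]:
    """Multi-dose experiment where the responsive set carries the
    per-dose shifts and every other cell is Normal(0, residual_sd^2).

    If the design names no responsive genes, the first 50 (or n_genes,
    if fewer) genes of the universe are used.  Returns the experiment
    and the ground-truth gene set.
    """
    universe = list(universe) if universe is not None else gene_universe(n_genes)
    if len(universe) != n_genes or len(set(universe)) != n_genes:
        raise ValueError("universe must hold n_genes unique symbols")
    responsive = list(design.responsive_genes) or universe[: min(50, n_genes)]
    missing = set(responsive) - set(universe)
    if missing:
        raise ValueError(f"responsive genes outside the universe: {sorted(missing)[:3]}")

    rng = np.random.default_rng(np.random.SeedSequence(design.seed))
    sample_ids = []
    doses = []
    for level in design.dose_levels:
        for r in range(1, design.replicates_per_dose + 1):
            sample_ids.append(f"d{level}_r{r}")
            doses.append(str(level))
    arr = rng.normal(0.0, design.residual_sd, size=(n_genes, len(sample_ids)))
    resp_idx = [universe.index(g) for g in responsive]
    for j, dose in enumerate(doses):
        shift = design.per_dose_shift[design.dose_levels.index(dose)]
        if shift != 0.0:
            arr[resp_idx, j] += shift
    values = pd.DataFrame(arr, index=universe, columns=sample_ids)
    dose_of = pd.Series(doses, index=sample_ids, name="dose")
    exp = DoseExperiment(values=values, dose_of=dose_of)
    truth = GeneSet(
        name=design.responsive_set,
        description="planted dose-responsive gene set",
        genes=tuple(responsive),
    )
    return exp, truth


def random_gene_sets(
    universe: Sequence[str],
    n_sets: int,
    set_size: int,
    rng: np.random.Generator,
    prefix: str = "random",
) -> list[GeneSet]:
    """Random same-size gene sets drawn without replacement, for null
    calibration and decoy ranking."""
    universe = list(universe)
    if set_size > len(universe):
        raise ValueError("set_size exceeds the universe")
    sets = []
    for i in range(1, n_sets + 1):
        genes = rng.choice(universe, size=set_size, replace=False)
        sets.append(
            GeneSet(
                name=f"{prefix}_{i:04d}",
                description="random gene set",
                genes=tuple(sorted(genes)),
            )
        )
    return sets


def dose_metadata(exp: DoseExperiment, study: str = SYNTHETIC_STUDY) -> pd.DataFrame:
    """Sample-metadata frame (shared TSV dialect) for a dose experiment."""
    rows = []
    for sid in exp.values.columns:
        rows.append(
            {
                "sample": sid,
                "study": study,
                "condition": f"dose_{exp.dose_of[sid]}",
                "dose": exp.dose_of[sid],
                "timepoint": "",
                "is_control": False,
                "replicate": sid.rsplit("_r", 1)[-1],
            }
        )
    return pd.DataFrame(rows).set_index("sample")
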