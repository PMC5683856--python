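"""Dose-effect gene-set enrichment.

For a multi-dose exposure experiment, each gene gets a one-way ANOVA
F statistic with dose group as the (unordered) factor; a large F marks
a strong dose effect.  A gene set is then scored competitively: a
two-sample t-test assuming unequal variances (Welch) compares the mean
of the log2 F statistics inside the set against the mean over all
measured genes.  The default alternative is one-sided "greater", since
enrichment is defined as the set's F distribution being skewed toward
larger values; set members stay in the background by default ("all
genes").  Genes whose F is non-finite or zero (no within-group or no
between-group variation) have no usable log2 F and are excluded from
both groups, with the count reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet

logger = logging.getLogger(__name__)


@dataclass
class DoseExperiment:
    """Gene-by-sample log2 expression with a dose group per sample."""

    values: pd.DataFrame
    dose_of: pd.Series  # sample id -> dose group label

    def __post_init__(self) -> None:
        if set(self.dose_of.index) != set(self.values.columns):
            raise ValueError("dose labels do not cover the sample columns")
        self.dose_of = self.dose_of.loc[list(self.values.columns)].astype(str)
        counts = self.dose_of.value_counts()
        if len(counts) < 2:
            raise ValueError("need at least 2 distinct dose groups")
        small = counts[counts < 2]
        if len(small):
            raise ValueError(
                f"dose group(s) with fewer than 2 samples: {sorted(small.index)}"
            )
        if self.values.isna().to_numpy().any():
            raise ValueError("missing values in dose experiment")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene symbols in dose experiment")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def dose_groups(self) -> list[str]:
        return sorted(self.dose_of.unique())


@dataclass
class GeneFStats:
    """Per-gene one-way dose-effect F statistics and their log2."""

    f: pd.Series
    log2_f: pd.Series
    df_between: int
    df_within: int

    def usable(self) -> pd.Series:
        """Genes whose log2 F is finite (F finite and > 0)."""
        return self.log2_f[np.isfinite(self.log2_f)]


@dataclass
class EnrichmentResult:
    set_name: str
    t_statistic: float
    df: float
    p_value: float
    mean_in_set: float
    mean_background: float
    n_in_set: int
    n_background: int
    n_excluded_nonfinite: int


def dose_f_statistics(exp: DoseExperiment) -> GeneFStats:
    """One-way ANOVA F per gene, dose group as the factor.

    F = (SSB/df_between) / (SSW/df_within).  Genes with zero
    within-group variation get F = +inf; the log2 transform leaves
    those (and F = 0 genes) non-finite, flagged downstream.
    """
    X = exp.values.to_numpy(dtype=float)
    doses = exp.dose_of.to_numpy()
    groups = sorted(pd.unique(doses))
    k = len(groups)
    n_total = X.shape[1]
    grand = X.mean(axis=1)
    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    for g in groups:
        block = X[:, doses == g]
        mu = block.mean(axis=1)
        ssb += block.shape[1] * (mu - grand) ** 2
        ssw += ((block - mu[:, None]) ** 2).sum(axis=1)
    df_between = k - 1
    df_within = n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_between) / (ssw / df_within)
        f = np.where(ssw == 0.0, np.inf, f)
        # no between-group variation means no dose effect, F = 0,
        # even when the within-group variation also vanishes
        f = np.where(ssb == 0.0, 0.0, f)
        log2_f = np.log2(f)
    n_inf = int(np.sum(np.isinf(f)))
    if n_inf:
        logger.info("%d gene(s) with zero within-group variance (F = inf)", n_inf)
    idx = exp.values.index
    return GeneFStats(
        f=pd.Series(f, index=idx, name="F"),
        log2_f=pd.Series(log2_f, index=idx, name="log2F"),
        df_between=df_between,
        df_within=df_within,
    )


def welch_t_test(
    a: np.ndarray, b: np.ndarray, alternative: str = "greater"
) -> tuple[float, float, float]:
    """Two-sample t-test assuming unequal variances.

    Returns (t, Welch-Satterthwaite df, p).  ``alternative`` is
    'greater' (mean(a) > mean(b)) or 'two-sided'.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    sa, sb = va / na, vb / nb
    se2 = sa + sb
    diff = a.mean() - b.mean()
    if se2 == 0.0:
        # both groups constant: no evidence either way
        t = 0.0 if diff == 0.0 else math.inf * np.sign(diff)
        df = float(na + nb - 2)
    else:
        t = diff / math.sqrt(se2)
        df = se2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    if alternative == "greater":
        p = float(stats.t.sf(t, df))
    elif alternative == "two-sided":
        p = float(2.0 * stats.t.sf(abs(t), df))
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    return float(t), float(df), p


def gene_set_enrichment(
    fstats: GeneFStats,
    gene_set: GeneSet,
    alternative: str = "greater",
    background: str = "all",
) -> EnrichmentResult:
    """Welch t-test of in-set vs background mean log2 F.

    ``background='all'`` keeps set members in the background (all
    measured genes); ``'rest'`` excludes them.  Set genes missing from
    the experiment are intersected away with a warning; fewer than two
    usable set genes is a hard error.
    """
    if background not in {"all", "rest"}:
        raise ValueError("background must be 'all' or 'rest'")
    usable = fstats.usable()
    n_excluded = int(len(fstats.log2_f) - len(usable))
    members = [g for g in gene_set.genes if g in usable.index]
    n_missing = len(set(gene_set.genes)) - len(
        set(gene_set.genes) & set(fstats.log2_f.index)
    )
    if n_missing:
        logger.warning(
            "gene set %r: %d gene(s) not measured in this experiment",
            gene_set.name,
            n_missing,
        )
    if len(members) < 2:
        raise ValueError(
            f"gene set {gene_set.name!r}: fewer than 2 usable genes in the experiment"
        )
    in_set = usable.loc[members].to_numpy()
    if background == "all":
        bg = usable.to_numpy()
    else:
        bg = usable.drop(index=members).to_numpy()
    t, df, p = welch_t_test(in_set, bg, alternative)
    return EnrichmentResult(
        set_name=gene_set.name,
        t_statistic=t,
        df=df,
        p_value=p,
        mean_in_set=float(in_set.mean()),
        mean_background=float(bg.mean()),
        n_in_set=len(in_set),
        n_background=len(bg),
        n_excluded_nonfinite=n_excluded,
    )


def enrichment_report(
    exp: DoseExperiment,
    sets: list[GeneSet],
    alternative: str = "greater",
    background: str = "all",
    bh: bool = False,
) -> pd.DataFrame:
    """Score every gene set against one experiment.

    One row per set, sorted by p ascending (ties by set name).  Raw
    p-values by default; ``bh=True`` adds a Benjamini-Hochberg column
    (clearly labeled — the base report applies no correction).
    """
    columns = [
        "set_name",
        "t",
        "df",
        "p",
        "mean_in_set",
        "mean_background",
        "n_in_set",
        "n_background",
        "n_excluded",
    ]
    if not sets:
        return pd.DataFrame(columns=columns)
    fstats = dose_f_statistics(exp)
    rows = []
    for s in sets:
        r = gene_set_enrichment(fstats, s, alternative, background)
        rows.append(
            {
                "set_name": r.set_name,
                "t": r.t_statistic,
                "df": r.df,
                "p": r.p_value,
                "mean_in_set": r.mean_in_set,
                "mean_background": r.mean_background,
                "n_in_set": r.n_in_set,
                "n_background": r.n_background,
                "n_excluded": r.n_excluded_nonfinite,
            }
        )
    table = pd.DataFrame(rows, columns=columns)
    if bh:
        table["p_adj_bh"] = _benjamini_hochberg(table["p"].to_numpy())
    return table.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
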