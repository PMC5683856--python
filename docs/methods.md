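# Methods

## Preprocessing model

The pipeline begins from log2 signal intensities that are already
platform-normalized; raw-array normalization (LOWESS, RMA, quantile)
is deliberately out of scope, since mature implementations exist and
the interesting statistics start afterwards. From there every
collapsing step uses the median: repeated probe rows (technical
replicates), probes sharing a gene symbol, and biological replicates
of a condition. The median of an even count is the mean of the two
middle values. A probe annotated with several gene symbols contributes
its value to each symbol before the per-gene median; probes with no
symbol are dropped and counted. Each treated condition is standardized
to its matched control by subtraction on the log2 scale, and control
columns are removed from the result.

Control matching is an explicit map from treated condition to control
condition. When a study has exactly one control condition the map is
inferred; anything more complex must be supplied, because
control-to-treatment pairing in real studies is design-specific and
cannot be guessed safely.

Studies merge on gene symbol by **intersection**: only genes measured
in every study survive, which is what makes the merged binary matrix
meaningful (an absent measurement is not a 0). A union mode exists for
inspection but produces NaNs that the binarizer rejects by design.
Merged columns are renamed `study::condition` and sorted
lexicographically, so the merge is invariant to input order. Gene
symbols are case-sensitive throughout; the GMT reader has an opt-in
uppercase fold for cross-platform set matching.

Missing values are rejected at ingestion rather than imputed — an
explicit, visible failure beats a silent guess.

## Binarization

`up` marks cells with log2FC ≥ t, `down` marks cells with
log2FC ≤ −t, with t = 1 (2-fold) by default. The boundary is
inclusive — a gene exactly 2-fold up *is* 2-fold up — and for any
t > 0 the two matrices are disjoint and monotone in t (raising t can
only clear cells). Both properties are enforced by property tests.

## Bicluster enumeration

A bicluster is a pair (R, C) of row and column sets whose cells are
all 1 and which is inclusion-maximal: no row outside R is 1 on all of
C, and no column outside C is 1 on all of R. Maximal biclusters are
exactly the **closed column sets**: C with row support R(C) such that
C equals the set of columns that are 1 on all of R(C).

The enumerator is a depth-first search over column sets using
prefix-preserving closure extension (the scheme used by closed-itemset
miners): a node holds a closed set and its row support; a child
extends by one column j past the parent's extension point, intersects
the support, and takes the closure; if the closure acquires any column
ordered before j that the parent lacked, the child duplicates a branch
generated elsewhere and is pruned. Every closed set with nonempty
support is therefore emitted exactly once, with no memoization table.
The search uses an explicit stack (no recursion limit), and two
prunings are sound because support only shrinks and closure only grows
along a branch: branches whose support falls below `min_rows` and
branches whose closure already exceeds `max_cols` are cut.

Size constraints are **filters on the maximal set**, not part of the
maximality judgment: a maximal bicluster wider than `max_cols` is
discarded whole, never truncated (a truncated set would not be
maximal, and which columns to drop would be arbitrary). Output order
is area-descending with lexicographic tie-breaks, so results are a
pure function of the input. A configurable cap on emitted biclusters
raises a hard error on pathological inputs (dense matrices have
exponentially many closed sets) instead of silently truncating.

The test suite carries an independent brute-force oracle — enumerate
every nonempty column subset, keep the closed ones, size-filter — and
the enumerator must agree with it exactly on randomized matrices; an
additional audit re-checks maximality of every emitted bicluster
directly against the matrix. Defaults (min 15 rows, 5–15 columns)
match the discovery settings the workflow was designed around.

## Dose-effect enrichment

Per gene, a one-way ANOVA with dose group as an unordered factor:
F = (SSB/(k−1)) / (SSW/(N−k)). Treating dose as categorical (not a
trend test) is intentional — the "overall" dose effect — so
non-monotone responses count. Genes with SSW = 0 get F = +∞; genes
with SSB = 0 get F = 0. Both have undefined log2 F and are excluded
from the enrichment test on both sides, with the count reported, since
neither carries usable evidence on the log scale. Each group needs at
least two samples; each time point is analyzed as a separate
experiment.

The gene-set score is a two-sample t-test assuming unequal variances
(Welch) of mean log2 F, set versus **all measured genes** (set members
included — a deliberate, documented reading of a competitive test
against the whole array; a set-excluded background is available as
`background="rest"`). The default alternative is one-sided `greater`,
because enrichment is defined as the F distribution being skewed
toward larger values; `two-sided` is available. The statistic and
Satterthwaite degrees of freedom are computed directly from the
definitions, and the test suite requires agreement with scipy's
independent implementation to 1e−10 in t and df and 1e−8 in p over
1000 random instances. No multiple-testing correction is applied by
default (raw per-set p-values); an optional Benjamini–Hochberg column
can be added, clearly labeled.

With the set-inclusive background the two groups overlap, which makes
the test slightly conservative (the overlap adds positive covariance
the Welch variance estimate ignores); with a 50-gene set against a
2000-gene background the effect is below a percentage point of type-I
error and the null calibration check passes comfortably.

## Group-median ordering

For presentation, biological replicates collapse to per-group medians
and the groups (or genes) are ordered by agglomerative clustering with
average (UPGMA) linkage on d = 1 − Spearman ρ, midrank ties. d is
symmetric, zero on the diagonal, bounded by 2, and invariant under any
strictly increasing transform of a single item — the whole linkage
inherits that invariance, which the tests assert. Items are processed
in lexicographic label order so tie-breaking is deterministic. The
tested artifact is the merge history and leaf order; pixel rendering
is a thin optional matplotlib layer.

## Synthetic data: what it emulates, and what it does not

The generators define the package's study conditions:

* **Compendium**: background cells ~ N(0, noise_sd²), planted cells ~
  N(effect_mean, effect_sd²), written in planted order (last writer
  wins on overlap). Gaussian noise on the log2 scale is the standard
  model for log-intensity data. A planted bicluster is *recoverable*
  when |effect_mean| − 2·effect_sd ≥ 1, i.e. its cells clear the
  2-fold threshold with high probability. Recovery experiments use
  effect_mean ±2, effect_sd 0.1, noise_sd 0.2 in a 300 × 20 matrix —
  a deliberately favorable regime that tests the machinery, not the
  biology.
* **Raw study**: baseline 8.0 log2 units + the compendium's fold
  change + independent N(0, noise_sd²) per probe and sample, with
  labeled control samples at baseline, so
  `preprocess(generate_raw_study(c))` equals `generate_compendium(c)`
  exactly at noise_sd = 0 and to within the noise scale otherwise.
* **Dose experiment**: default design 4 dose levels (0/18/54/162 µg
  labels), 3 replicates per dose, a 50-gene responsive set with mean
  shifts (0, 1, 2, 3) log2 units and residual sd 0.5 — an unambiguous
  dose effect used for the power fixtures; the null design sets all
  shifts to 0.

Real data differ in ways the generators do not model: correlated
noise across genes, platform batch effects, heavy-tailed intensity
distributions, biclusters with ragged (non-constant) effects, and
partially overlapping disease programs. Passing the recovery and
calibration checks therefore demonstrates that the algorithms are
implemented correctly and behave as designed under their stated
model — not that real compendia will yield biclusters this cleanly.

Null-calibration runs spread the 1000 random gene sets over 250
independently simulated experiments (4 sets each) so the p-value draws
are nearly independent; scoring many sets against one experiment would
correlate them through the shared background mean.

All generators draw from a single `numpy` Generator seeded per call;
identical configs give bit-identical output, and no global RNG state
is touched.

## Numerical and design choices

* Even-count medians: mean of the middle pair (numpy convention).
* Binarization boundary: inclusive (≥ threshold).
* Welch p-values come from the t distribution survival function; the
  degenerate both-groups-constant case returns t = 0 (equal means) or
  ±∞ (unequal) with pooled df, rather than NaN.
* Spearman correlations are clipped to [−1, 1] before forming
  distances, guarding float overshoot.
* Bicluster output ordering and linkage tie-breaking are fully
  deterministic; the end-to-end pipeline writes no timestamps, so
  reruns with the same config and seed are byte-identical (checked).
* Problem sizes in tests and the acceptance script (300 × 20
  compendia, 1000–2000-gene experiments, 100–250 simulation
  repetitions) were chosen to estimate each rate with adequate
  precision while keeping the default suite fast to run.

## Known limitations

* The enumeration is exponential in the worst case (inherently so:
  dense matrices have exponentially many maximal biclusters); the cap
  turns pathological inputs into a clear error. Realistic sparse
  binarized compendia are far from that regime.
* Discovery-phase condition counts beyond a few hundred columns have
  not been profiled.
* The enrichment test assumes approximate normality of mean log2 F
  within a set (CLT at typical set sizes ≥ 15); very small sets with
  heavy-tailed F may be miscalibrated.
* No GEO ingestion: inputs must already be expression TSVs plus
  metadata, or synthetic.
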