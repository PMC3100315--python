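# Methods

This note records the models and procedures the package implements, the
conventions chosen where more than one was defensible, what the
synthetic-data generator does and does not emulate, and the limits of
what the test suite shows.

## Preprocessing

**Probe collapsing.** When several probes interrogate one gene, the
probe with the largest across-sample interquartile range is kept and
its row carried over unchanged — no averaging, so collapsed values
remain bit-identical to measured ones. Quartiles use the
linear-interpolation definition; ties between probes with equal IQR
(measure-zero on real data) break to the lexicographically smallest
probe id so the operation is deterministic.

**Ortholog mapping.** Cross-species matching goes exclusively through
a one-to-one map reflecting reciprocal-best-match orthology; the map is
required to be injective in both directions at construction and the
package never resolves many-to-many homology families itself. Gene
symbols are case-sensitive: human/mouse symbol-case conventions differ,
and implicit case-folding would hide mapping loss.

**Standardization.** A z-score linear transform with sample SD
(divisor n−1). The default mode standardizes across genes within each
sample, which remains well-defined for cohorts so homogeneous that
per-gene statistics are degenerate; a per-gene (across-sample) mode is
provided because either reading of "across genes standardization" is
defensible for heterogeneous cohorts. Each cohort is standardized
separately before any cross-cohort comparison. Missing values are not
supported anywhere: RMA-style summarized matrices are complete, and
both ranks and IQR become ambiguous under missingness.

## Subtype classification

Centroids are per-class means of standardized expression over a fixed
classifier-gene list; no gene selection or shrinkage is performed,
because the gene list is an input (e.g. the orthologs of a published
classifier, 723 of 840 genes). Two assignment routes are exposed:
highest Pearson correlation to a centroid (population-divisor
covariance; the divisor cancels in r) and smallest Euclidean distance
on standardized values. Their agreement is itself a meaningful check —
on real data the two routes agreeing on every sample is evidence the
classification is signal-driven — so `agreement()` is part of the API
rather than a test-only construct. Exact score ties assign the first
class in model order and set a `tie` flag. When a query platform lacks
some classifier genes, `CentroidModel.restrict()` retrains nothing: it
slices the centroid matrix to the surviving genes, mirroring how a
published classifier is reduced to cross-platform orthologs.

Unsupervised grouping uses average-linkage agglomeration on
1 − Pearson distance between samples, with no leaf-order optimization;
output is the SciPy linkage matrix.

## Single-sample enrichment

Expression is reduced to within-sample ranks (highest expression →
rank N; ties averaged), so any strictly monotone transform of a
sample's values leaves every score unchanged. The walk visits genes by
descending rank (average-rank ties in stable input order), rising at a
set member by rank^p normalized by the summed weights of all members,
falling by 1/(N − N_hit) otherwise. The weight exponent defaults to
p = 1/5 and is configurable but deliberately locked down in
`GseaConfig` defaults.

The reported score is read literally as the *signed sum* of the two
extreme deviations — max above zero plus min below zero — not the
maximum absolute deviation. This keeps ES in [−1, 1] and makes a set
split between both ends of a ranking cancel toward zero. Because hit
increments and miss decrements each sum to one, the walk ends at zero;
the tests use this as a structural invariant.

Set members absent from a matrix's gene universe are dropped with a
logged count — partial mapping is the expected regime when gene lists
cross platforms — and a set losing *all* members is a hard error. For
two-list contrasts, each list's ES is z-scored across samples (within
each dataset when dataset labels are given, since extreme-patient
selection is per dataset) and samples are ranked by the difference;
a list with zero ES spread z-scores to all-zeros with a warning rather
than failing the whole ranking. No permutation-based significance or
NES normalization is computed.

## Differential expression

Welch's t with Satterthwaite df is the default statistic; a moderated
variant shrinks the pooled per-gene variance toward the across-gene
mean, s̃²_g = (d0·s0² + d_g·s²_g)/(d0 + d_g), referred to d_g + d0
degrees of freedom. When d0 is not given it is estimated by matching
the observed variance of log s²_g to trigamma(d_g/2) + trigamma(d0/2)
(trigamma-inverse method of moments); no excess spread yields d0 = ∞,
i.e. a pooled z-like test, which is the statistically correct limit for
homogeneous variances. Genes with zero within-group spread in Welch
mode are flagged and fall back to the moderated p-value; a gene
constant in both groups gets difference 0 and p = 1. P-values are
two-sided; adjustment is Benjamini–Hochberg; list derivation uses
*strict* inequality at the FDR cutoff so boundary genes are excluded
deterministically. Covariates are not supported.

The pipeline-level list derivation uses the moderated mode: at small
group sizes (8+8) with a planted 1.5-SD effect and 10% non-null genes,
a Benjamini–Hochberg fixed-point analysis puts the Welch statistic's
expected recall near 0.33 while the moderated statistic reaches ~0.61,
and variance moderation is also the approach the field uses for
microarray-scale two-group comparisons.

## Survival stratification

Per dataset, the top and bottom floor(fraction × n) ranked samples
(default fraction one third) are pooled across datasets. Floor rather
than rounding keeps the two groups disjoint for any fraction ≤ 1/2 and
makes the per-dataset counts auditable; they are reported in the
result. Datasets too small to contribute are skipped with a warning.

The Kaplan–Meier estimator and the two-group Mantel–Cox log-rank test
are computed with lifelines. Conventions: median survival is the
smallest observed event time where Ŝ(t) ≤ 0.5, reported as not-reached
(`None`) when the curve never falls that far; events precede
censorings at tied times; the log-rank statistic is (ΣO − ΣE)²/ΣV
against χ² with 1 df, and a zero total variance is a hard error rather
than a silent p = 1.

## Synthetic cohorts

All generators work on the log2 scale with Gaussian noise, emulating
RMA-summarized arrays, and are deterministic given the config seed
(each generator draws from its own child stream). Defaults are the
study conditions the package is validated under:

- **Subtyped cohort** — 4 classes, 723 classifier genes of 1000, 20
  samples per class split into train/validation halves. Per-gene
  baselines are N(8, 1); class centroids on classifier genes are
  N(0, 1.5) (i.e. between-class effect 1.5 within-class SDs, noise
  SD 1); non-classifier genes are pure noise.
- **Mouse-like cohort** — 20 samples around one class centroid with
  within-cohort SD 0.5 (tumors driven by a single genetic program are
  far more homogeneous than a patient cohort), its own gene namespace
  and baseline, an ortholog map retaining 723/840 ≈ 86% of genes, and
  optional 2–3 probes per gene (probe jitter SD 0.2) to exercise
  collapsing.
- **Lineage sets** — five disjoint 80-gene sets; samples of a cell
  type have their matching set shifted up by log2(1.5) ≈ 0.585 against
  replicate noise SD 0.5 and a cross-gene baseline spread of SD 1.
  The within-type replicate SD of 0.5 is at the upper end of what
  sorted-cell-type array replicates show, making the planted fold a
  conservative signal.
- **Genotype/survival cohort** — 80 patients in 4 pseudo-datasets;
  one third lean toward the aggressive archetype (genotype ± 0.5 lean
  plus N(0, 0.15) jitter), mirroring the tertile logic of selecting the
  patients most resembling each model. 200 planted genes split evenly
  between the two directions at 1.5 SD between pure archetypes.
  Survival is exponential — no shape parameter to tune, and log-rank
  behavior under exponential hazards is well understood — with
  per-day baseline hazard ln 2 / 553 (a 553-day baseline median) and
  hazard ratio 2.5^lean01; censoring is an independent competing
  exponential tuned to censor ~20% of follow-ups.

What the generator does **not** emulate: probe-level intensity physics,
batch effects and normalization artifacts, correlated gene-gene
structure beyond the planted class/genotype programs, non-proportional
hazards, informative censoring, and clinical covariates (age, G-CIMP
status). Passing tests therefore demonstrate the pipeline's arithmetic
and its statistical behavior under its own model assumptions — not
robustness to the full messiness of cohort data.

## Problem sizes and validation design

The validation suite runs at desk scale: classifier recovery sweeps 50
seeds of the default cohort; null FDR control uses 50 repetitions of a
1000-gene 6+6 null; planted DGE performance is reported as the mean
over 20 repetitions of the 2000-gene 8+8 design, because a single
draw's recall has a sampling SD (~0.04) comparable to its distance
from the 0.6 benchmark while the mean estimates the design's true
recall; log-rank calibration uses 200 null and 100 powered
repetitions. The acceptance script uses one seed-derived cohort per
stage (10 repetitions for the DGE metrics) so a full run stays under a
few seconds.

## Known limitations

- The ortholog map must already be one-to-one; ambiguous homology
  families have to be resolved upstream.
- Nearest-centroid distance is plain Euclidean on standardized values;
  class-specific shrunken centroids and gene selection are out of
  scope, with the correlation-route agreement serving as the
  validation surface.
- The moderated statistic estimates only a global variance prior; no
  abundance-dependent trend, array weights, or covariates.
- Survival analysis is the two-group log-rank comparison only — no Cox
  regression or multivariate adjustment.
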