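# xsub

Cross-species tumor expression subtyping, single-sample gene-set
enrichment, and signature-based survival stratification.

## The problem

Mouse tumor models are only useful to the extent that they resemble a
definable subgroup of human tumors. Establishing that resemblance from
expression data — and then using the mouse models to partition human
patients into groups with different outcomes — takes a chain of
well-defined steps: collapsing array probes to genes, mapping genes
across species through one-to-one (reciprocal-best-match) orthology,
standardizing the two platforms onto a comparable scale, classifying
samples against published subtype centroids (for glioblastoma: the
Proneural, Neural, Classical and Mesenchymal classes), scoring each
sample against lineage and differential gene lists with a rank-based
single-sample enrichment statistic, and finally comparing the survival
of patients at the two extremes of a signature ranking. `xsub`
implements that chain as a typed, tested Python library, together with
a synthetic-data module that generates every input with known ground
truth so the whole pipeline is exercisable without any external cohort.

## The statistics at the core

**Centroid classification.** For class $c$ with training samples
$S_c$, the centroid is $\mu_{gc} = \frac{1}{|S_c|}\sum_{s\in S_c}
z_{gs}$ over classifier genes $g$, where $z$ is standardized
expression. A query sample $q$ is assigned to
$\arg\max_c\, r(z_{\cdot q}, \mu_{\cdot c})$ (Pearson correlation) or
$\arg\min_c\, \lVert z_{\cdot q} - \mu_{\cdot c}\rVert_2$ (nearest
centroid); the two routes should, and on clean data do, agree.

**Single-sample enrichment score.** Expression values in a sample are
replaced by ranks $r_g$ (highest expression gets rank $N$, ties
averaged). Walking genes from the top of the ranking downward, the
running sum rises by $r_g^{p}/\sum_{h\in S} r_h^{p}$ at genes in the
set $S$ and falls by $1/(N - |S|)$ otherwise, with weight exponent
$p = 1/5$. The enrichment score is the signed sum of the walk's two
extremes,

$$\mathrm{ES} = \max(\textstyle\max_i W_i,\,0) + \min(\textstyle\min_i W_i,\,0) \in [-1, 1].$$

Two gene lists $A$ and $B$ are contrasted per sample by z-scoring each
list's ES across samples (within each dataset) and ranking samples by
$z_A - z_B$.

**Differential expression.** Per gene, a two-sample $t$ statistic in
either Welch form or a moderated form that shrinks the pooled variance
toward the across-gene mean, $\tilde s_g^2 = (d_0 s_0^2 + d_g s_g^2)/
(d_0 + d_g)$, with $d_0$ estimated from the spread of $\log s_g^2$.
Benjamini–Hochberg adjustment at FDR 0.1 and the sign of the mean
difference yield the two gene lists ("up in A" / "up in B").

**Survival.** Per dataset, the top and bottom $\lfloor n/3\rfloor$ of
the signature ranking are pooled into two groups, compared by the
Kaplan–Meier product-limit estimator and the Mantel–Cox log-rank test
$(\sum O - \sum E)^2 / \sum V \sim \chi^2_1$.

## Worked example

`examples/signature_survival.py` runs the full chain on a synthetic
80-patient cohort in which a third of the patients lean toward an
aggressive expression archetype with 2.5-fold hazard:

```
differential expression at FDR 0.1: 112 genes up in PtenP53, 111 up in Pten
selected 24 patients per end ({'D2': 6, 'D3': 6, 'D4': 6, 'D1': 6} per dataset)
median survival, signature-high group: 256 days
median survival, signature-low group:  744 days
log-rank chi-square = 5.57, p = 0.0182
```

The differential analysis recovers the planted genotype signature; the
enrichment-difference ranking puts aggressive-archetype patients at the
top; and the pooled tertile groups separate in survival — the
signature-high group's median survival is roughly a third of the
signature-low group's, at a log-rank p below 0.05.

The other examples cover the remaining capabilities:
`classify_subtypes.py` (centroid training and dual-route
classification, 0% held-out error at default signal strength),
`cross_species_mapping.py` (probe collapsing, ortholog mapping, and
100% assignment of a homogeneous cohort to its planted class), and
`lineage_enrichment.py` (lineage-set scoring; the matching set has the
top ES in 100% of samples at 1.5-fold planting).

## Layout

- `src/xsub/containers.py` — typed in-memory objects (expression
  matrix, gene sets, ortholog map, survival records)
- `src/xsub/io.py` — TSV/GCT/GMT/ortholog/survival readers and writers
  with strict validation
- `src/xsub/preprocess.py` — probe collapsing (max IQR), ortholog
  mapping, z-standardization, dataset intersection
- `src/xsub/classify.py` — centroid training, correlation and
  nearest-centroid classification, hierarchical clustering
- `src/xsub/gsea.py` — rank-based single-sample enrichment and the
  ES-difference ranking
- `src/xsub/dge.py` — Welch/moderated differential expression, FDR,
  gene-list derivation and cross-species mapping
- `src/xsub/survival.py` — extreme-rank selection, Kaplan–Meier,
  log-rank
- `src/xsub/simulate.py` — synthetic cohorts with ground truth

See `docs/methods.md` for the modeling choices and their rationale.
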