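# Methods

This note documents the models and procedures `chromins` implements,
the parameter choices that matter, what the synthetic generator does
and does not emulate, and the numerical decisions taken where the
design was genuinely open.

## Interval algebra and co-deposition

All coordinates are BED-convention 0-based half-open `[start, end)`.
"Overlap by one base pair" means an intersection of length ≥ 1, so
abutting intervals (`a.end == b.start`) share no base and do not merge.
Chromosome names are compared as exact strings; callers harmonise
naming (e.g. `chr1` vs `1`) upstream.

`merge_overlapping` replaces each connected component of the
≥ `min_overlap`-base overlap graph by its union span.  With the default
`min_overlap = 1` components are contiguous, outputs are pairwise
disjoint and covered bases are preserved exactly.  For
`min_overlap > 1` two distinct components can overlap by fewer than
`min_overlap` bases; the component unions are returned as-is (the
requirement that outputs be disjoint is satisfiable only at
`min_overlap = 1`, which is the convention used throughout the
pipeline).

`codeposition_regions` pools both marks' peaks, builds ≥ 1 bp overlap
components, keeps components containing at least one peak of each mark,
and reports each component's union span (mark `region`, score = member
count).  The union-span rule is asserted for chains of any length, not
only pairs.  The operation is symmetric in its arguments; empty input
produces an empty result with a warning rather than an error.

The implementation is a per-chromosome sweep with union-find; it is
validated against a per-base brute-force oracle (union-find where every
base unions all intervals covering it) on hundreds of random instances.

## Regulatory map and gene connection

The integrated regulatory map pools three element kinds, each carrying
connected gene identifiers:

* **enhancers** from a flat BED4+genes export (element interval plus a
  comma-separated connected-gene list).  Connection scores are not
  filtered: a hit element contributes its entire gene list;
* **gene bodies**, one per gene model, connected to that gene;
* **promoters**, `promoter_len` bases (default 2000) immediately
  upstream of the TSS — `[start − L, start)` on "+", `[end, end + L)`
  on "−" — clipped at the chromosome origin and dropped (with a
  warning) when clipped away entirely.

A query region hits an element iff their intersection is ≥ 1 bp, the
same threshold as peak colocalization; the threshold is intentionally
not configurable per element kind.  Elements are deduplicated per gene,
giving the per-gene cis-RE count.  The stage also reports the fraction
of regions hitting at least one enhancer-kind element (the "within
cis-RE" fraction) and, per gene set, the fraction of member genes
connected to at least one region-bearing element.  Interval queries go
through an `intervaltree` index and are checked against a brute-force
double loop in the tests.

## Differential expression

The DE engine is a per-gene negative-binomial log-linear model with
median-of-ratios size factors as offsets — deliberately self-contained,
with no dispersion shrinkage, independent filtering or outlier
refitting.  Exact replication of any published gene counts is therefore
not expected; the engine's contract is calibration and parameter
recovery, which the test suite measures.

* **Size factors.**  Reference = per-gene geometric mean over units,
  restricted to genes expressed in every unit; factor = median ratio,
  rescaled to geometric mean 1.  When no gene is expressed everywhere a
  documented `pseudo_reference=True` fallback uses nonzero-unit
  geometric means.
* **Designs.**  `paired-contrast`: intercept + donor indicators +
  treatment term; the reported estimate is the treatment log₂ fold
  change.  `covariate`: intercept + continuous covariate (plasma
  insulin); the estimate is the log₂-scale slope per covariate unit.
  Requires ≥ 3 units per group (contrast) or ≥ 6 units (covariate).
* **Dispersion.**  Method of moments from the Pearson statistic of a
  Poisson fit of the full design, with a leverage correction:
  `phi = (X² − Σ(1 − h_ii)) / Σ((1 − h_ii) µ_i)`, floored at 1e−8 and
  capped at 50.  The leverage term matters: without it the estimate is
  biased low by roughly `1 − p/n`, which inflated the Wald type-I error
  to ~0.17 in the donor-indicator design during development.
* **Inference.**  Wald statistic on the coefficient of interest,
  referred to a t distribution on the residual degrees of freedom
  `n − p`.  The t reference (rather than the normal) absorbs the
  plug-in dispersion's finite-sample noise; measured type-I error at
  p < 0.05 is 0.037–0.062 across dispersions 0.05–0.5 in a 10 vs 10
  design and ~0.059 in the 6-donor paired design, against ~0.08–0.11
  for the normal reference.  All-zero genes get missing estimates and
  are excluded from the BH denominator; non-converged fits are flagged
  with missing p.
* **Multiple testing.**  Step-up Benjamini–Hochberg with monotonicity
  enforcement, capped at 1, missing values passed through.
* **Insulin-responsive union.**  Genes with `padj < alpha` (default
  0.05; no published threshold exists for this quantity, so the default
  is configurable) in the stimulation contrast, united with those from
  the insulin regression; both margins and the intersection are
  reported as Venn counts.  Genes tested in only one arm can enter the
  union.

Fits are batched across genes (IRLS on `(G, p, p)` stacked normal
equations), so a 5000-gene null simulation runs in about a second.
Exact invariance of estimates under per-unit count rescaling is not a
property of a count likelihood (rescaling one observation reweights the
score equation); the suite instead verifies offset-correctness — fitting
a pre-normalised matrix changes estimates by < 0.01 log₂ in the median.

## Gene-set scores, correlations, ORA

**SES.**  For gene set S and unit j, `SES_j = Σ_{g∈S} z_gj` where `z_g`
is the gene's expression z-scored across units with sample standard
deviation (ddof 1).  The sum (not the mean) is used, matching the
"expression sum" reading; `n_genes_used` is reported per set so a
mean-scaled variant is recoverable.  Member genes absent from the
matrix or with zero variance are dropped.  SES is cohort-relative:
scores sum to ~0 over the full unit collection, and recomputing on a
unit subset re-centres them — this is intended behaviour, not a bug.
SES is invariant under positive gene-wise affine transforms of the
expression matrix.

**Normalisation.**  Bulk: size-factor scaling then `log2(x + 1)`.
Single cell: per-cell scaling to the median total depth then
`log2(x + 1)`.  Both schemes are standard and configurable by passing
any pre-normalised matrix.

**Mean splits.**  `split_by_gene_mean` labels a unit `hi` iff its
normalised expression of the split gene (e.g. *BIRC5*) exceeds the
cohort mean; ties go to `lo` for determinism.

**Correlation.**  Spearman rho = Pearson on midranks, two-sided p by
the t approximation (n ≥ 4 required); constant vectors yield an
undefined, flagged result.  Expression ratios (e.g. *INSR*:*IGF1R*) are
computed on linear-scale normalised expression with a pseudocount
(default 1) in numerator and denominator.

**Over-representation.**  Enrichment of a discrete gene list is tested
with the hypergeometric upper tail (probability of ≥ k set members in
|query| draws from |universe|), BH-adjusted across sets.  This models a
discrete input list directly, in place of a ranked (KS-statistic) GSEA;
each set is intersected with the universe before testing and the query
must be a subset of the universe.

## ISM stratification

The per-cell insulin-signaling score is the **mean** normalised
log-expression of the ISM panel (*INSR, IGF1R, IRS1, IRS2*); absent
panel genes are dropped with a warning, and at least one must be
present.  A summed variant is obtainable through `SESScorer` with the
panel as a gene set — both readings of "mean expression" vs
"expression sum" are thus available, with the mean as default.

Classification thresholds at the mean score, with two scopes:

* **global** (default): one threshold, the mean over all cells.  Under
  a per-cluster split every cluster with a roughly symmetric, unimodal
  score distribution lands near 50% high, which cannot produce
  between-group prevalence contrasts such as 13.3% vs 6.7%; the global
  scope can, and is therefore the default.
* **per-cluster**: each cell is compared with its own cluster's mean;
  singleton clusters are labelled low with a warning.  The suite
  demonstrates both behaviours on synthetic data with cluster-level
  ISM differences (global tracks the differences; per-cluster pushes
  every cluster toward ~50%).

Ties at the threshold are labelled low.  Prevalence is
`100 · n_high / n_total` per cluster group; the cluster → group map is
configuration (default aggressive = {Tph, proliferating, Vdelta2}).
The 2×2 high/low × group table is tested with Pearson chi-square
(`Σ (O − E)²/E`, df = 1, no continuity correction, upper-tail p); zero
margins are an error.  Group-wise comparisons of SES or single genes
use Wilcoxon–Mann–Whitney (unpaired; exact permutation distribution for
tie-free samples up to 30 observations, otherwise a tie-corrected
normal approximation without continuity correction) or the Wilcoxon
signed-rank test (paired, pairs matched by within-group order,
all-zero differences giving p = 1 with a warning).

## Synthetic data

The generator produces every input the pipeline consumes, with exact
truth bookkeeping, threading all randomness through one seeded
`numpy.random.Generator` so outputs are byte-identical given (config,
seed).

* **Peaks** (`gen_peaks`): truth co-deposition regions are built as one
  peak per mark with a guaranteed ≥ 1 bp overlap; every other placement
  is rejection-sampled with ≥ 1 bp separation from all existing
  components, so the pipeline's recovered region set must equal the
  planted truth exactly.  Defaults: 500 peaks per mark, lengths uniform
  200–1000 bp, two 5 Mb chromosomes, co-deposited fraction 0.3.
* **Regulatory map** (`gen_regmap` / `gen_genomic`): genes tiled every
  25 kb (3 kb bodies, alternating strands, 2 kb promoter slots kept
  clear), 120 enhancers of 1.5 kb in intergenic gaps connected to 1–3
  nearest genes; a configurable fraction (default 0.4) of truth regions
  is placed inside enhancers.  The region → element → gene truth is
  computed by a plain double loop with direct coordinate arithmetic,
  independent of the indexed annotation path it validates.
* **Bulk counts** (`gen_bulk`): NB counts with log-normal baseline
  means (median 200, ln-sd 1), log-normal sample size factors (ln-sd
  0.15), dispersion 0.05 by default (0 gives the Poisson limit).
  Paired design: donor baseline wobble of 0.15 log₂ sd and a planted
  ±1 log₂ fold change on the responsive fraction (default 10%).
  Covariate design: plasma insulin log-normal (median 10, ln-sd 0.4 —
  a fasting-insulin-like scale in µU/mL) and a planted ±0.08 log₂ per
  insulin unit slope, centred at the mean insulin so baselines stay
  comparable.  `gen_bulk_pair` plants one shared responsive program in
  both arms: the two designs are two probes of the same biology, which
  is what the union rule assumes.
* **Single cell** (`gen_sc`): cells are assigned clusters by configured
  proportions, groups by the cluster → group map, and within each group
  a planted fraction of cells is true-high ISM with all four panel
  genes' means shifted up by 2 log₂ units.  Per-cluster marker genes
  (×4 in their own cluster), response genes (*BIRC5, IFNG, TNF*,
  down-shifted ×0.5 in true-high cells) and 300 background genes add
  structure; per-cell depth factors are log-normal (ln-sd 0.25).
  Preset twins: `rast_sc_config` (aggressive group 30% of cells,
  prevalences 13.3% / 6.7%) and `t2d_sc_config` (active group 40%,
  13% / 4%).

### What the single-cell generator does and does not emulate

The ISM panel is simulated highly expressed (mean 600 counts) with
near-Poisson dispersion (0.003) and background variability is modest
(dispersion 0.1).  These values were chosen from a noise budget: with a
global-mean threshold and ~9% overall prevalence, the threshold sits
only ~0.15 log₂ above the low mode, so recovering planted prevalences
within ±1.5 percentage points requires the four-gene mean score's
standard deviation (including the depth-normalisation noise contributed
by background-gene overdispersion, and after the ~0.2 log₂ shrinkage of
the planted shift caused by high-ISM cells' inflated totals) to stay
below ~0.06 log₂.  The generator therefore plants a cleanly bimodal,
low-noise signal: passing recovery tests demonstrates that the
scoring, classification, prevalence and chi-square bookkeeping is
correct, *not* that mean-split classification is robust to
droplet-level sparsity, dropout, doublets, ambient RNA or batch
effects, none of which are simulated.  On real sparse data the same
classifier will misclassify more cells and prevalence contrasts will
attenuate toward the mean.

## Problem sizes and runtimes

The test suite exercises: 200 random interval instances (≤ 300
intervals, 10 kb) against the per-base oracle; 25 seeds of 1000-peak
co-deposition and of full genomic truth recovery; a 5000-gene null
calibration (10 vs 10, dispersion 0.2); 10-seed recovery of the
responsive union (2000 genes, 200 planted) and of the regression slope
(n = 24); 10-seed stratification recovery at 5000 cells for both tissue
twins; and a byte-reproducibility check of the CLI on the shipped
fixture.  The full suite runs in well under a minute on one CPU; the
acceptance script in a few seconds.

## Known limitations

* Peak calling, input normalisation and enrichment filtering are
  consumed, not computed; peaks arrive as BED.
* The DE engine's per-gene dispersions are unshrunk; at very small
  sample sizes its power is below that of empirical-Bayes engines, and
  the paired 6-donor design relies on the regression arm to recover
  weakly powered genes through the union rule.
* GO structure is not traversed; gene sets are consumed flat (GMT).
* Cluster labels are consumed as metadata; no clustering, label
  transfer or embedding is performed.
* SES values are cohort-relative and not comparable across cohorts
  without re-computation.
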