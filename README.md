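# chromins

Chromatin co-deposition, insulin-responsive expression and single-cell
insulin-signaling stratification, in one tested pipeline.

## The problem

In chronically inflamed tissue (rheumatoid arthritis synovium) and in
hyperinsulinemic states (type 2 diabetes), CD4⁺ T-cell phenotype is
coupled to insulin signaling and to histone acetylation.  A typical
study of this coupling combines several analysis layers:

1. **Chromatin co-deposition.**  ChIP-seq peak sets for a
   chromatin-associated factor (survivin/BIRC5) and an active-enhancer
   mark (H3K27ac) are overlapped: peaks overlapping by ≥ 1 bp are
   merged, and connected components containing both marks define
   *co-deposition regions*.
2. **Regulatory annotation.**  Co-deposition regions are intersected
   with an integrated regulatory-element map — enhancers with
   experimentally supported target-gene connections (a GeneHancer-style
   export), gene bodies, and 2 kb upstream promoters — and the full
   list of connected genes is retrieved, with per-gene cis-RE counts
   and per-pathway connection fractions.
3. **Insulin-responsive genes.**  Two bulk RNA-seq designs are fit with
   a negative-binomial Wald model: a donor-paired insulin-stimulation
   contrast (log₂ fold change) and a regression of expression on plasma
   insulin level (log₂ slope per insulin unit).  The *insulin-responsive*
   set is the union of genes significant in either arm (BH FDR < α),
   with Venn counts and hypergeometric over-representation against GO
   pathway sets.
4. **Gene-set scores and stratification.**  Pathway activity per sample
   or cell is the standardized expression sum, SES = Σ_g z_g (z-scores
   across units); per-cell insulin signaling is the mean normalised
   expression of the ISM panel *INSR, IGF1R, IRS1, IRS2*.  Cells are
   classified high/low ISM at the global mean score, high-ISM prevalence
   is compared between "aggressive" and other cluster groups with a 2×2
   Pearson chi-square, and SES / single genes are compared between
   strata by Wilcoxon tests.

`chromins` implements each layer as a reusable library module plus a
CLI, and ships a seeded synthetic-data generator that plants every
structure the pipeline detects (co-deposited regions, regulatory
connections, responsive genes, high-ISM cells) with exact truth
bookkeeping, so the whole chain is testable end to end.

## Worked example

Stratify a synthetic twin of the RA synovial-tissue cohort (5000 cells,
aggressive clusters planted at 13.3% high-ISM prevalence vs 6.7%
elsewhere, ISM shift 2 log₂ units):

```python
from chromins.synthetic import rast_sc_config, gen_sc
from chromins.setscore import normalize_sc
from chromins.stratify import ISMStratifier

counts, meta, truth = gen_sc(rast_sc_config(), seed=1)
strat = ISMStratifier().fit(normalize_sc(counts), meta)
print(strat.prevalence_.prevalence.round(2))
print(strat.chi2_)
```

```
group
aggressive    13.08
other          7.37
Name: prevalence_pct, dtype: float64
ChiSquareResult(statistic=41.54124520871565, df=1, p=1.1541015743286824e-10)
```

The recovered prevalences sit within sampling error of the planted
13.3% / 6.7%, and the chi-square test on the 2×2 high/low × group table
is decisive — the same contrast shape the stratification stage reports
on real cluster labels.

The genomic arm runs the same way on the shipped fixture bundle:

```python
from chromins.intervals import read_bed, codeposition_regions
from chromins.annotate import (read_re_table, read_gene_models,
                               build_regmap, assign_regions)

a = read_bed("fixtures/peaks_survivin.bed")
b = read_bed("fixtures/peaks_h3k27ac.bed")
regions = codeposition_regions(a, b)
regmap = build_regmap(read_re_table("fixtures/re_map.tsv"),
                      read_gene_models("fixtures/gene_models.tsv"))
asn = assign_regions(regions, regmap)
print(f"{len(a)} + {len(b)} peaks -> {len(regions)} co-deposition regions")
print(f"{asn.n_enhancer_hit}/{asn.n_regions} regions within cis-RE "
      f"({100 * asn.enhancer_fraction:.1f}%), "
      f"{len(asn.connected_genes)} connected genes")
```

```
150 + 150 peaks -> 45 co-deposition regions
18/45 regions within cis-RE (40.0%), 18 connected genes
```

## Command line

```bash
chromins simulate --outdir bundle --seed 7        # synthetic inputs + truth
chromins all --config bundle/config.yaml          # all three analysis arms
chromins codeposition|insulin|stratify --config … # individual arms
```

Every analysis choice (promoter length, FDR threshold, classification
scope, ISM panel, cluster→group map, gene-set files) lives in the YAML
configuration; reruns with the same config and seed are byte-identical.
A small pre-generated bundle ships under `fixtures/`.

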