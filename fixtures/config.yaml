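inputs:
  bulk_gene_sets: bulk_genesets.gmt
  cell_meta: cell_meta.tsv
  gene_models: gene_models.tsv
  genome_gene_sets: genome_genesets.gmt
  peaks_a: peaks_survivin.bed
  peaks_b: peaks_h3k27ac.bed
  re_map: re_map.tsv
  reg_counts: reg_counts.tsv
  reg_meta: reg_meta.tsv
  sc_cells: sc_cells.txt
  sc_counts_mtx: sc_counts.mtx
  sc_gene_sets: sc_genesets.gmt
  sc_genes: sc_genes.txt
  stim_counts: stim_counts.tsv
  stim_meta: stim_meta.tsv
outdir: results
params:
  aggressive_clusters:
  - Tph
  - Vdelta2
  - proliferating
  alpha: 0.05
  ism_genes:
  - INSR
  - IGF1R
  - IRS1
  - IRS2
  promoter_len: 2000
  scope: global
  wilcoxon_genes:
  - BIRC5
  - IFNG
  - TNF
seed: 7
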