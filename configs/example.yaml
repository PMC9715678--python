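# Small end-to-end example: 2 x 2 Mb genome, 2 cell types x 3 replicates,
# 4 planted differential clusters, 2 planted enriched TFs.
simulation:
  seed: 7
  chrom_sizes: {chr1: 2000000, chr2: 2000000}
  n_genes: 60
  gene_length_range: [4000, 12000]
  n_repeats: 60
  rna_reads_per_sample: 200000
  reads_per_sample: {5mC: 100000, 5hmC: 100000, input: 20000}
  n_clusters: 4
  cluster_span_range: [4000, 40000]
  cluster_min_gap: 100000
  n_tfs: 12
  n_enriched_tfs: 2
  sites_per_tf: 60
analysis:
  window_sizes: [1000]
  alpha: 0.05
  gap_bp: 5000
  density: 0.125
  min_reads: 20
  min_total: 10
  tss_flank: 2000
  asymmetry_sizes: [1000, 10000, 100000]
  n_sample_windows: 2000
  n_shuffles: 30
  seed: 3
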