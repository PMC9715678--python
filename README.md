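# strandmod

Strand-resolved DNA-modification (5mC / 5hmC) analysis between two cell
populations, built around stranded immunoprecipitation reads where the read
strand reports the strand of the modified DNA. The package provides, as one
reproducible pipeline:

- **Window / TSS / gene-body differential calling** from pooled stranded
  counts with an exact conditional binomial test (a deliberate, self-contained
  replacement for MEDIPS/DESeq2-style fits) and Benjamini–Hochberg control.
- **Cluster construction** of differentially modified regions from
  significant 1-kb windows by a two-stage rule: same-direction windows less
  than 5 kb apart seed clusters, which then greedily absorb the nearest
  same-direction significant window while the significant-window density of
  the span stays strictly above 1/8.
- **Strand-asymmetry statistics**: the coefficient |plus − minus| / total
  (20-read minimum), multi-scale random-window sampling, asymmetric-region
  size estimation via adjacent-pair majority-strand concordance with a
  random-pair control, per-gene template/coding ratios stratified by
  expression deciles, repeat-family asymmetry, and CH-dinucleotide sequence
  asymmetry with its reverse-complement duality.
- **TFBS permutation enrichment**: overlap of significant windows with
  binding-site sets, z-scored against 100 genome-wide interval shuffles.
- **A synthetic experiment generator** (`strandmod.simulate`) that plants
  differential clusters (merge-safe under the clustering rule), nested
  two-scale strand-asymmetric domains, expression-coupled gene-body signal
  with TSS dips, repeat-family strand bias, CH sequence bias, and enriched
  TFBS sets — with full truth tables, so every downstream statistic is
  testable against planted ground truth.

Genome-scale counting uses fragment-midpoint assignment throughout (totals
are conserved and strand-decomposable); all coordinates are 0-based
half-open (BED-native).

## CLI

```bash
# full synthetic pipeline: simulate -> count -> diff -> cluster -> genes ->
# asymmetry -> tfbs -> report
strandmod run --config configs/example.yaml --outdir runs/demo

# write the synthetic inputs (FASTA, BED12 genes, BED6 reads/repeats/TFBS,
# TSV expression + truth tables) for stage-by-stage use
strandmod simulate --config configs/example.yaml --outdir sim/

# stage commands on files
strandmod validate --chrom-sizes sim/genome.chrom.sizes --sample s1:D1:5mC:1:sim/D1_5mC_r1.bed
strandmod diff --chrom-sizes sim/genome.chrom.sizes --assay 5mC \
    --sample D1_5mC_r1:D1:5mC:1:sim/D1_5mC_r1.bed ... \
    --group-a D1_5mC_r1,D1_5mC_r2,D1_5mC_r3 --group-b D2_5mC_r1,D2_5mC_r2,D2_5mC_r3 \
    --out diff.tsv
strandmod cluster --diff-table diff.tsv --out-bed clusters.bed --out-tsv clusters.tsv
strandmod asymmetry --chrom-sizes sim/genome.chrom.sizes --sample ... --out-prefix asym
strandmod chsym --fasta sim/genome.fa --bed regions.bed --out ch.tsv
strandmod tfbs --chrom-sizes sim/genome.chrom.sizes --diff-table diff.tsv \
    --tfbs-bed sim/tfbs.bed --out tfbs.tsv
```

`runs/demo/report.json` carries the headline numbers (significant-window
counts and cross-assay concordance, cluster tables with large-cluster
counts and grouped fractions, gene evidence Venns, expression-stratified
asymmetry medians, TFBS ranking, truth recall/precision); every number is
recomputed from the stage TSVs. Reruns with the same config are
byte-identical on all TSV outputs.

## Layout

| module | contents |
| --- | --- |
| `strandmod.genome` | coordinate types, tiling, midpoint counting, feature assignment |
| `strandmod.io` | BED6/BED12, chrom-sizes, FASTA, bedGraph, TSV readers/writers |
| `strandmod.simulate` | synthetic experiment generator + truth tables |
| `strandmod.differential` | exact binomial test, BH, pooled differential tables |
| `strandmod.clusters` | gap/density cluster builder + summaries |
| `strandmod.genes` | strata, metagene profiles, merged gene calls, coupling stats |
| `strandmod.asymmetry` | asymmetry coefficients, concordance curves, CH asymmetry |
| `strandmod.tfbs` | interval shuffling and permutation z-scores |
| `strandmod.pipeline` / `strandmod.cli` | orchestration, validation, CLI |
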