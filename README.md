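# bsascan

Bulked-segregant analysis (BSA-seq) of two-pool sequencing data for mapping a
recessive trait, plus a synthetic F2 pooled-sequencing data generator so the
whole pipeline runs with no external data.

The toolkit covers:

- **Simulation** (`bsascan.simulate`) — F2 progeny from a selfed F1 via a
  Markov gamete walk with Haldane recombination fractions (optional
  recombination-suppressed blocks), a single fully recessive causal locus,
  phenotype bulks, binomial pooled read sampling with symmetric sequencing
  error, and deterministic VCF 4.2 output (samples `WT_pool`, `GT_pool`) with
  a ground-truth TSV.
- **Input** (`bsascan.variants`) — two-pool VCF reading (AD-based counts,
  multi-allelic drop/split policies), GFF3 gene models, and strand-aware
  functional-region classification (exonic > promoter > intronic >
  intergenic; promoter = 2 kb upstream of the start codon).
- **Filters** (`bsascan.filters`) — combined/per-pool depth filter
  (default DP 25–250), shared-hom-alt and shared-het exclusions from
  pool-genotype calls reconstructed at 0.1/0.9 allele-fraction cutoffs, and an
  exact binomial test for exonic-variant depletion.
- **Statistics** (`bsascan.stats`) — per-site Euclidean distance between pool
  allele-frequency vectors (`sqrt(2)·|Δf|`), 2×2 likelihood-ratio
  G-statistic, signed Δ allele frequency, and the distance to the recessive
  "ideal frequency" vector (mutant pool fixed at 1, wild-type pool at 1/3).
- **Scan** (`bsascan.scan`) — sliding-window means (default 1 Mb window,
  100 kb step), candidate regions from the top empirical quantile of window
  scores (default 99%), and candidate-site ranking by ascending
  ideal-frequency distance with a top-5% ceiling selection.
- **Consequence** (`bsascan.consequence`) — applies a VCF-anchored variant to
  a spliced CDS, translates with the standard code, and reports frameshift /
  in-frame / substitution effects with original and truncated protein lengths.
- **Pipeline & CLI** (`bsascan.pipeline`, `bsascan.cli`) — orchestrated run
  writing TSV/BED artifacts and a JSON summary. The shared-het filter is
  applied after region calling (ranking stage only); applying it before the
  window scan leaves only extreme-noise sites outside the linked region and
  destroys the scan's contrast.

## CLI

```sh
# synthetic dataset -> VCF + truth
bsascan simulate --out-dir sim --n-f2 240 --n-sites 2000 --chrom-length 20000000 --seed 1

# full pipeline from a two-pool VCF (optionally with --config run.yaml)
bsascan run --vcf sim/bulks.vcf --out-dir out

# individual stages
bsascan filter sim/bulks.vcf --out kept.tsv --report attrition.tsv
bsascan stats sim/bulks.vcf --out site_stats.tsv
bsascan scan site_stats.tsv --out-windows windows.tsv --out-regions regions.bed
bsascan rank site_stats.tsv --regions-bed regions.bed --out candidates.tsv --all-classes
bsascan annotate variants.vcf --gff3 genes.gff3 --fasta genome.fa --out consequences.tsv
```

`bsascan run` writes `site_stats.tsv`, `windows.tsv`/`windows.bed`,
`regions.bed`, `candidates.tsv`, `filter_report.tsv`, `consequences.tsv`
(when GFF3+FASTA are given), `summary.json`, and a resolved-config YAML whose
re-run is bit-identical.

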