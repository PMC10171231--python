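# locusfilter

Alignment quality control, gene-tree filtration, supermatrix assembly,
and species-tree program configuration for target-capture phylogenomic
data sets, plus a synthetic-data generator so the whole workflow can be
exercised end to end without real sequence data.

## What it does

- **I/O** (`locusfilter.phyio`): FASTA / relaxed-Phylip alignments,
  Newick trees with integer bootstrap labels, RAxML partition files and
  NEXUS sets blocks.
- **Alignment statistics** (`aln_stats`): per-marker length, taxon
  sampling proportion, parsimony-informative-site counts/proportions,
  missing-data proportion; set-level aggregate tables.
- **Quality control** (`aln_qc`): reference-divergence screening
  (>40%), minimum taxa/length keep rule (>3 taxa, >100 bp), external
  end trimming to ≥50% coverage, 100-bp window masking of locally
  misaligned sequence (>40% divergence from consensus), reading-frame
  selection for coding markers (>90% stop-free inclusion).
- **Filtration** (`filtration`): built-in threshold series for four
  statistics in summary-tree and concatenation modes; keep-if-at-least
  filtering of alignments and their paired gene trees; full sweeps with
  survivor reports.
- **Supermatrix** (`supermatrix`): concatenation with gap-filling and
  codon-aware partitioning, 200-kb gene-jackknife replicate matrices,
  bipartition (clade) frequency summaries across tree sets.
- **Tree metrics** (`treemetrics`): unrooted clade monophyly and
  support scoring, low-support branch collapsing (<10), gene
  concordance factors, OLS branch-length/support regression.
- **Downstream configs** (`downstream_configs`): BPP v4 A01
  control/sequence/imap files (burnin 10000, sampfreq 2, nsample
  100000, gamma(3, 0.004) priors), SVDquartets NEXUS with PAUP block
  (evalq=all, multilocus bootstrap), collapsed multi-tree Newick input
  for quartet summary methods.
- **Synthetic data** (`synthgen`): random species trees, gene trees
  with length-dependent NNI error (Poisson-distributed, rate ∝
  1/length), JC69 sequence simulation, and full study generation with a
  truth manifest.

## CLI

All stages are exposed as subcommands of `locusfilter`:

```bash
locusfilter simulate --seed 7 --out study/            # synthetic study
locusfilter summarize --alignments study/alignments \
    --roster roster.txt --out stats.tsv               # statistics
locusfilter qc --alignments study/alignments --out qc/ --log qc.tsv
locusfilter filter --stats stats.tsv --trees study/gene_trees \
    --stat length_bp --mode summary_tree --out filtered/
locusfilter concat --alignments study/alignments --roster roster.txt \
    --out matrix.phy --partitions parts.txt
locusfilter jackknife --alignments study/alignments --roster roster.txt \
    --target-bp 200000 --reps 100 --seed 1 --out jk/
locusfilter clades --trees study/gene_trees --clades clades.tsv \
    --out clade_report.tsv
locusfilter collapse --trees study/gene_trees --min-support 10 --out collapsed/
locusfilter gcf --species-tree study/species_tree.nwk \
    --trees study/gene_trees --out gcf.tsv
locusfilter bpp --alignments study/alignments --out bpp/
```

The roster file is one taxon name per line; the clade file is TSV with
columns `name`, `member`, and optional `role=outgroup`.

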