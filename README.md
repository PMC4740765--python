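# ystrkit

A toolkit for Y-STR haplotype analysis in forensic and population
genetics: haplotype parsing and panel algebra, forensic summary
statistics, R_ST/AMOVA population structure with permutation testing,
classical MDS ordination, neighbor-joining phylogeny, multi-class linear
discriminant analysis, and a stepwise-mutation forward simulator for
generating test data with known structure.

## Features

- **Data model** (`ystrkit.haplotypes`) — exact-rational allele calls
  covering integer repeats, intermediate alleles (e.g. `34.1`), null
  alleles and duplications; built-in nested marker panels (minimal 9,
  PowerPlex Y12, Yfiler 17, PowerPlex Y23, 26-locus) with panel
  projection; delimited-text haplotype tables.
- **Forensic statistics** (`ystrkit.forensic`) — allele frequencies by
  direct counting (duplications contribute every copy, nulls form their
  own class), Nei gene diversity, haplotype diversity ± SE, match
  probability, discrimination capacity and proportion of unique
  haplotypes, multi-panel reports. All estimators run in exact rational
  arithmetic and round half-up only for display.
- **Population structure** (`ystrkit.structure`) — squared repeat-size
  distances, two- and three-level AMOVA variance components, pairwise
  R_ST matrices (negative values retained) and permutation p-values.
- **Ordination & phylogeny** (`ystrkit.ordination`) — Torgerson classical
  MDS and Saitou–Nei neighbor joining with deterministic tie-breaking;
  Newick read/write.
- **Discriminant analysis** (`ystrkit.discriminant`) — the marker
  exclusion rule (structural exclusion of multi-copy loci and the
  DYS389 pair; loci anomalous in more than one sample dropped), LDA via
  the between/within scatter generalized eigenproblem, factor scores and
  marker–factor correlations.
- **Simulation** (`ystrkit.simulate`) — forward stepwise-mutation model
  with population splits, admixture draws, anomaly injection, and
  resampling from marginal allele-frequency tables.
- **Bundled data** (`ystrkit.datasets`) — allele-count tables of a
  published 26-locus survey of 100 Uyghur males, reconstructed from the
  printed frequency columns and verified against the printed
  gene-diversity row.

## CLI

```sh
ystr validate table.csv --panel 26Y                 # schema/diagnostics
ystr stats table.csv --panel 26Y --out report.tsv   # forensic parameters per panel
ystr rst table.csv --panel ppy23 --perms 10000 --seed 42 --out rst.tsv
ystr mds rst.tsv --k 2 --out mds.tsv
ystr nj rst.tsv --out tree.nwk
ystr lda table.csv --panel yfiler17 --out scores.tsv --loadings loadings.tsv
ystr simulate config.yaml --out sim_table.csv
```

Haplotype tables are comma- or tab-delimited with header
`SampleID,Population,<locus...>`; allele tokens are integer repeats,
decimals (`34.1`), `null`, or comma/hyphen-separated duplications
(`13,14`).

A simulation config is YAML, e.g.

```yaml
panel: ppy23
mutation_rate: 0.01
generations: 150
within_generations: 10
splits: [[root, East, 0], [root, West, 0]]
sizes: {East: 50, West: 50}
seed: 7
```

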