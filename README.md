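# armfold

Comparative annotation and folding of extremely degenerate (arm-less,
mismatch-laden) mitochondrial tRNAs across a clade of closely related
species, together with the mitogenome descriptive statistics,
control-region scanning and gene-order comparison that support such an
analysis. A synthetic-clade simulator generates truth-annotated
mitogenomes so the whole pipeline is testable without downloads.

## What it does

- **mito I/O** (`armfold.io`, `armfold.model`): GenBank/FASTA/TSV feature
  tables over a circular-genome data model (0-based half-open internally,
  origin-spanning features supported), with gene-name normalization.
- **genome stats** (`armfold.stats`): A+T content and AT/GC skews per
  gene/strand/codon-position partition, start/stop codon tallies
  (including truncated `T`/`TA` stops), circular overlap/spacer maps,
  amino-acid frequencies and RSCU under the invertebrate mitochondrial
  code.
- **tRNA annotation** (`armfold.fold`, `armfold.grammar`): explicit
  grammar with four structural classes (cloverleaf, D-armless, T-armless,
  arm-less), anticodon-arm anchoring, candidate windows between
  non-tRNA genes (50-bp pads), and per-class best-fold enumeration scored
  by canonical pairs (+1), G·T wobbles (+0.5) and acceptor-stem
  mismatches (−1, at most 4 of 7).
- **comparative structure** (`armfold.consensus`): per-identity ortholog
  sets, deterministic star alignment, per-arm conservation flags
  (presence in all species + overlapping alignment columns + stem length
  tolerance 1), consensus class calls with near-tie alternatives.
- **control region** (`armfold.control_region`): maximal stem-loop
  (inverted repeat) finder with attached homopolymer runs, poly-N run
  detection, duplicated-motif discovery by seeded local self-alignment,
  and a non-coding region scan labelling CR/CR2.
- **gene order** (`armfold.gene_order`): signed circular permutations,
  strand counts, single-gene transposition/inversion diffs, shipped
  reference order fixtures.
- **simulator** (`armfold.simulate`): ~14-kb circular clades with planted
  tRNA classes, literal sequence-sharing gene overlaps, compensatory
  stem mutation, and a planted control region (hairpin + poly-A +
  duplicated unit shared with a second non-coding region).

## CLI

```sh
armfold simulate --seed 7 --n-species 6 --divergence 0.02 --out sim/
armfold stats sim/sp1.gb --out stats.tsv
armfold trnas sim/sp1.gb --out trnas/
armfold consensus sim/sp*.gb --out consensus.tsv
armfold cr sim/sp1.gb --out cr.tsv
armfold order-diff araneomorphae dysderoidea
armfold run --seed 7 --out run_out/
```

All tabular outputs are TSV; structures are written as dot-bracket.

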