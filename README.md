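# conservomics

Cross-species integration of differential expression and differential
chromatin accessibility between two cell states (lens epithelial vs fiber
cells), built as a tested, reusable pipeline:

- **io_core** — domain types and plain-text readers/writers (DE TSV, BED6 /
  BED6+2 peaks, TSS BED, JASPAR PFM, GMT, two-column ortholog TSV, FASTA via
  pyfaidx). Coordinates are uniformly 0-based half-open.
- **conserved_expression** — per-species epithelial/fiber/NS gene
  classification (`log2FC < 0 & q < alpha` → epithelial, `> 0` → fiber),
  ortholog intersection into conserved gene sets, and upper-tail
  hypergeometric association tests computed in log space.
- **promoter_chromatin** — strand-aware promoter windows (default −7.5 kb /
  +2.5 kb around the TSS) and the promoter chromatin-state rule
  (epithelial-preferred iff ≥1 epithelial-specific and 0 fiber-specific
  differential peaks in the window, and the mirror; BOTH / NONE otherwise).
- **peak_assignment** — nearest-TSS assignment by peak midpoint (ties to the
  lexicographically smallest gene) and partitioning of peaks by conserved
  class of the assigned gene.
- **motif_enrichment** — PFM→log-odds conversion, both-strand PWM scanning
  (N scores −∞), fixed-fraction hit thresholding (default 0.75 of the
  maximum achievable score), dinucleotide-preserving shuffled controls
  (Altschul–Erickson), one-sided Fisher hit-count tests with BH adjustment
  per test family, the six-way motif partition
  (EPI_ONLY / EPI_PREFERRED / FIBER_ONLY / FIBER_PREFERRED / SHARED / NONE),
  cross-species label combination, and the expressed-TF filter.
- **geneset_overlap** — hypergeometric overlap reports (k, n, K, N, percent,
  p) against curated gene sets and generic GMT-based over-representation
  analysis with BH correction. Symbols match case-insensitively.
- **synthetic_data** — a fully self-contained two-species fixture (genomes,
  TSS, orthologs, DE tables, differential peaks with planted motif
  instances, motif library with decoys, curated gene sets) plus a
  ground-truth manifest with per-file checksums. Everything derives from one
  seed, so two same-seed runs are byte-identical.
- **pipeline** — end-to-end orchestration from a fixture directory to
  deterministic TSV result tables.

## CLI

```sh
conservomics simulate --seed 1 --out fixture/          # synthetic fixture
conservomics validate fixture/de_a.tsv fixture/peaks_a.bed
conservomics run --fixture fixture/ --out results/ --alpha 0.05 --seed 17
conservomics motifs --epi-peaks epi.bed --fiber-peaks fiber.bed \
    --genome genome.fa --motifs motifs.jaspar \
    --alpha 0.05 --threshold-fraction 0.75 --seed 17
```

`run` writes one TSV per stage (expression classes, conserved gene pairs,
association tests, promoter states, conserved promoters, peak assignments,
motif enrichment per species and test family, combined motif partition, ORA
tables).

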