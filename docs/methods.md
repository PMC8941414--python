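# Methods

## Coordinate conventions

All internal coordinates are 0-based, half-open, on chromosome names with
any `chr` prefix stripped (mitochondrial synonyms collapse to `MT`).
GTF/GFF input (1-based, inclusive) and VCF/GWAS positions (1-based) are
converted at the I/O boundary; chain files are already half-open. Intervals
that share only an endpoint do not overlap; a union merges them into one
run. Only autosomes are analysed: by default any chromosome whose
normalized name is purely numeric, or an explicit list via
`AnnotationConfig.autosomes`.

## The twelve-category annotation

Gene models contribute the exonic and intronic categories:

* **ExonCDS** — the union of CDS intervals.
* **ExonUTR** — per protein-coding transcript, exon minus CDS, unioned
  across transcripts. A base translated in one isoform and untranslated in
  another belongs to both ExonCDS and ExonUTR; no transcript-collapsing
  rule is imposed.
* **ExonOther** — exons of transcripts whose biotype is not
  `protein_coding` (the transcript biotype decides, so non-coding isoforms
  of coding genes count here).
* **IntronProximal / IntronDistal** — introns are the gaps between
  consecutive exons of a transcript. The `splice_window` (default 10 bp)
  intronic bases adjacent to each junction are proximal; an intron no
  longer than twice the window is entirely proximal. The window is
  intron-side only — exonic bases next to a junction stay exonic, because
  the classes partition *intronic* nucleotides.

The regulatory build contributes **Promoter**, **EnhancerProximal**
(promoter-flanking regions), **EnhancerDistal** (standalone enhancers),
**CTCF**, and **Miscellaneous** (unannotated TF-binding sites and open
chromatin both collapse here). The feature-type vocabulary is a
configurable mapping; unknown types are counted and reported, and a file
with no recognized type at all is rejected as the wrong input.

**TADBoundary** is ±`tad_flank` (default 25 kb) around each domain edge,
clipped to chromosome bounds and merged when domains abut.

Non-residual categories keep their mutual overlaps, and each category's
denominator counts its bases independently (so coverage percentages can sum
past 100). Two categories are residual: IntronDistal drops any base that
carries another annotation, and Unannotated is the complement of everything
else. Consequently the twelve sets jointly cover every autosomal base, and
the residual sets are disjoint from all others — both properties are
asserted by `CategoryMap.validate()` and checked exactly against per-base
labelling loops in the tests.

## Alignment projection

The chain reader expands each chain's `size dt dq` body into gap-free
blocks, validates the arithmetic against the header span (an inconsistent
chain is rejected by id), and converts `-`-strand query coordinates onto
the query forward strand. Because the downstream question is "does this
human base have *an* orthologous mouse base", the index enforces single
coverage on the reference: where chains overlap, the higher-scoring chain
keeps its bases and the lower-scoring block is truncated to the remainder
(deterministically, ties broken by chain id; every truncation is logged).
Net-filtered pairwise alignments are already single-coverage, so on such
input this is a no-op safety net.

`map_position` is a binary search into the per-chromosome block arrays;
inside a `-` block the mouse position counts down from the block's far end.
UNALIGNED is an ordinary value (the statistic counts it); an unknown
chromosome is an error, so typos cannot silently deflate fractions. All
table computations go through a vectorized interval projector; per-base
loops exist only in the test oracles.

No minimum chain score is applied by default (`--min-chain-score` exposes
one).

## Conservation statistics

Per category: denominator = bp covered in the human map; aligned = bp
intersecting the chain blocks; common = aligned bp whose mouse image lies
in the *same* category in the mouse map, by set membership — the mouse base
may carry other categories too, which is the weaker and safer reading of
"same annotation in each species". Mapped segments are scored individually
rather than unioned, so reference bases whose images coincide each count
once.

Two aggregate rows use a different "common" notion because their bases are
multi-category: **Genome** (all bases) and **NonCoding** (bases not in
ExonCDS; `--noncoding-def non-exonic` excludes all three exonic classes
instead) count an aligned base as common when its image shares *at least
one* category with it. This is computed exactly by atomizing each
chromosome into runs of constant category membership and overlapping each
run's image with the union of the corresponding mouse category sets.

Variant sites get a single display category via an explicit precedence
order (most specific first: ExonCDS > ExonUTR > ExonOther > Promoter >
EnhancerProximal > EnhancerDistal > CTCF > TADBoundary > Miscellaneous >
IntronProximal > IntronDistal > Unannotated), configurable because no
single-category rule is canonical; a site is "common" when its image is in
its own category's mouse set.

The two-proportion z-test uses the pooled estimate and a two-sided normal
p-value. When the pooled proportion is 0 or 1 the statistic is undefined
and an explicit degenerate result is returned. p-values below 1e-300 are
floored and labelled `< 1.0e-300`, so extreme results print as bounded
inequalities rather than 0. No multiple-testing correction is applied to
the headline columns; a Bonferroni column is included and marked
supplementary. The implementation is cross-checked against
`statsmodels.stats.proportion.proportions_ztest` in the tests.

## The synthetic genome pair

The generator exists to make the pipeline falsifiable: it plants
annotations whose conservation parameters are known in closed form, then
checks that the pipeline recovers them.

* **Layout.** Each chromosome is tiled with shuffled cassettes separated by
  random gaps (defaults 50–400 bp): a 3-exon gene cassette (UTR-CDS /
  CDS / CDS-UTR with two introns, so UTRs, splice windows and distal
  introns all exist), single-exon non-coding genes, fixed-length regulatory
  features, and TAD domains whose edges are placed inside otherwise-empty
  sequence. Planted categories are disjoint by construction (the analysis
  tolerates overlap; the truth bookkeeping is simpler without it). An
  infeasible coverage request fails before any file is written.
* **Retention/turnover.** Every maximal single-category block (long blocks
  chunked to ≤2 kb first — real alignments come in finite ungapped blocks,
  and chunking keeps the sampling variance of the realized fractions
  commensurate with the planted bp) aligns with probability `r_c`. Aligned
  blocks keep their annotation with probability `1 − t_c`; otherwise the
  turnover splits evenly between feature loss and relabelling to a
  different regulatory category. The background category is relabel-only:
  an uncovered mouse base is Unannotated by definition, so "loss" cannot
  de-annotate it. Expected fraction aligned is exactly `r_c`, expected
  common `r_c(1−t_c)`, and the emitted truth table also records the
  realized post-coin-flip counts, which the pipeline must reproduce *bit
  exactly* (and does, in the acceptance tests).
* **Chains.** Aligned blocks are grouped into chains (geometric sizes,
  mean 4 blocks), ~30% on the `-` query strand; one mouse chromosome
  mirrors each human chromosome, with mouse coordinates packed with random
  gaps (reverse-packed for `-` chains so mouse position strictly decreases
  with human position).
* **Mouse annotations.** Retained images are realized in the file formats
  the pipeline actually reads: regulatory features directly; exon images as
  minimal one-exon transcripts; intron images via scaffold transcripts with
  1 bp anchor exons placed in the inter-image gaps; TAD boundary images as
  the left boundary of a mouse domain whose other edge sits in a scratch
  zone beyond all images. Scaffold side-effects occupy mouse positions that
  are never images of aligned human bases, so they cannot perturb the
  conservation counts — a claim the per-base oracle comparisons verify
  exactly.
* **Variants.** Site counts per (source, category) are sampled uniformly
  without replacement within that category's planted bases; their
  aligned/common truth is inherited from their block. ClinVar records for
  the Mendelian set carry passing significance/review strings, flanked by
  engineered failures (wrong significance, wrong review status, indels);
  GWAS rows carry qualifying traits and p < 1e-8, plus duplicates
  (multi-trait rows for one site), wrong-ontology rows, under-threshold
  p-values and unparseable p-values. Default composition concentrates
  Mendelian sites in coding/promoter sequence and complex-disease sites in
  distal introns and background.
* **Defaults.** Per-category `r_c` and `r_c(1−t_c)` default to the
  conservation levels characteristic of human–mouse comparisons for each
  annotation class — near-total alignment and retention for coding exons,
  intermediate for UTRs/promoters/proximal introns, heavy turnover for
  enhancers/CTCF/miscellaneous, and weak alignment for background — with
  plausible intermediate values chosen once for classes lacking a published
  anchor (non-coding exons, CTCF commonality, residual-category
  commonality). All randomness flows from one seeded generator;
  re-running with the same seed reproduces byte-identical files.

**What the generator does not emulate.** No nucleotide sequence (the
analysis is purely positional, so none is needed); no overlap between
planted categories; no spatial clustering of features or variants; no
extra conservation of variant sites beyond their category's block-level
rates — real Mendelian variant sites are far more aligned than their
surrounding annotation class average, which here is mimicked only through
the category composition of the planted site counts. Passing tests
therefore certify the *computation*, not any biological claim about real
genomes.

## Numerical and sizing choices

* All counting is exact integer interval arithmetic; there are no
  tolerances in the pipeline itself. Stochastic tests use 3 standard
  errors computed from the block-length moments
  (`SE = sqrt(p(1-p)·ΣL²)/ΣL`), because retention is a whole-block
  Bernoulli draw, and require ≥99% of seeded checks inside the band.
* Test fixtures use 2 × 30 kb chromosomes (brute-force per-base oracles
  stay fast) with a 500 bp TAD flank scaled to fixture size; parameter
  recovery runs 100 seeds at 2 × 1.8 Mb with ≥50,000 planted bases per
  category.
* Degenerate inputs: zero-length domains are rejected per record;
  single-exon transcripts contribute no introns; empty categories produce
  NaN fractions and are excluded from identity-limit assertions; the
  variant planter refuses a category with fewer planted bases than
  requested sites.

## Known limitations

* The reverse (mouse→human) index is built for round-trip validation, not
  exposed as a first-class mouse-perspective analysis.
* Genome-scale inputs work through the same code paths but the
  atomized aggregate rows and gffutils in-memory databases are tuned for
  fixture scale, not for a 3 Gb genome on one core.
* MAF/axt alignments and indel/structural variants are out of scope;
  GWAS LD expansion and allele-level consequence prediction are not
  attempted.
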