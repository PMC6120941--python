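# Methods

## The problem

Unique molecular identifiers (UMIs) tag each captured mRNA molecule before
PCR, so that all sequencing reads descending from one molecule share a tag
and can be collapsed to a single count. Standard UMI deduplication assumes
that reads from one molecule share a mapping coordinate. In practice, reads
sharing a UMI frequently map to a short run of *adjacent* coordinates — a
modal position holding most reads with diminishing numbers 1–3 bp up- and
downstream. We call such a run a **UMI-read cluster**. A counting scheme
that treats every (UMI, coordinate) pair as a molecule then inflates the
apparent expression of affected genes by up to the cluster size.

The package detects these clusters, collapses them, and quantifies the
artefact. The association of large clusters with homopolymers and short
tandem repeats in the modal read — and the restriction of coordinate
spacings to multiples of a repeat unit — points at repeat-stabilised PCR
stutter as a contributing mechanism, which is also what the bundled
simulator models.

## Pipeline

1. **Preprocess** (`preprocess`). Reads whose UMI substring has mean Phred
   quality < 30 (configurable) are discarded; the UMI (first `umi_length`
   bases, or the mate read's first bases, per layout) moves into the read
   header as `<id>_UMI:<seq>`, followed by removal of a fixed number of
   template-switch motif bases (4 for the GGGG motif, 3 for shorter
   variants). The motif trim is a fixed count, not a motif match; how often
   the expected all-G motif was present is tallied. Phred encoding is fixed
   at offset 33; offset-64 data is rejected loudly rather than guessed.
   Reads with N inside the UMI are kept if they pass the quality filter.
2. **Unique-alignment filter** (`alignio`). Only mapped records with
   `NH:i:1` pass. For aligners that omit NH, an opt-in MAPQ threshold
   (`--assume-unique`) substitutes. Position keys are (reference, strand,
   1-based leftmost POS). POS is used as-is for both strands: the intended
   aligner settings force end-to-end alignment, so soft-clip adjustment does
   not apply, and using POS for reverse reads matches a SAM-line-oriented
   reading of the pipeline. `--ignore-strand` merges orientations for a
   strand-blind analysis; the stranded default treats sense/antisense reads
   at one coordinate as distinct molecules.
3. **UMI merging per coordinate** (`umicluster`). UMIs at one coordinate
   within Levenshtein distance 1 are the same molecule. Because distance-1
   adjacency is not transitive, merging is greedy abundance-first: UMIs are
   visited in descending read count (ties lexicographic) and join the first
   group whose *representative* is within distance 1, else found a new
   group. This is deterministic and independent of input order. Across
   coordinates, identity is exact equality of representatives; fuzzy
   cross-position matching is not implemented (limitation below).
4. **Cluster chaining**. Per (reference, strand, representative UMI), sorted
   coordinates chain by single linkage with `max_gap` = 3 bp (configurable):
   a gap > `max_gap` starts a new cluster, so a cluster can span far more
   than 3 bp in total — observed real clusters reach dozens of adjacent
   positions. `max_gap = 0` degenerates exactly to per-coordinate UMI
   counting.
5. **Collapsing and statistics**. Each cluster collapses to one molecule
   observation at its modal coordinate (max read count, ties leftmost —
   deterministic and order-independent). Pooled shift distributions
   re-centre every cluster on its own mode and sum *read* counts per offset
   (per-read weighting, following "pooled by summing the number of reads");
   the density normalises to 1 and peaks at offset 0 by construction.
   Clusters whose consecutive gaps all equal n are "strictly n"; size-1
   clusters are classified "none" and excluded from strictly-n panels but
   included in the all-clusters panel. Any square-root display of densities
   is a plotting transform only; stored values are untransformed.
6. **Gene counting** (`genecount`). Observations are written as standard
   0-based half-open single-base BED intervals (deviating from a
   start==stop dialect; overlap logic is exact either way) and intersected
   with GFF3 `gene` features (1-based inclusive, conversion handled
   exactly). A site overlapping several genes counts for all of them,
   mirroring default interval-intersection behaviour; `--unique-only` drops
   ambiguous sites. Per gene the table reports raw reads, uncollapsed UMIs
   (every (UMI, coordinate) pair), collapsed UMIs (one per cluster, placed
   by its mode), and their ratio — the apparent over-expression factor,
   >= 1 wherever defined. A cluster spanning a gene boundary is assigned by
   its mode in collapsed mode and coordinate-by-coordinate in uncollapsed
   mode; that is the faithful rendering of the two schemes being compared,
   and it can leave a gene with uncollapsed > 0, collapsed = 0 (ratio NaN,
   flagged rather than clamped).
7. **Complexity** (`complexity`). For each cluster the most frequent read
   sequence at the modal coordinate (ties lexicographic) is scored with
   Shannon entropy H = -Σ p(x) log2 p(x) over base fractions (N excluded)
   and mutual information over consecutive non-overlapping 2-mers with
   whole-string marginals (odd-length strings drop their first base).
   Reference points: homopolymer H = 0, I = 0; perfect dinucleotide repeat
   H = 1, I = 2; uniform composition H = 2. The whole-string-marginal
   definition is deliberate — per-position marginals would score a perfect
   dinucleotide repeat 0 instead of 2. One-way fixed-effects ANOVA with
   cluster size as the factor tests the trend, on H and I separately; size
   groups with fewer than 2 records are dropped (within-group variance
   undefined), and zero within-group variance with differing means reports
   F = inf, p = 0 explicitly.

## Simulator

`simulate` generates ground-truthed libraries: genes tiled on one synthetic
chromosome, each with a fixed capture site; a configurable fraction of
genes carry a tandem repeat (unit 1–3 bp) across the capture window.
Each molecule draws a uniform random UMI; each PCR cycle duplicates every
copy, and with probability `stutter_prob` a new copy of a repeat template
shifts its start by ± one repeat unit. Offsets therefore accumulate as a
lazy random walk in unit steps — a bell-shaped cluster emerges without
being hard-coded, unit-u templates produce strictly-u spacings, and every
occupied offset's ancestor offsets are also occupied, so adjacent gaps never
exceed the unit. Stutter is modelled at the mapped-start level (the
pipeline consumes alignments); an optional FASTQ with inline UMI + GGGG
motif supports end-to-end runs through a real aligner. All randomness comes
from one seeded NumPy generator with a fixed draw order: identical configs
give byte-identical files.

Defaults (chosen once as a realistic desk-scale library): 50 genes of
400 bp, 30% repeat-bearing, 20 molecules per gene, 10 bp UMIs, 4 PCR
doublings with every final copy sequenced (16 reads per molecule — the
per-molecule depth of a small deeply sequenced library), 36 bp reads,
stutter probability 0.1 per cycle, sequencing substitution rate 0. The
zero default error rate is deliberate: recovery experiments then isolate
the stutter artefact, and `truth_compare` can demand exact agreement.
Substitution error (applied to read and UMI alike when enabled) is used in
tests to exercise Levenshtein merging.

`truth_compare` scores a pipeline gene table against the truth: absolute
error of collapsed counts per gene, the expected uncollapsed count (distinct
offsets per molecule, summed), and a per-gene UMI-collision flag — two
molecules of one gene whose true UMIs lie within Levenshtein distance 1 are
indistinguishable to any UMI method, so collision genes are scored
separately.

What the simulator does *not* emulate: transcriptome structure (splicing,
3' bias), cell barcodes, per-molecule amplification efficiency, mapping
errors, reverse-strand reads, and any stutter mechanism beyond ±1 unit per
cycle. Passing recovery tests therefore show that the method inverts the
modelled artefact exactly, not that real libraries are fully corrected;
on real data, shifts larger than `max_gap`, UMI collisions and mapping
noise all remain.

## Numerical and design choices

- Levenshtein distances are computed with edlib; a brute-force dynamic
  program serves as the test oracle.
- Cluster chaining is verified against explicit connected components of the
  within-gap graph on randomized instances; cluster counts are
  non-increasing in `max_gap`, and read totals are conserved exactly.
- All output tables have stable sort orders; re-running the pipeline on
  identical inputs is byte-identical.
- The ANOVA F statistic is computed from explicit sums of squares rather
  than delegated, so degenerate inputs have defined results; the regular
  case is cross-checked against an independent ANOVA routine in tests.
- Entropy/MI of "random 36-mers" have no asserted reference value: the
  plug-in entropy of uniform random 36-mers is ~1.94 bits in expectation
  and MI carries a small-sample positive bias; simulator-based tests assert
  only the direction of the repeat-vs-random contrast.

## Test problem sizes

Unit and property tests run on hand-built instances and 10–20-gene
simulations; the desk-scale statistical checks use 1000 random clustering
instances and a 60-run recovery grid (50 genes x 20 molecules; stutter
0/0.1/0.3; seeds 1–20, ~16k reads per run). The whole suite completes in
well under a minute on one CPU.

## Known limitations

- Cross-position UMI identity is exact; a fuzzy cross-position mode is not
  implemented.
- Shift pooling is per-read only; per-cluster weighting is not offered.
- Spliced alignments are keyed by POS only; intron-spanning shifts are out
  of scope.
- The mate-read layout assumes the two FASTQ streams iterate in lockstep
  (as produced by standard paired dumps); no re-pairing by id is attempted
  beyond the per-pair stem check.
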