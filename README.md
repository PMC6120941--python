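# umishift

Detection, quantification and collapsing of **UMI-read clusters** — the
read mapping-shift artefact in UMI-tagged sequencing libraries.

## The problem

Unique molecular identifiers (UMIs) tag each captured molecule before PCR,
so all reads descending from one molecule share a tag and can be collapsed
into a single count. Standard UMI deduplication additionally assumes those
reads share a mapping coordinate. They often do not: reads carrying one UMI
frequently map to a short run of *adjacent* coordinates — a modal position
with most of the reads and diminishing numbers 1–3 bp up- and downstream.
Counting every (UMI, coordinate) pair as a molecule then overestimates a
gene's expression by up to the size of the run. The regular spacing of the
runs (all gaps strictly 1, 2 or 3 bp) and the repeat content of the reads
involved implicate repeat-stabilised PCR stutter as a contributing
mechanism.

`umishift` is for anyone producing or consuming UMI-based count tables
(bulk or single-cell RNA-seq, UMI-tagged DNA-seq): it groups reads sharing
a UMI at each site (Levenshtein distance ≤ 1 merging), chains sites within
a configurable gap (default 3 bp) into clusters, collapses each cluster to
one molecule at its modal coordinate, and quantifies the artefact.

## The method in brief

Per (reference, strand, coordinate), UMIs within edit distance 1 merge
greedily in descending abundance. Per merged UMI, sorted coordinates chain
by single linkage with gap ≤ `max_gap`. Each cluster of coordinates
c₁ < … < cₖ with read counts n₁ … nₖ has size k, mode argmaxᵢ nᵢ, and
offsets cᵢ − mode; pooled over clusters, offset read counts normalised to 1
give the shift distribution. Clusters with all gaps equal to n are
"strictly n". Modal-read complexity is scored with Shannon entropy
H = −Σₓ p(x) log₂ p(x) over base fractions and mutual information
I = Σ p(x,y) log₂ ( p(x,y) / (p(x) p(y)) ) over consecutive non-overlapping
2-mers with whole-string marginals, and tested against cluster size by
one-way ANOVA. Gene tables report reads, uncollapsed UMIs, collapsed UMIs
and their ratio — the apparent over-expression factor.

A bundled simulator emits SAM + GFF3 + FASTA + ground truth for libraries
with a parameterised PCR-stutter model (per-cycle ± one repeat unit on
repeat-bearing templates), so every stage is testable without external
data.

## Worked example

`python examples/worked_cluster.py` builds a library of 811 reads sharing
UMI `AAAGGAGTGG` at five consecutive coordinates of Chr03 (per-coordinate
counts 1, 10, 796, 3, 1) and prints:

```
cluster size (adjacent coordinates): 5
total reads:                         811
strict spacing class:                1
collapsed observation at:            Chr03:591516
mode-centred read density:           -2: 0.00123, -1: 0.01233, +0: 0.98150, +1: 0.00370, +2: 0.00123
```

One cluster of size 5: per-coordinate UMI counting would report five
molecules here; collapsing reports one, at the modal coordinate 591516,
where 98.15 % of the reads sit. `python examples/simulate_and_recover.py`
runs the full pipeline on a simulated 50-gene × 20-molecule library with
stutter probability 0.3:

```
reads simulated:            16000
UMI-read clusters found:    1000 (max size 6)
clusters by size:           1: 701, 2: 47, 3: 137, 4: 88, 5: 22, 6: 5
genes with exact collapsed counts: 100%
UMI-collision genes (unresolvable): 0
mean uncollapsed/collapsed ratio:   1.698
```

Collapsed counts recover the true 20 molecules per gene exactly, while
uncollapsed counting would inflate expression by ~1.7× on average.
`python examples/complexity_trend.py` shows modal-read entropy falling and
mutual information rising with cluster size (ANOVA on H: F = 451.3,
p ≈ 1e-221 on this library).

## Command line

```sh
umishift simulate out/ --seed 7            # synthetic library + truth
umishift run out/reads.sam --gff out/genes.gff3 --outdir results/
umishift preprocess in.fastq out.fastq --umi-len 10 --post-umi-trim 4
umishift cluster aligned.sam clusters/ --max-gap 3
umishift count aligned.sam --gff genes.gff3 --out gene_counts.tsv
umishift complexity aligned.sam --out complexity.tsv
```

`umishift run` writes a bundle of plain files — `clusters.tsv`,
`shifts_all.tsv` and `shifts_strict{1,2,3}.tsv`, `collapsed.bed`,
`gene_counts.tsv`, `complexity.tsv`, `anova.json`, `summary.json` — with
per-stage record accounting, byte-identical across reruns.

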