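"""Gene-level counting of collapsed and uncollapsed UMI observations.

Produces the tables behind the apparent-overexpression analysis: per gene,
the number of uniquely aligning reads, the UMI count with every (UMI,
coordinate) pair treated as a molecule (uncollapsed — what coordinate-exact
UMI counting reports), the UMI count after collapsing each UMI-read cluster
into one observation, and their ratio.  The ratio of uncollapsed to
collapsed counts is the factor by which mapping shifts inflate the apparent
expression of a gene; it is >= 1 wherever defined.

Coordinates: observations are emitted as standard 0-based half-open
single-base BED intervals; GFF3 gene features are 1-based inclusive.  Both
conventions are handled exactly at the overlap step.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from gffutils.iterators import DataIterator
from intervaltree import IntervalTree

from .alignio import PositionKey
from .errors import ConfigError
from .umicluster import UmiReadCluster, collapse

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class BedObservation:
    """Single-base site (0-based half-open) with an observation count."""

    reference: str
    start: int
    end: int
    count: int

    def __post_init__(self) -> None:
        if self.end != self.start + 1:
            raise ValueError("observations are single-base sites")


def _aggregate_sites(site_counts: Counter) -> list[BedObservation]:
    return [
        BedObservation(ref, pos0, pos0 + 1, count)
        for (ref, pos0), count in sorted(site_counts.items())
    ]


def observations_from_positions(
    positions: Iterable[tuple[PositionKey, int]]
) -> list[BedObservation]:
    """Aggregate (1-based PositionKey, count) pairs into sorted BED sites.

    Strand is dropped at this stage: + and - observations at one base sum
    into a single line, matching a BED4 record of de-redundified UMI counts.
    """
    sites: Counter = Counter()
    for pos, count in positions:
        sites[(pos.reference, pos.coordinate - 1)] += count
    return _aggregate_sites(sites)


def write_bed(observations: Sequence[BedObservation], path) -> int:
    """Write BED4 lines (reference, start, end, count), sorted."""
    with open(path, "w") as handle:
        handle.write("# umishift observations: single-base sites, count in column 4\n")
        for obs in sorted(observations, key=lambda o: (o.reference, o.start)):
            handle.write(f"{obs.reference}\t{obs.start}\t{obs.end}\t{obs.count}\n")
    return len(observations)


class GeneIndex:
    """Interval index over the ``gene`` features of a GFF3 annotation."""

    def __init__(self, features: Iterable[tuple[str, int, int, str]]):
        """``features``: (reference, 1-based start, 1-based inclusive end, gene_id)."""
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.n_genes = 0
        for reference, start, end, gene_id in features:
            # GFF3 1-based inclusive -> 0-based half-open
            self._trees[reference].addi(start - 1, end, gene_id)
            self.n_genes += 1
        if self.n_genes == 0:
            raise ConfigError("annotation contains no 'gene' features")

    @classmethod
    def from_gff3(cls, path) -> "GeneIndex":
        feats = []
        for feature in DataIterator(str(path)):
            if feature.featuretype != "gene":
                continue
            gene_id = feature.attributes.get("ID", [feature.id or "?"])[0]
            feats.append((feature.seqid, feature.start, feature.end, gene_id))
        return cls(feats)

    def overlapping(self, reference: str, start0: int, end0: int) -> list[str]:
        tree = self._trees.get(reference)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(start0, end0))


@dataclass
class IntersectResult:
    counts: dict[str, int]  # gene_id -> summed observation count
    unassigned: int  # observation count overlapping no gene
    multi_gene: int  # observation count assigned to >1 gene (double-counted)


def intersect_genes(
    observations: Sequence[BedObservation],
    genes: GeneIndex,
    unique_only: bool = False,
) -> IntersectResult:
    """Sum observation counts per overlapping gene feature.

    An observation overlapping several genes contributes to every one of
    them (the behaviour of a plain interval intersection); ``unique_only``
    drops such ambiguous sites instead.  Sites in no gene accumulate in the
    unassigned tally, so mass is conserved up to the reported multi-gene
    double counting.
    """
    counts: Counter = Counter()
    unassigned = 0
    multi = 0
    for obs in observations:
        gene_ids = genes.overlapping(obs.reference, obs.start, obs.end)
        if not gene_ids:
            unassigned += obs.count
        elif len(gene_ids) == 1:
            counts[gene_ids[0]] += obs.count
        else:
            multi += obs.count
            if not unique_only:
                for gid in gene_ids:
                    counts[gid] += obs.count
    return IntersectResult(dict(counts), unassigned, multi)


def count_tables(
    clusters: Sequence[UmiReadCluster],
    genes: GeneIndex,
    unique_only: bool = False,
) -> pd.DataFrame:
    """Per-gene reads, uncollapsed UMI count, collapsed UMI count and ratio.

    Collapsed mode assigns each cluster once, at its modal coordinate;
    uncollapsed mode assigns every (UMI, coordinate) pair independently —
    the faithful rendering of the two counting schemes being compared.  Raw
    read counts come from the per-coordinate cluster counts (reads of
    uniquely aligning alignments).  ``ratio`` is uncollapsed/collapsed,
    NaN where a gene has no collapsed observation (a cluster whose mode
    falls outside the gene).
    """
    collapsed_obs = observations_from_positions(
        (collapse(c).position, 1) for c in clusters
    )
    uncollapsed_pairs = []
    read_pairs = []
    for c in clusters:
        for coord, count in zip(c.coordinates, c.counts):
            key = PositionKey(c.reference, c.strand, coord)
            uncollapsed_pairs.append((key, 1))
            read_pairs.append((key, count))
    uncollapsed_obs = observations_from_positions(uncollapsed_pairs)
    read_obs = observations_from_positions(read_pairs)

    res_collapsed = intersect_genes(collapsed_obs, genes, unique_only)
    res_uncollapsed = intersect_genes(uncollapsed_obs, genes, unique_only)
    res_reads = intersect_genes(read_obs, genes, unique_only)

    gene_ids = sorted(
        set(res_collapsed.counts) | set(res_uncollapsed.counts) | set(res_reads.counts)
    )
    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "reads": [res_reads.counts.get(g, 0) for g in gene_ids],
            "umis_uncollapsed": [res_uncollapsed.counts.get(g, 0) for g in gene_ids],
            "umis_collapsed": [res_collapsed.counts.get(g, 0) for g in gene_ids],
        }
    )
    collapsed = table["umis_collapsed"].astype(float).replace(0.0, float("nan"))
    table["ratio"] = table["umis_uncollapsed"] / collapsed
    table.attrs["unassigned"] = {
        "reads": res_reads.unassigned,
        "umis_uncollapsed": res_uncollapsed.unassigned,
        "umis_collapsed": res_collapsed.unassigned,
    }
    table.attrs["multi_gene"] = {
        "reads": res_reads.multi_gene,
        "umis_uncollapsed": res_uncollapsed.multi_gene,
        "umis_collapsed": res_collapsed.multi_gene,
    }
    return table
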