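"""UMI-read cluster detection, collapsing and shift statistics.

The central observation this package quantifies: reads carrying the same
UMI — hence PCR copies of one molecule — often map not to one coordinate but
to a short run of adjacent coordinates, with most reads at a modal position
and diminishing numbers up- and downstream.  Such a run is a *UMI-read
cluster*; counting each of its coordinates as a separate molecule inflates
UMI-based expression estimates.

Method, per (reference, strand) and coordinate:

1. UMIs observed at one coordinate are merged when their Levenshtein
   distance is <= 1 (PCR/sequencing errors in the UMI), greedily in
   descending read-count order — the abundance-first policy of established
   UMI error correctors; the distance-1 relation is not transitive, so a
   deterministic visit order is required.
2. Coordinates sharing a merged UMI are chained into clusters by
   single-linkage: a gap larger than ``max_gap`` (default 3 bp) starts a new
   cluster.  A cluster may therefore span more than ``max_gap`` in total.
3. Each cluster collapses to a single molecule observation at its modal
   coordinate (the coordinate with most reads; ties broken leftmost).

Shift distributions re-centre every cluster on its mode (offset 0, upstream
negative) and pool read counts across clusters; clusters whose consecutive
coordinate gaps all equal n are "strictly n", the signature of
repeat-stabilised PCR stutter with an n bp repeat unit.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import edlib

from .alignio import PositionKey, UmiAlignment
from .errors import UmishiftError

DEFAULT_MAX_GAP = 3


def levenshtein(a: str, b: str) -> int:
    """Standard edit distance (substitution, insertion, deletion, unit cost)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass
class UmiGroup:
    """UMIs merged at one coordinate; every member is within distance 1 of
    the representative, which holds the maximal read count (ties: lexicographic)."""

    representative: str
    members: dict[str, int]
    position: Optional[PositionKey] = None

    @property
    def count(self) -> int:
        return sum(self.members.values())


def merge_umis_at_position(
    umi_counts: Mapping[str, int], position: Optional[PositionKey] = None
) -> list[UmiGroup]:
    """Greedy abundance-first merging of UMIs observed at one coordinate.

    UMIs are visited in descending read count (ties lexicographic); each
    joins the first existing group whose representative is within Levenshtein
    distance 1, else founds a new group.  Deterministic and order-independent
    of the input mapping's iteration order.
    """
    groups: list[UmiGroup] = []
    for umi in sorted(umi_counts, key=lambda u: (-umi_counts[u], u)):
        for group in groups:
            if levenshtein(umi, group.representative) <= 1:
                group.members[umi] = umi_counts[umi]
                break
        else:
            groups.append(UmiGroup(umi, {umi: umi_counts[umi]}, position))
    return groups


@dataclass(frozen=True)
class UmiReadCluster:
    """A UMI's chained run of adjacent mapping coordinates.

    ``coordinates`` are strictly increasing 1-based positions; ``counts`` the
    per-coordinate read counts.  ``modal_sequence`` is the most frequent read
    sequence at the modal coordinate (ties lexicographic), retained for
    sequence-complexity analysis.
    """

    umi: str
    reference: str
    strand: str
    coordinates: tuple[int, ...]
    counts: tuple[int, ...]
    modal_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.coordinates) != len(self.counts) or not self.coordinates:
            raise UmishiftError("coordinates and counts must be non-empty, same length")
        if any(
            b <= a for a, b in zip(self.coordinates, self.coordinates[1:])
        ):
            raise UmishiftError("cluster coordinates must be strictly increasing")

    @property
    def size(self) -> int:
        """Number of adjacent mapping coordinates."""
        return len(self.coordinates)

    @property
    def total_reads(self) -> int:
        return sum(self.counts)

    @property
    def mode(self) -> int:
        """Coordinate holding the most reads; leftmost on ties."""
        best = max(self.counts)
        return self.coordinates[self.counts.index(best)]

    @property
    def offsets(self) -> tuple[int, ...]:
        """Coordinates re-centred on the mode (upstream negative)."""
        m = self.mode
        return tuple(c - m for c in self.coordinates)

    @property
    def gaps(self) -> tuple[int, ...]:
        return tuple(b - a for a, b in zip(self.coordinates, self.coordinates[1:]))


def classify_strict_shift(cluster: UmiReadCluster) -> Union[int, str]:
    """'none' for size-1 clusters; n if all consecutive gaps equal n; else 'mixed'."""
    gaps = cluster.gaps
    if not gaps:
        return "none"
    if all(g == gaps[0] for g in gaps):
        return gaps[0]
    return "mixed"


@dataclass(frozen=True)
class CollapsedObservation:
    """One molecule: a cluster reduced to its modal coordinate."""

    position: PositionKey
    umi: str
    total_reads: int


def collapse(cluster: UmiReadCluster) -> CollapsedObservation:
    """Collapse a cluster into a single molecule observation at its mode."""
    return CollapsedObservation(
        position=PositionKey(cluster.reference, cluster.strand, cluster.mode),
        umi=cluster.umi,
        total_reads=cluster.total_reads,
    )


def find_clusters(
    coordinate_counts: Sequence[tuple[int, int]],
    max_gap: int = DEFAULT_MAX_GAP,
    *,
    umi: str = "",
    reference: str = "",
    strand: str = "+",
    sequences: Optional[Mapping[int, Counter]] = None,
) -> list[UmiReadCluster]:
    """Chain sorted (coordinate, count) pairs of one UMI into clusters.

    Single-linkage: a new cluster starts whenever the gap to the previous
    coordinate exceeds ``max_gap``.  Every coordinate lands in exactly one
    cluster.  ``sequences`` optionally maps coordinate -> Counter of read
    sequences, from which each cluster's modal sequence is drawn.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    coords = [c for c, _ in coordinate_counts]
    if any(b <= a for a, b in zip(coords, coords[1:])):
        raise UmishiftError("find_clusters requires strictly increasing coordinates")

    clusters: list[UmiReadCluster] = []
    run: list[tuple[int, int]] = []

    def flush() -> None:
        if not run:
            return
        coordinates = tuple(c for c, _ in run)
        counts = tuple(n for _, n in run)
        modal_seq = None
        if sequences is not None:
            best = max(counts)
            mode = coordinates[counts.index(best)]
            seq_counter = sequences.get(mode)
            if seq_counter:
                top = max(seq_counter.values())
                modal_seq = min(s for s, k in seq_counter.items() if k == top)
        clusters.append(
            UmiReadCluster(umi, reference, strand, coordinates, counts, modal_seq)
        )
        run.clear()

    prev: Optional[int] = None
    for coord, count in coordinate_counts:
        if prev is not None and coord - prev > max_gap:
            flush()
        run.append((coord, count))
        prev = coord
    flush()
    return clusters


def build_position_index(
    groups_by_position: Iterable[UmiGroup],
) -> dict[tuple[str, str, str], list[tuple[int, int]]]:
    """Index merged UMI groups as (reference, strand, representative UMI) ->
    ascending (coordinate, read count) pairs.

    Cross-position identity is exact equality of representatives: the
    distance-1 merge applies only among UMIs at one coordinate.
    """
    index: dict[tuple[str, str, str], list[tuple[int, int]]] = defaultdict(list)
    for group in groups_by_position:
        if group.position is None:
            raise UmishiftError("position index requires positioned UmiGroups")
        key = (group.position.reference, group.position.strand, group.representative)
        index[key].append((group.position.coordinate, group.count))
    for pairs in index.values():
        pairs.sort()
    return dict(sorted(index.items()))


def cluster_alignments(
    alignments: Iterable[UmiAlignment],
    max_gap: int = DEFAULT_MAX_GAP,
    keep_sequences: bool = True,
) -> list[UmiReadCluster]:
    """Full clustering pipeline: UmiAlignments -> UMI-read clusters.

    Groups reads by site, merges UMIs at each site at Levenshtein <= 1,
    chains coordinates per merged UMI, and returns all clusters in a stable
    sort order (reference, strand, UMI, first coordinate).
    """
    by_site: dict[PositionKey, Counter] = defaultdict(Counter)
    seqs: dict[tuple[PositionKey, str], Counter] = defaultdict(Counter)
    for aln in alignments:
        by_site[aln.position][aln.umi] += 1
        if keep_sequences and aln.sequence:
            seqs[(aln.position, aln.umi)][aln.sequence] += 1

    groups: list[UmiGroup] = []
    for pos in sorted(by_site):
        groups.extend(merge_umis_at_position(by_site[pos], pos))

    # sequences observed under any member UMI vote for the group's modal read
    group_seqs: dict[tuple[str, str, str], dict[int, Counter]] = defaultdict(dict)
    if keep_sequences:
        for group in groups:
            key = (
                group.position.reference,
                group.position.strand,
                group.representative,
            )
            merged: Counter = Counter()
            for member in group.members:
                merged.update(seqs.get((group.position, member), ()))
            if merged:
                group_seqs[key][group.position.coordinate] = merged

    clusters: list[UmiReadCluster] = []
    for (reference, strand, umi), pairs in build_position_index(groups).items():
        clusters.extend(
            find_clusters(
                pairs,
                max_gap,
                umi=umi,
                reference=reference,
                strand=strand,
                sequences=group_seqs.get((reference, strand, umi)),
            )
        )
    clusters.sort(key=lambda c: (c.reference, c.strand, c.umi, c.coordinates[0]))
    return clusters


@dataclass
class ShiftDistribution:
    """Pooled mode-centred offset table: read counts and proportions.

    ``density`` sums to 1 and is maximal at offset 0 by construction of the
    mode.  Empty input gives empty tables (density undefined).
    """

    pooled: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.pooled.values())

    @property
    def density(self) -> dict[int, float]:
        t = self.total
        if t == 0:
            return {}
        return {off: n / t for off, n in sorted(self.pooled.items())}


def pooled_shift_distribution(
    clusters: Iterable[UmiReadCluster],
    restrict_to_strict: Optional[int] = None,
) -> ShiftDistribution:
    """Pool per-read offsets from the mode across clusters.

    Each cluster is re-centred on its own mode; read counts are summed per
    offset across clusters (per-read weighting).  ``restrict_to_strict=n``
    keeps only clusters classified strictly n.
    """
    pooled: Counter = Counter()
    for cluster in clusters:
        if (
            restrict_to_strict is not None
            and classify_strict_shift(cluster) != restrict_to_strict
        ):
            continue
        for off, count in zip(cluster.offsets, cluster.counts):
            pooled[off] += count
    return ShiftDistribution(dict(sorted(pooled.items())))


@dataclass
class ClusterSizeSummary:
    """Cluster-size spectrum: how clusters and reads distribute over sizes."""

    clusters_by_size: dict[int, tuple[int, float]]
    reads_by_size: dict[int, tuple[int, float]]
    strict_shift_tables: dict[int, ShiftDistribution]
    max_size: int
    n_clusters: int
    total_reads: int

    def as_dict(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "total_reads": self.total_reads,
            "max_size": self.max_size,
            "clusters_by_size": {
                s: {"count": c, "proportion": p}
                for s, (c, p) in self.clusters_by_size.items()
            },
            "reads_by_size": {
                s: {"reads": c, "proportion": p}
                for s, (c, p) in self.reads_by_size.items()
            },
            "strict_n_reads": {
                n: dist.total for n, dist in self.strict_shift_tables.items()
            },
        }


def summarize(
    clusters: Sequence[UmiReadCluster], strict_ns: Sequence[int] = (1, 2, 3)
) -> ClusterSizeSummary:
    """Cluster-count and read-share proportions by size, plus strictly-n
    pooled shift tables."""
    cluster_counter: Counter = Counter()
    read_counter: Counter = Counter()
    for cluster in clusters:
        cluster_counter[cluster.size] += 1
        read_counter[cluster.size] += cluster.total_reads
    n_clusters = sum(cluster_counter.values())
    total_reads = sum(read_counter.values())
    return ClusterSizeSummary(
        clusters_by_size={
            s: (c, c / n_clusters) for s, c in sorted(cluster_counter.items())
        },
        reads_by_size={
            s: (r, r / total_reads) for s, r in sorted(read_counter.items())
        },
        strict_shift_tables={
            n: pooled_shift_distribution(clusters, restrict_to_strict=n)
            for n in strict_ns
        },
        max_size=max(cluster_counter, default=0),
        n_clusters=n_clusters,
        total_reads=total_reads,
    )
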