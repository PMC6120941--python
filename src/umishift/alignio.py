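"""SAM/BAM ingestion: unique-alignment filtering and UMI-alignment records.

Only uniquely aligning reads (SAM auxiliary tag ``NH:i:1``) enter the
clustering method; multimappers would smear one molecule's reads over
several loci and fabricate spurious clusters.  Each retained record becomes
a :class:`UmiAlignment` keyed by (reference, strand, leftmost coordinate).

Coordinate convention: the 1-based leftmost mapping position (SAM POS) is
used for both strands.  This differs from UMI tools that use the 5' end of
reverse-strand reads; it is the right choice for end-to-end alignments of
fixed-length reads, where POS shifts are exactly the mapping-shift artefact
being measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional

import pysam

from .errors import FormatError
from .preprocess import UMI_HEADER_SEPARATOR

logger = logging.getLogger(__name__)


class PositionKey(NamedTuple):
    """Totally ordered genomic site: reference name, strand, 1-based coordinate."""

    reference: str
    strand: str
    coordinate: int


@dataclass(frozen=True)
class UmiAlignment:
    """One uniquely aligned read with its UMI."""

    read_id: str
    umi: str
    reference: str
    strand: str
    coordinate: int  # 1-based leftmost (SAM POS)
    sequence: str = ""

    @property
    def position(self) -> PositionKey:
        return PositionKey(self.reference, self.strand, self.coordinate)


@dataclass
class AlignFilterStats:
    """Why records were dropped; output == total - dropped, each tallied."""

    total: int = 0
    kept: int = 0
    unmapped: int = 0
    non_unique: int = 0
    missing_nh: int = 0
    duplicate_ids: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def umi_from_qname(qname: str) -> tuple[str, str]:
    """Split a ``<stem>_UMI:<seq>`` QNAME into (stem, umi)."""
    stem, sep, umi = qname.rpartition(UMI_HEADER_SEPARATOR)
    if not sep or not umi:
        raise FormatError(f"QNAME {qname!r} carries no {UMI_HEADER_SEPARATOR!r} field")
    return stem, umi


def filter_unique(
    segments: Iterable[pysam.AlignedSegment],
    assume_unique_mapq: Optional[int] = None,
    stats: Optional[AlignFilterStats] = None,
) -> Iterator[pysam.AlignedSegment]:
    """Yield mapped records with NH == 1.

    ``assume_unique_mapq``: for aligners that omit the NH tag, treat records
    with MAPQ >= this threshold as unique instead of failing.  Off by default
    (missing NH raises :class:`FormatError` naming the record).
    """
    stats = stats if stats is not None else AlignFilterStats()
    for seg in segments:
        stats.total += 1
        if seg.is_unmapped:
            stats.unmapped += 1
            continue
        try:
            nh = seg.get_tag("NH")
        except KeyError:
            if assume_unique_mapq is None:
                raise FormatError(
                    f"record {seg.query_name!r} has no NH tag; "
                    "pass assume_unique_mapq to use MAPQ instead"
                ) from None
            stats.missing_nh += 1
            if seg.mapping_quality < assume_unique_mapq:
                stats.non_unique += 1
                continue
        else:
            if nh != 1:
                stats.non_unique += 1
                continue
        stats.kept += 1
        yield seg


def to_umi_alignments(
    segments: Iterable[pysam.AlignedSegment],
    ignore_strand: bool = False,
    stats: Optional[AlignFilterStats] = None,
) -> Iterator[UmiAlignment]:
    """Convert unique records to :class:`UmiAlignment`.

    Strand comes from the reverse-complement flag; with ``ignore_strand``
    both orientations collapse onto '.' so that sense and antisense reads at
    one coordinate group together.  Duplicate QNAMEs are kept but logged.
    """
    seen: set[str] = set()
    for seg in segments:
        qname = seg.query_name or ""
        stem, umi = umi_from_qname(qname)
        if qname in seen:
            logger.warning("duplicate read id %r in unique-alignment stream", qname)
            if stats is not None:
                stats.duplicate_ids += 1
        else:
            seen.add(qname)
        strand = "." if ignore_strand else ("-" if seg.is_reverse else "+")
        yield UmiAlignment(
            read_id=stem,
            umi=umi,
            reference=seg.reference_name,
            strand=strand,
            coordinate=seg.reference_start + 1,
            sequence=seg.query_sequence or "",
        )


def read_alignments(path) -> Iterator[pysam.AlignedSegment]:
    """Iterate a SAM or BAM file (format auto-detected, sort order irrelevant)."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as handle:
        yield from handle


def load_umi_alignments(
    path,
    ignore_strand: bool = False,
    assume_unique_mapq: Optional[int] = None,
    stats: Optional[AlignFilterStats] = None,
) -> list[UmiAlignment]:
    """SAM/BAM path -> list of UmiAlignments from uniquely aligning reads."""
    return list(
        to_umi_alignments(
            filter_unique(read_alignments(path), assume_unique_mapq, stats),
            ignore_strand,
            stats,
        )
    )


def write_sam(
    alignments: Iterable[UmiAlignment],
    path,
    references: dict[str, int],
) -> int:
    """Write UmiAlignments back to SAM (NH:i:1, UMI in QNAME). Returns count.

    Round-trip guarantee: re-reading the file reproduces identical
    :class:`PositionKey` values.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": name, "LN": length} for name, length in references.items()],
        }
    )
    tid = {name: i for i, name in enumerate(references)}
    n = 0
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for aln in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = f"{aln.read_id}{UMI_HEADER_SEPARATOR}{aln.umi}"
            seg.reference_id = tid[aln.reference]
            seg.reference_start = aln.coordinate - 1
            seg.flag = 16 if aln.strand == "-" else 0
            seg.mapping_quality = 255
            if aln.sequence:
                seg.query_sequence = aln.sequence
                seg.cigartuples = [(0, len(aln.sequence))]
            seg.set_tag("NH", 1)
            out.write(seg)
            n += 1
    return n
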