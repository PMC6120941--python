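"""FASTQ-level UMI handling.

UMI-tagged libraries place the unique molecular identifier (UMI) either at
the 5' end of the biological read (tagmentation-style protocols), in the
mate read (SCRB / CEL-Seq2 style), or already in the read header (SRA dumps
configured to do so).  This module filters reads on the mean Phred quality
of the UMI substring, moves the UMI into the read header, trims the fixed
post-UMI motif bases, and optionally truncates reads to a fixed length.

The header convention is ``<read_id>_UMI:<sequence>``: the UMI is appended
to the read id with an underscore separator so that it survives alignment
inside the SAM QNAME field and can be recovered downstream without any
auxiliary file.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Optional

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FormatError, PairingError

PHRED_OFFSET = 33  # Sanger/Illumina 1.8+; offset-64 inputs are rejected, not guessed
UMI_HEADER_SEPARATOR = "_UMI:"

_MATE_SUFFIX = re.compile(r"/[123]$")


@dataclass
class ReadRecord:
    """One FASTQ read: id, sequence, Phred-33 quality, and the UMI once extracted."""

    read_id: str
    sequence: str
    quality: str
    umi: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise FormatError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class UmiLayout:
    """Where the UMI lives in a library and how much to trim around it.

    mode
        ``inline-5prime`` (UMI is the first ``umi_length`` bases of the read),
        ``mate-read`` (UMI is carried by the other read of the pair), or
        ``header`` (the UMI is already in the read id).
    umi_length
        UMI length in bp (published protocols range from 6 to 16).
    post_umi_trim
        Fixed number of bases removed after the UMI (the template-switch
        GGG(G) motif: 4 for the tagmentation protocol, 3 for others). This is
        a count, not a motif match; how often the expected all-G motif was
        actually observed is tallied separately.
    fixed_read_trim
        If set, truncate the biological read to this length.
    """

    mode: str = "inline-5prime"
    umi_length: int = 10
    post_umi_trim: int = 0
    fixed_read_trim: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode not in ("inline-5prime", "mate-read", "header"):
            raise ValueError(f"unknown UMI layout mode {self.mode!r}")
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")
        if self.post_umi_trim < 0:
            raise ValueError("post_umi_trim must be >= 0")


class ReadTooShortError(FormatError):
    """Read shorter than umi_length + post_umi_trim; discarded by the stream API."""


def _phred_scores(quality: str, read_id: str) -> list[int]:
    scores = [ord(c) - PHRED_OFFSET for c in quality]
    if any(s < 0 for s in scores):
        raise FormatError(
            f"read {read_id!r}: quality characters below Phred offset {PHRED_OFFSET}"
        )
    return scores


def filter_by_umi_quality(
    record: ReadRecord, layout: UmiLayout, min_mean_phred: float = 30.0
) -> bool:
    """Keep the read iff the arithmetic mean Phred score over the UMI substring
    is at least ``min_mean_phred``.

    The UMI is the most error-sensitive part of the read: a miscalled UMI
    detaches a read from its molecule of origin.  For ``mate-read`` layouts
    pass the UMI-carrying mate as ``record``.  For ``header`` layouts the UMI
    has no quality string any more and the read is always kept.
    """
    if layout.mode == "header":
        return True
    sub = record.quality[: layout.umi_length]
    if len(sub) < layout.umi_length:
        raise ReadTooShortError(
            f"read {record.read_id!r}: shorter than UMI length {layout.umi_length}"
        )
    scores = _phred_scores(sub, record.read_id)
    return sum(scores) / len(scores) >= min_mean_phred


def extract_umi(record: ReadRecord, layout: UmiLayout) -> ReadRecord:
    """Move the inline 5' UMI into the read header.

    Removes the first ``umi_length`` bases (the UMI) plus ``post_umi_trim``
    motif bases from sequence and quality, and appends ``_UMI:<seq>`` to the
    read id.
    """
    if layout.mode != "inline-5prime":
        raise ValueError("extract_umi applies to inline-5prime layouts only")
    cut = layout.umi_length + layout.post_umi_trim
    if len(record.sequence) <= cut:
        raise ReadTooShortError(
            f"read {record.read_id!r}: length {len(record.sequence)} <= "
            f"umi_length + post_umi_trim = {cut}"
        )
    umi = record.sequence[: layout.umi_length]
    return ReadRecord(
        read_id=f"{record.read_id}{UMI_HEADER_SEPARATOR}{umi}",
        sequence=record.sequence[cut:],
        quality=record.quality[cut:],
        umi=umi,
    )


def _id_stem(read_id: str) -> str:
    stem = read_id.split()[0]
    return _MATE_SUFFIX.sub("", stem)


def transfer_umi_from_mate(
    biological_read: ReadRecord, umi_read: ReadRecord, layout: UmiLayout
) -> ReadRecord:
    """Attach the UMI carried by the mate read to the biological read's header.

    The two records must be a proper pair (same read-id stem, ``/1``/``/2``
    suffixes allowed).  The biological read's sequence is unchanged apart from
    an optional ``fixed_read_trim``.
    """
    if layout.mode != "mate-read":
        raise ValueError("transfer_umi_from_mate applies to mate-read layouts only")
    if _id_stem(biological_read.read_id) != _id_stem(umi_read.read_id):
        raise PairingError(
            f"unpaired records: {biological_read.read_id!r} vs {umi_read.read_id!r}"
        )
    if len(umi_read.sequence) < layout.umi_length:
        raise ReadTooShortError(
            f"read {umi_read.read_id!r}: UMI mate shorter than {layout.umi_length} bp"
        )
    umi = umi_read.sequence[: layout.umi_length]
    out = ReadRecord(
        read_id=f"{biological_read.read_id}{UMI_HEADER_SEPARATOR}{umi}",
        sequence=biological_read.sequence,
        quality=biological_read.quality,
        umi=umi,
    )
    if layout.fixed_read_trim is not None:
        out = trim_to_length(out, layout.fixed_read_trim)
    return out


def trim_to_length(record: ReadRecord, n: int) -> ReadRecord:
    """Truncate sequence and quality to at most ``n`` bases."""
    if n < 1:
        raise ValueError("trim length must be >= 1")
    if len(record.sequence) <= n:
        return record
    return replace(record, sequence=record.sequence[:n], quality=record.quality[:n])


@dataclass
class PreprocessStats:
    """Per-run accounting; kept + discarded always equals total."""

    total: int = 0
    kept: int = 0
    discarded_low_quality: int = 0
    discarded_too_short: int = 0
    motif_checked: int = 0
    motif_present: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _open_text(path, mode: str = "rt") -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[ReadRecord]:
    """Iterate a (possibly gzipped) 4-line FASTQ file."""
    with _open_text(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield ReadRecord(read_id=title, sequence=seq.upper(), quality=qual)


def write_fastq(records: Iterable[ReadRecord], path) -> int:
    n = 0
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")
            n += 1
    return n


def preprocess_records(
    records: Iterable[ReadRecord],
    layout: UmiLayout,
    min_umi_qual: Optional[float] = 30.0,
    umi_mates: Optional[Iterable[ReadRecord]] = None,
    stats: Optional[PreprocessStats] = None,
) -> Iterator[ReadRecord]:
    """Filter on UMI quality and extract UMIs into headers, streaming.

    ``min_umi_qual=None`` disables the quality filter.  For ``mate-read``
    layouts ``umi_mates`` must iterate in lockstep with ``records``.
    """
    stats = stats if stats is not None else PreprocessStats()
    expect_g = layout.post_umi_trim > 0
    if layout.mode == "mate-read":
        if umi_mates is None:
            raise ValueError("mate-read layout requires the UMI mate stream")
        pairs: Iterable = zip(records, umi_mates)
    else:
        pairs = ((r, None) for r in records)

    for record, mate in pairs:
        stats.total += 1
        quality_carrier = mate if layout.mode == "mate-read" else record
        try:
            if min_umi_qual is not None and not filter_by_umi_quality(
                quality_carrier, layout, min_umi_qual
            ):
                stats.discarded_low_quality += 1
                continue
            if layout.mode == "inline-5prime":
                if expect_g:
                    motif = record.sequence[
                        layout.umi_length : layout.umi_length + layout.post_umi_trim
                    ]
                    stats.motif_checked += 1
                    if motif and set(motif) == {"G"}:
                        stats.motif_present += 1
                out = extract_umi(record, layout)
                if layout.fixed_read_trim is not None:
                    out = trim_to_length(out, layout.fixed_read_trim)
            elif layout.mode == "mate-read":
                out = transfer_umi_from_mate(record, mate, layout)
            else:  # header: UMI already encoded upstream
                out = record
                if layout.fixed_read_trim is not None:
                    out = trim_to_length(out, layout.fixed_read_trim)
        except ReadTooShortError:
            stats.discarded_too_short += 1
            continue
        stats.kept += 1
        yield out


def preprocess_fastq(
    in_fastq,
    out_fastq,
    layout: UmiLayout,
    min_umi_qual: Optional[float] = 30.0,
    umi_fastq=None,
) -> PreprocessStats:
    """File-level driver: FASTQ in, UMI-tagged FASTQ out, stats returned."""
    stats = PreprocessStats()
    mates = read_fastq(umi_fastq) if umi_fastq is not None else None
    write_fastq(
        preprocess_records(read_fastq(in_fastq), layout, min_umi_qual, mates, stats),
        out_fastq,
    )
    return stats
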