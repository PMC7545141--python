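"""Reading and normalizing long-read split alignments.

A long read spanning a rearrangement is reported by the aligner as several
records: one primary plus supplementary records (flag 2048), each covering a
different interval of the read. This module loads those records into
:class:`AlignmentSegment` objects with read coordinates re-expressed in the
original read orientation, so that segments of one read can be ordered along
the read and adjacent pairs interpreted as novel genomic adjacencies.

Record-level filters applied here:

* secondary alignments (flag 256, alternative placements) are dropped;
* unmapped records are dropped (counted and logged);
* records with mapping quality below ``Thresholds.min_mapq`` are dropped.

All coordinates are 0-based half-open internally; emitted files use each
format's native convention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pysam

logger = logging.getLogger("clclkit")

CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")

# CIGAR operations consuming query / reference sequence
_QUERY_OPS = set("MIS=XH")  # H counted toward full read length only
_QUERY_ALN_OPS = set("MI=X")
_REF_OPS = set("MDN=X")


@dataclass(frozen=True)
class Thresholds:
    """Filter constants of the calling pipeline.

    min_mapq
        Records below this mapping quality are discarded (default 30).
    max_read_gap
        Maximum absolute distance, on the read, between two consecutive
        aligned segments for the implied junction to be considered
        (default 300 bp). Small positive gaps are non-templated insertions.
    merge_dist
        Junction candidates whose breakpoints are each strictly closer than
        this are merged into one call (default 50 bp).
    min_support
        Minimum number of distinct supporting reads per call (default 5).
    min_span
        Minimum distance between the two breakpoints of an intra-chromosomal
        call (default 2000 bp); inter-chromosomal calls are exempt.
    sample_margin
        Breakpoint margin when collapsing redundant calls across samples
        (default 100 bp).
    proximal_flank
        Flank around gene bodies used when assigning breakpoints to gene
        loci (default 10 kb).
    """

    min_mapq: int = 30
    max_read_gap: int = 300
    merge_dist: int = 50
    min_support: int = 5
    min_span: int = 2000
    sample_margin: int = 100
    proximal_flank: int = 10_000

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"Thresholds.{name} must be non-negative")
        if self.min_support < 1:
            raise ValueError("Thresholds.min_support must be >= 1")

    def replace(self, **kwargs) -> "Thresholds":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass(frozen=True, order=True)
class AlignmentSegment:
    """One aligned block of one read.

    ``read_start``/``read_end`` are 0-based half-open coordinates on the read
    in its original (pre-reverse-complement) orientation, so segments of one
    read are directly comparable regardless of the strand each block aligned
    to. ``ref_start``/``ref_end`` are 0-based half-open reference coordinates.
    """

    read_id: str
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    read_start: int
    read_end: int
    mapq: int
    cigar: str
    is_secondary: bool = False

    def __post_init__(self) -> None:
        if not (self.ref_start < self.ref_end):
            raise ValueError(
                f"segment of read {self.read_id!r}: ref_start must be < ref_end"
            )
        if not (self.read_start < self.read_end):
            raise ValueError(
                f"segment of read {self.read_id!r}: read_start must be < read_end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into (length, op) tuples; malformed input raises."""
    if not cigar or cigar == "*":
        raise ValueError("missing CIGAR string")
    pos = 0
    out: list[tuple[int, str]] = []
    for m in CIGAR_TOKEN.finditer(cigar):
        if m.start() != pos:
            raise ValueError(f"malformed CIGAR {cigar!r}")
        out.append((int(m.group(1)), m.group(2)))
        pos = m.end()
    if pos != len(cigar) or not out:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return out


def cigar_read_length(cigar: str) -> int:
    """Full read length implied by a CIGAR, hard clips included."""
    return sum(n for n, op in parse_cigar(cigar) if op in _QUERY_OPS)


def _segment_from_record(rec: pysam.AlignedSegment) -> AlignmentSegment:
    cigar = rec.cigarstring
    if cigar is None:
        raise ValueError(f"retained record {rec.query_name!r} has no CIGAR")
    ops = parse_cigar(cigar)
    read_len = sum(n for n, op in ops if op in _QUERY_OPS)
    lead = 0
    for n, op in ops:
        if op in ("S", "H"):
            lead += n
        else:
            break
    aln_len = sum(n for n, op in ops if op in _QUERY_ALN_OPS)
    qs, qe = lead, lead + aln_len
    if rec.is_reverse:
        qs, qe = read_len - qe, read_len - qs
    return AlignmentSegment(
        read_id=rec.query_name,
        chrom=rec.reference_name,
        ref_start=rec.reference_start,
        ref_end=rec.reference_end,
        strand="-" if rec.is_reverse else "+",
        read_start=qs,
        read_end=qe,
        mapq=rec.mapping_quality,
        cigar=cigar,
    )


def read_alignments(path: str, thresholds: Thresholds) -> list[AlignmentSegment]:
    """Load SAM/BAM records into segments, applying record-level filters.

    Secondary records (flag 256) and records with MAPQ below
    ``thresholds.min_mapq`` are dropped; supplementary records (flag 2048)
    are kept as split evidence. Unmapped records are dropped with a logged
    count. A retained record without a CIGAR is a hard error.
    """
    import os

    if os.path.exists(path) and os.path.getsize(path) == 0:
        logger.info("read_alignments(%s): empty file, no segments", path)
        return []
    segments: list[AlignmentSegment] = []
    n_secondary = n_unmapped = n_lowmapq = 0
    verbosity = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(path, check_sq=False) as af:
            for rec in af.fetch(until_eof=True):
                if rec.is_unmapped:
                    n_unmapped += 1
                    continue
                if rec.is_secondary:
                    n_secondary += 1
                    continue
                if rec.mapping_quality < thresholds.min_mapq:
                    n_lowmapq += 1
                    continue
                segments.append(_segment_from_record(rec))
    finally:
        pysam.set_verbosity(verbosity)
    logger.info(
        "read_alignments(%s): %d segments retained; dropped %d secondary, "
        "%d unmapped, %d MAPQ<%d",
        path, len(segments), n_secondary, n_unmapped, n_lowmapq,
        thresholds.min_mapq,
    )
    return segments


def write_segments(
    segments: Iterable[AlignmentSegment],
    path: str,
    references: Mapping[str, int],
) -> None:
    """Write segments back to a SAM file (CIGAR-only records, no sequence)."""
    names = list(references)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": references[n]} for n in names],
    }
    seen: set[str] = set()
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for seg in segments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = seg.read_id
            flag = 16 if seg.strand == "-" else 0
            if seg.read_id in seen:
                flag |= 2048
            seen.add(seg.read_id)
            rec.flag = flag
            rec.reference_id = names.index(seg.chrom)
            rec.reference_start = seg.ref_start
            rec.mapping_quality = seg.mapq
            rec.cigarstring = seg.cigar
            out.write(rec)


def segments_by_read(
    segments: Iterable[AlignmentSegment],
) -> dict[str, list[AlignmentSegment]]:
    """Group segments per read, ordered along the read.

    Segments are sorted ascending by ``read_start`` with a stable tie-break
    by (chrom, ref_start), so the result is independent of input order.
    """
    table: dict[str, list[AlignmentSegment]] = {}
    for seg in segments:
        table.setdefault(seg.read_id, []).append(seg)
    for segs in table.values():
        segs.sort(key=lambda s: (s.read_start, s.chrom, s.ref_start))
    return table


def cigar_deletions(
    segment: AlignmentSegment, min_size: int
) -> list[tuple[str, int, int]]:
    """Reference intervals of within-alignment deletions larger than min_size.

    One interval per CIGAR ``D`` operation of length strictly greater than
    ``min_size``, placed at the correct reference offset.
    """
    out: list[tuple[str, int, int]] = []
    offset = segment.ref_start
    for n, op in parse_cigar(segment.cigar):
        if op == "D" and n > min_size:
            out.append((segment.chrom, offset, offset + n))
        if op in _REF_OPS:
            offset += n
    return out
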