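"""Junction candidate extraction, clustering and filtering.

Two read-adjacent alignment segments of one read imply a novel adjacency
between two reference breakpoints. Each breakpoint carries an orientation:
``tail`` means the aligned segment extends to lower coordinates from the
break (the break follows the segment's last base), ``head`` means it extends
to higher coordinates (the break precedes the segment's first base).

Classification by strand and reference order of the two segments:

* different chromosomes -> TRA (translocation);
* strand flip -> INV (inversion);
* same strand, second segment continues downstream in read direction -> DEL;
* same strand, second segment re-enters upstream -> DUP (tandem duplication).

Candidates are clustered by single linkage (both breakpoints strictly closer
than ``merge_dist``), calls below the read-support or span thresholds are
removed, matched-normal evidence subtracts germline calls, and redundant
calls across samples are collapsed within ``sample_margin``.

Breakpoint positions are 0-based inter-base break coordinates internally.
``Breakpoint.pos1`` gives the conventional printed position: the 1-based
last aligned base for a ``tail`` breakpoint, the 1-based first aligned base
for a ``head`` breakpoint.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, replace
from statistics import median_low
from typing import Iterable, Mapping, Optional, Sequence

from .alignio import AlignmentSegment, Thresholds, cigar_deletions

logger = logging.getLogger("clclkit")

SV_TYPES = ("DEL", "DUP", "INV", "TRA")


@dataclass(frozen=True, order=True)
class Breakpoint:
    chrom: str
    pos: int  # 0-based inter-base break coordinate
    orient: str  # 'tail': segment ends here; 'head': segment starts here

    @property
    def pos1(self) -> int:
        """1-based position of the aligned base flanking the break."""
        return self.pos if self.orient == "tail" else self.pos + 1

    @property
    def strand(self) -> str:
        """BEDPE strand convention: '+' if the segment lies left of the break."""
        return "+" if self.orient == "tail" else "-"


@dataclass(frozen=True)
class JunctionCandidate:
    """One novel adjacency implied by two read-adjacent segments."""

    read_id: str
    bp_a: Breakpoint
    bp_b: Breakpoint
    sv_type: str
    read_gap: int  # signed bp between the two segments' read intervals
    inserted_len: int  # non-templated read bases at the junction
    read_pos: tuple[int, int] = (0, 0)  # (seg1.read_end, seg2.read_start)
    # True when the read traverses the junction from bp_b to bp_a, i.e. the
    # canonical breakpoint order reversed the read order (inserted sequence
    # must be reverse-complemented to the canonical orientation)
    reversed_traversal: bool = False

    @property
    def span(self) -> Optional[int]:
        if self.sv_type == "TRA":
            return None
        return abs(self.bp_b.pos - self.bp_a.pos)


@dataclass(frozen=True)
class JunctionCall:
    """A cluster of candidates with canonical breakpoints."""

    bp_a: Breakpoint
    bp_b: Breakpoint
    sv_type: str
    members: tuple[JunctionCandidate, ...]
    somatic: Optional[bool] = None

    @property
    def support(self) -> int:
        return len({m.read_id for m in self.members})

    @property
    def read_ids(self) -> frozenset[str]:
        return frozenset(m.read_id for m in self.members)

    @property
    def span(self) -> Optional[int]:
        if self.sv_type == "TRA":
            return None
        return abs(self.bp_b.pos - self.bp_a.pos)

    @property
    def name(self) -> str:
        return (
            f"{self.sv_type}_{self.bp_a.chrom}_{self.bp_a.pos1}"
            f"_{self.bp_b.chrom}_{self.bp_b.pos1}"
        )


def _exit_breakpoint(seg: AlignmentSegment) -> Breakpoint:
    """Breakpoint where the read leaves this segment (read direction)."""
    if seg.strand == "+":
        return Breakpoint(seg.chrom, seg.ref_end, "tail")
    return Breakpoint(seg.chrom, seg.ref_start, "head")


def _entry_breakpoint(seg: AlignmentSegment) -> Breakpoint:
    """Breakpoint where the read enters this segment (read direction)."""
    if seg.strand == "+":
        return Breakpoint(seg.chrom, seg.ref_start, "head")
    return Breakpoint(seg.chrom, seg.ref_end, "tail")


def pair_to_junction(
    seg1: AlignmentSegment,
    seg2: AlignmentSegment,
    thresholds: Thresholds,
) -> Optional[JunctionCandidate]:
    """Classify the adjacency implied by two read-adjacent segments.

    Returns ``None`` when the read-coordinate gap between the segments
    exceeds ``max_read_gap`` in absolute value (likely unaligned or
    artifactual sequence rather than a clean junction). Segment order must
    follow the read; segments from different reads are a hard error.
    """
    if seg1.read_id != seg2.read_id:
        raise ValueError(
            f"pair_to_junction: segments from different reads "
            f"({seg1.read_id!r}, {seg2.read_id!r})"
        )
    gap = seg2.read_start - seg1.read_end
    if abs(gap) > thresholds.max_read_gap:
        return None
    bp1 = _exit_breakpoint(seg1)
    bp2 = _entry_breakpoint(seg2)
    if seg1.chrom != seg2.chrom:
        sv_type = "TRA"
    elif seg1.strand != seg2.strand:
        sv_type = "INV"
    elif seg1.strand == "+":
        sv_type = "DEL" if bp2.pos >= bp1.pos else "DUP"
    else:
        sv_type = "DEL" if bp2.pos <= bp1.pos else "DUP"
    bp_a, bp_b = sorted((bp1, bp2), key=lambda b: (b.chrom, b.pos, b.orient))
    return JunctionCandidate(
        read_id=seg1.read_id,
        bp_a=bp_a,
        bp_b=bp_b,
        sv_type=sv_type,
        read_gap=gap,
        inserted_len=max(0, gap),
        read_pos=(seg1.read_end, seg2.read_start),
        reversed_traversal=bp_a is bp2,
    )


def candidates_from_reads(
    by_read: Mapping[str, Sequence[AlignmentSegment]],
    thresholds: Thresholds,
    with_cigar_deletions: bool = True,
) -> list[JunctionCandidate]:
    """All junction candidates from per-read ordered segments.

    Reads with three or more segments contribute one candidate per adjacent
    pair. Deletions embedded in single alignments as CIGAR ``D`` operations
    longer than ``min_span`` are converted to DEL candidates and pooled with
    the split-read evidence before clustering.
    """
    out: list[JunctionCandidate] = []
    for segs in by_read.values():
        for s1, s2 in zip(segs, segs[1:]):
            cand = pair_to_junction(s1, s2, thresholds)
            if cand is not None:
                out.append(cand)
        if with_cigar_deletions:
            for seg in segs:
                for chrom, ds, de in cigar_deletions(seg, thresholds.min_span):
                    out.append(
                        JunctionCandidate(
                            read_id=seg.read_id,
                            bp_a=Breakpoint(chrom, ds, "tail"),
                            bp_b=Breakpoint(chrom, de, "head"),
                            sv_type="DEL",
                            read_gap=0,
                            inserted_len=0,
                        )
                    )
    return out


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_junctions(
    candidates: Sequence[JunctionCandidate],
    thresholds: Thresholds,
) -> list[JunctionCall]:
    """Single-linkage clustering of candidates into calls.

    Two candidates merge when they share sv_type, chromosomes and breakpoint
    orientations, and both breakpoints are strictly closer than
    ``merge_dist``. The representative breakpoint of a cluster is the member
    median (lower of the two middles for even cluster sizes).
    """
    groups: dict[tuple, list[JunctionCandidate]] = {}
    for cand in candidates:
        key = (
            cand.sv_type,
            cand.bp_a.chrom, cand.bp_a.orient,
            cand.bp_b.chrom, cand.bp_b.orient,
        )
        groups.setdefault(key, []).append(cand)

    calls: list[JunctionCall] = []
    for key, group in groups.items():
        group.sort(key=lambda c: (c.bp_a.pos, c.bp_b.pos, c.read_id))
        uf = _UnionFind(len(group))
        for i, ci in enumerate(group):
            for j in range(i + 1, len(group)):
                cj = group[j]
                if cj.bp_a.pos - ci.bp_a.pos >= thresholds.merge_dist:
                    break
                if abs(cj.bp_b.pos - ci.bp_b.pos) < thresholds.merge_dist:
                    uf.union(i, j)
        clusters: dict[int, list[JunctionCandidate]] = {}
        for i, cand in enumerate(group):
            clusters.setdefault(uf.find(i), []).append(cand)
        sv_type, chrom_a, orient_a, chrom_b, orient_b = key
        for members in clusters.values():
            pos_a = median_low([m.bp_a.pos for m in members])
            pos_b = median_low([m.bp_b.pos for m in members])
            calls.append(
                JunctionCall(
                    bp_a=Breakpoint(chrom_a, pos_a, orient_a),
                    bp_b=Breakpoint(chrom_b, pos_b, orient_b),
                    sv_type=sv_type,
                    members=tuple(
                        sorted(members, key=lambda m: (m.read_id, m.bp_a.pos))
                    ),
                )
            )
    calls.sort(key=_call_sort_key)
    return calls


def _call_sort_key(call: JunctionCall):
    return (
        call.bp_a.chrom, call.bp_a.pos, call.bp_b.chrom, call.bp_b.pos,
        call.sv_type,
    )


def filter_calls(
    calls: Sequence[JunctionCall], thresholds: Thresholds
) -> list[JunctionCall]:
    """Support and span filters.

    Keeps calls supported by at least ``min_support`` distinct reads and,
    for intra-chromosomal types, spanning at least ``min_span`` bp between
    the two breakpoints. Translocations are exempt from the span rule.
    """
    kept = [
        c
        for c in calls
        if c.support >= thresholds.min_support
        and (c.sv_type == "TRA" or c.span >= thresholds.min_span)
    ]
    logger.info("filter_calls: %d -> %d calls", len(calls), len(kept))
    return kept


def _panel_index(
    normal_candidates: Iterable[JunctionCandidate],
) -> dict[tuple, list[tuple[int, int]]]:
    index: dict[tuple, list[tuple[int, int]]] = {}
    for cand in normal_candidates:
        key = (cand.sv_type, cand.bp_a.chrom, cand.bp_b.chrom)
        index.setdefault(key, []).append((cand.bp_a.pos, cand.bp_b.pos))
    for positions in index.values():
        positions.sort()
    return index


def subtract_panel(
    tumor: Sequence[JunctionCall],
    normal_candidates: Iterable[JunctionCandidate],
    thresholds: Thresholds,
) -> list[JunctionCall]:
    """Remove tumor calls with matching evidence in a normal control panel.

    The panel holds *unfiltered* candidates from the matched normal (no
    support threshold), so even weak germline evidence removes a call. A
    tumor call is removed when any normal candidate of the same sv_type has
    both breakpoints strictly within ``merge_dist``; survivors are flagged
    somatic.
    """
    index = _panel_index(normal_candidates)
    out: list[JunctionCall] = []
    removed = 0
    for call in tumor:
        key = (call.sv_type, call.bp_a.chrom, call.bp_b.chrom)
        positions = index.get(key, [])
        lo = bisect.bisect_left(positions, (call.bp_a.pos - thresholds.merge_dist, -1))
        matched = False
        for pa, pb in positions[lo:]:
            if pa - call.bp_a.pos >= thresholds.merge_dist:
                break
            if abs(pb - call.bp_b.pos) < thresholds.merge_dist:
                matched = True
                break
        if matched:
            removed += 1
        else:
            out.append(replace(call, somatic=True))
    logger.info("subtract_panel: removed %d of %d tumor calls", removed, len(tumor))
    return out


def _within_margin(a: JunctionCall, b: JunctionCall, margin: int) -> bool:
    return (
        a.sv_type == b.sv_type
        and a.bp_a.chrom == b.bp_a.chrom
        and a.bp_b.chrom == b.bp_b.chrom
        and abs(a.bp_a.pos - b.bp_a.pos) <= margin
        and abs(a.bp_b.pos - b.bp_b.pos) <= margin
    )


def dedupe_across_samples(
    calls_by_sample: Mapping[str, Sequence[JunctionCall]],
    margin: int,
) -> list[tuple[JunctionCall, list[str]]]:
    """Collapse redundant calls across samples.

    Calls whose breakpoints lie within ``margin`` bp of an already-seen call
    of the same type collapse onto it; the result lists each unique call
    with its carrier samples. Samples are processed in sorted order so the
    result does not depend on mapping iteration order.
    """
    unique: list[tuple[JunctionCall, list[str]]] = []
    for sample in sorted(calls_by_sample):
        for call in sorted(calls_by_sample[sample], key=_call_sort_key):
            for rep, carriers in unique:
                if _within_margin(rep, call, margin):
                    if sample not in carriers:
                        carriers.append(sample)
                    break
            else:
                unique.append((call, [sample]))
    return unique


def compare_sv_sets(
    set_a: Sequence[JunctionCall],
    set_b: Sequence[JunctionCall],
    margin: int,
) -> tuple[
    list[tuple[JunctionCall, JunctionCall]],
    list[JunctionCall],
    list[JunctionCall],
]:
    """Symmetric within-margin matching of two call sets.

    Each call is matched at most once; candidate pairs are taken
    nearest-first (by the larger of the two breakpoint offsets). Returns
    (common pairs, A-only, B-only).
    """
    pairs: list[tuple[int, int, int, int]] = []
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            if _within_margin(a, b, margin):
                dist = max(abs(a.bp_a.pos - b.bp_a.pos), abs(a.bp_b.pos - b.bp_b.pos))
                pairs.append((dist, i, j, 0))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    common: list[tuple[JunctionCall, JunctionCall]] = []
    for _, i, j, _ in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        common.append((set_a[i], set_b[j]))
    a_only = [a for i, a in enumerate(set_a) if i not in used_a]
    b_only = [b for j, b in enumerate(set_b) if j not in used_b]
    return common, a_only, b_only


# ---------------------------------------------------------------------------
# Writers / readers
# ---------------------------------------------------------------------------

BEDPE_COLUMNS = (
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "support", "strand1", "strand2", "svtype",
)


def write_bedpe(
    calls: Sequence[JunctionCall],
    path: str,
    thresholds: Optional[Thresholds] = None,
) -> None:
    """Write calls as BEDPE (0-based half-open single-base intervals)."""
    with open(path, "w") as fh:
        if thresholds is not None:
            fields = ", ".join(
                f"{k}={getattr(thresholds, k)}"
                for k in thresholds.__dataclass_fields__
            )
            fh.write(f"#thresholds: {fields}\n")
        fh.write("#" + "\t".join(BEDPE_COLUMNS) + "\n")
        for call in sorted(calls, key=_call_sort_key):
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        call.bp_a.chrom, call.bp_a.pos, call.bp_a.pos + 1,
                        call.bp_b.chrom, call.bp_b.pos, call.bp_b.pos + 1,
                        call.name, call.support,
                        call.bp_a.strand, call.bp_b.strand,
                        call.sv_type,
                    )
                )
                + "\n"
            )


def read_bedpe(path: str) -> list[JunctionCall]:
    """Read calls from BEDPE written by :func:`write_bedpe` (membership lost)."""
    calls: list[JunctionCall] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 11:
                raise ValueError(f"{path}:{ln}: expected 11 BEDPE columns")
            support = int(parts[7])
            members = tuple(
                JunctionCandidate(
                    read_id=f"{parts[6]}_r{i}",
                    bp_a=Breakpoint(parts[0], int(parts[1]),
                                    "tail" if parts[8] == "+" else "head"),
                    bp_b=Breakpoint(parts[3], int(parts[4]),
                                    "tail" if parts[9] == "+" else "head"),
                    sv_type=parts[10],
                    read_gap=0,
                    inserted_len=0,
                )
                for i in range(support)
            )
            calls.append(
                JunctionCall(
                    bp_a=Breakpoint(parts[0], int(parts[1]),
                                    "tail" if parts[8] == "+" else "head"),
                    bp_b=Breakpoint(parts[3], int(parts[4]),
                                    "tail" if parts[9] == "+" else "head"),
                    sv_type=parts[10],
                    members=members,
                )
            )
    return calls


def write_vcf(
    calls: Sequence[JunctionCall],
    path: str,
    contigs: Mapping[str, int],
) -> None:
    """Write calls as minimal VCF 4.2.

    Intra-chromosomal calls become one record with SVTYPE/END/SVLEN;
    translocations become a breakend pair linked by MATEID. The BEDPE output
    is authoritative; this conversion is lossy for reconstructed paths.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=CHR2,Number=1,Type=String,Description="Mate chromosome">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend">',
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=DUP,Description="Tandem duplication">',
        '##ALT=<ID=INV,Description="Inversion">',
    ]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for k, call in enumerate(sorted(calls, key=_call_sort_key)):
        vid = f"CLCLKIT_{k}"
        if call.sv_type == "TRA":
            info_a = (
                f"SVTYPE=BND;CHR2={call.bp_b.chrom};SUPPORT={call.support};"
                f"MATEID={vid}_2"
            )
            info_b = (
                f"SVTYPE=BND;CHR2={call.bp_a.chrom};SUPPORT={call.support};"
                f"MATEID={vid}_1"
            )
            alt_a = _bnd_alt(call.bp_a, call.bp_b)
            alt_b = _bnd_alt(call.bp_b, call.bp_a)
            lines.append(
                f"{call.bp_a.chrom}\t{call.bp_a.pos1}\t{vid}_1\tN\t{alt_a}\t.\tPASS\t{info_a}"
            )
            lines.append(
                f"{call.bp_b.chrom}\t{call.bp_b.pos1}\t{vid}_2\tN\t{alt_b}\t.\tPASS\t{info_b}"
            )
        else:
            svlen = call.span if call.sv_type != "DEL" else -call.span
            # END = 1-based last affected base = the break coordinate
            info = (
                f"SVTYPE={call.sv_type};END={call.bp_b.pos};SVLEN={svlen};"
                f"SUPPORT={call.support}"
            )
            lines.append(
                f"{call.bp_a.chrom}\t{call.bp_a.pos1}\t{vid}\tN\t"
                f"<{call.sv_type}>\t.\tPASS\t{info}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _bnd_alt(here: Breakpoint, mate: Breakpoint) -> str:
    mate_ref = f"{mate.chrom}:{mate.pos1}"
    bracket = "]" if mate.orient == "tail" else "["
    if here.orient == "tail":
        return f"N{bracket}{mate_ref}{bracket}"
    return f"{bracket}{mate_ref}{bracket}N"
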