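"""Gene-locus grouping of junction calls and local structure reconstruction.

A complex local copy-number lesion (CLCL) is a medium-scale aberration —
a combination of local duplications, inversions and deletions — evidenced by
two or more breakpoints within one gene locus (gene bodies plus a proximal
flank, plus genes connected by a shared junction call). This module:

* loads gene models (BED12 or GFF3) into an interval index;
* annotates call breakpoints with overlapping genes and genomic context;
* groups annotated calls into loci and emits a CLCL when a locus
  accumulates at least two breakpoint positions (positions, not
  adjacencies: a single tandem-duplication junction contributes two);
* reconstructs the local allele as an ordered, oriented segment path from
  the supporting reads, labelling the structure (e.g. "tandem duplication",
  "inversion + deletion", "combination of local inversions");
* extracts the consensus non-templated inserted sequence at a junction;
* counts reads split-aligned across two loci (targeted fusion support).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .alignio import AlignmentSegment, Thresholds
from .junctions import Breakpoint, JunctionCall, pair_to_junction

logger = logging.getLogger("clclkit")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    name: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        for es, ee in self.exons:
            if es < self.start or ee > self.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene bounds")


class GeneIndex:
    """Interval index of gene models, queryable by position with a flank."""

    def __init__(self, genes: Iterable[GeneModel] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._genes: list[GeneModel] = []
        for gene in genes:
            self.add(gene)

    def add(self, gene: GeneModel) -> None:
        self._genes.append(gene)
        self._trees.setdefault(gene.chrom, IntervalTree()).addi(
            gene.start, gene.end, gene
        )

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self):
        return iter(self._genes)

    def query(self, chrom: str, pos: int, flank: int = 0) -> list[GeneModel]:
        """Genes whose body extended by ``flank`` contains ``pos``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(pos - flank, pos + flank + 1)
        return sorted((iv.data for iv in hits), key=lambda g: (g.start, g.gene_id))


def _load_bed12(path: str) -> GeneIndex:
    index = GeneIndex()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected >=6 BED columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                name = parts[3]
                strand = parts[5]
                exons: tuple[tuple[int, int], ...] = ()
                if len(parts) >= 12:
                    sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                    starts = [int(x) for x in parts[11].rstrip(",").split(",")]
                    if len(sizes) != len(starts) or len(sizes) != int(parts[9]):
                        raise ValueError("inconsistent block columns")
                    exons = tuple(
                        (start + off, start + off + size)
                        for off, size in zip(starts, sizes)
                    )
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed BED line ({exc})") from exc
            index.add(GeneModel(name, name, chrom, start, end, strand, exons))
    return index


def _load_gff3(path: str) -> GeneIndex:
    import gffutils

    # pre-check column structure so errors carry line numbers
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 GFF3 columns")
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    index = GeneIndex()
    for gene in db.features_of_type("gene"):
        name = gene.attributes.get("Name", [gene.id])[0]
        exons = tuple(
            sorted(
                (exon.start - 1, exon.end)
                for exon in db.children(gene, featuretype="exon")
            )
        )
        index.add(
            GeneModel(
                gene_id=gene.id,
                name=name,
                chrom=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand,
                exons=exons,
            )
        )
    return index


def load_gene_models(path: str) -> GeneIndex:
    """Load gene models from BED (BED6/BED12) or GFF3 into a GeneIndex."""
    lower = str(path).lower()
    if lower.endswith((".gff", ".gff3")):
        return _load_gff3(path)
    if lower.endswith(".bed"):
        return _load_bed12(path)
    # sniff: GFF3 data lines have 9 columns with key=value attributes
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 9 and "=" in parts[8]:
                return _load_gff3(path)
            break
    return _load_bed12(path)


def load_repeat_track(path: str) -> dict[str, IntervalTree]:
    """Load a RepeatMasker-style BED track (name column = repeat class)."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected >=4 BED columns")
            trees.setdefault(parts[0], IntervalTree()).addi(
                int(parts[1]), int(parts[2]), parts[3]
            )
    return trees


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotatedCall:
    """A junction call with per-breakpoint gene labels and context classes."""

    call: JunctionCall
    genes_a: tuple[GeneModel, ...]
    genes_b: tuple[GeneModel, ...]
    context_a: str = "unannotated"
    context_b: str = "unannotated"

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(sorted({g.name for g in self.genes_a + self.genes_b}))


def _repeat_context(
    repeats: Optional[Mapping[str, IntervalTree]], bp: Breakpoint
) -> str:
    if repeats is None:
        return "unannotated"
    tree = repeats.get(bp.chrom)
    if tree is None:
        return "none"
    hits = tree.overlap(bp.pos, bp.pos + 1)
    if not hits:
        return "none"
    return sorted(iv.data for iv in hits)[0]


def annotate_calls(
    calls: Sequence[JunctionCall],
    genes: GeneIndex,
    thresholds: Thresholds,
    repeats: Optional[Mapping[str, IntervalTree]] = None,
) -> list[AnnotatedCall]:
    """Label each breakpoint with genes within gene body +- proximal_flank.

    A chromosome absent from the gene set yields an empty label (logged
    once). The optional repeat track assigns each breakpoint a genomic
    context class (its repeat class name, "none" outside any repeat,
    "unannotated" when no track is supplied).
    """
    missing: set[str] = set()
    out: list[AnnotatedCall] = []
    for call in calls:
        labels = []
        for bp in (call.bp_a, call.bp_b):
            hits = genes.query(bp.chrom, bp.pos, flank=thresholds.proximal_flank)
            if not hits and bp.chrom not in {g.chrom for g in genes}:
                missing.add(bp.chrom)
            labels.append(tuple(hits))
        out.append(
            AnnotatedCall(
                call=call,
                genes_a=labels[0],
                genes_b=labels[1],
                context_a=_repeat_context(repeats, call.bp_a),
                context_b=_repeat_context(repeats, call.bp_b),
            )
        )
    if missing:
        logger.info(
            "annotate_calls: chromosomes absent from gene models: %s",
            ", ".join(sorted(missing)),
        )
    return out


# ---------------------------------------------------------------------------
# CLCL detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentPath:
    """Ordered, oriented reference segments of a reconstructed local allele.

    ``segments`` are (chrom, start, end, orientation) with 0-based half-open
    coordinates; ``insertions`` holds the non-templated length at each of the
    ``len(segments) - 1`` junctions. ``label`` is a structure classification
    derived from strandedness and reference coverage of the path.
    """

    segments: tuple[tuple[str, int, int, str], ...]
    insertions: tuple[int, ...] = ()
    label: str = "unclassified"
    ambiguous: bool = False

    @property
    def length(self) -> int:
        return sum(e - s for _, s, e, _ in self.segments) + sum(self.insertions)

    def __str__(self) -> str:
        return ",".join(
            f"{c}:{s}-{e}/{o}" for c, s, e, o in self.segments
        )


@dataclass
class CLCLCall:
    """A gene-locus group of junction calls with >=2 breakpoint positions."""

    genes: tuple[GeneModel, ...]
    calls: tuple[AnnotatedCall, ...]
    n_breakpoints: int
    read_ids: frozenset[str]
    path: Optional[SegmentPath] = None
    n_full_cover: int = 0

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes)

    @property
    def breakpoints(self) -> tuple[Breakpoint, ...]:
        bps = {bp for ac in self.calls for bp in (ac.call.bp_a, ac.call.bp_b)}
        return tuple(sorted(bps, key=lambda b: (b.chrom, b.pos)))

    @property
    def support(self) -> int:
        return len(self.read_ids)


class _Components:
    """Union-find over gene ids."""

    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: str, y: str) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[max(rx, ry)] = min(rx, ry)


def detect_clcl(
    annotated_calls: Sequence[AnnotatedCall],
    thresholds: Thresholds,
) -> list[CLCLCall]:
    """Group annotated calls into gene loci and emit CLCL calls.

    A locus is a connected component of genes linked by shared junction
    calls. A CLCL is emitted when the locus accumulates at least two
    distinct breakpoint positions lying within its gene bodies +-
    ``proximal_flank``. Output is sorted by locus coordinate and is
    invariant to the order of the input calls.
    """
    comp = _Components()
    gene_by_id: dict[str, GeneModel] = {}
    for ac in annotated_calls:
        touched = {g.gene_id for g in ac.genes_a + ac.genes_b}
        for g in ac.genes_a + ac.genes_b:
            gene_by_id[g.gene_id] = g
        ids = sorted(touched)
        for gid in ids[1:]:
            comp.union(ids[0], gid)

    locus_calls: dict[str, list[AnnotatedCall]] = {}
    for ac in sorted(
        annotated_calls,
        key=lambda a: (a.call.bp_a.chrom, a.call.bp_a.pos, a.call.bp_b.pos,
                       a.call.sv_type),
    ):
        roots = {comp.find(g.gene_id) for g in ac.genes_a + ac.genes_b}
        for root in sorted(roots):
            locus_calls.setdefault(root, []).append(ac)

    out: list[CLCLCall] = []
    for root in sorted(locus_calls):
        members = locus_calls[root]
        genes = sorted(
            (g for g in gene_by_id.values() if comp.find(g.gene_id) == root),
            key=lambda g: (g.chrom, g.start, g.gene_id),
        )
        in_locus: set[tuple[str, int]] = set()
        for ac in members:
            for bp, labels in ((ac.call.bp_a, ac.genes_a), (ac.call.bp_b, ac.genes_b)):
                if any(comp.find(g.gene_id) == root for g in labels):
                    in_locus.add((bp.chrom, bp.pos))
        if len(in_locus) < 2:
            continue
        read_ids = frozenset(
            rid for ac in members for rid in ac.call.read_ids
        )
        out.append(
            CLCLCall(
                genes=tuple(genes),
                calls=tuple(members),
                n_breakpoints=len(in_locus),
                read_ids=read_ids,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Structure reconstruction
# ---------------------------------------------------------------------------

def _flip(orient: str) -> str:
    return "-" if orient == "+" else "+"


def _canonical_path(
    path: tuple[tuple[str, int, int, str], ...]
) -> tuple[tuple[tuple[str, int, int, str], ...], bool]:
    """Orient a per-read path canonically; returns (path, was_flipped)."""
    flipped = tuple(
        (c, s, e, _flip(o)) for c, s, e, o in reversed(path)
    )
    if flipped < path:
        return flipped, True
    return path, False


def _match_call(
    cand_bp_a: Breakpoint,
    cand_bp_b: Breakpoint,
    sv_type: str,
    calls: Sequence[AnnotatedCall],
    merge_dist: int,
) -> Optional[int]:
    for k, ac in enumerate(calls):
        c = ac.call
        if (
            c.sv_type == sv_type
            and c.bp_a.chrom == cand_bp_a.chrom
            and c.bp_b.chrom == cand_bp_b.chrom
            and abs(c.bp_a.pos - cand_bp_a.pos) < merge_dist
            and abs(c.bp_b.pos - cand_bp_b.pos) < merge_dist
        ):
            return k
    return None


def classify_path(
    segments: Sequence[tuple[str, int, int, str]],
    call_types: Sequence[str] = (),
    extent: Optional[tuple[int, int]] = None,
) -> str:
    """Structure label from a path's strandedness and reference coverage.

    Inversion is a mix of segment orientations (a path aligned entirely to
    the minus strand is just the reverse-strand reading of the same
    structure). Duplication is reference self-overlap of the path — or a
    member DUP call, since a read shorter than the duplicated unit never
    overlaps itself. Deletion is an uncovered region between the outermost
    path coordinates; terminal segments are first extended outward to
    ``extent`` so ragged read ends do not mimic missing sequence.
    """
    if len(segments) <= 1:
        return "wild type"
    if len({c for c, _, _, _ in segments}) > 1 or "TRA" in call_types:
        return "complex rearrangement"
    ivs = [(s, e) for _, s, e, _ in segments]
    if extent is not None:
        lo, hi = extent
        first, last = segments[0], segments[-1]
        # the outward coordinate of a terminal segment is its read end, not
        # a junction; stretch it to the known breakpoint extent
        s, e = ivs[0]
        ivs[0] = (min(s, lo), e) if first[3] == "+" else (s, max(e, hi))
        s, e = ivs[-1]
        ivs[-1] = (s, max(e, hi)) if last[3] == "+" else (min(s, lo), e)
    ivs.sort()
    has_inv = len({o for _, _, _, o in segments}) > 1 or "INV" in call_types
    has_dup = (
        any(b[0] < a[1] for a, b in zip(ivs, ivs[1:])) or "DUP" in call_types
    )
    covered_to = ivs[0][1]
    has_del = False
    for s, e in ivs[1:]:
        if s > covered_to:
            has_del = True
        covered_to = max(covered_to, e)
    if has_inv:
        if has_del and not has_dup:
            return "inversion + deletion"
        if has_dup and not has_del:
            return "combination of local inversions"
        if not has_dup and not has_del:
            return "inversion"
        return "complex rearrangement"
    if has_dup and not has_del:
        return "tandem duplication"
    if has_del and not has_dup:
        return "deletion"
    if has_dup and has_del:
        return "complex rearrangement"
    return "wild type"


def reconstruct_structure(
    clcl: CLCLCall,
    read_segments: Mapping[str, Sequence[AlignmentSegment]],
    thresholds: Thresholds,
) -> SegmentPath:
    """Rebuild the local allele of a CLCL from its supporting reads.

    Each supporting read contributes a path of oriented reference segments
    (restricted to the locus window); junctions between consecutive path
    segments are matched to the CLCL's member calls and the breakpoint
    coordinates snapped to the call representatives. The consensus path is
    the per-read junction signature covering the most member junctions,
    preferring the most frequent signature and then the path covered by the
    longest single read (reads traversing the full structure are the
    strongest evidence for it). ``clcl.n_full_cover`` is set to
    the number of reads traversing every member junction; reads covering no
    member junction are ignored (wild-type allele reads). When no read
    covers any junction the locus reference segment is returned labelled
    "wild type"; a consensus that does not include every member call is
    flagged ambiguous.
    """
    bps = clcl.breakpoints
    chroms = {bp.chrom for bp in bps}
    lo = min(bp.pos for bp in bps) - thresholds.proximal_flank
    hi = max(bp.pos for bp in bps) + thresholds.proximal_flank
    n_calls = len(clcl.calls)
    snap_positions = sorted(
        {bp.pos for ac in clcl.calls for bp in (ac.call.bp_a, ac.call.bp_b)}
    )

    def snap(pos: int) -> int:
        best = pos
        for p in snap_positions:
            if abs(p - pos) < thresholds.merge_dist and abs(p - pos) < abs(best - pos):
                best = p
        return best if abs(best - pos) < thresholds.merge_dist else pos

    # per-read: (signature, full path, matched set, read span)
    per_read: list[tuple[tuple, tuple, frozenset[int], int]] = []
    wild_candidates: list[tuple[int, tuple[str, int, int, str]]] = []
    for rid in sorted(clcl.read_ids):
        segs = [
            s
            for s in read_segments.get(rid, ())
            if s.chrom in chroms and s.ref_end > lo and s.ref_start < hi
        ]
        if not segs:
            continue
        matched: set[int] = set()
        ins_lens: list[int] = []
        for s1, s2 in zip(segs, segs[1:]):
            cand = pair_to_junction(s1, s2, thresholds)
            if cand is None:
                ins_lens.append(0)
                continue
            k = _match_call(
                cand.bp_a, cand.bp_b, cand.sv_type, clcl.calls,
                thresholds.merge_dist,
            )
            ins_lens.append(cand.inserted_len)
            if k is not None:
                matched.add(k)
        span = segs[-1].read_end - segs[0].read_start
        if not matched:
            if len(segs) == 1:
                s = segs[0]
                wild_candidates.append(
                    (s.ref_end - s.ref_start, (s.chrom, s.ref_start, s.ref_end, s.strand))
                )
            continue
        raw = tuple(
            (s.chrom, snap(s.ref_start), snap(s.ref_end), s.strand) for s in segs
        )
        path, was_flipped = _canonical_path(raw)
        if was_flipped:
            ins_lens = list(reversed(ins_lens))
        # signature masks the outward (read-end) coordinate of the terminal
        # segments, so ragged read ends do not fragment the consensus
        first = path[0]
        last = path[-1]
        sig_first = (first[0], first[2] if first[3] == "+" else first[1], first[3])
        sig_last = (last[0], last[1] if last[3] == "+" else last[2], last[3])
        signature = (sig_first,) + path[1:-1] + (sig_last,) if len(path) > 1 else (
            (first[0], first[3]),
        )
        per_read.append((signature, (path, tuple(ins_lens)), frozenset(matched), span))

    if not per_read:
        if wild_candidates:
            _, seg = max(wild_candidates)
            return SegmentPath((seg,), (), "wild type")
        return SegmentPath((), (), "wild type", ambiguous=True)

    clcl.n_full_cover = sum(
        1 for _, _, matched, _ in per_read if len(matched) == n_calls
    )

    counts = Counter(sig for sig, _, _, _ in per_read)
    n_matched = {sig: 0 for sig in counts}
    for sig, _, matched, _ in per_read:
        n_matched[sig] = max(n_matched[sig], len(matched))
    best_sig = max(
        counts,
        key=lambda sig: (
            n_matched[sig],
            counts[sig],
            max(span for s, _, _, span in per_read if s == sig),
        ),
    )
    candidates = [pr for pr in per_read if pr[0] == best_sig]
    _, (path, ins_lens), matched, _ = max(candidates, key=lambda pr: pr[3])
    matched_types = tuple(clcl.calls[k].call.sv_type for k in sorted(matched))
    label = classify_path(
        path,
        call_types=matched_types,
        extent=(min(bp.pos for bp in bps), max(bp.pos for bp in bps)),
    )
    result = SegmentPath(
        segments=path,
        insertions=ins_lens,
        label=label,
        ambiguous=len(matched) < n_calls,
    )
    clcl.path = result
    return result


# ---------------------------------------------------------------------------
# Junction inserted sequence
# ---------------------------------------------------------------------------

def junction_inserted_sequence(
    call: JunctionCall,
    read_sequences: Mapping[str, str],
) -> Optional[tuple[str, int]]:
    """Consensus non-templated bases at a junction.

    For each supporting read with a sequence available, the read bases
    between the two aligned segments (in original read orientation) are
    extracted; the plurality read-gap length wins and the per-position
    majority base forms the consensus. Returns (sequence, length), or
    ``None`` (logged) when no supporting read has a sequence.
    """
    from .simulate import revcomp

    pieces: list[str] = []
    for member in call.members:
        seq = read_sequences.get(member.read_id)
        if seq is None:
            continue
        lo, hi = member.read_pos
        piece = seq[lo:hi] if hi > lo else ""
        if member.reversed_traversal:
            piece = revcomp(piece)
        pieces.append(piece)
    if not pieces:
        logger.warning(
            "junction_inserted_sequence: no supporting read with sequence for %s",
            call.name,
        )
        return None
    length_votes = Counter(len(p) for p in pieces)
    top = max(length_votes.values())
    length = max(l for l, n in length_votes.items() if n == top)
    chosen = [p for p in pieces if len(p) == length]
    consensus = "".join(
        Counter(bases).most_common(1)[0][0] for bases in zip(*chosen)
    ) if length else ""
    return consensus, length


# ---------------------------------------------------------------------------
# Targeted fusion support
# ---------------------------------------------------------------------------

def count_fusion_support(
    segments: Iterable[AlignmentSegment],
    locus_a: tuple[str, int, int],
    locus_b: tuple[str, int, int],
    thresholds: Thresholds,
) -> int:
    """Distinct reads split-aligned to both loci with adequate MAPQ.

    A read counts when it has at least one segment with MAPQ >=
    ``min_mapq`` overlapping each of the two disjoint regions.
    """
    ca, sa, ea = locus_a
    cb, sb, eb = locus_b
    if ca == cb and sa < eb and sb < ea:
        raise ValueError("count_fusion_support: loci overlap")
    reads_a: set[str] = set()
    reads_b: set[str] = set()
    for seg in segments:
        if seg.mapq < thresholds.min_mapq:
            continue
        if seg.chrom == ca and seg.ref_end > sa and seg.ref_start < ea:
            reads_a.add(seg.read_id)
        if seg.chrom == cb and seg.ref_end > sb and seg.ref_start < eb:
            reads_b.add(seg.read_id)
    return len(reads_a & reads_b)


# ---------------------------------------------------------------------------
# Report writer
# ---------------------------------------------------------------------------

REPORT_COLUMNS = (
    "locus", "genes", "n_breakpoints", "label", "path",
    "support", "full_cover_reads",
)


def write_clcl_report(
    clcls: Sequence[CLCLCall],
    path: str,
    thresholds: Optional[Thresholds] = None,
) -> None:
    """Write a tab-separated CLCL report (one row per locus)."""
    with open(path, "w") as fh:
        if thresholds is not None:
            fields = ", ".join(
                f"{k}={getattr(thresholds, k)}"
                for k in thresholds.__dataclass_fields__
            )
            fh.write(f"#thresholds: {fields}\n")
        fh.write("#" + "\t".join(REPORT_COLUMNS) + "\n")
        for clcl in clcls:
            bps = clcl.breakpoints
            locus = (
                f"{bps[0].chrom}:{min(b.pos for b in bps)}-{max(b.pos for b in bps)}"
                if bps
                else "."
            )
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        locus,
                        ",".join(clcl.gene_names) or ".",
                        clcl.n_breakpoints,
                        clcl.path.label if clcl.path else "unreconstructed",
                        str(clcl.path) if clcl.path else ".",
                        clcl.support,
                        clcl.n_full_cover,
                    )
                )
                + "\n"
            )
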