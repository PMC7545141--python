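"""Rearranged-allele read simulator with ground-truth split alignments.

The generator builds a local haplotype (allele) by concatenating ordered,
oriented reference segments — optionally separated by short non-templated
insertion sequences — then samples long reads from it and emits the split
alignments a long-read aligner would produce: one primary record plus one
supplementary record (flag 2048) per additional junction crossed, with
soft clips encoding the read offsets and junction insertions left
unaligned. This makes the whole calling pipeline testable with no aligner
and no external data, and provides per-read ground truth for support
accounting.

References are seeded uniform-random nucleotide sequences occupying an
arbitrary coordinate window of a named chromosome, so fixtures can use
genome-scale coordinates without shipping a genome.

Read lengths are log-normal; the default parameters give a base-weighted
median (N50) of ~25 kb, matching a recent nanopore long-read run
(N50 20-30 kb). The default per-base error rate is 0 so that truth tests
are exact; uniform substitution errors are available as a knob.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pysam

logger = logging.getLogger("clclkit")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _child_seed(seed: int, k: int) -> int:
    # keep derived seeds below 2**31
    return (seed * 1_000_003 + k) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

class SyntheticReference:
    """Seeded random sequence windows standing in for reference chromosomes.

    Each chromosome is a uniform-random nucleotide sequence occupying
    ``[offset, offset + len)`` in that chromosome's coordinate frame; the
    declared chromosome length is ``offset + len`` so emitted SAM headers
    are consistent with genome-scale positions.
    """

    def __init__(self, windows: Mapping[str, tuple[int, int]], seed: int = 0) -> None:
        self.windows = dict(windows)
        self.seed = seed
        self._seqs: dict[str, str] = {}
        for k, (chrom, (offset, length)) in enumerate(sorted(self.windows.items())):
            rng = np.random.default_rng(_child_seed(seed, 1000 + k))
            self._seqs[chrom] = "".join(
                np.array(list("ACGT"))[rng.integers(0, 4, size=length)]
            )

    @property
    def contigs(self) -> dict[str, int]:
        return {c: off + ln for c, (off, ln) in self.windows.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        offset, length = self.windows[chrom]
        if start < offset or end > offset + length or start >= end:
            raise ValueError(
                f"segment {chrom}:{start}-{end} outside reference window "
                f"{chrom}:{offset}-{offset + length}"
            )
        return self._seqs[chrom][start - offset : end - offset]

    def write_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._seqs):
                offset, _ = self.windows[chrom]
                fh.write(f">{chrom} window_offset={offset}\n")
                seq = self._seqs[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# Simulation spec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimSegment:
    chrom: str
    start: int  # 0-based half-open, reference frame
    end: int
    orient: str = "+"


@dataclass(frozen=True)
class SimSpec:
    """Specification of one simulated rearranged allele and its read set.

    ``path`` lists the ordered, oriented reference segments of the allele;
    ``insertions`` gives the non-templated sequence at each internal
    junction (empty string = blunt). Coverage is in fold coverage of the
    allele; reads are sampled until the base budget is met, so realized
    coverage is within one read length of the target.
    """

    reference: Mapping[str, tuple[int, int]]  # chrom -> (offset, length)
    path: tuple[SimSegment, ...]
    insertions: tuple[str, ...] = ()
    coverage: float = 20.0
    read_n50: int = 25_000
    length_sigma: float = 0.6
    min_read_length: int = 500
    error_rate: float = 0.0
    tumor_fraction: float = 1.0
    mapq: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.insertions and len(self.insertions) != len(self.path) - 1:
            raise ValueError("insertions must have len(path) - 1 entries")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must be in [0, 1]")
        for seg in self.path:
            if seg.start >= seg.end:
                raise ValueError(f"empty segment {seg}")
            if seg.orient not in ("+", "-"):
                raise ValueError(f"invalid orientation {seg.orient!r}")

    def with_(self, **kwargs) -> "SimSpec":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Allele construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthAdjacency:
    """One novel adjacency of the simulated allele (ground truth)."""

    chrom_a: str
    pos_a: int  # 0-based break coordinate
    orient_a: str  # 'tail' / 'head'
    chrom_b: str
    pos_b: int
    orient_b: str
    sv_type: str
    inserted_len: int

    @property
    def pos1_a(self) -> int:
        return self.pos_a if self.orient_a == "tail" else self.pos_a + 1

    @property
    def pos1_b(self) -> int:
        return self.pos_b if self.orient_b == "tail" else self.pos_b + 1


@dataclass(frozen=True)
class AlleleBlock:
    """One block of the allele: an aligned segment or an insertion."""

    allele_start: int
    allele_end: int
    kind: str  # 'segment' | 'insert'
    chrom: str = ""
    ref_start: int = 0
    ref_end: int = 0
    orient: str = "+"


@dataclass(frozen=True)
class Allele:
    seq: str
    blocks: tuple[AlleleBlock, ...]
    truth: tuple[TruthAdjacency, ...]

    @property
    def segment_blocks(self) -> tuple[AlleleBlock, ...]:
        return tuple(b for b in self.blocks if b.kind == "segment")


def _truth_adjacency(
    seg1: SimSegment, seg2: SimSegment, inserted_len: int
) -> TruthAdjacency:
    # typing logic independent of the caller's pair classification
    if seg1.orient == "+":
        a = (seg1.chrom, seg1.end, "tail")
    else:
        a = (seg1.chrom, seg1.start, "head")
    if seg2.orient == "+":
        b = (seg2.chrom, seg2.start, "head")
    else:
        b = (seg2.chrom, seg2.end, "tail")
    if seg1.chrom != seg2.chrom:
        sv = "TRA"
    elif seg1.orient != seg2.orient:
        sv = "INV"
    elif seg1.orient == "+":
        sv = "DEL" if b[1] >= a[1] else "DUP"
    else:
        sv = "DEL" if b[1] <= a[1] else "DUP"
    (ca, pa, oa), (cb, pb, ob) = sorted((a, b), key=lambda t: (t[0], t[1]))
    return TruthAdjacency(ca, pa, oa, cb, pb, ob, sv, inserted_len)


def build_allele(reference: SyntheticReference, spec: SimSpec) -> Allele:
    """Concatenate oriented segments (plus junction insertions) into an allele.

    Returns the allele sequence, its block map (for truth alignments) and
    the truth table of novel adjacencies with types and breakpoints.
    Out-of-bounds segments are a hard error.
    """
    insertions = spec.insertions or ("",) * (len(spec.path) - 1)
    parts: list[str] = []
    blocks: list[AlleleBlock] = []
    pos = 0
    for i, seg in enumerate(spec.path):
        seq = reference.fetch(seg.chrom, seg.start, seg.end)
        if seg.orient == "-":
            seq = revcomp(seq)
        blocks.append(
            AlleleBlock(pos, pos + len(seq), "segment",
                        seg.chrom, seg.start, seg.end, seg.orient)
        )
        parts.append(seq)
        pos += len(seq)
        if i < len(spec.path) - 1 and insertions[i]:
            ins = insertions[i]
            blocks.append(AlleleBlock(pos, pos + len(ins), "insert"))
            parts.append(ins)
            pos += len(ins)
    truth = tuple(
        _truth_adjacency(s1, s2, len(insertions[i]))
        for i, (s1, s2) in enumerate(zip(spec.path, spec.path[1:]))
    )
    return Allele(seq="".join(parts), blocks=tuple(blocks), truth=truth)


# ---------------------------------------------------------------------------
# Read sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimRead:
    read_id: str
    seq: str
    allele_start: int
    allele_end: int
    strand: str  # strand of the allele the read was sampled from

    def __len__(self) -> int:
        return len(self.seq)


def simulate_reads(
    allele: Allele, spec: SimSpec, id_prefix: str = "read"
) -> list[SimRead]:
    """Sample reads uniformly from the allele until the base budget is met.

    Lengths are log-normal with base-weighted median ``read_n50``
    (mu = ln(read_n50) - sigma^2); reads are truncated at the allele end and
    drawn from either strand with equal probability. Optional uniform
    substitution errors at ``error_rate``. Fully deterministic under
    ``spec.seed``.
    """
    rng = np.random.default_rng(_child_seed(spec.seed, 2))
    allele_len = len(allele.seq)
    target = spec.coverage * allele_len
    mu = np.log(spec.read_n50) - spec.length_sigma**2
    reads: list[SimRead] = []
    total = 0
    i = 0
    while total < target:
        length = int(rng.lognormal(mu, spec.length_sigma))
        length = max(length, min(spec.min_read_length, allele_len))
        start = int(rng.integers(0, allele_len))
        end = min(start + length, allele_len)
        if end - start < min(spec.min_read_length, allele_len):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        seq = allele.seq[start:end]
        if spec.error_rate > 0:
            seq = _mutate(seq, spec.error_rate, rng)
        if strand == "-":
            seq = revcomp(seq)
        reads.append(SimRead(f"{id_prefix}{i:05d}", seq, start, end, strand))
        total += end - start
        i += 1
    return reads


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.where(rng.random(len(arr)) < rate)[0]
    bases = np.array([b"A", b"C", b"G", b"T"])
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def junctions_crossed(read: SimRead, allele: Allele) -> list[int]:
    """Indices of allele junctions this read's placement spans.

    Junction ``k`` (between segment blocks k and k+1) is crossed when the
    read covers at least one aligned base on each side.
    """
    segs = allele.segment_blocks
    out = []
    for k in range(len(segs) - 1):
        if read.allele_start < segs[k].allele_end and read.allele_end > segs[k + 1].allele_start:
            out.append(k)
    return out


# ---------------------------------------------------------------------------
# Truth alignment emission
# ---------------------------------------------------------------------------

def truth_records(
    reads: Sequence[SimRead],
    allele: Allele,
    reference: SyntheticReference,
    mapq: Optional[int] = None,
    spec: Optional[SimSpec] = None,
) -> tuple[dict, list[dict]]:
    """Ground-truth split alignment records for a read set.

    Each read crossing k junctions yields k+1 records — one primary plus k
    supplementary (flag 2048) — with correct strands, soft-clip CIGARs
    encoding the read offsets, and junction insertions left unaligned
    between the segments. Returns (SAM header dict, record dicts).
    """
    if mapq is None:
        mapq = spec.mapq if spec is not None else 60
    contigs = reference.contigs
    names = sorted(contigs)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": contigs[n]} for n in names],
    }
    records: list[dict] = []
    for read in reads:
        a, b = read.allele_start, read.allele_end
        read_len = b - a
        pieces: list[dict] = []
        for block in allele.segment_blocks:
            ia, ib = max(a, block.allele_start), min(b, block.allele_end)
            if ia >= ib:
                continue
            if block.orient == "+":
                rs = block.ref_start + (ia - block.allele_start)
                re_ = block.ref_start + (ib - block.allele_start)
            else:
                rs = block.ref_start + (block.allele_end - ib)
                re_ = block.ref_start + (block.allele_end - ia)
            rec_strand = "+" if block.orient == read.strand else "-"
            if read.strand == "+":
                qs, qe = ia - a, ib - a
            else:
                qs, qe = b - ib, b - ia
            pieces.append(
                dict(chrom=block.chrom, ref_start=rs, ref_end=re_,
                     strand=rec_strand, qs=qs, qe=qe)
            )
        if not pieces:
            continue  # read lies entirely inside an insertion
        primary = max(range(len(pieces)), key=lambda i: pieces[i]["qe"] - pieces[i]["qs"])
        for i, p in enumerate(pieces):
            qs, qe = p["qs"], p["qe"]
            if p["strand"] == "-":
                qs_seq, qe_seq = read_len - qe, read_len - qs
                seq = revcomp(read.seq)
            else:
                qs_seq, qe_seq = qs, qe
                seq = read.seq
            cigar = ""
            if qs_seq:
                cigar += f"{qs_seq}S"
            cigar += f"{qe_seq - qs_seq}M"
            if read_len - qe_seq:
                cigar += f"{read_len - qe_seq}S"
            flag = (16 if p["strand"] == "-" else 0) | (0 if i == primary else 2048)
            records.append(
                dict(
                    read_id=read.read_id, flag=flag, chrom=p["chrom"],
                    ref_start=p["ref_start"], mapq=mapq, cigar=cigar, seq=seq,
                )
            )
    records.sort(key=lambda r: (names.index(r["chrom"]), r["ref_start"], r["read_id"]))
    return header, records


def emit_truth_alignments(
    reads: Sequence[SimRead],
    allele: Allele,
    reference: SyntheticReference,
    path: str,
    mapq: Optional[int] = None,
    spec: Optional[SimSpec] = None,
) -> int:
    """Write ground-truth split alignments to a SAM file; returns record count."""
    header, records = truth_records(reads, allele, reference, mapq=mapq, spec=spec)
    names = [sq["SN"] for sq in header["SQ"]]
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in records:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = r["read_id"]
            rec.flag = r["flag"]
            rec.reference_id = names.index(r["chrom"])
            rec.reference_start = r["ref_start"]
            rec.mapping_quality = r["mapq"]
            rec.cigarstring = r["cigar"]
            rec.query_sequence = r["seq"]
            out.write(rec)
    return len(records)


def write_fastq(reads: Sequence[SimRead], path: str) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.seq}\n+\n{'I' * len(read.seq)}\n")


def write_truth_table(allele: Allele, path: str) -> None:
    """Tab-separated truth adjacencies (1-based printed breakpoints)."""
    with open(path, "w") as fh:
        fh.write("#chrom_a\tpos_a\torient_a\tchrom_b\tpos_b\torient_b\tsvtype\tinserted_len\n")
        for t in allele.truth:
            fh.write(
                f"{t.chrom_a}\t{t.pos1_a}\t{t.orient_a}\t{t.chrom_b}\t{t.pos1_b}"
                f"\t{t.orient_b}\t{t.sv_type}\t{t.inserted_len}\n"
            )


def mix_tumor_normal(
    tumor_reads: Sequence[SimRead],
    normal_reads: Sequence[SimRead],
    fraction: float,
    seed: int,
    n_reads: Optional[int] = None,
) -> list[SimRead]:
    """Mix tumor and normal reads at a given tumor fraction.

    Each of ``n_reads`` output reads is drawn from the tumor pool with
    probability ``fraction``, without replacement; mixing stops early if the
    designated pool is exhausted (the realized fraction is never distorted
    by substitution). Read ids are prefixed ``tumor_``/``normal_`` to stay
    unique. Reproducible under ``seed``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(_child_seed(seed, 3))
    if n_reads is None:
        n_reads = len(tumor_reads) + len(normal_reads)
    ti = ni = 0
    out: list[SimRead] = []
    for _ in range(n_reads):
        take_tumor = rng.random() < fraction
        if take_tumor and ti >= len(tumor_reads):
            break
        if not take_tumor and ni >= len(normal_reads):
            break
        if take_tumor:
            r = tumor_reads[ti]
            ti += 1
            out.append(replace(r, read_id=f"tumor_{r.read_id}"))
        else:
            r = normal_reads[ni]
            ni += 1
            out.append(replace(r, read_id=f"normal_{r.read_id}"))
    return out


def simulate_to_files(
    spec: SimSpec,
    out_dir: str,
    prefix: str = "sim",
) -> dict[str, str]:
    """Run the full simulation and write FASTA/FASTQ/SAM/truth outputs."""
    import os

    reference = SyntheticReference(spec.reference, seed=spec.seed)
    allele = build_allele(reference, spec)
    reads = simulate_reads(allele, spec)
    paths = {
        "reference": os.path.join(out_dir, f"{prefix}_reference.fa"),
        "allele": os.path.join(out_dir, f"{prefix}_allele.fa"),
        "reads": os.path.join(out_dir, f"{prefix}_reads.fastq"),
        "alignments": os.path.join(out_dir, f"{prefix}_truth.sam"),
        "truth": os.path.join(out_dir, f"{prefix}_truth.tsv"),
    }
    reference.write_fasta(paths["reference"])
    with open(paths["allele"], "w") as fh:
        fh.write(f">{prefix}_allele\n")
        for i in range(0, len(allele.seq), 80):
            fh.write(allele.seq[i : i + 80] + "\n")
    write_fastq(reads, paths["reads"])
    emit_truth_alignments(reads, allele, reference, paths["alignments"], spec=spec)
    write_truth_table(allele, paths["truth"])
    logger.info(
        "simulate_to_files: %d reads (%.1f kb allele) -> %s",
        len(reads), len(allele.seq) / 1000, out_dir,
    )
    return paths


# ---------------------------------------------------------------------------
# Worked-example fixtures
# ---------------------------------------------------------------------------
# Local lesions reported in lung cancer cell lines and a clinical case,
# rebuilt on seeded synthetic references occupying the published hg38
# coordinate windows. Junction coordinates are the published 1-based
# breakpoint positions; flanks and (for PTEN) internal coordinates are this
# package's choices. The STK11 junction I/III insertion sequence is a
# synthetic 5-mer (the published length is 5 bp; the bases are not printed).

def stk11_spec(seed: int = 0, coverage: float = 25.0, insertion: str = "GATTC") -> SimSpec:
    """STK11 lesion (RERF-LC-KJ): combination of local inversions.

    Forward up to breakpoint II (chr19:1,216,572), inverted segment from
    breakpoint IV (1,228,569) back to breakpoint I (1,216,360), resuming
    forward at breakpoint III (1,219,538); ~12-kb reference span, with a
    5-bp non-templated insertion at junction I/III.
    """
    return SimSpec(
        reference={"chr19": (1_205_000, 33_000)},
        path=(
            SimSegment("chr19", 1_210_000, 1_216_572, "+"),
            SimSegment("chr19", 1_216_359, 1_228_569, "-"),
            SimSegment("chr19", 1_219_537, 1_226_000, "+"),
        ),
        insertions=("", insertion),
        coverage=coverage,
        seed=seed,
    )


def nf1_spec(seed: int = 0, coverage: float = 20.0) -> SimSpec:
    """NF1 lesion (RERF-LC-MS): 78-kb tandem duplication.

    The duplicated unit runs from chr17:31,200,948 (intron 9) to
    chr17:31,278,880 (downstream of the last exon).
    """
    return SimSpec(
        reference={"chr17": (31_188_000, 104_000)},
        path=(
            SimSegment("chr17", 31_195_000, 31_278_880, "+"),
            SimSegment("chr17", 31_200_947, 31_285_000, "+"),
        ),
        coverage=coverage,
        seed=seed,
    )


def smarca4_spec(seed: int = 0, coverage: float = 20.0) -> SimSpec:
    """SMARCA4 lesion (PC-14): ~50-kb tandem duplication.

    Duplicated unit chr19:10,973,314 (intron 1) to chr19:11,022,573
    (intron 20).
    """
    return SimSpec(
        reference={"chr19": (10_960_000, 78_000)},
        path=(
            SimSegment("chr19", 10_966_000, 11_022_573, "+"),
            SimSegment("chr19", 10_973_313, 11_030_000, "+"),
        ),
        coverage=coverage,
        seed=seed,
    )


def rnf20_spec(seed: int = 0, coverage: float = 20.0) -> SimSpec:
    """RNF20 lesion (clinical case S8): ~8-kb tandem duplication.

    Duplicated unit chr9:101,536,324 (intron 2) to chr9:101,544,752
    (intron 6).
    """
    return SimSpec(
        reference={"chr9": (101_525_000, 31_000)},
        path=(
            SimSegment("chr9", 101_530_000, 101_544_752, "+"),
            SimSegment("chr9", 101_536_323, 101_551_000, "+"),
        ),
        coverage=coverage,
        seed=seed,
    )


def pten_spec(seed: int = 0, coverage: float = 20.0) -> SimSpec:
    """PTEN-style lesion (PC-14): inversion + deletion, ~7-kb extent.

    Coordinates are synthetic (placed inside the PTEN gene body): a 2-kb
    deletion followed by an inverted 5-kb segment.
    """
    return SimSpec(
        reference={"chr10": (87_950_000, 25_000)},
        path=(
            SimSegment("chr10", 87_952_000, 87_958_000, "+"),
            SimSegment("chr10", 87_960_000, 87_965_000, "-"),
            SimSegment("chr10", 87_965_000, 87_970_000, "+"),
        ),
        coverage=coverage,
        seed=seed,
    )


EXAMPLE_SPECS = {
    "stk11": stk11_spec,
    "nf1": nf1_spec,
    "smarca4": smarca4_spec,
    "rnf20": rnf20_spec,
    "pten": pten_spec,
}

# Gene bodies for the fixture loci (hg38-scale coordinates, 0-based
# half-open). Synthetic stand-ins adequate for locus assignment.
EXAMPLE_GENES = (
    ("STK11", "chr19", 1_205_798, 1_228_431, "+"),
    ("SMARCA4", "chr19", 10_960_623, 11_062_256, "+"),
    ("NF1", "chr17", 31_094_977, 31_377_677, "+"),
    ("RNF20", "chr9", 101_533_000, 101_565_000, "+"),
    ("PTEN", "chr10", 87_863_625, 87_971_930, "+"),
)


def write_example_gene_bed(path: str) -> None:
    """Write the fixture gene models as BED12 (one block per gene)."""
    with open(path, "w") as fh:
        for name, chrom, start, end, strand in EXAMPLE_GENES:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        chrom, start, end, name, 0, strand, start, end,
                        "0", 1, end - start, 0,
                    )
                )
                + "\n"
            )
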