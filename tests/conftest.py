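import os

import pytest

from clclkit import (
    SimSpec,
    SyntheticReference,
    Thresholds,
    build_allele,
    emit_truth_alignments,
    read_alignments,
    segments_by_read,
    simulate_reads,
)
from clclkit.alignio import AlignmentSegment
from clclkit.simulate import write_example_gene_bed


@pytest.fixture
def thresholds():
    return Thresholds()


def make_segment(
    read_id="r1",
    chrom="chr1",
    ref_start=1000,
    ref_end=2000,
    strand="+",
    read_start=0,
    read_end=1000,
    mapq=60,
    cigar=None,
):
    """Segment factory with a CIGAR consistent with the read interval."""
    if cigar is None:
        cigar = f"{read_end - read_start}M"
    return AlignmentSegment(
        read_id=read_id,
        chrom=chrom,
        ref_start=ref_start,
        ref_end=ref_end,
        strand=strand,
        read_start=read_start,
        read_end=read_end,
        mapq=mapq,
        cigar=cigar,
    )


class SimRun:
    """A simulation materialized to disk plus its parsed-back segments."""

    def __init__(self, spec: SimSpec, out_dir: str, thresholds: Thresholds):
        self.spec = spec
        self.reference = SyntheticReference(spec.reference, seed=spec.seed)
        self.allele = build_allele(self.reference, spec)
        self.reads = simulate_reads(self.allele, spec)
        self.sam = os.path.join(out_dir, "truth.sam")
        emit_truth_alignments(self.reads, self.allele, self.reference, self.sam, spec=spec)
        self.segments = read_alignments(self.sam, thresholds)
        self.by_read = segments_by_read(self.segments)
        self.read_seqs = {r.read_id: r.seq for r in self.reads}


@pytest.fixture
def sim_run_factory(tmp_path, thresholds):
    counter = [0]

    def factory(spec: SimSpec) -> SimRun:
        counter[0] += 1
        d = tmp_path / f"sim{counter[0]}"
        d.mkdir()
        return SimRun(spec, str(d), thresholds)

    return factory


def make_candidate(pos_a, pos_b, sv="DEL", read="r1", chrom="chr1",
                   orients=("tail", "head"), chrom_b=None, read_pos=(0, 0)):
    from clclkit import Breakpoint, JunctionCandidate

    return JunctionCandidate(
        read_id=read,
        bp_a=Breakpoint(chrom, pos_a, orients[0]),
        bp_b=Breakpoint(chrom_b or chrom, pos_b, orients[1]),
        sv_type=sv,
        read_gap=0,
        inserted_len=0,
        read_pos=read_pos,
    )


def make_call(pos_a, pos_b, sv="DEL", n_reads=5, chrom="chr1",
              orients=("tail", "head"), chrom_b=None):
    from clclkit import JunctionCall

    members = tuple(
        make_candidate(pos_a, pos_b, sv, f"r{i}", chrom, orients, chrom_b)
        for i in range(n_reads)
    )
    return JunctionCall(
        bp_a=members[0].bp_a, bp_b=members[0].bp_b, sv_type=sv, members=members
    )


@pytest.fixture
def gene_bed(tmp_path):
    path = tmp_path / "genes.bed"
    write_example_gene_bed(str(path))
    return str(path)
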