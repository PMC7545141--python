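"""Gene annotation, CLCL detection, reconstruction and fusion counting."""

import pytest

from clclkit import (
    GeneIndex,
    GeneModel,
    Thresholds,
    annotate_calls,
    classify_path,
    cluster_junctions,
    count_fusion_support,
    candidates_from_reads,
    detect_clcl,
    filter_calls,
    junction_inserted_sequence,
    load_gene_models,
    load_repeat_track,
    reconstruct_structure,
)
from clclkit.simulate import nf1_spec, pten_spec, rnf20_spec, stk11_spec

from conftest import make_call, make_candidate, make_segment

THREE_GENES = [
    ("chr1", 1000, 5000, "GENE_A"),
    ("chr1", 20_000, 30_000, "GENE_B"),
    ("chr2", 100, 900, "GENE_C"),
]


@pytest.fixture
def three_gene_bed(tmp_path):
    p = tmp_path / "three.bed"
    with open(p, "w") as fh:
        for chrom, start, end, name in THREE_GENES:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t+\n")
    return str(p)


class TestGeneModels:
    def test_point_queries_match_linear_scan(self, three_gene_bed):
        index = load_gene_models(three_gene_bed)
        positions = [0, 999, 1000, 3000, 4999, 5000, 19_999, 25_000, 31_000]
        for chrom in ("chr1", "chr2", "chr3"):
            for pos in positions:
                expected = sorted(
                    name
                    for c, s, e, name in THREE_GENES
                    if c == chrom and s <= pos < e
                )
                got = sorted(g.name for g in index.query(chrom, pos))
                assert got == expected, (chrom, pos)

    def test_empty_file_empty_index(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert len(load_gene_models(str(p))) == 0

    def test_gff3_and_bed12_agree(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1001\t5000\t.\t+\t.\tID=GENE_A;Name=GENE_A\n"
            "chr1\tsrc\texon\t1001\t1200\t.\t+\t.\tID=e1;Parent=GENE_A\n"
            "chr1\tsrc\texon\t4801\t5000\t.\t+\t.\tID=e2;Parent=GENE_A\n"
        )
        bed = tmp_path / "g.bed"
        bed.write_text(
            "chr1\t1000\t5000\tGENE_A\t0\t+\t1000\t5000\t0\t2\t200,200\t0,3800\n"
        )
        from_gff = list(load_gene_models(str(gff)))
        from_bed = list(load_gene_models(str(bed)))
        key = lambda g: (g.chrom, g.start, g.end, g.name, g.strand, g.exons)
        assert [key(g) for g in from_gff] == [key(g) for g in from_bed]

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t200\tok\t0\t+\nchr1\tnotanumber\t300\tbad\t0\t+\n")
        with pytest.raises(ValueError, match=":2"):
            load_gene_models(str(p))

    def test_exon_outside_gene_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("g", "g", "chr1", 100, 200, "+", exons=((50, 150),))


class TestAnnotateCalls:
    def test_breakpoint_inside_gene_labeled(self, gene_bed, thresholds):
        genes = load_gene_models(gene_bed)
        call = make_call(1_216_572, 1_228_569, sv="INV", chrom="chr19",
                         orients=("tail", "tail"))
        (ann,) = annotate_calls([call], genes, thresholds)
        assert "STK11" in ann.gene_names

    def test_intergenic_beyond_flank_unlabeled(self, gene_bed, thresholds):
        genes = load_gene_models(gene_bed)
        call = make_call(5_000_000, 5_010_000, chrom="chr19")
        (ann,) = annotate_calls([call], genes, thresholds)
        assert ann.gene_names == ()

    def test_five_kb_past_gene_end_with_ten_kb_flank(self, thresholds):
        genes = GeneIndex([GeneModel("G", "G", "chr1", 10_000, 50_000, "+")])
        call = make_call(55_000, 58_000)  # 5 kb past the gene end
        (ann,) = annotate_calls([call], genes, thresholds)
        assert ann.gene_names == ("G",)

    def test_absent_chromosome_gives_empty_label(self, thresholds):
        genes = GeneIndex([GeneModel("G", "G", "chr1", 10_000, 50_000, "+")])
        call = make_call(10_000, 20_000, chrom="chrUn", chrom_b="chrUn")
        (ann,) = annotate_calls([call], genes, thresholds)
        assert ann.gene_names == ()

    def test_repeat_context_classes(self, tmp_path, thresholds):
        genes = GeneIndex([GeneModel("G", "G", "chr1", 0, 100_000, "+")])
        track = tmp_path / "rpt.bed"
        track.write_text("chr1\t9000\t11000\tLINE\nchr1\t19000\t21000\tSINE\n")
        repeats = load_repeat_track(str(track))
        call = make_call(10_000, 20_000)
        (ann,) = annotate_calls([call], genes, thresholds, repeats=repeats)
        assert (ann.context_a, ann.context_b) == ("LINE", "SINE")
        (bare,) = annotate_calls([call], genes, thresholds)
        assert bare.context_a == "unannotated"


class TestDetectClcl:
    def test_two_inversion_calls_one_clcl(self, gene_bed, thresholds):
        genes = load_gene_models(gene_bed)
        calls = [
            make_call(1_216_572, 1_228_569, sv="INV", chrom="chr19",
                      orients=("tail", "tail")),
            make_call(1_216_359, 1_219_537, sv="INV", chrom="chr19",
                      orients=("head", "head")),
        ]
        clcls = detect_clcl(annotate_calls(calls, genes, thresholds), thresholds)
        assert len(clcls) == 1
        assert clcls[0].gene_names == ("STK11",)
        assert clcls[0].n_breakpoints == 4

    def test_single_duplication_adjacency_qualifies(self, gene_bed, thresholds):
        # one tandem-duplication adjacency contributes two breakpoint
        # positions, enough for a CLCL
        genes = load_gene_models(gene_bed)
        calls = [make_call(31_200_947, 31_278_880, sv="DUP", chrom="chr17",
                           orients=("head", "tail"))]
        clcls = detect_clcl(annotate_calls(calls, genes, thresholds), thresholds)
        assert len(clcls) == 1 and clcls[0].gene_names == ("NF1",)
        assert clcls[0].n_breakpoints == 2

    def test_single_breakpoint_in_locus_no_clcl(self, thresholds):
        genes = GeneIndex([GeneModel("G", "G", "chr1", 100_000, 150_000, "+")])
        # one DEL breakpoint inside the gene, partner 2 Mb away
        calls = [make_call(120_000, 2_120_000)]
        clcls = detect_clcl(annotate_calls(calls, genes, thresholds), thresholds)
        assert clcls == []

    def test_output_invariant_to_call_order(self, gene_bed, thresholds):
        genes = load_gene_models(gene_bed)
        calls = [
            make_call(1_216_572, 1_228_569, sv="INV", chrom="chr19",
                      orients=("tail", "tail")),
            make_call(1_216_359, 1_219_537, sv="INV", chrom="chr19",
                      orients=("head", "head")),
            make_call(31_200_947, 31_278_880, sv="DUP", chrom="chr17",
                      orients=("head", "tail")),
        ]
        ref = detect_clcl(annotate_calls(calls, genes, thresholds), thresholds)
        rev = detect_clcl(annotate_calls(calls[::-1], genes, thresholds), thresholds)
        key = lambda cs: [(c.gene_names, c.n_breakpoints, c.breakpoints) for c in cs]
        assert key(ref) == key(rev)


def _pipeline(run, thresholds, gene_bed):
    calls = filter_calls(
        cluster_junctions(candidates_from_reads(run.by_read, thresholds), thresholds),
        thresholds,
    )
    genes = load_gene_models(gene_bed)
    return detect_clcl(annotate_calls(calls, genes, thresholds), thresholds)


class TestReconstruction:
    def test_stk11_path_follows_printed_breakpoints(
        self, sim_run_factory, gene_bed, thresholds
    ):
        run = sim_run_factory(stk11_spec(seed=3))
        (clcl,) = _pipeline(run, thresholds, gene_bed)
        path = reconstruct_structure(clcl, run.by_read, thresholds)
        assert path.label == "combination of local inversions"
        assert not path.ambiguous
        # forward segment ending at II, inverted IV->I segment, resume at III
        assert [o for _, _, _, o in path.segments] in (["+", "-", "+"], ["-", "+", "-"])
        mid = path.segments[1]
        assert {path.segments[0][2], mid[1], mid[2], path.segments[2][1]} >= {
            1_216_572, 1_216_359, 1_228_569, 1_219_537
        }
        assert clcl.n_full_cover >= 1
        assert path.insertions[1] == 5  # non-templated bases at junction I/III

    def test_nf1_path_doubles_the_duplicated_unit(
        self, sim_run_factory, gene_bed, thresholds
    ):
        run = sim_run_factory(nf1_spec(seed=3))
        (clcl,) = _pipeline(run, thresholds, gene_bed)
        path = reconstruct_structure(clcl, run.by_read, thresholds)
        assert path.label == "tandem duplication"
        assert len(path.segments) == 2
        # the two path segments overlap on the duplicated unit boundaries
        (c1, s1, e1, o1), (c2, s2, e2, o2) = sorted(path.segments)[:2]
        junction_coords = {e1, s2} if o1 == "+" else {s1, e2}
        assert junction_coords <= {31_278_880, 31_200_947}

    def test_wild_type_reads_give_reference_path(self, thresholds):
        from clclkit.clcl import CLCLCall, AnnotatedCall

        gene = GeneModel("G", "G", "chr1", 10_000, 50_000, "+")
        call = make_call(20_000, 30_000, sv="INV", orients=("tail", "tail"))
        ann = AnnotatedCall(call, (gene,), (gene,))
        clcl = CLCLCall(
            genes=(gene,), calls=(ann,), n_breakpoints=2,
            read_ids=frozenset({"w1"}),
        )
        # the only read is a plain reference alignment
        by_read = {"w1": [make_segment("w1", "chr1", 15_000, 45_000, "+", 0, 30_000)]}
        path = reconstruct_structure(clcl, by_read, thresholds)
        assert path.label == "wild type"
        assert path.segments == (("chr1", 15_000, 45_000, "+"),)

    def test_path_length_matches_allele_for_full_cover_read(
        self, sim_run_factory, gene_bed, thresholds
    ):
        from clclkit.simulate import SimRead, SyntheticReference, build_allele
        from clclkit import emit_truth_alignments, read_alignments, segments_by_read

        spec = pten_spec(seed=5)
        ref = SyntheticReference(spec.reference, seed=spec.seed)
        allele = build_allele(ref, spec)
        # reads spanning the entire allele, so terminal ends are exact
        reads = [
            SimRead(f"full{i}", allele.seq, 0, len(allele.seq), "+")
            for i in range(6)
        ]
        import os, tempfile

        d = tempfile.mkdtemp()
        sam = os.path.join(d, "full.sam")
        emit_truth_alignments(reads, allele, ref, sam, spec=spec)
        by_read = segments_by_read(read_alignments(sam, thresholds))

        class Run:
            pass

        run = Run()
        run.by_read = by_read
        (clcl,) = _pipeline(run, thresholds, gene_bed)
        path = reconstruct_structure(clcl, by_read, thresholds)
        assert path.length == len(allele.seq)
        assert path.label == "inversion + deletion"

    def test_classify_path_orientation_invariance(self):
        fwd = (("chr1", 0, 100, "+"), ("chr1", 50, 200, "-"), ("chr1", 150, 300, "+"))
        rev = tuple(
            (c, s, e, {"+": "-", "-": "+"}[o]) for c, s, e, o in reversed(fwd)
        )
        assert classify_path(fwd) == classify_path(rev)


class TestInsertedSequence:
    def test_blunt_junction_empty_insertion(self):
        call = make_call(10_000, 20_000)
        seqs = {f"r{i}": "A" * 200 for i in range(5)}
        assert junction_inserted_sequence(call, seqs) == ("", 0)

    def test_shared_five_mer_consensus(self, sim_run_factory, gene_bed, thresholds):
        run = sim_run_factory(stk11_spec(seed=3))
        calls = filter_calls(
            cluster_junctions(
                candidates_from_reads(run.by_read, thresholds), thresholds
            ),
            thresholds,
        )
        target = next(c for c in calls if c.bp_a.pos1 == 1_216_360)
        assert junction_inserted_sequence(target, run.read_seqs) == ("GATTC", 5)

    def test_plurality_length_wins(self):
        from clclkit import JunctionCall

        members = tuple(
            make_candidate(10_000, 20_000, read=f"r{i}", read_pos=(100, 105))
            for i in range(9)
        ) + (make_candidate(10_000, 20_000, read="r9", read_pos=(100, 104)),)
        call = JunctionCall(members[0].bp_a, members[0].bp_b, "DEL", members)
        seqs = {f"r{i}": "A" * 100 + "GATTC" + "A" * 100 for i in range(10)}
        seq, length = junction_inserted_sequence(call, seqs)
        assert length == 5 and seq == "GATTC"

    def test_no_sequences_returns_none(self):
        call = make_call(10_000, 20_000)
        assert junction_inserted_sequence(call, {}) is None


class TestFusionSupport:
    def _spanning_segments(self, n, mapq_b=60):
        segs = []
        for i in range(n):
            segs.append(make_segment(f"f{i}", "chr10", 43_100_000, 43_120_000,
                                     "+", 0, 20_000))
            segs.append(make_segment(f"f{i}", "chr10", 61_000_000, 61_020_000,
                                     "+", 20_000, 40_000, mapq=mapq_b))
        return segs

    def test_simulated_spanning_reads_all_counted(self, thresholds):
        segs = self._spanning_segments(12)
        n = count_fusion_support(
            segs, ("chr10", 43_000_000, 43_200_000),
            ("chr10", 60_900_000, 61_100_000), thresholds,
        )
        assert n == 12

    def test_no_read_in_second_locus(self, thresholds):
        segs = [make_segment("f0", "chr10", 43_100_000, 43_120_000, "+", 0, 20_000)]
        n = count_fusion_support(
            segs, ("chr10", 43_000_000, 43_200_000),
            ("chr10", 60_900_000, 61_100_000), thresholds,
        )
        assert n == 0

    def test_low_mapq_segment_not_counted(self, thresholds):
        segs = self._spanning_segments(3, mapq_b=29)
        n = count_fusion_support(
            segs, ("chr10", 43_000_000, 43_200_000),
            ("chr10", 60_900_000, 61_100_000), thresholds,
        )
        assert n == 0

    def test_overlapping_loci_hard_error(self, thresholds):
        with pytest.raises(ValueError):
            count_fusion_support(
                [], ("chr10", 100, 300), ("chr10", 200, 400), thresholds
            )
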