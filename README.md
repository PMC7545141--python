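# clclkit

Detection and reconstruction of **complex local copy-number lesions
(CLCLs)** — medium-scale structural aberrations combining local tandem
duplications, inversions, micro-deletions and junction micro-insertions
within one gene locus — from the split alignments of long sequencing reads
(nanopore or similar). The package also ships a rearranged-allele read
simulator that emits ground-truth split alignments, so every stage of the
caller is testable with no aligner and no external data.

It is aimed at cancer-genomics analysts working with tumor (and optionally
matched-normal) long-read whole-genome alignments who want junction-level
calls, somatic filtering against a control panel, and a per-locus
reconstruction of the rearranged allele.

## Method

A long read crossing a rearrangement is reported by the aligner as a chain
of split alignments: a primary record plus supplementary records (flag
2048), each covering a different read interval. After removing secondary
records (flag 256) and records with MAPQ < 30, segments of each read are
ordered by read position. Each adjacent pair whose read-coordinate gap is
at most 300 bp implies a novel adjacency between two oriented breakpoints,
classified by strand and reference order:

| configuration | type |
|---|---|
| different chromosomes | TRA |
| strand flip | INV |
| same strand, downstream continuation | DEL |
| same strand, upstream re-entry | DUP (tandem) |

Deletions embedded in single alignments as CIGAR `D` operations > 2 kb are
pooled with the split-read evidence. Candidates are clustered by single
linkage (both breakpoints < 50 bp apart; cluster representative = member
median), and calls are kept when supported by ≥ 5 distinct reads and, for
intra-chromosomal types, spanning ≥ 2 kb. Matched-normal candidates
(unfiltered) subtract germline calls; redundant calls across samples
collapse within a 100-bp margin.

Breakpoints are then annotated against gene models (gene body ± 10 kb); a
CLCL is emitted when a locus accumulates ≥ 2 breakpoint positions
(positions, not adjacencies — a single tandem-duplication junction
contributes two). The local allele is reconstructed per supporting read as
an ordered, oriented segment path; the consensus path is the junction
signature covering the most member junctions, and its structure is
labelled from strandedness and reference coverage ("tandem duplication",
"inversion + deletion", "combination of local inversions", ...). The
non-templated inserted sequence at any junction is recovered as a
plurality-length, per-position-majority consensus of the supporting reads'
unaligned bases.

## Worked example

Simulate the STK11 lesion preset — a combination of local inversions with
four breakpoints on chromosome 19 and a 5-bp insertion at one junction —
then call it:

```sh
$ printf 'preset: stk11\nseed: 7\n' > stk11.yaml
$ clclkit simulate stk11.yaml --out-dir sim
$ python -c 'from clclkit.simulate import write_example_gene_bed; write_example_gene_bed("genes.bed")'
$ clclkit call sim/sim_truth.sam --genes genes.bed --out-dir out
2 junction calls, 1 CLCLs
  bedpe: out/junctions.bedpe
  vcf: out/junctions.vcf
  clcl_report: out/clcl_report.tsv
  clcl_bedpe: out/clcl_junctions.bedpe
```

The CLCL report (`out/clcl_report.tsv`):

```
#locus	genes	n_breakpoints	label	path	support	full_cover_reads
chr19:1216359-1228569	STK11	4	combination of local inversions	chr19:1211693-1216572/+,chr19:1216359-1228569/-,chr19:1219537-1225617/+	38	7
```

Reading the row: the STK11 locus carries four breakpoints; the
reconstructed allele runs forward to 1,216,572, continues through the
downstream segment in inverted orientation back from 1,228,569 to
1,216,360, and resumes forward at 1,219,538 — 38 distinct reads support
the member junctions and 7 single reads traverse the entire structure.
The two junction calls land in `out/junctions.bedpe` with their supports
(29 and 16 reads here); every output header records the thresholds used.

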