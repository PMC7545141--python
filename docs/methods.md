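# Methods

## Problem and model

Medium-scale complex rearrangements — local tandem duplications,
inversions and micro-deletions stacked within a single gene locus — are
hard to resolve from short reads because individual junctions fall in
repeats and the event extent (kilobases to tens of kilobases) exceeds the
insert size. A single long read, however, can traverse several junctions,
so the chain of split alignments of one read is direct evidence for the
local allele structure. clclkit models a rearranged locus as a *segment
path*: an ordered list of oriented reference segments, optionally
separated by short non-templated insertions. Every consecutive pair of
aligned segments on a read implies one novel adjacency between two
oriented breakpoints, and the caller works junction-first: type and
cluster adjacencies, then group them into gene loci and reconstruct the
path.

## Coordinates and breakpoint conventions

All internal coordinates are 0-based half-open. A breakpoint is an
inter-base break coordinate plus an orientation: `tail` when the aligned
segment lies at lower coordinates (the break follows its last base),
`head` when it lies at higher coordinates. Reported positions follow the
field convention of printing the flanking aligned base 1-based: a `tail`
breakpoint prints as its break coordinate (the 1-based last aligned base),
a `head` breakpoint as break coordinate + 1 (the 1-based first aligned
base). Emitted files use each format's native convention (BEDPE 0-based
half-open, VCF 1-based with `END` = last affected base).

Read coordinates of minus-strand records are flipped into the original
read orientation using the full read length implied by the CIGAR (clips
included), so segments of one read are comparable regardless of the strand
each block aligned to; the flip is an involution and is covered by tests.

## Filters and tunable parameters

All constants live in one `Thresholds` object and are printed into every
output header:

| parameter | default | unit | role |
|---|---|---|---|
| `min_mapq` | 30 | — | drop records below this mapping quality |
| `max_read_gap` | 300 | bp | max |read gap| between adjacent segments for a junction |
| `merge_dist` | 50 | bp | single-linkage clustering radius (strict `<`) |
| `min_support` | 5 | reads | distinct supporting reads per call |
| `min_span` | 2000 | bp | min intra-chromosomal breakpoint span (TRA exempt) |
| `sample_margin` | 100 | bp | cross-sample redundancy margin (inclusive `<=`) |
| `proximal_flank` | 10000 | bp | gene-body flank for locus assignment |

Record-level filtering (secondary/unmapped/MAPQ) precedes junction
extraction. Small negative read gaps (segment overlap on the read, common
at microhomologies) are allowed up to `max_read_gap` in absolute value.
CIGAR `D` operations strictly longer than `min_span` become DEL candidates
and are pooled with split-read DELs before clustering; note the boundary
differs by one case from the span filter, which keeps spans equal to
`min_span`.

Cluster representatives are the member median (lower middle for even
sizes), which is robust to ragged alignment ends; ties in all orderings
break toward lower coordinates so results are independent of input order.
Reads with three or more segments contribute one candidate per adjacent
pair only — non-adjacent pairs would double-count the intervening
junctions.

The span rule is applied to each call's own breakpoint span, including
for inversion junctions (the alternative — measuring the full event
extent — would couple the filter to locus grouping, which happens later).

## Locus grouping and reconstruction

"Proximal" genes are the gene body ± `proximal_flank`, plus genes
connected by a shared junction call (a breakpoint just downstream of a
gene's last exon still counts toward that gene's locus). Breakpoints are
counted as distinct positions, not adjacencies, so a single
tandem-duplication junction (two breakpoints) qualifies as a CLCL.

Reconstruction builds each supporting read's path of oriented segments
restricted to the locus window, snaps coordinates to call representatives
(within `merge_dist`), and normalizes path orientation (a path and its
reverse-complement are the same structure). Per-read paths are compared by
a *junction signature* that masks the outward coordinate of the two
terminal segments, so ragged read ends do not fragment the consensus. The
consensus is the signature covering the most member junctions, preferring
the most frequent and then the longest single read; reads traversing every
member junction are counted separately (`full_cover_reads`). No published
algorithmic consensus rule exists for this step (it has typically involved
manual curation); this rule is the package's own design and is flagged as
such.

Structure labels derive from strandedness and reference coverage of the
consensus path: mixed orientations mean inversion; reference self-overlap
— or a member DUP call, since a read shorter than the duplicated unit
never overlaps itself — means duplication; an uncovered region between the
outermost coordinates (after stretching terminal segments to the known
breakpoint extent) means deletion. The combinations map to "tandem
duplication", "deletion", "inversion", "inversion + deletion",
"combination of local inversions", otherwise "complex rearrangement".

Junction inserted sequences are extracted per read from the unaligned
bases between the two segments, reverse-complemented to a canonical
junction orientation when the read traverses the junction backwards; the
plurality gap length wins and the per-position majority base forms the
consensus.

## Simulator

The generator emulates exactly the input contract the caller consumes:
error-free (by default) long reads sampled from a constructed allele, with
split alignments emitted directly as ground truth (one primary plus one
supplementary record per additional junction, soft clips encoding read
offsets, insertions left unaligned, MAPQ 60 unless perturbed for filter
tests). References are seeded uniform-random sequences occupying an
arbitrary coordinate window of a named chromosome, so fixtures use
genome-scale positions without shipping a genome.

Read lengths are log-normal with `mu = ln(read_n50) - sigma^2`,
`sigma = 0.6`, giving a base-weighted median (N50) of 25 kb by default —
representative of a recent nanopore run (N50 20–30 kb). Reads are drawn
until the base budget (`coverage x allele length`) is met, so realized
coverage is within one read of the target; starts are uniform, strands
equiprobable, and truncation at the allele end thins coverage near the
edges, as at any real contig boundary. Worked-example fixtures use 20–25x
coverage, which yields ~50–190 reads per locus and runs in well under a
second each; these sizes are the package's study conditions throughout the
tests and the acceptance script.

What the simulator does **not** emulate: nanopore error profiles (only
uniform substitutions are available, default 0), chimeric artifacts,
mapping ambiguity in repeats, MAPQ degradation, or reference bias. Passing
tests therefore demonstrate the correctness of the calling logic given
faithful split alignments — not robustness to aligner noise on real data,
where recall depends on the aligner and repeat content of the locus.

The truth table of adjacencies is typed by code independent of the
caller's classifier, so caller-vs-truth tests are a genuine dual route.
The tumor-fraction mixer draws each output read from the tumor pool with
the given probability, without replacement, stopping early if a pool is
exhausted rather than substituting (which would distort the realized
fraction).

## Numerical and degenerate-input choices

* Clustering strictness: candidates merge only when both breakpoints are
  strictly closer than `merge_dist` (49 bp merges, 50 bp does not);
  cross-sample margins are inclusive.
* Adjacent segments continuing contiguously on the reference classify as
  DEL with span 0 and are removed by the span filter.
* An empty alignment file yields an empty call set; a CIGAR-less mapped
  record is demoted to unmapped by htslib at parse time and is dropped
  with a logged count (a retained in-memory record without a CIGAR is a
  hard error).
* When no supporting read covers two junctions of a multi-junction CLCL,
  the best partial path is returned flagged `ambiguous`; when no read
  covers any junction, the longest plain reference alignment is returned
  labelled "wild type".
* Derived RNG streams use small integer arithmetic on the user seed
  (children stay below 2^31), so all outputs are byte-reproducible.

## Known limitations

* No insertion (INS) calling: the target lesion classes are DEL/DUP/INV/
  TRA; long-read insertion calling is a separate problem.
* No genotyping, VAF estimation, or breakend micro-assembly.
* Locus grouping requires gene models; without them the pipeline stops at
  junction calls.
* The VCF output is a minimal 4.2 dialect (SVTYPE/END/SVLEN/CHR2/MATEID);
  BEDPE is authoritative, and reconstructed paths appear only in the
  report.
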