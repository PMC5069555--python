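# Methods

`uridylome` implements the computational analysis of a DIS3L2 CLIP-seq
"uridylome": identifying protein-bound RNA fragments that carry
post-transcriptionally added 3' oligo(U) tails, assigning them to functional
RNA classes, detecting intramolecular-ligation hybrid reads, and summarising
where on their source RNAs the uridylated 3' ends sit. This note documents
the model behind each stage, the parameters that matter, the numerical
conventions, and what the synthetic data used for validation does and does
not establish.

## The tail-calling model

A read with a non-templated 3' extension either fails to align end-to-end or
aligns with an unaligned 3' remainder. The pipeline handles both routes:

1. **Pass 1** aligns raw reads with a 5'-anchored, gapless seed-and-extend
   aligner (k-mer seed index over both strands, k = 12). A placement's span
   is chosen difference-ranked: among spans satisfying the mismatch
   allowance (one mismatch per 25 aligned nt) and the minimum span (18 nt),
   the fewest-mismatch span wins, ties going to the longest. This makes the
   chosen span the maximal exact-match prefix for error-free reads, so
   alignments never "creep" into a tail by paying mismatches to reach
   matching bases further 3'. A placement whose best span leaves a 3'
   remainder longer than 40% of the read fails soft mapping outright rather
   than distorting the span.
2. **Pass 2** takes pass-1 failures, removes the 3'-terminal T run if it is
   at least `trim_min_run` = 4 nt long ("more than three" Ts), and remaps.
   Reads trimmed to nothing are flagged *all-tail*; every read lands in
   exactly one of {pass-1 mapped, pass-2 mapped, unmapped, all-tail}.
3. **Uniqueness**: a placement is unique when its score (span − 4·mismatches)
   beats the second-best placement by at least 2. Multi-mapping reads are
   excluded from tail calling (and are not trimmed/remapped; they are counted
   inside "unmapped" with a separate `multimapped` tally in the manifest).
4. **Tail calling** reconstructs the raw 3' remainder (unaligned suffix plus
   any trimmed Ts) and extends it base-by-base along the genome past the
   alignment end, strand-aware in transcript orientation. The maximal
   matching prefix is *templated*; the residue is the *untemplated* tail,
   whose anchor is the last templated base.

**Maximal-templated convention.** A tail base that coincides with the next
genomic base is inherently ambiguous (an untemplated U next to an encoded U
cannot be distinguished from transcription read-through). The pipeline
resolves the ambiguity conservatively by always assigning such bases to the
genome, undercounting tails that abut genomic T runs. The convention is
stated in every tail-call TSV header, and all ground-truth comparisons in
the test suite apply the same convention to the truth tails.

**Composition classes.** The untemplated tail is classified as `U+` when its
3'-terminal T run is ≥ `min_u` = 4 nt (earlier bases may differ: `ATTTT` is
U+, `TTTTA` is not); shorter homopolymers are labelled by their base (`U`,
`A`, `C`, `G`), heterogeneous tails `mixed`, and empty tails `none`. The
`U` label for sub-threshold uridine runs keeps the class set total. The
threshold is configurable because the boundary between "at least four" and
"longer than four" uridines is not sharp in practice; 4 is the default.

**Strict pass-1 mode.** For studying the two-pass rescue itself, pass 1 can
be run end-to-end exact (`pass1_mode: strict`). With a per-window mismatch
allowance an end-to-end aligner would absorb short tails as mismatches and
bypass pass 2 entirely; exact matching is the coherent strict semantics for
error-free reads, and it guarantees that every read with ≥ 4 untemplated
terminal Ts at a unique locus is recovered in pass 2. The default remains
`soft` (3' remainder permitted), which is how a production aligner would be
run.

**External alignments.** SAM/BAM from another aligner can replace the
built-in one: 3' soft-clips become remainders (strand-aware), secondary and
supplementary records are dropped, and uniqueness is MAPQ ≥ 20. The `XT`
tag carries trimmed-T counts through the pipeline's own SAM writer so the
native and imported paths produce identical calls.

## Annotation

Reads are assigned to one functional category by a fixed priority order —
tRNA > miRNA > snRNA > 5S rRNA > miscRNA > snoRNA > mRNA > lincRNA — so a
read overlapping both an intronic snoRNA and its host mRNA annotates to the
snoRNA. Assignment is same-strand only, requires ≥ 1 nt overlap (a
configurable minimum), and breaks within-category ties by the largest
overlap, then the lexicographically smallest gene id. tRNA genes are indexed
with 60 nt extensions on both sides so pre-tRNA leader and trailer fragments
annotate to their tRNA; mature bounds are retained for positional analysis.
Pseudogene records are carried verbatim and rank below the eight listed
categories.

Anchors are then positioned within the gene: the signed offset from the
mature 3' end (0 = the last mature base) drives both the
5' leader / mature / 3' extension region and the snRNA-style end state (Mat
at 0, Trim below, ext above; `+U` tallies U+ calls per gene). mRNA anchors
are sub-classified into 5'UTR/CDS/3'UTR/intron, so 5'-proximal fragments
running from exon 1 into intron 1 — the unspliced-precursor signature —
are visible directly. tRNA positions are mapped onto a canonical cloverleaf
partition of the mature length (acceptor stem 0–10%, D-arm 10–33%,
anticodon arm 33–60%, T-loop 60–87%, 3' acceptor-stem side 87–100%), a
stand-in for structure-derived arm boundaries; positions outside the mature
bounds are the 5'/3' trailers.

## Hybrid (chimeric) reads

Intramolecular ligation during the CLIP protocol joins two RNase T1
fragments of one folded molecule; because the enzyme cuts 3' of guanosine,
both ligated ends derive from positions immediately after a G. Detection is
an exhaustive split search on reads that are not contiguously explainable:
the 3' T tail is trimmed first, every split point is tried with the 5' half
aligned end-to-end exactly and the 3' half 5'-anchored (tail remainder
allowed), and candidates survive when both halves map uniquely on one
strand with a skipped gap in [4 nt, 10 kb]. Model selection requires the
split to beat the best contiguous alignment's score by at least half an arm
(6 nt): a genuine downstream arm contributes ≥ `min_arm` = 12 newly aligned
bases, whereas a spurious split of a contiguous read only re-houses its few
unaligned tail bases. Arms in different annotated loci are reported as
inter-locus and excluded from the hybrid table.

**Junction normalisation.** When the bases flanking a split match the
genome on both continuations — typically inside G runs at cut sites —
neighbouring splits produce byte-identical reads and the true junction is
unidentifiable from sequence. As with indel normalisation in variant
calling, the caller reports a canonical representative: highest total
score, then an arm1 ending in G, then a G immediately 5' of arm2, then
smallest gap, leftmost arm1, largest split. `canonical_junction_shift`
exposes the same normalisation so ground-truth junctions can be compared in
canonical form. The arm1-ends-in-G property itself is recorded as a
consistency *flag*, never used as a filter.

The remainder after the downstream arm goes through the ordinary tail
caller, so uridylated hybrids carry a regular `U+` call anchored at the
arm-2 end.

## Positional summaries

* **Tail histograms** count untemplated lengths per composition class (and
  optionally per category); medians and quartiles are computed on
  untemplated lengths only.
* **U+ fraction per category** reports percentage and denominator per
  functional class; empty categories are dropped with a logged note.
* **Scaled coverage** maps each covered mature base to one of 100 bins
  (bin 100 abuts the mature 3' end on either strand) and row-normalises to
  a maximum of 1; an anchor-density mode counts 3' anchors instead of
  covered bases.
* **TSS metagenes** count each U+ read once at its 3' anchor, at the signed
  offset from the nearest TSS (downstream along the TSS strand positive,
  upstream negative). Reads on the TSS strand form the sense profile,
  opposite-strand reads the antisense profile — an antisense 3' end
  upstream of the TSS therefore appears at a negative offset, and the
  antisense peak of promoter-proximal short RNAs is reported as −200 under
  this convention. Profiles are smoothed with a 5-nt moving average before
  peak localisation; the window (±500 nt) and smoothing width are
  configurable because published metagenes rarely state them. An external
  bedGraph (e.g. polymerase occupancy) can be averaged over the same
  offsets for a side-by-side overlay; no cross-track statistics are
  computed.

## The synthetic-data generator

The simulator emulates exactly the structure the analysis assumes, with
ground truth for every read (source locus, fragment coordinates, the exact
appended tail, chimera arm intervals):

* **Reference**: one contig with genes of all eight categories (plus
  optional pseudogenes) separated by 300-nt spacers, GC 0.5, seeded; mRNAs
  have a two-exon/one-intron structure with a CDS so UTR/intron assignment
  is exercised; options add snoRNAs nested in mRNA introns (annotation
  overlap), duplicated loci (multi-mappers) and minus-strand genes.
* **Fragmentation**: partial RNase T1 digestion — each G is cut 3' with
  probability 0.5 (digestion extent in a real experiment is unknown and
  pooled across enzyme concentrations; the value is configurable, not
  fitted). Gel selection keeps fragments of 25–90 nt, so reads stay within
  a 20–110 nt envelope after tailing and remain alignable (≥ 18 nt) after
  T-trimming. When a digest yields no gel-sized fragment, a window ending
  at the transcript 3' end is taken instead.
* **Tailing**: a read receives an oligo(U) tail with probability 0.35
  (lengths Poisson(7) truncated to 4–20, preserving the observed ~7-nt
  median), a 1–3-nt A, C or G run with probability 0.05 each, or nothing
  (0.5). The truth table records the tail exactly as appended, independent
  of coincidences with downstream genomic bases; the evaluation applies the
  maximal-templated convention to the truth at scoring time. A
  `templated_junction_bias` option deliberately enriches ambiguous
  junctions; it defaults to 0 because ~25% of junctions are ambiguous by
  chance already.
* **Chimeras**: a configurable fraction of reads (allocated exactly, e.g.
  10% of 100 reads is 10 reads) joins two non-overlapping fragments of one
  gene, the upstream arm ending at a G cut and the downstream arm starting
  immediately 3' of a G — both boundaries are RNase T1 products.
* **Determinism**: one seed drives everything; identical inputs give
  byte-identical FASTQ, truth TSV, FASTA and GFF3.

**What passing on synthetic data does not show.** The simulator omits
sequencing errors, PCR duplication, crosslink-induced mutations, adapter
read-through, expression-weighted locus sampling and repeat-induced
multi-mapping beyond literal duplications. Recovery rates measured here are
therefore upper bounds for real libraries; the external-alignment import
path exists precisely so real data can be mapped with a production aligner.

## Validation scale and numerical choices

The test suite and the reproduction script measure, per run: U+ precision
and recall and exact untemplated-length agreement on 10,000 simulated
unique-locus reads; exact read-count partition and 100% pass-2 rescue under
strict pass 1 (2,000 reads); equality with a brute-force
all-positions/both-strands aligner and tail caller on 200 reads against a
≤ 10 kb reference; junction recovery on 500 simulated chimeras and absence
of chimera calls on 10,000 contiguous reads; the 28 ordered priority pairs;
TSS peak recovery at +50/−200 over 100 seeded replicates (20,000 anchors
per orientation per replicate, sized so the mode estimator's sampling
jitter stays within the ±2 nt check); and byte-identical reruns. Problem
sizes are the package's validation defaults and complete in a few minutes
on one CPU.

Coordinates are 0-based half-open internally, 1-based inclusive only at
GFF3 and report boundaries; junctions are reported 1-based in transcript
coordinates of the assigned locus. FASTQ qualities are emitted as constant
'I' and ignored throughout. Ties anywhere (category assignment, span
choice, split choice) are broken deterministically as documented above, so
a config plus a seed fully determines every output byte.

## Known limitations

* Tails abutting genomic T runs are undercounted by construction
  (conservative convention); anchors can shift 3' by the length of the
  templated overlap.
* The built-in aligner is gapless and desk-scale (k-mer dictionary over
  both strands); indel-containing tails and genome-scale mapping are out of
  scope — import external alignments instead.
* Only single-split (two-arm) intramolecular hybrids are modelled; higher-
  order ligations and inter-molecular hybrids are not called.
* Junctions inside G runs are reported in canonical form, not resolved —
  no method can resolve them from sequence alone.
* The tRNA cloverleaf partition is proportional, not structure-derived; the
  outputs flag it as such.
* 5S rRNA/pseudogene multi-copy ambiguity is not re-resolved; category
  labels are taken from the annotation verbatim.
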