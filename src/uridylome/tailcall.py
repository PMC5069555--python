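"""Two-pass mapping and non-templated 3' tail calling.

The analysis rests on one observation: reads carrying post-transcriptionally
added 3' oligo(U) stretches either fail to map end-to-end or map with an
unaligned 3' remainder. The pipeline therefore (pass 1) maps raw reads with a
5'-anchored, gapless seed-and-extend aligner that tolerates a 3' remainder;
(pass 2) trims 3'-terminal runs of four or more Ts from pass-1 failures and
remaps; and finally reconstructs each mapped read's raw 3' remainder and
splits it into a templated part (the maximal prefix matching the genome
immediately downstream of the alignment, strand-aware) and an untemplated
tail. Only uniquely mapping reads are analysed.

The templated/untemplated split is deliberately conservative (maximal
templated extension): genomic Ts immediately downstream of an anchor absorb
tail Ts, so tails abutting templated T runs are undercounted rather than
overcounted. Every TSV written by :func:`write_tail_calls` records this
convention and the thresholds in its header.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import encode, revcomp
from .config import TailcallConfig

#: score = span - MISMATCH_PENALTY * mismatches; the penalty is high enough
#: that extending through a mismatch never pays unless several matching
#: bases follow, so alignments do not creep into non-templated tails
MISMATCH_PENALTY = 4

CATEGORY_PASS1 = "pass1"
CATEGORY_PASS2 = "pass2"
CATEGORY_UNMAPPED = "unmapped"
CATEGORY_ALL_TAIL = "all-tail"


@dataclass
class AlignmentRecord:
    """A read placed on the reference, 5'-anchored, gapless.

    ``start``/``end`` are genomic, 0-based half-open. ``span`` is the number
    of read bases aligned (a prefix of the possibly-trimmed read);
    ``remainder`` is the unaligned 3' suffix. ``trimmed_t_count`` is the
    number of Ts removed before pass 2 (0 for pass 1).
    """

    read_id: str
    contig: str
    start: int
    end: int
    strand: str
    span: int
    remainder: str
    mapping_pass: int
    trimmed_t_count: int
    unique: bool
    score: int
    n_mismatch: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("alignment end must exceed start")
        if self.mapping_pass not in (1, 2):
            raise ValueError("mapping pass must be 1 or 2")
        if self.mapping_pass == 1 and self.trimmed_t_count != 0:
            raise ValueError("pass-1 alignments cannot carry trimmed Ts")


@dataclass
class TailCall:
    """The called non-templated 3' extension of one uniquely mapped read."""

    read_id: str
    contig: str
    anchor: int  # genomic position of the last templated base, 0-based
    strand: str
    tail_seq: str  # raw 3' remainder, read orientation (DNA)
    templated_overlap: int
    untemplated_seq: str
    comp_class: str
    tail_source: str  # remainder | trimmed-Ts | both | none
    gene_id: str | None = None
    category: str | None = None

    @property
    def untemplated_length(self) -> int:
        return len(self.untemplated_seq)

    @property
    def uplus(self) -> bool:
        return self.comp_class == "U+"

    def base_counts(self) -> dict[str, int]:
        return {b: self.untemplated_seq.count(b) for b in "TACG"}


class ReferenceIndex:
    """Seed index over both strands of a small reference.

    Each contig is stored twice: forward and reverse-complemented ("strand
    space"), so alignment and downstream-context lookup read left-to-right in
    transcript orientation on either strand. Position ``p`` in minus-strand
    space corresponds to genomic position ``L - 1 - p``.
    """

    def __init__(self, sequences: Mapping[str, str], k: int = 12):
        self.k = k
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}
        self.lengths = {name: len(seq) for name, seq in self.sequences.items()}
        self.arrays: dict[tuple[str, str], np.ndarray] = {}
        self.strings: dict[tuple[str, str], str] = {}
        self.seeds: dict[str, list[tuple[str, str, int]]] = {}
        for name, seq in self.sequences.items():
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                self.strings[(name, strand)] = s
                self.arrays[(name, strand)] = encode(s)
                for pos in range(0, len(s) - k + 1):
                    self.seeds.setdefault(s[pos : pos + k], []).append(
                        (name, strand, pos)
                    )

    @classmethod
    def from_fasta(cls, path, k: int = 12) -> "ReferenceIndex":
        from .gffio import read_fasta

        return cls(read_fasta(path), k=k)

    def to_genome(self, contig: str, strand: str, s_start: int, s_end: int) -> tuple[int, int]:
        """Strand-space interval -> genomic 0-based half-open interval."""
        if strand == "+":
            return s_start, s_end
        L = self.lengths[contig]
        return L - s_end, L - s_start

    def strand_pos_to_genome(self, contig: str, strand: str, pos: int) -> int:
        return pos if strand == "+" else self.lengths[contig] - 1 - pos

    def downstream_context(
        self, contig: str, strand: str, s_end: int, n: int
    ) -> str:
        """Up to ``n`` genomic bases 3' of strand-space position ``s_end``,
        in transcript orientation."""
        return self.strings[(contig, strand)][s_end : s_end + n]


def _allowed_mismatches(spans: np.ndarray, window: int) -> np.ndarray:
    return -(-spans // window)  # ceil(span / window)


def _evaluate_candidate(
    read_arr: np.ndarray,
    ref_arr: np.ndarray,
    start: int,
    cfg: TailcallConfig,
    mode: str,
) -> tuple[int, int, int] | None:
    """Best (score, span, mismatches) for a 5'-anchored placement at ``start``.

    Valid spans respect the per-window mismatch allowance, the minimal span,
    and the mode's remainder constraint; among valid spans the highest score
    wins, ties to the longer span.
    """
    n = len(read_arr)
    L = min(n, len(ref_arr) - start)
    if L < cfg.min_aligned_span:
        return None
    mism = np.cumsum(read_arr[:L] != ref_arr[start : start + L])
    spans = np.arange(1, L + 1)
    if mode == "strict":
        if L < n or mism[n - 1] != 0:
            return None
        return (n, n, 0)
    valid = (spans >= cfg.min_aligned_span) & (
        mism <= _allowed_mismatches(spans, cfg.mismatch_window)
    )
    if not valid.any():
        return None
    # difference-ranked span choice: fewest mismatches first, then the
    # longest such span. Paying a mismatch to reach matching genomic bases
    # further 3' never wins, so alignments cannot creep into non-templated
    # tails; the longest minimal-difference span is the maximal exact-match
    # prefix for error-free reads (templated tail bases included, which the
    # maximal-templated convention requires).
    idx = np.flatnonzero(valid)
    min_mm = mism[idx].min()
    best = idx[mism[idx] == min_mm][-1]
    score = spans - MISMATCH_PENALTY * mism
    # the remainder cap is a mapping criterion, not an optimisation
    # constraint: if the best explanation of the read leaves too long a 3'
    # remainder, the read fails soft mapping (and may be rescued by
    # T-trimming in pass 2) rather than absorbing tail bases as mismatches
    if n - spans[best] > cfg.max_remainder_frac * n:
        return None
    return int(score[best]), int(spans[best]), int(mism[best])


def align_read(
    read_id: str,
    sequence: str,
    index: ReferenceIndex,
    cfg: TailcallConfig | None = None,
    mode: str = "soft",
    mapping_pass: int = 1,
    trimmed_t_count: int = 0,
) -> AlignmentRecord | None:
    """Seed-and-extend alignment of one read against both strands.

    Returns the best-scoring placement (``unique`` reflects the
    best-minus-second-best margin) or None when no placement satisfies the
    span/mismatch/remainder constraints. Non-unique placements are returned
    with ``unique=False`` so callers can exclude them without losing counts.
    """
    cfg = cfg or TailcallConfig()
    seq = sequence.upper()
    n = len(seq)
    if n < cfg.min_aligned_span:
        return None
    read_arr = encode(seq)
    k = index.k
    candidates: set[tuple[str, str, int]] = set()
    offsets = list(range(0, max(n - k, 0) + 1, k))
    if n - k >= 0 and (n - k) not in offsets:
        offsets.append(n - k)
    for off in offsets:
        for contig, strand, pos in index.seeds.get(seq[off : off + k], ()):
            start = pos - off
            if start >= 0:
                candidates.add((contig, strand, start))

    scored: list[tuple[int, int, int, str, str, int]] = []
    for contig, strand, start in candidates:
        res = _evaluate_candidate(read_arr, index.arrays[(contig, strand)], start, cfg, mode)
        if res is not None:
            score, span, mism = res
            scored.append((score, span, mism, contig, strand, start))
    if not scored:
        return None
    # deterministic order: best score, longest span, then position
    scored.sort(key=lambda t: (-t[0], -t[1], t[3], t[4], t[5]))
    score, span, mism, contig, strand, start = scored[0]
    unique = len(scored) == 1 or (score - scored[1][0]) >= cfg.uniqueness_margin
    g_start, g_end = index.to_genome(contig, strand, start, start + span)
    return AlignmentRecord(
        read_id=read_id,
        contig=contig,
        start=g_start,
        end=g_end,
        strand=strand,
        span=span,
        remainder=seq[span:],
        mapping_pass=mapping_pass,
        trimmed_t_count=trimmed_t_count,
        unique=unique,
        score=score,
        n_mismatch=mism,
    )


def trim_t_tail(sequence: str, trim_min_run: int = 4) -> tuple[str, int]:
    """Remove the maximal 3'-terminal T run iff it is >= ``trim_min_run``.

    Idempotent; an all-T read trims to the empty string (callers flag it
    "all-tail" and exclude it from remapping).
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    run = len(seq) - len(seq.rstrip("T"))
    if run >= trim_min_run:
        return seq[: len(seq) - run], run
    return seq, 0


@dataclass
class TwoPassResult:
    """Alignments plus the exhaustive 4-way read classification."""

    alignments: dict[str, AlignmentRecord]
    categories: dict[str, str]  # read id -> pass1 | pass2 | unmapped | all-tail
    multimapped: set[str]

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in (CATEGORY_PASS1, CATEGORY_PASS2, CATEGORY_UNMAPPED, CATEGORY_ALL_TAIL)}
        for cat in self.categories.values():
            out[cat] += 1
        out["multimapped"] = len(self.multimapped)
        return out


def two_pass_map(
    reads: Sequence[tuple[str, str]],
    index: ReferenceIndex,
    cfg: TailcallConfig | None = None,
) -> TwoPassResult:
    """Pass 1 on raw reads; pass 2 (after T-trimming) on pass-1 failures.

    Every read lands in exactly one of {pass1, pass2, unmapped, all-tail}.
    Multimapped reads are terminal (not trimmed/remapped) and count as
    unmapped for the partition, with ids kept separately.
    """
    cfg = cfg or TailcallConfig()
    alignments: dict[str, AlignmentRecord] = {}
    categories: dict[str, str] = {}
    multimapped: set[str] = set()
    for read_id, seq in reads:
        aln = align_read(read_id, seq, index, cfg, mode=cfg.pass1_mode, mapping_pass=1)
        if aln is not None and aln.unique:
            alignments[read_id] = aln
            categories[read_id] = CATEGORY_PASS1
            continue
        if aln is not None and not aln.unique:
            multimapped.add(read_id)
            categories[read_id] = CATEGORY_UNMAPPED
            continue
        trimmed, removed = trim_t_tail(seq, cfg.trim_min_run)
        if not trimmed:
            categories[read_id] = CATEGORY_ALL_TAIL
            continue
        if removed == 0 and cfg.pass1_mode == "soft":
            # an identical soft alignment already failed in pass 1
            categories[read_id] = CATEGORY_UNMAPPED
            continue
        aln2 = align_read(
            read_id, trimmed, index, cfg, mode="soft", mapping_pass=2, trimmed_t_count=removed
        )
        if aln2 is not None and aln2.unique:
            alignments[read_id] = aln2
            categories[read_id] = CATEGORY_PASS2
        elif aln2 is not None:
            multimapped.add(read_id)
            categories[read_id] = CATEGORY_UNMAPPED
        else:
            categories[read_id] = CATEGORY_UNMAPPED
    return TwoPassResult(alignments, categories, multimapped)


def classify_tail(untemplated: str, min_u: int = 4) -> str:
    """Composition class of an untemplated tail.

    U+ iff the 3'-terminal T run is >= ``min_u`` (earlier bases may differ);
    shorter homopolymers are labelled by their base (T runs as "U");
    heterogeneous tails are "mixed"; empty tails are "none".
    """
    tail = untemplated.upper()
    if any(b not in "ACGT" for b in tail):
        raise ValueError(f"non-ACGT character in tail {untemplated!r}")
    if not tail:
        return "none"
    terminal_t = len(tail) - len(tail.rstrip("T"))
    if terminal_t >= min_u:
        return "U+"
    if len(set(tail)) == 1:
        return "U" if tail[0] == "T" else tail[0]
    return "mixed"


def call_untemplated_tail(
    alignment: AlignmentRecord,
    index: ReferenceIndex,
    cfg: TailcallConfig | None = None,
) -> TailCall:
    """Split a mapped read's raw 3' remainder into templated and untemplated.

    The raw remainder (unaligned suffix plus any Ts trimmed before pass 2) is
    extended base-by-base along the genome past the alignment end, in
    transcript orientation; the maximal matching prefix is templated, the
    residue is the untemplated tail. The anchor is the genomic position of
    the last templated base.
    """
    cfg = cfg or TailcallConfig()
    if not alignment.unique:
        raise ValueError("tail calling requires a unique alignment")
    if alignment.contig not in index.lengths:
        raise KeyError(
            f"contig {alignment.contig!r} absent from the reference index"
        )
    raw = alignment.remainder + "T" * alignment.trimmed_t_count
    L = index.lengths[alignment.contig]
    if alignment.strand == "+":
        s_end = alignment.end
    else:
        s_end = L - alignment.start
    downstream = index.downstream_context(alignment.contig, alignment.strand, s_end, len(raw))
    overlap = 0
    for a, b in zip(raw, downstream):
        if a != b:
            break
        overlap += 1
    untemplated = raw[overlap:]
    if not raw:
        source = "none"
    elif alignment.trimmed_t_count and alignment.remainder:
        source = "both"
    elif alignment.trimmed_t_count:
        source = "trimmed-Ts"
    else:
        source = "remainder"
    anchor_strand_pos = s_end + overlap - 1  # last templated base in strand space
    anchor = index.strand_pos_to_genome(alignment.contig, alignment.strand, anchor_strand_pos)
    return TailCall(
        read_id=alignment.read_id,
        contig=alignment.contig,
        anchor=anchor,
        strand=alignment.strand,
        tail_seq=raw,
        templated_overlap=overlap,
        untemplated_seq=untemplated,
        comp_class=classify_tail(untemplated, cfg.min_u),
        tail_source=source,
    )


def call_tails(
    result: TwoPassResult,
    index: ReferenceIndex,
    cfg: TailcallConfig | None = None,
) -> list[TailCall]:
    """Tail calls for every uniquely mapped read, in read-id order."""
    cfg = cfg or TailcallConfig()
    return [
        call_untemplated_tail(result.alignments[rid], index, cfg)
        for rid in sorted(result.alignments)
    ]


_TSV_COLUMNS = [
    "read_id", "contig", "anchor", "strand", "gene_id", "category",
    "tail_seq", "templated_overlap", "untemplated_seq", "untemplated_length",
    "n_T", "n_A", "n_C", "n_G", "comp_class", "tail_source",
]


def calls_to_frame(calls: Iterable[TailCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        counts = c.base_counts()
        rows.append(
            {
                "read_id": c.read_id,
                "contig": c.contig,
                "anchor": c.anchor,
                "strand": c.strand,
                "gene_id": c.gene_id if c.gene_id is not None else ".",
                "category": c.category if c.category is not None else ".",
                "tail_seq": c.tail_seq or ".",
                "templated_overlap": c.templated_overlap,
                "untemplated_seq": c.untemplated_seq or ".",
                "untemplated_length": c.untemplated_length,
                "n_T": counts["T"],
                "n_A": counts["A"],
                "n_C": counts["C"],
                "n_G": counts["G"],
                "comp_class": c.comp_class,
                "tail_source": c.tail_source,
            }
        )
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def write_tail_calls(calls: Sequence[TailCall], path, cfg: TailcallConfig | None = None) -> None:
    """Tail-call TSV, one row per unique read, convention noted in the header."""
    cfg = cfg or TailcallConfig()
    with open(path, "w") as fh:
        fh.write("# uridylome tail calls; junction ambiguity resolved by maximal templated extension\n")
        fh.write(
            f"# trim_min_run={cfg.trim_min_run} min_u={cfg.min_u} "
            f"min_aligned_span={cfg.min_aligned_span} mismatch_window={cfg.mismatch_window} "
            f"uniqueness_margin={cfg.uniqueness_margin} pass1_mode={cfg.pass1_mode}\n"
        )
        calls_to_frame(calls).to_csv(fh, sep="\t", index=False)


def read_tail_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"contig": str})
    for col in ("tail_seq", "untemplated_seq", "gene_id", "category"):
        if col in df:
            df[col] = df[col].replace(".", "")
    return df


def write_anchor_bed(calls: Sequence[TailCall], path) -> None:
    """BED6 of anchors: name = composition class, score = untemplated length."""
    with open(path, "w") as fh:
        for c in sorted(calls, key=lambda c: (c.contig, c.anchor, c.read_id)):
            fh.write(
                f"{c.contig}\t{c.anchor}\t{c.anchor + 1}\t{c.comp_class}\t"
                f"{c.untemplated_length}\t{c.strand}\n"
            )
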