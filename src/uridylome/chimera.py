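"""Hybrid (chimeric) read detection from intramolecular RNase T1 ligation.

During the CLIP protocol, two fragments of one folded molecule can be
ligated intramolecularly, yielding reads whose 5' and 3' halves map to two
non-adjacent, same-strand intervals of one locus. Because RNase T1 cleaves
3' of guanosine, the upstream arm of a genuine ligation ends in G; this is
recorded as a consistency flag, not used as a filter.

Detection is an exhaustive split search: every split point of an (otherwise
unmappable) read is tried, the 5' half aligned end-to-end and the 3' half
5'-anchored with a tail-style remainder permitted; candidates where both
halves map uniquely, on one strand of one annotated locus and with a
plausible skipped gap are scored by total alignment score. The read's 3'
remainder after the downstream arm goes through the ordinary tail caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .annotate import AnnotationIndex
from .config import ChimeraConfig, TailcallConfig
from .tailcall import (
    AlignmentRecord,
    ReferenceIndex,
    TailCall,
    align_read,
    call_untemplated_tail,
    trim_t_tail,
)


@dataclass
class ChimeraCall:
    """Two same-locus arms of a hybrid read with their ligation junction.

    Arm intervals are genomic, 0-based half-open; the junction is reported in
    transcript coordinates of the assigned locus (1-based): position of the
    arm-1 3' end and of the arm-2 5' start.
    """

    read_id: str
    contig: str
    strand: str
    locus_id: str | None
    arm1: tuple[int, int]
    arm2: tuple[int, int]
    junction: tuple[int, int]
    arm1_terminal_base: str
    rnase_t1_consistent: bool
    gap: int
    split: int  # read offset of the arm boundary
    tail: TailCall | None = None
    inter_locus: bool = False


@dataclass
class SplitCandidate:
    split: int
    arm1: AlignmentRecord
    arm2: AlignmentRecord
    gap: int
    total_score: int


def _transcript_gap(a1: AlignmentRecord, a2: AlignmentRecord) -> int | None:
    """Bases skipped between arm1's 3' end and arm2's 5' start, or None if the
    arms are not ordered/non-overlapping in transcript orientation."""
    if a1.contig != a2.contig or a1.strand != a2.strand:
        return None
    if a1.strand == "+":
        gap = a2.start - a1.end
    else:
        gap = a1.start - a2.end
    return gap if gap >= 0 else None


def enumerate_split_candidates(
    read_id: str,
    sequence: str,
    index: ReferenceIndex,
    cfg: ChimeraConfig | None = None,
    tail_cfg: TailcallConfig | None = None,
) -> list[SplitCandidate]:
    """All split points where both halves map uniquely on one strand.

    The 5' arm must align end-to-end exactly (its 3' end is the ligation
    junction); the 3' arm is 5'-anchored with a 3' remainder allowed (the
    read's tail). Reads shorter than twice the minimal arm yield nothing.
    """
    cfg = cfg or ChimeraConfig()
    tail_cfg = tail_cfg or TailcallConfig()
    seq = sequence.upper()
    n = len(seq)
    out: list[SplitCandidate] = []
    if n < 2 * cfg.min_arm:
        return out
    arm_cfg = TailcallConfig(
        min_aligned_span=cfg.min_arm,
        mismatch_window=tail_cfg.mismatch_window,
        uniqueness_margin=tail_cfg.uniqueness_margin,
        max_remainder_frac=tail_cfg.max_remainder_frac,
        seed_k=tail_cfg.seed_k,
    )
    for split in range(cfg.min_arm, n - cfg.min_arm + 1):
        a1 = align_read(f"{read_id}/arm1", seq[:split], index, arm_cfg, mode="strict")
        if a1 is None or not a1.unique:
            continue
        a2 = align_read(f"{read_id}/arm2", seq[split:], index, arm_cfg, mode="soft")
        if a2 is None or not a2.unique:
            continue
        gap = _transcript_gap(a1, a2)
        if gap is None:
            continue
        out.append(
            SplitCandidate(split, a1, a2, gap, a1.score + a2.score)
        )
    return out


def _locus_of(
    aln: AlignmentRecord, annotation: AnnotationIndex | None
) -> str | None:
    if annotation is None:
        return None
    hit = annotation.assign_category(aln.contig, aln.start, aln.end, aln.strand)
    return hit[0] if hit else None


def detect_chimera(
    read_id: str,
    sequence: str,
    index: ReferenceIndex,
    annotation: AnnotationIndex | None = None,
    cfg: ChimeraConfig | None = None,
    tail_cfg: TailcallConfig | None = None,
    skip_contiguous_check: bool = False,
) -> ChimeraCall | None:
    """Best intramolecular split of a read, or None.

    Contiguously mappable reads are never called chimeric. Among candidates
    with gap in [min_gap, max_gap] and both arms in one annotated locus, the
    highest total alignment score wins; score ties are resolved by RNase T1
    geometry (arm1 ending in G, then a G 5' of arm2), then smallest gap,
    leftmost arm1, largest split — the canonical form of
    :func:`canonical_junction_shift`. If the only candidates join two
    different loci the best is returned flagged ``inter_locus`` (excluded
    from hybrid tables by default).
    """
    cfg = cfg or ChimeraConfig()
    tail_cfg = tail_cfg or TailcallConfig()
    # Mirror the two-pass logic: strip the 3' oligo(T) tail first, so a long
    # U tail cannot mask either the contiguous alignment or the split search;
    # the trimmed Ts are restored when the downstream arm's tail is called.
    trimmed, removed = trim_t_tail(sequence, tail_cfg.trim_min_run)
    if not trimmed:
        return None
    contiguous_score = None
    if not skip_contiguous_check:
        contiguous = align_read(read_id, trimmed, index, tail_cfg, mode="soft")
        if contiguous is not None and contiguous.unique:
            if contiguous.span == len(trimmed) and contiguous.n_mismatch == 0:
                return None  # perfect end-to-end: unambiguously contiguous
            contiguous_score = contiguous.score
    candidates = enumerate_split_candidates(read_id, trimmed, index, cfg, tail_cfg)
    candidates = [c for c in candidates if cfg.min_gap <= c.gap <= cfg.max_gap]
    # model selection: a split must explain the read clearly better than the
    # best contiguous alignment. A genuine downstream arm contributes at
    # least ~min_arm newly aligned bases, whereas a spurious split of a
    # contiguous read only absorbs the few unaligned tail bases, so half an
    # arm is a safe margin.
    if contiguous_score is not None:
        margin = cfg.min_arm // 2
        candidates = [c for c in candidates if c.total_score > contiguous_score + margin]
    if not candidates:
        return None

    def order(c: SplitCandidate):
        # Ties between neighbouring perfect splits are resolved by RNase T1
        # geometry: both ligated ends derive from cuts 3' of G, so prefer an
        # arm1 ending in G, then an arm2 whose genomic 5' neighbour is G;
        # then smallest gap, leftmost arm1, smallest split.
        ends_in_g = trimmed[c.split - 1] == "G"
        a2 = c.arm2
        if a2.strand == "+":
            pre = index.sequences[a2.contig][a2.start - 1] if a2.start > 0 else ""
        else:
            s = index.strings[(a2.contig, a2.strand)]
            p = index.lengths[a2.contig] - a2.end
            pre = s[p - 1] if p > 0 else ""
        return (-c.total_score, not ends_in_g, pre != "G", c.gap, c.arm1.start, -c.split)

    intra: list[tuple[SplitCandidate, str | None]] = []
    inter: list[SplitCandidate] = []
    for c in candidates:
        l1 = _locus_of(c.arm1, annotation)
        l2 = _locus_of(c.arm2, annotation)
        if annotation is not None and (l1 is None or l1 != l2):
            inter.append(c)
        else:
            intra.append((c, l1))
    if intra:
        best, locus = min(intra, key=lambda t: order(t[0]))
        inter_locus = False
    elif inter:
        best, locus = min(inter, key=order), None
        inter_locus = True
    else:
        return None

    seq = trimmed
    arm1_iv = (best.arm1.start, best.arm1.end)
    arm2_iv = (best.arm2.start, best.arm2.end)
    junction = _junction_coordinates(best, locus, annotation, index)
    best.arm2.trimmed_t_count = removed
    best.arm2.mapping_pass = 2 if removed else 1
    tail = call_untemplated_tail(best.arm2, index, tail_cfg)
    tail.read_id = read_id
    tail.gene_id = locus
    return ChimeraCall(
        read_id=read_id,
        contig=best.arm1.contig,
        strand=best.arm1.strand,
        locus_id=locus,
        arm1=arm1_iv,
        arm2=arm2_iv,
        junction=junction,
        arm1_terminal_base=seq[best.split - 1],
        rnase_t1_consistent=seq[best.split - 1] == "G",
        gap=best.gap,
        split=best.split,
        tail=tail,
        inter_locus=inter_locus,
    )


def _junction_coordinates(
    cand: SplitCandidate,
    locus: str | None,
    annotation: AnnotationIndex | None,
    index: ReferenceIndex,
) -> tuple[int, int]:
    """1-based transcript positions of (arm1 3' end, arm2 5' start), relative
    to the assigned locus 5' end when annotated, else to the contig."""
    a1, a2 = cand.arm1, cand.arm2
    if locus is not None and annotation is not None:
        gene = annotation.genes[locus]
        if gene.strand == "+":
            origin = gene.start
            end1 = a1.end - 1 - origin
            start2 = a2.start - origin
        else:
            origin = gene.end - 1
            end1 = origin - a1.start
            start2 = origin - (a2.end - 1)
        return end1 + 1, start2 + 1
    if a1.strand == "+":
        return a1.end, a2.start + 1
    L = index.lengths[a1.contig]
    return L - a1.start, L - (a2.end - 1)


def canonical_junction_shift(
    strand_seq: str,
    arm1_end: int,
    arm2_start: int,
    max_left: int,
    max_right: int,
) -> int:
    """Canonical representative of an ambiguous ligation junction.

    When the read base(s) flanking a split match the genome on both arms'
    continuations, neighbouring splits explain the read identically and the
    true junction is unidentifiable from sequence — exactly as with indel
    left-alignment in variant calling. All coordinates here are in strand
    space (transcript orientation) of one contig strand: ``arm1_end`` /
    ``arm2_start`` are the half-open end of arm1 and start of arm2. Returns
    the signed shift ``d`` selecting the canonical variant among all
    equivalent ones, preferring (as the detector does) an arm1 ending in G,
    then a G immediately 5' of arm2, then the largest split.

    ``max_left``/``max_right`` bound the shift so both arms keep their
    minimal length.
    """
    valid = [0]
    d = 1
    while d <= max_right and arm2_start + d - 1 < len(strand_seq) and \
            strand_seq[arm1_end + d - 1] == strand_seq[arm2_start + d - 1]:
        valid.append(d)
        d += 1
    d = -1
    while d >= -max_left and arm2_start + d >= 1 and \
            strand_seq[arm1_end + d] == strand_seq[arm2_start + d]:
        valid.append(d)
        d -= 1

    def key(d: int):
        g1 = strand_seq[arm1_end + d - 1] == "G"
        g2 = strand_seq[arm2_start + d - 1] == "G"
        return (not g1, not g2, -d)

    return min(valid, key=key)


def chimera_tail(call: ChimeraCall) -> TailCall | None:
    """The tail call anchored at the downstream arm's end (already computed
    during detection; exposed for symmetry with the contiguous path)."""
    return call.tail


def chimera_frame(calls: Sequence[ChimeraCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "read_id": c.read_id,
                "contig": c.contig,
                "strand": c.strand,
                "locus_id": c.locus_id or ".",
                "arm1_start": c.arm1[0],
                "arm1_end": c.arm1[1],
                "arm2_start": c.arm2[0],
                "arm2_end": c.arm2[1],
                "junction_end1": c.junction[0],
                "junction_start2": c.junction[1],
                "gap": c.gap,
                "arm1_terminal_base": c.arm1_terminal_base,
                "rnase_t1_consistent": int(c.rnase_t1_consistent),
                "tail_class": c.tail.comp_class if c.tail else "none",
                "tail_untemplated_length": c.tail.untemplated_length if c.tail else 0,
                "inter_locus": int(c.inter_locus),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id", "contig", "strand", "locus_id",
            "arm1_start", "arm1_end", "arm2_start", "arm2_end",
            "junction_end1", "junction_start2", "gap",
            "arm1_terminal_base", "rnase_t1_consistent",
            "tail_class", "tail_untemplated_length", "inter_locus",
        ],
    )


def write_chimera_bed12(calls: Sequence[ChimeraCall], path) -> None:
    """Two-block BED12-style records for genome-browser viewing."""
    with open(path, "w") as fh:
        for c in sorted(calls, key=lambda c: (c.contig, c.arm1[0], c.read_id)):
            start = min(c.arm1[0], c.arm2[0])
            end = max(c.arm1[1], c.arm2[1])
            blocks = sorted([c.arm1, c.arm2])
            sizes = f"{blocks[0][1] - blocks[0][0]},{blocks[1][1] - blocks[1][0]}"
            starts = f"0,{blocks[1][0] - start}"
            fh.write(
                f"{c.contig}\t{start}\t{end}\t{c.read_id}\t0\t{c.strand}\t{start}\t{end}\t"
                f"0,0,0\t2\t{sizes}\t{starts}\n"
            )
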