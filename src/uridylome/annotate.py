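"""Priority annotation of mapped reads and 3'-end state classification.

Each mapped read is assigned to one functional category by a fixed priority
order (tRNA > miRNA > snRNA > 5S rRNA > miscRNA > snoRNA > mRNA > lincRNA):
among all same-strand genes a read overlaps, the category earliest in the
order wins; ties within a category go to the largest overlap, then the
lexicographically smallest gene id. tRNA genes are queried with 60 nt
extensions on both sides so pre-tRNA leader/trailer fragments annotate to
their tRNA, while mature bounds are retained for positional analysis.

A tail-call anchor is then positioned within its gene: signed offset from
the mature 3' end (0 = the last mature base), the 5' leader / mature /
3' extension region, mRNA sub-features (5'UTR/CDS/3'UTR/intron, so reads
running from exon 1 into intron 1 flag unspliced precursors), and pre-tRNA
subregions using canonical cloverleaf proportions. snRNA-style 3'-end states
(Mat / Trim / ext, with a +U tally) follow the offset sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .gffio import (
    GeneModel,
    PRIORITY_ORDER,
    parse_bed_genes,
    parse_gff3,
)
from .tailcall import TailCall

#: canonical cloverleaf partition of the mature tRNA length (fractions of
#: mature length, 5'->3'): acceptor stem, D-arm, anticodon arm, T-loop, and
#: the 3' acceptor-stem side. A stand-in for structure-derived arm bounds.
TRNA_PARTITION = [
    (0.00, 0.10, "acceptor stem"),
    (0.10, 0.33, "D-arm"),
    (0.33, 0.60, "anticodon arm"),
    (0.60, 0.87, "T-loop"),
    (0.87, 1.01, "acceptor stem"),
]

_PRIORITY_RANK = {cat: i for i, cat in enumerate(PRIORITY_ORDER)}


def _rank(category: str) -> int:
    # non-priority categories (e.g. pseudogene) sort after the listed eight
    return _PRIORITY_RANK.get(category, len(PRIORITY_ORDER))


@dataclass
class RegionAssignment:
    gene_id: str
    category: str
    region: str  # "5' leader" | "mature" | "3' extension"
    offset: int  # anchor vs mature 3' end, signed, 0 = last mature base
    mrna_subfeature: str | None = None  # 5'UTR | CDS | 3'UTR | intron
    trna_subregion: str | None = None


class AnnotationIndex:
    """Strand-aware interval index over gene models.

    tRNA intervals are stored with +/- ``trna_extension`` nt; mature bounds
    stay on the :class:`GeneModel`.
    """

    def __init__(self, genes: Iterable[GeneModel], trna_extension: int = 60):
        self.trna_extension = trna_extension
        self.genes: dict[str, GeneModel] = {}
        self.trees: dict[tuple[str, str], IntervalTree] = {}
        for gene in genes:
            if gene.gene_id in self.genes:
                raise ValueError(f"duplicate gene id {gene.gene_id!r}")
            self.genes[gene.gene_id] = gene
            s, e = self.query_interval(gene)
            self.trees.setdefault((gene.contig, gene.strand), IntervalTree()).addi(
                s, e, gene.gene_id
            )

    def __len__(self) -> int:
        return len(self.genes)

    def query_interval(self, gene: GeneModel) -> tuple[int, int]:
        """The indexed (possibly extended) interval for a gene."""
        if gene.category == "tRNA":
            return max(0, gene.start - self.trna_extension), gene.end + self.trna_extension
        return gene.start, gene.end

    def overlapping(
        self, contig: str, start: int, end: int, strand: str
    ) -> list[GeneModel]:
        tree = self.trees.get((contig, strand))
        if tree is None:
            return []
        return [self.genes[iv.data] for iv in tree.overlap(start, end)]

    def assign_category(
        self, contig: str, start: int, end: int, strand: str, min_overlap: int = 1
    ) -> tuple[str, str] | None:
        """(gene id, category) of the priority winner, or None if unannotated."""
        best = None
        for gene in self.overlapping(contig, start, end, strand):
            qs, qe = self.query_interval(gene)
            ov = min(end, qe) - max(start, qs)
            if ov < min_overlap:
                continue
            key = (_rank(gene.category), -ov, gene.gene_id)
            if best is None or key < best[0]:
                best = (key, gene)
        if best is None:
            return None
        return best[1].gene_id, best[1].category


def load_annotation(
    path, category_map: Mapping[str, str] | None = None, trna_extension: int = 60
) -> AnnotationIndex:
    """Load GFF3 (default) or BED6 gene annotation into an index."""
    path = str(path)
    if path.endswith((".bed", ".bed6")):
        genes = parse_bed_genes(path, category_map)
    else:
        genes = parse_gff3(path, category_map)
    return AnnotationIndex(genes, trna_extension=trna_extension)


def three_prime_offset(anchor: int, gene: GeneModel) -> int:
    """Signed distance of an anchor from the mature 3' end (strand-aware).

    0 means the anchor sits exactly on the last mature base; positive values
    lie downstream (3' extension), negative upstream.
    """
    if gene.strand == "+":
        return anchor - (gene.end - 1)
    return gene.start - anchor


def five_prime_position(anchor: int, gene: GeneModel) -> int:
    """Anchor position relative to the mature 5' end (0 = first mature base)."""
    if gene.strand == "+":
        return anchor - gene.start
    return (gene.end - 1) - anchor


def _mrna_subfeature(anchor: int, gene: GeneModel) -> str | None:
    if not gene.exons:
        return None
    in_exon = any(s <= anchor < e for s, e in gene.exons)
    if not in_exon:
        if any(s <= anchor < e for s, e in gene.introns()):
            return "intron"
        return None
    if gene.cds is None:
        return None
    cs, ce = gene.cds
    if cs <= anchor < ce:
        return "CDS"
    before_cds = anchor < cs
    # 5'UTR is the pre-CDS side in transcript orientation
    if (gene.strand == "+") == before_cds:
        return "5'UTR"
    return "3'UTR"


def trna_subregion(anchor: int, gene: GeneModel, extension: int = 60) -> str:
    """Pre-tRNA subregion of a position, canonical cloverleaf proportions.

    Positions upstream/downstream of the mature bounds are the 5'/3'
    trailers; beyond the +/- ``extension`` window is a range error.
    """
    if gene.category != "tRNA":
        raise ValueError(f"{gene.gene_id} is not a tRNA")
    rel5 = five_prime_position(anchor, gene)
    if rel5 < -extension or rel5 >= gene.length + extension:
        raise ValueError(
            f"position {anchor} outside the extended span of {gene.gene_id}"
        )
    if rel5 < 0:
        return "5' trailer"
    if rel5 >= gene.length:
        return "3' trailer"
    frac = rel5 / gene.length
    for lo, hi, label in TRNA_PARTITION:
        if lo <= frac < hi:
            return label
    return TRNA_PARTITION[-1][2]


def assign_region(
    anchor: int, gene: GeneModel, trna_extension: int = 60
) -> RegionAssignment:
    """Position a tail-call anchor within a gene model."""
    if gene.end <= gene.start:
        raise ValueError(f"{gene.gene_id}: gene lacks valid mature bounds")
    offset = three_prime_offset(anchor, gene)
    rel5 = five_prime_position(anchor, gene)
    if rel5 < 0:
        region = "5' leader"
    elif offset > 0:
        region = "3' extension"
    else:
        region = "mature"
    sub = _mrna_subfeature(anchor, gene) if gene.category == "mRNA" else None
    trna = (
        trna_subregion(anchor, gene, trna_extension)
        if gene.category == "tRNA"
        else None
    )
    return RegionAssignment(
        gene_id=gene.gene_id,
        category=gene.category,
        region=region,
        offset=offset,
        mrna_subfeature=sub,
        trna_subregion=trna,
    )


def classify_end_state(offset: int) -> str:
    """Mat (offset 0), Trim (negative) or ext (positive)."""
    if offset == 0:
        return "Mat"
    return "Trim" if offset < 0 else "ext"


def end_state_tally(
    calls: Sequence[TailCall] | pd.DataFrame,
    index: AnnotationIndex,
) -> pd.DataFrame:
    """Per-gene tally of Mat/Trim/ext 3'-end states and +U counts.

    Accepts tail calls that already carry a ``gene_id``; per-read state
    follows the sign of the anchor's offset from the mature 3' end, and +U
    counts reads whose composition class is U+.
    """
    if isinstance(calls, pd.DataFrame):
        records = calls.to_dict("records")
    else:
        records = [
            {"gene_id": c.gene_id, "anchor": c.anchor, "comp_class": c.comp_class}
            for c in calls
        ]
    tallies: dict[str, dict[str, int]] = {}
    for rec in records:
        gid = rec.get("gene_id")
        if not gid or gid == "." or gid not in index.genes:
            continue
        gene = index.genes[gid]
        state = classify_end_state(three_prime_offset(int(rec["anchor"]), gene))
        t = tallies.setdefault(gid, {"Mat": 0, "Trim": 0, "ext": 0, "plus_U": 0})
        t[state] += 1
        if rec.get("comp_class") == "U+":
            t["plus_U"] += 1
    rows = [
        {"gene_id": gid, **counts} for gid, counts in sorted(tallies.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "Mat", "Trim", "ext", "plus_U"])


def annotate_calls(
    calls: Sequence[TailCall],
    index: AnnotationIndex,
    alignments: Mapping[str, "AlignmentRecord"] | None = None,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Annotate tail calls in place and return the annotated frame.

    Category assignment uses the read's full aligned interval when
    alignments are supplied, falling back to the 1-nt anchor interval
    otherwise. Adds region/offset/sub-feature columns.
    """
    from .tailcall import calls_to_frame  # local import to avoid cycle at load

    rows = []
    for call in calls:
        if alignments is not None and call.read_id in alignments:
            aln = alignments[call.read_id]
            interval = (aln.start, aln.end)
        else:
            interval = (call.anchor, call.anchor + 1)
        hit = index.assign_category(
            call.contig, interval[0], interval[1], call.strand, min_overlap
        )
        region = offset = sub = trna = None
        if hit is not None:
            call.gene_id, call.category = hit
            gene = index.genes[call.gene_id]
            ra = assign_region(call.anchor, gene, index.trna_extension)
            region, offset, sub, trna = (
                ra.region,
                ra.offset,
                ra.mrna_subfeature,
                ra.trna_subregion,
            )
        rows.append((region, offset, sub, trna))
    frame = calls_to_frame(calls)
    frame["region"] = [r[0] if r[0] is not None else "." for r in rows]
    frame["offset"] = [r[1] if r[1] is not None else pd.NA for r in rows]
    frame["mrna_subfeature"] = [r[2] if r[2] is not None else "." for r in rows]
    frame["trna_subregion"] = [r[3] if r[3] is not None else "." for r in rows]
    return frame
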