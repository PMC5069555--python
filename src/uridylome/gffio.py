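"""File formats and the shared gene-model container.

The annotation dialect understood here is deliberately small: gene-level GFF3
records whose feature type (or ``category=``/``gene_biotype=`` attribute)
names one of the functional categories used by the priority annotator, plus
optional ``exon``/``CDS`` children for mRNAs. Coordinates follow the GFF3
standard (1-based, inclusive) on disk and are converted to 0-based half-open
intervals in memory. BED6 is accepted as a flat alternative with the category
carried in the name field (``gene_id:category``).

FASTA/FASTQ go through Biopython; SAM/BAM handling lives in
:mod:`uridylome.pipeline` (pysam).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Functional categories in the annotator's priority order (highest first).
PRIORITY_ORDER = [
    "tRNA",
    "miRNA",
    "snRNA",
    "5S_rRNA",
    "miscRNA",
    "snoRNA",
    "mRNA",
    "lincRNA",
]

#: Common aliases seen in annotation sources, normalised to canonical tokens.
CATEGORY_ALIASES = {
    "5S rRNA": "5S_rRNA",
    "rRNA_5S": "5S_rRNA",
    "misc_RNA": "miscRNA",
    "lncRNA": "lincRNA",
    "protein_coding": "mRNA",
}

KNOWN_CATEGORIES = set(PRIORITY_ORDER) | {"pseudogene"}


class AnnotationParseError(ValueError):
    """Malformed annotation input; message carries the 1-based line number."""


@dataclass
class GeneModel:
    """One annotated gene: mature bounds plus optional substructure.

    ``start``/``end`` are the mature-RNA genomic bounds, 0-based half-open.
    mRNAs may carry exons and a CDS interval; the TSS is the 5' end of the
    mature span.
    """

    gene_id: str
    category: str
    contig: str
    start: int
    end: int
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Genomic position of the transcription start (5' end)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def mature_three_prime(self) -> int:
        """Genomic position of the last mature base (3' end)."""
        return self.end - 1 if self.strand == "+" else self.start

    def introns(self) -> list[tuple[int, int]]:
        if len(self.exons) < 2:
            return []
        ex = sorted(self.exons)
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]


def normalise_category(raw: str, category_map: Mapping[str, str] | None = None) -> str:
    cat = (category_map or {}).get(raw, CATEGORY_ALIASES.get(raw, raw))
    if cat not in KNOWN_CATEGORIES:
        raise ValueError(
            f"unknown category {raw!r}; accepted: {sorted(KNOWN_CATEGORIES)}"
        )
    return cat


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in text.strip().rstrip(";").split(";"):
        if not chunk:
            continue
        if "=" not in chunk:
            raise ValueError(f"malformed attribute {chunk!r}")
        key, value = chunk.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def parse_gff3(
    path_or_handle, category_map: Mapping[str, str] | None = None
) -> list[GeneModel]:
    """Parse the gene-level GFF3 dialect into :class:`GeneModel` objects.

    Raises :class:`AnnotationParseError` with a line number on malformed
    coordinates or unknown categories.
    """
    if hasattr(path_or_handle, "read"):
        lines = path_or_handle.read().splitlines()
    else:
        with open(path_or_handle) as fh:
            lines = fh.read().splitlines()

    genes: dict[str, GeneModel] = {}
    children: list[tuple[int, str, str, int, int]] = []  # lineno, parent, type, s, e
    for lineno, line in enumerate(lines, start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise AnnotationParseError(f"line {lineno}: expected 9 columns")
        contig, _source, ftype, start_s, end_s, _score, strand, _frame, attrs_s = fields
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise AnnotationParseError(
                f"line {lineno}: non-integer coordinates {start_s!r}..{end_s!r}"
            ) from None
        if start1 < 1 or end1 < start1:
            raise AnnotationParseError(
                f"line {lineno}: invalid interval {start1}..{end1}"
            )
        try:
            attrs = _parse_gff_attributes(attrs_s)
        except ValueError as exc:
            raise AnnotationParseError(f"line {lineno}: {exc}") from None
        start, end = start1 - 1, end1  # to 0-based half-open

        if ftype in ("exon", "CDS"):
            parent = attrs.get("Parent")
            if parent is None:
                raise AnnotationParseError(f"line {lineno}: {ftype} without Parent")
            children.append((lineno, parent, ftype, start, end))
            continue

        raw_cat = attrs.get("category") or attrs.get("gene_biotype") or ftype
        if ftype == "gene" and "category" not in attrs and "gene_biotype" not in attrs:
            raise AnnotationParseError(
                f"line {lineno}: gene record lacks a category/gene_biotype attribute"
            )
        try:
            category = normalise_category(raw_cat, category_map)
        except ValueError as exc:
            raise AnnotationParseError(f"line {lineno}: {exc}") from None
        gene_id = attrs.get("ID") or attrs.get("Name")
        if gene_id is None:
            raise AnnotationParseError(f"line {lineno}: record lacks an ID attribute")
        if strand not in "+-":
            raise AnnotationParseError(f"line {lineno}: strand must be '+' or '-'")
        genes[gene_id] = GeneModel(gene_id, category, contig, start, end, strand)

    for lineno, parent, ftype, start, end in children:
        gene = genes.get(parent)
        if gene is None:
            raise AnnotationParseError(f"line {lineno}: unknown Parent {parent!r}")
        if ftype == "exon":
            gene.exons.append((start, end))
        else:
            cds = gene.cds
            gene.cds = (start, end) if cds is None else (min(cds[0], start), max(cds[1], end))
    for gene in genes.values():
        gene.exons.sort()
    return list(genes.values())


def write_gff3(genes: Iterable[GeneModel], path_or_handle) -> None:
    """Write gene models back out in the same GFF3 dialect (1-based inclusive)."""
    handle = (
        path_or_handle
        if hasattr(path_or_handle, "write")
        else open(path_or_handle, "w")
    )
    close = handle is not path_or_handle
    try:
        handle.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig, g.start, g.gene_id)):
            handle.write(
                f"{g.contig}\turidylome\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};category={g.category}\n"
            )
            for i, (es, ee) in enumerate(g.exons, start=1):
                handle.write(
                    f"{g.contig}\turidylome\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
            if g.cds is not None:
                handle.write(
                    f"{g.contig}\turidylome\tCDS\t{g.cds[0] + 1}\t{g.cds[1]}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds;Parent={g.gene_id}\n"
                )
    finally:
        if close:
            handle.close()


def parse_bed_genes(
    path_or_handle, category_map: Mapping[str, str] | None = None
) -> list[GeneModel]:
    """BED6 genes with ``gene_id:category`` in the name column."""
    if hasattr(path_or_handle, "read"):
        lines = path_or_handle.read().splitlines()
    else:
        with open(path_or_handle) as fh:
            lines = fh.read().splitlines()
    genes = []
    for lineno, line in enumerate(lines, start=1):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise AnnotationParseError(f"line {lineno}: BED6 requires 6 columns")
        contig, start_s, end_s, name, _score, strand = fields[:6]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise AnnotationParseError(f"line {lineno}: non-integer coordinates") from None
        if ":" not in name:
            raise AnnotationParseError(
                f"line {lineno}: BED name must be 'gene_id:category'"
            )
        gene_id, raw_cat = name.rsplit(":", 1)
        try:
            category = normalise_category(raw_cat, category_map)
        except ValueError as exc:
            raise AnnotationParseError(f"line {lineno}: {exc}") from None
        genes.append(GeneModel(gene_id, category, contig, start, end, strand))
    return genes


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: Sequence[tuple[str, str]], path, quality_char: str = "I") -> None:
    """Write (id, sequence) pairs as FASTQ with constant quality."""
    records = []
    for read_id, seq in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [ord(quality_char) - 33] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_reads(path) -> list[tuple[str, str]]:
    """Read FASTQ or FASTA (sniffed from the first byte) as (id, seq) pairs."""
    path = str(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, fmt)]


def read_bedgraph(path) -> pd.DataFrame:
    """bedGraph as a DataFrame with columns contig/start/end/value."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["contig", "start", "end", "value"],
        dtype={"contig": str},
    )
    if df["value"].isna().any():
        raise ValueError("bedGraph requires 4 columns: contig start end value")
    return df


def read_tss_bed(path) -> list[tuple[str, int, str, str]]:
    """TSS sites from BED6 as (contig, position, strand, name)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationParseError(f"line {lineno}: BED6 requires 6 columns")
            contig, start_s, end_s, name, _score, strand = fields[:6]
            start, end = int(start_s), int(end_s)
            pos = start if strand == "+" else end - 1
            out.append((contig, pos, strand, name))
    return out
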