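"""Synthetic CLIP-read simulator with machine-readable ground truth.

The simulator emulates the statistical structure the analysis assumes:

* a random reference carrying genes of the eight functional categories the
  annotator prioritises (plus optional pseudogenes), with marked TSS and at
  least one intron per mRNA;
* RNase T1 fragmentation — partial digestion cutting immediately 3' of G;
* class-specific non-templated 3' tailing: oligo(U) tails with configurable
  median (default 7 nt, support 4-20) and short A/C/G additions (1-3 nt);
* intramolecular-ligation chimeras: two non-overlapping fragments of one
  gene joined 5'->3', the upstream arm ending in G;
* uniquely- vs multi-mapping source loci via optional gene duplication.

Simulation happens in DNA space (U -> T) since reads are sequenced cDNA.
Everything is seeded; identical inputs and seed give byte-identical FASTQ
and truth-table outputs. The truth table (TSV, one row per read) records the
source locus, fragment coordinates, the exact appended tail and chimera arm
intervals, independent of whether the tail happens to coincide with
downstream genomic bases.

What real data has that these reads do not: sequencing errors, PCR
duplicates, adapter read-through and crosslink-induced mutations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp
from .gffio import GeneModel, write_fasta, write_fastq, write_gff3

#: default mature-length ranges (nt) per category, loosely life-like
DEFAULT_GENE_LENGTHS: dict[str, tuple[int, int]] = {
    "tRNA": (70, 90),
    "miRNA": (60, 90),
    "snRNA": (100, 200),
    "5S_rRNA": (119, 121),
    "miscRNA": (90, 300),
    "snoRNA": (60, 150),
    "mRNA": (600, 1500),
    "lincRNA": (300, 800),
    "pseudogene": (100, 300),
}


class SizingError(ValueError):
    """Requested genes cannot fit in the requested contig length."""


@dataclass
class ReferenceSpec:
    """Layout of a synthetic reference contig.

    ``n_genes`` maps category -> count. ``nested_snorna_pairs`` places that
    many snoRNAs inside mRNA introns (overlapping annotation, for priority
    tests). ``duplicate_genes`` copies that many genes verbatim elsewhere on
    the contig so their reads multi-map.
    """

    n_genes: dict[str, int] = field(default_factory=dict)
    gene_lengths: dict[str, tuple[int, int]] = field(default_factory=dict)
    spacer: int = 300
    gc_content: float = 0.5
    contig: str = "simchr"
    contig_length: int | None = None
    minus_strand_fraction: float = 0.0
    nested_snorna_pairs: int = 0
    duplicate_genes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for cat, n in self.n_genes.items():
            if n < 0:
                raise ValueError(f"negative gene count for {cat}")
        for cat, (lo, hi) in self.gene_lengths.items():
            if lo < 20 or hi < lo:
                raise ValueError(f"gene lengths for {cat} must be >= 20 and ordered")
        if not 0 <= self.gc_content <= 1:
            raise ValueError("gc_content must be in [0, 1]")

    def length_range(self, category: str) -> tuple[int, int]:
        return self.gene_lengths.get(category, DEFAULT_GENE_LENGTHS[category])


@dataclass
class TailModel:
    """Class-specific non-templated 3' tailing.

    ``p_composition`` gives the probability of appending an oligo(U) tail, a
    short A/C/G run, or nothing. U-tail lengths follow a Poisson(``u_median``)
    truncated to ``u_support`` (median preserved for the defaults); A/C/G run
    lengths are uniform on ``acg_support``. ``templated_junction_bias`` is
    the probability that the fragment 3' end is nudged so the first appended
    base equals the genomic base immediately downstream (making the junction
    deliberately ambiguous).
    """

    p_composition: dict[str, float] = field(
        default_factory=lambda: {"U": 0.35, "A": 0.05, "C": 0.05, "G": 0.05, "none": 0.5}
    )
    u_median: int = 7
    u_support: tuple[int, int] = (4, 20)
    acg_support: tuple[int, int] = (1, 3)
    templated_junction_bias: float = 0.0

    def __post_init__(self) -> None:
        probs = self.p_composition
        if set(probs) != {"U", "A", "C", "G", "none"}:
            raise ValueError("p_composition must have keys U, A, C, G, none")
        if any(p < 0 or p > 1 for p in probs.values()):
            raise ValueError("composition probabilities must lie in [0, 1]")
        if not math.isclose(sum(probs.values()), 1.0, abs_tol=1e-9):
            raise ValueError("composition probabilities must sum to 1")
        if self.u_support[0] < 1 or self.u_support[1] < self.u_support[0]:
            raise ValueError("u_support minimum must be >= 1 and ordered")

    def draw_u_length(self, rng: np.random.Generator) -> int:
        lo, hi = self.u_support
        while True:
            n = int(rng.poisson(self.u_median))
            if lo <= n <= hi:
                return n

    def draw_tail(self, rng: np.random.Generator) -> str:
        comps = ["U", "A", "C", "G", "none"]
        probs = [self.p_composition[c] for c in comps]
        comp = comps[rng.choice(len(comps), p=probs)]
        if comp == "none":
            return ""
        if comp == "U":
            return "T" * self.draw_u_length(rng)
        lo, hi = self.acg_support
        return comp * int(rng.integers(lo, hi + 1))


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def generate_reference(spec: ReferenceSpec) -> tuple[dict[str, str], list[GeneModel]]:
    """Build one contig and its gene models, deterministically for a seed.

    mRNAs get a two-exon structure (exon1 / intron / exon2) with a CDS from
    mid-exon1 to mid-exon2 so that 5'-fragments spanning exon 1 into intron 1
    — the unspliced-precursor signature — can be simulated.
    """
    rng = np.random.default_rng(spec.seed)
    categories = [c for c in DEFAULT_GENE_LENGTHS if spec.n_genes.get(c, 0) > 0]
    pieces: list[str] = [_random_seq(spec.spacer, spec.gc_content, rng)]
    pos = spec.spacer
    genes: list[GeneModel] = []
    for cat in categories:
        for i in range(spec.n_genes[cat]):
            lo, hi = spec.length_range(cat)
            glen = int(rng.integers(lo, hi + 1))
            strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
            seq = _random_seq(glen, spec.gc_content, rng)
            gene = GeneModel(
                gene_id=f"{cat}_{i + 1}",
                category=cat,
                contig=spec.contig,
                start=pos,
                end=pos + glen,
                strand=strand,
            )
            if cat == "mRNA":
                e1 = max(30, glen // 4)
                ilen = max(60, glen // 4)
                gene.exons = [(pos, pos + e1), (pos + e1 + ilen, pos + glen)]
                gene.cds = (pos + e1 // 2, pos + e1 + ilen + (glen - e1 - ilen) // 2)
            genes.append(gene)
            pieces.append(seq)
            pos += glen
            pieces.append(_random_seq(spec.spacer, spec.gc_content, rng))
            pos += spec.spacer

    contig_seq = "".join(pieces)

    # nested snoRNA-in-mRNA pairs: relabel part of an mRNA intron as a snoRNA
    mrnas = [g for g in genes if g.category == "mRNA" and g.introns()]
    for j in range(spec.nested_snorna_pairs):
        if j >= len(mrnas):
            break
        host = mrnas[j]
        istart, iend = host.introns()[0]
        slen = min(70, iend - istart - 4)
        genes.append(
            GeneModel(
                gene_id=f"snoRNA_nested_{j + 1}",
                category="snoRNA",
                contig=spec.contig,
                start=istart + 2,
                end=istart + 2 + slen,
                strand=host.strand,
            )
        )

    # duplicated loci: append verbatim copies so their reads multi-map
    for j in range(spec.duplicate_genes):
        if j >= len(genes):
            break
        src = genes[j]
        seq = contig_seq[src.start : src.end]
        start = len(contig_seq)
        contig_seq += seq + _random_seq(spec.spacer, spec.gc_content, rng)
        genes.append(
            GeneModel(
                gene_id=f"{src.gene_id}_copy",
                category=src.category,
                contig=spec.contig,
                start=start,
                end=start + len(seq),
                strand=src.strand,
            )
        )

    if spec.contig_length is not None:
        if len(contig_seq) > spec.contig_length:
            raise SizingError(
                f"genes + spacers need {len(contig_seq)} nt but contig_length is "
                f"{spec.contig_length}"
            )
        contig_seq += _random_seq(spec.contig_length - len(contig_seq), spec.gc_content, rng)

    return {spec.contig: contig_seq}, genes


def fragment_rnase_t1(
    sequence: str, cut_probability: float, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Partial RNase T1 digest: cuts immediately 3' of G with given probability.

    Returns (start, end) offsets into ``sequence``; fragments concatenate to
    the input. ``cut_probability=1`` cuts after every G; 0 leaves the input
    whole. Accepts RNA or DNA spelling (G is G either way).
    """
    if not sequence:
        raise ValueError("empty sequence")
    if not 0 <= cut_probability <= 1:
        raise ValueError("cut_probability must be in [0, 1]")
    seq = sequence.upper()
    cuts = [0]
    for i, base in enumerate(seq[:-1]):  # a cut after the last base is a no-op
        if base == "G" and rng.random() < cut_probability:
            cuts.append(i + 1)
    cuts.append(len(seq))
    return [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]


def add_tail(
    fragment: str,
    model: TailModel,
    downstream_context: str,
    rng: np.random.Generator,
    forced_tail: str | None = None,
) -> tuple[str, str]:
    """Append a non-templated tail; returns (read sequence, true tail in DNA).

    ``downstream_context`` (genomic bases 3' of the fragment, transcript
    orientation) is only consulted for the templated-junction bias; the truth
    tail is recorded exactly as appended regardless of coincidences with it.
    """
    if not fragment:
        raise ValueError("fragment must be non-empty")
    tail = forced_tail.replace("U", "T") if forced_tail is not None else model.draw_tail(rng)
    return fragment + tail, tail


@dataclass
class SimRead:
    read_id: str
    sequence: str
    locus_id: str
    category: str
    contig: str
    strand: str
    frag_start: int
    frag_end: int
    tail: str
    is_chimera: bool = False
    arm1: tuple[int, int] | None = None
    arm2: tuple[int, int] | None = None


def make_chimera(
    arm5_seq: str,
    arm3_seq: str,
    arm5_interval: tuple[int, int],
    arm3_interval: tuple[int, int],
) -> str:
    """Join two same-locus fragments 5'->3' into a hybrid read.

    Enforces the RNase T1 ligation geometry: the arms must be ordered and
    non-overlapping in transcript orientation and the 5' arm must end in G
    (the residue the enzyme leaves).
    """
    if arm5_interval[1] > arm3_interval[0]:
        raise ValueError("chimera arms must be ordered and non-overlapping")
    if not arm5_seq or arm5_seq[-1].upper() != "G":
        raise ValueError("5' arm must end in G (RNase T1 leaves 3'-terminal G)")
    return arm5_seq + arm3_seq


def _gene_sense_seq(contig_seq: str, gene: GeneModel) -> str:
    seq = contig_seq[gene.start : gene.end]
    return seq if gene.strand == "+" else revcomp(seq)


def _sense_to_genome(gene: GeneModel, s: int, e: int) -> tuple[int, int]:
    """Transcript-orientation offsets [s, e) -> genomic half-open interval."""
    if gene.strand == "+":
        return gene.start + s, gene.start + e
    return gene.end - e, gene.end - s


@dataclass
class SimulationResult:
    reads: list[SimRead]
    reference: dict[str, str]
    genes: list[GeneModel]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reads:
            rows.append(
                {
                    "read_id": r.read_id,
                    "locus_id": r.locus_id,
                    "category": r.category,
                    "contig": r.contig,
                    "strand": r.strand,
                    "frag_start": r.frag_start,
                    "frag_end": r.frag_end,
                    "tail": r.tail or ".",
                    "is_chimera": int(r.is_chimera),
                    "arm1_start": r.arm1[0] if r.arm1 else -1,
                    "arm1_end": r.arm1[1] if r.arm1 else -1,
                    "arm2_start": r.arm2[0] if r.arm2 else -1,
                    "arm2_end": r.arm2[1] if r.arm2 else -1,
                }
            )
        return pd.DataFrame(rows)

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "reads": out / "reads.fastq",
            "truth": out / "truth.tsv",
            "reference": out / "reference.fasta",
            "annotation": out / "annotation.gff3",
        }
        write_fastq([(r.read_id, r.sequence) for r in self.reads], paths["reads"])
        self.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
        write_fasta(self.reference, paths["reference"])
        write_gff3(self.genes, paths["annotation"])
        return paths


def _draw_fragment(
    sense: str,
    cut_probability: float,
    min_frag: int,
    max_frag: int,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """One gel-selectable RNase T1 fragment (sense-orientation offsets)."""
    for _ in range(10):
        frags = fragment_rnase_t1(sense, cut_probability, rng)
        ok = [f for f in frags if min_frag <= f[1] - f[0] <= max_frag]
        if ok:
            return ok[int(rng.integers(len(ok)))]
    # highly G-poor or G-dense digests: fall back to a gel-sized window
    # ending at the transcript 3' end (itself a natural fragment boundary)
    end = len(sense)
    hi = min(max_frag, end)
    lo = min(min_frag, hi)
    length = int(rng.integers(lo, hi + 1))
    return end - length, end


def simulate_clip_run(
    spec: ReferenceSpec,
    model: TailModel | None = None,
    n_reads: int = 1000,
    chimera_fraction: float = 0.0,
    seed: int = 0,
    cut_probability: float = 0.5,
    min_frag: int = 25,
    max_frag: int = 90,
    min_arm: int = 12,
    min_gap: int = 4,
    out_dir=None,
) -> SimulationResult:
    """Simulate a CLIP run; optionally write FASTQ/truth/reference/GFF3.

    Exactly ``round(n_reads * chimera_fraction)`` reads are chimeric
    (deterministic allocation: the first reads drawn). Fragments are 25-90 nt
    by default so reads stay within the gel-selected 20-110 nt envelope after
    tailing and remain alignable after T-trimming.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not 0 <= chimera_fraction <= 1:
        raise ValueError("chimera_fraction must be in [0, 1]")
    model = model or TailModel()
    rng = np.random.default_rng(seed)
    reference, genes = generate_reference(spec)
    contig_seq = reference[spec.contig]
    source_genes = [g for g in genes if not g.gene_id.endswith("_copy")] or genes
    if not source_genes:
        raise ValueError("reference has no genes to draw reads from")
    chimera_capable = [
        g for g in source_genes if g.length >= 2 * min_arm + min_gap + 2
    ]
    n_chimeric = round(n_reads * chimera_fraction)
    if n_chimeric and not chimera_capable:
        raise ValueError("no gene long enough to host chimeras")

    reads: list[SimRead] = []
    for i in range(n_reads):
        read_id = f"read{i:06d}"
        if i < n_chimeric:
            reads.append(
                _simulate_chimeric_read(
                    read_id, chimera_capable, contig_seq, model, rng, min_arm, min_gap
                )
            )
        else:
            gene = source_genes[int(rng.integers(len(source_genes)))]
            reads.append(
                _simulate_plain_read(
                    read_id, gene, contig_seq, model, rng,
                    cut_probability, min_frag, max_frag,
                )
            )
    result = SimulationResult(reads, reference, genes)
    if out_dir is not None:
        result.write(out_dir)
    return result


def _simulate_plain_read(
    read_id: str,
    gene: GeneModel,
    contig_seq: str,
    model: TailModel,
    rng: np.random.Generator,
    cut_probability: float,
    min_frag: int,
    max_frag: int,
) -> SimRead:
    sense = _gene_sense_seq(contig_seq, gene)
    s, e = _draw_fragment(sense, cut_probability, min_frag, max_frag, rng)
    tail_preview = model.draw_tail(rng)
    if (
        tail_preview
        and rng.random() < model.templated_junction_bias
        and e < len(sense)
    ):
        # nudge the 3' end so the next genomic base equals the tail base
        for back in range(0, max(0, min(10, e - s - min_frag + 1))):
            nxt = e - back
            if nxt < len(sense) and sense[nxt] == tail_preview[0]:
                e = nxt
                break
    frag = sense[s:e]
    read_seq, tail = add_tail(frag, model, sense[e : e + len(tail_preview)], rng,
                              forced_tail=tail_preview)
    g_start, g_end = _sense_to_genome(gene, s, e)
    return SimRead(
        read_id=read_id,
        sequence=read_seq,
        locus_id=gene.gene_id,
        category=gene.category,
        contig=gene.contig,
        strand=gene.strand,
        frag_start=g_start,
        frag_end=g_end,
        tail=tail,
    )


def _simulate_chimeric_read(
    read_id: str,
    candidates: Sequence[GeneModel],
    contig_seq: str,
    model: TailModel,
    rng: np.random.Generator,
    min_arm: int,
    min_gap: int,
) -> SimRead:
    for _ in range(200):
        gene = candidates[int(rng.integers(len(candidates)))]
        sense = _gene_sense_seq(contig_seq, gene)
        # arm1 must end in G with room for gap + arm2
        g_positions = [
            i for i, b in enumerate(sense)
            if b == "G"
            and i + 1 >= min_arm
            and len(sense) - (i + 1) >= min_gap + min_arm
        ]
        if not g_positions:
            continue
        g = g_positions[int(rng.integers(len(g_positions)))]
        a1_len = int(rng.integers(min_arm, min(35, g + 1) + 1))
        a1 = (g + 1 - a1_len, g + 1)
        # arm2's 5' end is itself an RNase T1 cut product: it starts just
        # 3' of a G
        b_lo = g + 1 + min_gap
        b_candidates = [
            b for b in range(b_lo, len(sense) - min_arm + 1) if sense[b - 1] == "G"
        ]
        if not b_candidates:
            continue
        b = b_candidates[int(rng.integers(len(b_candidates)))]
        a2_len = int(rng.integers(min_arm, min(35, len(sense) - b) + 1))
        a2 = (b, b + a2_len)
        arm5_seq, arm3_seq = sense[a1[0] : a1[1]], sense[a2[0] : a2[1]]
        read_core = make_chimera(arm5_seq, arm3_seq, a1, a2)
        read_seq, tail = add_tail(read_core, model, "", rng)
        if len(read_seq) > 110:
            continue
        arm1_g = _sense_to_genome(gene, a1[0], a1[1])
        arm2_g = _sense_to_genome(gene, a2[0], a2[1])
        return SimRead(
            read_id=read_id,
            sequence=read_seq,
            locus_id=gene.gene_id,
            category=gene.category,
            contig=gene.contig,
            strand=gene.strand,
            frag_start=min(arm1_g[0], arm2_g[0]),
            frag_end=max(arm1_g[1], arm2_g[1]),
            tail=tail,
            is_chimera=True,
            arm1=arm1_g,
            arm2=arm2_g,
        )
    raise RuntimeError("could not place a chimera; genes too short or G-poor")


def simulate_tss_anchor_calls(
    n_per_orientation: int,
    tss_sites: Sequence[tuple[str, int, str, str]],
    sense_mu: float = 50.0,
    antisense_mu: float = -200.0,
    sigma: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """U+ anchor calls placed at Gaussian offsets around TSS sites.

    Emulates the promoter-proximal short-RNA geometry: sense-strand 3' ends
    peaking downstream of the TSS, antisense 3' ends peaking upstream.
    Returns a tail-call-like frame consumable by the metagene profiler.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for orient, mu in (("sense", sense_mu), ("antisense", antisense_mu)):
        offsets = np.rint(rng.normal(mu, sigma, size=n_per_orientation)).astype(int)
        sites = [tss_sites[int(i)] for i in rng.integers(len(tss_sites), size=n_per_orientation)]
        for j, ((contig, pos, strand, _name), off) in enumerate(zip(sites, offsets)):
            anchor = pos + off if strand == "+" else pos - off
            read_strand = strand if orient == "sense" else ("-" if strand == "+" else "+")
            rows.append(
                {
                    "read_id": f"{orient}{j:06d}",
                    "contig": contig,
                    "anchor": int(anchor),
                    "strand": read_strand,
                    "comp_class": "U+",
                    "untemplated_length": 5,
                }
            )
    return pd.DataFrame(rows)
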