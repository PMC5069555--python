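"""Shared fixtures and truth-side helpers for the suite.

Truth evaluation helpers recompute expected quantities from the simulator's
ground truth and the raw reference sequence, independently of the pipeline's
internals.
"""

from __future__ import annotations

import pytest

from uridylome._seq import revcomp
from uridylome.annotate import AnnotationIndex
from uridylome.chimera import canonical_junction_shift
from uridylome.simclip import ReferenceSpec, SimRead, TailModel, simulate_clip_run
from uridylome.tailcall import ReferenceIndex

MIXED_GENES = {
    "tRNA": 4,
    "miRNA": 4,
    "snRNA": 3,
    "5S_rRNA": 2,
    "miscRNA": 3,
    "snoRNA": 3,
    "mRNA": 4,
    "lincRNA": 2,
}


def true_untemplated(read: SimRead, reference: dict[str, str]) -> str:
    """The part of a simulated read's true tail that the maximal-templated
    convention counts as untemplated: the tail minus its genome-matching
    prefix immediately 3' of the fragment (transcript orientation)."""
    seq = reference[read.contig]
    if read.strand == "+":
        downstream = seq[read.frag_end : read.frag_end + len(read.tail)]
    else:
        lo = max(0, read.frag_start - len(read.tail))
        downstream = revcomp(seq[lo : read.frag_start])
    overlap = 0
    for a, b in zip(read.tail, downstream):
        if a != b:
            break
        overlap += 1
    return read.tail[overlap:]


def truth_is_uplus(read: SimRead, reference: dict[str, str], min_u: int = 4) -> bool:
    """True when the untemplated part of the truth tail ends in >= min_u Ts."""
    tail = true_untemplated(read, reference)
    return tail.endswith("T" * min_u)


def canonical_truth_junction(
    read: SimRead,
    index: ReferenceIndex,
    genes,
    min_arm: int = 12,
) -> tuple[int, int]:
    """Truth junction of a simulated chimera in 1-based transcript
    coordinates of its locus, canonicalized by the shared junction
    normalisation (ambiguous G-run junctions have one representative)."""
    gene = next(g for g in genes if g.gene_id == read.locus_id)
    L = index.lengths[read.contig]
    strand_seq = index.strings[(read.contig, read.strand)]

    def to_strand_space(iv):
        return iv if read.strand == "+" else (L - iv[1], L - iv[0])

    s1, s2 = to_strand_space(read.arm1), to_strand_space(read.arm2)
    d = canonical_junction_shift(
        strand_seq, s1[1], s2[0], (s1[1] - s1[0]) - min_arm, (s2[1] - s2[0]) - min_arm
    )
    if gene.strand == "+":
        return read.arm1[1] - gene.start + d, read.arm2[0] - gene.start + 1 + d
    return gene.end - read.arm1[0] + d, gene.end - read.arm2[1] + 1 + d


@pytest.fixture(scope="session")
def mixed_sim():
    """A mid-sized seeded simulation with every category and a few chimeras."""
    spec = ReferenceSpec(n_genes=dict(MIXED_GENES), seed=42)
    return simulate_clip_run(
        spec, TailModel(), n_reads=2000, chimera_fraction=0.02, seed=42
    )


@pytest.fixture(scope="session")
def mixed_index(mixed_sim):
    return ReferenceIndex(mixed_sim.reference)


@pytest.fixture(scope="session")
def mixed_annotation(mixed_sim):
    return AnnotationIndex(mixed_sim.genes)
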