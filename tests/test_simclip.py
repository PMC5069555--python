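"""Simulator: determinism, digestion, tailing and truth-table guarantees."""

import filecmp

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import MIXED_GENES
from uridylome._seq import revcomp
from uridylome.gffio import write_fasta, write_gff3
from uridylome.simclip import (
    ReferenceSpec,
    SizingError,
    TailModel,
    add_tail,
    fragment_rnase_t1,
    generate_reference,
    make_chimera,
    simulate_clip_run,
)


class TestGenerateReference:
    def test_seeded_determinism(self, tmp_path):
        spec = ReferenceSpec(n_genes={"tRNA": 1}, gene_lengths={"tRNA": (72, 72)}, seed=42)
        out = []
        for run in ("a", "b"):
            ref, genes = generate_reference(spec)
            write_fasta(ref, tmp_path / f"{run}.fa")
            write_gff3(genes, tmp_path / f"{run}.gff3")
            out.append(run)
        assert filecmp.cmp(tmp_path / "a.fa", tmp_path / "b.fa", shallow=False)
        assert filecmp.cmp(tmp_path / "a.gff3", tmp_path / "b.gff3", shallow=False)

    def test_empty_spec_gives_spacer_only(self):
        ref, genes = generate_reference(ReferenceSpec(n_genes={}, spacer=250, seed=1))
        assert genes == []
        assert len(ref["simchr"]) == 250

    def test_every_requested_gene_present_with_one_category(self):
        spec = ReferenceSpec(n_genes=dict(MIXED_GENES), seed=3)
        ref, genes = generate_reference(spec)
        by_cat = {}
        for g in genes:
            by_cat.setdefault(g.category, []).append(g)
            assert 0 <= g.start < g.end <= len(ref["simchr"])
        for cat, n in MIXED_GENES.items():
            assert len(by_cat[cat]) == n

    def test_mrna_has_intron_and_tss(self):
        spec = ReferenceSpec(n_genes={"mRNA": 2}, seed=5)
        _, genes = generate_reference(spec)
        for g in genes:
            assert len(g.exons) >= 2 and g.introns()
            assert g.tss == g.start

    def test_nested_snorna_overlaps_host_intron(self):
        spec = ReferenceSpec(n_genes={"mRNA": 2}, nested_snorna_pairs=2, seed=6)
        _, genes = generate_reference(spec)
        snos = [g for g in genes if g.category == "snoRNA"]
        hosts = [g for g in genes if g.category == "mRNA"]
        assert len(snos) == 2
        for sno in snos:
            host = next(h for h in hosts if h.start <= sno.start < h.end)
            istart, iend = host.introns()[0]
            assert istart <= sno.start and sno.end <= iend

    def test_contig_length_too_small_raises(self):
        spec = ReferenceSpec(n_genes={"mRNA": 2}, contig_length=100, seed=1)
        with pytest.raises(SizingError):
            generate_reference(spec)


class TestFragmentRnaseT1:
    def test_cuts_after_every_g(self):
        frags = fragment_rnase_t1("AUGGAUC", 1.0, np.random.default_rng(0))
        pieces = ["AUGGAUC"[s:e] for s, e in frags]
        assert pieces == ["AUG", "G", "AUC"]

    def test_no_digestion_at_zero_probability(self):
        frags = fragment_rnase_t1("AUGGAUC", 0.0, np.random.default_rng(0))
        assert frags == [(0, 7)]

    def test_no_g_no_cuts(self):
        assert fragment_rnase_t1("CCCC", 1.0, np.random.default_rng(0)) == [(0, 4)]

    @settings(derandomize=True, max_examples=150)
    @given(
        st.text(alphabet="ACGU", min_size=1, max_size=80),
        st.floats(min_value=0, max_value=1),
        st.integers(min_value=0, max_value=10_000),
    )
    def test_fragments_concatenate_to_input(self, seq, p, seed):
        frags = fragment_rnase_t1(seq, p, np.random.default_rng(seed))
        assert "".join(seq[s:e] for s, e in frags) == seq
        for s, e in frags[:-1]:
            assert seq[e - 1].upper() == "G"


class TestAddTail:
    def test_forced_tail_is_recorded_exactly(self):
        read, tail = add_tail(
            "ACGTACGT", TailModel(), "", np.random.default_rng(0), forced_tail="UUUUUU"
        )
        assert read == "ACGTACGT" + "TTTTTT" and tail == "TTTTTT"

    def test_none_composition_leaves_fragment(self):
        model = TailModel(p_composition={"U": 0, "A": 0, "C": 0, "G": 0, "none": 1})
        read, tail = add_tail("ACGT", model, "", np.random.default_rng(0))
        assert read == "ACGT" and tail == ""

    def test_u_length_median_matches_configuration(self):
        model = TailModel()
        rng = np.random.default_rng(12)
        lengths = [model.draw_u_length(rng) for _ in range(10_000)]
        assert abs(np.median(lengths) - 7) <= 1
        assert min(lengths) >= 4 and max(lengths) <= 20

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            TailModel(p_composition={"U": 0.5, "A": 0.5, "C": 0.5, "G": 0, "none": 0})


class TestMakeChimera:
    def test_arm_concatenation(self):
        read = make_chimera("ACG", "TTA", (0, 3), (10, 13))
        assert read == "ACGTTA"

    def test_adjacent_arms_equal_contiguous_fragment(self):
        seq = "ACGTACGTAG" + "CCCCTTTTAA"
        read = make_chimera(seq[:10], seq[10:], (0, 10), (10, 20))
        assert read == seq

    def test_arm5_must_end_in_g(self):
        with pytest.raises(ValueError):
            make_chimera("ACGTC", "AAAA", (0, 5), (10, 14))

    def test_overlapping_arms_rejected(self):
        with pytest.raises(ValueError):
            make_chimera("ACG", "TTA", (0, 3), (2, 5))


class TestSimulateClipRun:
    def test_exact_chimera_allocation(self):
        spec = ReferenceSpec(n_genes={"snRNA": 3, "mRNA": 2}, seed=7)
        sim = simulate_clip_run(spec, TailModel(), n_reads=100, chimera_fraction=0.1, seed=7)
        truth = sim.truth_frame()
        assert len(truth) == 100
        assert int(truth["is_chimera"].sum()) == 10

    def test_single_read_run(self):
        spec = ReferenceSpec(n_genes={"snRNA": 1}, seed=2)
        sim = simulate_clip_run(spec, TailModel(), n_reads=1, seed=2)
        assert len(sim.reads) == 1 and len(sim.truth_frame()) == 1

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        spec = ReferenceSpec(n_genes={"snRNA": 2, "tRNA": 2}, seed=9)
        for d in ("run1", "run2"):
            simulate_clip_run(
                spec, TailModel(), n_reads=150, chimera_fraction=0.05, seed=9,
                out_dir=tmp_path / d,
            )
        for name in ("reads.fastq", "truth.tsv", "reference.fasta", "annotation.gff3"):
            assert filecmp.cmp(tmp_path / "run1" / name, tmp_path / "run2" / name, shallow=False)

    def test_read_lengths_within_envelope(self, mixed_sim):
        for r in mixed_sim.reads:
            assert 20 <= len(r.sequence) <= 110

    def test_sequence_conservation(self, mixed_sim):
        """Stripping the truth tail recovers the reference substring at the
        recorded fragment coordinates (non-chimeric reads)."""
        ref = mixed_sim.reference["simchr"]
        for r in mixed_sim.reads:
            if r.is_chimera:
                continue
            core = r.sequence[: len(r.sequence) - len(r.tail)]
            expected = ref[r.frag_start : r.frag_end]
            if r.strand == "-":
                expected = revcomp(expected)
            assert core == expected

    def test_chimera_truth_geometry(self, mixed_sim):
        ref = mixed_sim.reference["simchr"]
        for r in mixed_sim.reads:
            if not r.is_chimera:
                continue
            a1, a2 = r.arm1, r.arm2
            assert a1[1] <= a2[0] or a2[1] <= a1[0]  # non-overlapping
            arm5 = a1 if r.strand == "+" else a2
            seq5 = ref[arm5[0] : arm5[1]]
            terminal = seq5[-1] if r.strand == "+" else revcomp(seq5)[-1]
            assert terminal == "G"

    def test_composition_frequencies_recovered(self):
        """Empirical tail-composition frequencies within 3 SE of the model."""
        spec = ReferenceSpec(n_genes=dict(MIXED_GENES), seed=21)
        model = TailModel()
        sim = simulate_clip_run(spec, model, n_reads=10_000, seed=21)
        n = len(sim.reads)
        tallies = {"U": 0, "A": 0, "C": 0, "G": 0, "none": 0}
        for r in sim.reads:
            if not r.tail:
                tallies["none"] += 1
            else:
                base = r.tail[0]
                tallies["U" if base == "T" else base] += 1
        for comp, p in model.p_composition.items():
            se = (p * (1 - p) / n) ** 0.5
            assert abs(tallies[comp] / n - p) <= 3 * se + 1e-9

    def test_chimera_fraction_out_of_range(self):
        spec = ReferenceSpec(n_genes={"snRNA": 1}, seed=2)
        with pytest.raises(ValueError):
            simulate_clip_run(spec, TailModel(), n_reads=10, chimera_fraction=1.5, seed=2)
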