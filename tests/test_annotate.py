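"""Priority annotation, gene-model positioning and 3'-end states."""

import io

import numpy as np
import pytest

from uridylome.annotate import (
    AnnotationIndex,
    assign_region,
    classify_end_state,
    end_state_tally,
    load_annotation,
    three_prime_offset,
    trna_subregion,
)
from uridylome.gffio import (
    AnnotationParseError,
    GeneModel,
    PRIORITY_ORDER,
    parse_gff3,
)
from uridylome.tailcall import TailCall


def make_gene(gene_id, category, start, end, strand="+", **kw):
    return GeneModel(gene_id, category, "chr1", start, end, strand, **kw)


class TestLoadAnnotation:
    def test_gff3_one_based_conversion(self):
        gff = "##gff-version 3\nchr1\tsrc\tsnRNA\t100\t199\t.\t+\t.\tID=g1\n"
        genes = parse_gff3(io.StringIO(gff))
        assert (genes[0].start, genes[0].end) == (99, 199)

    def test_trna_query_interval_extended_60(self):
        index = AnnotationIndex([make_gene("t1", "tRNA", 1000, 1072)])
        assert index.query_interval(index.genes["t1"]) == (940, 1132)
        # a read entirely in the extension still annotates to the tRNA
        assert index.assign_category("chr1", 1080, 1110, "+") == ("t1", "tRNA")

    def test_empty_annotation_annotates_nothing(self):
        index = AnnotationIndex([])
        assert index.assign_category("chr1", 0, 100, "+") is None

    def test_unknown_category_rejected_with_listing(self):
        gff = "chr1\tsrc\tgene\t1\t50\t.\t+\t.\tID=g1;category=ribozyme\n"
        with pytest.raises(AnnotationParseError, match="accepted"):
            parse_gff3(io.StringIO(gff))

    def test_malformed_coordinates_report_line_number(self):
        gff = "chr1\tsrc\tsnRNA\t10\t5\t.\t+\t.\tID=g1\n"
        with pytest.raises(AnnotationParseError, match="line 1"):
            parse_gff3(io.StringIO(gff))

    def test_bed_loading(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t100\t200\tg1:miRNA\t0\t+\n")
        index = load_annotation(bed)
        assert index.genes["g1"].category == "miRNA"


class TestPriority:
    @pytest.mark.parametrize("hi_idx", range(len(PRIORITY_ORDER) - 1))
    def test_each_category_beats_all_lower(self, hi_idx):
        hi = PRIORITY_ORDER[hi_idx]
        for lo in PRIORITY_ORDER[hi_idx + 1 :]:
            index = AnnotationIndex(
                [make_gene("hi", hi, 100, 200), make_gene("lo", lo, 100, 200)]
            )
            assert index.assign_category("chr1", 120, 160, "+") == ("hi", hi)

    def test_intronic_snorna_beats_host_mrna(self):
        host = make_gene("host", "mRNA", 0, 1000, exons=[(0, 200), (700, 1000)])
        sno = make_gene("sno", "snoRNA", 300, 380)
        index = AnnotationIndex([host, sno])
        assert index.assign_category("chr1", 310, 350, "+") == ("sno", "snoRNA")

    def test_trna_trailer_beats_mrna(self):
        index = AnnotationIndex(
            [make_gene("t1", "tRNA", 1000, 1072), make_gene("m1", "mRNA", 1050, 3000)]
        )
        # read 40 nt downstream of the mature tRNA end, inside the extension
        assert index.assign_category("chr1", 1110, 1130, "+") == ("t1", "tRNA")

    def test_same_category_tie_largest_overlap_then_id(self):
        index = AnnotationIndex(
            [make_gene("a", "snRNA", 100, 160), make_gene("b", "snRNA", 100, 300)]
        )
        assert index.assign_category("chr1", 120, 250, "+")[0] == "b"
        index2 = AnnotationIndex(
            [make_gene("b2", "snRNA", 100, 200), make_gene("a2", "snRNA", 100, 200)]
        )
        assert index2.assign_category("chr1", 120, 150, "+")[0] == "a2"

    def test_strand_specific(self):
        index = AnnotationIndex([make_gene("g", "snRNA", 100, 200, "+")])
        assert index.assign_category("chr1", 120, 150, "-") is None

    def test_no_overlap_unannotated(self):
        index = AnnotationIndex([make_gene("g", "snRNA", 100, 200)])
        assert index.assign_category("chr1", 500, 540, "+") is None


class TestAssignRegion:
    def test_extension_offset_plus_strand(self):
        gene = make_gene("g", "snRNA", 100, 200)
        ra = assign_region(214, gene)  # 15 nt past the last mature base (199)
        assert ra.region == "3' extension" and ra.offset == 15

    def test_mature_end_is_offset_zero(self):
        gene = make_gene("g", "snRNA", 100, 200)
        ra = assign_region(199, gene)
        assert ra.region == "mature" and ra.offset == 0

    def test_minus_strand_offsets_mirror(self):
        gene = make_gene("g", "snRNA", 100, 200, "-")
        assert three_prime_offset(100, gene) == 0
        assert three_prime_offset(85, gene) == 15
        assert assign_region(85, gene).region == "3' extension"
        assert assign_region(210, gene).region == "5' leader"

    def test_intronic_anchor_flags_unspliced_precursor(self):
        gene = make_gene(
            "m", "mRNA", 0, 1000, exons=[(0, 200), (700, 1000)], cds=(100, 850)
        )
        ra = assign_region(350, gene)
        assert ra.mrna_subfeature == "intron"
        assert assign_region(50, gene).mrna_subfeature == "5'UTR"
        assert assign_region(150, gene).mrna_subfeature == "CDS"
        assert assign_region(900, gene).mrna_subfeature == "3'UTR"

    def test_region_partition_no_gaps_or_overlaps(self):
        rng = np.random.default_rng(4)
        for strand in "+-":
            gene = make_gene("g", "snRNA", 500, 700, strand)
            for anchor in range(440, 760):
                ra = assign_region(anchor, gene)
                assert ra.region in ("5' leader", "mature", "3' extension")
                rel5 = (anchor - 500) if strand == "+" else (699 - anchor)
                if rel5 < 0:
                    assert ra.region == "5' leader"
                elif rel5 < 200:
                    assert ra.region == "mature"
                else:
                    assert ra.region == "3' extension"


class TestTrnaSubregion:
    @pytest.fixture()
    def trna(self):
        return make_gene("t", "tRNA", 1000, 1076)

    def test_downstream_is_three_prime_trailer(self, trna):
        assert trna_subregion(1081, trna) == "3' trailer"

    def test_80_percent_is_t_loop(self, trna):
        assert trna_subregion(1000 + int(0.8 * 76), trna) == "T-loop"

    def test_upstream_is_five_prime_trailer(self, trna):
        assert trna_subregion(990, trna) == "5' trailer"

    def test_out_of_range_raises(self, trna):
        with pytest.raises(ValueError):
            trna_subregion(1076 + 61, trna)

    def test_every_position_has_exactly_one_label(self, trna):
        labels = {
            "5' trailer", "acceptor stem", "D-arm", "anticodon arm",
            "T-loop", "3' trailer",
        }
        for pos in range(1000 - 60, 1076 + 60):
            assert trna_subregion(pos, trna) in labels


class TestEndStates:
    def test_trichotomy(self):
        assert classify_end_state(0) == "Mat"
        assert classify_end_state(-3) == "Trim"
        assert classify_end_state(12) == "ext"

    def test_tally_counts_states_and_uplus(self):
        gene = make_gene("g", "snRNA", 100, 200)
        index = AnnotationIndex([gene])
        calls = [
            TailCall("r1", "chr1", 199, "+", "", 0, "", "none", "none", "g", "snRNA"),
            TailCall("r2", "chr1", 196, "+", "", 0, "", "none", "none", "g", "snRNA"),
            TailCall("r3", "chr1", 211, "+", "TTTTT", 0, "TTTTT", "U+", "remainder", "g", "snRNA"),
        ]
        tally = end_state_tally(calls, index)
        row = tally.set_index("gene_id").loc["g"]
        assert (row["Mat"], row["Trim"], row["ext"], row["plus_U"]) == (1, 1, 1, 1)

    def test_no_reads_gives_empty_tally(self):
        index = AnnotationIndex([make_gene("g", "snRNA", 100, 200)])
        assert end_state_tally([], index).empty

    def test_extended_uridylated_fraction_recovered(self, mixed_sim, mixed_index, mixed_annotation):
        """End states computed from annotated simulated calls are internally
        consistent: every annotated call lands in exactly one state."""
        from uridylome.annotate import annotate_calls
        from uridylome.tailcall import call_tails, two_pass_map

        res = two_pass_map([(r.read_id, r.sequence) for r in mixed_sim.reads], mixed_index)
        calls = call_tails(res, mixed_index)
        annotate_calls(calls, mixed_annotation, res.alignments)
        tally = end_state_tally(calls, mixed_annotation)
        annotated = [c for c in calls if c.gene_id]
        assert tally[["Mat", "Trim", "ext"]].to_numpy().sum() == len(annotated)
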