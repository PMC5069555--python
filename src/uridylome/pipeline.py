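"""End-to-end orchestration: simulate -> map -> call -> annotate -> profile.

A run is fully determined by (config, seed): the manifest snapshots the
normalised config, input checksums, per-stage read counts and the tool
version, and two runs with identical config + seed produce byte-identical
TSV outputs. External alignments (SAM/BAM from a production aligner) can
replace the built-in mapper: 3' soft-clipped segments become
remainders, secondary/supplementary records are dropped, and uniqueness is
taken from mapping quality.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pysam

from . import __version__
from .annotate import AnnotationIndex, annotate_calls, end_state_tally, load_annotation
from .chimera import chimera_frame, detect_chimera, write_chimera_bed12
from .config import PipelineConfig, SimulateConfig, load_config, validate_config
from .gffio import read_fasta, read_reads, read_tss_bed
from .profiles import (
    scaled_coverage,
    tail_length_histogram,
    tss_metagene,
    overlay_signal_track,
    uplus_fraction_by_category,
    write_profiles,
)
from .simclip import ReferenceSpec, SimulationResult, TailModel, simulate_clip_run
from .tailcall import (
    AlignmentRecord,
    ReferenceIndex,
    TwoPassResult,
    call_tails,
    two_pass_map,
    write_anchor_bed,
    write_tail_calls,
)

logger = logging.getLogger(__name__)


class PreflightError(ValueError):
    """Missing or inconsistent inputs, all reported at once."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("pre-flight failed:\n  - " + "\n  - ".join(problems))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def import_alignments(
    sam_path,
    index: ReferenceIndex,
    min_mapq: int = 20,
) -> dict[str, AlignmentRecord]:
    """AlignmentRecords from an external SAM/BAM file.

    The 3' soft clip (CIGAR end for plus-strand records, CIGAR start for
    minus-strand, where the read's 3' end sits leftmost in genome space)
    becomes the tail remainder. Uniqueness is MAPQ >= ``min_mapq``.
    """
    out: dict[str, AlignmentRecord] = {}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        header_contigs = set(fh.references or ())
        missing = header_contigs - set(index.lengths)
        if missing:
            raise ValueError(
                f"SAM header contigs absent from the reference: {sorted(missing)}"
            )
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            seq = rec.query_sequence or ""
            cigar = rec.cigartuples or []
            strand = "-" if rec.is_reverse else "+"
            # soft clip at the read's 3' end
            if strand == "+":
                clip = cigar[-1][1] if cigar and cigar[-1][0] == 4 else 0
                remainder = seq[len(seq) - clip :] if clip else ""
            else:
                clip = cigar[0][1] if cigar and cigar[0][0] == 4 else 0
                # query_sequence is genome-forward; the read's 3' tail is the
                # reverse complement of the leading clipped bases
                from ._seq import revcomp

                remainder = revcomp(seq[:clip]) if clip else ""
            span = len(seq) - clip
            out[rec.query_name] = AlignmentRecord(
                read_id=rec.query_name,
                contig=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand=strand,
                span=span,
                remainder=remainder,
                mapping_pass=1,
                trimmed_t_count=int(rec.get_tag("XT")) if rec.has_tag("XT") else 0,
                unique=(rec.mapping_quality or 0) >= min_mapq,
                score=span,
                n_mismatch=0,
            )
    return out


def write_sam(
    result: TwoPassResult,
    reads: dict[str, str],
    index: ReferenceIndex,
    path,
) -> None:
    """Write the native aligner's unique alignments as SAM (external style).

    Remainders become 3' soft clips; the pass-2 trimmed-T count is kept in
    the ``XT`` tag so the imported path can reconstruct raw tails.
    """
    names = sorted(index.lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": index.lengths[n]} for n in names],
    }
    from ._seq import revcomp

    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rid in sorted(result.alignments):
            aln = result.alignments[rid]
            if not aln.unique:
                continue
            seq = reads[rid]
            trimmed_seq = seq[: len(seq) - aln.trimmed_t_count] if aln.trimmed_t_count else seq
            a = pysam.AlignedSegment(fh.header)
            a.query_name = rid
            a.reference_id = names.index(aln.contig)
            a.reference_start = aln.start
            a.mapping_quality = 60
            clip = len(trimmed_seq) - aln.span
            if aln.strand == "+":
                a.query_sequence = trimmed_seq
                cigar = [(0, aln.span)] + ([(4, clip)] if clip else [])
            else:
                a.flag = 16
                a.query_sequence = revcomp(trimmed_seq)
                cigar = ([(4, clip)] if clip else []) + [(0, aln.span)]
            a.cigartuples = cigar
            a.set_tag("XT", aln.trimmed_t_count)
            fh.write(a)


def _preflight(cfg: PipelineConfig) -> None:
    problems = []
    if cfg.simulate is None:
        if cfg.reads is None:
            problems.append("no reads: set 'reads' or a 'simulate' section")
        elif not Path(cfg.reads).exists():
            problems.append(f"reads file not found: {cfg.reads}")
        if cfg.reference is None:
            problems.append("no reference: set 'reference' or a 'simulate' section")
        elif not Path(cfg.reference).exists():
            problems.append(f"reference file not found: {cfg.reference}")
        if cfg.annotation is not None and not Path(cfg.annotation).exists():
            problems.append(f"annotation file not found: {cfg.annotation}")
    for key in ("alignments", "tss", "signal_track"):
        val = getattr(cfg, key)
        if val is not None and not Path(val).exists():
            problems.append(f"{key} file not found: {val}")
    if problems:
        raise PreflightError(problems)


def run_pipeline(config, out_dir, seed: int | None = None) -> dict:
    """Run every stage and return the manifest (also written as JSON).

    ``config`` may be a path to YAML, a raw mapping, or a PipelineConfig.
    A stage failure keeps prior outputs and marks the failed stage in the
    manifest before re-raising.
    """
    if isinstance(config, PipelineConfig):
        cfg = config
    elif isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = validate_config(config)
    if seed is not None:
        cfg.seed = seed
    _preflight(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "uridylome",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "inputs": {},
        "counts": {},
        "outputs": {},
        "failed_stage": None,
    }
    stage = "setup"
    try:
        # --- inputs (simulated or loaded) -------------------------------
        stage = "simulate" if cfg.simulate is not None else "load"
        truth_frame = None
        if cfg.simulate is not None:
            sim = _run_simulation(cfg.simulate, cfg.seed, out / "sim")
            reference, genes = sim.reference, sim.genes
            reads = [(r.read_id, r.sequence) for r in sim.reads]
            truth_frame = sim.truth_frame()
            ann_index = AnnotationIndex(genes, cfg.annotate.trna_extension)
            for name in ("reads", "truth", "reference", "annotation"):
                manifest["inputs"][name] = _sha256(out / "sim" / {
                    "reads": "reads.fastq", "truth": "truth.tsv",
                    "reference": "reference.fasta", "annotation": "annotation.gff3",
                }[name])
        else:
            reference = read_fasta(cfg.reference)
            reads = read_reads(cfg.reads)
            manifest["inputs"]["reads"] = _sha256(Path(cfg.reads))
            manifest["inputs"]["reference"] = _sha256(Path(cfg.reference))
            ann_index = None
            if cfg.annotation:
                ann_index = load_annotation(
                    cfg.annotation, trna_extension=cfg.annotate.trna_extension
                )
                manifest["inputs"]["annotation"] = _sha256(Path(cfg.annotation))
        index = ReferenceIndex(reference, k=cfg.tailcall.seed_k)

        # --- mapping ----------------------------------------------------
        stage = "map"
        if cfg.alignments:
            imported = import_alignments(cfg.alignments, index, cfg.min_mapq)
            result = TwoPassResult(
                alignments={r: a for r, a in imported.items() if a.unique},
                categories={
                    rid: ("pass1" if rid in imported and imported[rid].unique else "unmapped")
                    for rid, _ in reads
                },
                multimapped={r for r, a in imported.items() if not a.unique},
            )
            manifest["inputs"]["alignments"] = _sha256(Path(cfg.alignments))
        else:
            result = two_pass_map(reads, index, cfg.tailcall)
        counts = result.counts()
        logger.info("mapping: %s", counts)

        # --- tail calling -----------------------------------------------
        stage = "call-tails"
        calls = call_tails(result, index, cfg.tailcall)

        # --- chimeras ---------------------------------------------------
        stage = "chimeras"
        candidate_ids = {
            rid for rid, cat in result.categories.items() if cat == "unmapped"
        } - result.multimapped
        # a hybrid whose upstream arm dominates can map "contiguously" with
        # the downstream arm left as a long remainder; re-examine any call
        # whose untemplated part could hide an arm
        candidate_ids |= {
            c.read_id
            for c in calls
            if c.untemplated_length >= cfg.chimera.min_arm
        }
        read_seq = dict(reads)
        chimeras = []
        for rid in sorted(candidate_ids):
            call = detect_chimera(
                rid, read_seq[rid], index, ann_index, cfg.chimera, cfg.tailcall,
            )
            if call is not None and not call.inter_locus:
                chimeras.append(call)
        chimera_frame(chimeras).to_csv(out / "chimeras.tsv", sep="\t", index=False)
        write_chimera_bed12(chimeras, out / "chimeras.bed12")
        counts["chimeric"] = len(chimeras)
        # a read in the hybrid table is explained as two arms; its
        # contiguous tail call (anchored at the upstream arm) is superseded
        chimeric_ids = {c.read_id for c in chimeras}
        calls = [c for c in calls if c.read_id not in chimeric_ids]
        write_tail_calls(calls, out / "tail_calls.tsv", cfg.tailcall)
        write_anchor_bed(calls, out / "tail_anchors.bed")
        counts["unique_calls"] = len(calls)
        counts["uplus"] = sum(c.uplus for c in calls)

        # --- annotation -------------------------------------------------
        stage = "annotate"
        if ann_index is not None:
            annotated = annotate_calls(
                calls, ann_index, result.alignments, cfg.annotate.min_overlap
            )
            annotated.to_csv(out / "tail_calls_annotated.tsv", sep="\t", index=False)
            tally = end_state_tally(calls, ann_index)
            tally.to_csv(out / "end_states.tsv", sep="\t", index=False)
        else:
            annotated = None

        # --- profiles ---------------------------------------------------
        stage = "profiles"
        frame = annotated if annotated is not None else None
        hist = tail_length_histogram(
            frame if frame is not None else _calls_only_frame(calls)
        )
        uplus_tab = uplus_fraction_by_category(frame) if frame is not None else None
        coverage = None
        metagene = None
        if frame is not None and ann_index is not None:
            cov_reads = _coverage_frame(frame, result.alignments)
            coverage = scaled_coverage(cov_reads, ann_index.genes, cfg.profiles.bins)
            tss_sites = (
                read_tss_bed(cfg.tss)
                if cfg.tss
                else [
                    (g.contig, g.tss, g.strand, g.gene_id)
                    for g in ann_index.genes.values()
                    if g.category == "mRNA"
                ]
            )
            if tss_sites:
                metagene = tss_metagene(
                    frame, tss_sites, cfg.profiles.tss_window, cfg.profiles.smooth
                )
                if cfg.signal_track:
                    overlay_signal_track(metagene, cfg.signal_track, tss_sites)
        written = write_profiles(
            out / "profiles", hist, uplus_tab, coverage, metagene, plots=cfg.plots
        )
        manifest["outputs"].update(written)

        # --- summary ----------------------------------------------------
        stage = "summary"
        n_reads = len(reads)
        summary = {
            "n_reads": n_reads,
            "pct_unmapped_pass1": 100.0 * (n_reads - counts["pass1"]) / n_reads,
            "pct_uplus_of_unique": (
                100.0 * counts["uplus"] / counts["unique_calls"]
                if counts["unique_calls"]
                else 0.0
            ),
            "category_shares_uplus": _uplus_shares(frame),
            "counts": counts,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        manifest["counts"] = counts
        for name in ("tail_calls.tsv", "tail_anchors.bed", "chimeras.tsv", "summary.json"):
            p = out / name
            if p.exists():
                manifest["outputs"][name] = _sha256(p)
        if truth_frame is not None:
            manifest["counts"]["truth_chimeric"] = int(truth_frame["is_chimera"].sum())
    except Exception:
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _run_simulation(sim_cfg: SimulateConfig, seed: int, out_dir) -> SimulationResult:
    ref_kwargs = dict(sim_cfg.reference)
    ref_kwargs.setdefault(
        "n_genes",
        {
            "tRNA": 4, "miRNA": 4, "snRNA": 3, "5S_rRNA": 2, "miscRNA": 3,
            "snoRNA": 3, "mRNA": 4, "lincRNA": 2,
        },
    )
    ref_kwargs.setdefault("seed", seed)
    ref_kwargs.setdefault("minus_strand_fraction", sim_cfg.minus_strand_fraction)
    spec = ReferenceSpec(**ref_kwargs)
    model = TailModel(**sim_cfg.tail_model) if sim_cfg.tail_model else TailModel()
    return simulate_clip_run(
        spec,
        model,
        n_reads=sim_cfg.n_reads,
        chimera_fraction=sim_cfg.chimera_fraction,
        seed=seed,
        cut_probability=sim_cfg.cut_probability,
        out_dir=out_dir,
    )


def _calls_only_frame(calls):
    from .tailcall import calls_to_frame

    return calls_to_frame(calls)


def _coverage_frame(frame, alignments):
    df = frame[frame["gene_id"].astype(str) != "."].copy()
    starts, ends = [], []
    for rid in df["read_id"]:
        aln = alignments.get(rid)
        starts.append(aln.start if aln else 0)
        ends.append(aln.end if aln else 0)
    df["start"] = starts
    df["end"] = ends
    return df


def _uplus_shares(frame) -> dict[str, float]:
    if frame is None:
        return {}
    up = frame[(frame["comp_class"] == "U+") & (frame["category"].astype(str) != ".")]
    if up.empty:
        return {}
    shares = up.groupby("category").size() / len(up) * 100.0
    return {str(k): float(v) for k, v in shares.sort_index().items()}
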