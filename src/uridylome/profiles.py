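"""Positional summaries: tail histograms, scaled coverage, TSS metagenes.

These are the presentation-layer statistics of the analysis: length
histograms of untemplated homopolymer tails per composition class and RNA
category, the percentage of U+ reads per category, gene-body coverage with
every mature RNA scaled to 100 bins (row-normalised heatmap input), and
strand-resolved metagene profiles of U+ read 3' ends around mRNA TSSs with
peak localisation after light smoothing. Every plot has a TSV twin so the
numbers are testable headless; figures are produced with matplotlib (Agg).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gffio import GeneModel, read_bedgraph

logger = logging.getLogger(__name__)


@dataclass
class TailHistogram:
    """Length distribution of untemplated tails for one group."""

    group: tuple
    counts: dict[int, int]
    median: float | None
    q1: float | None
    q3: float | None

    @property
    def n(self) -> int:
        return sum(self.counts.values())


def tail_length_histogram(
    calls: pd.DataFrame,
    by: Sequence[str] = ("comp_class",),
    length_col: str = "untemplated_length",
) -> dict[tuple, TailHistogram]:
    """One histogram of untemplated tail lengths per group.

    Groups with no calls simply do not appear; medians/quartiles are None
    for empty inputs. Counts conserve the number of calls per group.
    """
    out: dict[tuple, TailHistogram] = {}
    if calls.empty:
        return out
    for key, sub in calls.groupby(list(by), sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        lengths = sub[length_col].astype(int)
        lengths = lengths[lengths > 0]
        if lengths.empty:
            counts, med = {}, None
            q1 = q3 = None
        else:
            counts = lengths.value_counts().sort_index().to_dict()
            med = float(lengths.median())
            q1 = float(lengths.quantile(0.25))
            q3 = float(lengths.quantile(0.75))
        out[key] = TailHistogram(key, counts, med, q1, q3)
    return out


def histogram_frame(histograms: Mapping[tuple, TailHistogram]) -> pd.DataFrame:
    rows = []
    for key, h in sorted(histograms.items()):
        for length, count in sorted(h.counts.items()):
            rows.append({"group": "|".join(map(str, key)), "length": length, "count": count})
    return pd.DataFrame(rows, columns=["group", "length", "count"])


def uplus_fraction_by_category(calls: pd.DataFrame) -> pd.DataFrame:
    """Percentage of U+ reads per functional category, with denominators.

    Unannotated calls (empty category) are excluded; categories with zero
    reads never appear (a note is logged per excluded category).
    """
    df = calls[calls["category"].astype(str).isin(["", "."]) == False]  # noqa: E712
    if df.empty:
        return pd.DataFrame(columns=["category", "n_reads", "n_uplus", "pct_uplus"])
    rows = []
    for cat, sub in df.groupby("category", sort=True):
        n = len(sub)
        n_u = int((sub["comp_class"] == "U+").sum())
        rows.append(
            {"category": cat, "n_reads": n, "n_uplus": n_u, "pct_uplus": 100.0 * n_u / n}
        )
    dropped = set(calls["category"].astype(str)) - {r["category"] for r in rows}
    for cat in sorted(dropped - {"", "."}):
        logger.info("category %s has no reads after filtering; excluded", cat)
    return pd.DataFrame(rows, columns=["category", "n_reads", "n_uplus", "pct_uplus"])


def scaled_coverage(
    reads: pd.DataFrame,
    genes: Mapping[str, GeneModel],
    bins: int = 100,
    mode: str = "coverage",
) -> pd.DataFrame:
    """Gene x bin matrix of read signal over the mature body, rows scaled.

    Each mature RNA is scaled to ``bins`` bins (bin ``bins-1`` abuts the
    mature 3' end on either strand). ``reads`` needs gene_id plus start/end
    (coverage mode) or anchor (anchor-density mode). Rows with any signal are
    normalised to a maximum of exactly 1.
    """
    if mode not in ("coverage", "anchor"):
        raise ValueError("mode must be 'coverage' or 'anchor'")
    order = sorted({g for g in reads["gene_id"] if g in genes})
    mat = np.zeros((len(order), bins), dtype=float)
    row_of = {g: i for i, g in enumerate(order)}
    for _, rec in reads.iterrows():
        gid = rec["gene_id"]
        if gid not in row_of:
            continue
        gene = genes[gid]
        M = gene.length
        if M <= 0:
            raise ValueError(f"{gid}: zero-length gene")
        if mode == "anchor":
            positions = [int(rec["anchor"])]
        else:
            positions = range(max(int(rec["start"]), gene.start), min(int(rec["end"]), gene.end))
        for pos in positions:
            if gene.strand == "+":
                rel = pos - gene.start
            else:
                rel = gene.end - 1 - pos
            if 0 <= rel < M:
                mat[row_of[gid], min(bins * rel // M, bins - 1)] += 1
    maxima = mat.max(axis=1)
    nonzero = maxima > 0
    mat[nonzero] /= maxima[nonzero, None]
    return pd.DataFrame(mat, index=order, columns=[f"bin{i + 1}" for i in range(bins)])


@dataclass
class MetageneProfile:
    """Strand-resolved positional counts of U+ 3' ends around TSSs."""

    offsets: np.ndarray  # contiguous, negative = upstream of the TSS
    sense: np.ndarray
    antisense: np.ndarray
    smooth: int = 5
    overlay: np.ndarray | None = None
    skipped_tss: int = 0

    def smoothed(self, track: np.ndarray) -> np.ndarray:
        if self.smooth <= 1:
            return track.astype(float)
        kernel = np.ones(self.smooth) / self.smooth
        return np.convolve(track, kernel, mode="same")

    def peak(self, orientation: str) -> int | None:
        """Offset of the smoothed maximum; None for an empty profile."""
        track = self.sense if orientation == "sense" else self.antisense
        if track.sum() == 0:
            return None
        sm = self.smoothed(track)
        return int(self.offsets[int(np.argmax(sm))])

    def frame(self) -> pd.DataFrame:
        data = {
            "offset": self.offsets,
            "sense": self.sense,
            "antisense": self.antisense,
        }
        if self.overlay is not None:
            data["overlay"] = self.overlay
        return pd.DataFrame(data)


def tss_metagene(
    calls: pd.DataFrame,
    tss_sites: Sequence[tuple[str, int, str, str]],
    window: int = 500,
    smooth: int = 5,
    uplus_only: bool = True,
) -> MetageneProfile:
    """Metagene of U+ read 3' anchors around TSSs.

    Each call contributes one count at the offset of its 3' anchor from the
    nearest TSS (signed along the TSS strand: downstream positive, upstream
    negative). Calls on the TSS strand feed the sense profile, the others
    the antisense profile; an antisense read's 3' end upstream of the TSS
    therefore lands at a negative offset.
    """
    if not tss_sites:
        raise ValueError("TSS list is empty")
    offsets = np.arange(-window, window + 1)
    sense = np.zeros(offsets.size, dtype=int)
    antisense = np.zeros(offsets.size, dtype=int)
    df = calls[calls["comp_class"] == "U+"] if uplus_only else calls
    by_contig: dict[str, list[tuple[int, str]]] = {}
    for contig, pos, strand, _name in tss_sites:
        by_contig.setdefault(contig, []).append((pos, strand))
    if df.empty:
        return MetageneProfile(offsets, sense, antisense, smooth=smooth)
    for contig, sub in df.groupby("contig"):
        sites = by_contig.get(str(contig))
        if not sites:
            continue
        sites.sort()
        pos = np.array([p for p, _ in sites])
        tss_strand = np.array([s for _, s in sites])
        anchors = sub["anchor"].to_numpy(dtype=int)
        read_strand = sub["strand"].to_numpy(dtype=object)
        # nearest TSS by anchor position
        right = np.searchsorted(pos, anchors)
        cand = np.clip(np.stack([right - 1, right]), 0, pos.size - 1)
        dists = np.abs(anchors[None, :] - pos[cand])
        pick = cand[np.argmin(dists, axis=0), np.arange(anchors.size)]
        t_pos, t_strand = pos[pick], tss_strand[pick]
        off = np.where(t_strand == "+", anchors - t_pos, t_pos - anchors)
        in_win = (off >= -window) & (off <= window)
        is_sense = read_strand == t_strand
        np.add.at(sense, off[in_win & is_sense] + window, 1)
        np.add.at(antisense, off[in_win & ~is_sense] + window, 1)
    return MetageneProfile(offsets, sense, antisense, smooth=smooth)


def overlay_signal_track(
    profile: MetageneProfile,
    track_path,
    tss_sites: Sequence[tuple[str, int, str, str]],
) -> MetageneProfile:
    """Average an external bedGraph signal over the profile's offsets.

    The signal is aligned TSS-by-TSS in the same strand-aware offset frame
    and averaged; no statistics are computed across tracks. TSSs on contigs
    missing from the track are skipped (count recorded and logged); if every
    TSS is missing the assemblies are considered mismatched.
    """
    track = read_bedgraph(track_path)
    track_contigs = set(track["contig"])
    tss_contigs = {c for c, *_ in tss_sites}
    if not (track_contigs & tss_contigs):
        raise ValueError(
            f"assembly mismatch: track contigs {sorted(track_contigs)} share nothing "
            f"with TSS contigs {sorted(tss_contigs)}"
        )
    window = (profile.offsets.size - 1) // 2
    total = np.zeros(profile.offsets.size, dtype=float)
    used = 0
    skipped = 0
    per_contig = {c: sub for c, sub in track.groupby("contig")}
    for contig, pos, strand, _name in tss_sites:
        sub = per_contig.get(contig)
        if sub is None:
            skipped += 1
            continue
        values = np.zeros(profile.offsets.size, dtype=float)
        lo, hi = pos - window, pos + window
        for _, seg in sub.iterrows():
            s = max(int(seg["start"]), lo)
            e = min(int(seg["end"]), hi + 1)
            if s >= e:
                continue
            g = np.arange(s, e)
            off = g - pos if strand == "+" else pos - g
            values[off + window] = seg["value"]
        total += values
        used += 1
    if skipped:
        logger.info("%d TSS sites skipped: contig absent from signal track", skipped)
    profile.overlay = total / used if used else total
    profile.skipped_tss = skipped
    return profile


def write_profiles(
    out_dir,
    histograms: Mapping[tuple, TailHistogram] | None = None,
    uplus_table: pd.DataFrame | None = None,
    coverage: pd.DataFrame | None = None,
    metagene: MetageneProfile | None = None,
    plots: bool = False,
) -> dict[str, str]:
    """Write the TSV twins (and optionally PNG plots) of each summary."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    if histograms is not None:
        p = out / "tail_histograms.tsv"
        histogram_frame(histograms).to_csv(p, sep="\t", index=False)
        written["histograms"] = str(p)
    if uplus_table is not None:
        p = out / "uplus_fraction_by_category.tsv"
        uplus_table.to_csv(p, sep="\t", index=False, float_format="%.4f")
        written["uplus_fractions"] = str(p)
    if coverage is not None:
        p = out / "scaled_coverage.tsv"
        coverage.to_csv(p, sep="\t", index_label="gene_id", float_format="%.6f")
        written["coverage"] = str(p)
    if metagene is not None:
        p = out / "tss_metagene.tsv"
        metagene.frame().to_csv(p, sep="\t", index=False, float_format="%.6f")
        written["metagene"] = str(p)
    if plots:
        written.update(_write_plots(out, histograms, coverage, metagene))
    return written


def _write_plots(out, histograms, coverage, metagene) -> dict[str, str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = {}
    if histograms:
        fig, ax = plt.subplots(figsize=(6, 4))
        for key, h in sorted(histograms.items()):
            if not h.counts:
                continue
            lengths = sorted(h.counts)
            ax.plot(lengths, [h.counts[l] for l in lengths], label="|".join(map(str, key)))
        ax.set_xlabel("untemplated tail length (nt)")
        ax.set_ylabel("reads")
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = out / "tail_histograms.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written["histograms_plot"] = str(p)
    if coverage is not None and len(coverage):
        fig, ax = plt.subplots(figsize=(6, max(2, 0.1 * len(coverage))))
        ax.imshow(coverage.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xlabel("scaled mature position (bin)")
        ax.set_ylabel("gene")
        fig.tight_layout()
        p = out / "scaled_coverage.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written["coverage_plot"] = str(p)
    if metagene is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(metagene.offsets, metagene.smoothed(metagene.sense), label="sense")
        ax.plot(metagene.offsets, metagene.smoothed(metagene.antisense), label="antisense")
        if metagene.overlay is not None:
            ax2 = ax.twinx()
            ax2.plot(metagene.offsets, metagene.overlay, color="grey", alpha=0.6, label="overlay")
        ax.set_xlabel("offset from TSS (nt; upstream negative)")
        ax.set_ylabel("U+ read 3' ends")
        ax.legend()
        fig.tight_layout()
        p = out / "tss_metagene.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written["metagene_plot"] = str(p)
    return written
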