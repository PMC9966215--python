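"""1D Pol2 signal extraction and positional metrics.

Two metrics summarize where polymerase sits on a gene:

* **pause ratio** (traveling ratio): mean per-bp Pol2 density in the
  promoter-proximal window [TSS-30, TSS+300) over the mean density in the
  gene body downstream of it. High values mean Pol2 accumulates at the
  early elongation checkpoint.
* **loading ratio**: mean density over promoter plus gene body over the mean
  density in a window just past the TES. High values mean Pol2 is loaded on
  the transcription unit but scarce downstream of termination.

Both use mean per-bp densities so unequal window lengths compare fairly, are
strand-oriented, and add a pseudocount epsilon to numerator and denominator
so silent genes stay finite: ratio = (d1 + eps) / (d2 + eps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ContactPairSet, CoverageTrack, GeneModel, GenomicInterval


@dataclass(frozen=True)
class MetricWindows:
    """Strand-oriented window definitions for the pause and loading ratios.

    Distances are bp relative to the TSS/TES in the direction of
    transcription. Defaults: pause window -30..+300 around the TSS,
    promoter from -1000 to the pause-window end (so promoter and pause
    windows overlap by construction), 3 kb past the TES for the
    termination window, pseudocount 0.1 density units.
    """

    pause_upstream: int = 30
    pause_downstream: int = 300
    promoter_upstream: int = 1000
    post_tes_length: int = 3000
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if self.pause_upstream + self.pause_downstream <= 0:
            raise ValueError("pause window is empty")
        if self.post_tes_length < 1 or self.promoter_upstream < 1:
            raise ValueError("window lengths must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")

    # genomic (half-open) windows; minus-strand genes are exact mirrors
    def pause_window(self, gene: GeneModel) -> GenomicInterval:
        if gene.strand == "+":
            s = gene.tss - self.pause_upstream
            e = gene.tss + self.pause_downstream
        else:
            s = gene.tss - self.pause_downstream + 1
            e = gene.tss + self.pause_upstream + 1
        return GenomicInterval(gene.chrom, max(0, s), e)

    def body_window(self, gene: GeneModel) -> GenomicInterval:
        if gene.length <= self.pause_downstream:
            raise ValueError(
                f"gene {gene.name!r} ({gene.length} bp) too short for a body "
                f"window beyond +{self.pause_downstream}"
            )
        if gene.strand == "+":
            return GenomicInterval(
                gene.chrom, gene.tss + self.pause_downstream, gene.interval.end
            )
        return GenomicInterval(
            gene.chrom, gene.interval.start, gene.tss - self.pause_downstream + 1
        )

    def promoter_window(self, gene: GeneModel) -> GenomicInterval:
        if gene.strand == "+":
            s = gene.tss - self.promoter_upstream
            e = gene.tss + self.pause_downstream
        else:
            s = gene.tss - self.pause_downstream + 1
            e = gene.tss + self.promoter_upstream + 1
        return GenomicInterval(gene.chrom, max(0, s), e)

    def post_tes_window(self, gene: GeneModel) -> GenomicInterval:
        if gene.strand == "+":
            s = gene.tes + 1
            e = gene.tes + 1 + self.post_tes_length
        else:
            s = gene.tes - self.post_tes_length
            e = gene.tes
        return GenomicInterval(gene.chrom, max(0, s), e)

    def gene_segments(self, gene: GeneModel) -> dict[str, GenomicInterval]:
        """Named segments for per-gene delta reports."""
        return {
            "promoter": self.promoter_window(gene),
            "body": self.body_window(gene),
            "post_tes": self.post_tes_window(gene),
        }


@dataclass
class GeneMetrics:
    """Per-gene metric record for one condition."""

    gene: str
    pause_ratio: float
    loading_ratio: float
    pause_density: float
    body_density: float
    promoter_density: float
    post_tes_density: float


def coverage_from_pairs(
    pairs: ContactPairSet, bin_size: int = 50
) -> list[CoverageTrack]:
    """Two-ended pileup: each contact record adds its count to the bins
    overlapped by each of its two anchors (fractional by bp overlap), so
    total track mass equals 2 x sum of counts. This is the 1D
    ChIP-seq-style view of the HiChIP data.
    """
    df = pairs.df
    anchors = []
    for side in ("1", "2"):
        anchors.append(
            pd.DataFrame(
                {
                    "chrom": df[f"chrom{side}"],
                    "start": df[f"start{side}"],
                    "end": df[f"end{side}"],
                    "count": df["count"],
                }
            )
        )
    stacked = pd.concat(anchors, ignore_index=True)

    tracks: list[CoverageTrack] = []
    for chrom in sorted(stacked["chrom"].unique()):
        sub = stacked[stacked["chrom"] == chrom]
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        counts = sub["count"].to_numpy(dtype=float)
        n_bins = int(-(-ends.max() // bin_size))
        values = np.zeros(n_bins)
        widths = (ends - starts).astype(float)
        lo = starts // bin_size
        max_span = int((ends - starts).max() // bin_size) + 2
        for j in range(max_span):
            b = lo + j
            in_range = b < n_bins
            bin_start = b * bin_size
            ov = np.minimum(bin_start + bin_size, ends) - np.maximum(bin_start, starts)
            ov = np.clip(ov, 0, None).astype(float)
            mask = in_range & (ov > 0)
            if mask.any():
                np.add.at(values, b[mask], counts[mask] * ov[mask] / widths[mask])
        tracks.append(CoverageTrack(chrom=str(chrom), bin_size=bin_size, values=values))
    return tracks


def pause_ratio(
    track: CoverageTrack, gene: GeneModel, w: MetricWindows | None = None
) -> float:
    """(pause-window density + eps) / (body density + eps), strand-oriented."""
    w = w or MetricWindows()
    d_pause = track.density(w.pause_window(gene))
    d_body = track.density(w.body_window(gene))
    return (d_pause + w.epsilon) / (d_body + w.epsilon)


def loading_ratio(
    track: CoverageTrack, gene: GeneModel, w: MetricWindows | None = None
) -> float:
    """(promoter+body density + eps) / (post-TES density + eps).

    The numerator is the mean density over the union of the promoter and
    gene-body windows. The post-TES window is truncated at the track edge
    with a warning.
    """
    w = w or MetricWindows()
    prom = w.promoter_window(gene)
    body = w.body_window(gene)
    num_signal = track.signal(prom) + track.signal(body)
    num_len = prom.length + body.length

    post = w.post_tes_window(gene)
    post_start = max(post.start, 0)
    post_end = min(post.end, track.end)
    if post_end <= post_start:
        warnings.warn(
            f"gene {gene.name!r}: post-TES window lies entirely off the "
            "track; treating its density as 0"
        )
        d_post = 0.0
    else:
        if (post_start, post_end) != (post.start, post.end):
            warnings.warn(
                f"gene {gene.name!r}: post-TES window truncated to "
                f"[{post_start},{post_end}) at the track edge"
            )
        clipped = GenomicInterval(post.chrom, post_start, post_end)
        d_post = track.density(clipped)
    return (num_signal / num_len + w.epsilon) / (d_post + w.epsilon)


def gene_metrics(
    track: CoverageTrack, gene: GeneModel, w: MetricWindows | None = None
) -> GeneMetrics:
    """All per-gene densities and ratios in one record."""
    w = w or MetricWindows()
    return GeneMetrics(
        gene=gene.name,
        pause_ratio=pause_ratio(track, gene, w),
        loading_ratio=loading_ratio(track, gene, w),
        pause_density=track.density(w.pause_window(gene)),
        body_density=track.density(w.body_window(gene)),
        promoter_density=track.density(w.promoter_window(gene)),
        post_tes_density=track.density(w.post_tes_window(gene)),
    )


def segment_deltas(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    segments: dict[str, GenomicInterval],
    epsilon: float = 0.1,
) -> pd.DataFrame:
    """Per-segment density differences between two conditions.

    Returns a DataFrame with density_a, density_b, delta (b - a) and
    log2((density_b+eps)/(density_a+eps)) per named segment.
    """
    if track_a.bin_size != track_b.bin_size:
        raise ValueError(
            f"mismatched bin sizes: {track_a.bin_size} vs {track_b.bin_size}"
        )
    if track_a.chrom != track_b.chrom:
        raise ValueError(f"mismatched chromosomes: {track_a.chrom} vs {track_b.chrom}")
    rows = []
    for name, iv in segments.items():
        da = track_a.density(iv)
        db = track_b.density(iv)
        rows.append(
            {
                "segment": name,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "density_a": da,
                "density_b": db,
                "delta": db - da,
                "log2_ratio": float(np.log2((db + epsilon) / (da + epsilon))),
            }
        )
    return pd.DataFrame(rows)


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper/MRI tumor volume in mm^3: 0.5 * L * W^2 (L >= W; swapped
    with a warning if given the other way around)."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("tumor dimensions must be positive")
    if width_mm > length_mm:
        warnings.warn("width > length; swapping so L >= W")
        length_mm, width_mm = width_mm, length_mm
    return 0.5 * length_mm * width_mm**2


def fold_change(a: float, b: float) -> float:
    """a / b; e.g. the ratio of two IC50s."""
    if b <= 0:
        raise ValueError("fold_change denominator must be > 0")
    return a / b
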