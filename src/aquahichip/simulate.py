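"""Two-condition, two-species synthetic HiChIP data with known ground truth.

The generator emulates the statistical structure of a Pol2 AQuA-HiChIP
experiment on a single target chromosome plus a spike-in chromosome:

* genes packed into non-overlapping slots, mixed strands;
* multi-loop anchor chains (A-B, B-C, ...) planted in super-enhancer-like
  regions upstream of genes, so shared-anchor clustering provably recovers
  each chain as one connected component; plus background loops;
* contact pairs drawn from the planted loops, uniform target background,
  and spike-in pairs at a configured fraction of total depth;
* per-condition Pol2 coverage tracks with a TSS-proximal pause peak,
  gene-body signal, enhancer peaks, and a post-TES termination shoulder.

Ground truth is defined as the fixed point of the package's own estimators:
densities are planted so that the pause and loading ratios *as measured with
the pseudocount epsilon* equal the configured values exactly in the absence
of noise (pause-window density = p*(d_body+eps)-eps; post-TES density =
(D_num+eps)/R-eps). Noise, when enabled, is Poisson per coverage bin and
binomial for the spike split.

Two gene classes model the two regulatory responses: in the treated
condition, "crtf"-like genes (core regulatory TFs) gain loading ratio at an
unchanged pause ratio, with enhancer/promoter/body densities up and post-TES
density down; "target"-like genes gain pause ratio at an unchanged loading
ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import write_bedpe, write_bedgraph, write_gene_bed, write_pairs
from .metrics import MetricWindows
from .model import (
    ContactPairSet,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    Loop,
    PAIR_COLUMNS,
)

import pandas as pd

# anchor-chain spacing (bp); above typical min-distance filters, below max
_SPACING_LO, _SPACING_HI = 8_000, 12_000
# background-loop distance range (bp)
_BG_DIST_LO, _BG_DIST_HI = 8_000, 200_000
# enhancer geometry: two 1 kb elements this far upstream of the TSS
_ENHANCER_OFFSETS = (5_000, 8_000)
_ENHANCER_WIDTH = 1_000
_ENHANCER_GAIN = 2.0  # enhancer density relative to gene body
_COORD_QUANTUM = 10  # gene/window coordinates land on this grid


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic experiment; identical config + seed give
    byte-identical outputs.

    ``spike_fraction`` defaults to 0.09, the spike:target chromatin input
    proportion of a 100 ng spike-in per ~1000 ng target IP. ``depth`` is the
    total sequenced pair count per condition; ``coverage_depth`` the
    expected Pol2 reads per gene in the 1D tracks.
    """

    seed: int = 0
    n_genes: int = 20
    chrom_length: int = 2_000_000
    target_chrom: str = "chr1"
    spike_chrom: str = "mm_chr1"
    spike_prefix: str = "mm_"
    n_clusters: int = 5
    loops_per_cluster: tuple[int, int] = (3, 6)
    anchor_span: int = 1_000
    background_loops: int = 20
    spike_fraction: float = 0.09
    depth: int = 100_000
    pause_strength: float = 4.0
    loading_ratio_true: float = 2.0
    condition_effect: float = 2.0
    body_gain: float = 1.5
    coverage_depth: int = 100_000
    bin_size: int = 10
    gene_length: tuple[int, int] = (8_000, 16_000)
    planted_count: tuple[int, int] = (20, 60)
    background_count: tuple[int, int] = (1, 2)
    noise: bool = True
    conditions: tuple[str, str] = ("control", "treated")
    windows: MetricWindows = MetricWindows()

    def __post_init__(self) -> None:
        if not (0 < self.spike_fraction < 1):
            raise ValueError("spike_fraction must be in (0, 1)")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_clusters > self.n_genes:
            raise ValueError("n_clusters must be <= n_genes (one slot per cluster)")
        if self.loops_per_cluster[0] < 1 or self.loops_per_cluster[0] > self.loops_per_cluster[1]:
            raise ValueError("invalid loops_per_cluster range")
        if self.pause_strength < 0 or self.loading_ratio_true <= 0:
            raise ValueError("pause_strength >= 0 and loading_ratio_true > 0 required")
        if self.condition_effect <= 0 or self.body_gain <= 0:
            raise ValueError("condition_effect and body_gain must be > 0")

    @property
    def slot(self) -> int:
        return self.chrom_length // self.n_genes

    def gene_class(self, idx: int) -> str:
        return "crtf" if idx < (self.n_genes + 1) // 2 else "target"


@dataclass
class GroundTruth:
    """Everything a downstream stage should recover."""

    loops: list[Loop]
    cluster_of_loop: list[int]  # per loop; -1 = background
    gene_class: dict[str, str]
    true_pause: dict[str, dict[str, float]]  # condition -> gene -> value
    true_loading: dict[str, dict[str, float]]
    enhancers: dict[str, list[GenomicInterval]]
    n_spike: dict[str, int]
    suggested_min_aqua_cpm: dict[str, float]

    def planted_partition(self) -> set[frozenset]:
        """Planted clusters as frozensets of loop keys."""
        groups: dict[int, set] = {}
        for lp, cid in zip(self.loops, self.cluster_of_loop):
            if cid >= 0:
                groups.setdefault(cid, set()).add(lp.key())
        return {frozenset(v) for v in groups.values()}

    def to_json(self, path: str | Path) -> None:
        d = {
            "loops": [
                {
                    "chrom1": lp.anchor1.chrom,
                    "start1": lp.anchor1.start,
                    "end1": lp.anchor1.end,
                    "chrom2": lp.anchor2.chrom,
                    "start2": lp.anchor2.start,
                    "end2": lp.anchor2.end,
                    "raw_count": lp.raw_count,
                    "cluster": cid,
                }
                for lp, cid in zip(self.loops, self.cluster_of_loop)
            ],
            "gene_class": self.gene_class,
            "true_pause": self.true_pause,
            "true_loading": self.true_loading,
            "enhancers": {
                g: [[iv.chrom, iv.start, iv.end] for iv in ivs]
                for g, ivs in self.enhancers.items()
            },
            "n_spike": self.n_spike,
            "suggested_min_aqua_cpm": self.suggested_min_aqua_cpm,
        }
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *stream])


def _snap(x: int) -> int:
    return int(x) // _COORD_QUANTUM * _COORD_QUANTUM


def simulate_genes(config: SimulationConfig) -> list[GeneModel]:
    """Non-overlapping genes, one per chromosome slot, mixed strands.

    Each gene keeps a clear margin inside its slot so every metric window
    (promoter, pause, body, post-TES) fits regardless of strand; gene
    coordinates land on a 10 bp grid so window edges align with coverage
    bins. Raises on infeasible packing.
    """
    rng = _rng(config, 1)
    slot = config.slot
    w = config.windows
    margin = max(w.post_tes_length, w.promoter_upstream) + 1_000
    region_lo_off = slot // 2 + margin
    region_hi_off = slot - margin
    gmin, gmax = config.gene_length
    gmax_eff = min(gmax, region_hi_off - region_lo_off)
    if gmax_eff < gmin or gmin <= w.pause_downstream:
        raise ValueError(
            f"infeasible packing: slot {slot} bp cannot hold a "
            f"{gmin}-{gmax} bp gene with {margin} bp margins"
        )
    genes: list[GeneModel] = []
    for k in range(config.n_genes):
        length = _snap(rng.integers(gmin, gmax_eff + 1))
        lo = k * slot + region_lo_off
        start = _snap(lo + rng.integers(0, region_hi_off - region_lo_off - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                GenomicInterval(config.target_chrom, start, start + length),
                strand=strand,
                name=f"gene_{k:03d}",
            )
        )
    return genes


def enhancer_intervals(config: SimulationConfig, gene: GeneModel) -> list[GenomicInterval]:
    """Two 1 kb enhancer elements upstream of the TSS (strand-aware)."""
    out = []
    for off in _ENHANCER_OFFSETS:
        if gene.strand == "+":
            s = gene.tss - off - _ENHANCER_WIDTH
        else:
            s = gene.tss + off + 1
            s = _snap(s - 1) + _COORD_QUANTUM  # keep on the coordinate grid
        if s >= 0:
            out.append(GenomicInterval(gene.chrom, s, s + _ENHANCER_WIDTH))
    return out


def _plant_loops(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[Loop], list[int]]:
    """Planted anchor chains (one per cluster slot) plus background loops."""
    chrom = config.target_chrom
    slot = config.slot
    span = config.anchor_span
    lo_k, hi_k = config.loops_per_cluster
    needed = 4_000 + hi_k * _SPACING_HI + span
    if needed > slot:
        raise ValueError(
            f"infeasible packing: cluster chain of up to {hi_k} loops needs "
            f"{needed} bp but the slot is {slot} bp"
        )
    loops: list[Loop] = []
    membership: list[int] = []
    for c in range(config.n_clusters):
        k = int(rng.integers(lo_k, hi_k + 1))
        pos = c * slot + 2_000 + int(rng.integers(0, 2_000))
        anchors = []
        for _ in range(k + 1):
            anchors.append(GenomicInterval(chrom, pos, pos + span))
            pos += int(rng.integers(_SPACING_LO, _SPACING_HI + 1))
        for j in range(k):
            count = int(rng.integers(config.planted_count[0], config.planted_count[1] + 1))
            loops.append(Loop(anchors[j], anchors[j + 1], raw_count=count))
            membership.append(c)
    for _ in range(config.background_loops):
        d = int(rng.integers(_BG_DIST_LO, _BG_DIST_HI + 1))
        s1 = int(rng.integers(0, max(1, config.chrom_length - d - 2 * span)))
        count = int(rng.integers(config.background_count[0], config.background_count[1] + 1))
        loops.append(
            Loop(
                GenomicInterval(chrom, s1, s1 + span),
                GenomicInterval(chrom, s1 + d, s1 + d + span),
                raw_count=count,
            )
        )
        membership.append(-1)
    return loops, membership


def simulate_contacts(
    config: SimulationConfig, genes: list[GeneModel]
) -> tuple[dict[str, ContactPairSet], GroundTruth]:
    """Per-condition contact sets plus the ground truth.

    Target pairs comprise the planted/background loop contacts (at anchor
    midpoints, so boundary containment and APA centering are exact) and a
    uniform short-range scatter; spike pairs land on the spike chromosome at
    the configured expected fraction of total depth. The loop structure is
    shared between conditions; scatter and spike draws differ by stream.
    """
    if config.n_genes != len(genes):
        raise ValueError("genes list does not match config.n_genes")
    structure_rng = _rng(config, 2)
    loops, membership = _plant_loops(config, structure_rng)
    loop_pair_total = sum(lp.raw_count for lp in loops)
    span = config.anchor_span

    pair_sets: dict[str, ContactPairSet] = {}
    n_spike_by_cond: dict[str, int] = {}
    suggested: dict[str, float] = {}
    raw_cut = (config.background_count[1] + config.planted_count[0]) / 2

    for ci, cond in enumerate(config.conditions):
        rng = _rng(config, 3, ci)
        if config.depth == 0:
            pair_sets[cond] = ContactPairSet.empty(sample_id=cond)
            n_spike_by_cond[cond] = 0
            suggested[cond] = float("inf")
            continue
        if config.noise:
            n_spike = int(rng.binomial(config.depth, config.spike_fraction))
        else:
            n_spike = int(round(config.depth * config.spike_fraction))
        n_scatter = max(0, config.depth - n_spike - loop_pair_total)

        frames = []
        if loops:
            frames.append(
                pd.DataFrame(
                    {
                        "chrom1": [lp.anchor1.chrom for lp in loops],
                        "start1": [lp.anchor1.start for lp in loops],
                        "end1": [lp.anchor1.end for lp in loops],
                        "chrom2": [lp.anchor2.chrom for lp in loops],
                        "start2": [lp.anchor2.start for lp in loops],
                        "end2": [lp.anchor2.end for lp in loops],
                        "count": [lp.raw_count for lp in loops],
                        "species": "target",
                    }
                )
            )
        if n_scatter > 0:
            pos1 = rng.integers(span, config.chrom_length - _BG_DIST_HI - span, n_scatter)
            dist = rng.integers(1_000, _BG_DIST_HI + 1, n_scatter)
            pos2 = pos1 + dist
            frames.append(
                pd.DataFrame(
                    {
                        "chrom1": config.target_chrom,
                        "start1": pos1 - span // 2,
                        "end1": pos1 - span // 2 + span,
                        "chrom2": config.target_chrom,
                        "start2": pos2 - span // 2,
                        "end2": pos2 - span // 2 + span,
                        "count": 1,
                        "species": "target",
                    }
                )
            )
        if n_spike > 0:
            pos1 = rng.integers(span, config.chrom_length - _BG_DIST_HI - span, n_spike)
            dist = rng.integers(1_000, _BG_DIST_HI + 1, n_spike)
            pos2 = pos1 + dist
            frames.append(
                pd.DataFrame(
                    {
                        "chrom1": config.spike_chrom,
                        "start1": pos1 - span // 2,
                        "end1": pos1 - span // 2 + span,
                        "chrom2": config.spike_chrom,
                        "start2": pos2 - span // 2,
                        "end2": pos2 - span // 2 + span,
                        "count": 1,
                        "species": "spike",
                    }
                )
            )
        df = (
            pd.concat(frames, ignore_index=True)
            if frames
            else ContactPairSet.empty().df
        )
        pair_sets[cond] = ContactPairSet(df, sample_id=cond)
        n_spike_by_cond[cond] = n_spike
        suggested[cond] = raw_cut * 1e6 / n_spike if n_spike else float("inf")

    control = config.conditions[0]
    true_pause: dict[str, dict[str, float]] = {c: {} for c in config.conditions}
    true_loading: dict[str, dict[str, float]] = {c: {} for c in config.conditions}
    gene_class: dict[str, str] = {}
    enhancers: dict[str, list[GenomicInterval]] = {}
    for idx, gene in enumerate(genes):
        cls = config.gene_class(idx)
        gene_class[gene.name] = cls
        enhancers[gene.name] = enhancer_intervals(config, gene)
        for cond in config.conditions:
            treated = cond != control
            p = config.pause_strength * (
                config.condition_effect if treated and cls == "target" else 1.0
            )
            r = config.loading_ratio_true * (
                config.condition_effect if treated and cls == "crtf" else 1.0
            )
            true_pause[cond][gene.name] = p
            true_loading[cond][gene.name] = r

    truth = GroundTruth(
        loops=loops,
        cluster_of_loop=membership,
        gene_class=gene_class,
        true_pause=true_pause,
        true_loading=true_loading,
        enhancers=enhancers,
        n_spike=n_spike_by_cond,
        suggested_min_aqua_cpm=suggested,
    )
    return pair_sets, truth


def _gene_density_profile(
    config: SimulationConfig, gene: GeneModel, cls: str, condition: str
) -> dict[str, float]:
    """Segment densities (reads per bp) for one gene in one condition.

    The control body density is solved in closed form so the expected read
    mass over the gene's segments equals ``coverage_depth``; the treated
    condition inherits it scaled by ``body_gain`` (crtf genes) rather than
    renormalizing, so the condition contrast survives in absolute signal.
    Pause and post-TES densities are epsilon-compensated so the measured
    ratios equal the configured truths exactly without noise.
    """
    w = config.windows
    eps = w.epsilon
    control = config.conditions[0]
    treated = condition != control

    p = config.pause_strength
    r = config.loading_ratio_true
    gain = 1.0
    if treated:
        if cls == "crtf":
            r *= config.condition_effect
            gain = config.body_gain
        else:
            p *= config.condition_effect

    l_pause = w.pause_upstream + w.pause_downstream
    l_prom_rest = w.promoter_upstream - w.pause_upstream
    l_body = gene.length - w.pause_downstream
    l_post = w.post_tes_length
    l_enh = len(enhancer_intervals(config, gene)) * _ENHANCER_WIDTH

    def derived(d_b: float, p_: float, r_: float) -> tuple[float, float, float, float]:
        d_pause = p_ * (d_b + eps) - eps
        d_num = (l_prom_rest * d_b + l_pause * d_pause + l_body * d_b) / (
            l_prom_rest + l_pause + l_body
        )
        d_post = (d_num + eps) / r_ - eps
        d_enh = _ENHANCER_GAIN * d_b
        mass = (
            l_enh * d_enh
            + l_prom_rest * d_b
            + l_pause * d_pause
            + l_body * d_b
            + l_post * d_post
        )
        return d_pause, d_post, d_enh, mass

    # control body density from mass(d_b) = coverage_depth (mass is affine in d_b)
    p0, r0 = config.pause_strength, config.loading_ratio_true
    m0 = derived(0.0, p0, r0)[3]
    m1 = derived(1.0, p0, r0)[3]
    d_b_control = (config.coverage_depth - m0) / (m1 - m0)
    if d_b_control <= 0:
        raise ValueError("coverage_depth too small for the epsilon pseudocount")

    d_b = gain * d_b_control
    d_pause, d_post, d_enh, _ = derived(d_b, p, r)
    if d_pause < 0 or d_post < 0:
        raise ValueError(
            "configured ratios are infeasible at this depth (negative planted density)"
        )
    return {
        "body": d_b,
        "pause": d_pause,
        "prom_rest": d_b,
        "post_tes": d_post,
        "enhancer": d_enh,
    }


def _prom_rest_window(w: MetricWindows, gene: GeneModel) -> GenomicInterval:
    prom = w.promoter_window(gene)
    pause = w.pause_window(gene)
    if gene.strand == "+":
        return GenomicInterval(gene.chrom, prom.start, pause.start)
    return GenomicInterval(gene.chrom, pause.end, prom.end)


def simulate_coverage(
    config: SimulationConfig, genes: list[GeneModel], condition: str
) -> list[CoverageTrack]:
    """Pol2 coverage track(s) for one condition (strand-aware geometry,
    Poisson noise per bin when ``config.noise``)."""
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    w = config.windows
    n_bins = -(-config.chrom_length // config.bin_size)
    track = CoverageTrack(
        chrom=config.target_chrom,
        bin_size=config.bin_size,
        values=np.zeros(n_bins),
    )
    for idx, gene in enumerate(genes):
        cls = config.gene_class(idx)
        d = _gene_density_profile(config, gene, cls, condition)
        segs = [
            (_prom_rest_window(w, gene), d["prom_rest"]),
            (w.pause_window(gene), d["pause"]),
            (w.body_window(gene), d["body"]),
            (w.post_tes_window(gene), d["post_tes"]),
        ]
        for iv in enhancer_intervals(config, gene):
            segs.append((iv, d["enhancer"]))
        for iv, dens in segs:
            track.add_interval(iv.start, iv.end, dens * iv.length)
    if config.noise:
        rng = _rng(config, 4, config.conditions.index(condition))
        track.values = rng.poisson(track.values).astype(float)
    return [track]


@dataclass
class SyntheticDataset:
    """The full two-condition bundle."""

    config: SimulationConfig
    genes: list[GeneModel]
    pairs: dict[str, ContactPairSet]
    coverage: dict[str, list[CoverageTrack]]
    truth: GroundTruth


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate everything: genes, contacts per condition, coverage per
    condition, and the ground-truth record."""
    genes = simulate_genes(config)
    pairs, truth = simulate_contacts(config, genes)
    coverage = {
        cond: simulate_coverage(config, genes, cond) for cond in config.conditions
    }
    return SyntheticDataset(
        config=config, genes=genes, pairs=pairs, coverage=coverage, truth=truth
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit the dataset in the pipeline's input formats plus a ground-truth
    JSON sidecar and an enhancer BED."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genes"] = outdir / "genes.bed"
    write_gene_bed(ds.genes, paths["genes"])

    paths["loops"] = outdir / "loops.bedpe"
    write_bedpe(ds.truth.loops, paths["loops"])

    for cond in ds.config.conditions:
        p = outdir / f"{cond}.pairs"
        write_pairs(ds.pairs[cond], p)
        paths[f"pairs_{cond}"] = p
        c = outdir / f"coverage_{cond}.bedGraph"
        for i, track in enumerate(ds.coverage[cond]):
            write_bedgraph(track, c, append=i > 0)
        paths[f"coverage_{cond}"] = c

    paths["truth"] = outdir / "ground_truth.json"
    ds.truth.to_json(paths["truth"])

    paths["enhancers"] = outdir / "enhancers.bed"
    with paths["enhancers"].open("w") as fh:
        for gene_name, ivs in ds.truth.enhancers.items():
            for j, iv in enumerate(ivs):
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gene_name}_enh{j}\t0\t.\n"
                )
    return paths
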