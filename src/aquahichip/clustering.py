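"""Loop filtering, shared-anchor clustering, component ranking, and APA.

The clustering model: filtered loops are vertices of a graph; two loops are
adjacent when *any* pair of their anchor ends (left-left, left-right,
right-left, right-right) overlaps after expansion by ``pad`` bp. Connected
components of this graph are the 3D elements: components with fewer than
``min_loops`` members are called *loops*, those with at least ``min_loops``
are *clusters* (multi-loop structures of the kind seen around super
enhancers). Sub-``min_distance`` self-contacts are reported separately as 2D
peak candidates rather than classified, since no independent threshold
defines them.

Components are ranked by 3D connectivity: the AQuA-CPM sum of all contacts
whose anchors both fall inside the component boundary (min to max coordinate
of the member anchors, optionally expanded).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .aqua import AquaFactors
from .model import ContactPairSet, GenomicInterval, Loop

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterThresholds:
    """Loop-filter and classification thresholds."""

    min_distance: int = 5_000
    max_distance: int = 2_000_000
    min_aqua_cpm: float = 1.0
    min_loops: int = 3

    def __post_init__(self) -> None:
        if not (0 <= self.min_distance < self.max_distance):
            raise ValueError("require 0 <= min_distance < max_distance")
        if self.min_aqua_cpm < 0:
            raise ValueError("min_aqua_cpm must be >= 0")
        if self.min_loops < 2:
            raise ValueError("min_loops must be >= 2")


@dataclass
class LoopComponent:
    """A connected set of loops with class label and connectivity score."""

    component_id: int
    loops: list[Loop]
    anchors: list[GenomicInterval]
    boundary: GenomicInterval
    label: str  # "loop" | "cluster"
    connectivity: float = 0.0
    rank: int | None = None

    @property
    def n_loops(self) -> int:
        return len(self.loops)


def filter_loops(loops: list[Loop], t: FilterThresholds) -> list[Loop]:
    """Keep cis loops with min_distance <= distance <= max_distance and
    aqua_cpm >= min_aqua_cpm; input order is preserved.

    Trans loops are dropped with a logged count (distance and boundary are
    undefined across chromosomes).
    """
    n_trans = sum(1 for lp in loops if not lp.is_cis)
    if n_trans:
        log.warning("dropped %d trans loops before filtering", n_trans)
    return [
        lp
        for lp in loops
        if lp.is_cis
        and t.min_distance <= lp.distance <= t.max_distance
        and lp.aqua_cpm >= t.min_aqua_cpm
    ]


def short_range_candidates(loops: list[Loop], t: FilterThresholds) -> list[Loop]:
    """Cis loops below min_distance: self-contact / 2D-peak candidates,
    reported separately from the filtered set."""
    return [lp for lp in loops if lp.is_cis and lp.distance < t.min_distance]


def anchors_connected(a: GenomicInterval, b: GenomicInterval, pad: int = 0) -> bool:
    """True iff the two anchor intervals, each expanded by ``pad`` bp on
    both sides, intersect (half-open)."""
    return a.overlaps(b, pad=pad)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_loops(
    filtered: list[Loop], t: FilterThresholds, pad: int = 0
) -> list[LoopComponent]:
    """Group loops into connected components by shared/overlapping anchors.

    Starting from any loop, all loops reachable through overlapping left or
    right ends receive the same component id; this repeats until every loop
    is visited. Implemented as a sorted endpoint sweep feeding a union-find,
    which yields exactly the connected components of the anchor-overlap
    graph. Components are numbered densely from 0 in order of leftmost
    boundary and classified against ``t.min_loops``.
    """
    n = len(filtered)
    uf = _UnionFind(n)

    # sweep per chromosome over both anchors of every loop
    events: dict[str, list[tuple[int, int, int]]] = {}
    for i, lp in enumerate(filtered):
        for anchor in (lp.anchor1, lp.anchor2):
            events.setdefault(anchor.chrom, []).append((anchor.start, anchor.end, i))
    for chrom_events in events.values():
        chrom_events.sort()
        chain_rep = -1
        chain_max_end = -math.inf
        for start, end, i in chrom_events:
            if chain_rep >= 0 and start < chain_max_end + 2 * pad:
                uf.union(chain_rep, i)
            else:
                chain_rep = i
                chain_max_end = end
            chain_max_end = max(chain_max_end, end)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    components: list[LoopComponent] = []
    for members in groups.values():
        loops = [filtered[i] for i in members]
        anchors = sorted(
            {a for lp in loops for a in (lp.anchor1, lp.anchor2)},
            key=lambda a: (a.chrom, a.start, a.end),
        )
        chrom = anchors[0].chrom
        boundary = GenomicInterval(
            chrom, min(a.start for a in anchors), max(a.end for a in anchors)
        )
        label = "cluster" if len(loops) >= t.min_loops else "loop"
        components.append(
            LoopComponent(
                component_id=-1,
                loops=loops,
                anchors=anchors,
                boundary=boundary,
                label=label,
            )
        )

    components.sort(key=lambda c: (c.boundary.chrom, c.boundary.start, c.boundary.end))
    for cid, comp in enumerate(components):
        comp.component_id = cid
    return components


def component_connectivity(
    comp: LoopComponent, pairs: ContactPairSet, factors: AquaFactors, pad: int = 0
) -> float:
    """AQuA-CPM sum of target contacts with BOTH anchors inside the
    component boundary expanded by ``pad``."""
    df = pairs.df
    b = comp.boundary
    lo, hi = b.start - pad, b.end + pad
    mask = (
        (df["species"] == "target")
        & (df["chrom1"] == b.chrom)
        & (df["chrom2"] == b.chrom)
        & (df["start1"] >= lo)
        & (df["end1"] <= hi)
        & (df["start2"] >= lo)
        & (df["end2"] <= hi)
    )
    return float(df.loc[mask, "count"].sum()) * factors.scale


def rank_components(
    components: list[LoopComponent],
    pairs: ContactPairSet,
    factors: AquaFactors,
    pad: int = 0,
) -> list[LoopComponent]:
    """Score every component's 3D connectivity and return the list sorted
    descending, ties broken by leftmost boundary. Ranks start at 1."""
    for comp in components:
        comp.connectivity = component_connectivity(comp, pairs, factors, pad=pad)
    ranked = sorted(
        components,
        key=lambda c: (
            -c.connectivity,
            c.boundary.chrom,
            c.boundary.start,
            c.boundary.end,
        ),
    )
    for r, comp in enumerate(ranked, start=1):
        comp.rank = r
    return ranked


@dataclass
class ApaMatrix:
    """Aggregate peak analysis grid in contacts per million per loop."""

    matrix: np.ndarray
    bin_size: int
    n_loops: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("APA matrix must be square")
        if self.matrix.shape[0] % 2 == 0:
            raise ValueError("APA matrix must have odd dimensions")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    @property
    def center_value(self) -> float:
        c = self.n_bins // 2
        return float(self.matrix[c, c])

    def center_enrichment(self, corner: int = 3) -> float:
        """Center cell over the mean of the four corner blocks; a standard
        APA QC score (inf when the corners are empty but the center not)."""
        k = corner
        m = self.matrix
        corners = np.concatenate(
            [
                m[:k, :k].ravel(),
                m[:k, -k:].ravel(),
                m[-k:, :k].ravel(),
                m[-k:, -k:].ravel(),
            ]
        )
        denom = float(corners.mean())
        if denom == 0:
            return math.inf if self.center_value > 0 else 0.0
        return self.center_value / denom

    @property
    def total_mass(self) -> float:
        return float(self.matrix.sum())


def apa(
    loops: list[Loop],
    pairs: ContactPairSet,
    factors: AquaFactors,
    bin_size: int = 5_000,
    n_bins: int = 21,
) -> ApaMatrix:
    """Aggregate peak analysis over called loops.

    For every loop, the ``n_bins`` x ``n_bins`` contact grid of ``bin_size``
    bp cells centered on (mid(anchor1), mid(anchor2)) is accumulated in
    AQuA-CPM, then divided by the number of loops: units are contacts per
    million spike pairs per loop, with the loop itself in the central cell.
    """
    if not loops:
        raise ValueError("APA requires at least one loop")
    if n_bins % 2 == 0 or n_bins < 1:
        raise ValueError("n_bins must be a positive odd integer")
    half = n_bins // 2

    df = pairs.df
    cis_target = df[
        (df["species"] == "target") & (df["chrom1"] == df["chrom2"])
    ]
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in cis_target.groupby("chrom1"):
        p1 = ((sub["start1"].to_numpy() + sub["end1"].to_numpy()) // 2).astype(np.int64)
        p2 = ((sub["start2"].to_numpy() + sub["end2"].to_numpy()) // 2).astype(np.int64)
        by_chrom[str(chrom)] = (p1, p2, sub["count"].to_numpy(dtype=np.int64))

    mat = np.zeros((n_bins, n_bins))
    for lp in loops:
        if not lp.is_cis or lp.anchor1.chrom not in by_chrom:
            continue
        p1, p2, counts = by_chrom[lp.anchor1.chrom]
        w1 = lp.anchor1.mid - half * bin_size - bin_size // 2
        w2 = lp.anchor2.mid - half * bin_size - bin_size // 2
        rows = (p1 - w1) // bin_size
        cols = (p2 - w2) // bin_size
        ok = (rows >= 0) & (rows < n_bins) & (cols >= 0) & (cols < n_bins)
        if ok.any():
            np.add.at(mat, (rows[ok], cols[ok]), counts[ok])

    mat *= factors.scale / len(loops)
    return ApaMatrix(matrix=mat, bin_size=bin_size, n_loops=len(loops))
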