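"""Shared test utilities: random instance generators and the brute-force
transitive-closure clustering oracle (networkx over pairwise anchor
overlap), kept independent of the package's sweep implementation."""

from __future__ import annotations

import networkx as nx
import numpy as np

from aquahichip.clustering import anchors_connected
from aquahichip.model import GenomicInterval, Loop


def random_loops(
    rng: np.random.Generator,
    n: int,
    chrom: str = "chr1",
    coord_max: int = 20_000,
    width_max: int = 1_500,
) -> list[Loop]:
    loops = []
    for _ in range(n):
        ivs = []
        for _ in range(2):
            s = int(rng.integers(0, coord_max))
            w = int(rng.integers(100, width_max))
            ivs.append(GenomicInterval(chrom, s, s + w))
        loops.append(
            Loop(
                ivs[0],
                ivs[1],
                raw_count=int(rng.integers(1, 10)),
                aqua_cpm=float(rng.integers(1, 10)),
            )
        )
    return loops


def oracle_partition(loops: list[Loop], pad: int) -> set[frozenset]:
    """Connected components by explicit pairwise edge enumeration and
    transitive closure (networkx), as index sets."""
    g = nx.Graph()
    g.add_nodes_from(range(len(loops)))
    for i in range(len(loops)):
        ai = (loops[i].anchor1, loops[i].anchor2)
        for j in range(i + 1, len(loops)):
            aj = (loops[j].anchor1, loops[j].anchor2)
            if any(anchors_connected(a, b, pad) for a in ai for b in aj):
                g.add_edge(i, j)
    return {frozenset(c) for c in nx.connected_components(g)}


def partition_of(components, loops: list[Loop]) -> set[frozenset]:
    """Partition produced by cluster_loops, as index sets into ``loops``."""
    index = {id(lp): i for i, lp in enumerate(loops)}
    return {frozenset(index[id(lp)] for lp in c.loops) for c in components}
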