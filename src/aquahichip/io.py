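"""Readers and writers for the text formats the pipeline touches.

Formats: BEDPE (7-, 8- and >=10-column dialects), BED6 gene models, 4DN-style
pairs text, and bedGraph. All are tab-separated; lines starting with ``#``
(and the pairs ``##``/column header) are skipped. Every reader/writer pair is
a lossless round trip at its declared resolution.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .model import (
    ContactPairSet,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    Loop,
    PAIR_COLUMNS,
)

log = logging.getLogger(__name__)


def _fmt_float(x: float) -> str:
    # repr round-trips doubles exactly through float()
    return repr(float(x))


# ---------------------------------------------------------------------------
# BEDPE

def read_bedpe(path: str | Path, score_as: str = "count") -> list[Loop]:
    """Read loops from a BEDPE file.

    Dialects: 7 columns (chrom1,start1,end1,chrom2,start2,end2,score) where
    the score maps to ``raw_count`` (``score_as="count"``) or ``aqua_cpm``
    (``score_as="aqua_cpm"``); 8 columns carrying both raw_count and
    aqua_cpm (this package's write format); >=10 standard BEDPE columns
    where column 8 is the score, interpreted per ``score_as``.
    Malformed lines raise with their line number.
    """
    if score_as not in ("count", "aqua_cpm"):
        raise ValueError(f"score_as must be 'count' or 'aqua_cpm', got {score_as!r}")
    path = Path(path)
    loops: list[Loop] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                loops.append(_parse_bedpe_fields(fields, score_as))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BEDPE line: {exc}") from exc
    return loops


def _parse_bedpe_fields(fields: list[str], score_as: str) -> Loop:
    if len(fields) < 7:
        raise ValueError(f"expected >=7 tab-separated columns, got {len(fields)}")
    a1 = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
    a2 = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
    if len(fields) == 7:
        if score_as == "count":
            return Loop(a1, a2, raw_count=int(fields[6]))
        return Loop(a1, a2, raw_count=0, aqua_cpm=float(fields[6]))
    if len(fields) == 8:
        return Loop(a1, a2, raw_count=int(fields[6]), aqua_cpm=float(fields[7]))
    # standard BEDPE: name, score, strand1, strand2, ...
    score = fields[7]
    if score_as == "count":
        return Loop(a1, a2, raw_count=int(score))
    return Loop(a1, a2, raw_count=0, aqua_cpm=float(score))


def write_bedpe(loops: Iterable[Loop], path: str | Path) -> None:
    """Write loops as 8-column BEDPE (both raw_count and aqua_cpm kept so
    ``read_bedpe`` round-trips exactly)."""
    path = Path(path)
    with path.open("w") as fh:
        for lp in loops:
            fh.write(
                "\t".join(
                    (
                        lp.anchor1.chrom,
                        str(lp.anchor1.start),
                        str(lp.anchor1.end),
                        lp.anchor2.chrom,
                        str(lp.anchor2.start),
                        str(lp.anchor2.end),
                        str(lp.raw_count),
                        _fmt_float(lp.aqua_cpm),
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED6 gene models

def read_gene_bed(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 (chrom, start, end, name, score, strand).

    Duplicate gene names are an error: downstream metric tables are keyed
    by name.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected BED6, got {len(fields)} columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                gene = GeneModel(iv, strand=fields[5], name=fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if gene.name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene name {gene.name!r}")
            seen.add(gene.name)
            genes.append(gene)
    return genes


def write_gene_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.name}\t0\t{g.strand}\n"
            )


# ---------------------------------------------------------------------------
# pairs text

def read_pairs(
    path: str | Path,
    sample_id: str = "",
    spike_prefix: str = "mm_",
    anchor_width: int = 1000,
    strict: bool = False,
) -> ContactPairSet:
    """Read a 4DN-style pairs text file into a :class:`ContactPairSet`.

    Columns: readID, chrom1, pos1, chrom2, pos2 (extra columns ignored);
    positions are 1-based on disk. Each line becomes one record with
    count 1 and anchors of ``anchor_width`` bp centered on the position.

    Species is inferred from the chromosome-name prefix: both chromosomes
    carrying ``spike_prefix`` tags the record ``spike``, neither tags it
    ``target``; chimeric target/spike pairs are dropped with a logged count.
    With ``strict=True``, chromosome names must start with ``spike_prefix``
    or ``chr``.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            usecols=[0, 1, 2, 3, 4],
            names=["read_id", "chrom1", "pos1", "chrom2", "pos2"],
            dtype={"chrom1": str, "chrom2": str},
        )
    except pd.errors.EmptyDataError:
        return ContactPairSet.empty(sample_id=sample_id)
    if len(raw) == 0:
        return ContactPairSet.empty(sample_id=sample_id)

    c1 = raw["chrom1"].str.startswith(spike_prefix)
    c2 = raw["chrom2"].str.startswith(spike_prefix)
    if strict:
        known = (
            raw["chrom1"].str.startswith(("chr", spike_prefix))
            & raw["chrom2"].str.startswith(("chr", spike_prefix))
        )
        if not bool(known.all()):
            bad = raw.loc[~known, ["chrom1", "chrom2"]].iloc[0]
            raise ValueError(
                f"{path}: unknown chromosome prefix in pair "
                f"({bad['chrom1']}, {bad['chrom2']}); expected 'chr' or "
                f"{spike_prefix!r}"
            )
    chimeric = c1 ^ c2
    n_chim = int(chimeric.sum())
    if n_chim:
        log.warning("%s: dropped %d chimeric target/spike pairs", path, n_chim)
        raw = raw[~chimeric]
        c1 = c1[~chimeric]

    half = anchor_width // 2
    pos1 = raw["pos1"].to_numpy(dtype=np.int64) - 1  # to 0-based
    pos2 = raw["pos2"].to_numpy(dtype=np.int64) - 1
    s1 = np.maximum(0, pos1 - half)
    s2 = np.maximum(0, pos2 - half)
    df = pd.DataFrame(
        {
            "chrom1": raw["chrom1"].to_numpy(),
            "start1": s1,
            "end1": s1 + anchor_width,
            "chrom2": raw["chrom2"].to_numpy(),
            "start2": s2,
            "end2": s2 + anchor_width,
            "count": np.ones(len(raw), dtype=np.int64),
            "species": np.where(c1.to_numpy(), "spike", "target"),
        }
    )
    return ContactPairSet(df, sample_id=sample_id)


def write_pairs(pairs: ContactPairSet, path: str | Path) -> None:
    """Write a contact set as pairs text (one line per pair; records with
    count > 1 are expanded). Positions are anchor midpoints, 1-based."""
    path = Path(path)
    df = pairs.df
    counts = df["count"].to_numpy(dtype=np.int64)
    rep = np.repeat(np.arange(len(df)), counts)
    mid1 = ((df["start1"].to_numpy() + df["end1"].to_numpy()) // 2)[rep] + 1
    mid2 = ((df["start2"].to_numpy() + df["end2"].to_numpy()) // 2)[rep] + 1
    chrom1 = df["chrom1"].to_numpy()[rep]
    chrom2 = df["chrom2"].to_numpy()[rep]
    with path.open("w") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#columns: readID chr1 position1 chr2 position2\n")
        for i in range(len(rep)):
            fh.write(f"read{i}\t{chrom1[i]}\t{mid1[i]}\t{chrom2[i]}\t{mid2[i]}\n")


# ---------------------------------------------------------------------------
# bedGraph

def write_bedgraph(track: CoverageTrack, path: str | Path, append: bool = False) -> None:
    """Write a track as bedGraph; adjacent equal-valued bins are merged into
    one line and zero-valued bins are omitted."""
    path = Path(path)
    mode = "a" if append else "w"
    bs = track.bin_size
    vals = track.values
    with path.open(mode) as fh:
        i = 0
        n = len(vals)
        while i < n:
            v = vals[i]
            j = i + 1
            while j < n and vals[j] == v:
                j += 1
            if v != 0:
                start = track.origin + i * bs
                end = track.origin + j * bs
                fh.write(f"{track.chrom}\t{start}\t{end}\t{_fmt_float(v)}\n")
            i = j


def read_bedgraph(path: str | Path, bin_size: int) -> list[CoverageTrack]:
    """Read bedGraph into per-chromosome tracks at ``bin_size`` resolution.

    Intervals must be aligned to ``bin_size`` (the write format guarantees
    this); overlapping intervals are an error. Bins absent from the file
    are 0.
    """
    path = Path(path)
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if start % bin_size or end % bin_size:
                raise ValueError(
                    f"{path}:{lineno}: interval [{start},{end}) not aligned to "
                    f"bin_size {bin_size}"
                )
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty or inverted interval")
            per_chrom.setdefault(chrom, []).append((start, end, value))

    tracks: list[CoverageTrack] = []
    for chrom in sorted(per_chrom):
        runs = sorted(per_chrom[chrom])
        n_bins = runs[-1][1] // bin_size
        values = np.zeros(n_bins)
        seen_end = -1
        for start, end, value in runs:
            if start < seen_end:
                raise ValueError(f"{path}: overlapping intervals on {chrom} at {start}")
            seen_end = end
            values[start // bin_size : end // bin_size] = value
        tracks.append(CoverageTrack(chrom=chrom, bin_size=bin_size, values=values))
    return tracks
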