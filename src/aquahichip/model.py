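"""Core genomic data types for AQuA-HiChIP analysis.

Coordinate convention: 0-based, half-open ``[start, end)`` everywhere in the
package, matching BED/BEDPE. Pairs-format positions are 1-based on disk and
converted at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
import pandas as pd

Species = Literal["target", "spike"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def mid(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", pad: int = 0) -> bool:
        """True iff the two intervals, each expanded by ``pad`` on both
        sides, share at least one base (half-open intersection)."""
        if self.chrom != other.chrom:
            return False
        return (self.start - pad < other.end + pad) and (
            other.start - pad < self.end + pad
        )

    def contains(self, other: "GenomicInterval", pad: int = 0) -> bool:
        """True iff ``other`` lies entirely inside this interval expanded
        by ``pad``."""
        return (
            self.chrom == other.chrom
            and other.start >= self.start - pad
            and other.end <= self.end + pad
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GeneModel:
    """A gene as an oriented interval; TSS/TES derive from the strand.

    On ``+`` the TSS is ``interval.start`` and the TES ``interval.end - 1``;
    on ``-`` the roles are mirrored.
    """

    interval: GenomicInterval
    strand: str
    name: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name!r}: invalid strand {self.strand!r}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    @property
    def length(self) -> int:
        return self.interval.length


def _ordered(a: GenomicInterval, b: GenomicInterval) -> tuple[GenomicInterval, GenomicInterval]:
    if (b.chrom, b.start, b.end) < (a.chrom, a.start, a.end):
        return b, a
    return a, b


@dataclass(frozen=True)
class ContactRecord:
    """One species-tagged contact between two anchors.

    Anchors are order-normalized so ``(chrom1, start1) <= (chrom2, start2)``.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    count: int = 1
    species: Species = "target"

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"contact count must be >= 1, got {self.count}")
        if self.species not in ("target", "spike"):
            raise ValueError(f"invalid species tag {self.species!r}")
        a, b = _ordered(self.anchor1, self.anchor2)
        if a is not self.anchor1:
            object.__setattr__(self, "anchor1", a)
            object.__setattr__(self, "anchor2", b)


PAIR_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "count", "species"]


@dataclass
class ContactPairSet:
    """A table of species-tagged contact records for one sample.

    Backed by a :class:`pandas.DataFrame` with columns ``chrom1, start1,
    end1, chrom2, start2, end2, count, species`` for vectorized downstream
    work (ranking, APA, pileup). Rows are order-normalized on construction.
    """

    df: pd.DataFrame
    sample_id: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in PAIR_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"contact table missing columns: {missing}")
        df = self.df.loc[:, PAIR_COLUMNS].reset_index(drop=True)
        swap = (df["chrom1"] > df["chrom2"]) | (
            (df["chrom1"] == df["chrom2"]) & (df["start1"] > df["start2"])
        )
        if bool(swap.any()):
            a_cols, b_cols = ["chrom1", "start1", "end1"], ["chrom2", "start2", "end2"]
            left = df.loc[swap, a_cols].to_numpy()
            df.loc[swap, a_cols] = df.loc[swap, b_cols].to_numpy()
            df.loc[swap, b_cols] = left
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_target(self) -> int:
        m = self.df["species"] == "target"
        return int(self.df.loc[m, "count"].sum())

    @property
    def n_spike(self) -> int:
        m = self.df["species"] == "spike"
        return int(self.df.loc[m, "count"].sum())

    @property
    def total_pairs(self) -> int:
        return int(self.df["count"].sum())

    def subset(self, species: Species) -> "ContactPairSet":
        sub = self.df[self.df["species"] == species].reset_index(drop=True)
        return ContactPairSet(sub, sample_id=self.sample_id)

    def records(self) -> Iterator[ContactRecord]:
        for row in self.df.itertuples(index=False):
            yield ContactRecord(
                GenomicInterval(row.chrom1, row.start1, row.end1),
                GenomicInterval(row.chrom2, row.start2, row.end2),
                count=int(row.count),
                species=row.species,
            )

    @classmethod
    def from_records(
        cls, records: list[ContactRecord], sample_id: str = ""
    ) -> "ContactPairSet":
        rows = [
            (
                r.anchor1.chrom,
                r.anchor1.start,
                r.anchor1.end,
                r.anchor2.chrom,
                r.anchor2.start,
                r.anchor2.end,
                r.count,
                r.species,
            )
            for r in records
        ]
        df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
        if not rows:
            df = df.astype(
                {
                    "start1": int,
                    "end1": int,
                    "start2": int,
                    "end2": int,
                    "count": int,
                }
            )
        return cls(df, sample_id=sample_id)

    @classmethod
    def empty(cls, sample_id: str = "") -> "ContactPairSet":
        return cls.from_records([], sample_id=sample_id)


def merge_pair_sets(a: ContactPairSet, b: ContactPairSet) -> ContactPairSet:
    """Concatenate two contact sets (inverse of a species split)."""
    df = pd.concat([a.df, b.df], ignore_index=True)
    return ContactPairSet(df, sample_id=a.sample_id or b.sample_id)


@dataclass
class Loop:
    """A pair of anchors with a raw contact count and its AQuA-CPM value.

    ``aqua_cpm`` is 0 until :func:`aquahichip.aqua.normalize_loops` fills it.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    raw_count: int = 0
    aqua_cpm: float = 0.0

    def __post_init__(self) -> None:
        if self.raw_count < 0:
            raise ValueError(f"raw_count must be >= 0, got {self.raw_count}")
        if self.aqua_cpm < 0:
            raise ValueError(f"aqua_cpm must be >= 0, got {self.aqua_cpm}")
        self.anchor1, self.anchor2 = _ordered(self.anchor1, self.anchor2)

    @property
    def is_cis(self) -> bool:
        return self.anchor1.chrom == self.anchor2.chrom

    @property
    def distance(self) -> int | None:
        """Distance in bp between anchor midpoints; None for trans loops."""
        if not self.is_cis:
            return None
        return abs(self.anchor2.mid - self.anchor1.mid)

    def key(self) -> tuple:
        return (
            self.anchor1.chrom,
            self.anchor1.start,
            self.anchor1.end,
            self.anchor2.chrom,
            self.anchor2.start,
            self.anchor2.end,
        )


@dataclass
class CoverageTrack:
    """Binned non-negative 1D signal over one chromosome.

    ``values[i]`` is the signal *mass* in bin ``[origin + i*bin_size,
    origin + (i+1)*bin_size)``. Queries outside the track return 0.
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    origin: int = 0

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def end(self) -> int:
        return self.origin + self.n_bins * self.bin_size

    @property
    def total_mass(self) -> float:
        return float(self.values.sum())

    def signal(self, interval: GenomicInterval) -> float:
        """Mass inside ``interval``; bins partially covered contribute
        fractionally. Out-of-range queries contribute 0."""
        if interval.chrom != self.chrom:
            return 0.0
        s = interval.start - self.origin
        e = interval.end - self.origin
        bs = self.bin_size
        lo = max(0, s // bs)
        hi = min(self.n_bins, -(-e // bs))
        if lo >= hi:
            return 0.0
        idx = np.arange(lo, hi)
        bin_start = idx * bs
        ov = np.minimum(bin_start + bs, e) - np.maximum(bin_start, s)
        return float(np.sum(self.values[lo:hi] * ov / bs))

    def density(self, interval: GenomicInterval) -> float:
        """Mean per-bp signal density over ``interval``."""
        return self.signal(interval) / interval.length

    def add_interval(self, start: int, end: int, mass: float) -> None:
        """Distribute ``mass`` over ``[start, end)`` proportional to bp
        overlap with each bin. Portions outside the track are dropped."""
        if end <= start or mass == 0:
            return
        s = start - self.origin
        e = end - self.origin
        bs = self.bin_size
        lo = max(0, s // bs)
        hi = min(self.n_bins, -(-e // bs))
        if lo >= hi:
            return
        idx = np.arange(lo, hi)
        bin_start = idx * bs
        ov = np.minimum(bin_start + bs, e) - np.maximum(bin_start, s)
        self.values[lo:hi] += mass * ov / (end - start)
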