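"""Spike-in separation and AQuA normalization of contact counts.

AQuA (absolute quantification of architecture) adds a fixed amount of
second-species chromatin to each sample before immunoprecipitation; contact
counts are then scaled to *AQuA-CPM*, contacts per million spike-in pairs:

    aqua_cpm = raw_count * 10^6 / n_spike

Because the spike-in input is constant across samples, AQuA-CPM values are
absolutely comparable between conditions: a global loss of target contacts is
not normalized away, unlike per-target-million scaling. ``n_spike`` counts
valid spike pairs weighted by record count, since counts are the unit of
signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .model import ContactPairSet, Loop


@dataclass(frozen=True)
class AquaFactors:
    """Per-sample AQuA normalizer."""

    sample_id: str
    n_target: int
    n_spike: int

    def __post_init__(self) -> None:
        if self.n_spike < 1:
            raise ValueError(
                f"sample {self.sample_id!r}: AQuA normalization requires at "
                "least one spike-in pair (n_spike >= 1); disable AQuA mode "
                "for spike-free data"
            )
        if self.n_target < 0:
            raise ValueError("n_target must be >= 0")

    @property
    def scale(self) -> float:
        return 1e6 / self.n_spike


def split_species(pairs: ContactPairSet) -> tuple[ContactPairSet, ContactPairSet]:
    """Partition a species-tagged contact set into (target, spike).

    The partition is exhaustive and disjoint; counts are conserved.
    """
    return pairs.subset("target"), pairs.subset("spike")


def compute_aqua_factors(pairs: ContactPairSet) -> AquaFactors:
    """Compute the AQuA scale factor 10^6 / n_spike for one sample.

    Raises if the sample has no spike-in pairs.
    """
    return AquaFactors(
        sample_id=pairs.sample_id,
        n_target=pairs.n_target,
        n_spike=pairs.n_spike,
    )


def normalize_loops(loops: list[Loop], factors: AquaFactors) -> list[Loop]:
    """Return loops with ``aqua_cpm = raw_count * factors.scale``.

    Raw counts are preserved; the input list is not modified.
    """
    return [
        Loop(
            anchor1=lp.anchor1,
            anchor2=lp.anchor2,
            raw_count=lp.raw_count,
            aqua_cpm=lp.raw_count * factors.scale,
        )
        for lp in loops
    ]


def write_factors_report(factors: AquaFactors, path: str | Path) -> None:
    """Write the per-sample normalizer to JSON for auditability."""
    Path(path).write_text(
        json.dumps(
            {
                "sample_id": factors.sample_id,
                "n_target": factors.n_target,
                "n_spike": factors.n_spike,
                "scale": factors.scale,
            },
            indent=2,
        )
        + "\n"
    )


def read_factors_report(path: str | Path) -> AquaFactors:
    d = json.loads(Path(path).read_text())
    return AquaFactors(
        sample_id=d["sample_id"], n_target=d["n_target"], n_spike=d["n_spike"]
    )
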