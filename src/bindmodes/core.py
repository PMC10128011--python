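"""Core in-memory containers shared across the pipeline.

All coordinates are 0-based half-open internally; 1-based inclusive
conventions exist only at I/O boundaries (see :mod:`bindmodes.io_formats`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np

VALID_BASES = frozenset("ACGTN")


class Interval(NamedTuple):
    """A strandless genomic interval, 0-based half-open."""

    replicon: str
    start: int
    end: int
    score: float | None = None

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        # floor of midpoint: deterministic tie-break for even widths
        return (self.start + self.end) // 2


class GeneRecord(NamedTuple):
    """A stranded gene, 0-based half-open."""

    replicon: str
    start: int
    end: int
    strand: str
    gene_id: str

    @property
    def orf_start(self) -> int:
        """ORF translation start site: `start` on +, `end - 1` on -."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GenomeSequence:
    """Named replicons of A/C/G/T/N characters."""

    replicons: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.replicons.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"replicon {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.replicons.values())

    def __getitem__(self, replicon: str) -> str:
        return self.replicons[replicon]

    def __contains__(self, replicon: str) -> bool:
        return replicon in self.replicons

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.replicons.items()}

    def extract(self, iv: Interval) -> str:
        seq = self.replicons[iv.replicon]
        if not (0 <= iv.start < iv.end <= len(seq)):
            raise ValueError(f"interval {iv} outside replicon bounds")
        return seq[iv.start : iv.end]


@dataclass
class IntervalSet:
    """An ordered collection of intervals (ChIP-seq peaks, random segments...)."""

    records: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for iv in self.records:
            if iv.start < 0 or iv.start >= iv.end:
                raise ValueError(f"malformed interval {iv}: need 0 <= start < end")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.records)

    def validate_against(self, genome: GenomeSequence) -> None:
        lengths = genome.lengths()
        for iv in self.records:
            if iv.replicon not in lengths:
                raise ValueError(f"unknown replicon {iv.replicon!r} in interval {iv}")
            if iv.end > lengths[iv.replicon]:
                raise ValueError(f"interval {iv} exceeds replicon length")

    def widths(self) -> np.ndarray:
        return np.array([iv.width for iv in self.records], dtype=np.int64)

    def by_replicon(self) -> dict[str, list[Interval]]:
        out: dict[str, list[Interval]] = {}
        for iv in self.records:
            out.setdefault(iv.replicon, []).append(iv)
        return out


@dataclass
class GeneAnnotation:
    """Stranded gene records; defines coding space and occupancy anchors."""

    records: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.records:
            if g.strand not in ("+", "-"):
                raise ValueError(f"gene {g.gene_id!r}: strand must be '+' or '-'")
            if g.start >= g.end:
                raise ValueError(f"gene {g.gene_id!r}: zero or negative length")
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    def intervals(self) -> IntervalSet:
        return IntervalSet([Interval(g.replicon, g.start, g.end) for g in self.records])

    def by_replicon(self) -> dict[str, list[GeneRecord]]:
        out: dict[str, list[GeneRecord]] = {}
        for g in self.records:
            out.setdefault(g.replicon, []).append(g)
        return out


@dataclass
class CoverageTrack:
    """Per-base non-negative read depth per replicon."""

    depths: dict[str, np.ndarray]
    label: str = "IP"

    def __post_init__(self) -> None:
        for name, vec in self.depths.items():
            vec = np.asarray(vec, dtype=float)
            if (vec < 0).any():
                raise ValueError(f"negative depth on replicon {name!r}")
            self.depths[name] = vec

    def __getitem__(self, replicon: str) -> np.ndarray:
        return self.depths[replicon]

    def total(self) -> float:
        return float(sum(vec.sum() for vec in self.depths.values()))

    def lengths(self) -> dict[str, int]:
        return {name: len(vec) for name, vec in self.depths.items()}


def merge_intervals(
    intervals: list[tuple[int, int]], bookend: bool = True
) -> list[tuple[int, int]]:
    """Union of (start, end) pairs on one replicon; bookended runs merge by default."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        touches = s <= out[-1][1] if bookend else s < out[-1][1]
        if touches:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def union_length(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))
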