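"""Shared domain containers and coordinate conventions.

Every interval in this package is 0-based half-open (BED convention).
VCF-side positions are 1-based; :func:`to_vcf_pos` / :func:`from_vcf_pos`
are the only sanctioned converters. Fine-scale map positions are stored
0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


def to_vcf_pos(pos0: int) -> int:
    """Convert a 0-based coordinate to a 1-based VCF POS."""
    return pos0 + 1


def from_vcf_pos(pos1: int) -> int:
    """Convert a 1-based VCF POS to a 0-based coordinate."""
    return pos1 - 1


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered chromosome name/length table (reference assembly container)."""

    chroms: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chroms) != len(self.lengths):
            raise ValueError("chroms and lengths differ in length")
        if len(set(self.chroms)) != len(self.chroms):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_items(cls, items: Iterable[tuple[str, int]]) -> "GenomeIndex":
        items = list(items)
        return cls(tuple(c for c, _ in items), tuple(int(l) for _, l in items))

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[self.chroms.index(chrom)]
        except ValueError as exc:
            raise KeyError(f"unknown chromosome {chrom!r}") from exc

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    def items(self) -> list[tuple[str, int]]:
        return list(zip(self.chroms, self.lengths))


@dataclass(frozen=True)
class IntervalRecord:
    """Generic genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor of the interval mean position (even-length convention)."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "IntervalRecord") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "IntervalRecord") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class FineScaleMap:
    """Per-inter-SNP-interval recombination rate landscape.

    ``positions`` are the SNP coordinates (0-based, strictly increasing);
    ``rates`` holds one value per adjacent SNP pair, in ``units``
    (population-scaled rho/bp or cM/Mb, recorded in the tag only — the
    landscape operations are unit-agnostic).
    """

    chrom: str
    positions: np.ndarray
    rates: np.ndarray
    units: str = "rho/bp"
    source: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape[0] != self.positions.shape[0] - 1:
            raise ValueError("need len(rates) == len(positions) - 1")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    @property
    def n_intervals(self) -> int:
        return int(self.rates.shape[0])

    @property
    def interval_lengths(self) -> np.ndarray:
        return np.diff(self.positions).astype(float)

    @property
    def interval_midpoints(self) -> np.ndarray:
        return (self.positions[:-1] + self.positions[1:]) // 2


@dataclass
class WindowMap:
    """Fixed-width window recombination map (default windows: 1 Mb).

    ``rates`` is NaN where a window carries no information (missing, not
    zero). ``rate_units`` is cM/Mb for pedigree maps; aggregated
    population maps keep the source units.
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    rates: np.ndarray
    sex: str = "both"
    n_meioses: int = 0
    rate_units: str = "cM/Mb"

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.rates = np.asarray(self.rates, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.rates)):
            raise ValueError("starts/ends/rates length mismatch")
        if np.any(self.ends <= self.starts):
            raise ValueError("windows must have positive length")
        finite = self.rates[np.isfinite(self.rates)]
        if np.any(finite < 0):
            raise ValueError("rates must be non-negative")

    @property
    def widths_mb(self) -> np.ndarray:
        return (self.ends - self.starts) / 1e6

    def to_series_index(self) -> list[tuple[str, int]]:
        return [(self.chrom, int(s)) for s in self.starts]


def merge_intervals(
    intervals: Sequence[IntervalRecord],
) -> list[IntervalRecord]:
    """Union of intervals, per chromosome, sorted."""
    out: list[IntervalRecord] = []
    by_chrom: dict[str, list[IntervalRecord]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(IntervalRecord(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(IntervalRecord(chrom, cur_s, cur_e))
    return out
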