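"""Filtering-based recombination hotspot and coldspot calling.

A hotspot candidate is a maximal run of consecutive inter-SNP intervals
whose rate strictly exceeds ``fold`` (default 10) times the chromosomal
mean rate. Candidates spanning fewer than ``min_snps`` SNPs or more than
``max_len`` bp are discarded, and surviving candidates separated by at
most ``merge_max_snps`` intervening SNPs across a gap of at most
``merge_max_gap`` bp are merged (transitively). Coldspots are maximal
runs strictly below ``fold`` (default 1/10) times the mean that span at
least ``min_snps`` SNPs; they get no length cap and no merging.

Thresholds are relative, so calls are invariant to rescaling the map by
any positive constant. Because the thresholds are strict, a uniform (or
all-zero) map yields no calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FineScaleMap, IntervalRecord
from .finescale_map import chromosome_mean_rate

__all__ = [
    "HotspotCall",
    "ColdspotCall",
    "call_hotspots",
    "call_coldspots",
    "recovery_score",
]


@dataclass(frozen=True)
class HotspotCall:
    interval: IntervalRecord  # first SNP .. last SNP + 1 (half-open emission)
    n_snps: int
    mean_rate: float
    fold_over_mean: float
    merged_from: int = 1


@dataclass(frozen=True)
class ColdspotCall:
    interval: IntervalRecord
    n_snps: int
    mean_rate: float


def _runs(mask: np.ndarray):
    """Yield (first_interval, last_interval) index pairs of maximal True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for a, b in zip(starts, ends):
        yield int(idx[a]), int(idx[b])


def _span_stats(fmap: FineScaleMap, i0: int, i1: int) -> tuple[int, int, int, float]:
    """(start_snp, end_snp, n_snps, length-weighted mean rate) of intervals i0..i1."""
    start = int(fmap.positions[i0])
    end = int(fmap.positions[i1 + 1])
    lens = fmap.interval_lengths[i0 : i1 + 1]
    mean = float(np.sum(fmap.rates[i0 : i1 + 1] * lens) / np.sum(lens))
    return start, end, i1 - i0 + 2, mean


def call_hotspots(
    fmap: FineScaleMap,
    fold: float = 10.0,
    min_snps: int = 2,
    max_len: int = 5_000,
    merge_max_snps: int = 2,
    merge_max_gap: int = 1_000,
    weighted_mean: bool = True,
) -> list[HotspotCall]:
    if fmap.n_intervals == 0:
        return []
    chrom_mean = chromosome_mean_rate(fmap, weighted=weighted_mean)
    thresh = fold * chrom_mean
    candidates = []  # (i0, i1) interval-index runs surviving stage 2
    for i0, i1 in _runs(fmap.rates > thresh):
        start, end, n_snps, _ = _span_stats(fmap, i0, i1)
        if n_snps < min_snps or (end - start) > max_len:
            continue
        candidates.append((i0, i1))

    # stage 3: transitive merge of candidates separated by <= merge_max_snps
    # intervening SNPs and a gap of <= merge_max_gap bp
    merged: list[list[int]] = []
    for i0, i1 in candidates:
        if merged:
            p0, p1 = merged[-1][-2], merged[-1][-1]
            # prev cluster's last SNP has index p1+1, next candidate's first
            # SNP has index i0; SNPs strictly between number i0 - p1 - 2
            intervening = i0 - p1 - 2
            gap = int(fmap.positions[i0]) - int(fmap.positions[p1 + 1])
            if intervening <= merge_max_snps and gap <= merge_max_gap:
                merged[-1][-1] = i1
                merged[-1][0] += 1
                continue
        merged.append([1, i0, i1])

    out = []
    for count, i0, i1 in merged:
        start, end, n_snps, mean = _span_stats(fmap, i0, i1)
        out.append(
            HotspotCall(
                interval=IntervalRecord(fmap.chrom, start, end + 1, "hot"),
                n_snps=n_snps,
                mean_rate=mean,
                fold_over_mean=mean / chrom_mean if chrom_mean > 0 else np.inf,
                merged_from=count,
            )
        )
    return out


def call_coldspots(
    fmap: FineScaleMap,
    fold: float = 0.1,
    min_snps: int = 3,
    weighted_mean: bool = True,
) -> list[ColdspotCall]:
    if fmap.n_intervals == 0:
        return []
    chrom_mean = chromosome_mean_rate(fmap, weighted=weighted_mean)
    thresh = fold * chrom_mean
    out = []
    for i0, i1 in _runs(fmap.rates < thresh):
        start, end, n_snps, mean = _span_stats(fmap, i0, i1)
        if n_snps < min_snps:
            continue
        out.append(
            ColdspotCall(
                interval=IntervalRecord(fmap.chrom, start, end + 1, "cold"),
                n_snps=n_snps,
                mean_rate=mean,
            )
        )
    return out


def recovery_score(
    calls: list[IntervalRecord],
    truth: list[IntervalRecord],
    min_reciprocal_overlap: float = 0.5,
) -> tuple[float | None, float | None]:
    """(sensitivity, precision) of calls against planted intervals.

    A planted interval is recovered when some call overlaps it by at least
    ``min_reciprocal_overlap`` of BOTH lengths. Sensitivity is None when
    there is no truth; precision is None when there are no calls.
    """

    def recip(a: IntervalRecord, b: IntervalRecord) -> bool:
        ov = a.overlap_len(b)
        return (
            ov >= min_reciprocal_overlap * a.length
            and ov >= min_reciprocal_overlap * b.length
        )

    sens = (
        None
        if not truth
        else sum(any(recip(t, c) for c in calls) for t in truth) / len(truth)
    )
    prec = (
        None
        if not calls
        else sum(any(recip(c, t) for t in truth) for c in calls) / len(calls)
    )
    return sens, prec
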