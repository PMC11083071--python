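"""GC content and nucleotide diversity of interval sets, matched
random-interval null distributions, and the significance comparisons
built on them.

Nucleotide diversity follows the unbiased per-site estimator
pi_site = 2 j (n - j) / (n (n - 1)) with n the non-missing haplotype
count and j the alternate-haplotype count; interval diversity divides
the summed site values by the interval's physical length in bp (the
convention of windowed-diversity outputs), so monomorphic positions
contribute zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomeIndex, IntervalRecord, merge_intervals
from .io_formats import MISSING, VariantTable

_GC_SET = set("GCgc")
_ACGT = set("ACGTacgt")


@dataclass
class NullDistribution:
    """Per-set values of a statistic over matched random interval sets."""

    statistic: str
    values: np.ndarray
    seed: int
    matched_sizes: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise ValueError("need at least one null set")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("null values must be finite")

    @property
    def n_sets(self) -> int:
        return int(self.values.size)


def gc_of_sequence(seq: str) -> float:
    """GC fraction over unambiguous bases; NaN if none (e.g. all-N)."""
    gc = sum(seq.count(b) for b in "GCgc")
    informative = gc + sum(seq.count(b) for b in "ATat")
    return gc / informative if informative else float("nan")


def gc_of_intervals(fasta, intervals: list) -> np.ndarray:
    """GC fraction per interval from an indexed FASTA (pyfaidx.Fasta or
    plain dict of sequences)."""
    out = np.empty(len(intervals))
    for i, iv in enumerate(intervals):
        ref = fasta[iv.chrom]
        if iv.end > len(ref):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} beyond sequence end"
            )
        out[i] = gc_of_sequence(str(ref[iv.start : iv.end]))
    return out


def site_pi(j: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-site pairwise diversity 2j(n-j)/(n(n-1))."""
    j = np.asarray(j, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n >= 2, 2.0 * j * (n - j) / (n * (n - 1)), np.nan)


def variant_site_pi(table: VariantTable) -> tuple[np.ndarray, int]:
    """(per-site pi, number of sites skipped for n < 2) for a table."""
    if table.haplotypes is not None:
        called = table.haplotypes != MISSING
        n = called.sum(axis=1)
        j = np.where(table.haplotypes == 1, 1, 0).sum(axis=1)
    else:
        called = table.genotypes != MISSING
        n = 2 * called.sum(axis=1)
        j = np.where(table.genotypes != MISSING, table.genotypes, 0).sum(axis=1)
    pi = site_pi(j, n)
    skipped = int(np.sum(n < 2))
    return np.where(np.isnan(pi), 0.0, pi), skipped


class PiCalculator:
    """Reusable per-chromosome prefix-sum index of per-site pi, so each
    interval query costs two binary searches."""

    def __init__(self, table: VariantTable) -> None:
        pi_sites, self.n_skipped = variant_site_pi(table)
        pos0 = table.pos - 1
        self._per_chrom: dict = {}
        for chrom in dict.fromkeys(table.chrom):
            sel = table.chrom == chrom
            self._per_chrom[chrom] = (
                pos0[sel],
                np.concatenate(([0.0], np.cumsum(pi_sites[sel]))),
            )

    def of_intervals(self, intervals: list) -> np.ndarray:
        out = np.empty(len(intervals))
        for i, iv in enumerate(intervals):
            if iv.chrom not in self._per_chrom:
                out[i] = 0.0
                continue
            p, csum = self._per_chrom[iv.chrom]
            lo = np.searchsorted(p, iv.start, side="left")
            hi = np.searchsorted(p, iv.end, side="left")
            out[i] = (csum[hi] - csum[lo]) / iv.length
        return out


def pi_of_intervals(table: VariantTable, intervals: list) -> np.ndarray:
    """Per-bp nucleotide diversity of each interval.

    Sums per-site pi over segregating sites inside the interval and
    divides by the interval's physical length; sites with fewer than two
    called haplotypes are skipped. For repeated queries against the same
    table (permutation nulls) build one :class:`PiCalculator` instead.
    """
    return PiCalculator(table).of_intervals(intervals)


def feature_table(
    intervals: list,
    label: str,
    fasta=None,
    variants: VariantTable | None = None,
) -> pd.DataFrame:
    """FeatureTable rows: chrom, start, end, class, length, gc, pi."""
    df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "class": label,
            "length": [iv.length for iv in intervals],
        }
    )
    df["gc"] = gc_of_intervals(fasta, intervals) if fasta is not None else np.nan
    df["pi"] = (
        pi_of_intervals(variants, intervals) if variants is not None else np.nan
    )
    return df


# ---------------------------------------------------------------------------
# matched random nulls


def sample_matched_random_intervals(
    genome: GenomeIndex,
    sizes: list,
    n_sets: int = 1000,
    seed: int = 0,
    exclude: list | None = None,
    max_attempts: int = 10_000,
) -> list:
    """``n_sets`` random interval sets, each matching ``sizes`` exactly.

    Start positions are uniform over valid placements (chromosome chosen
    in proportion to the number of valid starts for that size); proposals
    overlapping the exclusion mask are rejected.
    """
    rng = np.random.default_rng(seed)
    mask = merge_intervals(exclude) if exclude else []
    mask_by_chrom: dict = {}
    for iv in mask:
        mask_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    sets = []
    for _ in range(n_sets):
        one = []
        for size in sizes:
            weights = np.array(
                [max(0, l - size + 1) for _, l in genome.items()], dtype=float
            )
            if weights.sum() <= 0:
                raise ValueError(f"no chromosome can hold a {size} bp fragment")
            weights /= weights.sum()
            for _attempt in range(max_attempts):
                ci = int(rng.choice(len(genome.chroms), p=weights))
                chrom = genome.chroms[ci]
                start = int(rng.integers(0, genome.lengths[ci] - size + 1))
                end = start + size
                hits_mask = any(
                    start < me and ms < end
                    for ms, me in mask_by_chrom.get(chrom, [])
                )
                if not hits_mask:
                    one.append(IntervalRecord(chrom, start, end, "random"))
                    break
            else:
                raise ValueError(
                    f"could not place a {size} bp fragment outside the mask "
                    f"after {max_attempts} attempts"
                )
        sets.append(one)
    return sets


def empirical_p(
    observed: float, null: NullDistribution, tail: str = "upper"
) -> float:
    """Permutation p-value with the +1 convention (never exactly 0)."""
    n = null.n_sets
    if tail == "upper":
        return (int(np.sum(null.values >= observed)) + 1) / (n + 1)
    if tail == "lower":
        return (int(np.sum(null.values <= observed)) + 1) / (n + 1)
    if tail == "two-sided":
        up = (int(np.sum(null.values >= observed)) + 1) / (n + 1)
        lo = (int(np.sum(null.values <= observed)) + 1) / (n + 1)
        return min(1.0, 2.0 * min(up, lo))
    raise ValueError(f"unknown tail {tail!r}")


def ranksum_compare(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) between two samples.

    Uses SciPy's tie-corrected test (exact for small untied samples,
    normal approximation otherwise). All-tied input returns U = n1 n2 / 2
    and p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        return a.size * b.size / 2.0, 1.0
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(u), float(p)
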