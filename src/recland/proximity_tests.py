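"""TSS-proximity test for recombination hotspots and interval overlap
accounting.

A hotspot is deemed TSS-proximal when its midpoint falls inside the
+-``flank`` (default 3 kb) region around any annotated TSS, with inclusive
bounds. Significance comes from a random-point null: sets of uniformly
placed genomic points, scored the same way. The empirical permutation
p-value is the recommended number; a one-sample t-test of the null values
against the observation is reported alongside for comparability with
density-plot style summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomeIndex, IntervalRecord, merge_intervals
from .interval_features import NullDistribution, empirical_p


@dataclass(frozen=True)
class TssRegion:
    """TSS +- flank window with closed (inclusive) bounds, clipped to the
    chromosome."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    lo: int
    hi: int


@dataclass
class OverlapTestResult:
    observed: int
    null_values: np.ndarray
    null_mean: float
    null_sd: float
    empirical_p: float
    t_test_p: float
    direction: str  # enriched / depleted / none


def build_tss_windows(
    annotations: pd.DataFrame, flank: int = 3_000, genome: GenomeIndex | None = None
) -> list:
    """One window per gene around the strand-aware TSS; duplicates
    (identical chrom+TSS) collapsed; clipped at chromosome bounds."""
    required = {"gene_id", "chrom", "tss", "strand"}
    if not required.issubset(annotations.columns):
        raise ValueError(f"annotations need columns {sorted(required)}")
    bad = annotations.loc[~annotations["strand"].isin(["+", "-"]), "gene_id"]
    if len(bad):
        raise ValueError(f"genes without strand: {list(bad)}")
    out = []
    seen = set()
    for row in annotations.itertuples():
        key = (row.chrom, int(row.tss))
        if key in seen:
            continue
        seen.add(key)
        lo = max(0, int(row.tss) - flank)
        hi = int(row.tss) + flank
        if genome is not None:
            hi = min(hi, genome.length_of(row.chrom) - 1)
        out.append(
            TssRegion(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                tss=int(row.tss),
                strand=str(row.strand),
                lo=lo,
                hi=hi,
            )
        )
    return out


def _window_arrays(tss: list) -> dict:
    """Merged closed windows per chromosome as (los, his) sorted arrays."""
    merged = merge_intervals(
        [IntervalRecord(t.chrom, t.lo, t.hi + 1) for t in tss]
    )
    per_chrom: dict = {}
    for iv in merged:
        los, his = per_chrom.setdefault(iv.chrom, ([], []))
        los.append(iv.start)
        his.append(iv.end - 1)  # back to closed bound
    return {
        c: (np.asarray(l), np.asarray(h)) for c, (l, h) in per_chrom.items()
    }


def _points_in_windows(
    chroms: np.ndarray, points: np.ndarray, windows: dict
) -> int:
    total = 0
    for chrom, (los, his) in windows.items():
        pts = points[chroms == chrom]
        if pts.size == 0:
            continue
        idx = np.searchsorted(los, pts, side="right") - 1
        ok = idx >= 0
        total += int(np.sum(pts[ok] <= his[idx[ok]]))
    return total


def count_midpoint_overlaps(hotspots: list, tss: list) -> int:
    """Hotspots whose midpoint lies inside >=1 TSS window (inclusive
    bounds); each hotspot counted at most once."""
    if not hotspots or not tss:
        return 0
    windows = _window_arrays(tss)
    chroms = np.array([h.chrom for h in hotspots], dtype=object)
    mids = np.array([h.midpoint for h in hotspots], dtype=np.int64)
    return _points_in_windows(chroms, mids, windows)


def random_point_null_test(
    n_points: int,
    observed: int,
    tss: list,
    genome: GenomeIndex,
    n_sets: int = 1000,
    seed: int = 0,
    exclude: list | None = None,
) -> OverlapTestResult:
    """Random-point null for the TSS midpoint-overlap count.

    Each null set places ``n_points`` uniform positions genome-wide
    (weighted by chromosome length, avoiding ``exclude`` regions when
    given) and counts how many fall inside TSS windows.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    windows = _window_arrays(tss) if tss else {}
    lengths = np.array(genome.lengths, dtype=float)
    weights = lengths / lengths.sum()
    mask = merge_intervals(exclude) if exclude else []
    mask_by_chrom: dict = {}
    for iv in mask:
        mask_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    null_counts = np.empty(n_sets)
    chrom_names = np.array(genome.chroms, dtype=object)
    for s in range(n_sets):
        ci = rng.choice(len(genome.chroms), size=n_points, p=weights)
        pts = rng.integers(0, np.asarray(genome.lengths)[ci])
        if mask_by_chrom:
            for k in range(n_points):
                chrom = genome.chroms[ci[k]]
                for _ in range(10_000):
                    if not any(
                        ms <= pts[k] < me
                        for ms, me in mask_by_chrom.get(chrom, [])
                    ):
                        break
                    pts[k] = int(rng.integers(0, genome.lengths[ci[k]]))
                else:
                    raise ValueError(
                        "could not place a random point outside mask"
                    )
        null_counts[s] = _points_in_windows(chrom_names[ci], pts, windows)

    null = NullDistribution("tss_overlap_count", null_counts, seed, [n_points])
    mean = float(null_counts.mean())
    sd = float(null_counts.std(ddof=1)) if n_sets > 1 else 0.0
    if observed < mean:
        direction, tail = "depleted", "lower"
    elif observed > mean:
        direction, tail = "enriched", "upper"
    else:
        direction, tail = "none", "two-sided"
    emp = empirical_p(observed, null, tail)
    if sd == 0:
        t_p = 1.0 if observed == mean else 0.0
    else:
        _, t_p = stats.ttest_1samp(null_counts, popmean=observed)
        t_p = float(t_p)
    return OverlapTestResult(
        observed=int(observed),
        null_values=null_counts,
        null_mean=mean,
        null_sd=sd,
        empirical_p=float(emp),
        t_test_p=t_p,
        direction=direction,
    )


def interval_overlap_stats(a: list, b: list) -> dict:
    """Any-overlap (>=1 bp, half-open semantics) counts and fractions,
    both directions."""

    def count_overlapping(xs: list, ys: list) -> int:
        merged = merge_intervals(ys) if ys else []
        per_chrom: dict = {}
        for iv in merged:
            s, e = per_chrom.setdefault(iv.chrom, ([], []))
            s.append(iv.start)
            e.append(iv.end)
        per_chrom = {
            c: (np.asarray(s), np.asarray(e)) for c, (s, e) in per_chrom.items()
        }
        n = 0
        for iv in xs:
            if iv.chrom not in per_chrom:
                continue
            starts, ends = per_chrom[iv.chrom]
            # merged intervals are sorted and disjoint, so ends are increasing
            i = np.searchsorted(starts, iv.end, side="left")
            if i > 0 and ends[i - 1] > iv.start:
                n += 1
        return n

    n_a = count_overlapping(a, b)
    n_b = count_overlapping(b, a)
    return {
        "n_a": len(a),
        "n_b": len(b),
        "a_overlapping_b": n_a,
        "frac_a": n_a / len(a) if a else 0.0,
        "b_overlapping_a": n_b,
        "frac_b": n_b / len(b) if b else 0.0,
    }
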