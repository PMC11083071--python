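"""Independent brute-force oracles, deliberately written with plain
Python loops and literal rule application, separate from the library's
vectorized implementations."""

from __future__ import annotations

import numpy as np


def brute_mean_rate(positions, rates, weighted=True):
    lens = [positions[i + 1] - positions[i] for i in range(len(rates))]
    if weighted:
        return sum(r * l for r, l in zip(rates, lens)) / sum(lens)
    return sum(rates) / len(rates)


def brute_hotspots(
    positions,
    rates,
    fold=10.0,
    min_snps=2,
    max_len=5_000,
    merge_max_snps=2,
    merge_max_gap=1_000,
):
    """Literal three-stage hotspot filter; returns (start, end_snp, n_snps)
    spans (closed at SNP positions)."""
    mean = brute_mean_rate(positions, rates)
    thresh = fold * mean
    # stage 1: maximal runs of intervals strictly above threshold
    runs = []
    i = 0
    while i < len(rates):
        if rates[i] > thresh:
            j = i
            while j + 1 < len(rates) and rates[j + 1] > thresh:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    # stage 2: discard short-SNP or over-long candidates
    kept = []
    for i, j in runs:
        n_snps = j - i + 2
        span = positions[j + 1] - positions[i]
        if n_snps < min_snps or span > max_len:
            continue
        kept.append((i, j))
    # stage 3: transitive merge
    merged = []
    for i, j in kept:
        if merged:
            pi, pj = merged[-1]
            intervening = i - (pj + 1) - 1  # SNP indices between pj+1 and i
            gap = positions[i] - positions[pj + 1]
            if intervening <= merge_max_snps and gap <= merge_max_gap:
                merged[-1] = (pi, j)
                continue
        merged.append((i, j))
    return [
        (positions[i], positions[j + 1], j - i + 2) for i, j in merged
    ]


def brute_coldspots(positions, rates, fold=0.1, min_snps=3):
    mean = brute_mean_rate(positions, rates)
    thresh = fold * mean
    runs = []
    i = 0
    while i < len(rates):
        if rates[i] < thresh:
            j = i
            while j + 1 < len(rates) and rates[j + 1] < thresh:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return [
        (positions[i], positions[j + 1], j - i + 2)
        for i, j in runs
        if j - i + 2 >= min_snps
    ]


def brute_pi_per_bp(haplotypes, positions, start, end):
    """Mean pairwise difference per bp over [start, end), no missing data."""
    n = haplotypes.shape[1]
    total = 0
    n_pairs = 0
    for a in range(n):
        for b in range(a + 1, n):
            n_pairs += 1
            for s in range(haplotypes.shape[0]):
                if start <= positions[s] < end:
                    if haplotypes[s, a] != haplotypes[s, b]:
                        total += 1
    return total / n_pairs / (end - start)


def brute_gc(seq: str):
    gc = inf = 0
    for b in seq.upper():
        if b in "GC":
            gc += 1
            inf += 1
        elif b in "AT":
            inf += 1
    return gc / inf if inf else float("nan")


def brute_max_pwm_score(seq: str, log_odds: np.ndarray, complement: dict):
    """Exhaustive scan of both strands with explicit loops."""
    order = "ACGT"
    L = log_odds.shape[0]
    rc = "".join(complement[b] for b in reversed(seq))
    best = None
    for s in (seq, rc):
        for off in range(len(s) - L + 1):
            window = s[off : off + L]
            if any(b not in order for b in window):
                continue
            score = sum(log_odds[i, order.index(b)] for i, b in enumerate(window))
            if best is None or score > best:
                best = score
    return float("nan") if best is None else best


def random_small_map(rng: np.random.Generator):
    """Random fine-scale map with <=60 SNPs, mixing hot/cold-like rates and
    occasional near-threshold values to stress the caller."""
    n_snps = int(rng.integers(2, 61))
    gaps = rng.integers(1, 2_500, size=n_snps - 1)
    positions = np.concatenate(([0], np.cumsum(gaps)))
    base = rng.uniform(0.5, 2.0)
    rates = base * rng.choice(
        [0.0, 0.01, 0.05, 0.5, 1.0, 5.0, 20.0, 100.0],
        p=[0.05, 0.1, 0.15, 0.2, 0.2, 0.1, 0.1, 0.1],
        size=n_snps - 1,
    )
    return positions, rates
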