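"""Synthetic inputs with known ground truth for the recombination pipeline.

The generators emulate the statistical structure the analysis assumes,
at desk scale, with every planted feature recorded in a :class:`TruthSet`
so downstream stages can be scored (recovery, power, calibration) without
any external data:

* a fine-scale rate landscape with planted hotspots (rate x fold) and
  coldspots (rate x a small fraction) under multiplicative lognormal noise;
* chip-density pedigree genotypes from a two-founder-breed cross design
  (F1 focal parents x purebred mates, markers ascertained to differentiate
  the founder breeds, mirroring hybrid pig pedigrees), with crossovers
  placed by inverse CDF of a genetic map and Poisson counts per meiosis;
* interval sequences with GC bias and planted motif consensus occurrences;
* segregating-site tables with a nucleotide-diversity contrast, allele
  counts drawn from the neutral 1/j frequency spectrum;
* TSS and promoter-proxy peak annotations with a controllable fraction of
  peaks near TSSs.

All draws are deterministic given ``SimConfig.seed``; each generator uses
an independent child stream so adding one stage never perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FineScaleMap, GenomeIndex, IntervalRecord, WindowMap
from .io_formats import MISSING, VariantTable

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# child-stream tags, one per generator
_S_FINEMAP, _S_PEDIGREE, _S_SEQ, _S_VAR, _S_ANNOT = range(5)


@dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline inputs.

    Defaults follow the porcine setting the pipeline targets: a 10 Mb
    chromosome sampled at ~500 bp SNP spacing, hotspots ~50-fold over
    background at the 2-3 kb scale, 36 diploid (72 haplotype) samples,
    hotspot/coldspot GC of 46.46%/40.53% around a 42.96% background, site
    densities calibrated so hotspot/coldspot diversity sit at
    0.00291/0.00198 per bp under the neutral spectrum, chip markers every
    50 kb, and 63.5% of promoter-proxy peaks near TSSs.
    """

    seed: int = 1
    chrom: str = "1"
    chrom_length: int = 10_000_000
    # fine-scale landscape
    snp_spacing: float = 500.0
    background_rate: float = 0.001
    hotspot_count: int = 20
    hotspot_width_range: tuple[int, int] = (2_000, 3_000)
    hotspot_fold: float = 50.0
    coldspot_count: int = 20
    coldspot_width_range: tuple[int, int] = (5_000, 20_000)
    coldspot_fold: float = 0.02
    rate_noise_sd: float = 0.3
    broad_scale_sd: float = 0.5
    broad_scale_block: int = 1_000_000
    # pedigree genotypes
    n_fids: int = 20
    offspring_per_fid: int = 50
    marker_spacing: int = 50_000
    genotype_error_rate: float = 0.001
    enforce_obligate_crossover: bool = False
    breed_a_freq_range: tuple[float, float] = (0.05, 0.25)
    breed_b_freq_range: tuple[float, float] = (0.75, 0.95)
    n_populations: int = 2
    # interval sequences
    gc_background: float = 0.4296
    gc_hotspot: float = 0.4646
    gc_coldspot: float = 0.4053
    motif_plant_rate_hot: float = 0.8
    motif_plant_rate_cold: float = 0.05
    # segregating sites
    n_haplotypes: int = 72
    site_density_hot: float = 0.0141
    site_density_cold: float = 0.0096
    site_density_background: float = 0.0118
    # annotations
    n_genes: int = 100
    n_peaks: int = 200
    peak_width: int = 1_648
    peak_tss_fraction: float = 0.635

    def __post_init__(self) -> None:
        probs = [
            self.genotype_error_rate,
            self.gc_background,
            self.gc_hotspot,
            self.gc_coldspot,
            self.motif_plant_rate_hot,
            self.motif_plant_rate_cold,
            self.peak_tss_fraction,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.hotspot_fold <= 0 or self.coldspot_fold <= 0:
            raise ValueError("folds must be positive")
        for lo, hi in (self.hotspot_width_range, self.coldspot_width_range):
            if not (0 < lo <= hi < self.chrom_length):
                raise ValueError("planted widths must fit the chromosome")
        if self.n_haplotypes < 2 or self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be an even number >= 2")

    def genome(self) -> GenomeIndex:
        return GenomeIndex.from_items([(self.chrom, self.chrom_length)])

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class TruthSet:
    """Planted ground truth sufficient to score every downstream stage."""

    hotspots: list = field(default_factory=list)
    coldspots: list = field(default_factory=list)
    crossovers: dict = field(default_factory=dict)  # meiosis id -> positions
    crossover_sex: dict = field(default_factory=dict)  # meiosis id -> M/F
    motif_plants: list = field(default_factory=list)  # dicts: pos, strand, class

    def to_json(self, path: str | Path) -> None:
        payload = {
            "hotspots": [[h.chrom, h.start, h.end] for h in self.hotspots],
            "coldspots": [[c.chrom, c.start, c.end] for c in self.coldspots],
            "crossovers": {k: list(map(float, v)) for k, v in self.crossovers.items()},
            "crossover_sex": self.crossover_sex,
            "motif_plants": self.motif_plants,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        d = json.loads(Path(path).read_text())
        return cls(
            hotspots=[IntervalRecord(c, s, e, "hot") for c, s, e in d["hotspots"]],
            coldspots=[IntervalRecord(c, s, e, "cold") for c, s, e in d["coldspots"]],
            crossovers={k: list(v) for k, v in d["crossovers"].items()},
            crossover_sex=dict(d["crossover_sex"]),
            motif_plants=list(d["motif_plants"]),
        )


def _place_nonoverlapping(
    rng: np.random.Generator,
    widths: list[int],
    chrom_length: int,
    taken: list[tuple[int, int]],
    max_attempts: int = 10_000,
) -> list[tuple[int, int]]:
    placed = []
    occupied = list(taken)
    for w in widths:
        for _ in range(max_attempts):
            s = int(rng.integers(0, chrom_length - w))
            e = s + w
            if all(e <= a or s >= b for a, b in occupied):
                placed.append((s, e))
                occupied.append((s, e))
                break
        else:
            raise ValueError(
                "could not place planted intervals without overlap; "
                "reduce counts/widths or enlarge the chromosome"
            )
    return placed


def simulate_fine_map(config: SimConfig) -> tuple[FineScaleMap, TruthSet]:
    """Fine-scale landscape with planted hotspots/coldspots.

    SNP spacings are exponential with mean ``snp_spacing``; each
    inter-SNP interval's rate is ``background_rate`` times the planted
    fold of the region containing the interval midpoint, times
    ``exp(N(0, rate_noise_sd))`` multiplicative noise (exactly 1 when the
    noise sd is 0).
    """
    rng = config.rng(_S_FINEMAP)
    hot_w = [int(rng.integers(*config.hotspot_width_range, endpoint=True))
             for _ in range(config.hotspot_count)]
    cold_w = [int(rng.integers(*config.coldspot_width_range, endpoint=True))
              for _ in range(config.coldspot_count)]
    hot_iv = _place_nonoverlapping(rng, hot_w, config.chrom_length, [])
    cold_iv = _place_nonoverlapping(rng, cold_w, config.chrom_length, hot_iv)

    n_guess = int(config.chrom_length / config.snp_spacing * 1.3) + 100
    gaps = rng.exponential(config.snp_spacing, size=n_guess)
    positions = np.cumsum(gaps).astype(np.int64)
    positions = positions[positions < config.chrom_length]
    positions = np.unique(np.concatenate(([0], positions)))
    if positions.size < 2:
        raise ValueError("chromosome too short for the requested SNP spacing")

    mids = (positions[:-1] + positions[1:]) // 2
    fold = np.ones(mids.size)
    for s, e in hot_iv:
        fold[(mids >= s) & (mids < e)] = config.hotspot_fold
    for s, e in cold_iv:
        fold[(mids >= s) & (mids < e)] = config.coldspot_fold
    rates = config.background_rate * fold
    if config.broad_scale_sd > 0:
        # Mb-scale landscape variation (real maps vary severalfold between
        # 1 Mb windows, which is what broad-scale map comparisons measure)
        n_blocks = int(np.ceil(config.chrom_length / config.broad_scale_block))
        block_mult = rng.lognormal(0.0, config.broad_scale_sd, size=n_blocks)
        rates = rates * block_mult[mids // config.broad_scale_block]
    if config.rate_noise_sd > 0:
        rates = rates * rng.lognormal(0.0, config.rate_noise_sd, size=rates.size)

    truth = TruthSet(
        hotspots=[IntervalRecord(config.chrom, s, e, "hot") for s, e in sorted(hot_iv)],
        coldspots=[IntervalRecord(config.chrom, s, e, "cold") for s, e in sorted(cold_iv)],
    )
    fmap = FineScaleMap(config.chrom, positions, rates, units="rho/bp", source="simulated")
    return fmap, truth


# ---------------------------------------------------------------------------
# pedigree meioses


def _map_breakpoints(genetic_map) -> tuple[np.ndarray, np.ndarray]:
    """(bp positions, cumulative Morgans) knots of a cM/Mb genetic map."""
    if isinstance(genetic_map, WindowMap):
        pos = np.concatenate(([genetic_map.starts[0]], genetic_map.ends))
        rates = np.nan_to_num(genetic_map.rates, nan=0.0)
        seg_m = rates * (genetic_map.ends - genetic_map.starts) / 1e8
    elif isinstance(genetic_map, FineScaleMap):
        pos = genetic_map.positions
        seg_m = genetic_map.rates * np.diff(pos) / 1e8
    else:
        raise TypeError("genetic_map must be a WindowMap or FineScaleMap")
    cum = np.concatenate(([0.0], np.cumsum(seg_m)))
    return pos.astype(float), cum


def total_map_length_morgans(genetic_map) -> float:
    _, cum = _map_breakpoints(genetic_map)
    return float(cum[-1])


def simulate_pedigree_meioses(
    config: SimConfig, genetic_map
) -> tuple[VariantTable, pd.DataFrame, TruthSet]:
    """Chip-density family genotypes with known crossovers.

    Per meiosis (one transmitted gamete per offspring) the crossover count
    is Poisson with mean equal to the map length in Morgans (optionally
    resampled to be >= 1 when ``enforce_obligate_crossover``); positions
    follow the inverse CDF of the cumulative genetic map. Focal parents
    are F1s of two founder breeds and mates are breed-A purebreds, so most
    chip markers are informative for transmission. Genotype errors are
    applied to offspring genotypes only, each error replacing the true
    genotype with one of the other two values.
    """
    rng = config.rng(_S_PEDIGREE)
    pos_knots, cum = _map_breakpoints(genetic_map)
    L = float(cum[-1])
    if L <= 0:
        raise ValueError("genetic map has non-positive total length")
    chrom_length = int(pos_knots[-1])

    markers = np.arange(
        config.marker_spacing // 2, chrom_length, config.marker_spacing, dtype=np.int64
    )
    n_mark = markers.size
    p_a = rng.uniform(*config.breed_a_freq_range, size=n_mark)
    p_b = rng.uniform(*config.breed_b_freq_range, size=n_mark)

    fid_ids = [f"FID{i:03d}" for i in range(config.n_fids)]
    fid_sex = ["M" if i % 2 == 0 else "F" for i in range(config.n_fids)]
    fid_pop = [f"POP{i % config.n_populations}" for i in range(config.n_fids)]
    mate_ids = [f"MATE{i:03d}" for i in range(config.n_fids)]

    # FID haplotypes: hap 0 from breed A, hap 1 from breed B (F1 design)
    fid_h = np.stack(
        [
            np.stack(
                [
                    (rng.random(n_mark) < p_a).astype(np.int8),
                    (rng.random(n_mark) < p_b).astype(np.int8),
                ]
            )
            for _ in fid_ids
        ]
    )  # (n_fids, 2, n_mark)
    mate_h = np.stack(
        [
            np.stack(
                [
                    (rng.random(n_mark) < p_a).astype(np.int8),
                    (rng.random(n_mark) < p_a).astype(np.int8),
                ]
            )
            for _ in mate_ids
        ]
    )

    truth = TruthSet()
    ped_rows = []
    samples, genotype_cols = [], []
    for i, fid in enumerate(fid_ids):
        ped_rows.append((fid, f"SIREF{i}", "0", fid_sex[i], fid_pop[i]))
        ped_rows.append(
            (mate_ids[i], "0", "0", "F" if fid_sex[i] == "M" else "M", fid_pop[i])
        )
        samples += [fid, mate_ids[i]]
        genotype_cols += [fid_h[i].sum(axis=0), mate_h[i].sum(axis=0)]

    def gamete(haps: np.ndarray, record_as: str, sex: str) -> np.ndarray:
        n_xo = int(rng.poisson(L))
        if config.enforce_obligate_crossover:
            while n_xo == 0:
                n_xo = int(rng.poisson(L))
        u = np.sort(rng.uniform(0.0, L, size=n_xo))
        xo_pos = np.interp(u, cum, pos_knots)
        truth.crossovers[record_as] = [float(x) for x in xo_pos]
        truth.crossover_sex[record_as] = sex
        origin = int(rng.integers(0, 2))
        switch_counts = np.searchsorted(xo_pos, markers, side="right")
        hap_idx = (origin + switch_counts) % 2
        return haps[hap_idx, np.arange(n_mark)]

    for i, fid in enumerate(fid_ids):
        mate_sex = "F" if fid_sex[i] == "M" else "M"
        for k in range(config.offspring_per_fid):
            off = f"{fid}.O{k:03d}"
            fid_allele = gamete(fid_h[i], f"{fid}|{off}", fid_sex[i])
            mate_allele = gamete(mate_h[i], f"{mate_ids[i]}|{off}", mate_sex)
            gt = (fid_allele + mate_allele).astype(np.int8)
            if config.genotype_error_rate > 0:
                err = rng.random(n_mark) < config.genotype_error_rate
                if err.any():
                    shift = rng.integers(1, 3, size=int(err.sum()))
                    gt[err] = ((gt[err] + shift) % 3).astype(np.int8)
            sex = "M" if rng.random() < 0.5 else "F"
            ped_rows.append(
                (off, fid if fid_sex[i] == "M" else mate_ids[i],
                 fid if fid_sex[i] == "F" else mate_ids[i], sex, fid_pop[i])
            )
            samples.append(off)
            genotype_cols.append(gt)

    genotypes = np.stack(genotype_cols, axis=1).astype(np.int8)
    table = VariantTable(
        chrom=np.array([config.chrom] * n_mark, dtype=object),
        pos=markers + 1,
        ref=np.array(["A"] * n_mark, dtype=object),
        alt=[["G"]] * n_mark,
        qual=np.full(n_mark, 100.0),
        mean_depth=np.full(n_mark, np.nan),
        samples=samples,
        genotypes=genotypes,
    )
    ped = pd.DataFrame(
        ped_rows, columns=["id", "sire", "dam", "sex", "population"]
    )
    return table, ped, truth


# ---------------------------------------------------------------------------
# sequences


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _gc_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def simulate_sequences(config: SimConfig, truth: TruthSet, pwm) -> dict[str, str]:
    """Chromosome sequence with GC bias in planted intervals and motif plants.

    Bases are i.i.d. at ``gc_hotspot`` / ``gc_coldspot`` GC inside planted
    hotspots / coldspots and ``gc_background`` elsewhere. The PWM consensus
    is planted (random strand and offset) with probability
    ``motif_plant_rate_hot`` per hotspot and ``motif_plant_rate_cold`` per
    coldspot; plants are appended to ``truth.motif_plants``.
    """
    for gc in (config.gc_background, config.gc_hotspot, config.gc_coldspot):
        if not (0.0 <= gc <= 1.0):
            raise ValueError("GC fractions must lie in [0, 1]")
    planted = truth.hotspots + truth.coldspots
    if planted:
        shortest = min(iv.length for iv in planted)
        if pwm is not None and pwm.length > shortest:
            raise ValueError("PWM longer than the shortest planted interval")

    rng = config.rng(_S_SEQ)
    seq = _gc_bases(rng, config.chrom_length, config.gc_background)
    for iv in truth.hotspots:
        seq[iv.start : iv.end] = _gc_bases(rng, iv.length, config.gc_hotspot)
    for iv in truth.coldspots:
        seq[iv.start : iv.end] = _gc_bases(rng, iv.length, config.gc_coldspot)

    if pwm is not None:
        consensus = pwm.consensus()
        for iv, rate in [(h, config.motif_plant_rate_hot) for h in truth.hotspots] + [
            (c, config.motif_plant_rate_cold) for c in truth.coldspots
        ]:
            if rng.random() >= rate:
                continue
            offset = int(rng.integers(0, iv.length - pwm.length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            planted_seq = consensus if strand == "+" else reverse_complement(consensus)
            seq[iv.start + offset : iv.start + offset + pwm.length] = list(planted_seq)
            truth.motif_plants.append(
                {
                    "chrom": iv.chrom,
                    "pos": iv.start + offset,
                    "strand": strand,
                    "class": iv.label or "",
                }
            )
    return {config.chrom: "".join(seq)}


# ---------------------------------------------------------------------------
# segregating sites


def neutral_spectrum_probs(n_haplotypes: int) -> np.ndarray:
    """P(derived count = j) proportional to 1/j for j = 1..n-1."""
    j = np.arange(1, n_haplotypes)
    w = 1.0 / j
    return w / w.sum()


def simulate_variants(config: SimConfig, truth: TruthSet) -> VariantTable:
    """Segregating sites with a hotspot-vs-coldspot diversity contrast.

    Site counts are Poisson with per-bp density ``site_density_hot`` inside
    planted hotspots, ``site_density_cold`` inside coldspots and
    ``site_density_background`` elsewhere; derived-allele counts follow the
    neutral 1/j spectrum over ``n_haplotypes`` haplotypes (phased, paired
    into diploids).
    """
    rng = config.rng(_S_VAR)
    n = config.n_haplotypes
    probs = neutral_spectrum_probs(n)

    regions: list[tuple[int, int, float]] = []
    cut = sorted(
        [(iv.start, iv.end, config.site_density_hot) for iv in truth.hotspots]
        + [(iv.start, iv.end, config.site_density_cold) for iv in truth.coldspots]
    )
    cursor = 0
    for s, e, d in cut:
        if s > cursor:
            regions.append((cursor, s, config.site_density_background))
        regions.append((s, e, d))
        cursor = e
    if cursor < config.chrom_length:
        regions.append((cursor, config.chrom_length, config.site_density_background))

    positions = []
    for s, e, d in regions:
        k = int(rng.poisson(d * (e - s)))
        if k:
            positions.append(rng.integers(s, e, size=k))
    if positions:
        pos = np.unique(np.concatenate(positions))
    else:
        pos = np.array([], dtype=np.int64)
    m = pos.size

    haps = np.zeros((m, n), dtype=np.int8)
    counts = rng.choice(np.arange(1, n), size=m, p=probs)
    for i in range(m):
        carriers = rng.choice(n, size=int(counts[i]), replace=False)
        haps[i, carriers] = 1
    genotypes = (haps[:, 0::2] + haps[:, 1::2]).astype(np.int8)
    samples = [f"WGS{i:03d}" for i in range(n // 2)]
    return VariantTable(
        chrom=np.array([config.chrom] * m, dtype=object),
        pos=pos + 1,
        ref=np.array(["A"] * m, dtype=object),
        alt=[["G"]] * m,
        qual=np.full(m, 100.0),
        mean_depth=np.full(m, 10.0),
        samples=samples,
        genotypes=genotypes,
        haplotypes=haps,
    )


# ---------------------------------------------------------------------------
# annotations


def simulate_annotations(
    config: SimConfig,
) -> tuple[pd.DataFrame, list[IntervalRecord]]:
    """TSS table and promoter-proxy peak intervals.

    Each peak's midpoint is placed uniformly within +-3 kb of a random TSS
    with probability ``peak_tss_fraction`` and uniformly on the chromosome
    otherwise.
    """
    rng = config.rng(_S_ANNOT)
    if config.n_genes == 0 and config.n_peaks > 0 and config.peak_tss_fraction > 0:
        raise ValueError("cannot place peaks near TSSs with n_genes=0")
    tss_pos = np.sort(
        rng.choice(config.chrom_length, size=config.n_genes, replace=False)
    )
    strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    tss = pd.DataFrame(
        {
            "gene_id": [f"GENE{i:04d}" for i in range(config.n_genes)],
            "chrom": config.chrom,
            "tss": tss_pos.astype(int),
            "strand": strands,
        }
    )
    peaks = []
    half = config.peak_width // 2
    for i in range(config.n_peaks):
        if config.n_genes > 0 and rng.random() < config.peak_tss_fraction:
            anchor = int(tss_pos[rng.integers(0, config.n_genes)])
            mid = anchor + int(rng.integers(-3_000, 3_001))
        else:
            mid = int(rng.integers(0, config.chrom_length))
        s = max(0, mid - half)
        e = min(config.chrom_length, mid + config.peak_width - half)
        if e <= s:
            s, e = max(0, e - 1), max(1, e)
        peaks.append(IntervalRecord(config.chrom, s, e, f"peak{i:04d}"))
    return tss, peaks
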