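"""Crossover detection from pedigree genotypes and 1 Mb meiotic maps.

The workflow mirrors classic family-based recombination mapping: select
focal individuals (FIDs) whose meioses are observable through genotyped
offspring, phase each FID by transmission, detect crossovers as origin
switches supported by ``min_support`` informative markers on both sides,
mask unreliable close double crossovers (< 3 Mb), and estimate per-window
rates by Monte-Carlo allocation of each crossover within its bounding
marker interval. The transmission phasing + run-based detector here is a
deliberately simple stand-in for dedicated pedigree-phasing tools and is
validated against simulation truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomeIndex, IntervalRecord, WindowMap
from .io_formats import MISSING, VariantTable

UNKNOWN = "0"


@dataclass(frozen=True)
class CrossoverEvent:
    """One detected crossover, bounded by flanking informative markers."""

    meiosis: str
    chrom: str
    left_pos: int  # last informative marker before the switch (0-based)
    right_pos: int  # first informative marker after the switch
    sex: str

    def __post_init__(self) -> None:
        if self.left_pos >= self.right_pos:
            raise ValueError("left_pos must be < right_pos")

    @property
    def midpoint(self) -> float:
        return (self.left_pos + self.right_pos) / 2.0


@dataclass
class Meiosis:
    fid: str
    offspring: str
    sex: str
    population: str
    crossovers: list = field(default_factory=list)
    masked: list = field(default_factory=list)

    @property
    def meiosis_id(self) -> str:
        return f"{self.fid}|{self.offspring}"


@dataclass
class MeiosisSet:
    meioses: list

    @property
    def n_meioses(self) -> int:
        return len(self.meioses)

    def all_crossovers(self) -> list:
        return [xo for m in self.meioses for xo in m.crossovers]

    def mean_crossovers_per_meiosis(self) -> float:
        if not self.meioses:
            raise ValueError("empty meiosis set")
        return len(self.all_crossovers()) / self.n_meioses

    def filter_sex(self, sex: str) -> "MeiosisSet":
        return MeiosisSet([m for m in self.meioses if m.sex == sex])


@dataclass
class OriginSequence:
    """Per-offspring grand-parental origin calls along one chromosome.

    ``origins`` is 1 or 2 for the two FID haplotypes and 0 where the
    marker is uninformative or missing.
    """

    chrom: str
    positions: np.ndarray  # 0-based marker positions (FID-het markers)
    origins: np.ndarray


# ---------------------------------------------------------------------------
# FID selection


def offspring_counts(ped: pd.DataFrame) -> pd.Series:
    counts = pd.concat([ped["sire"], ped["dam"]]).value_counts()
    counts = counts.drop(UNKNOWN, errors="ignore")
    return counts.reindex(ped["id"], fill_value=0)


def select_fids(ped: pd.DataFrame) -> set:
    """FIDs: known parent and >=2 offspring, or no known parent and >=4."""
    counts = offspring_counts(ped)
    has_parent = ((ped["sire"] != UNKNOWN) | (ped["dam"] != UNKNOWN)).to_numpy()
    n_off = counts.to_numpy()
    keep = (has_parent & (n_off >= 2)) | (~has_parent & (n_off >= 4))
    return set(ped["id"].to_numpy()[keep])


# ---------------------------------------------------------------------------
# transmission phasing


@dataclass
class PhasingResult:
    fid: str
    origins: dict  # offspring id -> {chrom -> OriginSequence}
    n_mendelian_errors: int


def _transmitted_allele(g_off: int, g_mate: int) -> int | None:
    """FID-transmitted allele at a FID-het marker; -1 ambiguous, None = error."""
    if g_off == MISSING:
        return -1
    if g_mate in (0, 2):
        a = g_off - g_mate // 2
        return a if a in (0, 1) else None  # Mendelian inconsistency
    if g_off == 0:
        return 0
    if g_off == 2:
        return 1
    return -1  # mate het/missing and offspring het: ambiguous


def phase_by_transmission(
    table: VariantTable, ped: pd.DataFrame, fid: str
) -> PhasingResult:
    """Assign each offspring's inherited allele to FID haplotype 1 or 2.

    At each FID-heterozygous marker the transmitted allele is determined
    when the other parent is homozygous (or the offspring is homozygous);
    the FID's phase is then fixed greedily, marker by marker, by majority
    vote of offspring continuity (minimum-recombinant heuristic), anchored
    at the first informative marker of the first offspring.
    """
    ped_idx = ped.set_index("id")
    kids = ped[(ped["sire"] == fid) | (ped["dam"] == fid)]
    kids = kids[kids["id"].isin(table.samples)]
    if len(kids) < 2:
        raise ValueError(f"FID {fid} has fewer than 2 genotyped offspring")
    col = {s: i for i, s in enumerate(table.samples)}
    if fid not in col:
        raise ValueError(f"FID {fid} is not genotyped")

    n_mendel = 0
    origins: dict = {row.id: {} for row in kids.itertuples()}
    mates = []
    for row in kids.itertuples():
        mate = row.dam if row.sire == fid else row.sire
        mates.append(col.get(mate))  # None when mate unknown/ungenotyped

    for chrom in dict.fromkeys(table.chrom):
        cmask = table.chrom == chrom
        fid_gt = table.genotypes[cmask, col[fid]]
        het = fid_gt == 1
        positions = table.pos[cmask][het] - 1  # store 0-based
        n_m = positions.size
        kid_ids = [row.id for row in kids.itertuples()]
        trans = np.full((len(kid_ids), n_m), -1, dtype=np.int8)
        for k, row in enumerate(kids.itertuples()):
            g_off = table.genotypes[cmask, col[row.id]][het]
            g_mate = (
                table.genotypes[cmask, mates[k]][het]
                if mates[k] is not None
                else np.full(n_m, MISSING, dtype=np.int8)
            )
            for j in range(n_m):
                t = _transmitted_allele(int(g_off[j]), int(g_mate[j]))
                if t is None:
                    n_mendel += 1
                    trans[k, j] = -1
                else:
                    trans[k, j] = t

        # greedy phase: h[j] = allele carried by FID haplotype 1 at marker j
        orig = np.zeros((len(kid_ids), n_m), dtype=np.int8)
        prev = np.zeros(len(kid_ids), dtype=np.int8)  # 0 = no origin yet
        for j in range(n_m):
            informative = np.flatnonzero(trans[:, j] >= 0)
            if informative.size == 0:
                continue
            votes = []
            for k in informative:
                if prev[k] == 1:
                    votes.append(int(trans[k, j]))
                elif prev[k] == 2:
                    votes.append(1 - int(trans[k, j]))
            if votes:
                h = int(round(np.mean(votes))) if np.mean(votes) != 0.5 else votes[0]
            else:
                h = int(trans[informative[0], j])  # anchor
            for k in informative:
                o = 1 if trans[k, j] == h else 2
                orig[k, j] = o
                prev[k] = o
        for k, kid in enumerate(kid_ids):
            origins[kid][chrom] = OriginSequence(chrom, positions.copy(), orig[k])
    return PhasingResult(fid=fid, origins=origins, n_mendelian_errors=n_mendel)


# ---------------------------------------------------------------------------
# crossover detection


def detect_crossovers(
    origin_seq: OriginSequence,
    min_support: int = 3,
    meiosis: str = "",
    sex: str = "U",
) -> list:
    """Crossovers at run boundaries with >= min_support markers on each side.

    Runs of consistent origin shorter than ``min_support`` are treated as
    genotyping errors: they are dropped and their flanking same-origin runs
    merged, iteratively, before boundaries are emitted.
    """
    keep = origin_seq.origins > 0
    pos = origin_seq.positions[keep]
    orig = origin_seq.origins[keep]
    if pos.size == 0:
        return []

    runs = []  # [origin, count, first_pos, last_pos]
    for p, o in zip(pos, orig):
        if runs and runs[-1][0] == o:
            runs[-1][1] += 1
            runs[-1][3] = int(p)
        else:
            runs.append([int(o), 1, int(p), int(p)])

    while True:
        short = [i for i, r in enumerate(runs) if r[1] < min_support]
        if not short or len(runs) <= 1:
            if short:
                runs = [r for i, r in enumerate(runs) if i not in set(short)]
            break
        runs = [r for i, r in enumerate(runs) if i not in set(short)]
        merged = []
        for r in runs:
            if merged and merged[-1][0] == r[0]:
                merged[-1][1] += r[1]
                merged[-1][3] = r[3]
            else:
                merged.append(r)
        runs = merged
        if all(r[1] >= min_support for r in runs):
            break

    events = []
    for left, right in zip(runs[:-1], runs[1:]):
        events.append(
            CrossoverEvent(
                meiosis=meiosis,
                chrom=origin_seq.chrom,
                left_pos=left[3],
                right_pos=right[2],
                sex=sex,
            )
        )
    return events


def mask_close_double_crossovers(
    mset: MeiosisSet, min_sep: int = 3_000_000
) -> MeiosisSet:
    """Remove pairs of successive crossovers closer than ``min_sep``.

    Distances are measured midpoint to midpoint within one meiosis and
    chromosome; both members of a violating pair are removed and the
    spanned region recorded as masked. Applied iteratively until no pair
    violates (removal can make new neighbours adjacent).
    """
    out = []
    for m in mset.meioses:
        events = sorted(m.crossovers, key=lambda e: (e.chrom, e.midpoint))
        masked = list(m.masked)
        changed = True
        while changed:
            changed = False
            for i in range(len(events) - 1):
                a, b = events[i], events[i + 1]
                if a.chrom == b.chrom and (b.midpoint - a.midpoint) < min_sep:
                    masked.append(
                        IntervalRecord(a.chrom, a.left_pos, b.right_pos, "masked")
                    )
                    del events[i : i + 2]
                    changed = True
                    break
        out.append(replace(m, crossovers=events, masked=masked))
    return MeiosisSet(out)


def filter_cohort_artifacts(
    meioses: list, min_count: int = 3, min_fraction: float = 0.25
) -> list:
    """Drop phase-artifact events shared across one FID's offspring.

    A wrong haplotype orientation at a sparsely informative marker makes
    a large fraction of a FID's offspring appear to "cross over" in the
    same marker interval. Genuine crossovers cannot recur in the same
    50-200 kb interval in a quarter of a parent's meioses (that would be
    tens of cM locally), so events whose exact bounds repeat in
    >= max(min_count, min_fraction x offspring) meioses of one FID are
    removed as artifacts. Input is a list of Meiosis from a single FID.
    """
    if not meioses:
        return meioses
    counts: dict = {}
    for m in meioses:
        for e in m.crossovers:
            counts[(e.chrom, e.left_pos, e.right_pos)] = (
                counts.get((e.chrom, e.left_pos, e.right_pos), 0) + 1
            )
    cutoff = max(min_count, min_fraction * len(meioses))
    bad = {k for k, v in counts.items() if v >= cutoff}
    if not bad:
        return meioses
    return [
        replace(
            m,
            crossovers=[
                e
                for e in m.crossovers
                if (e.chrom, e.left_pos, e.right_pos) not in bad
            ],
        )
        for m in meioses
    ]


def build_meiosis_set(
    table: VariantTable,
    ped: pd.DataFrame,
    fids: set | None = None,
    min_support: int = 3,
    min_sep: int = 3_000_000,
    qc: bool = True,
) -> MeiosisSet:
    """Phase, detect, filter cohort-level phase artifacts, and
    (optionally) apply the double-crossover QC.

    QC masks close double crossovers, sets the masked regions' origin
    calls to missing, re-detects once, and re-masks so that no surviving
    pair violates ``min_sep``.
    """
    if fids is None:
        fids = select_fids(ped)
    fids = sorted(f for f in fids if f in table.samples)
    ped_idx = ped.set_index("id")
    meioses = []
    phasings = {}
    for fid in fids:
        res = phase_by_transmission(table, ped, fid)
        phasings[fid] = res
        sex = str(ped_idx.loc[fid, "sex"])
        popl = str(ped_idx.loc[fid, "population"])
        fid_meioses = []
        for kid, per_chrom in res.origins.items():
            m = Meiosis(fid=fid, offspring=kid, sex=sex, population=popl)
            for chrom, oseq in per_chrom.items():
                m.crossovers.extend(
                    detect_crossovers(oseq, min_support, m.meiosis_id, sex)
                )
            fid_meioses.append(m)
        meioses.extend(filter_cohort_artifacts(fid_meioses))
    mset = MeiosisSet(meioses)
    if not qc:
        return mset

    masked1 = mask_close_double_crossovers(mset, min_sep)
    by_fid: dict = {}
    for m in masked1.meioses:
        if m.masked:
            res = phasings[m.fid]
            events = []
            for chrom, oseq in res.origins[m.offspring].items():
                orig = oseq.origins.copy()
                for iv in m.masked:
                    if iv.chrom == chrom:
                        inside = (oseq.positions >= iv.start) & (
                            oseq.positions <= iv.end
                        )
                        orig[inside] = 0
                events.extend(
                    detect_crossovers(
                        OriginSequence(chrom, oseq.positions, orig),
                        min_support,
                        m.meiosis_id,
                        m.sex,
                    )
                )
            m = replace(m, crossovers=events)
        by_fid.setdefault(m.fid, []).append(m)
    redetected = []
    for fid in sorted(by_fid):
        redetected.extend(filter_cohort_artifacts(by_fid[fid]))
    return mask_close_double_crossovers(MeiosisSet(redetected), min_sep)


# ---------------------------------------------------------------------------
# window rates


def estimate_window_rates_mc(
    mset: MeiosisSet,
    genome: GenomeIndex,
    window: int = 1_000_000,
    n_mc: int = 100,
    seed: int = 0,
    sex: str | None = None,
) -> dict:
    """Monte-Carlo 1 Mb window recombination rates, cM/Mb, per chromosome.

    Each crossover's position is unknown within its bounding marker
    interval; every replicate draws it uniformly there, window counts are
    averaged over replicates, and rate = 100 x mean count / (meioses x
    window Mb). The last partial window of a chromosome uses its true
    length. Returns {chrom: WindowMap}.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    if sex is not None:
        mset = mset.filter_sex(sex)
    n_mei = mset.n_meioses
    if n_mei == 0:
        raise ValueError("no meioses to estimate from")
    rng = np.random.default_rng(seed)
    events = mset.all_crossovers()
    out = {}
    for chrom, length in genome.items():
        n_win = int(np.ceil(length / window))
        starts = np.arange(n_win, dtype=np.int64) * window
        ends = np.minimum(starts + window, length)
        counts = np.zeros(n_win)
        ch_events = [e for e in events if e.chrom == chrom]
        if ch_events:
            lefts = np.array([e.left_pos for e in ch_events], dtype=float)
            rights = np.array([e.right_pos for e in ch_events], dtype=float)
            for _ in range(n_mc):
                draws = rng.uniform(lefts, rights)
                w = np.minimum((draws // window).astype(int), n_win - 1)
                counts += np.bincount(w, minlength=n_win)
            counts /= n_mc
        width_mb = (ends - starts) / 1e6
        rates = 100.0 * counts / (n_mei * width_mb)
        out[chrom] = WindowMap(
            chrom=chrom,
            starts=starts,
            ends=ends,
            rates=rates,
            sex=sex or "both",
            n_meioses=n_mei,
            rate_units="cM/Mb",
        )
    return out


def genetic_length_morgans(mset: MeiosisSet) -> float:
    """Total genetic length: mean crossovers per meiosis, in Morgans."""
    return mset.mean_crossovers_per_meiosis()


# ---------------------------------------------------------------------------
# ACM comparison


def acm_table(mset: MeiosisSet) -> pd.DataFrame:
    """Per-FID average number of crossovers per meiosis (ACM)."""
    rows: dict = {}
    for m in mset.meioses:
        rec = rows.setdefault(
            m.fid, {"fid": m.fid, "sex": m.sex, "population": m.population,
                    "n_meioses": 0, "n_crossovers": 0}
        )
        rec["n_meioses"] += 1
        rec["n_crossovers"] += len(m.crossovers)
    df = pd.DataFrame(rows.values())
    df["acm"] = df["n_crossovers"] / df["n_meioses"]
    return df


def acm_compare(mset: MeiosisSet) -> pd.DataFrame:
    """Pairwise one-way ANOVA F-tests of per-FID ACM between populations,
    within each sex."""
    acm = acm_table(mset)
    rows = []
    for sex, sub in acm.groupby("sex"):
        pops = sorted(sub["population"].unique())
        for i, pa in enumerate(pops):
            for pb in pops[i + 1 :]:
                a = sub.loc[sub["population"] == pa, "acm"].to_numpy()
                b = sub.loc[sub["population"] == pb, "acm"].to_numpy()
                if len(a) < 2 or len(b) < 2:
                    warnings.warn(
                        f"skipping {pa} vs {pb} ({sex}): group with <2 FIDs",
                        stacklevel=2,
                    )
                    continue
                if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
                    F, p = 0.0, 1.0
                else:
                    F, p = stats.f_oneway(a, b)
                    # guard against cancellation noise when the group
                    # means are (near-)identical
                    if not np.isfinite(F) or F < 0:
                        F = max(float(F), 0.0) if np.isfinite(F) else 0.0
                    if not np.isfinite(p):
                        p = float(stats.f.sf(F, 1, len(a) + len(b) - 2))
                rows.append(
                    {
                        "sex": sex,
                        "pop_a": pa,
                        "pop_b": pb,
                        "F": float(F),
                        "df_between": 1,
                        "df_within": len(a) + len(b) - 2,
                        "p": float(p),
                        "n_a": len(a),
                        "n_b": len(b),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["sex", "pop_a", "pop_b", "F", "df_between", "df_within", "p",
                 "n_a", "n_b"],
    )
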