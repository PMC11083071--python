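"""Readers/writers for the external formats the pipeline touches, plus the
sequencing-variant filter stage.

Coordinate contract: everything interval-like is 0-based half-open on disk
(BED) and in memory; VCF POS is 1-based on disk and stored 1-based inside
:class:`VariantTable` (the one container that mirrors its format).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .core import GenomeIndex, IntervalRecord, FineScaleMap

MISSING = -1  # genotype / haplotype sentinel


@dataclass
class VariantTable:
    """Bi/multi-allelic SNP table with per-individual genotypes.

    ``pos`` is 1-based (VCF convention). ``genotypes`` holds diploid dosages
    in {0, 1, 2} with -1 for missing; ``haplotypes`` (optional, phased data)
    holds per-haplotype alleles in {0, 1} with -1 missing and has twice as
    many columns as there are samples.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: list
    qual: np.ndarray
    mean_depth: np.ndarray
    samples: list
    genotypes: np.ndarray
    haplotypes: np.ndarray | None = None
    filter_report: dict | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.qual = np.asarray(self.qual, dtype=float)
        self.mean_depth = np.asarray(self.mean_depth, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {c}"
                )
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if np.any(bad):
            raise ValueError("genotypes must be in {0, 1, 2, missing}")

    @property
    def n_sites(self) -> int:
        return int(self.pos.shape[0])

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def n_alt(self) -> np.ndarray:
        return np.array([len(a) for a in self.alt], dtype=int)

    def alt_freq(self) -> np.ndarray:
        """Alt-dosage frequency per site from non-missing genotypes."""
        gt = self.genotypes.astype(float)
        called = gt != MISSING
        n_chrom = 2.0 * called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(gt != MISSING, gt, 0.0).sum(axis=1) / n_chrom

    def maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.fmin(f, 1.0 - f)

    def subset(self, mask: np.ndarray) -> "VariantTable":
        mask = np.asarray(mask, dtype=bool)
        return VariantTable(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=[a for a, m in zip(self.alt, mask) if m],
            qual=self.qual[mask],
            mean_depth=self.mean_depth[mask],
            samples=list(self.samples),
            genotypes=self.genotypes[mask],
            haplotypes=None if self.haplotypes is None else self.haplotypes[mask],
        )


def filter_variants(
    table: VariantTable,
    min_qual: float = 30.0,
    min_maf: float = 0.05,
    biallelic_only: bool = True,
    depth_bounds: tuple[float, float] = (1.0 / 3.0, 2.0),
) -> VariantTable:
    """Sequencing-variant QC: site quality, biallelic, MAF and depth filters.

    Depth is filtered relative to the population mean of the per-site mean
    depths: sites below ``depth_bounds[0] x mean`` or above
    ``depth_bounds[1] x mean`` are removed (defaults: below one-third, above
    twice). All retention thresholds are inclusive (``>=`` / within closed
    bounds). Missing (NaN) quality or depth passes the corresponding rule.

    The returned table carries a ``filter_report`` dict with the number of
    sites failing each rule (rules evaluated independently).
    """
    if table.n_sites == 0:
        raise ValueError("cannot filter an empty variant table")

    qual_ok = ~(table.qual < min_qual)  # NaN-safe: NaN compares False
    bi_ok = (
        table.n_alt() == 1 if biallelic_only else np.ones(table.n_sites, bool)
    )
    maf_ok = table.maf() >= min_maf
    # the depth rule is iterated to a fixed point: removing extreme sites
    # shifts the population mean, so the bounds are re-applied until stable
    # (this makes the whole filter idempotent)
    depth_ok = np.ones(table.n_sites, dtype=bool)
    pop_mean = float("nan")
    while depth_ok.any():
        pop_mean = float(np.nanmean(table.mean_depth[depth_ok]))
        lo, hi = depth_bounds[0] * pop_mean, depth_bounds[1] * pop_mean
        new_ok = depth_ok & ~(
            (table.mean_depth < lo) | (table.mean_depth > hi)
        )
        if np.array_equal(new_ok, depth_ok):
            break
        depth_ok = new_ok

    keep = qual_ok & bi_ok & maf_ok & depth_ok
    report = {
        "n_input": table.n_sites,
        "fail_qual": int((~qual_ok).sum()),
        "fail_biallelic": int((~bi_ok).sum()),
        "fail_maf": int((~maf_ok).sum()),
        "fail_depth": int((~depth_ok).sum()),
        "n_kept": int(keep.sum()),
        "mean_depth_used": pop_mean,
    }
    if report["n_kept"] == 0:
        warnings.warn("all sites removed by variant filters", stacklevel=2)
    out = table.subset(keep)
    out.filter_report = report
    return out


# ---------------------------------------------------------------------------
# rate maps


def read_rate_map(
    path: str | Path,
    dialect: str = "per-snp-interval",
    chrom: str = "1",
) -> FineScaleMap:
    """Parse a recombination-rate table into a :class:`FineScaleMap`.

    ``per-snp-interval``: rows ``[chrom] start end rate`` where each row's
    end equals the next row's start (SNP-to-SNP intervals, one SNP step).
    ``fixed-window``: rows ``chrom start end rate`` from a sliding-window
    estimator; overlapping windows are decomposed at all window boundaries
    and the overlapped pieces averaged.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 3:
                c = chrom
                s, e, r = parts
            elif len(parts) >= 4:
                c, s, e, r = parts[:4]
            else:
                raise ValueError(f"line {lineno}: expected >=3 columns")
            try:
                s, e, r = int(s), int(e), float(r)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: unparsable row") from exc
            if e <= s:
                raise ValueError(f"line {lineno}: end <= start")
            if r < 0:
                raise ValueError(f"line {lineno}: negative rate {r}")
            rows.append((lineno, c, s, e, r))
    if not rows:
        raise ValueError(f"no rate rows in {path}")
    chroms = {c for _, c, *_ in rows}
    if len(chroms) > 1:
        raise ValueError("rate map spans multiple chromosomes; read per chrom")
    chrom = rows[0][1]

    if dialect == "per-snp-interval":
        positions = [rows[0][2]]
        rates = []
        for lineno, _, s, e, r in rows:
            if s != positions[-1]:
                raise ValueError(
                    f"line {lineno}: start {s} does not abut previous end "
                    f"{positions[-1]}"
                )
            positions.append(e)
            rates.append(r)
        return FineScaleMap(chrom, np.array(positions), np.array(rates))

    if dialect == "fixed-window":
        starts = np.array([s for _, _, s, _, _ in rows])
        ends = np.array([e for _, _, _, e, _ in rows])
        rates = np.array([r for _, _, _, _, r in rows])
        bounds = np.unique(np.concatenate([starts, ends]))
        seg_rates = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            cover = (starts <= lo) & (ends >= hi)
            if not cover.any():
                raise ValueError(
                    f"coverage gap [{lo}, {hi}) in fixed-window rate map"
                )
            seg_rates.append(float(rates[cover].mean()))
        return FineScaleMap(chrom, bounds, np.array(seg_rates))

    raise ValueError(f"unknown rate-map dialect {dialect!r}")


def write_rate_map(fmap: FineScaleMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, e, r in zip(fmap.positions[:-1], fmap.positions[1:], fmap.rates):
            fh.write(f"{fmap.chrom}\t{s}\t{e}\t{float(r)!r}\n")


def write_window_map(wmap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\trate_cM_per_Mb\tsex\n")
        for s, e, r in zip(wmap.starts, wmap.ends, wmap.rates):
            fh.write(f"{wmap.chrom}\t{s}\t{e}\t{'NA' if np.isnan(r) else repr(float(r))}\t{wmap.sex}\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[IntervalRecord]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: BED needs >=3 columns")
            name = parts[3] if len(parts) > 3 else None
            out.append(
                IntervalRecord(parts[0], int(parts[1]), int(parts[2]), name)
            )
    return out


def write_bed(
    intervals: Sequence[IntervalRecord],
    path: str | Path,
    scores: Sequence[float] | None = None,
    strands: Sequence[str] | None = None,
) -> None:
    """BED3 by default; BED6 when scores/strands are given."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.label is not None or scores is not None or strands is not None:
                cols.append(iv.label if iv.label is not None else ".")
            if scores is not None or strands is not None:
                score = scores[i] if scores is not None else 0
                cols.append(str(int(min(round(score), 1000))))
                cols.append(strands[i] if strands is not None else ".")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def genome_index_from_fasta(path: str | Path) -> GenomeIndex:
    import pyfaidx

    fa = pyfaidx.Fasta(str(path))
    return GenomeIndex.from_items((name, len(fa[name])) for name in fa.keys())


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=recland
##INFO=<ID=MD,Number=1,Type=Float,Description="Site mean sequencing depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(
    table: VariantTable, path: str | Path, genome: GenomeIndex | None = None
) -> None:
    """Emit a plain-text VCF with GT per sample and site mean depth in INFO/MD."""
    phased = table.haplotypes is not None
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        if genome is not None:
            for c, l in genome.items():
                fh.write(f"##contig=<ID={c},length={l}>\n")
        else:
            for c in dict.fromkeys(table.chrom):
                fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for i in range(table.n_sites):
            qual = "." if np.isnan(table.qual[i]) else f"{table.qual[i]:g}"
            md = table.mean_depth[i]
            info = "." if np.isnan(md) else f"MD={md:g}"
            alt = ",".join(table.alt[i]) if table.alt[i] else "."
            cols = [
                str(table.chrom[i]),
                str(table.pos[i]),
                ".",
                str(table.ref[i]),
                alt,
                qual,
                "PASS",
                info,
                "GT",
            ]
            for j in range(table.n_samples):
                if phased:
                    a, b = table.haplotypes[i, 2 * j], table.haplotypes[i, 2 * j + 1]
                    cols.append(
                        "./."
                        if a == MISSING or b == MISSING
                        else f"{a}|{b}"
                    )
                else:
                    g = table.genotypes[i, j]
                    cols.append(
                        "./." if g == MISSING else ["0/0", "0/1", "1/1"][g]
                    )
            fh.write("\t".join(cols) + "\n")


def read_vcf(path: str | Path) -> VariantTable:
    """Read GT (and INFO/MD, QUAL) from a plain or bgzipped VCF via pysam."""
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    chrom, pos, ref, alt, qual, depth = [], [], [], [], [], []
    gts, haps = [], []
    all_phased = True
    for rec in vf:
        chrom.append(rec.chrom)
        pos.append(rec.pos)
        ref.append(rec.ref)
        alt.append(list(rec.alts) if rec.alts else [])
        qual.append(np.nan if rec.qual is None else float(rec.qual))
        depth.append(float(rec.info.get("MD", np.nan)))
        row_gt, row_hap = [], []
        for s in samples:
            alleles = rec.samples[s]["GT"]
            if alleles is None or any(a is None for a in alleles):
                row_gt.append(MISSING)
                row_hap.extend([MISSING, MISSING])
            else:
                row_gt.append(int(sum(alleles)))
                row_hap.extend(int(a) for a in alleles)
                if not rec.samples[s].phased:
                    all_phased = False
        gts.append(row_gt)
        haps.append(row_hap)
    vf.close()
    return VariantTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos),
        ref=np.array(ref, dtype=object),
        alt=alt,
        qual=np.array(qual),
        mean_depth=np.array(depth),
        samples=samples,
        genotypes=np.array(gts, dtype=np.int8).reshape(len(pos), len(samples)),
        haplotypes=(
            np.array(haps, dtype=np.int8).reshape(len(pos), 2 * len(samples))
            if all_phased and samples
            else None
        ),
    )


# ---------------------------------------------------------------------------
# pedigree (FAM-style TSV)

PED_COLUMNS = ["id", "sire", "dam", "sex", "population"]
UNKNOWN_PARENT = "0"


def read_pedigree(path: str | Path) -> pd.DataFrame:
    ped = pd.read_csv(
        path, sep="\t", dtype=str, comment="#", names=PED_COLUMNS, header=None
    )
    if list(ped.iloc[0]) == PED_COLUMNS:  # optional header row
        ped = ped.iloc[1:].reset_index(drop=True)
    ped["sire"] = ped["sire"].fillna(UNKNOWN_PARENT).replace(".", UNKNOWN_PARENT)
    ped["dam"] = ped["dam"].fillna(UNKNOWN_PARENT).replace(".", UNKNOWN_PARENT)
    return ped


def write_pedigree(ped: pd.DataFrame, path: str | Path) -> None:
    ped[PED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene annotations / TSS

TSS_COLUMNS = ["gene_id", "chrom", "tss", "strand"]


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """TSS TSV: gene_id, chrom, tss (0-based), strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = set(TSS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"TSS table missing columns: {sorted(missing)}")
    return df[TSS_COLUMNS]


def write_tss_table(df: pd.DataFrame, path: str | Path) -> None:
    df[TSS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gff_tss(path: str | Path, feature: str = "gene") -> pd.DataFrame:
    """Extract strand-aware TSSs (0-based) from gene features of a GFF3 file."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"line {lineno}: GFF3 needs 9 columns")
            if parts[2] != feature:
                continue
            start1, end1, strand = int(parts[3]), int(parts[4]), parts[6]
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", attrs.get("gene_id", f"gene{lineno}"))
            if strand == "+":
                tss = start1 - 1
            elif strand == "-":
                tss = end1 - 1
            else:
                raise ValueError(f"line {lineno}: gene {gene_id} has no strand")
            rows.append((gene_id, parts[0], tss, strand))
    return pd.DataFrame(rows, columns=TSS_COLUMNS)
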