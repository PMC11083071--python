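# recland

Recombination-landscape analysis for pigs (and other diploid livestock)
at two scales: **broad-scale meiotic maps** estimated from pedigree
genotypes, and **fine-scale historical maps** from population data, with
the downstream genomic characterization that links the two — hotspot and
coldspot calling, GC/diversity contrasts against matched random nulls,
TSS-proximity permutation tests, and PRDM9-style zinc-finger motif
enrichment.

The package is written for analyses whose original pedigree and WGS data
are private: a first-class synthetic-data module generates every input
the pipeline consumes (fine-scale rate landscape, chip-density family
genotypes, genome sequence, variant panel, TSS/peak annotations) with a
recorded ground truth, so every stage can be scored for recovery, power
and calibration.

## What it computes

**Crossovers and meiotic maps.** Focal individuals (FIDs) are parents
whose meioses are observable through genotyped offspring (selected by
the rule: known parent and ≥2 offspring, or unknown parents and ≥4).
Each FID is phased by transmission; a crossover is an origin switch
supported by ≥3 informative markers on both sides; double crossovers
closer than 3 Mb are masked as unreliable. Window rates come from
Monte-Carlo allocation of each crossover within its bounding marker
interval:

    rate(cM/Mb) = 100 · E[count in window] / (meioses · window length in Mb)

and the map's genetic length in Morgans is the mean crossover count per
meiosis. Per-FID ACM (average number of crossovers per meiosis) is
compared between populations by sex with one-way ANOVA F-tests.

**Hotspots and coldspots.** On a fine-scale map (one rate per inter-SNP
interval, e.g. population-scaled ρ = 4·Ne·r per bp), a hotspot is a
maximal run of intervals each strictly above 10× the chromosomal mean
rate, spanning ≥2 SNPs and ≤5 kb, with nearby runs (≤2 intervening
SNPs, gap ≤1 kb) merged; a coldspot is a run strictly below 1/10 of the
mean spanning ≥3 SNPs. The thresholds are relative, so calls are
invariant to rescaling the map.

**Genomic features.** Per interval: GC fraction, and nucleotide
diversity π = Σ_sites 2j(n−j)/(n(n−1)) / length, with n the called
haplotype count and j the alternate count. Both are compared against
1000 sets of length-matched random genomic fragments (empirical p with
the +1/(n+1) convention) and between classes (Wilcoxon rank-sum).

**TSS proximity.** A hotspot is TSS-proximal when its midpoint falls in
the ±3 kb window around any annotated, strand-aware TSS; significance
comes from 1000 sets of uniformly placed random points.

**Motif enrichment.** Sequences are scanned with a position weight
matrix in log2-odds units (both strands, ambiguous windows skipped);
hotspot-vs-coldspot enrichment uses a one-sided rank-sum on per-sequence
maximum scores (or a one-sided Fisher exact test on hits above a score
threshold).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 1, one 10 Mb chromosome) and write their tables to
`results/`. Equivalent stages are exposed by the `recland` command
(`recland run --seed 1 --outdir myrun`).

```bash
python analysis/01_simulate_inputs.py
python analysis/02_crossovers_and_maps.py
python analysis/03_call_hotspots.py
python analysis/04_interval_features.py
python analysis/05_tss_proximity.py
python analysis/06_motif_enrichment.py
python analysis/07_map_correlations.py
```

Output (abridged) from the run above:

```
detected 185 crossovers in 2000 meioses (0.0925 Morgans per meiosis)
called 20 hotspots (mean 2459 bp) and 20 coldspots
recovery vs planted truth: hotspots sens=1.00 prec=1.00; coldspots sens=1.00 prec=1.00
GC: hotspots 46.62% vs coldspots 40.70% (matched-random null 42.92%)
pi: hotspots 0.00295 vs coldspots 0.00199 (null 0.00241)
hot vs cold Wilcoxon: GC p=6.8e-08, pi p=7.9e-08
0/20 hotspot midpoints within 3 kb of a TSS (null mean 1.14 +- 1.02)
direction: depleted; empirical p=0.3147
peaks near TSS: 128/200 (64.0%)
motif enrichment (hot > cold, rank-sum): U=295.0, p=0.00401
meiotic vs historical (both sexes): Spearman rho = 0.624 over 10 windows
```

Reading this: the caller recovered every planted hotspot with no false
calls; hotspots are GC-rich and more diverse than coldspots with the
random-fragment null sitting between them; hotspot midpoints avoid TSS
regions while promoter-proxy peaks concentrate there; and the
zinc-finger motif planted preferentially into hotspots is detected as
enriched. The pedigree-based and fine-scale maps agree at the 1 Mb
scale to the extent ~200 observed crossovers allow.

## Layout

```
src/recland/        library: io_formats, synthetic_data, pedigree_recomb,
                    finescale_map, hotspot_caller, interval_features,
                    proximity_tests, motif_enrich, cli
analysis/           numbered narrative drivers over the library
scripts/            acceptance.py (end-to-end recomputation)
tests/              pytest suite with independent brute-force oracles
docs/methods.md     models, parameters, numerical choices, limitations
```
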