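# Methods

This note documents the models and procedures implemented in `recland`,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions adopted where the
underlying methods literature leaves choices open.

## Variant filtering

Sequencing variants pass four independent rules: site quality ≥ 30,
exactly one alternate allele, minor-allele frequency ≥ 0.05, and site
mean depth within [mean/3, 2·mean] of the population average depth. All
retention thresholds are inclusive. Two deliberate readings:

* The MAF rule *removes* rare variants (MAF < 5%). A literal
  `max-maf < 0.05` invocation of standard VCF tooling would do the
  opposite (keep only rare variants); the analysis intent — and the
  fraction of sites the rule removes — only makes sense as a minimum-MAF
  filter, which is what we implement.
* The depth rule is iterated to a fixed point: removing extreme-depth
  sites shifts the population mean, so the bounds are re-applied until
  the kept set is stable. This makes the filter idempotent (filtering a
  filtered table changes nothing), which a single-pass rule is not.

## Pedigree crossover detection

The detector is a deliberately simple, transparent stand-in for
dedicated pedigree-phasing software, validated against simulation truth
rather than against any external tool's output.

1. **FID selection** — parents with a known parent and ≥2 offspring, or
   no known parent and ≥4 offspring.
2. **Transmission phasing** — at each FID-heterozygous marker the
   transmitted allele is determined when the other parent is homozygous
   or the offspring is homozygous; Mendelian-inconsistent markers are
   set missing and counted. The FID's haplotype orientation is fixed
   greedily, marker by marker, by majority vote of offspring continuity
   (a minimum-recombinant heuristic), anchored at the first informative
   marker of the first offspring; exact ties follow the lowest-index
   voting offspring.
3. **Run-based detection** — with `min_support = 3` (default), origin
   runs shorter than the support threshold are treated as genotyping
   errors (dropped, neighbours merged, iteratively); a crossover is
   emitted at each boundary between surviving runs, bounded by the
   flanking informative markers.
4. **Cohort artifact filter** — a wrong orientation committed at a
   sparsely informative marker flips the labels of part of a cohort and
   later surfaces as a batch of identical "crossovers" across one
   parent's offspring. Events whose exact bounds recur in
   ≥ max(3, 25% of a FID's meioses) are removed as phase artifacts:
   genuine crossovers cannot recur in the same 50–200 kb interval in a
   quarter of a parent's meioses (that would be tens of cM locally).
5. **Double-crossover QC** — successive crossovers in one meiosis whose
   midpoints are closer than 3 Mb are both removed (iteratively until no
   pair violates), the spanned region is masked, origins inside masked
   regions are set missing, and detection is re-run once, followed by a
   final masking pass so the ≥3 Mb separation invariant always holds.
   Midpoints are used as the reference points because the event's true
   position within its bounding interval is unknown.

**What this detector cannot see.** A crossover needs `min_support`
informative markers on each side before the chromosome end or the next
crossover. At 50 kb marker spacing this leaves terminal windows of a few
hundred kb per chromosome end where crossovers are undetectable in
principle — roughly 1–2% of events on a 50 Mb chromosome, independent of
the detector. Recovery is therefore quoted both unconditionally
(typically ~98–99% at zero genotyping error) and on the detectable set
(100% in our simulations).

## Window rates by Monte-Carlo allocation

Each crossover's position is uniform on its bounding marker interval;
each replicate (default `n_mc = 100`) draws all positions, counts per
1 Mb window, and the counts are averaged. Rate in cM/Mb is
`100 · mean count / (meioses · window Mb)`; the last partial window of a
chromosome uses its true length. This realizes a Poisson-rate MLE with
the positional uncertainty integrated out by sampling; no smoothing or
prior is applied. Crossover mass is conserved exactly: summing
`rate · window Mb / 100` over windows returns the mean crossover count
per meiosis.

ACM contrasts between populations (within sex) use pairwise one-way
ANOVA F-tests on per-FID ACM values; groups with a single FID are
skipped with a warning.

## Fine-scale maps, aggregation, and comparisons

Fine-scale maps store one rate per inter-SNP interval (units tagged,
ρ/bp or cM/Mb; all operations are unit-agnostic). Two input dialects are
parsed: per-SNP-interval tables (each row's end abuts the next row's
start) and sliding-window tables, which are decomposed at all window
boundaries with overlapped pieces averaged.

* 1 Mb aggregation is a length-weighted mean of interval rates clipped
  to the window; windows with no covered bp are missing (NaN), never
  zero, and total map length is conserved exactly.
* The chromosomal mean rate is physical-length-weighted by default
  (per-SNP intervals have wildly unequal lengths); an unweighted mean is
  available for sensitivity analysis.
* Map correlations default to Spearman (rank-based, hence unit-free)
  over the intersection of non-missing windows; Pearson by flag.
  Windows missing in either map are excluded, not imputed as zero.
* The within-group vs between-group contrast of a correlation matrix
  uses a Welch t-test on the off-diagonal coefficients split by group
  pair.

## Hotspot/coldspot calling

Candidates are maximal runs of consecutive intervals with rate strictly
greater than `fold = 10` times the chromosomal mean. Candidates spanning
fewer than 2 SNPs **or** more than 5 kb are discarded — two independent
rules, since a conjunctive reading would retain long single-interval
spans the filter clearly intends to drop. Surviving candidates separated
by ≤2 intervening SNPs across a gap ≤1 kb are merged transitively;
merging happens after the length filter (so merged calls may exceed
5 kb, recorded in `merged_from`). Coldspots are runs strictly below
`0.1 ×` mean spanning ≥3 SNPs, with no length cap and no merging. Both
thresholds are strict inequalities, so a uniform or all-zero map yields
no calls, and rescaling the map leaves calls unchanged. Spans run from
the first to the last SNP of the run and are emitted half-open
(`last SNP + 1`).

The caller is verified against an independent brute-force implementation
that enumerates every run and applies the three filter stages literally,
on hundreds of randomized small maps.

## Interval features and nulls

* GC is counted over unambiguous bases only; all-N intervals are
  missing.
* π uses the unbiased per-site estimator `2j(n−j)/(n(n−1))` summed over
  segregating sites in the interval and divided by the interval's
  physical length in bp (the convention of windowed-diversity outputs),
  not by the number of genotyped sites. Sites with fewer than two called
  haplotypes are skipped and counted.
* Matched random nulls draw, per null set, one fragment per observed
  interval with exactly the observed length, uniformly over valid
  placements, rejecting proposals that touch the exclusion mask
  (assembly gaps, when supplied).
* Empirical p-values use the +1/(n+1) convention — `p = (#{null ≥ obs} + 1)/(n_sets + 1)`
  for the upper tail — which can never return 0; two-sided doubles the
  smaller tail, capped at 1.
* Class comparisons use the two-sided Wilcoxon rank-sum (independent
  samples; the interval sets are unpaired), exact for small untied
  samples and tie-corrected normal approximation otherwise; fully tied
  input returns p = 1.

## TSS proximity

TSS = strand-aware 5′ gene end. Windows are ±3 kb with inclusive bounds,
clipped at chromosome ends, duplicates collapsed. A hotspot counts when
its midpoint — `floor((start+end)/2)` of the half-open interval — lies
in any window, at most once. The null places the same number of uniform
random points genome-wide (chromosome chosen by length) and counts them
identically. The empirical p (tail chosen by the observed direction) is
the recommended value; a one-sample t-test of the null values against
the observation is reported alongside because density-plot summaries of
such nulls conventionally quote it, loose as it is. The null-set size
defaults to the number of observed hotspots — the only choice under
which observed and null counts are directly comparable — with 1000 sets.

## Motif scanning and enrichment

PWM log-odds are `log2(((p + 0.01·bg)/(1.01))/bg)` in bits; with a
uniform matrix this is exactly zero everywhere. The default background
is uniform; a 0-order background estimated from coldspot sequences is
available as the conservative, GC-aware choice. A sequence's score is
the maximum windowed sum over all offsets on both strands; windows
containing ambiguous bases are skipped, and sequences with no valid
window are excluded with counts reported. Enrichment defaults to a
one-sided rank-sum on per-sequence maxima (hot > cold); the Fisher
branch dichotomizes at a score threshold and is exactly hypergeometric.
`example_zinc_finger_pwm()` is a synthetic 15-mer stand-in (one dominant
base per position, moderately GC-rich) for an externally predicted
zinc-finger PWM; any MEME minimal-format motif can be supplied instead.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
at desk scale (defaults: one 10 Mb chromosome), with every planted
feature recorded so downstream stages can be scored.

* **Fine map** — SNP spacing exponential (mean 500 bp); interval rate =
  background × 50 inside planted hotspots (2–3 kb wide) and × 0.02
  inside coldspots (5–20 kb), × a per-Mb-block lognormal multiplier
  (σ = 0.5) giving the severalfold Mb-scale variation real maps show,
  × per-interval lognormal noise (σ = 0.3). Planted hotspot widths sit
  at the 2–3 kb scale because hotspots much narrower than the SNP
  spacing are unresolvable in principle.
* **Pedigree** — a two-founder-breed cross: focal parents are F1s
  (haplotypes drawn from breed-A and breed-B allele frequencies,
  U(0.05–0.25) and U(0.75–0.95) per marker), mates are breed-A
  purebreds, markers every 50 kb — the design hybrid pig pedigrees use,
  and the reason most markers are informative for transmission
  (~65%). Per meiosis the crossover count is Poisson with mean equal to
  the map length in Morgans (no interference; the <3 Mb QC makes close
  doubles rare anyway; an obligate-crossover resampling flag exists,
  default off), positions follow the inverse CDF of the cumulative
  genetic map, and one gamete per meiosis is transmitted — for both the
  focal parent and the mate, so maternal and paternal meioses are both
  real. Genotype errors replace an offspring genotype with one of the
  other two values, independently at the configured rate (default
  0.001).
* **Sequence** — i.i.d. bases at 46.46% GC in hotspots, 40.53% in
  coldspots, 42.96% elsewhere; the PWM consensus is planted at random
  offset and strand with probability 0.8 per hotspot and 0.05 per
  coldspot.
* **Variants** — segregating sites as an inhomogeneous Poisson process
  (densities 0.0141/bp hot, 0.0096 cold, 0.0118 background over 72
  haplotypes = 36 diploids); derived-allele counts follow the neutral
  spectrum P(j) ∝ 1/j, under which E[site π] = 1/H_{n−1}, so those
  densities put hotspot/coldspot π at 0.00291/0.00198 per bp in
  expectation.
* **Annotations** — uniform TSS positions with random strand; each
  promoter-proxy peak (1648 bp) has its midpoint placed within ±3 kb of
  a random TSS with probability 0.635, else uniform.

**What it does not emulate** — and hence what passing tests do not show
about real data: no linkage disequilibrium among the variant panel's
sites (the LD-based rate estimators themselves are out of scope; their
output is the consumed rate table), no coalescent genealogy (π is
calibrated in expectation, not in its correlation structure), no
crossover interference, no genotyping-batch or call-rate structure, no
assembly gaps unless a mask is supplied, and single-nucleotide motif
planting rather than a binding-affinity landscape. Determinism: every
generator draws from a child stream keyed by (seed, stage), so adding a
stage never perturbs another's output.

## Problem sizes

The test suite and the acceptance script run at sizes chosen so the
statistical assertions have comfortable margins on a single CPU: 10 Mb
chromosomes for landscape work (≈20k SNP intervals), 50 Mb with 1000
markers and 300–800 meioses for crossover and window-map recovery, 500
random small maps for caller/oracle equivalence, 500 replicates for
p-value calibration checks, and 1000 null sets for the permutation
tests (matching the analysis default).

## Known limitations

* The transmission phaser is family-local: it does not use population
  haplotype frequencies or multi-generation information, and purebred
  (mostly homozygous) parents yield sparse origin tracks with lower
  crossover recovery — visible in the worked example, where mate
  meioses contribute fewer detected events than F1 meioses.
* Terminal-window crossovers are undetectable by construction (see
  above); genetic lengths estimated from detected crossovers are
  accordingly a few percent short.
* The ρ→cM/Mb conversion is a scalar utility (requires an external Ne);
  correlations are rank-based precisely so the conversion never enters.
* `estimate_window_rates_mc` returns one map per chromosome (a dict);
  the per-chromosome container itself is single-chromosome.
* Fixed-window rate tables must tile their span; coverage gaps are an
  error rather than silently interpolated.
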