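import numpy as np
import pytest
from scipy import stats

from recland.core import WindowMap
from recland.interval_features import pi_of_intervals, ranksum_compare
from recland.motif_enrich import example_zinc_finger_pwm
from recland.synthetic_data import (
    SimConfig,
    reverse_complement,
    simulate_annotations,
    simulate_fine_map,
    simulate_pedigree_meioses,
    simulate_sequences,
    simulate_variants,
)


def small_config(**kw) -> SimConfig:
    defaults = dict(
        seed=1,
        chrom_length=1_000_000,
        hotspot_count=5,
        coldspot_count=5,
        coldspot_width_range=(4_000, 8_000),
        n_fids=4,
        offspring_per_fid=5,
        n_genes=20,
        n_peaks=30,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def uniform_genetic_map(length_bp=10_000_000, cm_per_mb=10.0) -> WindowMap:
    starts = np.arange(0, length_bp, 1_000_000, dtype=np.int64)
    return WindowMap(
        "1", starts, starts + 1_000_000, np.full(starts.size, cm_per_mb)
    )


class TestFineMap:
    def test_noiseless_background_is_exact(self):
        cfg = small_config(hotspot_count=0, coldspot_count=0,
                           rate_noise_sd=0.0, broad_scale_sd=0.0)
        fmap, _ = simulate_fine_map(cfg)
        assert np.all(fmap.rates == cfg.background_rate)

    def test_hotspot_fold_by_construction(self):
        cfg = small_config(rate_noise_sd=0.0, broad_scale_sd=0.0,
                           hotspot_fold=50.0)
        fmap, truth = simulate_fine_map(cfg)
        mids = fmap.interval_midpoints
        inside = np.zeros(fmap.n_intervals, bool)
        for iv in truth.hotspots:
            inside |= (mids >= iv.start) & (mids < iv.end)
        assert inside.any()
        assert np.allclose(
            fmap.rates[inside].mean() / cfg.background_rate, 50.0
        )

    def test_same_seed_is_byte_identical(self):
        a, ta = simulate_fine_map(small_config(seed=7))
        b, tb = simulate_fine_map(small_config(seed=7))
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.rates, b.rates)
        assert ta.hotspots == tb.hotspots

    def test_unplaceable_intervals_raise(self):
        cfg = small_config(
            chrom_length=100_000,
            hotspot_count=60,
            hotspot_width_range=(2_000, 3_000),
        )
        with pytest.raises(ValueError, match="place"):
            simulate_fine_map(cfg)


class TestPedigreeMeioses:
    def test_poisson_crossover_mean(self):
        # 1 Morgan map, ~2000 meioses: mean count within 3 SE of 1.0
        cfg = SimConfig(seed=2, chrom_length=10_000_000, n_fids=10,
                        offspring_per_fid=100)
        gmap = uniform_genetic_map()
        _, _, truth = simulate_pedigree_meioses(cfg, gmap)
        counts = np.array([len(v) for v in truth.crossovers.values()])
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - 1.0) < 3 * se + 1e-12

    def test_uniform_map_gives_uniform_positions(self):
        cfg = SimConfig(seed=3, chrom_length=10_000_000, n_fids=10,
                        offspring_per_fid=100)
        _, _, truth = simulate_pedigree_meioses(cfg, uniform_genetic_map())
        pos = np.concatenate([v for v in truth.crossovers.values() if v])
        assert pos.size > 1000
        _, p = stats.kstest(pos / 10_000_000, "uniform")
        assert p > 0.01

    def test_error_free_offspring_are_mendelian(self):
        from recland.pedigree_recomb import phase_by_transmission

        cfg = small_config(genotype_error_rate=0.0, marker_spacing=10_000)
        gmap = uniform_genetic_map(1_000_000)
        table, ped, _ = simulate_pedigree_meioses(cfg, gmap)
        for fid in [f"FID{i:03d}" for i in range(cfg.n_fids)]:
            res = phase_by_transmission(table, ped, fid)
            assert res.n_mendelian_errors == 0

    def test_nonpositive_map_raises(self):
        starts = np.array([0])
        gmap = WindowMap("1", starts, starts + 1_000_000, np.array([0.0]))
        with pytest.raises(ValueError, match="length"):
            simulate_pedigree_meioses(small_config(), gmap)

    def test_obligate_crossover_flag(self):
        cfg = SimConfig(seed=4, chrom_length=5_000_000, n_fids=4,
                        offspring_per_fid=10, enforce_obligate_crossover=True)
        gmap = uniform_genetic_map(5_000_000, cm_per_mb=2.0)  # L = 0.1
        _, _, truth = simulate_pedigree_meioses(cfg, gmap)
        assert all(len(v) >= 1 for v in truth.crossovers.values())


class TestSequences:
    def test_degenerate_gc_one(self):
        cfg = small_config(gc_hotspot=1.0, motif_plant_rate_hot=0.0)
        _, truth = simulate_fine_map(cfg)
        seqs = simulate_sequences(cfg, truth, example_zinc_finger_pwm())
        for iv in truth.hotspots:
            assert set(seqs["1"][iv.start : iv.end]) <= set("GC")

    def test_plant_rates_one_and_zero(self):
        cfg = small_config(motif_plant_rate_hot=1.0, motif_plant_rate_cold=0.0)
        _, truth = simulate_fine_map(cfg)
        pwm = example_zinc_finger_pwm()
        seqs = simulate_sequences(cfg, truth, pwm)
        cons = pwm.consensus()
        rc = reverse_complement(cons)
        for iv in truth.hotspots:
            sub = seqs["1"][iv.start : iv.end]
            assert cons in sub or rc in sub
        for iv in truth.coldspots:
            sub = seqs["1"][iv.start : iv.end]
            assert cons not in sub and rc not in sub

    def test_background_gc_within_three_se(self):
        cfg = small_config(hotspot_count=0, coldspot_count=0, seed=5)
        _, truth = simulate_fine_map(cfg)
        seqs = simulate_sequences(cfg, truth, None)
        s = seqs["1"][:200_000]
        gc = (s.count("G") + s.count("C")) / len(s)
        se = np.sqrt(cfg.gc_background * (1 - cfg.gc_background) / len(s))
        assert abs(gc - cfg.gc_background) < 3 * se

    def test_invalid_gc_raises(self):
        cfg = small_config()
        _, truth = simulate_fine_map(cfg)
        cfg.gc_hotspot = 1.5  # mutate past the constructor check
        with pytest.raises(ValueError, match="GC"):
            simulate_sequences(cfg, truth, None)


class TestVariants:
    def test_zero_cold_density_means_zero_pi(self):
        cfg = small_config(site_density_cold=0.0, seed=6)
        _, truth = simulate_fine_map(cfg)
        table = simulate_variants(cfg, truth)
        pis = pi_of_intervals(table, truth.coldspots)
        assert np.all(pis == 0.0)

    def test_two_haplotypes_force_singletons(self):
        cfg = small_config(n_haplotypes=2, seed=7)
        _, truth = simulate_fine_map(cfg)
        table = simulate_variants(cfg, truth)
        from recland.interval_features import variant_site_pi

        pi, _ = variant_site_pi(table)
        assert np.all(pi == 1.0)

    def test_equal_densities_calibrate_ranksum(self):
        # with no hot/cold density contrast the Wilcoxon comparison should
        # be non-significant in >=90% of seeds
        nonsig = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = small_config(
                seed=seed,
                chrom_length=400_000,
                site_density_hot=0.01,
                site_density_cold=0.01,
                hotspot_count=6,
                coldspot_count=6,
                hotspot_width_range=(2_000, 3_000),
                coldspot_width_range=(2_000, 3_000),
            )
            _, truth = simulate_fine_map(cfg)
            table = simulate_variants(cfg, truth)
            hot_pi = pi_of_intervals(table, truth.hotspots)
            cold_pi = pi_of_intervals(table, truth.coldspots)
            _, p = ranksum_compare(hot_pi, cold_pi)
            nonsig += p >= 0.05
        assert nonsig >= 0.9 * n_seeds

    def test_determinism(self):
        cfg = small_config(seed=8)
        _, truth = simulate_fine_map(cfg)
        a = simulate_variants(cfg, truth)
        b = simulate_variants(cfg, truth)
        np.testing.assert_array_equal(a.pos, b.pos)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)


class TestAnnotations:
    def test_all_peaks_near_tss_when_fraction_one(self):
        from recland.core import IntervalRecord
        from recland.proximity_tests import interval_overlap_stats

        cfg = small_config(peak_tss_fraction=1.0, seed=9)
        tss, peaks = simulate_annotations(cfg)
        windows = [
            IntervalRecord("1", max(0, t - 3000), t + 3001)
            for t in tss["tss"]
        ]
        st_ = interval_overlap_stats(peaks, windows)
        assert st_["frac_a"] == 1.0

    def test_zero_genes_with_tss_fraction_raises(self):
        with pytest.raises(ValueError, match="n_genes"):
            simulate_annotations(small_config(n_genes=0, peak_tss_fraction=0.5))

    def test_chance_level_overlap_when_fraction_zero(self):
        from recland.core import IntervalRecord, merge_intervals

        cfg = small_config(
            seed=10, chrom_length=5_000_000, n_genes=10, n_peaks=500,
            peak_tss_fraction=0.0,
        )
        tss, peaks = simulate_annotations(cfg)
        # peak overlaps a TSS window iff its midpoint falls within the
        # window extended by the peak half-widths
        half_lo = cfg.peak_width // 2
        half_hi = cfg.peak_width - half_lo
        ext = merge_intervals(
            [
                IntervalRecord(
                    "1",
                    max(0, t - 3000 - half_hi + 1),
                    min(cfg.chrom_length, t + 3001 + half_lo),
                )
                for t in tss["tss"]
            ]
        )
        coverage = sum(iv.length for iv in ext) / cfg.chrom_length
        hits = sum(
            1
            for p in peaks
            if any(iv.start <= p.midpoint < iv.end for iv in ext)
        )
        se = np.sqrt(coverage * (1 - coverage) / cfg.n_peaks)
        assert abs(hits / cfg.n_peaks - coverage) < 3 * se + 1e-9
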