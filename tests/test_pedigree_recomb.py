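import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recland.core import GenomeIndex, WindowMap
from recland.pedigree_recomb import (
    CrossoverEvent,
    Meiosis,
    MeiosisSet,
    OriginSequence,
    acm_compare,
    acm_table,
    build_meiosis_set,
    detect_crossovers,
    estimate_window_rates_mc,
    genetic_length_morgans,
    mask_close_double_crossovers,
    phase_by_transmission,
    select_fids,
)
from recland.synthetic_data import SimConfig, simulate_pedigree_meioses
from conftest import make_variant_table


def ped_frame(rows):
    return pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "population"])


class TestSelectFids:
    def test_known_parent_needs_two_offspring(self):
        ped = ped_frame(
            [
                ("P", "0", "0", "M", "X"),
                ("A", "P", "0", "M", "X"),
                ("C1", "A", "0", "F", "X"),
                ("C2", "A", "0", "F", "X"),
            ]
        )
        assert "A" in select_fids(ped)

    def test_founder_with_three_offspring_rejected(self):
        ped = ped_frame(
            [("A", "0", "0", "M", "X")]
            + [(f"C{i}", "A", "0", "F", "X") for i in range(3)]
        )
        assert "A" not in select_fids(ped)

    def test_founder_with_four_offspring_selected(self):
        ped = ped_frame(
            [("A", "0", "0", "M", "X")]
            + [(f"C{i}", "A", "0", "F", "X") for i in range(4)]
        )
        assert "A" in select_fids(ped)


class TestPhaseByTransmission:
    def family(self, fid_gt, mate_gt, kid_gts, pos=None):
        """FID + mate + offspring table; genotypes per row = one site."""
        n_kids = len(kid_gts[0])
        gt = np.column_stack(
            [fid_gt, mate_gt] + [[row[k] for row in kid_gts] for k in range(n_kids)]
        ).astype(np.int8)
        t = make_variant_table(gt, pos=pos)
        t.samples = ["FID", "MATE"] + [f"K{k}" for k in range(n_kids)]
        ped = ped_frame(
            [("FID", "GP", "0", "M", "X"), ("MATE", "0", "0", "F", "X")]
            + [(f"K{k}", "FID", "MATE", "M", "X") for k in range(n_kids)]
        )
        return t, ped

    def test_forced_transmission_from_homozygous_mate(self):
        # FID het, mate 0/0, offspring het: FID transmitted the alt allele.
        # Two markers with opposite transmission to K0/K1 anchor both labels.
        t, ped = self.family(
            fid_gt=[1, 1], mate_gt=[0, 0], kid_gts=[(1, 0), (1, 0)]
        )
        res = phase_by_transmission(t, ped, "FID")
        o0 = res.origins["K0"]["1"].origins
        o1 = res.origins["K1"]["1"].origins
        # K0 consistently received one haplotype, K1 the other
        assert set(o0) == {1} and set(o1) == {2}

    def test_homozygous_fid_markers_are_uninformative(self):
        t, ped = self.family(
            fid_gt=[0, 1], mate_gt=[0, 0], kid_gts=[(0, 0), (1, 1)]
        )
        res = phase_by_transmission(t, ped, "FID")
        # first marker (FID hom) is not part of the origin track at all
        assert res.origins["K0"]["1"].positions.size == 1

    def test_mendelian_inconsistency_is_counted_and_masked(self):
        t, ped = self.family(
            fid_gt=[1], mate_gt=[2], kid_gts=[(0, 2)]
        )
        # offspring K0 gt 0 with mate 2/2 is impossible
        res = phase_by_transmission(t, ped, "FID")
        assert res.n_mendelian_errors == 1
        assert res.origins["K0"]["1"].origins[0] == 0

    def test_fewer_than_two_offspring_raises(self):
        t, ped = self.family(fid_gt=[1], mate_gt=[0], kid_gts=[(1, 1)])
        ped = ped[ped["id"] != "K1"]
        with pytest.raises(ValueError, match="fewer than 2"):
            phase_by_transmission(t, ped, "FID")

    def test_recovers_simulated_truth_up_to_label_swap(self):
        cfg = SimConfig(seed=21, chrom_length=5_000_000, n_fids=2,
                        offspring_per_fid=6, genotype_error_rate=0.0,
                        marker_spacing=25_000)
        starts = np.arange(5, dtype=np.int64) * 1_000_000
        gmap = WindowMap("1", starts, starts + 1_000_000, np.full(5, 1.0))
        table, ped, truth = simulate_pedigree_meioses(cfg, gmap)
        res = phase_by_transmission(table, ped, "FID000")
        for kid, per_chrom in res.origins.items():
            oseq = per_chrom["1"]
            true_xo = sorted(truth.crossovers[f"FID000|{kid}"])
            informative = oseq.origins > 0
            pos = oseq.positions[informative]
            orig = oseq.origins[informative]
            # origin switches exactly at true crossovers: the number of
            # switches equals the number of crossovers between informative
            # markers, and each switch brackets a true position
            switches = np.flatnonzero(np.diff(orig) != 0)
            for s in switches:
                left, right = pos[s], pos[s + 1]
                assert any(left <= x <= right for x in true_xo)


class TestDetectCrossovers:
    def run_case(self, origins, min_support):
        origins = np.asarray(origins)
        pos = np.arange(origins.size) * 100
        return detect_crossovers(
            OriginSequence("1", pos, origins), min_support, "m", "M"
        )

    def test_clean_switch(self):
        ev = self.run_case([1, 1, 1, 2, 2, 2], 3)
        assert len(ev) == 1
        assert (ev[0].left_pos, ev[0].right_pos) == (200, 300)

    def test_isolated_flip_discarded(self):
        assert self.run_case([1, 1, 2, 1, 1], 2) == []

    def test_double_switch_kept(self):
        ev = self.run_case([1, 1, 2, 2, 1, 1], 2)
        assert len(ev) == 2

    def test_all_missing_returns_empty(self):
        assert self.run_case([0, 0, 0, 0], 2) == []

    def test_short_terminal_runs_do_not_emit(self):
        # trailing run of 2 < min_support: no event
        assert self.run_case([1, 1, 1, 2, 2], 3) == []


class TestMaskCloseDoubles:
    def mk(self, positions, width=1000):
        events = [
            CrossoverEvent("m", "1", int(p - width // 2), int(p + width // 2), "M")
            for p in positions
        ]
        return MeiosisSet([Meiosis("f", "o", "M", "X", crossovers=events)])

    def test_close_pair_removed_and_masked(self):
        out = mask_close_double_crossovers(self.mk([10e6, 12.5e6]))
        assert out.meioses[0].crossovers == []
        assert len(out.meioses[0].masked) == 1

    def test_distant_pair_kept(self):
        out = mask_close_double_crossovers(self.mk([10e6, 13.5e6]))
        assert len(out.meioses[0].crossovers) == 2

    def test_triple_keeps_the_distant_one(self):
        out = mask_close_double_crossovers(self.mk([10e6, 12.5e6, 20e6]))
        kept = out.meioses[0].crossovers
        assert len(kept) == 1
        assert kept[0].midpoint == 20e6

    def test_iterative_until_no_violation(self):
        out = mask_close_double_crossovers(self.mk([10e6, 12.5e6, 14e6, 20e6]))
        kept = [e.midpoint for e in out.meioses[0].crossovers]
        assert kept == [14e6, 20e6] or kept == [20e6]
        mids = sorted(kept)
        assert all(b - a >= 3e6 for a, b in zip(mids, mids[1:]))


class TestWindowRatesMC:
    def genome(self, length=3_000_000):
        return GenomeIndex.from_items([("1", length)])

    def test_single_contained_event(self):
        events = [CrossoverEvent("m0", "1", 1_200_000, 1_300_000, "M")]
        meioses = [Meiosis(f"f{i}", f"o{i}", "M", "X") for i in range(100)]
        meioses[0].crossovers = events
        wmap = estimate_window_rates_mc(
            MeiosisSet(meioses), self.genome(), n_mc=10, seed=1
        )["1"]
        np.testing.assert_allclose(wmap.rates, [0.0, 1.0, 0.0])

    def test_straddling_event_splits_mass(self):
        events = [CrossoverEvent("m0", "1", 500_000, 1_500_000, "M")]
        meioses = [Meiosis(f"f{i}", f"o{i}", "M", "X") for i in range(10)]
        meioses[0].crossovers = events
        wmap = estimate_window_rates_mc(
            MeiosisSet(meioses), self.genome(), n_mc=4000, seed=2
        )["1"]
        # each of the two windows receives half the event mass +- MC error
        assert abs(wmap.rates[0] - 5.0) < 0.5
        assert abs(wmap.rates[1] - 5.0) < 0.5
        assert wmap.rates[2] == 0.0

    def test_deterministic_given_seed(self):
        events = [CrossoverEvent("m0", "1", 0, 2_999_999, "M")]
        mset = MeiosisSet([Meiosis("f", "o", "M", "X", crossovers=events)])
        a = estimate_window_rates_mc(mset, self.genome(), n_mc=1, seed=42)["1"]
        b = estimate_window_rates_mc(mset, self.genome(), n_mc=1, seed=42)["1"]
        np.testing.assert_array_equal(a.rates, b.rates)

    def test_mass_conservation_is_exact(self):
        rng = np.random.default_rng(3)
        meioses = []
        for i in range(50):
            m = Meiosis(f"f{i % 5}", f"o{i}", "M", "X")
            for _ in range(rng.integers(0, 4)):
                left = int(rng.integers(0, 2_900_000))
                m.crossovers.append(
                    CrossoverEvent(m.meiosis_id, "1", left, left + 50_000, "M")
                )
            meioses.append(m)
        mset = MeiosisSet(meioses)
        wmap = estimate_window_rates_mc(mset, self.genome(), n_mc=7, seed=4)["1"]
        mass = np.sum(wmap.rates * wmap.widths_mb) / 100
        assert abs(mass - mset.mean_crossovers_per_meiosis()) < 1e-9
        assert genetic_length_morgans(mset) == mset.mean_crossovers_per_meiosis()

    def test_partial_last_window_uses_true_length(self):
        genome = GenomeIndex.from_items([("1", 2_500_000)])
        events = [CrossoverEvent("m0", "1", 2_100_000, 2_400_000, "M")]
        mset = MeiosisSet([Meiosis("f", "o", "M", "X", crossovers=events)])
        wmap = estimate_window_rates_mc(mset, genome, n_mc=5, seed=5)["1"]
        # one event in 1 meiosis over a 0.5 Mb window: 100 * 1 / 0.5 = 200
        assert wmap.rates[2] == pytest.approx(200.0)

    def test_more_replicates_reduce_variance(self):
        events = [CrossoverEvent("m0", "1", 0, 2_999_999, "M")]
        mset = MeiosisSet([Meiosis("f", "o", "M", "X", crossovers=events)])

        def spread(n_mc):
            vals = [
                estimate_window_rates_mc(
                    mset, self.genome(), n_mc=n_mc, seed=s
                )["1"].rates[0]
                for s in range(30)
            ]
            return np.var(vals)

        assert spread(64) < spread(1)

    def test_zero_meioses_raise(self):
        with pytest.raises(ValueError):
            estimate_window_rates_mc(MeiosisSet([]), self.genome(), seed=1)


class TestAcmCompare:
    def mk_set(self, acms_by_group, sex="M"):
        meioses = []
        for pop, acms in acms_by_group.items():
            for i, acm in enumerate(acms):
                fid = f"{pop}_f{i}"
                # 10 meioses with acm*10 total crossovers
                for k in range(10):
                    m = Meiosis(fid, f"{fid}o{k}", sex, pop)
                    n = int(acm) if k < 10 else 0
                    m.crossovers = [
                        CrossoverEvent(m.meiosis_id, "1", j * 10_000,
                                       j * 10_000 + 1000, sex)
                        for j in range(n)
                    ]
                    meioses.append(m)
        return MeiosisSet(meioses)

    def test_identical_groups_give_f_zero_p_one(self):
        mset = self.mk_set({"A": [10, 12, 14], "B": [10, 12, 14]})
        res = acm_compare(mset)
        assert res.loc[0, "F"] == 0.0
        assert res.loc[0, "p"] == 1.0

    def test_matches_textbook_anova(self):
        mset = self.mk_set({"A": [10, 12, 14], "B": [20, 22, 24]})
        res = acm_compare(mset)
        a, b = np.array([10.0, 12, 14]), np.array([20.0, 22, 24])
        grand = np.concatenate([a, b]).mean()
        ssb = 3 * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
        ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        f_oracle = (ssb / 1) / (ssw / 4)
        p_oracle = stats.f.sf(f_oracle, 1, 4)
        assert res.loc[0, "F"] == pytest.approx(f_oracle)
        assert res.loc[0, "p"] == pytest.approx(p_oracle)

    def test_single_group_yields_empty_table(self):
        mset = self.mk_set({"A": [10, 12, 14]})
        assert len(acm_compare(mset)) == 0

    def test_single_fid_group_skipped_with_warning(self):
        mset = self.mk_set({"A": [10, 12], "B": [20]})
        with pytest.warns(UserWarning, match="<2 FIDs"):
            res = acm_compare(mset)
        assert len(res) == 0

    def test_acm_values(self):
        mset = self.mk_set({"A": [3, 5]})
        t = acm_table(mset).set_index("fid")
        assert t.loc["A_f0", "acm"] == pytest.approx(3.0)
        assert t.loc["A_f1", "acm"] == pytest.approx(5.0)


class TestQcIntegration:
    def test_no_surviving_pair_below_min_sep(self):
        # a hot genetic map makes close double crossovers common
        cfg = SimConfig(seed=31, chrom_length=20_000_000, n_fids=6,
                        offspring_per_fid=15, genotype_error_rate=0.0,
                        marker_spacing=50_000)
        starts = np.arange(20, dtype=np.int64) * 1_000_000
        gmap = WindowMap("1", starts, starts + 1_000_000, np.full(20, 15.0))
        table, ped, _ = simulate_pedigree_meioses(cfg, gmap)
        fids = {f"FID{i:03d}" for i in range(cfg.n_fids)}
        mset = build_meiosis_set(table, ped, fids=fids, qc=True)
        assert len(mset.all_crossovers()) > 0
        for m in mset.meioses:
            mids = sorted(e.midpoint for e in m.crossovers)
            assert all(b - a >= 3_000_000 for a, b in zip(mids, mids[1:]))
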