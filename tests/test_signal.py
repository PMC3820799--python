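"""Read-retention rules, RPKM, windows, metaplots and the Mann-Whitney U test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rddm.core import DMR, GenomicInterval
from rddm.signal import (CollapsedReadSet, collapse_duplicates, dmr_window_density,
                         dmr_windows, mann_whitney_exact_enumeration,
                         mann_whitney_u, metaplot, rpkm, select_srna,
                         weighted_change_correlation)

from conftest import chh_tables, make_reads


def gi(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def reads_at(positions, length=50, unique=True, mult=1, chrom="chr1"):
    return make_reads([(chrom, int(p), int(p) + length, "+", unique, mult)
                       for p in positions])


class TestCollapse:
    def test_srna_cap_flattens_150_to_100(self):
        reads = make_reads([("chr1", 0, 24, "+", True, 150)])
        assert collapse_duplicates(reads, cap=100).df["multiplicity"].iloc[0] == 100

    def test_chip_duplicates_collapse_to_one(self):
        reads = make_reads([("chr1", 0, 50, "+", True, 1)] * 3)
        out = collapse_duplicates(reads, cap=1)
        assert len(out) == 1 and out.df["multiplicity"].iloc[0] == 1

    def test_distinct_reads_unchanged(self):
        reads = make_reads([("chr1", i * 100, i * 100 + 50, "+", True, 1)
                            for i in range(5)])
        out = collapse_duplicates(reads, cap=100)
        assert len(out) == 5 and (out.df["multiplicity"] == 1).all()

    def test_invalid_cap_rejected(self):
        with pytest.raises(ValueError):
            collapse_duplicates(make_reads([]), cap=0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 20), st.integers(1, 8),
                              st.booleans(), st.integers(1, 30)),
                    min_size=1, max_size=30),
           st.integers(1, 20))
    def test_idempotent_and_order_independent(self, raw, cap):
        rows = [("chr1", s, s + l, "+", u, m) for s, l, u, m in raw]
        once = collapse_duplicates(make_reads(rows), cap)
        twice = collapse_duplicates(once, cap)
        assert once.df.equals(twice.df)
        assert once.total_mapped == twice.total_mapped
        shuffled = collapse_duplicates(make_reads(rows[::-1]), cap)
        assert once.df.equals(shuffled.df)


class TestSelectSrna:
    def test_length_window_18_to_28(self):
        reads = reads_at([0, 100, 200, 300, 400], length=50)
        for i, l in enumerate([17, 18, 24, 28, 29]):
            reads.df.loc[i, "end"] = reads.df.loc[i, "start"] + l
        kept = select_srna(reads)
        assert sorted(kept.lengths) == [18, 24, 28]

    def test_exact_size_class(self):
        reads = reads_at([0, 100, 200], length=21)
        reads.df.loc[1, "end"] = reads.df.loc[1, "start"] + 24
        reads.df.loc[2, "end"] = reads.df.loc[2, "start"] + 24
        assert len(select_srna(reads, size_class=24)) == 2

    def test_empty_input(self):
        assert len(select_srna(make_reads([]))) == 0

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            select_srna(make_reads([]), min_len=28, max_len=18)


class TestRpkm:
    def test_formula_ten_reads_kilobase_region(self):
        reads = collapse_duplicates(reads_at(range(0, 1000, 100)), cap=1)
        reads.total_mapped = 1_000_000
        assert rpkm(reads, gi(0, 1000)) == pytest.approx(10.0)

    def test_formula_five_reads_500bp(self):
        reads = collapse_duplicates(reads_at([0, 50, 100, 150, 200]), cap=1)
        reads.total_mapped = 2_000_000
        assert rpkm(reads, gi(0, 500)) == pytest.approx(5.0)

    def test_hand_audited_six_read_toy(self):
        """Unique reads in the numerator, unique + non-unique in the
        denominator: 3 of 4 unique reads overlap the region (one by a single
        base), both non-unique reads are excluded from the numerator."""
        rows = [
            ("chr1", 100, 150, "+", True, 1),    # inside
            ("chr1", 951, 1001, "+", True, 1),   # 1 bp overlap with [0,1000)
            ("chr1", 1000, 1050, "+", True, 1),  # abuts: excluded
            ("chr1", 500, 550, "+", True, 2),    # inside, duplicate pair
            ("chr1", 200, 250, "+", False, 3),   # non-unique inside
            ("chr2", 100, 150, "+", False, 1),   # non-unique elsewhere
        ]
        collapsed = collapse_duplicates(make_reads(rows), cap=100)
        # totals: 1+1+1+2+3+1 = 9; numerator: 1+1+2 = 4
        assert collapsed.total_mapped == 9
        expected = 4 * 1e9 / (1000 * 9)
        assert rpkm(collapsed, gi(0, 1000)) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        empty = collapse_duplicates(make_reads([]), cap=1)
        with pytest.raises(ValueError):
            rpkm(empty, gi(0, 1000))

    def test_linear_in_reads_at_fixed_total(self):
        one = collapse_duplicates(reads_at([10, 70, 130]), cap=1)
        one.total_mapped = 10_000
        three = collapse_duplicates(reads_at(list(range(10, 190, 30))), cap=1)
        three.total_mapped = 10_000
        assert rpkm(three, gi(0, 1000)) == pytest.approx(2 * rpkm(one, gi(0, 1000)))


class TestWindows:
    def test_midpoint_window_construction(self):
        w = dmr_windows([gi(1000, 1200)], flank=500)[0]
        assert (w.start, w.end) == (600, 1600)

    def test_odd_length_midpoint_floors(self):
        w = dmr_windows([gi(100, 201)], flank=50)[0]
        assert (w.start, w.end) == (100, 200)

    def test_clipping_corrects_denominator(self):
        reads = collapse_duplicates(reads_at([0, 100, 200, 300]), cap=1)
        reads.total_mapped = 1_000_000
        clipped = dmr_window_density([gi(300, 500)], reads, flank=500,
                                     chrom_sizes={"chr1": 900})[0]
        # window [0, 900): all 4 reads, realized length 900
        assert clipped == pytest.approx(4 * 1e9 / (900 * 1e6))

    def test_no_reads_gives_zero(self):
        reads = collapse_duplicates(reads_at([5000]), cap=1)
        assert dmr_window_density([gi(100, 200)], reads)[0] == 0


class TestMetaplot:
    def make_collapsed(self, positions, length=50, total=None):
        out = collapse_duplicates(reads_at(positions, length=length), cap=1)
        if total is not None:
            out.total_mapped = total
        return out

    def test_reads_only_in_flanks_leave_body_zero(self):
        reads = self.make_collapsed([1000, 1100, 5200, 5300])
        profile = metaplot([gi(3000, 4000)], reads, flank=1000)
        body = profile.df[profile.df["kind"] == "body"]
        assert (body["density"] == 0).all()

    def test_single_read_lands_in_its_bin(self):
        reads = self.make_collapsed([3000], length=50)  # first body bin of [3000,4000)
        profile = metaplot([gi(3000, 4000)], reads, n_body_bins=20, flank=1000)
        body = profile.df[profile.df["kind"] == "body"].reset_index(drop=True)
        assert body.loc[0, "density"] > 0
        assert (body.loc[2:, "density"] == 0).all()

    def test_duplicating_region_set_leaves_profile_unchanged(self, rng):
        reads = self.make_collapsed(sorted(rng.integers(0, 50_000, size=400)))
        regions = [gi(int(s), int(s) + 800) for s in (10_000, 20_000, 30_000)]
        once = metaplot(regions, reads)
        twice = metaplot(regions + regions, reads)
        assert np.allclose(once.df["density"], twice.df["density"])

    def test_uniform_reads_give_flat_profile(self, rng):
        positions = np.sort(rng.integers(0, 200_000, size=40_000))
        reads = self.make_collapsed(positions)
        regions = [gi(int(s), int(s) + 2000) for s in range(20_000, 180_000, 8000)]
        profile = metaplot(regions, reads)
        dens = profile.df["density"].to_numpy()
        assert dens.std() / dens.mean() < 0.12

    def test_short_region_uses_fractional_bins(self):
        reads = self.make_collapsed([3000, 3002, 3004], length=3)
        profile = metaplot([gi(3000, 3010)], reads, n_body_bins=20, flank=100)
        assert profile.df["density"].sum() > 0

    def test_empty_regions_rejected(self):
        with pytest.raises(ValueError):
            metaplot([], self.make_collapsed([0]))


class TestMannWhitney:
    def test_separated_samples_exact_enumeration(self):
        """x=[1,2,3] vs y=[4,5,6]: U(x)=0 and the two-sided exact p is
        2 x 1/C(6,3) = 0.1."""
        r = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0
        assert r.method == "exact"
        assert r.p_value == pytest.approx(0.1)
        assert mann_whitney_exact_enumeration([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_p_near_one(self):
        r = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value > 0.9

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_matches_enumeration_oracle_all_small_configs(self, rng):
        """Exact p equals full enumeration for every n1+n2 <= 12 split
        without ties."""
        for n1 in range(1, 7):
            for n2 in range(1, 13 - n1):
                vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
                x, y = vals[:n1], vals[n1:]
                r = mann_whitney_u(x, y)
                assert r.method == "exact"
                assert r.p_value == pytest.approx(
                    mann_whitney_exact_enumeration(x, y), abs=1e-12)

    def test_normal_approximation_close_to_exact_at_n8(self, rng):
        """Documented tolerance: |p_exact - p_approx| < 0.06 for n=8 draws."""
        for _ in range(20):
            vals = rng.permutation(np.arange(1.0, 9.0))
            x, y = vals[:4], vals[4:]
            p_exact = mann_whitney_exact_enumeration(x, y)
            p_approx = mann_whitney_u(x, y, exact_max_n=0).p_value
            assert abs(p_exact - p_approx) < 0.06


class TestWeightedChangeCorrelation:
    def build(self, chip_counts_mut):
        """5 spaced DMRs; WT ChIP flat, mutant ChIP counts per DMR as given;
        mutant methylation drop increases with DMR index."""
        dmr_ivs = [gi(i * 10_000, i * 10_000 + 1000) for i in range(5)]
        pos = np.concatenate([np.arange(iv.start + 100, iv.start + 900, 40)
                              for iv in dmr_ivs])
        wt_props = np.full(pos.shape, 0.8)
        mut_props = np.concatenate([
            np.full(20, 0.8 - 0.15 * i) for i in range(5)])
        wt, mut = chh_tables(pos, wt_props, mut_props, coverage=20)
        chip_wt = collapse_duplicates(
            reads_at([iv.start + 500 for iv in dmr_ivs]), cap=1)
        mut_positions = []
        for i, iv in enumerate(dmr_ivs):
            mut_positions += [iv.start + 300 + 10 * j for j in range(chip_counts_mut[i])]
        chip_mut = collapse_duplicates(reads_at(mut_positions), cap=1)
        chip_wt.total_mapped = chip_mut.total_mapped = 10_000
        return dmr_ivs, chip_wt, chip_mut, wt, mut

    def test_monotone_pairing_gives_rho_one(self):
        dmrs, cw, cm, wt, mut = self.build([1, 2, 3, 4, 5])
        rho, table = weighted_change_correlation(dmrs, cw, cm, wt, mut)
        assert rho == pytest.approx(1.0)
        assert len(table) == 5

    def test_antimonotone_pairing_gives_rho_minus_one(self):
        dmrs, cw, cm, wt, mut = self.build([5, 4, 3, 2, 1])
        rho, _ = weighted_change_correlation(dmrs, cw, cm, wt, mut)
        assert rho == pytest.approx(-1.0)

    def test_too_few_dmrs_rejected(self):
        dmrs, cw, cm, wt, mut = self.build([1, 2, 3, 4, 5])
        with pytest.raises(ValueError):
            weighted_change_correlation(dmrs[:2], cw, cm, wt, mut)
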