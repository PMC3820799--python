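"""DMR caller stages: coverage filter, smoother, t statistics, segmentation,
filter cascade, and the caller-level invariants."""

import numpy as np
import pandas as pd
import pytest

from rddm.dmr import (CandidateRegion, DmrParams, RetainedSites, SmoothedTrack,
                      audit_dmrs, call_chh_dmrs, coverage_filter, filter_dmrs,
                      segment_candidates, site_statistics, smooth_track)

from conftest import chh_tables, make_methylome


def retained_from(positions, wt_props, mut_props, **kw):
    wt, mut = chh_tables(positions, wt_props, mut_props, **kw)
    return coverage_filter(wt, mut)


def stats_frame(positions, t, raw_wt=0.5, raw_mut=0.2, chrom="chr1"):
    n = len(positions)
    return pd.DataFrame({
        "chrom": chrom, "pos": positions, "t": t,
        "raw_wt": np.broadcast_to(raw_wt, n).astype(float),
        "raw_mut": np.broadcast_to(raw_mut, n).astype(float),
    })


class TestCoverageFilter:
    def make(self, wt_covs, mut_cov):
        rows = lambda cov: [("chr1", 100, "+", "CHH", 0, cov)]
        wt = [make_methylome(f"wt{i}", rows(c)) for i, c in enumerate(wt_covs)]
        mut = make_methylome("mut", rows(mut_cov))
        return coverage_filter(wt, mut)

    def test_majority_three_of_four_retained(self):
        assert len(self.make([2, 2, 2, 0], mut_cov=2)) == 1

    def test_two_of_four_is_not_a_majority(self):
        assert len(self.make([2, 2, 0, 0], mut_cov=5)) == 0

    def test_low_mutant_coverage_drops_site_regardless_of_wt(self):
        assert len(self.make([5, 5, 5, 5], mut_cov=1)) == 0

    def test_zero_wt_libraries_rejected(self):
        mut = make_methylome("mut", [("chr1", 1, "+", "CHH", 0, 5)])
        with pytest.raises(ValueError, match="wild-type"):
            coverage_filter([], mut)

    def test_only_chh_sites_considered(self):
        rows = [("chr1", 10, "+", "CG", 5, 10), ("chr1", 20, "+", "CHH", 5, 10)]
        wt = [make_methylome(f"wt{i}", rows) for i in range(4)]
        retained = coverage_filter(wt, make_methylome("m", rows))
        assert list(retained.pos) == [20]


class TestSmoother:
    def test_constant_methylation_is_preserved(self):
        pos = np.arange(0, 5000, 50)
        sites = retained_from(pos, 0.5, 0.5)
        track = smooth_track(sites)
        assert np.allclose(track.df["mu_wt"], 0.5)
        assert np.allclose(track.df["mu_mut"], 0.5)

    def test_single_isolated_site_keeps_raw_value(self, caplog):
        sites = retained_from([1000], 0.7, 0.3)
        with caplog.at_level("WARNING"):
            track = smooth_track(sites)
        assert "unsmoothed" in caplog.text
        assert track.df["mu_wt"].iloc[0] == pytest.approx(0.7)
        assert track.df["mu_mut"].iloc[0] == pytest.approx(0.3)

    def test_step_function_smooths_monotonically(self):
        pos = np.arange(0, 10_000, 50)
        wt = np.where(pos < 5000, 0.8, 0.2)
        sites = retained_from(pos, wt, 0.5)
        track = smooth_track(sites)
        mu = track.df["mu_wt"].to_numpy()
        assert (np.diff(mu) <= 1e-12).all()
        assert mu[0] == pytest.approx(0.8) and mu[-1] == pytest.approx(0.2)

    def test_sparse_window_expands_to_min_sites(self):
        # 12 sites spread over 20 kb: every +/-500 bp window is sparse, so all
        # values smooth over the nearest 10 sites rather than staying raw
        pos = np.arange(12) * 1700
        props = np.linspace(0.2, 0.8, 12)
        sites = retained_from(pos, props, props)
        track = smooth_track(sites, half_width=500, min_sites=10)
        mu = track.df["mu_wt"].to_numpy()
        assert not np.allclose(mu, props)  # genuinely smoothed
        assert mu.min() >= props.min() and mu.max() <= props.max()


class TestSiteStatistics:
    def make_track(self, mu_wt, mu_mut, sigma):
        n = len(mu_wt)
        return SmoothedTrack(pd.DataFrame({
            "chrom": "chr1", "pos": np.arange(n) * 100,
            "mu_wt": mu_wt, "mu_mut": mu_mut, "sigma": sigma,
            "raw_wt": mu_wt, "raw_mut": mu_mut,
        }))

    def test_equal_means_give_zero(self):
        track = self.make_track([0.5, 0.2], [0.5, 0.2], [0.1, 0.1])
        assert (site_statistics(track, floor=0.05)["t"] == 0).all()

    def test_definition_arithmetic(self):
        track = self.make_track([0.5], [0.1], [0.1])
        assert site_statistics(track, floor=0.01)["t"].iloc[0] == pytest.approx(4.0)

    def test_sigma_floor_applies(self):
        track = self.make_track([0.5], [0.1], [0.001])
        assert site_statistics(track, floor=0.1)["t"].iloc[0] == pytest.approx(4.0)

    def test_group_swap_negates_every_t(self, rng):
        mu_wt = rng.random(50)
        mu_mut = rng.random(50)
        sigma = rng.random(50) * 0.2 + 0.01
        fwd = site_statistics(self.make_track(mu_wt, mu_mut, sigma), floor=0.02)
        rev = site_statistics(self.make_track(mu_mut, mu_wt, sigma), floor=0.02)
        assert np.allclose(fwd["t"], -rev["t"])


class TestSegmentation:
    def test_single_run(self):
        stats = stats_frame([0, 50, 100], [2.5, 2.5, 2.5])
        cands = segment_candidates(stats)
        assert len(cands) == 1 and cands[0].n_chh == 3
        assert cands[0].interval.start == 0 and cands[0].interval.end == 101

    def test_sign_change_splits(self):
        stats = stats_frame([0, 50, 100], [2.5, -2.5, 2.5])
        assert [c.n_chh for c in segment_candidates(stats)] == [1, 1, 1]

    def test_gap_boundary_splits_at_max_gap(self):
        joined = segment_candidates(stats_frame([0, 300], [2.5, 2.5]))
        split = segment_candidates(stats_frame([0, 301], [2.5, 2.5]))
        assert len(joined) == 1 and len(split) == 2

    def test_subthreshold_site_breaks_run(self):
        stats = stats_frame([0, 50, 100], [2.5, 1.0, 2.5])
        assert [c.n_chh for c in segment_candidates(stats)] == [1, 1]

    def test_empty_input(self):
        assert segment_candidates(stats_frame([], [])) == []


def candidate(n, t_value, raw_wt, raw_mut):
    pos = np.arange(n) * 50
    return CandidateRegion("chr1", pos, np.full(n, float(t_value)),
                           np.full(n, float(raw_wt)), np.full(n, float(raw_mut)))


class TestFilterCascade:
    def test_all_thresholds_at_boundary_pass(self):
        # n=20, mean_diff=0.1, area=20*5=100: every clause exactly at its limit
        c = candidate(20, 5.0, 0.1, 0.0)
        assert len(filter_dmrs([c])) == 1

    def test_nineteen_sites_rejected(self):
        c = candidate(19, 5.3, 0.3, 0.0)  # area 100.7, mean diff 0.3: only n fails
        assert filter_dmrs([c]) == []

    def test_mean_difference_below_point_one_rejected(self):
        c = candidate(25, 5.0, 0.09, 0.0)
        assert filter_dmrs([c]) == []

    def test_area_99_rejected(self):
        c = candidate(25, 99.0 / 25, 0.3, 0.0)
        assert filter_dmrs([c]) == []

    def test_hyper_direction_hidden_by_default(self):
        c = candidate(25, -8.0, 0.0, 0.4)  # mutant gained methylation
        assert filter_dmrs([c]) == []
        hyper = filter_dmrs([c], directions=("hypo", "hyper"))
        assert len(hyper) == 1 and hyper[0].direction == "hyper"

    def test_area_exceeds_40_whenever_cascade_passes(self, rng):
        """n >= 20 member sites with |t| > 2 force |area| > 40, so the area
        filter is strictly stronger than vacuous on every retained DMR."""
        for _ in range(200):
            n = int(rng.integers(20, 60))
            t = rng.uniform(2.0001, 8.0, size=n) * rng.choice([-1.0, 1.0])
            c = CandidateRegion("chr1", np.arange(n) * 50, t,
                                rng.random(n), rng.random(n))
            for d in filter_dmrs([c], directions=("hypo", "hyper")):
                assert abs(d.area) > 40


@pytest.fixture(scope="module")
def noisy_scenario():
    rng = np.random.default_rng(99)
    pos = np.sort(rng.choice(60_000, size=2_000, replace=False))
    wt = np.full(pos.shape, 0.5)
    mut = np.where((pos >= 20_000) & (pos < 24_000), 0.1, 0.5)
    return chh_tables(pos, wt, mut, coverage=12, noise=np.random.default_rng(5))


class TestCallerInvariants:

    def test_recovers_the_induced_region(self, noisy_scenario):
        wt, mut = noisy_scenario
        dmrs = call_chh_dmrs(wt, mut)
        assert len(dmrs) >= 1
        assert any(d.interval.start < 24_000 and d.interval.end > 20_000 for d in dmrs)
        for d in dmrs:
            assert d.direction == "hypo"

    def test_threshold_tightening_nests_output(self, noisy_scenario):
        wt, mut = noisy_scenario
        base = {(d.interval.chrom, d.interval.start, d.interval.end)
                for d in call_chh_dmrs(wt, mut)}
        for change in ({"t_cut": 2.5}, {"min_sites": 30}, {"min_meandiff": 0.2},
                       {"min_area": 150.0}):
            tightened = call_chh_dmrs(wt, mut, DmrParams(**change))
            for d in tightened:
                key = (d.interval.chrom, d.interval.start, d.interval.end)
                # tightening t_cut can shrink runs; every tightened DMR must
                # lie within some baseline DMR's span
                assert any(key[0] == b[0] and key[1] >= b[1] and key[2] <= b[2]
                           for b in base)
        # for the three pure filter thresholds the set is an exact subset
        for change in ({"min_sites": 30}, {"min_meandiff": 0.2}, {"min_area": 150.0}):
            tightened = {(d.interval.chrom, d.interval.start, d.interval.end)
                         for d in call_chh_dmrs(wt, mut, DmrParams(**change))}
            assert tightened <= base

    def test_audit_passes_all_emitted_dmrs(self, noisy_scenario):
        wt, mut = noisy_scenario
        dmrs = call_chh_dmrs(wt, mut)
        audit = audit_dmrs(dmrs, wt, mut)
        assert audit["ok"].all()

    def test_audit_flags_hand_edited_dmr(self, noisy_scenario):
        from rddm.core import DMR, GenomicInterval
        wt, mut = noisy_scenario
        bogus = DMR(GenomicInterval("chr1", 40_000, 40_200), 19, 0.3, 120.0, "hypo")
        audit = audit_dmrs([bogus], wt, mut)
        assert not audit["ok"].iloc[0]
        assert audit["failed"].iloc[0] != ""
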