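"""mCpG designation, window/region summaries, QC and in-silico MspI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import eetaps as e
from eetaps import analysis, calling
from eetaps.calling import CallerConfig, CpGCallTable, FragmentInterval
from eetaps.errors import ParameterError


def table_from(positions, cleaved, readthrough, length=10_000, contig="chr1"):
    idx = e.CpGIndex({contig: np.array(positions, dtype=np.int64)},
                     {contig: length})
    return CpGCallTable(idx, {contig: np.array(cleaved)},
                        {contig: np.array(readthrough)})


class TestDesignateMcpgs:
    def test_boundary_level_excluded(self):
        # level exactly 0.1 fails the strict > criterion
        table = table_from([10], [1], [9])
        assert analysis.site_count(e.designate_mcpgs(table)) == 0

    def test_needs_cleaved_evidence(self):
        table = table_from([10], [0], [5])  # level 0 anyway
        t2 = table_from([10, 20], [0, 1], [0, 1])  # site 10 uncovered
        assert analysis.site_count(e.designate_mcpgs(table)) == 0
        assert e.designate_mcpgs(t2)["chr1"].tolist() == [20]

    def test_filter_enumeration(self):
        # {A: (.3, cleaved 3), B: (.05, 1), C: (.2, 1)} -> {A, C}
        table = table_from([10, 20, 30], [3, 1, 1], [7, 19, 4])
        assert e.designate_mcpgs(table)["chr1"].tolist() == [10, 30]


class TestCoveredSites:
    def test_empty_table(self):
        table = table_from([], [], [])
        assert analysis.site_count(e.covered_sites(table, 1)) == 0

    def test_min_depth_thresholds(self):
        table = table_from([10, 20, 30], [1, 0, 2], [1, 0, 3])
        assert len(e.covered_sites(table, 1)["chr1"]) == 2
        assert e.covered_sites(table, 5)["chr1"].tolist() == [30]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        cl = rng.integers(0, 4, 50)
        rt = rng.integers(0, 4, 50)
        table = table_from(np.arange(0, 100, 2), cl, rt)
        want = [int(p) for p, c, r in zip(np.arange(0, 100, 2), cl, rt)
                if c + r >= 3]
        assert e.covered_sites(table, 3)["chr1"].tolist() == want


class TestWindowMeans:
    def test_single_site_window(self):
        table = table_from([150], [4], [1], length=1000)
        wm = e.window_means(table, 100)
        assert wm.loc[1, "mean"] == pytest.approx(0.8)

    def test_empty_window_has_no_value(self):
        table = table_from([150], [4], [1], length=1000)
        wm = e.window_means(table, 100)
        assert np.isnan(wm.loc[0, "mean"]) and wm.loc[0, "n_sites"] == 0

    def test_matches_brute_force_grouping(self):
        rng = np.random.default_rng(7)
        pos = np.sort(rng.choice(np.arange(0, 5000, 2), 80, replace=False))
        cl = rng.integers(0, 5, 80)
        rt = rng.integers(0, 5, 80)
        table = table_from(pos, cl, rt, length=5000)
        wm = e.window_means(table, 500)
        lv = table.level("chr1")
        for i in range(10):
            vals = [l for p, l in zip(pos, lv)
                    if 500 * i <= p < 500 * (i + 1) and not np.isnan(l)]
            if vals:
                assert wm.loc[i, "mean"] == pytest.approx(np.mean(vals))
            else:
                assert np.isnan(wm.loc[i, "mean"])


class TestRegionMeans:
    def test_boundary_site_at_end_excluded(self):
        table = table_from([100, 200], [1, 1], [0, 3])
        rs = e.RegionSet([("chr1", 50, 200, "r")])
        rm = e.region_means(table, rs)
        assert rm.loc[0, "mean"] == pytest.approx(1.0)  # only site 100
        assert rm.loc[0, "n_sites"] == 1

    def test_empty_region_no_value(self):
        table = table_from([100], [1], [0])
        rs = e.RegionSet([("chr1", 500, 900, "r")])
        assert np.isnan(e.region_means(table, rs).loc[0, "mean"])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.choice(np.arange(0, 3000, 2), 60, replace=False))
        table = table_from(pos, rng.integers(0, 4, 60), rng.integers(0, 4, 60),
                           length=3000)
        rs = e.RegionSet([("chr1", 0, 1000, "a"), ("chr1", 1200, 2500, "b")])
        rm = e.region_means(table, rs)
        lv = table.level("chr1")
        for i, (s, t) in enumerate([(0, 1000), (1200, 2500)]):
            vals = [l for p, l in zip(pos, lv) if s <= p < t and not np.isnan(l)]
            assert rm.loc[i, "mean"] == pytest.approx(np.mean(vals))


class TestMetaprofile:
    def test_uniform_level_gives_flat_profile(self):
        pos = np.arange(100, 9900, 100)
        table = table_from(pos, np.full(len(pos), 1), np.full(len(pos), 4))
        rs = e.RegionSet([("chr1", 4000, 6000, "r")])
        prof = e.metaprofile(table, rs, flank=4000, n_body_bins=10,
                             n_flank_bins=10)
        filled = prof.dropna(subset=["mean"])
        assert len(filled) == 30
        assert np.allclose(filled["mean"], 0.2)

    def test_no_covered_sites_empty_bins(self):
        table = table_from([5000], [0], [0])
        rs = e.RegionSet([("chr1", 4000, 6000, "r")])
        prof = e.metaprofile(table, rs)
        assert prof["n_sites"].sum() == 0

    def test_two_region_hand_computed(self):
        # regions [100,200) and [300,500); flank 100, 1 flank bin, 2 body bins
        table = table_from([50, 120, 160, 350, 420, 520],
                           [1, 1, 0, 1, 1, 1],
                           [0, 0, 1, 1, 3, 0], length=1000)
        rs = e.RegionSet([("chr1", 100, 200, "a"), ("chr1", 300, 500, "b")])
        prof = e.metaprofile(table, rs, flank=100, n_body_bins=2,
                             n_flank_bins=1)
        # upstream bin: site 50 (region a, level 1.0) — site 250 absent
        assert prof.loc[0, "mean"] == pytest.approx(1.0)
        # body bin 1: site 120 (a, 1.0) + site 350 (b, 0.5) -> 0.75
        assert prof.loc[1, "mean"] == pytest.approx(0.75)
        # body bin 2: site 160 (a, 0.0) + site 420 (b, 0.25) -> 0.125
        assert prof.loc[2, "mean"] == pytest.approx(0.125)
        # downstream bin: site 520 only (after region b, level 1.0)
        assert prof.loc[3, "mean"] == pytest.approx(1.0)


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        s = np.full(20, 0.37)
        assert np.allclose(e.moving_average(s, 3), s)

    def test_bw_larger_than_series_gives_global_mean(self):
        s = np.array([1.0, 2.0, 3.0])
        assert np.allclose(e.moving_average(s, 10), 2.0)

    def test_hand_computed_centered_window(self):
        s = [0, 0, 0, 10, 0, 0, 0]
        want = [0, 0, 10 / 3, 10 / 3, 10 / 3, 0, 0]
        assert np.allclose(e.moving_average(s, 1), want)

    def test_nan_excluded_from_windows(self):
        s = [1.0, np.nan, 3.0]
        assert np.allclose(e.moving_average(s, 1), [1.0, 2.0, 3.0])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40),
           st.integers(1, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_against_naive_window(self, values, bw):
        got = e.moving_average(values, bw)
        for i in range(len(values)):
            window = values[max(0, i - bw): i + bw + 1]
            assert got[i] == pytest.approx(np.mean(window))


class TestCorrelate:
    def test_identity_and_negation(self):
        a = np.array([0.1, 0.5, 0.9, 0.3])
        assert e.correlate(a, a) == pytest.approx(1.0)
        assert e.correlate(a, -a) == pytest.approx(-1.0)

    def test_textbook_formula(self):
        rng = np.random.default_rng(9)
        a = rng.random(50)
        b = 0.5 * a + rng.random(50)
        am, bm = a - a.mean(), b - b.mean()
        want = np.sum(am * bm) / np.sqrt(np.sum(am ** 2) * np.sum(bm ** 2))
        assert e.correlate(a, b) == pytest.approx(want, abs=1e-12)

    def test_zero_variance_undefined(self):
        assert np.isnan(e.correlate([1.0, 1.0, 1.0], [0.2, 0.5, 0.9]))

    def test_nan_pairs_dropped(self):
        a = [0.1, np.nan, 0.9, 0.4]
        b = [0.2, 0.5, np.nan, 0.8]
        assert e.correlate(a, b) == pytest.approx(
            e.correlate([0.1, 0.4], [0.2, 0.8]))


class TestSubsample:
    @pytest.fixture
    def frags(self):
        return [FragmentInterval("chr1", i, i + 100) for i in range(10_000)]

    def test_fraction_one_is_identity(self, frags):
        assert e.subsample_fragments(frags, 1.0, seed=1) == frags

    def test_fraction_zero_is_empty(self, frags):
        assert e.subsample_fragments(frags, 0.0, seed=1) == []

    def test_binomial_count(self, frags):
        kept = e.subsample_fragments(frags, 0.5, seed=13)
        assert abs(len(kept) - 5000) < 3 * np.sqrt(10_000 * 0.25)

    def test_nested_property(self, frags):
        sets = [set((f.start, f.end) for f in
                    e.subsample_fragments(frags, f10 / 10, seed=7))
                for f10 in range(11)]
        for a, b in zip(sets[:-1], sets[1:]):
            assert a <= b


class TestDetectionStats:
    def test_perfect_agreement(self):
        s = {"chr1": np.array([1, 5, 9])}
        st_ = e.detection_stats(s, s)
        assert st_.recall == st_.precision == st_.jaccard == 1.0

    def test_disjoint_sets(self):
        a = {"chr1": np.array([1, 3])}
        b = {"chr1": np.array([5, 7])}
        st_ = e.detection_stats(a, b)
        assert st_.recall == st_.precision == st_.jaccard == 0.0

    def test_set_arithmetic(self):
        truth = {"chr1": np.arange(1, 11)}
        called = {"chr1": np.arange(6, 16)}
        st_ = e.detection_stats(called, truth)
        assert st_.recall == pytest.approx(0.5)
        assert st_.precision == pytest.approx(0.5)
        assert st_.jaccard == pytest.approx(1 / 3)


class TestEndComposition:
    def test_pure_cleavage_ends_all_on_cpg(self, small_genome, small_index):
        meth = e.Methylome(small_index,
                           {c: np.ones(len(small_index[c]))
                            for c in small_index.contigs})
        model = e.EfficiencyModel(1.0, 0.0, default_cleavage=1.0,
                                  context_dependent=False)
        mols = e.whole_contig_molecules(small_genome)
        frags = e.run_digestion(mols, meth, small_genome, model, seed=3)
        interior = [f for f in frags
                    if f.left_end_kind == "cleavage"
                    and f.right_end_kind == "cleavage"]
        st_ = e.end_composition(interior, small_genome, small_index)
        assert st_.on_cpg_fraction == 1.0
        assert st_.cg_end_fraction == 1.0

    def test_single_fragment_left_distance_zero(self):
        g = e.ReferenceGenome((("chr1", "A" * 40 + "CG" + "A" * 158),))
        idx = e.CpGIndex.from_genome(g)
        st_ = e.end_composition([FragmentInterval("chr1", 42, 100)], g, idx)
        assert st_.distance_histogram.get(0, 0) >= 1

    def test_undigested_shear_baseline(self, small_genome, small_index):
        # shear ends should land on C/G at roughly the genome's base rate
        rng = np.random.default_rng(17)
        frags = [FragmentInterval("chr1", int(s), int(s) + 500)
                 for s in rng.integers(10, 9000, 600)]
        st_ = e.end_composition(frags, small_genome, small_index)
        seq = small_genome.sequence("chr1")
        baseline = (seq.count("C") + seq.count("G")) / len(seq)
        assert abs(st_.cg_end_fraction - baseline) < 0.08
        assert st_.on_cpg_fraction < 0.2


class TestInsilicoMspi:
    def test_no_ccgg_gives_no_retained(self):
        g = e.ReferenceGenome((("chr1", "AT" * 400),))
        frags, covered = e.insilico_mspi(g)
        assert frags == [] and covered["chr1"].size == 0

    def test_hand_enumerated_cut_sites(self):
        seq = "A" * 4 + "CCGG" + "A" * 150 + "CCGG" + "A" * 38
        g = e.ReferenceGenome((("chr1", seq),))
        frags, covered = e.insilico_mspi(g, size_min=10, size_max=200)
        # cuts at C^CGG: offsets 4+1=5 and 158+1=159; pieces [0,5),[5,159),[159,200)
        assert [(f.start, f.end) for f in frags] == [(5, 159), (159, 200)]
        # CpGs at 5 and 159 (inside CCGG); both inside retained fragments
        assert covered["chr1"].tolist() == [5, 159]

    def test_length_conservation(self, small_genome):
        frags = analysis.mspi_fragments_all(small_genome)
        by_contig = {}
        for f in frags:
            by_contig.setdefault(f.contig, []).append(f)
        for name, ln in small_genome.lengths.items():
            assert sum(f.length for f in by_contig[name]) == ln

    def test_coverage_far_below_eetaps(self, small_genome, small_index,
                                       small_methylome):
        _, covered = e.insilico_mspi(small_genome)
        mspi_frac = sum(len(v) for v in covered.values()) / small_index.n_sites
        mols = e.sample_molecules(small_genome, 150, (4000, 800, 500), seed=19)
        frags = e.run_digestion(mols, small_methylome, small_genome, seed=20)
        kept = e.size_select(frags)
        table = e.tally(calling.intervals_from_fragments(kept), small_index)
        ee_frac = analysis.site_count(e.covered_sites(table, 1)) / small_index.n_sites
        assert ee_frac > mspi_frac


class TestDensityBias:
    def test_perfect_caller_no_bias(self):
        g = e.generate_genome(50_000, 1, 0.5, 0.25, seed=23)
        idx = e.CpGIndex.from_genome(g)
        rng = np.random.default_rng(24)
        meth = e.Methylome(idx, {"chr1": (rng.random(len(idx["chr1"])) < 0.5)
                                 .astype(float)})
        model = e.EfficiencyModel(1.0, 0.0, default_cleavage=1.0,
                                  context_dependent=False)
        frags = e.run_digestion(e.whole_contig_molecules(g, 3), meth, g,
                                model, seed=25)
        table = e.tally(calling.intervals_from_fragments(frags), idx,
                        CallerConfig(offset_window=0))
        df = e.density_bias(table, meth, window_size=5000, n_density_bins=3)
        assert np.all(np.abs(df["mean_error"]) < 1e-9)

    def test_single_bin_equals_global_mean(self, small_genome, small_index,
                                           small_methylome):
        mols = e.sample_molecules(small_genome, 100, (3000, 500, 500), seed=26)
        frags = e.run_digestion(mols, small_methylome, small_genome, seed=27)
        table = e.tally(calling.intervals_from_fragments(frags), small_index)
        df = e.density_bias(table, small_methylome, window_size=2000,
                            n_density_bins=1)
        assert len(df) == 1
        wm = e.window_means(table, 2000)
        # recompute global mean error by hand
        errors = []
        for c in small_index.contigs:
            pos = small_index[c]
            lv = small_methylome.level_array(c)
            sub = wm[wm.contig == c].reset_index(drop=True)
            for i in range(len(sub)):
                mask = (pos >= i * 2000) & (pos < (i + 1) * 2000)
                if mask.any() and not np.isnan(sub.loc[i, "mean"]):
                    errors.append(sub.loc[i, "mean"] - lv[mask].mean())
        assert df.loc[0, "mean_error"] == pytest.approx(np.mean(errors))
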