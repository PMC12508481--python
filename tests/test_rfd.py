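"""RFD computation, high-|RFD| region calling, and TRC-site geometry."""
import numpy as np
import pytest

from trc_atlas.intervals import GenomeAssembly, GenomeInterval, IntervalSet
from trc_atlas.rfd import (
    SignedGene,
    StrandedBinnedCounts,
    TRCParams,
    call_high_rfd_regions,
    classify_orientation,
    compute_rfd,
    define_trc_sites,
    frame_to_sites,
    genes_in_regions,
    read_stranded_counts,
    sites_to_frame,
    write_stranded_counts,
)


def counts_of(w, c, bin_size=1000):
    return StrandedBinnedCounts(bin_size, {"chr1": np.array(w)}, {"chr1": np.array(c)})


class TestComputeRfd:
    @pytest.mark.parametrize(
        "w,c,expected",
        [(10, 90, 0.8), (50, 50, 0.0), (90, 10, -0.8)],
    )
    def test_single_bin_arithmetic(self, w, c, expected):
        track = compute_rfd(counts_of([w], [c]), min_total=1, smooth_bins=0)
        assert track.values["chr1"][0] == pytest.approx(expected)

    def test_zero_coverage_is_missing(self):
        track = compute_rfd(counts_of([0, 10], [0, 90]), min_total=1, smooth_bins=0)
        assert np.isnan(track.values["chr1"][0])
        assert track.values["chr1"][1] == pytest.approx(0.8)

    def test_min_total_applies_to_smoothed_coverage(self):
        track = compute_rfd(counts_of([2, 2, 2], [2, 2, 2]), min_total=10, smooth_bins=0)
        assert np.all(np.isnan(track.values["chr1"]))

    def test_watson_crick_swap_antisymmetry(self, rng):
        w = rng.poisson(100, size=200)
        c = rng.poisson(100, size=200)
        fwd = compute_rfd(counts_of(w, c), min_total=1, smooth_bins=2)
        rev = compute_rfd(counts_of(c, w), min_total=1, smooth_bins=2)
        np.testing.assert_allclose(rev.values["chr1"], -fwd.values["chr1"])

    def test_bounded_wherever_defined(self, rng):
        w = rng.poisson(30, size=500)
        c = rng.poisson(30, size=500)
        vals = compute_rfd(counts_of(w, c)).values["chr1"]
        ok = ~np.isnan(vals)
        assert np.all(np.abs(vals[ok]) <= 1.0)

    def test_smoothing_averages_counts(self):
        # W constant, C stepped: smoothing over 3 bins blends the step
        track = compute_rfd(
            counts_of([100, 100, 100, 100], [0, 0, 200, 200]),
            min_total=1, smooth_bins=1,
        )
        # bin 1: smoothed C = (0+0+200)/3, W = 100 -> (66.7-100)/166.7
        assert track.values["chr1"][1] == pytest.approx((200 / 3 - 100) / (200 / 3 + 100))

    def test_round_trip_counts_tsv(self, tmp_path, rng):
        assembly = GenomeAssembly({"chr1": 20_000, "chr2": 10_000})
        counts = StrandedBinnedCounts(
            1000,
            {"chr1": rng.poisson(50, 20), "chr2": rng.poisson(50, 10)},
            {"chr1": rng.poisson(50, 20), "chr2": rng.poisson(50, 10)},
        )
        p = tmp_path / "ok.tsv"
        write_stranded_counts(counts, p)
        back = read_stranded_counts(p, assembly, 1000)
        for chrom in counts.watson:
            np.testing.assert_array_equal(back.watson[chrom], counts.watson[chrom])
            np.testing.assert_array_equal(back.crick[chrom], counts.crick[chrom])


def rfd_track(values, bin_size=1000):
    from trc_atlas.intervals import BinnedTrack

    return BinnedTrack(bin_size, {"chr1": np.asarray(values, dtype=float)}, "RFD")


class TestCallHighRfdRegions:
    def test_constant_high_rfd_single_region(self):
        regions = call_high_rfd_regions(rfd_track([0.9] * 20))
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.name) == (0, 20_000, "+")

    def test_exactly_at_threshold_is_excluded(self):
        assert len(call_high_rfd_regions(rfd_track([0.75] * 20))) == 0

    def test_negative_sign_region(self):
        regions = call_high_rfd_regions(rfd_track([-0.9] * 10))
        assert regions[0].name == "-"

    def test_gap_bridging_and_min_bins(self):
        vals = [0.9] * 3 + [0.1] + [0.9] * 3  # 6 qualifying bins, 1-bin gap
        params = TRCParams(min_region_bins=5, merge_gap_bins=1)
        regions = call_high_rfd_regions(rfd_track(vals), params)
        assert len(regions) == 1 and (regions[0].start, regions[0].end) == (0, 7000)
        # without gap tolerance the two 3-bin runs fall below min_region_bins
        params = TRCParams(min_region_bins=5, merge_gap_bins=0)
        assert len(call_high_rfd_regions(rfd_track(vals), params)) == 0

    def test_opposite_sign_never_bridged(self):
        vals = [0.9] * 5 + [-0.9] + [0.9] * 5
        params = TRCParams(min_region_bins=5, merge_gap_bins=1)
        regions = call_high_rfd_regions(rfd_track(vals), params)
        spans = sorted((r.start, r.end) for r in regions if r.name == "+")
        assert spans == [(0, 5000), (6000, 11_000)]

    def test_matches_exhaustive_run_scan_oracle(self, rng):
        vals = rng.uniform(-1, 1, size=400)
        vals[rng.random(400) < 0.05] = np.nan
        params = TRCParams(min_region_bins=3, merge_gap_bins=1)
        got = sorted(
            (r.start // 1000, r.end // 1000, r.name)
            for r in call_high_rfd_regions(rfd_track(vals), params)
        )

        def oracle(sign):
            qual = [
                (not np.isnan(v)) and (v > 0.75 if sign == "+" else v < -0.75)
                for v in vals
            ]
            opp = [
                (not np.isnan(v)) and (v < -0.75 if sign == "+" else v > 0.75)
                for v in vals
            ]
            regions = []
            run = []
            for i, q in enumerate(qual):
                if q:
                    if run and (
                        i - run[-1] - 1 > params.merge_gap_bins
                        or any(opp[run[-1] + 1 : i])
                    ):
                        regions.append(run)
                        run = []
                    run.append(i)
            if run:
                regions.append(run)
            return [
                (r[0], r[-1] + 1, sign)
                for r in regions
                if len(r) >= params.min_region_bins
            ]

        assert got == sorted(oracle("+") + oracle("-"))


class TestGenesInRegions:
    def region(self, start, end, sign="+"):
        return GenomeInterval("chr1", start, end, ".", sign)

    def test_containment_and_straddle(self):
        regions = IntervalSet([self.region(10_000, 30_000)])
        inside = GenomeInterval("chr1", 12_000, 20_000, "+", "in")
        straddle = GenomeInterval("chr1", 25_000, 35_000, "+", "out")
        tagged = genes_in_regions(IntervalSet([inside, straddle]), regions)
        assert [sg.gene.name for sg in tagged] == ["in"]
        assert tagged[0].sign == "+"

    def test_matches_all_pairs_oracle(self, rng):
        regions = IntervalSet(
            self.region(int(s), int(s) + 20_000, rng.choice(["+", "-"]))
            for s in np.arange(0, 500_000, 100_000)
        )
        genes = IntervalSet(
            GenomeInterval(
                "chr1", int(s), int(s) + int(rng.integers(5000, 40_000)), "+", f"g{i}"
            )
            for i, s in enumerate(rng.integers(0, 450_000, size=50))
        )
        got = {sg.gene.name for sg in genes_in_regions(genes, regions)}
        expected = {
            g.name
            for g in genes
            if any(r.start <= g.start and g.end <= r.end for r in regions)
        }
        assert got == expected


class TestDefineTrcSites:
    assembly = GenomeAssembly({"chr1": 5_000_000})

    def test_stated_geometry(self):
        gene = GenomeInterval("chr1", 2_050_000, 2_060_000, "+", "g")
        dripc = IntervalSet([GenomeInterval("chr1", 2_054_000, 2_056_000)])
        params = TRCParams()
        (site,) = define_trc_sites([SignedGene(gene, "+")], dripc, params, self.assembly)
        assert (site.window.start, site.window.end) == (2_045_000, 2_065_000)
        assert (site.control_up.start, site.control_up.end) == (1_045_000, 1_065_000)
        assert (site.control_down.start, site.control_down.end) == (3_045_000, 3_065_000)
        assert len(site.window) == 2 * params.flank
        assert len(site.control_up) == len(site.control_down) == params.control_length

    def test_no_dripc_overlap_no_site(self):
        gene = GenomeInterval("chr1", 2_050_000, 2_060_000, "+", "g")
        dripc = IntervalSet([GenomeInterval("chr1", 3_000_000, 3_001_000)])
        assert define_trc_sites([SignedGene(gene, "+")], dripc, TRCParams(), self.assembly) == []

    def test_out_of_bounds_controls_dropped(self):
        gene = GenomeInterval("chr1", 50_000, 60_000, "+", "g")  # control_up < 0
        dripc = IntervalSet([GenomeInterval("chr1", 54_000, 56_000)])
        assert define_trc_sites([SignedGene(gene, "+")], dripc, TRCParams(), self.assembly) == []

    def test_multi_peak_overlap_span(self):
        gene = GenomeInterval("chr1", 2_000_000, 2_100_000, "-", "g")
        dripc = IntervalSet(
            [
                GenomeInterval("chr1", 1_990_000, 2_010_000),  # clipped at gene start
                GenomeInterval("chr1", 2_080_000, 2_085_000),
            ]
        )
        (site,) = define_trc_sites([SignedGene(gene, "-")], dripc, TRCParams(), self.assembly)
        assert (site.overlap_span.start, site.overlap_span.end) == (2_000_000, 2_085_000)
        center = (2_000_000 + 2_085_000) // 2
        assert site.window.start == center - 10_000

    def test_geometry_oracle_random(self, rng):
        """30 random genes/peaks on a 5 Mb toy: independent recomputation."""
        genes, dripc, signed = [], [], []
        for i in range(30):
            # non-overlapping genes so each DRIPc peak hits exactly one gene
            s = 1_100_000 + 90_000 * i + int(rng.integers(0, 50_000))
            g = GenomeInterval("chr1", s, s + int(rng.integers(5000, 30_000)), "+", f"g{i}")
            signed.append(SignedGene(g, "+"))
            genes.append(g)
            if i % 2 == 0:
                ps = int(rng.integers(g.start, g.end - 500))
                dripc.append(GenomeInterval("chr1", ps, ps + 500))
        params = TRCParams()
        sites = define_trc_sites(signed, IntervalSet(dripc), params, self.assembly)
        by_gene = {s.gene_id: s for s in sites}
        for g, pk in zip(genes[::2], dripc):
            lo, hi = max(g.start, pk.start), min(g.end, pk.end)
            center = (lo + hi) // 2
            site = by_gene[g.name]
            assert site.window.start == center - params.flank
            assert site.control_down.end == center + params.control_distance + 10_000

    def test_frame_round_trip(self):
        gene = GenomeInterval("chr1", 2_050_000, 2_060_000, "+", "g")
        dripc = IntervalSet([GenomeInterval("chr1", 2_054_000, 2_056_000)])
        sites = define_trc_sites([SignedGene(gene, "+")], dripc, TRCParams(), self.assembly)
        assert frame_to_sites(sites_to_frame(sites)) == sites


class TestClassifyOrientation:
    @pytest.mark.parametrize(
        "gene_strand,sign,expected",
        [
            ("+", "+", "co_directional"),
            ("+", "-", "head_on"),
            ("-", "+", "head_on"),
            ("-", "-", "co_directional"),
        ],
    )
    def test_all_combinations(self, gene_strand, sign, expected):
        gene = GenomeInterval("chr1", 2_050_000, 2_060_000, gene_strand, "g")
        dripc = IntervalSet([GenomeInterval("chr1", 2_054_000, 2_056_000)])
        (site,) = define_trc_sites(
            [SignedGene(gene, sign)], dripc, TRCParams(),
            GenomeAssembly({"chr1": 5_000_000}),
        )
        assert classify_orientation(site) == expected
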