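"""Coordinate model, interval algebra and format round-trips."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trc_atlas.intervals import (
    BinnedTrack,
    CoordinateError,
    GenomeInterval,
    GenomeSequence,
    IntervalSet,
    ParseError,
    bin_counts,
    extract_sequence,
    merge_overlapping,
    read_bed,
    read_bedgraph,
    read_gtf_genes,
    reverse_complement,
    signed_tss_distance,
    tss_of_gene,
    write_bed,
    write_bedgraph,
    write_gtf_genes,
)

from conftest import make_intervals


class TestBedIO:
    def test_bed3_line(self, tmp_path, toy_assembly):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        iset = read_bed(p, toy_assembly)
        assert list(iset) == [GenomeInterval("chr1", 100, 200, ".")]

    def test_empty_file(self, tmp_path, toy_assembly):
        p = tmp_path / "a.bed"
        p.write_text("")
        assert len(read_bed(p, toy_assembly)) == 0

    def test_bed6_strand_preserved(self, tmp_path, toy_assembly):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\tpk1\t5\t-\n")
        iv = read_bed(p, toy_assembly)[0]
        assert (iv.strand, iv.name, iv.score) == ("-", "pk1", 5.0)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\nchr1\tnope\t300\n")
        with pytest.raises(ParseError, match=":2"):
            read_bed(p)

    def test_unknown_chrom_rejected(self, tmp_path, toy_assembly):
        p = tmp_path / "a.bed"
        p.write_text("chrX\t0\t10\n")
        with pytest.raises(CoordinateError):
            read_bed(p, toy_assembly)

    def test_round_trip(self, tmp_path, rng):
        ivs = [
            GenomeInterval("chr1", 5, 10, "+", "a", 1.5),
            GenomeInterval("chr1", 20, 30, "-", "b", 2.0),
            GenomeInterval("chr2", 0, 7, ".", None, None),
        ]
        p = tmp_path / "rt.bed"
        write_bed(IntervalSet(ivs), p)
        assert read_bed(p) == IntervalSet(ivs)


class TestGtfLite:
    def test_round_trip_and_coordinate_convention(self, tmp_path):
        genes = IntervalSet(
            [
                GenomeInterval("chr1", 100, 500, "+", "gA"),
                GenomeInterval("chr1", 1000, 1800, "-", "gB"),
            ]
        )
        p = tmp_path / "g.gtf"
        write_gtf_genes(genes, p)
        # 0-based half-open [100, 500) must appear as 1-based closed 101..500
        assert "\t101\t500\t" in p.read_text()
        assert read_gtf_genes(p) == genes

    def test_tss_anchor_convention(self):
        plus = GenomeInterval("chr1", 100, 500, "+", "g")
        minus = GenomeInterval("chr1", 100, 500, "-", "g")
        assert tss_of_gene(plus).start == 100
        assert tss_of_gene(minus).start == 499


class TestMerge:
    @pytest.mark.parametrize(
        "spans,gap,expected",
        [
            ([(0, 10), (5, 20)], 0, [(0, 20)]),
            ([(0, 10), (20, 30)], 0, [(0, 10), (20, 30)]),
            ([(0, 10), (12, 20)], 2, [(0, 20)]),
            ([(0, 10), (13, 20)], 2, [(0, 10), (13, 20)]),
        ],
    )
    def test_small_cases(self, spans, gap, expected):
        iset = IntervalSet(GenomeInterval("chr1", s, e) for s, e in spans)
        got = [(iv.start, iv.end) for iv in merge_overlapping(iset, gap)]
        assert got == expected

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            merge_overlapping(IntervalSet(), -1)

    def test_matches_occupancy_oracle(self, rng):
        """Union of 200 random intervals equals a per-bp boolean array union."""
        iset = make_intervals(rng, 200, max_pos=10_000)
        occupancy = np.zeros(10_000, dtype=bool)
        for iv in iset:
            occupancy[iv.start : iv.end] = True
        merged = merge_overlapping(iset, 0)
        got = np.zeros(10_000, dtype=bool)
        for iv in merged:
            assert not got[iv.start : iv.end].any()  # pairwise disjoint
            got[iv.start : iv.end] = True
        assert np.array_equal(got, occupancy)

    def test_idempotent(self, rng):
        iset = make_intervals(rng, 100)
        once = merge_overlapping(iset, 0)
        assert merge_overlapping(once, 0) == once


class TestSignedTssDistance:
    def test_strand_sign_convention(self):
        tss_plus = IntervalSet([GenomeInterval("chr1", 1000, 1001, "+")])
        tss_minus = IntervalSet([GenomeInterval("chr1", 1000, 1001, "-")])
        q = GenomeInterval("chr1", 450, 550)  # midpoint 500, 500 bp left
        assert signed_tss_distance(q, tss_plus)[1] == -500
        assert signed_tss_distance(q, tss_minus)[1] == +500

    def test_matches_all_pairs_oracle(self, rng):
        tss = IntervalSet(
            GenomeInterval("chr1", int(p), int(p) + 1, rng.choice(["+", "-"]))
            for p in rng.integers(0, 50_000, size=10)
        )
        for _ in range(50):
            s = int(rng.integers(0, 49_000))
            q = GenomeInterval("chr1", s, s + int(rng.integers(1, 1000)))
            _, dist = signed_tss_distance(q, tss)
            oracle = min(abs(q.midpoint - t.start) for t in tss)
            assert abs(dist) == oracle

    def test_empty_tss_set_errors(self):
        with pytest.raises(ValueError):
            signed_tss_distance(GenomeInterval("chr1", 0, 10), IntervalSet())


class TestExtractSequence:
    def test_forward_and_reverse(self):
        g = GenomeSequence.from_dict({"c": "AAACCC"})
        assert extract_sequence(g, GenomeInterval("c", 1, 5, "+")) == "AACC"
        assert extract_sequence(g, GenomeInterval("c", 1, 5, "-")) == "GGTT"

    def test_out_of_bounds_raises(self):
        g = GenomeSequence.from_dict({"c": "ACGT"})
        with pytest.raises(CoordinateError):
            extract_sequence(g, GenomeInterval("c", 2, 10))

    def test_fasta_reader_agrees_with_dict(self, tmp_path):
        from trc_atlas.intervals import write_fasta

        seqs = {"chr1": "ACGTACGTGGGCCCAT" * 10}
        p = tmp_path / "g.fa"
        write_fasta(seqs, p, width=7)
        fa = GenomeSequence.from_fasta(p)
        assert fa.fetch("chr1", 3, 140) == seqs["chr1"][3:140]
        assert fa.assembly.lengths == {"chr1": 160}

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=60))
    @settings(deadline=None, max_examples=60)
    def test_revcomp_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestBinCounts:
    def test_boundary_goes_to_right_bin(self, toy_assembly):
        track = bin_counts([("chr1", 100)], toy_assembly, 100)
        assert track.values["chr1"][1] == 1

    def test_matches_histogram_oracle(self, toy_assembly, rng):
        positions = [("chr1", int(p)) for p in rng.integers(0, 100_000, size=1000)]
        track = bin_counts(positions, toy_assembly, 1000)
        oracle, _ = np.histogram([p for _, p in positions], bins=100, range=(0, 100_000))
        assert np.array_equal(track.values["chr1"], oracle)
        assert track.values["chr1"].sum() == 1000  # count conservation


class TestBedgraph:
    def test_round_trip_with_missing(self, toy_assembly, rng):
        track = BinnedTrack.missing(toy_assembly, 1000)
        track.values["chr1"][:] = rng.integers(0, 5, size=100).astype(float)
        track.values["chr1"][[3, 40, 41]] = np.nan
        track.values["chr2"][10:20] = 2.5
        return_path = "rt.bedgraph"
        import tempfile, os

        with tempfile.TemporaryDirectory() as d:
            p = os.path.join(d, return_path)
            write_bedgraph(track, p)
            back = read_bedgraph(p, toy_assembly, 1000)
        for chrom in track.values:
            np.testing.assert_array_equal(back.values[chrom], track.values[chrom])

    def test_window_mean_weights_partial_bins(self, toy_assembly):
        track = BinnedTrack.zeros(toy_assembly, 100)
        track.values["chr1"][0] = 10.0
        track.values["chr1"][1] = 20.0
        # [50, 150): 50 bp of value 10 and 50 bp of value 20
        assert track.window_mean("chr1", 50, 150) == pytest.approx(15.0)

    def test_window_mean_ignores_missing(self, toy_assembly):
        track = BinnedTrack.missing(toy_assembly, 100)
        track.values["chr1"][0] = 8.0
        assert track.window_mean("chr1", 0, 300) == pytest.approx(8.0)
        assert np.isnan(track.window_mean("chr1", 500, 900))
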