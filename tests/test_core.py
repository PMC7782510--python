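"""Interval algebra, sequence/track I/O, coverage and aggregation."""

import numpy as np
import pytest

from loopgrammar.core import (
    AggregateMatrix,
    FormatError,
    GenomeSequence,
    Interval,
    SignalTrack,
    _NearestIndex,
    aggregate_signal_matrix,
    binned_track_correlation,
    coverage_track,
    extend_reads,
    nearest_feature,
    read_bedgraph,
    read_genome,
    read_intervals,
    signed_gap,
    write_bedgraph,
    write_genome,
    write_intervals,
)


class TestInterval:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="c1", start=5, end=5),
            dict(chrom="c1", start=7, end=3),
            dict(chrom="c1", start=-1, end=3),
            dict(chrom="", start=0, end=3),
            dict(chrom="c1", start=0, end=3, strand="x"),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Interval(**kwargs)

    def test_len_and_midpoint(self):
        iv = Interval("c1", 10, 20)
        assert len(iv) == 10 and iv.midpoint == 15


class TestFastaIO:
    def test_case_folding(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1\nacgt\n")
        g = read_genome(p)
        assert g["c1"] == "ACGT" and g.lengths == {"c1": 4}

    def test_round_trip(self, tmp_path, random_genome_10kb):
        p = tmp_path / "g.fa"
        write_genome(random_genome_10kb, p)
        assert read_genome(p) == random_genome_10kb

    def test_duplicate_chrom_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1\nACGT\n>c1\nTTTT\n")
        with pytest.raises(FormatError):
            read_genome(p)

    def test_bad_alphabet_rejected(self):
        with pytest.raises(FormatError):
            GenomeSequence({"c1": "ACGU"})


class TestBedIO:
    def test_bed6_parse(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("c1\t10\t20\t.\t0\t+\n")
        (iv,) = read_intervals(p)
        assert iv == Interval("c1", 10, 20, strand="+", name=".", score=0.0)

    def test_round_trip(self, tmp_path):
        ivs = [
            Interval("c1", 0, 5, strand="+", name="a", score=1.5),
            Interval("c2", 10, 400, strand="-", name="b", score=0.0),
        ]
        p = tmp_path / "a.bed"
        write_intervals(ivs, p)
        assert read_intervals(p) == ivs

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("")
        assert read_intervals(p) == []

    def test_start_ge_end_reports_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("c1\t5\t10\nc1\t30\t20\n")
        with pytest.raises(FormatError, match="line 2"):
            read_intervals(p)


class TestExtendReads:
    def test_plus_strand_anchors_start(self, tiny_genome):
        (r,) = extend_reads([Interval("c1", 100, 136, strand="+")], tiny_genome)
        assert (r.start, r.end) == (100, 250)

    def test_minus_strand_clamped_left(self):
        g = GenomeSequence({"c1": "A" * 1000})
        (r,) = extend_reads([Interval("c1", 100, 136, strand="-")], g)
        assert (r.start, r.end) == (0, 136)

    def test_plus_strand_clamped_right(self):
        g = GenomeSequence({"c1": "A" * 1000})
        (r,) = extend_reads([Interval("c1", 900, 936, strand="+")], g)
        assert (r.start, r.end) == (900, 1000)

    def test_long_read_truncated(self, tiny_genome):
        (r,) = extend_reads([Interval("c1", 100, 400, strand="+")], tiny_genome)
        assert len(r) == 150

    def test_unknown_chromosome(self, tiny_genome):
        with pytest.raises(ValueError, match="unknown"):
            extend_reads([Interval("cX", 0, 36)], tiny_genome)


class TestCoverage:
    def test_normalized_single_read(self, tiny_genome):
        # one 150-bp read on a 1500-bp genome: raw mean 0.1 -> factor 10
        track = coverage_track(
            [Interval("c1", 200, 350)], tiny_genome, normalize=True
        )
        v = track.values["c1"]
        assert np.allclose(v[200:350], 10.0) and v[0] == 0
        assert abs(track.genome_mean - 1.0) < 1e-9

    def test_depth_accumulates(self, tiny_genome):
        track = coverage_track(
            [Interval("c1", 10, 60)] * 2, tiny_genome, normalize=False
        )
        assert np.allclose(track.values["c1"][10:60], 2.0)

    def test_total_equals_read_length_sum(self, tiny_genome):
        rng = np.random.default_rng(0)
        reads = [
            Interval("c1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 1400, 50), rng.integers(1, 100, 50))
        ]
        clamped_total = sum(min(r.end, 1500) - r.start for r in reads)
        track = coverage_track(reads, tiny_genome)
        assert track.total == clamped_total

    def test_zero_reads_normalize_error(self, tiny_genome):
        with pytest.raises(ValueError):
            coverage_track([], tiny_genome, normalize=True)


class TestGapProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    intervals = st.tuples(
        st.integers(min_value=0, max_value=10_000),
        st.integers(min_value=1, max_value=500),
    ).map(lambda t: Interval("c1", t[0], t[0] + t[1]))

    @given(a=intervals, b=intervals)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_signed_gap_antisymmetric(self, a, b):
        assert signed_gap(a, b) == -signed_gap(b, a)

    @given(a=intervals, b=intervals)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_gap_zero_iff_touching(self, a, b):
        # zero gap means overlap or direct adjacency (closest edges meet)
        touching = a.overlaps(b) or a.end == b.start or b.end == a.start
        assert (signed_gap(a, b) == 0) == touching


class TestNearestFeature:
    def test_gap_sign_convention(self):
        q = Interval("c1", 1000, 1015)
        s = Interval("c1", 1052, 1071)
        assert signed_gap(q, s) == 37
        assert nearest_feature(q, [s]) == (s, 37)

    def test_overlap_gap_zero(self):
        q = Interval("c1", 100, 200)
        s = Interval("c1", 150, 300)
        assert signed_gap(q, s) == 0

    def test_tie_broken_to_lower_start(self):
        q = Interval("c1", 100, 110)
        left = Interval("c1", 70, 80)  # gap -20
        right = Interval("c1", 130, 140)  # gap +20
        best, gap = nearest_feature(q, [right, left])
        assert best is left and gap == -20

    def test_empty_sentinel(self):
        assert nearest_feature(Interval("c1", 0, 5), []) == (None, None)

    def test_index_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        subjects = [
            Interval("c1", int(s), int(s) + int(l), name=f"s{k}")
            for k, (s, l) in enumerate(
                zip(rng.integers(0, 100_000, 400), rng.integers(1, 500, 400))
            )
        ]
        queries = [
            Interval("c1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 100_000, 300), rng.integers(1, 300, 300))
        ]
        index = _NearestIndex(subjects)
        for q in queries:
            assert index.nearest(q) == nearest_feature(q, subjects)


class TestAggregateMatrix:
    def test_constant_track(self, tiny_genome):
        track = SignalTrack({"c1": np.ones(1500)})
        agg = aggregate_signal_matrix(
            track, [Interval("c1", 700, 701)], flank=200, binsize=50
        )
        assert agg.matrix.shape == (1, 8) and np.allclose(agg.matrix, 1.0)

    def test_step_signal_bins(self):
        vals = np.zeros(1000)
        vals[500:] = 2.0  # step at the refpoint midpoint
        track = SignalTrack({"c1": vals})
        agg = aggregate_signal_matrix(
            track, [Interval("c1", 500, 501)], flank=100, binsize=50
        )
        assert np.allclose(agg.matrix[0], [0, 0, 2, 2])

    def test_minus_strand_flips(self):
        vals = np.arange(1000, dtype=float)
        track = SignalTrack({"c1": vals})
        plus = aggregate_signal_matrix(
            track, [Interval("c1", 500, 501, strand="+")], flank=100, binsize=10
        )
        minus = aggregate_signal_matrix(
            track, [Interval("c1", 500, 501, strand="-")], flank=100, binsize=10
        )
        assert np.allclose(minus.matrix[0], plus.matrix[0][::-1])

    def test_out_of_range_dropped(self, tiny_genome):
        track = SignalTrack({"c1": np.ones(1500)})
        agg = aggregate_signal_matrix(
            track,
            [Interval("c1", 10, 11), Interval("c1", 700, 701)],
            flank=200,
            binsize=50,
        )
        assert agg.matrix.shape[0] == 1 and agg.n_dropped == 1

    def test_column_means_invariant_under_ordering(self):
        rng = np.random.default_rng(3)
        track = SignalTrack({"c1": rng.random(10_000)})
        refs = [Interval("c1", int(p), int(p) + 1) for p in rng.integers(500, 9500, 20)]
        keys = list(rng.random(20))
        a = aggregate_signal_matrix(track, refs, 400, 100)
        b = aggregate_signal_matrix(track, refs, 400, 100, order_key=keys)
        assert np.allclose(a.mean_profile, b.mean_profile)


class TestTrackCorrelation:
    def test_self_and_negation(self):
        rng = np.random.default_rng(1)
        v = rng.random(100_000)
        t1 = SignalTrack({"c1": v})
        t2 = SignalTrack({"c1": (2 * v.mean() - v)})  # negation about the mean
        r = binned_track_correlation([t1, t1, t2], binsize=5000)
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(5)
        t1 = SignalTrack({"c1": rng.random(10_000_000)})
        t2 = SignalTrack({"c1": rng.random(10_000_000)})
        r = binned_track_correlation([t1, t2], binsize=5000)
        assert abs(r[0, 1]) < 0.05

    def test_constant_track_gives_nan(self):
        t1 = SignalTrack({"c1": np.ones(100_000)})
        t2 = SignalTrack({"c1": np.arange(100_000, dtype=float)})
        r = binned_track_correlation([t1, t2], binsize=5000)
        assert np.isnan(r[0, 1])


class TestBedGraph:
    def test_round_trip(self, tmp_path):
        vals = np.zeros(2000)
        vals[100:250] = 1.5
        vals[300:305] = 3.0
        track = SignalTrack({"c1": vals})
        p = tmp_path / "t.bedgraph"
        write_bedgraph(track, p)
        back = read_bedgraph(p, {"c1": 2000})
        assert np.allclose(back.values["c1"], vals)
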