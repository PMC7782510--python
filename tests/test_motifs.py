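"""PWM scoring/scanning, permutation nulls, spacing and orientation."""

import numpy as np
import pytest

from loopgrammar.core import GenomeSequence, Interval
from loopgrammar.motifs import (
    CONVERGENT,
    DIVERGENT,
    FORWARD_FORWARD,
    REVERSE_REVERSE,
    FormatError,
    MotifMatch,
    OrientationCounts,
    PositionWeightMatrix,
    SpacingHistogram,
    classify_orientation,
    load_pwm,
    log_odds_score,
    orientation_table,
    pair_spacing,
    permute_pwm,
    reverse_complement,
    scan_genome,
    spacing_summary,
)
from loopgrammar.motifs import SpacingPair


def match(start, end, strand, name="m", score=1.0, chrom="c1"):
    return MotifMatch(Interval(chrom, start, end, strand=strand, name=name), score, name)


class TestLoadPwm:
    def test_counts_to_probs_no_pseudocount(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">m\nA [7 7]\nC [1 1]\nG [1 1]\nT [1 1]\n")
        pwm = load_pwm(p, pseudocount=0.0)
        assert np.allclose(pwm.probs[:, 0], [0.7, 0.1, 0.1, 0.1])

    def test_probability_matrix_kept(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">m\nA [0.7]\nC [0.1]\nG [0.1]\nT [0.1]\n")
        pwm = load_pwm(p)
        assert np.allclose(pwm.probs[:, 0], [0.7, 0.1, 0.1, 0.1], atol=1e-3)

    def test_missing_row_rejected(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">m\nA [1]\nC [1]\nG [1]\n")
        with pytest.raises(FormatError):
            load_pwm(p)

    def test_zero_column_rejected(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">m\nA [1 0]\nC [1 0]\nG [1 0]\nT [1 0]\n")
        with pytest.raises(FormatError):
            load_pwm(p)


class TestLogOdds:
    def test_uniform_pwm_scores_zero(self):
        pwm = PositionWeightMatrix("u", np.full((4, 3), 0.25))
        assert log_odds_score(pwm, "ACG") == pytest.approx(0.0)

    def test_hand_computed_scores(self, two_col_pwm):
        # log2(0.7/0.25) + log2(0.85/0.25) and log2(0.4) + log2(0.2)
        assert log_odds_score(two_col_pwm, "AG") == pytest.approx(3.2509, abs=1e-4)
        assert log_odds_score(two_col_pwm, "TT") == pytest.approx(-3.6439, abs=1e-4)

    def test_n_gives_neg_inf(self, two_col_pwm):
        assert log_odds_score(two_col_pwm, "AN") == float("-inf")

    def test_length_mismatch(self, two_col_pwm):
        with pytest.raises(ValueError):
            log_odds_score(two_col_pwm, "AAG")


def brute_force_scan(pwm, genome, threshold_frac):
    """Independent oracle: score every window on both strands."""
    out = []
    thr = threshold_frac * pwm.max_score
    for chrom in genome.chroms:
        seq = genome[chrom]
        for i in range(len(seq) - pwm.width + 1):
            window = seq[i : i + pwm.width]
            for strand, s in (("+", window), ("-", reverse_complement(window))):
                score = log_odds_score(pwm, s)
                if score >= thr - 1e-12:
                    out.append((chrom, i, strand, round(score, 9)))
    return sorted(out)


class TestScanGenome:
    def test_matches_bruteforce_on_random_sequence(self, random_genome_10kb, znf_pwm):
        got = sorted(
            (m.interval.chrom, m.interval.start, m.strand, round(m.score, 9))
            for m in scan_genome(znf_pwm, random_genome_10kb, 0.35)
        )
        assert got == brute_force_scan(znf_pwm, random_genome_10kb, 0.35)
        assert len(got) > 0  # threshold low enough to exercise both strands

    def test_planted_consensus_found_once(self, znf_pwm):
        seq = list("A" * 10_000)
        seq[4000 : 4000 + znf_pwm.width] = znf_pwm.consensus
        g = GenomeSequence({"c1": "".join(seq)})
        hits = scan_genome(znf_pwm, g, 0.8)
        assert [(m.interval.start, m.strand) for m in hits] == [(4000, "+")]

    def test_palindromic_consensus_on_both_strands(self):
        probs = np.full((4, 4), 0.04)
        for j, b in enumerate("ACGT"):
            probs["ACGT".index(b), j] = 0.88
        pwm = PositionWeightMatrix("pal", probs)  # consensus ACGT, its own RC
        g = GenomeSequence({"c1": "TTTTTACGTTTTTT"})
        hits = scan_genome(pwm, g, 0.9)
        assert [(m.interval.start, m.strand) for m in hits] == [(5, "+"), (5, "-")]

    def test_threshold_validation(self, znf_pwm, random_genome_10kb):
        with pytest.raises(ValueError):
            scan_genome(znf_pwm, random_genome_10kb, 0.0)


class TestPermutePwm:
    def test_width_one_identity(self):
        pwm = PositionWeightMatrix("w1", np.array([[0.7, 0.1, 0.1, 0.1]]).T)
        assert np.array_equal(permute_pwm(pwm, 3).probs, pwm.probs)

    def test_information_content_preserved(self, ctcf_pwm):
        perm = permute_pwm(ctcf_pwm, 11)
        assert perm.information_content == pytest.approx(
            ctcf_pwm.information_content
        )
        # column multiset identical
        orig = sorted(map(tuple, ctcf_pwm.probs.T.round(9)))
        got = sorted(map(tuple, perm.probs.T.round(9)))
        assert got == orig

    def test_seed_determinism(self, ctcf_pwm):
        assert np.array_equal(
            permute_pwm(ctcf_pwm, 5).probs, permute_pwm(ctcf_pwm, 5).probs
        )
        assert permute_pwm(ctcf_pwm, 5).name.endswith("_perm5")


class TestPairSpacing:
    def test_empty_subjects(self):
        hist, pairs = pair_spacing([match(0, 5, "+")], [])
        assert hist.total == 0 and pairs == []

    def test_self_pairing_excluded_by_triple_rule(self):
        # same interval, opposite strands: a legitimate gap-0 pair
        a = match(100, 110, "+", name="m")
        b = match(100, 110, "-", name="m")
        hist, pairs = pair_spacing([a, b], [a, b])
        assert hist.modal_abs_distance == 0 and hist.total == 2

    def test_signed_bins(self):
        q = match(1000, 1015, "+")
        s_right = match(1052, 1071, "-", name="s")
        hist, pairs = pair_spacing([q], [s_right])
        assert hist.counts[hist.window + 37] == 1
        assert pairs[0].gap == 37


class TestOrientation:
    # the full 8-case rule table: 2 argument orders x 4 positional strand
    # combos; strands are those of the (lower, upper) genomic positions,
    # so the class is invariant to which match is passed first
    CASES = [
        (("+", "-"), CONVERGENT),
        (("-", "+"), DIVERGENT),
        (("+", "+"), FORWARD_FORWARD),
        (("-", "-"), REVERSE_REVERSE),
    ]

    @pytest.mark.parametrize("strands,expected", CASES)
    @pytest.mark.parametrize("swap", [False, True])
    def test_rule_table(self, strands, swap, expected):
        lower = match(1000, 1015, strands[0])
        upper = match(1052, 1071, strands[1])
        a, b = (upper, lower) if swap else (lower, upper)
        assert classify_orientation(a, b) == expected

    def test_strand_flip_maps_convergent_divergent(self):
        a, b = match(1000, 1015, "+"), match(1052, 1071, "-")
        flipped = (match(1000, 1015, "-"), match(1052, 1071, "+"))
        assert classify_orientation(a, b) == CONVERGENT
        assert classify_orientation(*flipped) == DIVERGENT

    def test_unstranded_rejected(self):
        with pytest.raises(ValueError):
            classify_orientation(match(0, 5, "."), match(10, 15, "+"))

    def test_table_counts_and_conservation(self):
        pairs = [
            SpacingPair(match(0, 5, "+"), match(10, 15, "-"), 5),  # convergent
            SpacingPair(match(0, 5, "+"), match(10, 15, "+"), 5),  # F-F
            SpacingPair(match(0, 5, "+"), match(10, 15, "+"), 5),  # F-F
            SpacingPair(match(0, 5, "-"), match(10, 15, "-"), 5),  # R-R
        ]
        t = orientation_table(pairs)
        assert (t.convergent, t.forward_forward, t.reverse_reverse) == (1, 2, 1)
        assert t.total == len(pairs)

    def test_percentages_one_decimal(self):
        t = OrientationCounts(convergent=10529, divergent=6, forward_forward=5, reverse_reverse=4)
        assert t.percentages()[CONVERGENT] == 99.9


class TestSpacingSummary:
    def test_reported_mode_share(self):
        # 10,544 pairs at the 37-bp mode among 17,319 within 100 bp
        counts = np.zeros(4001, dtype=int)
        counts[2000 + 37] = 10_544
        rest = 17_319 - 10_544
        counts[2000 + 60] = rest // 2
        counts[2000 - 60] = rest - rest // 2
        hist = SpacingHistogram(counts, window=2000)
        s = spacing_summary(hist)
        assert s["modal_distance"] == 37
        assert s["pct_at_mode_of_within100"] == 60.88

    def test_single_pair_is_100(self):
        counts = np.zeros(4001, dtype=int)
        counts[2000 + 12] = 1
        assert spacing_summary(SpacingHistogram(counts, 2000))["pct_at_mode_of_within100"] == 100.0

    def test_uniform_ties_break_to_smallest_distance(self):
        counts = np.ones(4001, dtype=int)
        hist = SpacingHistogram(counts, 2000)
        assert hist.modal_abs_distance == 1  # folded: |d|>0 bins have count 2, d=0 has 1

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            spacing_summary(SpacingHistogram(np.zeros(4001, dtype=int), 2000))
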