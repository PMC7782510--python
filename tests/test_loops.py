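"""Loop intensities, differential classes, anchor annotation, APA."""

import numpy as np
import pytest

from loopgrammar.annotate import PeakSet, RegulatoryAnnotation, call_promoters_enhancers
from loopgrammar.contacts import ContactMatrix, balance_matrix
from loopgrammar.core import Interval
from loopgrammar.loops import (
    DECREASED,
    INCREASED,
    UNCHANGED,
    Loop,
    aggregate_peak_analysis,
    annotate_loops,
    classify_differential,
    find_anchor_motifs,
    loop_intensity,
    quantify_loops,
)
from loopgrammar.motifs import MotifMatch


def make_loop(i, j, binsize=1000, chrom="c1", **kw):
    return Loop(
        Interval(chrom, i * binsize, (i + 1) * binsize),
        Interval(chrom, j * binsize, (j + 1) * binsize),
        **kw,
    )


def mmatch(start, end, strand, score=1.0, chrom="c1"):
    return MotifMatch(Interval(chrom, start, end, strand=strand, name="m"), score, "m")


class TestLoopGeometry:
    def test_anchor_order_enforced(self):
        with pytest.raises(ValueError):
            Loop(Interval("c1", 5000, 6000), Interval("c1", 1000, 2000))

    def test_cross_chromosome_rejected(self):
        with pytest.raises(ValueError):
            Loop(Interval("c1", 0, 1000), Interval("c2", 5000, 6000))


class TestLoopIntensity:
    def test_pad_zero_is_pixel_value(self):
        dense = np.ones((40, 40))
        dense[5, 20] = dense[20, 5] = 9.0
        m = ContactMatrix.from_dense("c1", 1000, dense)
        balance_matrix(m)
        lp = make_loop(5, 20)
        v_pad0 = loop_intensity(m, lp, pad_bins=0)
        d = m.dense(balanced=True)
        assert v_pad0 == pytest.approx(d[5, 20])

    def test_pad_on_constant_matrix_unchanged(self):
        m = ContactMatrix.from_dense("c1", 1000, np.full((40, 40), 3.0))
        balance_matrix(m)
        lp = make_loop(10, 25)
        assert loop_intensity(m, lp, pad_bins=1) == pytest.approx(
            loop_intensity(m, lp, pad_bins=0)
        )

    def test_anchor_outside_matrix_rejected(self):
        m = ContactMatrix.from_dense("c1", 1000, np.ones((10, 10)))
        balance_matrix(m)
        with pytest.raises(ValueError):
            loop_intensity(m, make_loop(2, 50))

    def test_misaligned_anchor_rejected(self):
        m = ContactMatrix.from_dense("c1", 1000, np.ones((10, 10)))
        balance_matrix(m)
        lp = Loop(Interval("c1", 1500, 2500), Interval("c1", 7000, 8000))
        with pytest.raises(ValueError):
            loop_intensity(m, lp)


class TestDifferentialClasses:
    def test_worked_decrease_example(self):
        lp = make_loop(1, 10, intensity1=10.0, intensity2=4.0)
        classify_differential([lp], pseudocount=1.0)
        assert lp.klass == DECREASED
        assert lp.log2fc == pytest.approx(np.log2(5 / 11))

    def test_equal_intensities_unchanged(self):
        lp = make_loop(1, 10, intensity1=7.0, intensity2=7.0)
        classify_differential([lp], pseudocount=1.0)
        assert lp.klass == UNCHANGED

    def test_double_zero_unchanged_via_pseudocount(self):
        lp = make_loop(1, 10, intensity1=0.0, intensity2=0.0)
        classify_differential([lp], pseudocount=1.0)
        assert lp.klass == UNCHANGED and lp.log2fc == 0.0

    def test_condition_swap_maps_classes(self):
        loops = [
            make_loop(1, 10, intensity1=10.0, intensity2=2.0),
            make_loop(2, 12, intensity1=2.0, intensity2=10.0),
            make_loop(3, 14, intensity1=5.0, intensity2=5.0),
        ]
        classify_differential(loops, pseudocount=0.5)
        fwd = [lp.klass for lp in loops]
        for lp in loops:
            lp.intensity1, lp.intensity2 = lp.intensity2, lp.intensity1
        classify_differential(loops, pseudocount=0.5)
        swap = {INCREASED: DECREASED, DECREASED: INCREASED, UNCHANGED: UNCHANGED}
        assert [lp.klass for lp in loops] == [swap[k] for k in fwd]

    def test_classes_partition(self):
        rng = np.random.default_rng(0)
        loops = [
            make_loop(k, k + 10, intensity1=float(a), intensity2=float(b))
            for k, (a, b) in enumerate(zip(rng.random(50) * 10, rng.random(50) * 10))
        ]
        counts = classify_differential(loops)
        assert sum(counts.values()) == 50
        assert all(lp.klass in counts for lp in loops)

    def test_negative_intensity_rejected(self):
        lp = make_loop(1, 10, intensity1=-1.0, intensity2=2.0)
        with pytest.raises(ValueError):
            classify_differential([lp])


class TestAnnotateLoops:
    def make_annotation(self):
        k27 = PeakSet(
            [
                Interval("c1", 900, 1600),    # promoter (TSS at 1000)
                Interval("c1", 10200, 10800),  # enhancer
                Interval("c1", 20100, 20900),  # enhancer
            ]
        )
        tss = [Interval("c1", 1000, 1001, strand="+", name="g1")]
        return call_promoters_enhancers(k27, tss)

    def test_pe_pp_ee_other(self):
        ann = self.make_annotation()
        pe = make_loop(1, 10)     # promoter anchor + enhancer anchor
        ee = make_loop(10, 20)    # enhancer + enhancer
        other = make_loop(30, 40)  # bare anchors
        fractions = annotate_loops([pe, ee, other], ann)
        assert pe.category == "P-E" and ee.category == "E-E" and other.category == "other"
        assert fractions["P-E"] == pytest.approx(1 / 3)
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_slack_extends_anchor(self):
        ann = self.make_annotation()
        lp = make_loop(3, 10)  # anchor1 [3000,4000) is 1400 bp from the promoter peak
        annotate_loops([lp], ann, slack_bp=0)
        assert lp.category == "other"
        annotate_loops([lp], ann, slack_bp=1500)
        assert lp.category == "P-E"


class TestAnchorMotifs:
    def test_convergent_flag(self):
        lp = make_loop(1, 10)
        find_anchor_motifs([lp], [mmatch(1200, 1215, "+"), mmatch(10300, 10315, "-")])
        assert lp.convergent is True

    def test_wrong_arrangement_not_convergent(self):
        lp = make_loop(1, 10)
        find_anchor_motifs([lp], [mmatch(1200, 1215, "-"), mmatch(10300, 10315, "+")])
        assert lp.convergent is False

    def test_best_score_wins(self):
        lp = make_loop(1, 10)
        weak = mmatch(1100, 1115, "+", score=5.0)
        strong = mmatch(1400, 1415, "-", score=9.0)
        find_anchor_motifs([lp], [weak, strong, mmatch(10300, 10315, "-")])
        assert lp.motif1 is strong

    def test_anchor_without_match_flagged(self):
        lp = make_loop(1, 10)
        find_anchor_motifs([lp], [mmatch(1200, 1215, "+")])
        assert lp.motif2 is None and lp.convergent is False


class TestAPA:
    def test_constructed_score_five(self):
        n = 60
        m = ContactMatrix.from_dense("c1", 1000, np.ones((n, n)))
        balance_matrix(m)
        oe = np.ones((n, n))
        oe[15, 45] = 5.0
        res = aggregate_peak_analysis(m, [make_loop(15, 45)], flank_bins=10, oe=oe)
        assert res.score == pytest.approx(5.0)
        assert res.n_aggregated == 1

    def test_close_or_edge_loops_skipped(self):
        n = 60
        m = ContactMatrix.from_dense("c1", 1000, np.ones((n, n)))
        balance_matrix(m)
        oe = np.ones((n, n))
        loops = [make_loop(20, 30), make_loop(2, 40), make_loop(15, 45)]
        res = aggregate_peak_analysis(m, loops, flank_bins=10, oe=oe)
        assert res.n_aggregated == 1 and res.n_skipped == 2

    def test_no_loops_rejected(self):
        n = 30
        m = ContactMatrix.from_dense("c1", 1000, np.ones((n, n)))
        balance_matrix(m)
        with pytest.raises(ValueError):
            aggregate_peak_analysis(m, [make_loop(5, 10)], flank_bins=10)

    def test_score_invariant_to_matrix_scaling(self):
        from loopgrammar.simulate import make_contact_map

        pix = [(50, 120), (200, 290), (400, 470)]
        m, _ = make_contact_map(
            3_000_000, 5000, loop_pixels=pix, bias_sd=0.0, depth=1e7, seed=3
        )
        balance_matrix(m)
        loops = [make_loop(i, j, binsize=5000, chrom="chrS") for i, j in pix]
        s1 = aggregate_peak_analysis(m, loops).score
        m2 = m.scaled(11.0)
        balance_matrix(m2)
        s2 = aggregate_peak_analysis(m2, loops).score
        assert s1 == pytest.approx(s2, rel=1e-6)


class TestQuantify:
    def test_cpm_normalization_cancels_depth(self):
        dense = np.ones((50, 50))
        dense[10, 30] = dense[30, 10] = 5.0
        m1 = ContactMatrix.from_dense("c1", 1000, dense)
        m2 = ContactMatrix.from_dense("c1", 1000, dense * 4)  # deeper, same shape
        balance_matrix(m1)
        balance_matrix(m2)
        lp = make_loop(10, 30)
        quantify_loops(m1, m2, [lp])
        assert lp.intensity1 == pytest.approx(lp.intensity2, rel=1e-6)
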