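"""Loop intensity, differential classes, anchor annotation, APA.

Loops are bin-aligned anchor pairs (anchor1 upstream). Intensities are
mean balanced counts at (or around) the loop pixel, depth-normalized to
contacts-per-million before two-condition comparison; the differential
rule is a plain fold-change threshold (1.5x up / down). Anchors are
annotated against active promoters/enhancers to name P-E, P-P and E-E
loops, and against genome-wide motif matches to flag the convergent
CTCF-orientation signature. Aggregate peak analysis (APA) averages O/E
submatrices around loop pixels; its score compares the center pixel to
a corner block far from the loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Interval
from .annotate import RegulatoryAnnotation, _overlap_index, overlaps_feature
from .contacts import ContactMatrix, observed_over_expected
from .motifs import MotifMatch

INCREASED = "increased"
DECREASED = "decreased"
UNCHANGED = "unchanged"
LOOP_CATEGORIES = ("P-E", "P-P", "E-E", "other")

__all__ = [
    "Loop",
    "APAResult",
    "loop_intensity",
    "depth_normalize",
    "classify_differential",
    "annotate_loops",
    "find_anchor_motifs",
    "aggregate_peak_analysis",
]


@dataclass
class Loop:
    """A chromatin loop: two bin-aligned anchors on one chromosome."""

    anchor1: Interval
    anchor2: Interval
    intensity1: float | None = None
    intensity2: float | None = None
    log2fc: float | None = None
    klass: str | None = None
    category: str | None = None  # P-E / P-P / E-E / other
    motif1: MotifMatch | None = None
    motif2: MotifMatch | None = None
    convergent: bool | None = None

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("loop anchors must share a chromosome")
        if self.anchor1.start >= self.anchor2.start:
            raise ValueError("anchor1 must be upstream of anchor2")


@dataclass
class APAResult:
    matrix: np.ndarray  # (2k+1, 2k+1) mean O/E
    score: float
    n_aggregated: int
    n_skipped: int


def _anchor_bin(anchor: Interval, m: ContactMatrix) -> int:
    if anchor.start % m.binsize:
        raise ValueError(
            f"anchor start {anchor.start} not aligned to bin size {m.binsize}"
        )
    b = anchor.start // m.binsize
    if not (0 <= b < m.n_bins):
        raise ValueError(f"anchor bin {b} outside matrix (n={m.n_bins})")
    return b


def loop_intensity(m: ContactMatrix, loop: Loop, pad_bins: int = 0) -> float:
    """Mean balanced count over the (2 pad + 1)^2 block at the loop pixel."""
    dense = m.dense(balanced=True)
    i = _anchor_bin(loop.anchor1, m)
    j = _anchor_bin(loop.anchor2, m)
    p = pad_bins
    lo1, hi1 = max(0, i - p), min(m.n_bins, i + p + 1)
    lo2, hi2 = max(0, j - p), min(m.n_bins, j + p + 1)
    block = dense[lo1:hi1, lo2:hi2]
    return float(np.nanmean(block))


def depth_normalize(intensity: float, m: ContactMatrix) -> float:
    """Scale a balanced intensity to contacts-per-million total contacts."""
    return intensity * 1e6 / m.total


def quantify_loops(
    m1: ContactMatrix, m2: ContactMatrix, loops: list[Loop], pad_bins: int = 0
) -> None:
    """Fill per-condition CPM intensities of each loop in place."""
    d1 = m1.dense(balanced=True)
    d2 = m2.dense(balanced=True)
    s1, s2 = 1e6 / m1.total, 1e6 / m2.total
    p = pad_bins
    for lp in loops:
        i, j = _anchor_bin(lp.anchor1, m1), _anchor_bin(lp.anchor2, m1)
        b1 = d1[max(0, i - p) : i + p + 1, max(0, j - p) : j + p + 1]
        b2 = d2[max(0, i - p) : i + p + 1, max(0, j - p) : j + p + 1]
        lp.intensity1 = float(np.nanmean(b1)) * s1
        lp.intensity2 = float(np.nanmean(b2)) * s2


def classify_differential(
    loops: list[Loop],
    fc_threshold: float = 1.5,
    pseudocount: float | None = None,
) -> dict[str, int]:
    """Three-way fold-change classes on depth-normalized loop intensities.

    FC = (I2 + eps) / (I1 + eps); increased iff FC >= threshold,
    decreased iff FC <= 1/threshold. The pseudocount defaults to one
    tenth of the median nonzero intensity across both conditions: it
    damps division blow-ups at empty pixels while staying far below any
    measured loop's intensity, so well-measured fold changes stay
    essentially unbiased.
    """
    vals = np.array(
        [v for lp in loops for v in (lp.intensity1, lp.intensity2) if v is not None]
    )
    if np.any(vals < 0):
        raise ValueError("negative loop intensity")
    if pseudocount is None:
        nz = vals[vals > 0]
        pseudocount = float(np.median(nz)) / 10.0 if nz.size else 1.0
    counts = {INCREASED: 0, DECREASED: 0, UNCHANGED: 0}
    for lp in loops:
        fc = (lp.intensity2 + pseudocount) / (lp.intensity1 + pseudocount)
        lp.log2fc = float(np.log2(fc))
        if fc >= fc_threshold:
            lp.klass = INCREASED
        elif fc <= 1.0 / fc_threshold:
            lp.klass = DECREASED
        else:
            lp.klass = UNCHANGED
        counts[lp.klass] += 1
    return counts


def annotate_loops(
    loops: list[Loop], annotation: RegulatoryAnnotation, slack_bp: int = 0
) -> dict[str, float]:
    """Label each loop P-E / P-P / E-E / other from its anchor overlaps.

    An anchor (extended by ``slack_bp`` each side) is a promoter anchor if
    it overlaps any active promoter peak, else an enhancer anchor if it
    overlaps any active enhancer, else bare; a loop with a bare anchor is
    "other". Returns category fractions (summing to 1 over the loops).
    """
    pidx = _overlap_index(annotation.promoters)
    eidx = _overlap_index(annotation.enhancers)

    def label(anchor: Interval) -> str:
        a = Interval(
            anchor.chrom, max(0, anchor.start - slack_bp), anchor.end + slack_bp
        )
        if overlaps_feature(a, pidx):
            return "P"
        if overlaps_feature(a, eidx):
            return "E"
        return "none"

    counts = {c: 0 for c in LOOP_CATEGORIES}
    for lp in loops:
        l1, l2 = label(lp.anchor1), label(lp.anchor2)
        if "none" in (l1, l2):
            cat = "other"
        else:
            cat = "-".join(sorted((l1, l2), reverse=True))  # P before E
        lp.category = cat
        counts[cat] += 1
    n = max(1, len(loops))
    return {c: counts[c] / n for c in LOOP_CATEGORIES}


def find_anchor_motifs(loops: list[Loop], matches: list[MotifMatch]) -> None:
    """Attach the best-scoring motif match inside each anchor, in place.

    Ties go to the lower start coordinate. The loop's convergence flag is
    True iff anchor1 carries a (+) match and anchor2 a (-) match — the
    loop-extrusion-compatible convergent arrangement.
    """
    by_chrom: dict[str, list[MotifMatch]] = {}
    for mm in matches:
        by_chrom.setdefault(mm.interval.chrom, []).append(mm)
    for lst in by_chrom.values():
        lst.sort(key=lambda mm: mm.interval.start)
    import bisect as _bisect

    def best_in(anchor: Interval) -> MotifMatch | None:
        lst = by_chrom.get(anchor.chrom, [])
        starts = [mm.interval.start for mm in lst]
        lo = _bisect.bisect_left(starts, anchor.start - 1000)
        best = None
        for mm in lst[lo:]:
            if mm.interval.start >= anchor.end:
                break
            if mm.interval.overlaps(anchor):
                if (
                    best is None
                    or mm.score > best.score
                    or (mm.score == best.score and mm.interval.start < best.interval.start)
                ):
                    best = mm
        return best

    for lp in loops:
        lp.motif1 = best_in(lp.anchor1)
        lp.motif2 = best_in(lp.anchor2)
        lp.convergent = (
            lp.motif1 is not None
            and lp.motif2 is not None
            and lp.motif1.strand == "+"
            and lp.motif2.strand == "-"
        )


def aggregate_peak_analysis(
    m: ContactMatrix,
    loops: list[Loop],
    flank_bins: int = 10,
    oe: np.ndarray | None = None,
) -> APAResult:
    """Mean O/E submatrix over loop pixels, with the APA enrichment score.

    Loops whose (2 flank + 1)^2 window leaves the matrix, or whose anchor
    separation is below 2 flank + 1 bins (window would cross the
    diagonal), are skipped and counted. The score divides the center
    value by the mean of the lower-left corner block of size
    floor(flank/2)^2 — background pixels at the same distance range but
    away from the loop.
    """
    k = flank_bins
    if oe is None:
        oe = observed_over_expected(m)
    acc = np.zeros((2 * k + 1, 2 * k + 1))
    n_agg = n_skip = 0
    for lp in loops:
        i, j = _anchor_bin(lp.anchor1, m), _anchor_bin(lp.anchor2, m)
        if j - i < 2 * k + 1 or i - k < 0 or j + k >= m.n_bins:
            n_skip += 1
            continue
        sub = oe[i - k : i + k + 1, j - k : j + k + 1]
        if not np.isfinite(sub).all():
            n_skip += 1
            continue
        acc += sub
        n_agg += 1
    if n_agg == 0:
        raise ValueError("no loops could be aggregated")
    mat = acc / n_agg
    q = max(1, k // 2)
    corner = mat[2 * k + 1 - q :, :q]  # lower-left: large anchor1, small anchor2
    score = float(mat[k, k] / corner.mean())
    return APAResult(mat, score, n_agg, n_skip)
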