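"""Promoter/enhancer calling, co-binding classes, expression integration.

Active promoters are H3K27ac peaks lying within 1 kb (edge-to-point,
boundary inclusive) of a transcription start site; remaining H3K27ac
peaks are active enhancers. Genes are split into differentially
expressed (DEG), non-differentially expressed (un-DEG) and non-expressed
groups, and "direct targets" of a transcription factor are DEGs whose
promoter window carries a TF peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import Interval, signed_gap

ACTIVE_PROMOTER = "active_promoter"
ACTIVE_ENHANCER = "active_enhancer"

__all__ = [
    "PeakSet",
    "RegulatoryAnnotation",
    "ExpressionTable",
    "GeneGroups",
    "CobindingClasses",
    "tss_point",
    "call_promoters_enhancers",
    "classify_cobinding",
    "differential_expression_test",
    "group_genes",
    "call_direct_targets",
    "boundary_peak_overlap",
]


@dataclass
class PeakSet:
    """A sorted collection of peak intervals from one experiment."""

    peaks: list[Interval]
    source: str = ""

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass
class RegulatoryAnnotation:
    """Mutually exclusive, exhaustive promoter/enhancer classes."""

    promoters: list[Interval]
    enhancers: list[Interval]
    promoter_gene: dict[Interval, str]  # promoter peak -> nearest gene id

    @property
    def classes(self) -> dict[Interval, str]:
        out = {p: ACTIVE_PROMOTER for p in self.promoters}
        out.update({e: ACTIVE_ENHANCER for e in self.enhancers})
        return out


@dataclass
class GeneGroups:
    """Disjoint DEG / un-DEG / non-expressed partition of the gene universe."""

    deg: set[str]
    undeg: set[str]
    non_expressed: set[str]

    @property
    def all_genes(self) -> set[str]:
        return self.deg | self.undeg | self.non_expressed


@dataclass
class CobindingClasses:
    """Overlap classification of two peak sets (>= 1 bp overlap = shared)."""

    shared_a: list[Interval]
    a_only: list[Interval]
    shared_b: list[Interval]
    b_only: list[Interval]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "shared": len(self.shared_a),
            "A_only": len(self.a_only),
            "B_only": len(self.b_only),
        }


class ExpressionTable:
    """Per-gene expression with TSS coordinates and two-condition replicates.

    Wraps a DataFrame with columns: gene, chrom, tss, strand,
    ``cond1_rep*``, ``cond2_rep*`` and, once computed, mean1, mean2,
    log2fc, pvalue.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"gene", "chrom", "tss", "strand"}
        if not required <= set(df.columns):
            raise ValueError(f"missing columns: {required - set(df.columns)}")
        self.df = df.reset_index(drop=True)
        self.rep_cols1 = [c for c in df.columns if c.startswith("cond1_rep")]
        self.rep_cols2 = [c for c in df.columns if c.startswith("cond2_rep")]
        if not self.rep_cols1 or not self.rep_cols2:
            raise ValueError("need cond1_rep* and cond2_rep* columns")

    @classmethod
    def read_tsv(cls, path) -> "ExpressionTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def tss_intervals(self) -> list[Interval]:
        return [
            Interval(r.chrom, int(r.tss), int(r.tss) + 1, strand=r.strand, name=r.gene)
            for r in self.df.itertuples()
        ]


def tss_point(tss: Interval) -> int:
    """The single-bp TSS position of a TSS interval (5' end by strand)."""
    return tss.end - 1 if tss.strand == "-" else tss.start


def _peak_tss_distance(peak: Interval, point: int) -> int:
    """Edge-to-point distance; 0 when the point falls inside the peak."""
    if peak.start <= point < peak.end:
        return 0
    return peak.start - point if point < peak.start else point - (peak.end - 1)


def call_promoters_enhancers(
    h3k27ac: PeakSet,
    tss: list[Interval],
    promoter_distance: int = 1000,
    use_summit: bool = False,
) -> RegulatoryAnnotation:
    """Split H3K27ac peaks into active promoters and active enhancers.

    A peak is an active promoter iff its nearest TSS lies within
    ``promoter_distance`` bp (inclusive) of the peak's nearest edge
    (or of the peak summit/midpoint with ``use_summit``). Every other
    peak is an active enhancer; each promoter maps to its nearest gene.
    """
    if not tss:
        raise ValueError("tss list is empty")
    by_chrom: dict[str, list[Interval]] = {}
    for t in tss:
        by_chrom.setdefault(t.chrom, []).append(t)
    promoters, enhancers = [], []
    promoter_gene: dict[Interval, str] = {}
    for peak in h3k27ac:
        best_d, best_gene = None, None
        for t in by_chrom.get(peak.chrom, []):
            point = tss_point(t)
            if use_summit:
                d = abs(peak.midpoint - point)
            else:
                d = _peak_tss_distance(peak, point)
            if best_d is None or d < best_d:
                best_d, best_gene = d, t.name
        if best_d is not None and best_d <= promoter_distance:
            promoters.append(peak)
            promoter_gene[peak] = best_gene
        else:
            enhancers.append(peak)
    return RegulatoryAnnotation(promoters, enhancers, promoter_gene)


def _overlaps_any(peak: Interval, others: list[Interval], starts: np.ndarray, ends_max: np.ndarray) -> bool:
    # others sorted by start; ends_max = running max of ends
    lo = int(np.searchsorted(starts, peak.end))  # candidates with start < peak.end
    if lo == 0:
        return False
    # any candidate among [0, lo) with end > peak.start?
    return bool(ends_max[lo - 1] > peak.start)


def _overlap_index(peaks: list[Interval]):
    by_chrom: dict[str, list[Interval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    out = {}
    for c, lst in by_chrom.items():
        lst.sort(key=lambda p: p.start)
        starts = np.array([p.start for p in lst])
        ends_max = np.maximum.accumulate([p.end for p in lst])
        out[c] = (lst, starts, ends_max)
    return out


def overlaps_feature(peak: Interval, index) -> bool:
    entry = index.get(peak.chrom)
    if entry is None:
        return False
    lst, starts, ends_max = entry
    return _overlaps_any(peak, lst, starts, ends_max)


def classify_cobinding(peaks_a: PeakSet, peaks_b: PeakSet) -> CobindingClasses:
    """Partition each peak set by >= 1 bp overlap with the other."""
    idx_b = _overlap_index(list(peaks_b))
    idx_a = _overlap_index(list(peaks_a))
    shared_a, a_only, shared_b, b_only = [], [], [], []
    for p in peaks_a:
        (shared_a if overlaps_feature(p, idx_b) else a_only).append(p)
    for p in peaks_b:
        (shared_b if overlaps_feature(p, idx_a) else b_only).append(p)
    return CobindingClasses(shared_a, a_only, shared_b, b_only)


def differential_expression_test(
    table: ExpressionTable, pooled_variance: bool = True
) -> ExpressionTable:
    """Two-sample t-test per gene on log2(x + 1) replicate values.

    The default pools the variance across conditions, mirroring
    shared-dispersion count models: at typical RNA-seq replication
    (n = 3) the pooled test holds its nominal size, whereas the
    unequal-variance (Welch) alternative — available via
    ``pooled_variance=False`` — is markedly conservative.

    Adds mean1, mean2, log2fc (of means, +1 offset) and pvalue columns.
    Genes with zero variance in both groups get p = 1 when the means are
    equal and p = 0 otherwise (the degenerate limits of the test).
    """
    df = table.df.copy()
    x1 = df[table.rep_cols1].to_numpy(float)
    x2 = df[table.rep_cols2].to_numpy(float)
    if x1.shape[1] < 2 or x2.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition")
    l1, l2 = np.log2(x1 + 1), np.log2(x2 + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(l1, l2, axis=1, equal_var=pooled_variance)
        p = np.asarray(res.pvalue, dtype=float)
    zero_var = (l1.std(axis=1) == 0) & (l2.std(axis=1) == 0)
    equal_means = np.isclose(l1.mean(axis=1), l2.mean(axis=1))
    p[zero_var & equal_means] = 1.0
    p[zero_var & ~equal_means] = 0.0
    df["mean1"] = x1.mean(axis=1)
    df["mean2"] = x2.mean(axis=1)
    df["log2fc"] = np.log2((df["mean2"] + 1) / (df["mean1"] + 1))
    df["pvalue"] = p
    return ExpressionTable(df)


def group_genes(
    table: ExpressionTable,
    p_threshold: float = 0.05,
    expressed_floor: float = 1.0,
    adjust: bool = False,
) -> GeneGroups:
    """Partition genes into DEG / un-DEG / non-expressed.

    Non-expressed: mean expression below ``expressed_floor`` in both
    conditions. DEG: expressed with p below ``p_threshold`` (raw p by
    default; ``adjust`` switches to Benjamini-Hochberg). un-DEG: the rest.
    """
    df = table.df
    if "pvalue" not in df.columns:
        raise ValueError("run differential_expression_test first")
    p = df["pvalue"].to_numpy(float)
    if adjust:
        p = stats.false_discovery_control(p)
    non_exp = (df["mean1"] < expressed_floor) & (df["mean2"] < expressed_floor)
    deg = ~non_exp & (p < p_threshold)
    undeg = ~non_exp & ~deg
    genes = df["gene"]
    return GeneGroups(
        set(genes[deg]), set(genes[undeg]), set(genes[non_exp])
    )


def call_direct_targets(
    groups: GeneGroups,
    tf_peaks: PeakSet,
    table: ExpressionTable,
    promoter_distance: int = 1000,
    min_peak_score: float = 0.0,
) -> tuple[set[str], pd.DataFrame]:
    """DEGs whose promoter window (TSS +/- 1 kb) carries a TF peak.

    Returns the target gene set and a per-gene evidence table.
    """
    peaks = [p for p in tf_peaks if p.score >= min_peak_score]
    idx = _overlap_index(peaks)
    records = []
    targets: set[str] = set()
    for t in table.tss_intervals():
        if t.name not in groups.deg:
            continue
        point = tss_point(t)
        win = Interval(t.chrom, max(0, point - promoter_distance), point + promoter_distance + 1)
        bound = overlaps_feature(win, idx)
        if bound:
            targets.add(t.name)
        records.append({"gene": t.name, "deg": True, "tf_on_promoter": bound})
    return targets, pd.DataFrame(records)


def boundary_peak_overlap(
    boundaries: list[Interval], cobinding: CobindingClasses
) -> dict[str, int]:
    """Per co-binding class, peaks overlapping >= 1 bp any boundary.

    A peak spanning two boundary intervals still counts once.
    """
    idx = _overlap_index(boundaries)
    out = {}
    for label, peaks in (
        ("shared", cobinding.shared_a),
        ("A_only", cobinding.a_only),
        ("B_only", cobinding.b_only),
    ):
        out[label] = sum(1 for p in peaks if overlaps_feature(p, idx))
    return out
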