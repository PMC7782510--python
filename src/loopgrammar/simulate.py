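"""Seeded generators for every input the pipeline consumes, with truth.

Each generator is a pure function of its parameters and a seed, and
returns its ground truth alongside the data so recovery metrics can be
computed without peeking at generator internals. The generators emulate
the statistical structure of the real study inputs at desk scale:

* random genomes with motif instances planted at controlled spacing and
  orientation, plus uniformly placed background instances (standing in
  for the genome-wide background match rate of a 2.7-Gb genome);
* TSS / H3K27ac / TF peak landscapes with known promoter-enhancer and
  co-binding layout, and reads with per-peak enrichment;
* two-condition expression tables with a planted downregulated target
  set (log-normal expression, multiplicative replicate noise);
* Poisson contact maps with power-law distance decay, TAD blocks,
  loop pixels, a compartment checkerboard and multiplicative bin biases.

The bundled ``ctcf_like`` / ``znf143_like`` matrices are synthetic
motifs built for these simulations (strong non-palindromic consensus
with a few degenerate columns); they are not database matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .core import Interval, GenomeSequence
from .motifs import PositionWeightMatrix, load_pwm, reverse_complement
from .motifs import CONVERGENT, DIVERGENT, FORWARD_FORWARD, REVERSE_REVERSE
from .annotate import PeakSet, ExpressionTable
from .contacts import ContactMatrix
from .loops import Loop

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

__all__ = [
    "TruthTable",
    "builtin_pwm",
    "make_genome",
    "plant_motif_pairs",
    "plant_instances",
    "make_peak_landscape",
    "make_expression_table",
    "make_target_peaks",
    "make_contact_map",
    "make_loop_maps",
]


@dataclass
class TruthTable:
    """Ground truth of a synthetic dataset, serializable to TSV files."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def write_dir(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(f"{outdir}/truth_{name}.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"param": k, "value": repr(v)} for k, v in self.params.items()]
        ).to_csv(f"{outdir}/truth_params.tsv", sep="\t", index=False)


def builtin_pwm(name: str) -> PositionWeightMatrix:
    """Load one of the bundled synthetic motifs: 'ctcf_like' or 'znf143_like'."""
    ref = resources.files("loopgrammar.data") / f"{name}.jaspar"
    with resources.as_file(ref) as path:
        return load_pwm(path)


# ---------------------------------------------------------------------------
# Genomes and motif planting


def make_genome(length: int, gc: float = 0.42, seed: int = 0, chrom: str = "chrS") -> GenomeSequence:
    """An i.i.d. random genome at the given GC content (mouse-like 0.42)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    seq = _BASES[codes].tobytes().decode("ascii")
    return GenomeSequence({chrom: seq})


def _place_nonoverlapping(
    rng,
    length: int,
    widths: list[int],
    occupied: list[tuple[int, int]],
    margin: int = 0,
    max_tries: int = 200,
):
    """Draw start positions for blocks of the given widths, non-overlapping.

    ``margin`` keeps planted blocks at least that many bp apart, so a
    planted pair's nearest neighbour is its own partner, not a block
    planted next door.
    """
    taken = sorted(occupied)
    starts = []
    for w in widths:
        for _ in range(max_tries):
            s = int(rng.integers(0, length - w))
            lo, hi = s - 1 - margin, s + w + 1 + margin
            import bisect

            i = bisect.bisect_left(taken, (lo,))
            clash = False
            for t0, t1 in taken[max(0, i - 1) : i + 2]:
                if t0 < hi and lo < t1:
                    clash = True
                    break
            if not clash:
                bisect.insort(taken, (s, s + w))
                starts.append(s)
                break
        else:
            raise RuntimeError("could not place motif instances without overlap")
    return starts, taken


def _write_instance(seq: list, start: int, consensus: str, strand: str) -> None:
    s = consensus if strand == "+" else reverse_complement(consensus)
    seq[start : start + len(s)] = s


_PAIR_STRANDS = {
    CONVERGENT: ("+", "-"),
    DIVERGENT: ("-", "+"),
    FORWARD_FORWARD: ("+", "+"),
    REVERSE_REVERSE: ("-", "-"),
}


def plant_motif_pairs(
    genome: GenomeSequence,
    pwm_a: PositionWeightMatrix,
    pwm_b: PositionWeightMatrix,
    n_pairs: int,
    gap: int = 37,
    orientation: str | list[str] = CONVERGENT,
    jitter: int = 0,
    seed: int = 0,
) -> tuple[GenomeSequence, TruthTable]:
    """Plant consensus instances of two motifs at a fixed edge-to-edge gap.

    Motif A sits upstream, motif B downstream at ``gap`` (+/- jitter) bp;
    the orientation pattern fixes the two strands (convergent puts A on +
    and B on -). ``orientation`` may be a per-pair list. Returns a new
    genome and the truth table of planted positions.
    """
    chrom = genome.chroms[0]
    seq = list(genome[chrom])
    L = len(seq)
    rng = np.random.default_rng(seed)
    orients = (
        [orientation] * n_pairs if isinstance(orientation, str) else list(orientation)
    )
    if len(orients) != n_pairs:
        raise ValueError("orientation list length must equal n_pairs")
    wa, wb = pwm_a.width, pwm_b.width
    gaps = gap + (rng.integers(-jitter, jitter + 1, n_pairs) if jitter else np.zeros(n_pairs, int))
    block_ws = [wa + int(g) + wb for g in gaps]
    starts, _ = _place_nonoverlapping(rng, L, block_ws, [], margin=200)
    rows = []
    for k, (s, g, orient) in enumerate(zip(starts, gaps, orients)):
        sa, sb = _PAIR_STRANDS[orient]
        a_start = s
        b_start = s + wa + int(g)
        _write_instance(seq, a_start, pwm_a.consensus, sa)
        _write_instance(seq, b_start, pwm_b.consensus, sb)
        rows.append(
            {
                "pair": k,
                "chrom": chrom,
                "a_start": a_start,
                "a_end": a_start + wa,
                "a_strand": sa,
                "b_start": b_start,
                "b_end": b_start + wb,
                "b_strand": sb,
                "gap": int(g),
                "orientation": orient,
            }
        )
    truth = TruthTable(
        {"motif_pairs": pd.DataFrame(rows)},
        {"gap": gap, "jitter": jitter, "seed": seed, "n_pairs": n_pairs},
    )
    return GenomeSequence({chrom: "".join(seq)}), truth


def _sample_positions(
    rng, length: int, width: int, n: int, occupied, margin: int = 0, rounds: int = 80
) -> list[int]:
    """Uniform non-overlapping start positions, vectorized for large n.

    Candidates overlapping an ``occupied`` block (inflated by ``margin``)
    are dropped, then a greedy sweep keeps candidates at least
    ``width + margin`` apart; repeated until ``n`` positions are placed.
    """
    occ = sorted(occupied)
    kept: list[int] = []
    for _ in range(rounds):
        need = n - len(kept)
        if need <= 0:
            return kept[:n]
        blocks = sorted(occ + [(s, s + width) for s in kept])
        ostarts = np.array([b[0] for b in blocks]) if blocks else np.empty(0)
        oends = np.array([b[1] for b in blocks]) if blocks else np.empty(0)
        cand = np.sort(rng.integers(0, length - width, size=int(need * 1.6) + 16))
        if ostarts.size:
            idx = np.searchsorted(ostarts, cand + width + margin)
            clash = (idx > 0) & (np.where(idx > 0, oends[np.maximum(idx - 1, 0)], 0) > cand - margin)
            cand = cand[~clash]
        prev_end = -margin - 1
        for s in cand:
            if s - prev_end > margin and len(kept) < n:
                kept.append(int(s))
                prev_end = s + width
    raise RuntimeError("could not place the requested number of instances")


def plant_instances(
    genome: GenomeSequence,
    pwm: PositionWeightMatrix,
    n: int,
    seed: int = 0,
    occupied: list[tuple[int, int]] | None = None,
) -> tuple[GenomeSequence, pd.DataFrame]:
    """Plant ``n`` consensus instances uniformly at random, random strand.

    Emulates background occurrences of a motif; placement avoids the
    ``occupied`` intervals and previously planted instances.
    """
    chrom = genome.chroms[0]
    seq = list(genome[chrom])
    rng = np.random.default_rng(seed)
    W = pwm.width
    starts = sorted(_sample_positions(rng, len(seq), W, n, occupied or []))
    strands = rng.choice(["+", "-"], n)
    rows = []
    for s, st in zip(starts, strands):
        _write_instance(seq, s, pwm.consensus, st)
        rows.append({"chrom": chrom, "start": s, "end": s + W, "strand": st})
    return GenomeSequence({chrom: "".join(seq)}), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Peak landscapes


def make_peak_landscape(
    genome: GenomeSequence,
    n_genes: int,
    promoter_k27_frac: float = 0.7,
    enhancers_per_gene: float = 1.0,
    tf_cobinding: dict | None = None,
    reads_per_peak: int = 50,
    background_reads: int = 0,
    peak_width: int = 600,
    seed: int = 0,
) -> dict:
    """TSSs, H3K27ac peaks, two co-binding TF peak sets and reads.

    TSSs are evenly spaced with jitter. A ``promoter_k27_frac`` share of
    genes gets an H3K27ac peak overlapping the TSS; enhancer H3K27ac
    peaks sit 5-20 kb away from their gene's TSS. TF site counts follow
    ``tf_cobinding`` = {"shared": n, "A_only": n, "B_only": n}; shared
    sites place an A and a B peak on the same spot. Reads (36 bp,
    stranded) are drawn per peak plus a uniform background.
    """
    tf_cobinding = tf_cobinding or {"shared": 40, "A_only": 20, "B_only": 20}
    chrom = genome.chroms[0]
    L = genome.lengths[chrom]
    rng = np.random.default_rng(seed)
    spacing = L // (n_genes + 1)
    if spacing < 45000:
        raise ValueError("genome too short for the requested gene count")
    tss_pos = np.array(
        [
            (i + 1) * spacing + int(rng.integers(-spacing // 8, spacing // 8))
            for i in range(n_genes)
        ]
    )
    strands = rng.choice(["+", "-"], n_genes)
    tss = [
        Interval(chrom, int(p), int(p) + 1, strand=s, name=f"gene{i}")
        for i, (p, s) in enumerate(zip(tss_pos, strands))
    ]
    k27, truth_rows = [], []
    hw = peak_width // 2
    is_promoter_gene = rng.random(n_genes) < promoter_k27_frac
    for i, p in enumerate(tss_pos):
        if is_promoter_gene[i]:
            c = int(p + rng.integers(-200, 201))
            k27.append(Interval(chrom, c - hw, c + hw, name=f"k27_prom_{i}", score=1.0))
            truth_rows.append({"peak": f"k27_prom_{i}", "class": "promoter", "gene": f"gene{i}"})
        n_enh = rng.poisson(enhancers_per_gene)
        for e in range(n_enh):
            off = int(rng.integers(5000, 20000)) * int(rng.choice([-1, 1]))
            c = int(np.clip(p + off, hw, L - hw))
            k27.append(Interval(chrom, c - hw, c + hw, name=f"k27_enh_{i}_{e}", score=1.0))
            truth_rows.append({"peak": f"k27_enh_{i}_{e}", "class": "enhancer", "gene": f"gene{i}"})
    # TF sites at fresh intergenic positions (>= 2 kb from any TSS)
    def _tf_site():
        while True:
            c = int(rng.integers(hw, L - hw))
            if np.abs(tss_pos - c).min() > 2000:
                return c

    peaks_a, peaks_b = [], []
    cobind_rows = []
    for _ in range(tf_cobinding.get("shared", 0)):
        c = _tf_site()
        peaks_a.append(Interval(chrom, c - 150, c + 150, name="A_shared", score=1.0))
        peaks_b.append(Interval(chrom, c - 160, c + 140, name="B_shared", score=1.0))
        cobind_rows.append({"center": c, "class": "shared"})
    for _ in range(tf_cobinding.get("A_only", 0)):
        c = _tf_site()
        peaks_a.append(Interval(chrom, c - 150, c + 150, name="A_only", score=1.0))
        cobind_rows.append({"center": c, "class": "A_only"})
    for _ in range(tf_cobinding.get("B_only", 0)):
        c = _tf_site()
        peaks_b.append(Interval(chrom, c - 150, c + 150, name="B_only", score=1.0))
        cobind_rows.append({"center": c, "class": "B_only"})
    reads = []
    for pk in k27:
        centers = rng.integers(pk.start, pk.end, reads_per_peak)
        for c in centers:
            s = rng.choice(["+", "-"])
            start = int(np.clip(c - 18, 0, L - 36))
            reads.append(Interval(chrom, start, start + 36, strand=s))
    for _ in range(background_reads):
        start = int(rng.integers(0, L - 36))
        reads.append(Interval(chrom, start, start + 36, strand=rng.choice(["+", "-"])))
    truth = TruthTable(
        {
            "k27_peaks": pd.DataFrame(truth_rows),
            "tf_sites": pd.DataFrame(cobind_rows),
        },
        {"seed": seed, "n_genes": n_genes},
    )
    return {
        "tss": tss,
        "h3k27ac": PeakSet(k27, "H3K27ac"),
        "tf_a": PeakSet(peaks_a, "TF_A"),
        "tf_b": PeakSet(peaks_b, "TF_B"),
        "reads": reads,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# Expression


def make_expression_table(
    n_genes: int,
    n_targets: int,
    target_lfc_mean: float = -1.0,
    target_lfc_sd: float = 0.3,
    null_sd: float = 0.25,
    reps: int = 3,
    rep_sd: float = 0.15,
    nonexpressed_frac: float = 0.15,
    genome_length: int | None = None,
    seed: int = 0,
) -> tuple[ExpressionTable, TruthTable]:
    """Two-condition expression table with a planted downregulated target set.

    Expressed genes get log-normal base expression (log2 mean 5, sd 1.5);
    condition-2 means are shifted by a per-gene log2 fold change drawn
    from Normal(target_lfc_mean, target_lfc_sd) for targets and
    Normal(0, null_sd) for the rest; replicates add Normal(0, rep_sd)
    noise on the log2 scale (multiplicative on counts). A
    ``nonexpressed_frac`` share of genes sits near zero in both
    conditions. TSS coordinates are laid out on one synthetic chromosome.
    """
    if n_targets > n_genes:
        raise ValueError("n_targets must be <= n_genes")
    rng = np.random.default_rng(seed)
    L = genome_length or max(1_000_000, n_genes * 5000)
    spacing = L // (n_genes + 1)
    tss = (np.arange(1, n_genes + 1) * spacing).astype(int)
    strands = rng.choice(["+", "-"], n_genes)
    n_nonexp = int(round(nonexpressed_frac * n_genes))
    nonexp = set(rng.choice(n_genes, n_nonexp, replace=False).tolist())
    expressed = [i for i in range(n_genes) if i not in nonexp]
    if n_targets > len(expressed):
        raise ValueError("not enough expressed genes for the target count")
    targets = set(rng.choice(expressed, n_targets, replace=False).tolist())
    log2_base = rng.normal(5.0, 1.5, n_genes)
    lfc = rng.normal(0.0, null_sd, n_genes) if null_sd > 0 else np.zeros(n_genes)
    for i in targets:
        lfc[i] = rng.normal(target_lfc_mean, target_lfc_sd)
    rows = []
    for i in range(n_genes):
        rec = {
            "gene": f"gene{i}",
            "chrom": "chrS",
            "tss": int(tss[i]),
            "strand": strands[i],
        }
        if i in nonexp:
            base1 = base2 = None
            for r in range(reps):
                rec[f"cond1_rep{r+1}"] = round(float(rng.uniform(0, 0.4)), 4)
                rec[f"cond2_rep{r+1}"] = round(float(rng.uniform(0, 0.4)), 4)
        else:
            for r in range(reps):
                rec[f"cond1_rep{r+1}"] = round(
                    float(2 ** (log2_base[i] + rng.normal(0, rep_sd))), 4
                )
                rec[f"cond2_rep{r+1}"] = round(
                    float(2 ** (log2_base[i] + lfc[i] + rng.normal(0, rep_sd))), 4
                )
        rows.append(rec)
    df = pd.DataFrame(rows)
    truth_df = pd.DataFrame(
        {
            "gene": [f"gene{i}" for i in range(n_genes)],
            "is_target": [i in targets for i in range(n_genes)],
            "is_nonexpressed": [i in nonexp for i in range(n_genes)],
            "true_log2fc": lfc,
        }
    )
    truth = TruthTable(
        {"expression": truth_df},
        {
            "seed": seed,
            "n_genes": n_genes,
            "n_targets": n_targets,
            "target_lfc_mean": target_lfc_mean,
            "genome_length": L,
        },
    )
    return ExpressionTable(df), truth


def make_target_peaks(
    table: ExpressionTable,
    truth: TruthTable,
    peak_width: int = 300,
    distal_sites: int = 50,
    bind_nonexpressed_frac: float = 0.3,
    seed: int = 0,
) -> tuple[PeakSet, PeakSet]:
    """TF and H3K27ac peak sets matching an expression table's truth.

    The TF binds every target gene's promoter (peak over the TSS), a
    share of non-expressed promoters (silent binding), and random distal
    sites; H3K27ac covers every expressed gene's TSS so promoters can be
    called. Returns (tf_peaks, h3k27ac_peaks).
    """
    rng = np.random.default_rng(seed)
    tdf = truth.tables["expression"].set_index("gene")
    L = truth.params["genome_length"]
    hw = peak_width // 2
    tf, k27 = [], []
    for r in table.df.itertuples():
        t = tdf.loc[r.gene]
        if not t["is_nonexpressed"]:
            k27.append(Interval(r.chrom, max(0, r.tss - 400), r.tss + 400, name=f"k27_{r.gene}", score=1.0))
        if t["is_target"] or (
            t["is_nonexpressed"] and rng.random() < bind_nonexpressed_frac
        ):
            tf.append(Interval(r.chrom, max(0, r.tss - hw), r.tss + hw, name=f"tf_{r.gene}", score=1.0))
    tss_arr = table.df["tss"].to_numpy()
    for d in range(distal_sites):
        while True:
            c = int(rng.integers(hw, L - hw))
            if np.abs(tss_arr - c).min() > 3000:
                break
        tf.append(Interval("chrS", c - hw, c + hw, name=f"tf_distal_{d}", score=1.0))
    return PeakSet(tf, "TF"), PeakSet(k27, "H3K27ac")


# ---------------------------------------------------------------------------
# Contact maps


def _segment_labels(n_bins: int, boundaries: list[int]) -> np.ndarray:
    """TAD segment id per bin given boundary bin indices."""
    labels = np.zeros(n_bins, dtype=int)
    seg = 0
    bset = sorted(boundaries)
    j = 0
    for i in range(n_bins):
        while j < len(bset) and i >= bset[j]:
            seg += 1
            j += 1
        labels[i] = seg
    return labels


def make_contact_map(
    chrom_len: int,
    binsize: int,
    tad_boundaries: list[int] | None = None,
    loop_pixels: list[tuple[int, int]] | None = None,
    loop_enrichment: float = 3.0,
    tad_factor: float = 3.0,
    compartment_labels: np.ndarray | None = None,
    compartment_factor: float = 0.3,
    decay_alpha: float = 1.0,
    bias_sd: float = 0.2,
    depth: float = 1e7,
    seed: int = 0,
    chrom: str = "chrS",
    loop_scales: dict[tuple[int, int], float] | None = None,
) -> tuple[ContactMatrix, TruthTable]:
    """Poisson contact map with planted TADs, loops, compartments, biases.

    The expected count of cell (i, j) is
    ``N * (1+|i-j|)^(-alpha) * T * L * C * b_i * b_j`` where T applies
    the TAD factor inside a shared TAD segment, L the loop enrichment at
    planted pixels (optionally rescaled per pixel via ``loop_scales``),
    C = 1 + compartment_factor for same-label bins, and b are log-normal
    bin biases; N is set so the expected total equals ``depth``.
    """
    n = chrom_len // binsize
    rng = np.random.default_rng(seed)
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    mu = (1.0 + sep) ** (-decay_alpha)
    if tad_boundaries:
        seg = _segment_labels(n, tad_boundaries)
        mu = mu * np.where(seg[:, None] == seg[None, :], tad_factor, 1.0)
    if compartment_labels is not None:
        lab = np.asarray(compartment_labels)
        mu = mu * np.where(lab[:, None] == lab[None, :], 1.0 + compartment_factor, 1.0)
    if loop_pixels:
        for (i, j) in loop_pixels:
            e = loop_enrichment * (loop_scales or {}).get((i, j), 1.0)
            mu[i, j] = mu[i, j] * e
            mu[j, i] = mu[i, j]
    biases = np.exp(rng.normal(0.0, bias_sd, n)) if bias_sd > 0 else np.ones(n)
    mu = mu * np.outer(biases, biases)
    iu = np.triu_indices(n)
    scale = depth / mu[iu].sum()
    counts = rng.poisson(mu[iu] * scale)
    nz = counts > 0
    m = ContactMatrix(chrom, binsize, n, iu[0][nz], iu[1][nz], counts[nz].astype(float))
    truth = TruthTable(
        {
            "tad_boundaries": pd.DataFrame({"bin": sorted(tad_boundaries or [])}),
            "loops": pd.DataFrame(
                [
                    {
                        "bin1": i,
                        "bin2": j,
                        "enrichment": loop_enrichment * (loop_scales or {}).get((i, j), 1.0),
                    }
                    for (i, j) in (loop_pixels or [])
                ]
            ),
            "biases": pd.DataFrame({"bin": idx, "bias": biases}),
            "compartments": pd.DataFrame(
                {
                    "bin": idx,
                    "label": (
                        np.asarray(compartment_labels)
                        if compartment_labels is not None
                        else np.zeros(n, int)
                    ),
                }
            ),
        },
        {
            "chrom_len": chrom_len,
            "binsize": binsize,
            "loop_enrichment": loop_enrichment,
            "tad_factor": tad_factor,
            "compartment_factor": compartment_factor,
            "decay_alpha": decay_alpha,
            "bias_sd": bias_sd,
            "depth": depth,
            "seed": seed,
        },
    )
    return m, truth


def make_loop_maps(
    chrom_len: int = 5_000_000,
    binsize: int = 5000,
    n_loops: int = 120,
    loop_enrichment: float = 3.0,
    decreased_frac: float = 0.5,
    scale: float = 1 / 3,
    depth: float = 2e7,
    bias_sd: float = 0.1,
    min_sep_bins: int = 30,
    max_sep_bins: int = 100,
    seed: int = 0,
) -> tuple[ContactMatrix, ContactMatrix, list[Loop], TruthTable]:
    """Two-condition loop maps with a subset of loops scaled in condition 2.

    Condition 1 carries ``n_loops`` pixels at ``loop_enrichment``; in
    condition 2 a random ``decreased_frac`` subset has its enrichment
    multiplied by ``scale`` (1/3 by default, i.e. lost loops). The two
    maps are independent Poisson draws. Returns both maps, the loop list
    (bin-aligned anchors), and truth with the per-loop class.
    """
    rng = np.random.default_rng(seed)
    n = chrom_len // binsize
    pixels = set()
    while len(pixels) < n_loops:
        s = int(rng.integers(min_sep_bins, max_sep_bins + 1))
        i = int(rng.integers(12, n - s - 12))
        # keep loop windows disjoint so APA submatrices do not collide
        if all(abs(i - a) > 3 or abs(i + s - b) > 3 for a, b in pixels):
            pixels.add((i, i + s))
    pixels = sorted(pixels)
    scaled = set(
        int(k) for k in rng.choice(len(pixels), int(round(decreased_frac * n_loops)), replace=False)
    )
    scales = {pixels[k]: scale for k in scaled}
    m1, truth1 = make_contact_map(
        chrom_len, binsize, loop_pixels=pixels, loop_enrichment=loop_enrichment,
        bias_sd=bias_sd, depth=depth, seed=seed * 2 + 1,
    )
    m2, _ = make_contact_map(
        chrom_len, binsize, loop_pixels=pixels, loop_enrichment=loop_enrichment,
        bias_sd=bias_sd, depth=depth, seed=seed * 2 + 2, loop_scales=scales,
    )
    loops = [
        Loop(
            Interval("chrS", i * binsize, (i + 1) * binsize, name=f"loop{k}"),
            Interval("chrS", j * binsize, (j + 1) * binsize, name=f"loop{k}"),
        )
        for k, (i, j) in enumerate(pixels)
    ]
    truth_df = pd.DataFrame(
        [
            {
                "loop": k,
                "bin1": i,
                "bin2": j,
                "true_class": "decreased" if k in scaled else "unchanged",
            }
            for k, (i, j) in enumerate(pixels)
        ]
    )
    truth = TruthTable(
        {"loops": truth_df},
        {"scale": scale, "seed": seed, "depth": depth, "binsize": binsize,
         "loop_enrichment": loop_enrichment},
    )
    return m1, m2, loops, truth
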