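"""Recovery benchmarks: end-to-end checks of the pipeline on synthetic data.

Each function builds a seeded synthetic dataset with the generators in
:mod:`loopgrammar.simulate`, runs the corresponding analysis chain, and
returns the recovery metrics a study of this kind reports: modal motif
spacing and orientation purity, null-histogram flatness, balancing
contract numbers, boundary recall, APA enrichment, differential-loop
recall/false-positive rate, direct-target overlap and the type-I error
of the expression test. They are used by the test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _stats

from . import annotate, contacts, loops as loops_mod, motifs, simulate
from .pipeline import histogram_is_flat

__all__ = [
    "spacing_recovery",
    "null_spacing_flatness",
    "balancing_recovery",
    "insulation_recovery",
    "apa_benchmark",
    "differential_loop_recovery",
    "target_recovery",
    "null_deg_fraction",
]


def spacing_recovery(
    seed: int,
    genome_length: int = 2_000_000,
    n_pairs: int = 300,
    gap: int = 37,
    n_background: int = 25,
    threshold: float = 0.8,
) -> dict:
    """Plant convergent motif pairs plus sparse background; recover the mode.

    Returns the modal |distance|, the share of modal pairs classified
    convergent, and the match counts.
    """
    znf = simulate.builtin_pwm("znf143_like")
    ctcf = simulate.builtin_pwm("ctcf_like")
    genome = simulate.make_genome(genome_length, seed=seed)
    genome, truth = simulate.plant_motif_pairs(
        genome, znf, ctcf, n_pairs, gap=gap, seed=seed
    )
    occupied = [
        (r.a_start, r.b_end) for r in truth.tables["motif_pairs"].itertuples()
    ]
    genome, bg_a = simulate.plant_instances(
        genome, znf, n_background, seed=seed + 1000, occupied=occupied
    )
    occupied += list(zip(bg_a.start, bg_a.end))
    genome, _ = simulate.plant_instances(
        genome, ctcf, n_background, seed=seed + 2000, occupied=occupied
    )
    qm = motifs.scan_genome(znf, genome, threshold)
    sm = motifs.scan_genome(ctcf, genome, threshold)
    hist, pairs = motifs.pair_spacing(qm, sm)
    summary = motifs.spacing_summary(hist)
    mode = summary["modal_distance"]
    mode_pairs = [p for p in pairs if abs(p.gap) == mode]
    table = motifs.orientation_table(mode_pairs)
    pct = table.percentages()
    return {
        "modal_distance": mode,
        "pct_convergent_at_mode": pct[motifs.CONVERGENT],
        "n_matches_query": len(qm),
        "n_matches_subject": len(sm),
        **summary,
    }


def null_spacing_flatness(
    perm_seed: int,
    genome_length: int = 20_000_000,
    n_subjects: int = 1000,
    n_null_instances: int = 85_000,
    threshold: float = 0.8,
) -> dict:
    """Column-permuted motif against uniformly placed sites: flat histogram.

    Plants subject-motif instances and (for this permutation seed)
    permuted-motif instances uniformly at random — emulating the
    genome-wide background occurrence rate of a destroyed motif — scans
    both, and checks that no 1-bp spacing bin exceeds five times the
    mean bin count over the +/-2 kb window.
    """
    znf = simulate.builtin_pwm("znf143_like")
    ctcf = simulate.builtin_pwm("ctcf_like")
    perm = motifs.permute_pwm(znf, perm_seed)
    genome = simulate.make_genome(genome_length, seed=10_000 + perm_seed)
    genome, sub_df = simulate.plant_instances(
        genome, ctcf, n_subjects, seed=20_000 + perm_seed
    )
    occupied = list(zip(sub_df.start, sub_df.end))
    genome, _ = simulate.plant_instances(
        genome, perm, n_null_instances, seed=30_000 + perm_seed, occupied=occupied
    )
    qm = motifs.scan_genome(perm, genome, threshold)
    sm = motifs.scan_genome(ctcf, genome, threshold)
    hist, _ = motifs.pair_spacing(qm, sm)
    mean = float(hist.counts.mean())
    return {
        "flat": histogram_is_flat(hist),
        "max_bin": int(hist.counts.max()),
        "mean_bin": mean,
        "n_pairs": hist.total,
    }


def balancing_recovery(
    seed: int, n_bins: int = 500, binsize: int = 25_000, bias_sd: float = 0.2
) -> dict:
    """Bias-only matrix: row-sum CV after balancing and 1/bias recovery.

    Uses a flat-decay matrix so the only departure from uniformity is the
    planted multiplicative bias; the recovered log-weights should then
    anti-correlate with the planted log-biases almost perfectly.
    """
    m, truth = simulate.make_contact_map(
        n_bins * binsize, binsize, bias_sd=bias_sd, decay_alpha=0.0,
        depth=1e7, seed=seed,
    )
    w = contacts.balance_matrix(m)
    active = np.isfinite(w)
    dense = m.dense(balanced=True)
    rows = np.nansum(dense[np.ix_(active, active)], axis=1)
    cv = float(rows.std() / rows.mean())
    b = truth.tables["biases"]["bias"].to_numpy()
    r = float(np.corrcoef(np.log(w[active]), -np.log(b[active]))[0, 1])
    return {"row_sum_cv": cv, "log_bias_correlation": r}


def insulation_recovery(
    seed: int,
    chrom_len: int = 25_000_000,
    binsize: int = 25_000,
    n_boundaries: int = 9,
    tolerance_bins: int = 1,
) -> dict:
    """Planted TAD boundaries recovered by the insulation caller."""
    n = chrom_len // binsize
    spacing = n // (n_boundaries + 1)
    bounds = [spacing * (k + 1) for k in range(n_boundaries)]
    m, truth = simulate.make_contact_map(
        chrom_len, binsize, tad_boundaries=bounds, seed=seed
    )
    contacts.balance_matrix(m)
    ins = contacts.insulation_profile(m)
    called = contacts.call_boundaries(ins)
    called_bins = np.array([b.bin for b in called])
    hit = sum(
        1 for tb in bounds if called_bins.size and np.abs(called_bins - tb).min() <= tolerance_bins
    )
    false = sum(
        1 for cb in called_bins if np.abs(np.array(bounds) - cb).min() > 2
    )
    return {
        "recall": hit / len(bounds),
        "n_called": len(called),
        "n_false_beyond_2bins": false,
    }


def apa_benchmark(
    seed: int,
    n_loops: int = 40,
    loop_enrichment: float = 3.0,
    chrom_len: int = 5_000_000,
    binsize: int = 5000,
    depth: float = 2e7,
) -> dict:
    """APA score at planted loop pixels vs at random non-loop pixels."""
    rng = np.random.default_rng(seed)
    n = chrom_len // binsize

    def draw_pixels(k, avoid=()):
        pix = []
        avoid = set(avoid)
        while len(pix) < k:
            s = int(rng.integers(30, 100))
            i = int(rng.integers(12, n - s - 12))
            p = (i, i + s)
            if p not in avoid and all(
                max(abs(i - a), abs(i + s - b)) > 12 for a, b in pix
            ):
                pix.append(p)
        return pix

    pixels = draw_pixels(n_loops)
    m, _ = simulate.make_contact_map(
        chrom_len, binsize, loop_pixels=pixels,
        loop_enrichment=loop_enrichment, bias_sd=0.1, depth=depth, seed=seed,
    )
    contacts.balance_matrix(m)
    oe = contacts.observed_over_expected(m)

    def to_loops(pix):
        from .core import Interval
        from .loops import Loop

        return [
            Loop(
                Interval("chrS", i * binsize, (i + 1) * binsize),
                Interval("chrS", j * binsize, (j + 1) * binsize),
            )
            for i, j in pix
        ]

    apa_loop = loops_mod.aggregate_peak_analysis(m, to_loops(pixels), oe=oe)
    random_pix = draw_pixels(n_loops, avoid=pixels)
    apa_null = loops_mod.aggregate_peak_analysis(m, to_loops(random_pix), oe=oe)
    return {"apa_planted": apa_loop.score, "apa_random": apa_null.score}


def differential_loop_recovery(seed: int, scale: float = 1 / 3) -> dict:
    """Recall/FPR of the 1.5-fold rule on loops scaled in condition 2."""
    m1, m2, loop_list, truth = simulate.make_loop_maps(seed=seed, scale=scale)
    contacts.balance_matrix(m1)
    contacts.balance_matrix(m2)
    loops_mod.quantify_loops(m1, m2, loop_list)
    loops_mod.classify_differential(loop_list)
    true_class = truth.tables["loops"]["true_class"].to_numpy()
    calls = np.array([lp.klass for lp in loop_list])
    dec = true_class == "decreased"
    recall = float(np.mean(calls[dec] == loops_mod.DECREASED)) if dec.any() else np.nan
    fpr = float(np.mean(calls[~dec] != loops_mod.UNCHANGED)) if (~dec).any() else np.nan
    return {"recall_decreased": recall, "fpr": fpr}


def target_recovery(seed: int, n_genes: int = 2000, n_targets: int = 150) -> dict:
    """Jaccard overlap of called direct targets with the planted set."""
    table, truth = simulate.make_expression_table(n_genes, n_targets, seed=seed)
    tf_peaks, _ = simulate.make_target_peaks(table, truth, seed=seed)
    table = annotate.differential_expression_test(table)
    groups = annotate.group_genes(table)
    called, _ = annotate.call_direct_targets(groups, tf_peaks, table)
    true_targets = set(
        truth.tables["expression"].query("is_target")["gene"]
    )
    jac = len(called & true_targets) / len(called | true_targets)
    return {"jaccard": jac, "n_called": len(called), "n_true": len(true_targets)}


def null_deg_fraction(seed: int, n_genes: int = 2000) -> dict:
    """DEG fraction under a no-effect simulation, with the binomial 99% band."""
    table, _ = simulate.make_expression_table(
        n_genes, 0, null_sd=0.0, nonexpressed_frac=0.0, seed=seed
    )
    table = annotate.differential_expression_test(table)
    groups = annotate.group_genes(table)
    frac = len(groups.deg) / n_genes
    lo, hi = _stats.binom.ppf([0.005, 0.995], n_genes, 0.05) / n_genes
    return {"deg_fraction": frac, "band_low": float(lo), "band_high": float(hi)}
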