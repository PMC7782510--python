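"""End-to-end analyses: spacing grammar, differential loops, structure.

Each ``run_*`` function takes a :class:`RunConfig`, reads the standard-
format inputs it names, executes the corresponding analysis chain and
writes its tables plus a machine-readable JSON summary and a manifest
(config echo, seeds, input checksums) under the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import core, motifs, annotate, contacts, loops as loops_mod

logger = logging.getLogger("loopgrammar")

__all__ = [
    "RunConfig",
    "run_spacing_analysis",
    "run_loop_analysis",
    "run_structure_analysis",
]


@dataclass
class RunConfig:
    """Paths and stage parameters for one pipeline run."""

    outdir: str = "out"
    # spacing
    genome: str | None = None
    pwm_a: str | None = None
    pwm_b: str | None = None
    window: int = 2000
    threshold: float = 0.8
    permutations: int = 0
    seed: int = 1
    # annotation
    h3k27ac: str | None = None
    tss: str | None = None
    tf_peaks: str | None = None
    expression: str | None = None
    promoter_distance: int = 1000
    p_threshold: float = 0.05
    expressed_floor: float = 1.0
    # contacts / loops
    contacts_a: str | None = None
    contacts_b: str | None = None
    loops: str | None = None
    binsize: int = 5000
    fc_threshold: float = 1.5
    apa_flank_bins: int = 10
    insulation_window_bins: int = 20
    delta_window_bins: int = 10
    boundary_strength_min: float = 0.1
    sign_track: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _write_manifest(config: RunConfig, stage: str, inputs: list[str]) -> None:
    manifest = {
        "stage": stage,
        "config": asdict(config),
        "inputs": {p: _checksum(p) for p in inputs if p and os.path.exists(p)},
    }
    with open(os.path.join(config.outdir, f"manifest_{stage}.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _hist_to_tsv(hist: motifs.SpacingHistogram, path) -> None:
    pd.DataFrame({"distance": hist.distances, "count": hist.counts}).to_csv(
        path, sep="\t", index=False
    )


def histogram_is_flat(hist: motifs.SpacingHistogram, max_ratio: float = 5.0) -> bool:
    """True when no 1-bp bin exceeds ``max_ratio`` times the mean bin count."""
    mean = hist.counts.mean()
    return bool(mean == 0 or hist.counts.max() <= max_ratio * mean)


def run_spacing_analysis(config: RunConfig) -> dict:
    """Motif scanning, spacing histogram, orientation table, permuted nulls."""
    os.makedirs(config.outdir, exist_ok=True)
    genome = core.read_genome(config.genome)
    pwm_a = motifs.load_pwm(config.pwm_a)
    pwm_b = motifs.load_pwm(config.pwm_b)
    matches_a = motifs.scan_genome(pwm_a, genome, config.threshold)
    matches_b = motifs.scan_genome(pwm_b, genome, config.threshold)
    for name, mm in (("matches_a", matches_a), ("matches_b", matches_b)):
        core.write_intervals(
            [m_.interval for m_ in mm], os.path.join(config.outdir, f"{name}.bed")
        )
    hist, pairs = motifs.pair_spacing(matches_a, matches_b, config.window)
    _hist_to_tsv(hist, os.path.join(config.outdir, "spacing_signed.tsv"))
    absd, folded = hist.abs_counts()
    pd.DataFrame({"distance": absd, "count": folded}).to_csv(
        os.path.join(config.outdir, "spacing_abs.tsv"), sep="\t", index=False
    )
    summary = motifs.spacing_summary(hist) if hist.total else {}
    mode = summary.get("modal_distance")
    mode_pairs = [p for p in pairs if abs(p.gap) == mode] if mode is not None else []
    table = motifs.orientation_table(mode_pairs)
    null_flat = []
    for k in range(1, config.permutations + 1):
        perm = motifs.permute_pwm(pwm_a, config.seed + k)
        perm_matches = motifs.scan_genome(perm, genome, config.threshold)
        null_hist, _ = motifs.pair_spacing(perm_matches, matches_b, config.window)
        _hist_to_tsv(null_hist, os.path.join(config.outdir, f"spacing_null_{k}.tsv"))
        null_flat.append(histogram_is_flat(null_hist))
    report = {
        "n_matches_a": len(matches_a),
        "n_matches_b": len(matches_b),
        **summary,
        "orientation_at_mode": {
            "convergent": table.convergent,
            "divergent": table.divergent,
            "F-F": table.forward_forward,
            "R-R": table.reverse_reverse,
        },
        "orientation_pct_at_mode": table.percentages(),
        "null_histograms_flat": null_flat,
    }
    with open(os.path.join(config.outdir, "spacing_summary.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    _write_manifest(config, "spacing", [config.genome, config.pwm_a, config.pwm_b])
    return report


def _load_annotation(config: RunConfig):
    k27 = annotate.PeakSet(core.read_intervals(config.h3k27ac), "H3K27ac")
    tss = core.read_intervals(config.tss)
    return annotate.call_promoters_enhancers(k27, tss, config.promoter_distance)


def run_loop_analysis(config: RunConfig) -> dict:
    """Differential loop classes, anchor annotation, convergence, APA."""
    os.makedirs(config.outdir, exist_ok=True)
    m1 = contacts.load_contacts(config.contacts_a, config.binsize)
    m2 = contacts.load_contacts(config.contacts_b, config.binsize)
    contacts.balance_matrix(m1)
    contacts.balance_matrix(m2)
    loop_list = [
        loops_mod.Loop(a, b) for a, b in core.read_bedpe(config.loops)
    ]
    loops_mod.quantify_loops(m1, m2, loop_list)
    class_counts = loops_mod.classify_differential(loop_list, config.fc_threshold)
    report: dict = {"classes": class_counts}
    if config.h3k27ac and config.tss:
        annotation = _load_annotation(config)
        fractions = loops_mod.annotate_loops(loop_list, annotation)
        report["category_fractions"] = fractions
    if config.pwm_a:
        genome = core.read_genome(config.genome)
        pwm = motifs.load_pwm(config.pwm_a)
        matches = motifs.scan_genome(pwm, genome, config.threshold)
        loops_mod.find_anchor_motifs(loop_list, matches)
        report["convergent_fraction"] = float(
            np.mean([bool(lp.convergent) for lp in loop_list])
        )
        if config.sign_track:
            # mean ChIP signal around anchor motifs, per differential class
            track = core.read_bedgraph(
                config.sign_track, core.read_genome(config.genome).lengths
            )
            profiles = {}
            for klass in (loops_mod.DECREASED, loops_mod.UNCHANGED, loops_mod.INCREASED):
                refs = [
                    lp.motif1.interval
                    for lp in loop_list
                    if lp.klass == klass and lp.motif1 is not None
                ] + [
                    lp.motif2.interval
                    for lp in loop_list
                    if lp.klass == klass and lp.motif2 is not None
                ]
                if refs:
                    agg = core.aggregate_signal_matrix(track, refs, 2000, 100)
                    if agg.matrix.size:
                        profiles[klass] = float(agg.mean_profile.max())
            report["anchor_motif_signal_peak"] = profiles
    apa_scores = {}
    for klass in (loops_mod.DECREASED, loops_mod.UNCHANGED, loops_mod.INCREASED):
        subset = [lp for lp in loop_list if lp.klass == klass]
        if len(subset) >= 5:
            apa_scores[klass] = {
                "cond1": loops_mod.aggregate_peak_analysis(
                    m1, subset, config.apa_flank_bins
                ).score,
                "cond2": loops_mod.aggregate_peak_analysis(
                    m2, subset, config.apa_flank_bins
                ).score,
            }
    report["apa_by_class"] = apa_scores
    extra = [
        (f"{lp.intensity1:.4f}", f"{lp.intensity2:.4f}", f"{lp.log2fc:.4f}",
         lp.klass, lp.category or ".",
         lp.motif1.strand if lp.motif1 else ".",
         lp.motif2.strand if lp.motif2 else ".",
         str(bool(lp.convergent)))
        for lp in loop_list
    ]
    core.write_bedpe(
        [(lp.anchor1, lp.anchor2) for lp in loop_list],
        os.path.join(config.outdir, "loops_classified.bedpe"),
        extra=extra,
    )
    with open(os.path.join(config.outdir, "loops_summary.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    _write_manifest(
        config, "loops", [config.contacts_a, config.contacts_b, config.loops]
    )
    return report


def run_structure_analysis(config: RunConfig) -> dict:
    """Compartments, insulation and boundaries for two conditions."""
    os.makedirs(config.outdir, exist_ok=True)
    m1 = contacts.load_contacts(config.contacts_a, config.binsize)
    m2 = contacts.load_contacts(config.contacts_b, config.binsize)
    report: dict = {}
    profiles, boundary_sets = [], []
    for tag, m in (("cond1", m1), ("cond2", m2)):
        contacts.balance_matrix(m)
        ins = contacts.insulation_profile(m, config.insulation_window_bins)
        bounds = contacts.call_boundaries(
            ins, config.delta_window_bins, config.boundary_strength_min
        )
        profiles.append(ins)
        boundary_sets.append(bounds)
        core.write_intervals(
            [b.interval for b in bounds],
            os.path.join(config.outdir, f"boundaries_{tag}.bed"),
        )
        pd.DataFrame(
            {"bin": np.arange(ins.n_bins), "insulation": ins.score}
        ).to_csv(
            os.path.join(config.outdir, f"insulation_{tag}.tsv"), sep="\t", index=False
        )
        report[f"n_boundaries_{tag}"] = len(bounds)
    if config.sign_track:
        lengths = {m1.chrom: m1.n_bins * m1.binsize}
        track = core.read_bedgraph(config.sign_track, lengths)
        evs = []
        for m in (m1, m2):
            oe = contacts.observed_over_expected(m)
            prof = contacts.compartment_eigenvector(oe, track, m.chrom, m.binsize)
            evs.append(prof.eigenvector)
        both = np.isfinite(evs[0]) & np.isfinite(evs[1])
        report["eigenvector_correlation"] = float(
            np.corrcoef(evs[0][both], evs[1][both])[0, 1]
        )
    ins1, ins2 = profiles
    both = ~ins1.masked & ~ins2.masked
    report["insulation_correlation"] = float(
        np.corrcoef(ins1.score[both], ins2.score[both])[0, 1]
    )
    with open(os.path.join(config.outdir, "structure_summary.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    _write_manifest(config, "structure", [config.contacts_a, config.contacts_b])
    return report
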