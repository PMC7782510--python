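# loopgrammar

Analytics for a transcription-factor spacing grammar and its role in
chromatin looping. The package implements, as a tested reusable
pipeline, the computational chain behind a regulatory-genomics
observation in murine hematopoietic stem and progenitor cells: ZNF143
and CTCF binding motifs co-occur genome-wide at a fixed, convergent
spacing, and loss of ZNF143 disrupts CTCF-bound promoter–enhancer loops
while leaving TADs and A/B compartments essentially intact.

It is written for computational genomicists who want each analysis step
as an importable, seedable function — with synthetic-data generators
that carry ground truth, so every recovery claim is testable end to end
without any external dataset.

## What it computes

**Motif spacing grammar.** A motif is a position weight matrix
*P ∈ ℝ^{4×W}* scored against background *b* as summed log-odds
`S(x) = Σ_j log2(P[x_j, j] / b[x_j])` (bits). `scan_genome` reports every
window on either strand with `S ≥ f·S_max` (default *f* = 0.8 of the
maximum attainable score). For each query-motif instance the signed
edge-to-edge gap to its nearest subject-motif instance is binned at 1 bp
over ±2 kb; the orientation of each pair is one of convergent /
divergent / F-F / R-R. Column-permuted matrices (`permute_pwm`) give a
matched null with identical information content. In the reference data,
10,544 of 17,319 nearby motif pairs (60.88%) sit exactly 37 bp apart and
99.9% of those are convergent — the quantities `spacing_summary` and
`orientation_table` reproduce.

**Regulatory annotation.** H3K27ac peaks within 1 kb of a TSS are active
promoters, the rest active enhancers; peak sets are intersected into
shared / A-only / B-only co-binding classes; genes are grouped into DEG
/ un-DEG / non-expressed from a per-gene two-sample t-test on
log-transformed replicates, and *direct targets* are DEGs whose
promoter window carries a TF peak.

**Contact-map analytics.** Binned intra-chromosomal maps are balanced by
iterative correction to per-bin weights *w* with `w_i w_j c_ij` having
uniform row sums; the distance-decay expectation gives O/E ratios; the
compartment profile is the leading eigenvector of the O/E correlation
matrix, signed by an active-chromatin track; the insulation score
`log2(mean contacts in the w×w off-diagonal square at bin i / chromosome
mean)` yields boundaries at upward zero crossings of its delta vector.

**Loops.** Per-loop intensity is the balanced, depth-normalized count at
the loop pixel; the differential rule is a plain ±1.5-fold threshold
with a small pseudocount; anchors are annotated as promoter/enhancer to
name P-E / P-P / E-E loops and searched for motif matches to flag the
convergent CTCF arrangement; aggregate peak analysis (APA) averages O/E
submatrices over loops and scores center vs corner enrichment.

## Worked example

```bash
python examples/spacing_grammar.py
```

prints (seeded, deterministic):

```
motif matches: 325 query, 300 subject
modal |spacing|: 37 bp (300 pairs, 99.67% of pairs within 100 bp)
orientation at the mode: {'convergent': 100.0, 'divergent': 0.0, 'F-F': 0.0, 'R-R': 0.0}
```

i.e. on a 2-Mb synthetic genome carrying 300 planted convergent pairs at
a 37-bp gap plus sparse background instances, scanning both motifs and
pairing each query with its nearest subject recovers the planted mode
exactly, and every modal pair is convergent. The other examples
(`structure_analysis.py`, `differential_loops.py`, `direct_targets.py`)
demonstrate boundary/compartment recovery, the 1.5-fold differential
loop rule with APA, and expression–binding integration the same way.

A thin CLI wraps the pipeline stages:

```bash
loopgrammar simulate --kind loops --seed 1 --out sim/
loopgrammar loops --contacts-a sim/contacts_cond1.tsv --contacts-b sim/contacts_cond2.tsv \
    --loops sim/loops.bedpe --binsize 5000 --out out/
```

## Layout

```
src/loopgrammar/   core, motifs, annotate, contacts, loops, simulate,
                   pipeline, benchmarks, cli
examples/          one narrative script per capability
tests/             unit, property and acceptance suites
docs/methods.md    models, conventions, parameter choices, limitations
```
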