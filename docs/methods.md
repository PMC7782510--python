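# Methods

This note documents the models, conventions and parameter choices in
loopgrammar: what each procedure assumes, which knobs matter, what the
synthetic generators do and do not emulate, and where design decisions
were genuinely open.

## Coordinates and distances

All intervals are 0-based half-open (`[start, end)`, BED convention),
including BEDPE anchors and bedGraph runs. The distance between two
intervals is the edge-to-edge gap, zero on any overlap, signed positive
when the subject lies at higher coordinates than the query. Nearest-
feature ties are broken deterministically toward the lower subject
start, then the lexicographically smaller name. A summit/midpoint
distance mode exists for promoter calling (`use_summit`), but the edge
convention is the default because peak width carries real signal extent.

## Motif model and scanning

A PWM is a 4×W column-stochastic matrix over (A, C, G, T). Count
matrices are converted to probabilities with a pseudocount (default 0.8
per column, split by background); probability matrices get a tiny floor
(1e-4·background) so log-odds stay finite. Scores are summed log2
odds against the background (uniform by default); windows containing N
score −∞.

The scan threshold is a *fraction of the maximum attainable score*
(default 0.8). This is scale-free across motifs of different widths and
information content, which matters when comparing a 14-bp and a 19-bp
motif in the same analysis; an absolute-bits threshold would not
transfer. All windows on both strands are reported, overlapping matches
included — the minus strand scores the reverse complement, implemented
by scanning with the reverse-complemented matrix in a single forward
pass, and verified exactly against per-window brute force in the tests.

Spacing histograms bin the *signed* gap at 1 bp over ±2 kb; the modal
distance is reported on the folded |gap| histogram (ties to the smaller
distance), and both signed and absolute tables are emitted, since
"distance" conventions differ between tools. Self-pairs are excluded
only when query and subject share interval, strand *and* motif name, so
a motif can be analysed against itself. The headline share statistic is
`100 × (pairs at the modal |distance|) / (pairs within 100 bp)`.

Orientation is defined positionally: on opposite strands the pair is
convergent when the (+) match has the lower genomic coordinate (the two
motifs point at each other), divergent otherwise; same-strand pairs are
F-F or R-R. The classification is invariant to argument order. An
alternative convention — orientation relative to the query→subject
order rather than the genome — exists in the wild; the positional rule
was chosen because it is the one under which the convergent class is
the loop-extrusion-compatible arrangement of CTCF sites.

The permutation null shuffles PWM columns with a seeded permutation,
preserving the column multiset and total information content. A
histogram is called flat when no 1-bp bin exceeds 5× the mean bin count
over the window.

## Regulatory annotation and expression

Active promoters are H3K27ac peaks whose nearest TSS lies within
1000 bp (inclusive) of the peak edge; all other H3K27ac peaks are
active enhancers — the two classes partition the peak set by
construction. Co-binding uses ≥1 bp overlap.

The per-gene test is a two-sample t-test on log2(x+1) replicate values
with **pooled variance** by default. The pooled choice is deliberate:
shared-dispersion count models (the standard for RNA-seq) estimate one
dispersion per gene across conditions, and at n = 3 replicates the
pooled t holds its nominal size while the Welch variant is markedly
conservative (true size ≈3.4% at α = 5%, measured by simulation);
Welch remains available via `pooled_variance=False`. Raw p-values are
used at p < 0.05 by default, with an optional Benjamini–Hochberg
switch, because the headline DEG definition in this analysis family is
a raw-p threshold. "Non-expressed" means mean expression below 1 unit
in both conditions; the floor is configurable since no universal
definition exists.

Direct targets are DEGs with a TF peak overlapping the TSS ± 1 kb
window. This is a documented surrogate for a promoter-enrichment
criterion that cannot be reconstructed exactly; an optional minimum
peak score tightens it.

## Contact-map analytics

Balancing uses iterative proportional correction to the row-sum
contract: weights `w` such that `w_i w_j c_ij` has uniform row sums
over unmasked bins (convergence when the coefficient of variation drops
below 1e-5; bins with zero marginal are masked). Any balancing scheme
meeting the contract is interchangeable here. Weights are rescaled so
the balanced matrix preserves the raw total: balancing removes bias,
not sequencing depth — depth is handled downstream by per-million
normalization, and normalizing twice would invert the depth dependence.

The expected model is the mean balanced count per bin separation;
O/E divides by it, with 0/0 at empty far diagonals treated as
no-information (NaN) rather than an error. The compartment profile is
the leading eigenvector of the Pearson-correlation matrix of O/E
columns over unmasked bins, unit-normalized. Its sign is fixed by
covariance with an active-chromatin track (positive = A): covariance
rather than an above-median split, because the median split degenerates
when more than half the bins share the top coverage value.

Insulation at bin i is the mean balanced count in the off-diagonal
square `{i−w..i−1} × {i+1..i+w}` (default w = 20 bins, i.e. 500 kb at
25-kb resolution), log2-normalized by the chromosome mean; bins within
w of either end are masked rather than given a shrunken window, so all
scores have equal support. Boundaries sit at negative-to-positive zero
crossings of the delta vector (mean score over the next d bins minus
the previous d, default d = 10), kept when the local strength
(max delta after − min delta before) reaches 0.1. Boundary count is
monotone non-increasing in the strength threshold. Note that a
compartment flip is itself an insulating transition and is legitimately
called as a boundary.

## Loops and APA

Loop intensity is the mean balanced count over the (2·pad+1)² block at
the loop pixel (pad 0 by default — padding dilutes single-pixel
signal), scaled to contacts per million. The differential rule is
`FC = (I₂+ε)/(I₁+ε)` with increased at FC ≥ 1.5 and decreased at
FC ≤ 1/1.5. The pseudocount ε defaults to one tenth of the median
nonzero loop intensity: an ε tied to a low quantile of the loop
intensities themselves (an earlier candidate) equals or exceeds the
intensity of the weakest quartile of loops whenever loop separations
span a realistic range, and silently caps their measurable fold change
below the 1.5× threshold; a small fraction of the median damps empty
pixels without biasing any measured loop.

APA averages O/E submatrices (±10 bins, i.e. a 105-kb window at 5-kb
resolution) over loops whose window fits inside the matrix and off the
diagonal; the score is the center value over the mean of the lower-left
corner block of ⌊flank/2⌋² pixels — background at comparable distance.
APA is invariant to global matrix scaling by construction.

## Synthetic data generators

Every generator is a pure function of its parameters and seed, and
serializes its ground truth to TSV. What they emulate, and what not:

- **Genomes** are i.i.d. base draws at GC 0.42 (mouse-like). No repeats,
  no CpG islands, no composition heterogeneity — so background motif
  match rates are lower and cleaner than in a real genome. Planted motif
  instances default to the consensus sequence so scanner recovery is
  deterministic; uniformly placed "background" instances stand in for
  the genome-wide occurrence rate a 2.7-Gb genome would supply. Planted
  pairs keep a 200-bp margin from each other so each query's nearest
  subject is its own partner.
- **Peak landscapes** lay out evenly spaced TSSs with jitter, H3K27ac
  peaks over promoters and at 5–20-kb distal sites, TF sites per
  co-binding rule, and stranded 36-bp reads with per-peak enrichment
  over uniform background. Real peak-width and signal-shape variation is
  not modeled.
- **Expression tables** use log-normal base expression (log2 mean 5,
  sd 1.5), per-gene log2 fold changes (targets ~ N(−1, 0.3), others ~
  N(0, 0.25)), and multiplicative replicate noise (sd 0.15 on log2).
  The N(0, 0.25) spread for non-targets models biological variability
  and is *not* a null; type-I checks set it to zero. The direct-target
  truth plants TF peaks exactly on target promoters (plus silent
  non-expressed promoters and distal sites), because "direct target" is
  by definition the bound-and-perturbed gene set.
- **Contact maps** draw `count_ij ~ Poisson(N·(1+|i−j|)^−α · T·L·C·
  b_i b_j)` with TAD factor T = 3 inside shared segments, loop
  enrichment L = 3 at planted pixels, compartment factor 1.3 for
  same-label bins, log-normal biases (sd 0.2) and α = 1. Depths default
  to 1e7 (25-kb structure maps, 1000 bins) and 2e7 (5-kb loop maps over
  5 Mb), chosen by Poisson power reasoning so loop pixels carry an
  expected count ≳30 and a 1.5-fold rule is limited by the effect, not
  shot noise. Fragment-level Hi-C artifacts (restriction sites,
  religation, trans contacts) are not simulated.

Because the generators are idealized, passing recovery tests
demonstrates correctness of the computations and their conventions —
not robustness to repeat-driven false motif matches, peak-calling
noise, or mapping artifacts in real data.

## Benchmark fixture choices

The balancing-recovery benchmark uses a flat-decay (α = 0) bias-only
matrix: with distance decay the *unbiased* matrix already has unequal
row sums near chromosome ends, so the row-sum contract lawfully folds
that structure into the weights and the log-weight/log-bias correlation
saturates near 0.97; the flat fixture isolates the bias-recovery claim
(r ≥ 0.999 observed). The APA benchmark plants loops on a map without
TADs or compartments so corner pixels are a clean background. The
permuted-motif flatness benchmark plants ~85,000 null-motif instances
and 1,000 subject instances uniformly on 20 Mb, sized so the expected
count per 1-bp bin (~5) makes the 5×-mean flatness bound statistically
meaningful; subject spacing (~20 kb) keeps the nearest-distance
distribution approximately uniform across the ±2-kb window.

## Known limitations

- Only intra-chromosomal contacts; no `.hic`/`.cool` binary parsing
  (bin-pair TSV and Matrix-Market-style text only), no loop or TAD
  *calling* beyond insulation boundaries — loops are inputs.
- The insulation caller's correspondence to corner-score TAD callers is
  not claimed; boundary counts are parameter-dependent.
- PWM match significance is threshold-based; no p-value calibration
  against higher-order background models.
- The per-gene t-test is a light surrogate for count-based differential
  models; it requires replicates and ignores mean–variance coupling.
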