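"""Binned Hi-C contact maps: balancing, O/E, compartments, insulation.

A :class:`ContactMatrix` holds intra-chromosomal contacts binned at a
fixed resolution, stored upper-triangular. Balancing assigns per-bin
weights w such that w_i w_j c_ij has uniform row sums, removing
multiplicative bin biases; iterative proportional correction is used,
which satisfies the same row-sum contract as Knight-Ruiz. On the
balanced map the pipeline derives the distance-decay expected model,
observed/expected ratios, the compartment eigenvector (leading
eigenvector of the O/E Pearson-correlation matrix, signed by an active
mark), and the insulation score whose minima mark domain boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Interval, SignalTrack, FormatError

__all__ = [
    "ContactMatrix",
    "InsulationProfile",
    "CompartmentProfile",
    "Boundary",
    "load_contacts",
    "write_contacts",
    "balance_matrix",
    "expected_by_distance",
    "observed_over_expected",
    "compartment_eigenvector",
    "insulation_profile",
    "call_boundaries",
]


class BalanceError(RuntimeError):
    pass


@dataclass
class ContactMatrix:
    """Sparse upper-triangular intra-chromosomal contact map."""

    chrom: str
    binsize: int
    n_bins: int
    # parallel arrays of upper-triangular cells (i <= j)
    bin1: np.ndarray
    bin2: np.ndarray
    count: np.ndarray
    weights: np.ndarray | None = None  # per-bin balancing weights; NaN = masked

    def __post_init__(self) -> None:
        if np.any(self.bin1 > self.bin2):
            raise ValueError("cells must be upper-triangular (i <= j)")
        if np.any(self.count < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.count.sum())

    def dense(self, balanced: bool = False) -> np.ndarray:
        """Symmetric dense matrix; balanced cells are w_i w_j c_ij."""
        m = np.zeros((self.n_bins, self.n_bins))
        m[self.bin1, self.bin2] = self.count
        m[self.bin2, self.bin1] = self.count
        if balanced:
            if self.weights is None:
                raise ValueError("matrix has no balancing weights; run balance_matrix")
            w = self.weights
            m = m * np.outer(w, w)  # NaN weights propagate to masked rows/cols
        return m

    def mask(self) -> np.ndarray:
        """Boolean array, True for masked (unbalanceable) bins."""
        if self.weights is None:
            marg = np.zeros(self.n_bins)
            np.add.at(marg, self.bin1, self.count)
            np.add.at(marg, self.bin2, self.count)
            return marg == 0
        return ~np.isfinite(self.weights)

    def scaled(self, factor: float) -> "ContactMatrix":
        return ContactMatrix(
            self.chrom, self.binsize, self.n_bins,
            self.bin1.copy(), self.bin2.copy(), self.count * factor,
            None if self.weights is None else self.weights.copy(),
        )

    @classmethod
    def from_dense(cls, chrom: str, binsize: int, dense: np.ndarray) -> "ContactMatrix":
        n = dense.shape[0]
        iu = np.triu_indices(n)
        vals = dense[iu]
        nz = vals != 0
        return cls(chrom, binsize, n, iu[0][nz], iu[1][nz], vals[nz].astype(float))


@dataclass
class Boundary:
    """An insulation boundary: a 1-bin interval with a strength."""

    bin: int
    interval: Interval
    strength: float


@dataclass
class InsulationProfile:
    chrom: str
    binsize: int
    score: np.ndarray  # log2 insulation per bin; NaN on masked bins
    masked: np.ndarray  # bool

    @property
    def n_bins(self) -> int:
        return self.score.size


@dataclass
class CompartmentProfile:
    chrom: str
    binsize: int
    eigenvector: np.ndarray  # unit norm; NaN on masked bins

    def sign_labels(self) -> np.ndarray:
        """+1 for A (positive), -1 for B, 0 for masked bins."""
        out = np.zeros(self.eigenvector.size, dtype=int)
        finite = np.isfinite(self.eigenvector)
        out[finite] = np.sign(self.eigenvector[finite]).astype(int)
        return out


# ---------------------------------------------------------------------------
# I/O: bin-pair TSV "chrom start_i start_j count"


def load_contacts(path, binsize: int) -> ContactMatrix:
    cells: dict[tuple[int, int], float] = {}
    chrom = None
    max_bin = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            c, s1, s2, cnt = line.split("\t")
            if chrom is None:
                chrom = c
            elif c != chrom:
                raise FormatError(f"line {lineno}: multiple chromosomes in one matrix file")
            s1, s2 = int(s1), int(s2)
            if s1 % binsize or s2 % binsize:
                raise FormatError(
                    f"line {lineno}: start not a multiple of bin size {binsize}"
                )
            i, j = sorted((s1 // binsize, s2 // binsize))
            cells[(i, j)] = cells.get((i, j), 0.0) + float(cnt)
            max_bin = max(max_bin, j)
    if chrom is None:
        raise FormatError(f"empty contact file {path}")
    keys = sorted(cells)
    b1 = np.array([k[0] for k in keys])
    b2 = np.array([k[1] for k in keys])
    cnt = np.array([cells[k] for k in keys])
    return ContactMatrix(chrom, binsize, max_bin + 1, b1, b2, cnt)


def write_contacts(m: ContactMatrix, path) -> None:
    with open(path, "w") as fh:
        for i, j, c in zip(m.bin1, m.bin2, m.count):
            fh.write(f"{m.chrom}\t{i * m.binsize}\t{j * m.binsize}\t{c:g}\n")


# ---------------------------------------------------------------------------
# Balancing (iterative proportional correction)


def balance_matrix(
    m: ContactMatrix, tol: float = 1e-5, max_iter: int = 200
) -> np.ndarray:
    """Compute per-bin weights equalizing row sums of w_i w_j c_ij.

    Bins with zero marginal are masked (weight NaN). Convergence is
    declared when the coefficient of variation of unmasked row sums
    drops below ``tol``; weights are then rescaled so the balanced
    matrix preserves the raw total count — balancing flattens biases
    without changing sequencing depth, which downstream per-million
    normalization handles. Raises :class:`BalanceError` with iteration
    diagnostics when ``max_iter`` is exhausted.
    """
    if m.count.size == 0:
        raise ValueError("empty matrix")
    dense = m.dense()
    marg = dense.sum(axis=1)
    masked = marg == 0
    active = ~masked
    if not active.any():
        raise BalanceError("all bins masked")
    w = np.ones(m.n_bins)
    sub = dense[np.ix_(active, active)]
    ws = np.ones(active.sum())
    cv = np.inf
    for it in range(max_iter):
        rows = (sub * np.outer(ws, ws)).sum(axis=1)
        cv = rows.std() / rows.mean()
        if cv < tol:
            break
        ws = ws / np.sqrt(rows / rows.mean())
    else:
        raise BalanceError(
            f"no convergence after {max_iter} iterations (row-sum CV {cv:.3g})"
        )
    balanced_total = (sub * np.outer(ws, ws)).sum()
    ws = ws * np.sqrt(dense.sum() / balanced_total)
    w[:] = np.nan
    w[active] = ws
    m.weights = w
    return w


# ---------------------------------------------------------------------------
# Expected model and O/E


def expected_by_distance(m: ContactMatrix, balanced: bool = True) -> np.ndarray:
    """Mean (balanced) count over all unmasked bin pairs at each separation."""
    dense = m.dense(balanced=balanced)
    masked = m.mask()
    dense[masked, :] = np.nan
    dense[:, masked] = np.nan
    n = m.n_bins
    expected = np.empty(n)
    for s in range(n):
        diag = np.diagonal(dense, offset=s)
        expected[s] = np.nanmean(diag) if np.isfinite(diag).any() else np.nan
    return expected


def observed_over_expected(
    m: ContactMatrix, decay: np.ndarray | None = None, balanced: bool = True
) -> np.ndarray:
    """Dense O/E matrix; masked bins propagate as NaN."""
    if decay is None:
        decay = expected_by_distance(m, balanced=balanced)
    dense = m.dense(balanced=balanced)
    n = m.n_bins
    seps = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    exp = decay[seps]
    used = np.isfinite(dense)
    if np.any((exp == 0) & used & (dense > 0)):
        raise ZeroDivisionError("zero expected value at a used distance")
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = dense / exp  # 0/0 diagonals carry no information -> NaN
    masked = m.mask()
    oe[masked, :] = np.nan
    oe[:, masked] = np.nan
    return oe


# ---------------------------------------------------------------------------
# Compartments


def compartment_eigenvector(
    oe: np.ndarray, sign_track: SignalTrack, chrom: str, binsize: int
) -> CompartmentProfile:
    """Leading eigenvector of the O/E Pearson-correlation matrix.

    The sign convention follows the active-chromatin track: the vector is
    flipped, if needed, so its covariance with per-bin track coverage is
    positive, i.e. active bins sit on the positive (A) side. Covariance
    is used rather than an above-median split, which degenerates when
    more than half the bins share the top coverage value.
    """
    n = oe.shape[0]
    unmasked = np.isfinite(oe).any(axis=1)
    if unmasked.sum() < 10:
        raise ValueError("need >= 10 unmasked bins")
    sub = oe[np.ix_(unmasked, unmasked)]
    # pairwise-complete Pearson correlation of columns
    dfm = sub - np.nanmean(sub, axis=0)
    dfm = np.where(np.isfinite(dfm), dfm, 0.0)
    norms = np.sqrt((dfm**2).sum(axis=0))
    if np.any(norms == 0):
        raise ValueError("degenerate correlation matrix (constant O/E column)")
    corr = (dfm.T @ dfm) / np.outer(norms, norms)
    vals, vecs = np.linalg.eigh(corr)
    ev = vecs[:, -1]
    ev = ev / np.linalg.norm(ev)
    full = np.full(n, np.nan)
    full[unmasked] = ev
    # orient by the sign track: active bins positive
    cov = sign_track.values[chrom]
    nbins_cov = min(n, cov.size // binsize)
    bin_cov = cov[: nbins_cov * binsize].reshape(nbins_cov, binsize).mean(axis=1)
    bin_cov = np.pad(bin_cov, (0, n - nbins_cov), constant_values=0.0)
    ok = unmasked & np.isfinite(full)
    centered = bin_cov[ok] - bin_cov[ok].mean()
    if float(full[ok] @ centered) < 0:
        full = -full
    return CompartmentProfile(chrom, binsize, full)


# ---------------------------------------------------------------------------
# Insulation


def insulation_profile(m: ContactMatrix, window_bins: int = 20) -> InsulationProfile:
    """Log2 insulation score per bin.

    The raw score at bin i is the mean balanced count over the square
    {i-w..i-1} x {i+1..i+w}; the final score is log2 of raw over the
    chromosome mean of raw. Bins within ``window_bins`` of either end,
    and masked bins, get NaN.
    """
    n = m.n_bins
    if n < 2 * window_bins + 1:
        raise ValueError("chromosome too short for the insulation window")
    dense = m.dense(balanced=m.weights is not None)
    masked_bins = m.mask()
    raw = np.full(n, np.nan)
    w = window_bins
    for i in range(w, n - w):
        if masked_bins[i]:
            continue
        block = dense[i - w : i, i + 1 : i + w + 1]
        if np.isfinite(block).any():
            raw[i] = np.nanmean(block)
    valid = np.isfinite(raw) & (raw > 0)
    if not valid.any():
        raise ValueError("all bins masked; cannot compute insulation")
    mean_raw = raw[valid].mean()
    score = np.full(n, np.nan)
    score[valid] = np.log2(raw[valid] / mean_raw)
    return InsulationProfile(m.chrom, m.binsize, score, ~valid)


def call_boundaries(
    ins: InsulationProfile,
    delta_window_bins: int = 10,
    strength_min: float = 0.1,
) -> list[Boundary]:
    """Boundaries at negative-to-positive zero crossings of the delta vector.

    delta_i = mean score over (i+1 .. i+dw) minus mean over (i-dw .. i-1);
    it crosses zero upward at insulation minima. A crossing is kept when
    its local strength, max delta in the following window minus min delta
    in the preceding window, reaches ``strength_min``.
    """
    score = ins.score
    n = score.size
    dw = delta_window_bins
    delta = np.full(n, np.nan)
    for i in range(n):
        right = score[i + 1 : i + dw + 1]
        left = score[max(0, i - dw) : i]
        if np.isfinite(right).any() and np.isfinite(left).any():
            delta[i] = np.nanmean(right) - np.nanmean(left)
    out: list[Boundary] = []
    for i in range(n - 1):
        if not (np.isfinite(delta[i]) and np.isfinite(delta[i + 1])):
            continue
        if delta[i] < 0 <= delta[i + 1]:
            after = delta[i + 1 : i + 1 + dw]
            before = delta[max(0, i - dw + 1) : i + 1]
            if not (np.isfinite(after).any() and np.isfinite(before).any()):
                continue
            strength = np.nanmax(after) - np.nanmin(before)
            if strength >= strength_min:
                b = i + 1
                out.append(
                    Boundary(
                        b,
                        Interval(
                            ins.chrom, b * ins.binsize, (b + 1) * ins.binsize,
                            name=f"boundary_{b}", score=float(strength),
                        ),
                        float(strength),
                    )
                )
    return out
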