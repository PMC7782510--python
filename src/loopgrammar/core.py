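"""Genomic primitives: intervals, sequences, coverage tracks, aggregation.

Coordinate convention is BED-native throughout: 0-based, half-open
``[start, end)``. Distances between intervals are edge-to-edge gaps with
overlap counting as zero; the sign is positive when the subject lies
downstream (higher coordinates) of the query.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRANDS = ("+", "-", ".")

__all__ = [
    "Interval",
    "GenomeSequence",
    "SignalTrack",
    "AggregateMatrix",
    "FormatError",
    "read_genome",
    "write_genome",
    "read_intervals",
    "write_intervals",
    "read_bedpe",
    "write_bedpe",
    "read_bedgraph",
    "write_bedgraph",
    "signed_gap",
    "nearest_feature",
    "extend_reads",
    "coverage_track",
    "aggregate_signal_matrix",
    "binned_track_correlation",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class Interval:
    """A genomic feature in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class GenomeSequence:
    """Mapping of chromosome name to an uppercase A/C/G/T/N sequence."""

    _ALPHABET = frozenset("ACGTN")

    def __init__(self, sequences: dict[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - self._ALPHABET
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains letters outside ACGTN: {sorted(bad)}"
                )
            self._seqs[name] = seq

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeSequence) and self._seqs == other._seqs

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self._seqs[chrom][start:end]


class SignalTrack:
    """Per-base-pair real-valued coverage over a genome."""

    def __init__(self, values: dict[str, np.ndarray]):
        self.values = {c: np.asarray(v, dtype=float) for c, v in values.items()}

    @property
    def genome_mean(self) -> float:
        total = sum(float(v.sum()) for v in self.values.values())
        nbp = sum(v.size for v in self.values.values())
        return total / nbp

    @property
    def total(self) -> float:
        return sum(float(v.sum()) for v in self.values.values())

    def normalized(self) -> "SignalTrack":
        """Rescale so the genome-wide mean coverage equals 1."""
        mean = self.genome_mean
        if mean == 0:
            raise ValueError("cannot normalize a track with zero total signal")
        return SignalTrack({c: v / mean for c, v in self.values.items()})


@dataclass
class AggregateMatrix:
    """Binned signal around a set of reference points (one row each)."""

    matrix: np.ndarray  # (n_refpoints, 2*flank/binsize)
    refpoints: list[Interval]
    flank: int
    binsize: int
    n_dropped: int = 0

    @property
    def mean_profile(self) -> np.ndarray:
        return self.matrix.mean(axis=0)


# ---------------------------------------------------------------------------
# I/O


def read_genome(path) -> GenomeSequence:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate chromosome name {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise FormatError(f"no FASTA records in {path}")
    return GenomeSequence(seqs)


def write_genome(genome: GenomeSequence, path) -> None:
    recs = [
        SeqRecord(Seq(genome[c]), id=c, description="") for c in genome.chroms
    ]
    SeqIO.write(recs, str(path), "fasta")


def _parse_bed_fields(fields: list[str], lineno: int) -> Interval:
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    if start >= end:
        raise FormatError(f"line {lineno}: start >= end ({start} >= {end})")
    name = fields[3] if len(fields) > 3 else "."
    score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
    strand = fields[5] if len(fields) > 5 else "."
    return Interval(chrom, start, end, strand=strand, name=name, score=score)


def read_intervals(path) -> list[Interval]:
    """Read a BED3/BED6 file. Empty files yield an empty list."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: BED needs >= 3 columns")
            out.append(_parse_bed_fields(fields, lineno))
    return out


def write_intervals(intervals: list[Interval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


def read_bedpe(path) -> list[tuple[Interval, Interval]]:
    """Read BEDPE anchor pairs (6+ tab-separated columns)."""
    out: list[tuple[Interval, Interval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"line {lineno}: BEDPE needs >= 6 columns")
            a = _parse_bed_fields([f[0], f[1], f[2]], lineno)
            b = _parse_bed_fields([f[3], f[4], f[5]], lineno)
            if len(f) > 6:
                a = replace(a, name=f[6])
                b = replace(b, name=f[6])
            out.append((a, b))
    return out


def write_bedpe(pairs: list[tuple[Interval, Interval]], path, extra=None) -> None:
    with open(path, "w") as fh:
        for i, (a, b) in enumerate(pairs):
            cols = [a.chrom, a.start, a.end, b.chrom, b.start, b.end, a.name]
            if extra is not None:
                cols.extend(extra[i])
            fh.write("\t".join(str(c) for c in cols) + "\n")


def read_bedgraph(path, lengths: dict[str, int]) -> SignalTrack:
    values = {c: np.zeros(n) for c, n in lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, val = line.split("\t")
            if chrom not in values:
                raise FormatError(f"line {lineno}: unknown chromosome {chrom!r}")
            values[chrom][int(start) : int(end)] = float(val)
    return SignalTrack(values)


def write_bedgraph(track: SignalTrack, path) -> None:
    """Run-length-encode a per-bp track as 4-column bedGraph (zeros skipped)."""
    with open(path, "w") as fh:
        for chrom, vals in track.values.items():
            if vals.size == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vals.size]))
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


# ---------------------------------------------------------------------------
# Interval algebra


def signed_gap(query: Interval, subject: Interval) -> int:
    """Edge-to-edge gap; 0 on overlap, positive when subject is downstream."""
    if subject.start >= query.end:
        return subject.start - query.end
    if subject.end <= query.start:
        return subject.end - query.start  # negative
    return 0


def nearest_feature(
    query: Interval, subjects: list[Interval]
) -> tuple[Interval | None, int | None]:
    """Nearest subject by |edge-to-edge gap|.

    Ties broken toward lower subject start, then lexicographic name.
    Returns ``(None, None)`` when no subject shares the query's chromosome.
    """
    best: Interval | None = None
    best_gap: int | None = None
    for s in subjects:
        if s.chrom != query.chrom:
            continue
        g = signed_gap(query, s)
        if (
            best is None
            or abs(g) < abs(best_gap)
            or (abs(g) == abs(best_gap) and (s.start, s.name) < (best.start, best.name))
        ):
            best, best_gap = s, g
    return best, best_gap


class _NearestIndex:
    """Sorted-array nearest-neighbour index over one subject list.

    Used by the motif pair-spacing scan, which calls nearest for every
    query; agrees with :func:`nearest_feature` (the brute-force contract)
    by resolving ties with the same (start, name) rule.
    """

    def __init__(self, subjects: list[Interval]):
        self.by_chrom: dict[str, list[Interval]] = {}
        for s in subjects:
            self.by_chrom.setdefault(s.chrom, []).append(s)
        self.starts: dict[str, list[int]] = {}
        self.maxlen: dict[str, int] = {}
        for c, lst in self.by_chrom.items():
            lst.sort(key=lambda s: (s.start, s.name))
            self.starts[c] = [s.start for s in lst]
            self.maxlen[c] = max(len(s) for s in lst)

    def nearest(self, query: Interval, exclude=None) -> tuple[Interval | None, int | None]:
        lst = self.by_chrom.get(query.chrom)
        if not lst:
            return None, None
        idx = bisect.bisect_left(self.starts[query.chrom], query.start)
        maxlen = self.maxlen[query.chrom]
        best, best_gap = None, None
        # scan outward; stop once the gap provably exceeds the current best
        for direction in (-1, 1):
            i = idx if direction == 1 else idx - 1
            while 0 <= i < len(lst):
                s = lst[i]
                g = signed_gap(query, s)
                if best is not None:
                    if direction == 1 and g > 0 and g > abs(best_gap):
                        break
                    # leftward: an interval starting further left may still
                    # overlap if long; bound the break by the longest subject
                    if direction == -1 and query.start - s.start - maxlen > abs(best_gap):
                        break
                if exclude is None or not exclude(s):
                    if (
                        best is None
                        or abs(g) < abs(best_gap)
                        or (
                            abs(g) == abs(best_gap)
                            and (s.start, s.name) < (best.start, best.name)
                        )
                    ):
                        best, best_gap = s, g
                i += direction
        return best, best_gap


# ---------------------------------------------------------------------------
# Reads and coverage


def extend_reads(
    reads: list[Interval], genome: GenomeSequence, target_len: int = 150
) -> list[Interval]:
    """Extend each read to ``target_len`` bp from its 5' end.

    Mimics single-end fragment extension: a (+)-strand read keeps its start
    and grows rightward; a (-)-strand read keeps its end and grows leftward;
    strandless reads are treated as (+). Results are clamped to the
    chromosome and reads longer than ``target_len`` are truncated.
    """
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    out = []
    for r in reads:
        if r.chrom not in genome:
            raise ValueError(f"read on unknown chromosome {r.chrom!r}")
        L = genome.lengths[r.chrom]
        if r.strand == "-":
            end = min(r.end, L)
            start = max(0, end - target_len)
        else:
            start = max(0, r.start)
            end = min(start + target_len, L)
        out.append(replace(r, start=start, end=end))
    return out


def coverage_track(
    reads: list[Interval], genome: GenomeSequence, normalize: bool = False
) -> SignalTrack:
    """Per-bp read depth; optionally rescaled to genome-wide mean 1."""
    values = {c: np.zeros(n) for c, n in genome.lengths.items()}
    for r in reads:
        if r.chrom not in values:
            raise ValueError(f"read on unknown chromosome {r.chrom!r}")
        L = values[r.chrom].size
        values[r.chrom][max(0, r.start) : min(r.end, L)] += 1.0
    track = SignalTrack(values)
    if normalize:
        track = track.normalized()
    return track


def aggregate_signal_matrix(
    track: SignalTrack,
    refpoints: list[Interval],
    flank: int,
    binsize: int,
    order_key: list[float] | None = None,
) -> AggregateMatrix:
    """Binned mean signal in ``[mid - flank, mid + flank)`` per reference point.

    Rows for (-)-strand reference points are flipped so the 5'->3' direction
    reads left to right. Reference points whose window leaves the chromosome
    are dropped (and counted). With ``order_key``, rows are sorted in
    descending key order (e.g. expression-ranked heatmaps).
    """
    if flank % binsize != 0:
        raise ValueError("flank must be a multiple of binsize")
    nbins = 2 * flank // binsize
    rows, kept, keys = [], [], []
    dropped = 0
    for i, rp in enumerate(refpoints):
        mid = rp.midpoint
        lo, hi = mid - flank, mid + flank
        vals = track.values.get(rp.chrom)
        if vals is None or lo < 0 or hi > vals.size:
            dropped += 1
            continue
        row = vals[lo:hi].reshape(nbins, binsize).mean(axis=1)
        if rp.strand == "-":
            row = row[::-1]
        rows.append(row)
        kept.append(rp)
        keys.append(order_key[i] if order_key is not None else 0.0)
    mat = np.vstack(rows) if rows else np.empty((0, nbins))
    if order_key is not None and rows:
        order = np.argsort(-np.asarray(keys), kind="stable")
        mat = mat[order]
        kept = [kept[j] for j in order]
    return AggregateMatrix(mat, kept, flank, binsize, n_dropped=dropped)


def binned_track_correlation(
    tracks: list[SignalTrack], binsize: int = 5000
) -> np.ndarray:
    """Pairwise Pearson correlation of tracks binned at ``binsize`` bp.

    Constant tracks (zero variance) yield NaN against every other track.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    chroms = sorted(tracks[0].values)
    binned = []
    for t in tracks:
        if sorted(t.values) != chroms:
            raise ValueError("tracks must share the same genome")
        parts = []
        for c in chroms:
            v = t.values[c]
            nfull = v.size // binsize
            if nfull:
                parts.append(v[: nfull * binsize].reshape(nfull, binsize).mean(axis=1))
        binned.append(np.concatenate(parts))
    X = np.vstack(binned)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    np.fill_diagonal(r, 1.0)
    return r
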