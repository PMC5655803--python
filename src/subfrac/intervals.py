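"""Strand-aware genomic intervals and the interval algebra shared by every stage.

All in-memory coordinates are 0-based half-open (BED convention). GFF3 is
converted at the I/O boundary (start decremented on read, incremented on
write). An :class:`IntervalSet` holds intervals on a single named genome and
supports merging, coverage and overlap queries backed by per-chromosome
sorted numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

import numpy as np

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """Raised when an on-disk record violates its format's contract."""


@dataclass(frozen=True)
class GenomeInterval:
    """A half-open interval ``[start, end)`` on a chromosome of a named genome."""

    genome: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shifted(self, offset: int) -> "GenomeInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


class IntervalSet:
    """An ordered collection of :class:`GenomeInterval` on one genome.

    The set keeps intervals in (chrom, start) order and lazily builds merged
    per-chromosome coverage arrays for fast ``covered_bp`` queries.
    """

    def __init__(self, intervals: Iterable[GenomeInterval] = (), genome: Optional[str] = None):
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        genomes = {iv.genome for iv in ivs}
        if genome is None:
            if len(genomes) > 1:
                raise ValueError(f"intervals span multiple genomes: {sorted(genomes)}")
            genome = next(iter(genomes)) if genomes else ""
        elif genomes - {genome}:
            raise ValueError(f"intervals not on genome {genome!r}: {sorted(genomes - {genome})}")
        self.genome = genome
        self._intervals: List[GenomeInterval] = ivs
        self._coverage: Optional[Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]] = None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomeInterval]:
        return iter(self._intervals)

    def __getitem__(self, i):
        return self._intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self._intervals == other._intervals

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals on {self.genome!r})"

    @property
    def intervals(self) -> List[GenomeInterval]:
        return list(self._intervals)

    def chroms(self) -> List[str]:
        return sorted({iv.chrom for iv in self._intervals})

    def on_chrom(self, chrom: str) -> "IntervalSet":
        return IntervalSet([iv for iv in self._intervals if iv.chrom == chrom], genome=self.genome)

    # -- algebra -------------------------------------------------------------
    def total_bp(self) -> int:
        """Total covered bp (union; overlaps counted once)."""
        total = 0
        for _, (starts, ends, _) in self._merged_arrays().items():
            total += int((ends - starts).sum())
        return total

    def span_bp(self) -> int:
        """Sum of interval lengths (overlaps counted multiply)."""
        return sum(iv.length for iv in self._intervals)

    def merge(self, max_gap: int = 0) -> "IntervalSet":
        return merge_intervals(self, max_gap)

    def _merged_arrays(self) -> Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chrom (starts, ends, cumulative-coverage) of the merged union."""
        if self._coverage is None:
            cov = {}
            merged = merge_intervals(self, 0)
            by_chrom: Dict[str, List[GenomeInterval]] = {}
            for iv in merged:
                by_chrom.setdefault(iv.chrom, []).append(iv)
            for chrom, ivs in by_chrom.items():
                starts = np.array([iv.start for iv in ivs], dtype=np.int64)
                ends = np.array([iv.end for iv in ivs], dtype=np.int64)
                cum = np.concatenate([[0], np.cumsum(ends - starts)])
                cov[chrom] = (starts, ends, cum)
            self._coverage = cov
        return self._coverage

    def covered_bp(self, interval: GenomeInterval) -> int:
        """Union bp of this set falling inside ``interval``."""
        return int(self.covered_bp_many(interval.chrom,
                                        np.array([interval.start]),
                                        np.array([interval.end]))[0])

    def covered_bp_many(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorized union-coverage for many query intervals on one chromosome."""
        arrays = self._merged_arrays().get(chrom)
        out = np.zeros(len(starts), dtype=np.int64)
        if arrays is None:
            return out
        ms, me, cum = arrays
        return _coverage_between(ms, me, cum, np.asarray(starts), np.asarray(ends))

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Set-difference: parts of self's union not covered by other's union."""
        out: List[GenomeInterval] = []
        other_arrays = other._merged_arrays()
        for iv in merge_intervals(self, 0):
            arrays = other_arrays.get(iv.chrom)
            if arrays is None:
                out.append(iv)
                continue
            ms, me, _ = arrays
            pos = int(iv.start)
            lo = int(np.searchsorted(me, iv.start, side="right"))
            for s, e in zip(ms[lo:].tolist(), me[lo:].tolist()):
                if s >= iv.end:
                    break
                if s > pos:
                    out.append(replace(iv, start=pos, end=min(s, iv.end)))
                pos = max(pos, e)
                if pos >= iv.end:
                    break
            if pos < iv.end:
                out.append(replace(iv, start=pos, end=iv.end))
        return IntervalSet(out, genome=self.genome)

    def intersect_bp(self, other: "IntervalSet") -> int:
        """Union-vs-union intersection in bp."""
        total = 0
        for iv in merge_intervals(self, 0):
            total += other.covered_bp(iv)
        return total


def _coverage_between(ms: np.ndarray, me: np.ndarray, cum: np.ndarray,
                      qs: np.ndarray, qe: np.ndarray) -> np.ndarray:
    """Union coverage of merged intervals (ms, me) inside each query [qs, qe)."""
    def prefix(pos: np.ndarray) -> np.ndarray:
        # coverage in [0, pos); intervals are disjoint and sorted
        idx = np.searchsorted(ms, pos, side="right")
        base = cum[idx]
        over = np.zeros_like(pos)
        inside = idx > 0
        if inside.any():
            i = idx[inside] - 1
            over[inside] = np.clip(me[i] - pos[inside], 0, None)
        return base - over

    return prefix(qe) - prefix(qs)


def merge_intervals(iset: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Union intervals whose gap is <= ``max_gap`` bp.

    With ``max_gap=0`` overlapping or book-ended intervals are joined; the
    operation is idempotent. Strand and label are dropped on merged output
    (a merged region has no single strand).
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    out: List[GenomeInterval] = []
    cur: Optional[GenomeInterval] = None
    for iv in iset:
        if cur is not None and iv.chrom == cur.chrom and iv.start - cur.end <= max_gap:
            if iv.end > cur.end:
                cur = replace(cur, end=iv.end)
        else:
            if cur is not None:
                out.append(cur)
            cur = GenomeInterval(iv.genome, iv.chrom, iv.start, iv.end)
    if cur is not None:
        out.append(cur)
    return IntervalSet(out, genome=iset.genome)


def overlap_fraction(a: GenomeInterval, iset: IntervalSet) -> float:
    """Fraction of ``a`` covered by the union of ``iset`` (in [0, 1])."""
    return iset.covered_bp(a) / a.length


# -- I/O ---------------------------------------------------------------------

def read_intervals(path: str, format: str = "bed", genome: str = "",
                   feature_types: Optional[Iterable[str]] = None) -> IntervalSet:
    """Read a BED (3+ columns) or GFF3 feature file into an :class:`IntervalSet`.

    GFF3 is 1-based closed on disk; starts are decremented on read so that
    in-memory coordinates are uniformly 0-based half-open. ``feature_types``
    restricts GFF3 records to the named types (column 3).
    """
    fmt = format.lower()
    if fmt == "bed":
        return _read_bed(path, genome)
    if fmt in ("gff3", "gff"):
        return _read_gff3(path, genome, feature_types)
    raise ValueError(f"unknown interval format {format!r}")


def _read_bed(path: str, genome: str) -> IntervalSet:
    ivs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinate") from exc
            label = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 and parts[5] in STRANDS else "."
            try:
                ivs.append(GenomeInterval(genome, parts[0], start, end, strand, label))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    return IntervalSet(ivs, genome=genome)


def _read_gff3(path: str, genome: str, feature_types: Optional[Iterable[str]]) -> IntervalSet:
    wanted = set(feature_types) if feature_types else None
    ivs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{ln}: GFF3 needs 9 columns")
            if wanted is not None and parts[2] not in wanted:
                continue
            try:
                start, end = int(parts[3]) - 1, int(parts[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinate") from exc
            strand = parts[6] if parts[6] in STRANDS else "."
            try:
                ivs.append(GenomeInterval(genome, parts[0], start, end, strand, parts[8]))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    return IntervalSet(ivs, genome=genome)


def write_bed(iset: IntervalSet, path: str, score: str = "0") -> None:
    with open(path, "w") as fh:
        for iv in iset:
            name = iv.label or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_chrom_sizes(path: str) -> Dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                sizes[chrom] = int(size)
    return sizes


def n_runs(sequence: str, genome: str, chrom: str, min_len: int = 10) -> IntervalSet:
    """Maximal runs of N of length >= ``min_len`` (assembly gaps)."""
    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    is_n = arr == ord("N")
    if not is_n.any():
        return IntervalSet([], genome=genome)
    padded = np.concatenate([[False], is_n, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.where(diff == 1)[0]
    ends = np.where(diff == -1)[0]
    ivs = [GenomeInterval(genome, chrom, int(s), int(e))
           for s, e in zip(starts, ends) if e - s >= min_len]
    return IntervalSet(ivs, genome=genome)
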