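"""Pairwise whole-genome homology blocks: reading, indexing and projection.

The canonical interchange format is a block-TSV dialect with a documented
header (one row per block, both genomes named explicitly); a MAF reader is
provided for interoperability. Projection maps an interval through every
overlapping block by clipping and proportional offset, so a colinear
gap-free block projects coordinates exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from intervaltree import IntervalTree

from .intervals import FormatError, GenomeInterval, IntervalSet, merge_intervals

logger = logging.getLogger(__name__)

BLOCK_TSV_COLUMNS = [
    "genome_a", "chrom_a", "start_a", "end_a",
    "genome_b", "chrom_b", "start_b", "end_b",
    "strand", "identity",
]


@dataclass(frozen=True)
class AlignmentBlock:
    """A homology block between intervals on two genomes.

    ``strand`` is the orientation of ``b`` relative to ``a``; both intervals
    are stored in forward coordinates. ``reciprocal`` marks blocks whose
    mirror (b->a) is also present, the paper-facing notion of reciprocal
    alignment.
    """

    a: GenomeInterval
    b: GenomeInterval
    identity: float
    strand: str = "+"
    reciprocal: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity must be in [0, 1], got {self.identity}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"block strand must be + or -, got {self.strand!r}")


class AlignmentSet:
    """All blocks between two named genomes, indexed on both sides."""

    def __init__(self, blocks: Iterable[AlignmentBlock], genome_a: str, genome_b: str):
        self.genome_a = genome_a
        self.genome_b = genome_b
        self.blocks: List[AlignmentBlock] = []
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        for blk in blocks:
            self.add(blk)

    def add(self, blk: AlignmentBlock) -> None:
        if blk.a.genome != self.genome_a or blk.b.genome != self.genome_b:
            raise ValueError(
                f"block genomes ({blk.a.genome}, {blk.b.genome}) do not match "
                f"set genomes ({self.genome_a}, {self.genome_b})")
        self.blocks.append(blk)
        self._trees.setdefault((self.genome_a, blk.a.chrom), IntervalTree()) \
            .addi(blk.a.start, blk.a.end, blk)
        self._trees.setdefault((self.genome_b, blk.b.chrom), IntervalTree()) \
            .addi(blk.b.start, blk.b.end, blk)

    def __len__(self) -> int:
        return len(self.blocks)

    def other(self, genome: str) -> str:
        if genome == self.genome_a:
            return self.genome_b
        if genome == self.genome_b:
            return self.genome_a
        raise ValueError(f"genome {genome!r} not in alignment ({self.genome_a}, {self.genome_b})")

    def query(self, interval: GenomeInterval, reciprocal_only: bool = False) -> List[AlignmentBlock]:
        """Blocks whose side on ``interval.genome`` overlaps the interval."""
        tree = self._trees.get((interval.genome, interval.chrom))
        if tree is None:
            return []
        hits = [node.data for node in tree.overlap(interval.start, interval.end)]
        if reciprocal_only:
            hits = [b for b in hits if b.reciprocal]
        hits.sort(key=lambda b: (b.a.start, b.b.start))
        return hits

    def side(self, blk: AlignmentBlock, genome: str) -> GenomeInterval:
        if genome == self.genome_a:
            return blk.a
        if genome == self.genome_b:
            return blk.b
        raise ValueError(f"genome {genome!r} not in alignment")

    def coverage(self, genome: str, reciprocal_only: bool = False) -> IntervalSet:
        """Union of block footprints on one genome."""
        ivs = [self.side(b, genome) for b in self.blocks
               if not reciprocal_only or b.reciprocal]
        return merge_intervals(IntervalSet(ivs, genome=genome), 0)

    def aligned_bp(self, interval: GenomeInterval, reciprocal_only: bool = False) -> int:
        """bp of ``interval`` covered by (reciprocal) blocks."""
        ivs = []
        for blk in self.query(interval, reciprocal_only):
            side = self.side(blk, interval.genome)
            ivs.append(GenomeInterval(interval.genome, side.chrom,
                                      max(side.start, interval.start),
                                      min(side.end, interval.end)))
        return IntervalSet(ivs, genome=interval.genome).total_bp() if ivs else 0


def project(interval: GenomeInterval, aln: AlignmentSet, target: str) -> IntervalSet:
    """Project ``interval`` through every overlapping block onto ``target``.

    The interval is clipped to each block and mapped by proportional offset;
    projection through a minus-strand block reverses orientation but target
    intervals are reported in forward coordinates. An empty result is valid
    (nothing aligned).
    """
    source = interval.genome
    if aln.other(source) != target:
        raise ValueError(f"alignment does not connect {source!r} to {target!r}")
    out: List[GenomeInterval] = []
    for blk in aln.query(interval):
        src = aln.side(blk, source)
        dst = aln.side(blk, target)
        lo = max(interval.start, src.start)
        hi = min(interval.end, src.end)
        if hi <= lo:
            continue
        scale = dst.length / src.length
        off_lo = (lo - src.start) * scale
        off_hi = (hi - src.start) * scale
        if blk.strand == "+" or src is dst:
            t_lo = dst.start + off_lo
            t_hi = dst.start + off_hi
        else:
            t_lo = dst.end - off_hi
            t_hi = dst.end - off_lo
        t_lo_i, t_hi_i = int(round(t_lo)), int(round(t_hi))
        if t_hi_i <= t_lo_i:
            t_hi_i = t_lo_i + 1
        out.append(GenomeInterval(target, dst.chrom, t_lo_i, t_hi_i,
                                  interval.strand, interval.label))
    return IntervalSet(out, genome=target)


# -- I/O ---------------------------------------------------------------------

def read_alignment_blocks(path: str, dialect: str = "block-tsv",
                          genome_a: Optional[str] = None,
                          genome_b: Optional[str] = None,
                          reciprocal: Optional[bool] = None) -> AlignmentSet:
    """Read blocks from block-TSV or MAF.

    The reciprocal flag on each block is set when the mirrored row exists in
    the file, or globally when ``reciprocal`` declares it for the dialect
    (MAF from a symmetric aligner, or synthetic blocks that are reciprocal
    by construction).
    """
    d = dialect.lower()
    if d in ("block-tsv", "tsv"):
        rows = _read_block_tsv_rows(path)
    elif d == "maf":
        rows = _read_maf_rows(path, genome_a, genome_b)
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    if not rows:
        if genome_a is None or genome_b is None:
            raise ValueError("empty alignment file needs explicit genome names")
        return AlignmentSet([], genome_a, genome_b)

    genomes = sorted({r[0] for r in rows} | {r[4] for r in rows})
    if genome_a is None or genome_b is None:
        if len(genomes) != 2:
            raise FormatError(f"{path}: expected exactly 2 genomes, found {genomes}")
        genome_a, genome_b = genomes
    for g in genomes:
        if g not in (genome_a, genome_b):
            raise FormatError(f"{path}: unknown genome identifier {g!r}")

    raw_keys = {(r[0], r[1], r[2], r[3], r[4], r[5], r[6], r[7]) for r in rows}
    blocks = []
    seen = set()
    n_duplicate = 0
    for ga, ca, sa, ea, gb, cb, sb, eb, strand, ident in rows:
        mirrored = (gb, cb, sb, eb, ga, ca, sa, ea) in raw_keys
        if ga == genome_b:  # orient every block as genome_a -> genome_b
            if mirrored:
                continue  # the a->b row carries this block
            ga, ca, sa, ea, gb, cb, sb, eb = gb, cb, sb, eb, ga, ca, sa, ea
        key = (ca, sa, ea, cb, sb, eb)
        if key in seen:
            n_duplicate += 1
            continue
        seen.add(key)
        recip = reciprocal if reciprocal is not None else mirrored
        blocks.append(AlignmentBlock(
            GenomeInterval(genome_a, ca, sa, ea),
            GenomeInterval(genome_b, cb, sb, eb),
            ident, strand, recip))
    if n_duplicate:
        logger.warning("%s: %d duplicate rows collapsed", path, n_duplicate)
    return AlignmentSet(blocks, genome_a, genome_b)


def _read_block_tsv_rows(path: str):
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "genome_a":  # header
                continue
            if len(parts) < 10:
                raise FormatError(f"{path}:{ln}: block-TSV needs 10 columns")
            try:
                rows.append((parts[0], parts[1], int(parts[2]), int(parts[3]),
                             parts[4], parts[5], int(parts[6]), int(parts[7]),
                             parts[8], float(parts[9])))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    return rows


def _read_maf_rows(path: str, genome_a, genome_b):
    """Minimal MAF: per alignment block take the first two ``s`` lines.

    Sequence names are expected as ``genome.chrom``; identity is computed
    from the aligned sequences. Minus-strand MAF coordinates are converted
    to forward.
    """
    rows = []
    with open(path) as fh:
        block: List[Tuple[str, str, int, int, str, int, str]] = []
        for line in fh:
            if line.startswith("a"):
                block = []
            elif line.startswith("s"):
                _, src, start, size, strand, src_size, text = line.split()[:7]
                if "." not in src:
                    raise FormatError(f"{path}: MAF sequence name {src!r} lacks genome prefix")
                genome, chrom = src.split(".", 1)
                block.append((genome, chrom, int(start), int(size), strand,
                              int(src_size), text))
                if len(block) == 2:
                    rows.append(_maf_pair_to_row(block))
    return rows


def _maf_pair_to_row(pair):
    (ga, ca, sa, za, stra, tot_a, txt_a), (gb, cb, sb, zb, strb, tot_b, txt_b) = pair
    if stra == "-":
        sa = tot_a - sa - za
    fwd_b = sb if strb == "+" else tot_b - sb - zb
    strand = "+" if stra == strb else "-"
    matches = sum(1 for x, y in zip(txt_a.upper(), txt_b.upper())
                  if x == y and x != "-")
    cols = sum(1 for x, y in zip(txt_a, txt_b) if x != "-" or y != "-")
    ident = matches / cols if cols else 0.0
    return (ga, ca, sa, sa + za, gb, cb, fwd_b, fwd_b + zb, strand, ident)


def write_block_tsv(aln: AlignmentSet, path: str, mirror: bool = False) -> None:
    """Write blocks as block-TSV; ``mirror=True`` also writes the b->a rows."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BLOCK_TSV_COLUMNS) + "\n")
        for blk in aln.blocks:
            a, b = blk.a, blk.b
            fh.write(f"{a.genome}\t{a.chrom}\t{a.start}\t{a.end}\t"
                     f"{b.genome}\t{b.chrom}\t{b.start}\t{b.end}\t"
                     f"{blk.strand}\t{blk.identity:.6g}\n")
            if mirror:
                fh.write(f"{b.genome}\t{b.chrom}\t{b.start}\t{b.end}\t"
                         f"{a.genome}\t{a.chrom}\t{a.start}\t{a.end}\t"
                         f"{blk.strand}\t{blk.identity:.6g}\n")
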