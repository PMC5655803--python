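"""High-confidence subgenome deletion calling from pairwise alignments.

A deletion from subgenome X is evidenced on the sister subgenome (the
retained copy): a region that reciprocally aligns to the outgroup but has
zero reciprocal alignment to X, flanked on both sides (500 bp) by sequence
that does reciprocally align to X. The residual gap between the projected
flank anchors on X must be at most 4 kb and at least three times shorter
than the retained span; the two thresholds together separate true
deletions (large retained span, tiny residual gap) from merely diverged or
unalignable sequence (gap roughly the size of the region itself).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .alignments import AlignmentBlock, AlignmentSet
from .intervals import GenomeInterval, IntervalSet, merge_intervals, n_runs

logger = logging.getLogger(__name__)


@dataclass
class DeletionCall:
    side: str                      # "LdS" = deleted from S (retained on L)
    retained_region: GenomeInterval
    gap_chrom: str
    gap_start: int
    gap_end: int
    size_retained: int
    size_gap: int
    flank_blocks: Tuple[AlignmentBlock, AlignmentBlock]

    @property
    def deleted_genome(self) -> str:
        return "S" if self.side == "LdS" else "L"


@dataclass
class CallSummary:
    """Bookkeeping of why candidates were dropped."""

    n_candidates: int = 0
    n_called: int = 0
    n_no_left_flank: int = 0
    n_no_right_flank: int = 0
    n_inconsistent_anchors: int = 0
    n_gap_too_large: int = 0
    n_ratio_failed: int = 0


def assembly_gaps(fasta_path: str, genome: str, min_len: int = 10) -> IntervalSet:
    """Maximal N-runs >= ``min_len`` bp over every sequence of a FASTA."""
    from pyfaidx import Fasta

    fa = Fasta(fasta_path, rebuild=False)
    ivs = []
    for name in fa.keys():
        runs = n_runs(str(fa[name][:]), genome, name, min_len)
        ivs.extend(runs)
    return IntervalSet(ivs, genome=genome)


def candidate_regions(aln_xT: AlignmentSet, aln_LS: AlignmentSet, subgenome: str,
                      gaps: Optional[IntervalSet] = None,
                      merge_gap: int = 10,
                      gap_overlap_max: float = 0.25) -> IntervalSet:
    """Regions of ``subgenome`` reciprocally aligned to the outgroup but with
    zero reciprocal alignment to the sister subgenome.

    Sub-regions within ``merge_gap`` bp are merged; candidates overlapping
    assembly gaps (N-runs) for more than ``gap_overlap_max`` of their
    length are removed.
    """
    cov_T = aln_xT.coverage(subgenome, reciprocal_only=True)
    cov_sister = aln_LS.coverage(subgenome, reciprocal_only=True)
    candidates = merge_intervals(cov_T.subtract(cov_sister), merge_gap)
    if gaps is not None and len(gaps):
        kept = [iv for iv in candidates
                if gaps.covered_bp(iv) / iv.length <= gap_overlap_max]
        candidates = IntervalSet(kept, genome=subgenome)
    return candidates


def _anchor(block: AlignmentBlock, aln: AlignmentSet, retained: str,
            pos: int) -> Tuple[str, int]:
    """Sister coordinate aligned to retained-genome position ``pos`` (clipped
    into the block)."""
    src = aln.side(block, retained)
    dst = aln.side(block, aln.other(retained))
    p = min(max(pos, src.start), src.end)
    frac = (p - src.start) / src.length
    if block.strand == "+":
        coord = dst.start + frac * dst.length
    else:
        coord = dst.end - frac * dst.length
    return dst.chrom, int(round(coord))


def call_deletions(candidates: IntervalSet, aln_LS: AlignmentSet,
                   retained_genome: str,
                   flank: int = 500, max_gap: int = 4000,
                   min_ratio: float = 3.0,
                   min_flank_overlap: int = 50) -> Tuple[List[DeletionCall], CallSummary]:
    """Apply the flank and size filters to candidate regions.

    Both ``flank``-bp flanks on the retained genome must contain at least
    one reciprocal block to the sister overlapping the flank by
    ``min_flank_overlap`` bp; the inter-flank gap on the sister is measured
    between the anchors of the block nearest the candidate on each side
    (ties broken by longer block). A call requires
    ``size_gap <= max_gap`` and ``size_retained >= min_ratio * size_gap``.
    """
    sister = aln_LS.other(retained_genome)
    side = "LdS" if retained_genome == "L" else "SdL"
    calls: List[DeletionCall] = []
    summary = CallSummary(n_candidates=len(candidates))
    for cand in candidates:
        left_iv = GenomeInterval(retained_genome, cand.chrom,
                                 max(cand.start - flank, 0), max(cand.start, 1))
        right_iv = GenomeInterval(retained_genome, cand.chrom,
                                  cand.end, cand.end + flank)
        left_block = _best_flank_block(aln_LS, left_iv, retained_genome,
                                       min_flank_overlap, prefer="end")
        if left_block is None:
            summary.n_no_left_flank += 1
            continue
        right_block = _best_flank_block(aln_LS, right_iv, retained_genome,
                                        min_flank_overlap, prefer="start")
        if right_block is None:
            summary.n_no_right_flank += 1
            continue
        lchrom, lpos = _anchor(left_block, aln_LS, retained_genome, cand.start)
        rchrom, rpos = _anchor(right_block, aln_LS, retained_genome, cand.end)
        if lchrom != rchrom:
            summary.n_inconsistent_anchors += 1
            continue
        gap_start, gap_end = sorted((lpos, rpos))
        size_gap = gap_end - gap_start
        if size_gap > max_gap:
            summary.n_gap_too_large += 1
            continue
        if cand.length < min_ratio * size_gap:
            summary.n_ratio_failed += 1
            continue
        calls.append(DeletionCall(
            side=side, retained_region=cand, gap_chrom=lchrom,
            gap_start=gap_start, gap_end=gap_end,
            size_retained=cand.length, size_gap=size_gap,
            flank_blocks=(left_block, right_block)))
    summary.n_called = len(calls)
    return calls, summary


def _best_flank_block(aln: AlignmentSet, flank_iv: GenomeInterval,
                      retained: str, min_overlap: int,
                      prefer: str) -> Optional[AlignmentBlock]:
    best = None
    best_key = None
    for blk in aln.query(flank_iv, reciprocal_only=True):
        src = aln.side(blk, retained)
        overlap = min(src.end, flank_iv.end) - max(src.start, flank_iv.start)
        if overlap < min_overlap:
            continue
        # nearest the candidate; ties broken by longer block
        key = (src.end, src.length) if prefer == "end" else (-src.start, src.length)
        if best_key is None or key > best_key:
            best, best_key = blk, key
    return best


def deletion_size_spectrum(calls: Sequence[DeletionCall],
                           bins: Optional[np.ndarray] = None
                           ) -> Dict[str, np.ndarray]:
    """Per-side size histogram (log-spaced bins) and per-bin LdS:SdL ratio.

    Empty SdL bins yield an infinite ratio (flagged by the caller via
    ``np.isinf``), never an exception.
    """
    if not calls:
        raise ValueError("no deletion calls")
    sizes = {side: np.array([c.size_retained for c in calls if c.side == side])
             for side in ("LdS", "SdL")}
    if bins is None:
        all_sizes = np.array([c.size_retained for c in calls])
        bins = np.geomspace(max(all_sizes.min(), 1), all_sizes.max() + 1, 11)
    h_lds, _ = np.histogram(sizes["LdS"], bins=bins)
    h_sdl, _ = np.histogram(sizes["SdL"], bins=bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = h_lds / h_sdl
    return {"bins": bins, "LdS": h_lds, "SdL": h_sdl, "ratio": ratio}


def score_against_truth(calls: Sequence[DeletionCall], truth,
                        min_reciprocal_overlap: float = 0.5) -> Dict[str, float]:
    """Precision/recall of calls against a truth ledger of implanted
    deletions (matched by >= 50% reciprocal overlap of retained regions and
    the same side)."""
    truth_sets: Dict[Tuple[str, str], List] = {}
    for t in truth:
        truth_sets.setdefault((t.side, t.retained.chrom), []).append(t)
    matched_truth = set()
    tp = 0
    for call in calls:
        hit = False
        for t in truth_sets.get((call.side, call.retained_region.chrom), []):
            ov = (min(call.retained_region.end, t.retained.end)
                  - max(call.retained_region.start, t.retained.start))
            if ov <= 0:
                continue
            if (ov / call.retained_region.length >= min_reciprocal_overlap
                    and ov / t.retained.length >= min_reciprocal_overlap):
                hit = True
                matched_truth.add(t.del_id)
        tp += hit
    n_calls = len(calls)
    n_truth = len(list(truth))
    return {
        "n_calls": n_calls,
        "n_truth": n_truth,
        "precision": tp / n_calls if n_calls else float("nan"),
        "recall": len(matched_truth) / n_truth if n_truth else float("nan"),
    }


def write_deletions_bed(calls: Sequence[DeletionCall], path: str) -> None:
    """BED6+ with side, gap size, retained size and gap coordinates."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tside\tsize_gap\tstrand\t"
                 "size_retained\tgap_chrom\tgap_start\tgap_end\n")
        for c in sorted(calls, key=lambda c: (c.retained_region.chrom,
                                              c.retained_region.start)):
            r = c.retained_region
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{c.side}\t{c.size_gap}\t.\t"
                     f"{c.size_retained}\t{c.gap_chrom}\t{c.gap_start}\t{c.gap_end}\n")
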