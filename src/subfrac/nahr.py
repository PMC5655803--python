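"""NAHR signature statistics on retained regions.

Non-allelic homologous recombination between repeats on the same
chromosome deletes the sequence between them. Two testable signatures on
the retained (surviving homeologous) regions: repeats overlapping them are
longer than repeats overlapping length-matched random regions, and the two
1-kb flanks of a retained region are more similar to each other than
random same-size sequence pairs (the recombining repeat pair straddles the
breakpoints).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio import Align

from .intervals import GenomeInterval, IntervalSet
from .randomization import mann_whitney_u, shuffle_within_chromosome

DEFAULT_SCORING = {"match": 1.0, "mismatch": -1.0, "gap_open": -2.0, "gap_extend": -1.0}


def global_align_identity(seq_a: str, seq_b: str,
                          scoring: Optional[Mapping[str, float]] = None) -> float:
    """Needleman-Wunsch global alignment identity (matches / columns).

    Identity values depend on the scoring parameters, so the defaults are
    pinned (match 1, mismatch -1, gap open -2, gap extend -1) and should be
    recorded alongside any reported similarity.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    sc = dict(DEFAULT_SCORING, **(scoring or {}))
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = sc["match"]
    aligner.mismatch_score = sc["mismatch"]
    aligner.open_gap_score = sc["gap_open"]
    aligner.extend_gap_score = sc["gap_extend"]
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    counts = aln.counts()
    columns = aln.shape[1]
    return counts.identities / columns if columns else 0.0


def repeat_length_ratio(retained: Sequence[GenomeInterval], repeats: IntervalSet,
                        chrom_sizes: Mapping[str, int], n_random: int = 1,
                        seed: int = 0) -> Dict[str, object]:
    """Lengths of repeat elements overlapping retained regions vs repeats
    overlapping length-matched random regions (same count, chromosome and
    sizes, drawn ``n_random`` times), with a Mann-Whitney comparison."""
    if not retained:
        raise ValueError("empty retained set")
    rng = np.random.default_rng(seed)
    obs = _overlapping_repeat_lengths(retained, repeats)
    rand: List[int] = []
    base = IntervalSet(list(retained))
    for _ in range(n_random):
        shuffled = shuffle_within_chromosome(base, chrom_sizes, rng)
        rand.extend(_overlapping_repeat_lengths(list(shuffled), repeats))
    if not obs or not rand:
        return {"flagged": True, "n_retained_hits": len(obs),
                "n_random_hits": len(rand)}
    u, p = mann_whitney_u(obs, rand)
    return {
        "flagged": False,
        "mean_length_retained": float(np.mean(obs)),
        "mean_length_random": float(np.mean(rand)),
        "ratio": float(np.mean(obs) / np.mean(rand)),
        "mann_whitney_p": p,
        "n_retained_hits": len(obs),
        "n_random_hits": len(rand),
    }


def _overlapping_repeat_lengths(regions: Sequence[GenomeInterval],
                                repeats: IntervalSet) -> List[int]:
    lengths = []
    by_chrom: Dict[str, List[GenomeInterval]] = {}
    for r in repeats:
        by_chrom.setdefault(r.chrom, []).append(r)
    for region in regions:
        for rep in by_chrom.get(region.chrom, []):
            if rep.start < region.end and region.start < rep.end:
                lengths.append(rep.length)
    return lengths


@dataclass
class FlankSimilarityResult:
    similarities: List[float]
    random_similarities: List[float]
    mann_whitney_p: float
    n_skipped_edge: int
    n_skipped_n: int
    scoring: Dict[str, float]


def flank_similarity(retained: Sequence[GenomeInterval], genome,
                     chrom_sizes: Mapping[str, int], flank: int = 1000,
                     n_random_pairs: int = 200, seed: int = 0,
                     scoring: Optional[Mapping[str, float]] = None,
                     mode: str = "left-vs-right") -> FlankSimilarityResult:
    """Global-alignment identity of each retained region's left vs right
    ``flank``-bp flank, compared with random same-chromosome pairs.

    ``genome`` is any mapping chrom -> sequence string (a ``pyfaidx.Fasta``
    works). Regions too close to a chromosome edge are skipped and counted,
    as are flanks with more than 50% N. ``mode='each-vs-random'`` instead
    scores each flank against a random same-size sequence.
    """
    rng = np.random.default_rng(seed)
    sc = dict(DEFAULT_SCORING, **(scoring or {}))
    sims: List[float] = []
    n_edge = n_n = 0
    chroms = sorted(chrom_sizes)
    for region in retained:
        size = chrom_sizes[region.chrom]
        if region.start < flank or region.end + flank > size:
            n_edge += 1
            continue
        left = str(genome[region.chrom][region.start - flank:region.start])
        right = str(genome[region.chrom][region.end:region.end + flank])
        if _frac_n(left) > 0.5 or _frac_n(right) > 0.5:
            n_n += 1
            continue
        if mode == "each-vs-random":
            for seq in (left, right):
                sims.append(global_align_identity(seq, _random_window(
                    genome, chrom_sizes, region.chrom, flank, rng), sc))
        else:
            sims.append(global_align_identity(left, right, sc))
    rand: List[float] = []
    for _ in range(n_random_pairs):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        a = _random_window(genome, chrom_sizes, chrom, flank, rng)
        b = _random_window(genome, chrom_sizes, chrom, flank, rng)
        rand.append(global_align_identity(a, b, sc))
    if sims and rand:
        _, p = mann_whitney_u(sims, rand)
    else:
        p = float("nan")
    return FlankSimilarityResult(sims, rand, p, n_edge, n_n, sc)


def _frac_n(seq: str) -> float:
    if not seq:
        return 1.0
    return seq.upper().count("N") / len(seq)


def _random_window(genome, chrom_sizes: Mapping[str, int], chrom: str,
                   size: int, rng: np.random.Generator) -> str:
    start = int(rng.integers(0, chrom_sizes[chrom] - size + 1))
    return str(genome[chrom][start:start + size])


def repeat_density_table(repeats_by_genome: Mapping[str, IntervalSet],
                         genome_sizes: Mapping[str, int]) -> Dict[str, float]:
    """Simple per-genome repeat density (elements per Mb)."""
    return {g: len(rs) / (genome_sizes[g] / 1e6)
            for g, rs in repeats_by_genome.items()}
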