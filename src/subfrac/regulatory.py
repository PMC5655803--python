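"""Regulatory-landscape statistics: peak conservation through alignment,
subgenome-specific peaks, annotation enrichment, repeats per megabase,
active-transcription thresholding and the 5-kb proximity expression test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .alignments import AlignmentSet, project
from .intervals import GenomeInterval, IntervalSet, overlap_fraction
from .randomization import hypergeometric_tail, hypergeometric_tail_log10, mann_whitney_u


@dataclass
class PeakSet:
    peaks: IntervalSet
    mark: str = "other"
    genome: str = ""

    def __post_init__(self) -> None:
        if not self.genome:
            self.genome = self.peaks.genome

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class AnnotationEnrichment:
    annotation: str
    k: int            # subset peaks overlapping the annotation
    n_subset: int
    K: int            # all peaks overlapping
    N_all: int
    fold: float
    p: float
    log10_p: float
    prevalence: float
    passing: bool


def peak_conservation(ref_peaks: PeakSet, aln: AlignmentSet,
                      target_peaks: PeakSet,
                      min_overlap_bp: int = 1) -> Tuple[float, Dict[int, bool]]:
    """Fraction of reference peaks whose projection overlaps >= 1 target
    peak by at least ``min_overlap_bp``. Peaks with no aligned sequence are
    not conserved."""
    labels: Dict[int, bool] = {}
    for i, peak in enumerate(ref_peaks.peaks):
        conserved = False
        for proj in project(peak, aln, target_peaks.genome):
            if target_peaks.peaks.covered_bp(proj) >= min_overlap_bp:
                conserved = True
                break
        labels[i] = conserved
    n = len(labels)
    fraction = sum(labels.values()) / n if n else float("nan")
    return fraction, labels


def subgenome_specific_peaks(peaks: PeakSet, aln_to_sister: AlignmentSet,
                             aln_to_outgroup: AlignmentSet,
                             max_aligned_bp: int = 0) -> PeakSet:
    """Peaks lacking any alignment to both the sister subgenome and the
    outgroup (<= ``max_aligned_bp`` aligned bp to each; default strictly
    zero)."""
    kept = []
    for peak in peaks.peaks:
        if aln_to_sister.aligned_bp(peak) > max_aligned_bp:
            continue
        if aln_to_outgroup.aligned_bp(peak) > max_aligned_bp:
            continue
        kept.append(peak)
    return PeakSet(IntervalSet(kept, genome=peaks.genome), peaks.mark, peaks.genome)


def annotation_enrichment(subset: PeakSet, all_peaks: PeakSet,
                          annotations: Mapping[str, IntervalSet],
                          min_overlap: float = 0.5,
                          p_max: float = 1e-4, fold_min: float = 2.0,
                          prevalence_min: float = 0.15
                          ) -> List[AnnotationEnrichment]:
    """Hypergeometric annotation enrichment of a peak subset against the
    full peak population.

    A peak overlaps an annotation when strictly more than ``min_overlap``
    of the peak is covered. An annotation passes at
    ``p <= p_max AND fold >= fold_min AND prevalence >= prevalence_min``;
    the full table is returned either way.
    """
    n_sub = len(subset.peaks)
    n_all = len(all_peaks.peaks)
    if n_sub == 0:
        raise ValueError("empty peak subset")
    results = []
    for name, ann in sorted(annotations.items()):
        k = sum(1 for p in subset.peaks if overlap_fraction(p, ann) > min_overlap)
        K = sum(1 for p in all_peaks.peaks if overlap_fraction(p, ann) > min_overlap)
        prevalence = k / n_sub
        background = K / n_all if n_all else float("nan")
        fold = (prevalence / background) if background > 0 else float("inf")
        p = hypergeometric_tail(k, K, n_sub, n_all) if K else 1.0
        lp = hypergeometric_tail_log10(k, K, n_sub, n_all) if K else 0.0
        passing = (p <= p_max and fold >= fold_min and prevalence >= prevalence_min)
        results.append(AnnotationEnrichment(name, k, n_sub, K, n_all, fold,
                                            p, lp, prevalence, passing))
    return results


def repeats_per_megabase(annotation: IntervalSet, genome_size: int) -> float:
    """Element count per megabase of genome."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    return len(annotation) / (genome_size / 1e6)


def active_transcription_threshold(background: Mapping[str, Sequence[float]]
                                   ) -> Dict[str, float]:
    """Per-mark activity threshold: mean + 2 SD of the background signal
    (RPKM over random regions)."""
    out = {}
    for mark, values in background.items():
        v = np.asarray(values, dtype=float)
        if len(v) < 2:
            raise ValueError(f"need >= 2 background values for {mark}")
        out[mark] = float(v.mean() + 2.0 * v.std())
    return out


def is_actively_transcribed(region_signal: Mapping[str, float],
                            thresholds: Mapping[str, float]) -> bool:
    """Active iff the region reaches the threshold for every mark
    independently (boundary counts as passing)."""
    return all(region_signal[mark] >= thr for mark, thr in thresholds.items())


def gene_tss(gene: GenomeInterval) -> GenomeInterval:
    """Strand-aware TSS as a 1-bp interval (start for +, end-1 for -)."""
    pos = gene.start if gene.strand != "-" else gene.end - 1
    return GenomeInterval(gene.genome, gene.chrom, pos, pos + 1,
                          gene.strand, gene.label)


def proximity_expression_test(enhancers: PeakSet, tss: IntervalSet,
                              expression: Mapping[str, float],
                              distance: int = 5000,
                              pseudo_tpm: float = 1e-3) -> Dict[str, object]:
    """Mann-Whitney on log-TPM between genes whose TSS lies within
    ``distance`` bp (inclusive) of an enhancer and all other genes."""
    enh_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for p in enhancers.peaks:
        enh_by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    near, far = [], []
    for t in tss:
        tpm = expression.get(t.label)
        if tpm is None:
            continue
        val = float(np.log2(tpm + pseudo_tpm))
        d = _min_distance(t.start, enh_by_chrom.get(t.chrom, []))
        (near if d is not None and d <= distance else far).append(val)
    if not near or not far:
        raise ValueError(f"empty group (near={len(near)}, far={len(far)})")
    u, p = mann_whitney_u(near, far)
    return {"U": u, "p": p, "n_near": len(near), "n_far": len(far),
            "median_log2_near": float(np.median(near)),
            "median_log2_far": float(np.median(far))}


def _min_distance(pos: int, intervals: List[Tuple[int, int]]) -> Optional[int]:
    best = None
    for s, e in intervals:
        if s <= pos < e:
            d = 0
        else:
            d = s - pos if pos < s else pos - e + 1
        best = d if best is None else min(best, d)
    return best
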