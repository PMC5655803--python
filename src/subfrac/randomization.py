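"""Randomization-based deletion-enrichment testing and the shared
statistical toolkit (Mann-Whitney U, chi-squared, hypergeometric tail,
Benjamini-Hochberg).

The enrichment test relocates deletions uniformly at random on their own
chromosome (length preserved), compares observed deleted bp overlapping a
feature class with the randomization mean, and converts the z-score to a
two-sided normal-tail p-value; direction is carried by the sign of the
log2 fold difference.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .intervals import GenomeInterval, IntervalSet, merge_intervals


@dataclass
class FeatureClass:
    """A named feature annotation to test deletions against.

    Intervals live on the genome being randomized; for deleted features the
    caller supplies the homeologous subgenome's annotation projected
    through the alignment as a proxy for the pre-deletion state.
    """

    name: str
    intervals: IntervalSet


@dataclass
class EnrichmentResult:
    feature: str
    chromosome: str
    observed_bp: int
    expected_bp: float
    sd_bp: float
    log2_fold: float
    z: float
    p: float
    q: float = float("nan")
    degenerate: bool = False


def shuffle_within_chromosome(intervals: IntervalSet,
                              chrom_sizes: Mapping[str, int],
                              seed: int | np.random.Generator = 0) -> IntervalSet:
    """Relocate each interval uniformly at random on its own chromosome.

    Lengths are preserved and no interval extends past the chromosome end;
    shuffled intervals may overlap one another.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for iv in intervals:
        size = chrom_sizes[iv.chrom]
        if iv.length > size:
            raise ValueError(f"interval of length {iv.length} exceeds "
                             f"chromosome {iv.chrom} ({size} bp)")
        start = int(rng.integers(0, size - iv.length + 1))
        out.append(GenomeInterval(iv.genome, iv.chrom, start, start + iv.length,
                                  iv.strand, iv.label))
    return IntervalSet(out, genome=intervals.genome)


def _null_overlaps(lengths: np.ndarray, chrom_size: int,
                   feature: IntervalSet, chrom: str, n_rand: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Total feature-overlap bp for n_rand random relocations of all
    intervals (vectorized)."""
    if len(lengths) == 0:
        return np.zeros(n_rand)
    highs = chrom_size - lengths + 1
    starts = (rng.random((n_rand, len(lengths))) * highs).astype(np.int64)
    ends = starts + lengths
    flat_cov = feature.covered_bp_many(chrom, starts.ravel(), ends.ravel())
    return flat_cov.reshape(n_rand, len(lengths)).sum(axis=1).astype(float)


def deletion_enrichment(deletions: IntervalSet,
                        classes: Sequence[FeatureClass],
                        chrom_sizes: Mapping[str, int],
                        n_rand: int = 1000,
                        seed: int = 0) -> List[EnrichmentResult]:
    """Per feature-class x chromosome: observed deleted bp vs the mean of
    ``n_rand`` within-chromosome randomizations, with z-score p-values and
    BH-adjusted q across all tests."""
    rng = np.random.default_rng(seed)
    results: List[EnrichmentResult] = []
    chroms = sorted({iv.chrom for iv in deletions})
    # per-chromosome deletion lengths, fixed across classes and replicates
    by_chrom: Dict[str, np.ndarray] = {
        c: np.array([iv.length for iv in deletions if iv.chrom == c], dtype=np.int64)
        for c in chroms}
    # one set of random placements per chromosome, reused for every class so
    # classes are compared against the same null draws
    placements: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for c in chroms:
        lens = by_chrom[c]
        highs = chrom_sizes[c] - lens + 1
        starts = (rng.random((n_rand, len(lens))) * highs).astype(np.int64)
        placements[c] = (starts, starts + lens)

    for fc in classes:
        for c in chroms:
            obs_iv = [iv for iv in deletions if iv.chrom == c]
            obs = sum(fc.intervals.covered_bp(iv) for iv in obs_iv)
            starts, ends = placements[c]
            null = fc.intervals.covered_bp_many(c, starts.ravel(), ends.ravel()) \
                .reshape(n_rand, -1).sum(axis=1).astype(float)
            exp = float(null.mean())
            sd = float(null.std())
            if sd == 0.0:
                degenerate = True
                z = 0.0
                p = 1.0 if obs == exp else 0.0
            else:
                degenerate = False
                z = (obs - exp) / sd
                p = 2.0 * stats.norm.sf(abs(z))
            if obs > 0 and exp > 0:
                lf = math.log2(obs / exp)
            elif obs == exp:
                lf = 0.0
            else:
                lf = float("-inf") if obs == 0 else float("inf")
            results.append(EnrichmentResult(fc.name, c, int(obs), exp, sd,
                                            lf, z, p, degenerate=degenerate))
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = q
    return results


def compare_fold_between_genomes(results_x: Sequence[EnrichmentResult],
                                 results_y: Sequence[EnrichmentResult]
                                 ) -> Dict[str, Dict[str, float]]:
    """Per feature class, Mann-Whitney U on per-chromosome log2 fold values
    between two genomes (the L-vs-S comparison)."""
    out = {}
    names = sorted({r.feature for r in results_x} & {r.feature for r in results_y})
    for name in names:
        x = [r.log2_fold for r in results_x
             if r.feature == name and math.isfinite(r.log2_fold)]
        y = [r.log2_fold for r in results_y
             if r.feature == name and math.isfinite(r.log2_fold)]
        if not x or not y:
            continue
        u, p = mann_whitney_u(x, y)
        out[name] = {"U": u, "p": p,
                     "median_x": float(np.median(x)),
                     "median_y": float(np.median(y))}
    return out


# -- statistical primitives --------------------------------------------------

def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   exact_limit: int = 14) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact permutation p (full enumeration over all label assignments) when
    n + m <= ``exact_limit``; otherwise the normal approximation with tie
    correction. Returns (U of the first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n, m = len(x), len(y)
    u_obs = _u_statistic(x, y)
    if np.all(np.concatenate([x, y]) == x[0]):
        return u_obs, 1.0
    if n + m <= exact_limit:
        pooled = np.concatenate([x, y])
        center = n * m / 2.0
        dev_obs = abs(u_obs - center)
        count = total = 0
        for idx in itertools.combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - center) >= dev_obs - 1e-9:
                count += 1
        return u_obs, count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                             use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x: number of (x_i, y_j) pairs with x_i > y_j, ties counting 1/2."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def chi_squared_2x2(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, no continuity correction, df=1."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be >= 0")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for hypergeometric(N, K, n), computed in log
    space so extreme tails do not underflow to exact zero prematurely."""
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    ks = np.arange(k, min(K, n) + 1)
    logpmf = (gammaln(K + 1) - gammaln(ks + 1) - gammaln(K - ks + 1)
              + gammaln(N - K + 1) - gammaln(n - ks + 1)
              - gammaln(N - K - n + ks + 1)
              + gammaln(n + 1) + gammaln(N - n + 1) - gammaln(N + 1))
    top = logpmf.max()
    return float(min(1.0, math.exp(top) * np.exp(logpmf - top).sum()))


def hypergeometric_tail_log10(k: int, K: int, n: int, N: int) -> float:
    """log10 of the upper-tail p (usable below the float underflow limit)."""
    if k == 0:
        return 0.0
    ks = np.arange(k, min(K, n) + 1)
    logpmf = (gammaln(K + 1) - gammaln(ks + 1) - gammaln(K - ks + 1)
              + gammaln(N - K + 1) - gammaln(n - ks + 1)
              - gammaln(N - K - n + ks + 1)
              + gammaln(n + 1) + gammaln(N - n + 1) - gammaln(N + 1))
    top = logpmf.max()
    return float((top + math.log(np.exp(logpmf - top).sum())) / math.log(10))


def bh_adjust(pvals: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]
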