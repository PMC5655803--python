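"""Codon-level molecular evolution: NG86 Ka/Ks, fourfold-degenerate sites,
parsimony ancestral reconstruction, unitary-pseudogene dating and codon
bootstrap.

Estimator conventions
---------------------
Ka/Ks uses Nei-Gojobori (1986) counting: per-codon synonymous site fractions
averaged over both sequences, multi-substitution codons averaged over all
minimal substitution paths, and a Jukes-Cantor correction applied to the
proportions. Mutations that create a stop codon are counted as
nonsynonymous; paths passing through a stop codon are excluded from the
path average unless every path does. Codons containing a gap, an ambiguous
base, or a stop in either sequence are excluded from counting.

The pseudogene date comes from a two-epoch mixture: a branch of total
length ``T`` evolves under constrained omega_f until the copy loses
constraint ``t`` My ago, then neutrally (omega = 1), so the observed ratio
is ``omega_obs = (omega_f * (T - t) + t) / T`` and

    t_loss = T * (omega_obs - omega_f) / (1 - omega_f),  clamped to [0, T].
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_table = CodonTable.unambiguous_dna_by_id[1]  # standard genetic code
CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
AA = np.array([("*" if c in _table.stop_codons else _table.forward_table[c])
               for c in CODONS])
IS_STOP = AA == "*"


def codon_code(codon: str) -> int:
    """Encode an ACGT codon as an integer in [0, 64); -1 if not pure ACGT."""
    try:
        return (_BASE_INDEX[codon[0]] * 16 + _BASE_INDEX[codon[1]] * 4
                + _BASE_INDEX[codon[2]])
    except (KeyError, IndexError):
        return -1


def _build_site_tables() -> Tuple[np.ndarray, np.ndarray]:
    syn = np.zeros(64)
    for c in range(64):
        if IS_STOP[c]:
            continue
        codon = CODONS[c]
        for pos in range(3):
            for b in BASES:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1:]
                mc = codon_code(mut)
                if not IS_STOP[mc] and AA[mc] == AA[c]:
                    syn[c] += 1 / 3
    return syn, 3.0 - syn


SYN_SITES, NONSYN_SITES = _build_site_tables()


def _classify_step(c_from: int, c_to: int) -> Tuple[float, float]:
    """(syn, nonsyn) contribution of one single-base codon change."""
    if IS_STOP[c_to] or IS_STOP[c_from]:
        return 0.0, 1.0  # change into/out of stop counted as nonsynonymous
    return (1.0, 0.0) if AA[c_from] == AA[c_to] else (0.0, 1.0)


def _build_path_tables() -> Tuple[np.ndarray, np.ndarray]:
    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    for c1 in range(64):
        for c2 in range(64):
            diff = [p for p in range(3) if CODONS[c1][p] != CODONS[c2][p]]
            if not diff:
                continue
            paths = []
            for order in itertools.permutations(diff):
                cur = CODONS[c1]
                s = n = 0.0
                through_stop = False
                for pos in order:
                    nxt = cur[:pos] + CODONS[c2][pos] + cur[pos + 1:]
                    ds, dn = _classify_step(codon_code(cur), codon_code(nxt))
                    s += ds
                    n += dn
                    if IS_STOP[codon_code(nxt)] and nxt != CODONS[c2]:
                        through_stop = True
                    cur = nxt
                paths.append((s, n, through_stop))
            valid = [p for p in paths if not p[2]] or paths
            sd[c1, c2] = sum(p[0] for p in valid) / len(valid)
            nd[c1, c2] = sum(p[1] for p in valid) / len(valid)
    return sd, nd


SD_TABLE, ND_TABLE = _build_path_tables()


@dataclass
class EvolutionRates:
    """NG86 substitution rates for one sequence pair (or branch)."""

    Ka: float
    Ks: float
    omega: Optional[float]
    Na: float
    Ns: float
    La: float
    Ls: float
    n_codons: int
    undefined: bool = False  # JC correction out of range somewhere


class CodonAlignment:
    """A gapped in-frame multiple alignment keyed by taxon.

    The frame is anchored to the first column; the alignment length must be
    divisible by 3. Gap runs whose length is not a multiple of 3 are
    frameshift candidates (see :func:`detect_frameshift`).
    """

    def __init__(self, sequences: Dict[str, str]):
        if not sequences:
            raise ValueError("alignment needs at least one sequence")
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"unequal alignment lengths: {sorted(lengths)}")
        self.length = lengths.pop()
        if self.length % 3 != 0:
            raise ValueError(f"alignment length {self.length} not divisible by 3")
        self.sequences = {t: s.upper() for t, s in sequences.items()}

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def taxa(self) -> List[str]:
        return list(self.sequences)

    def codon_codes(self, taxon: str) -> np.ndarray:
        """Per-codon integer codes; -1 for codons with gap/ambiguity."""
        seq = self.sequences[taxon]
        return np.array([codon_code(seq[i:i + 3])
                         for i in range(0, self.length, 3)], dtype=np.int64)


def _comparable(ca: np.ndarray, cb: np.ndarray) -> np.ndarray:
    ok = (ca >= 0) & (cb >= 0)
    ok &= ~IS_STOP[np.clip(ca, 0, 63)] & ~IS_STOP[np.clip(cb, 0, 63)]
    return ok


def _jc_correct(p: float) -> Tuple[float, bool]:
    if p >= 0.75:
        return float("nan"), True
    return max(-0.75 * math.log(1.0 - 4.0 * p / 3.0), 0.0), False


def ng86_from_codes(ca: np.ndarray, cb: np.ndarray) -> EvolutionRates:
    """NG86 on pre-encoded codon arrays (gap/stop codons already allowed in
    input; they are dropped here)."""
    ok = _comparable(ca, cb)
    ca, cb = ca[ok], cb[ok]
    n = len(ca)
    if n == 0:
        raise ValueError("no comparable codons")
    Ls = 0.5 * (SYN_SITES[ca].sum() + SYN_SITES[cb].sum())
    La = 0.5 * (NONSYN_SITES[ca].sum() + NONSYN_SITES[cb].sum())
    Sd = SD_TABLE[ca, cb].sum()
    Nd = ND_TABLE[ca, cb].sum()
    pS = Sd / Ls if Ls > 0 else 0.0
    pN = Nd / La if La > 0 else 0.0
    Ks, bad_s = _jc_correct(pS)
    Ka, bad_n = _jc_correct(pN)
    undefined = bad_s or bad_n
    omega = (Ka / Ks) if (not undefined and Ks > 0) else None
    return EvolutionRates(Ka=Ka, Ks=Ks, omega=omega, Na=Nd, Ns=Sd,
                          La=La, Ls=Ls, n_codons=n, undefined=undefined)


def ng86_ka_ks(pair: CodonAlignment,
               taxa: Optional[Tuple[str, str]] = None) -> EvolutionRates:
    """NG86 Ka/Ks between two taxa of an in-frame alignment."""
    if taxa is None:
        names = pair.taxa()
        if len(names) != 2:
            raise ValueError("pair alignment must have exactly 2 taxa (or pass taxa=)")
        taxa = (names[0], names[1])
    return ng86_from_codes(pair.codon_codes(taxa[0]), pair.codon_codes(taxa[1]))


# -- fourfold-degenerate sites ----------------------------------------------

def _build_fourfold() -> np.ndarray:
    ff = np.zeros(16, dtype=bool)
    for i, (b1, b2) in enumerate(itertools.product(BASES, repeat=2)):
        aas = {AA[codon_code(b1 + b2 + b3)] for b3 in BASES}
        ff[i] = len(aas) == 1 and "*" not in aas
    return ff


_FOURFOLD_PREFIX = _build_fourfold()


def fourfold_degenerate_sites(cds: str) -> List[int]:
    """0-based nucleotide positions (third codon positions) that are 4D.

    Codons that are stops (internal or terminal) are skipped.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    out = []
    for i in range(0, len(cds), 3):
        c = codon_code(cds[i:i + 3])
        if c < 0 or IS_STOP[c]:
            continue
        if _FOURFOLD_PREFIX[c // 4]:
            out.append(i + 2)
    return out


def site_conservation(seq_a: str, seq_b: str, positions: Sequence[int]) -> float:
    """Fraction of the listed alignment positions with identical ungapped
    nucleotides. Positions where either sequence is gapped or ambiguous are
    excluded from the denominator."""
    if len(positions) == 0:
        raise ValueError("empty position set")
    a, b = seq_a.upper(), seq_b.upper()
    usable = same = 0
    for p in positions:
        x, y = a[p], b[p]
        if x in BASES and y in BASES:
            usable += 1
            if x == y:
                same += 1
    if usable == 0:
        raise ValueError("no ungapped positions among those listed")
    return same / usable


# -- ancestral reconstruction ------------------------------------------------

def ancestral_at_split(triplet: CodonAlignment, outgroup: str = "T",
                       child_a: str = "L", child_b: str = "S") -> str:
    """Fitch parsimony ancestor of (child_a, child_b) rooted by ``outgroup``.

    Per column: agreement between the two children wins; otherwise the
    outgroup arbitrates; a three-way disagreement yields ``N`` (excluded
    from downstream rate counting by the NG86 gap/ambiguity rule).
    """
    sl = triplet.sequences[child_a]
    ss = triplet.sequences[child_b]
    so = triplet.sequences[outgroup]
    out = []
    for l, s, o in zip(sl, ss, so):
        if l == s:
            out.append(l)
        elif o == l:
            out.append(l)
        elif o == s:
            out.append(s)
        else:
            out.append("N" if not (l == "-" and s == "-") else "-")
    return "".join(out)


# -- dating ------------------------------------------------------------------

@dataclass
class PseudogeneDate:
    """Loss-of-constraint date for a unitary pseudogene, in My before present."""

    t_loss: float
    T: float
    omega_obs: float
    omega_f: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    n_boot: int = 0
    n_dropped: int = 0
    unreliable: bool = False


def date_pseudogene(omega_obs: float, omega_f: float, T: float) -> PseudogeneDate:
    """Closed-form date from the two-epoch omega mixture, clamped to [0, T]."""
    if not 0.0 <= omega_f < 1.0:
        raise ValueError(f"omega_f must be in [0, 1), got {omega_f}")
    t = T * (omega_obs - omega_f) / (1.0 - omega_f)
    return PseudogeneDate(t_loss=min(max(t, 0.0), T), T=T,
                          omega_obs=omega_obs, omega_f=omega_f)


def bootstrap_date(triplet: CodonAlignment, pseudo_taxon: str,
                   functional_taxon: str, outgroup: str, T: float,
                   n_boot: int = 1000, seed: int = 0,
                   omega_f: Optional[float] = None) -> PseudogeneDate:
    """Codon-resampling bootstrap of the pseudogene date.

    Codon columns are resampled with replacement to the original codon
    count; omega on both branches from the reconstructed split ancestor and
    the date are recomputed per replicate. The point estimate comes from
    the unresampled alignment; the CI is the 2.5/97.5 percentile interval.
    Replicates with Ks = 0 (or an undefined JC correction) on the
    pseudogene branch are dropped; if more than half drop, the CI is
    flagged unreliable.
    """
    if triplet.n_codons < 10:
        raise ValueError("need >= 10 aligned codons to bootstrap")
    anc = ancestral_at_split(triplet, outgroup=outgroup,
                             child_a=pseudo_taxon, child_b=functional_taxon)
    anc_codes = np.array([codon_code(anc[i:i + 3])
                          for i in range(0, len(anc), 3)], dtype=np.int64)
    pse_codes = triplet.codon_codes(pseudo_taxon)
    fun_codes = triplet.codon_codes(functional_taxon)

    def estimate(idx: Optional[np.ndarray]) -> Optional[Tuple[float, float, float]]:
        a = anc_codes if idx is None else anc_codes[idx]
        p = pse_codes if idx is None else pse_codes[idx]
        f = fun_codes if idx is None else fun_codes[idx]
        try:
            r_obs = ng86_from_codes(a, p)
        except ValueError:
            return None
        if r_obs.omega is None:
            return None
        if omega_f is not None:
            w_f = omega_f
        else:
            try:
                r_f = ng86_from_codes(a, f)
            except ValueError:
                return None
            if r_f.omega is None or r_f.omega >= 1.0:
                return None
            w_f = r_f.omega
        t = T * (r_obs.omega - w_f) / (1.0 - w_f)
        return min(max(t, 0.0), T), r_obs.omega, w_f

    point = estimate(None)
    if point is None:
        raise ValueError("point estimate undatable (Ks = 0 or omega_f >= 1)")
    t_hat, w_obs, w_f = point

    rng = np.random.default_rng(seed)
    n = triplet.n_codons
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        est = estimate(idx)
        if est is not None:
            reps.append(est[0])
    dropped = n_boot - len(reps)
    if reps:
        lo, hi = np.percentile(reps, [2.5, 97.5])
    else:
        lo = hi = float("nan")
    return PseudogeneDate(t_loss=t_hat, T=T, omega_obs=w_obs, omega_f=w_f,
                          ci_low=float(lo), ci_high=float(hi), n_boot=n_boot,
                          n_dropped=dropped,
                          unreliable=dropped > n_boot / 2)


# -- pseudogene sequence features --------------------------------------------

@dataclass(frozen=True)
class FrameshiftEvent:
    taxon: str
    column: int  # alignment column where the gap run starts
    gap_length: int


def detect_frameshift(pair: CodonAlignment,
                      taxa: Optional[Tuple[str, str]] = None) -> List[FrameshiftEvent]:
    """Gap runs whose length is not a multiple of 3, reported per run.

    Compensated frameshifts (net zero within a window) are still reported
    individually.
    """
    if taxa is None:
        names = pair.taxa()
        taxa = (names[0], names[1])
    events = []
    for taxon in taxa:
        seq = pair.sequences[taxon]
        i = 0
        while i < len(seq):
            if seq[i] == "-":
                j = i
                while j < len(seq) and seq[j] == "-":
                    j += 1
                if (j - i) % 3 != 0:
                    events.append(FrameshiftEvent(taxon, i, j - i))
                i = j
            else:
                i += 1
    return sorted(events, key=lambda e: (e.column, e.taxon))


def detect_premature_stop(cds: str) -> Tuple[List[int], bool]:
    """In-frame stop codons strictly before the terminal codon.

    Returns (0-based codon indices, flagged) where ``flagged`` marks a CDS
    whose length is not a multiple of 3 (the longest in-frame prefix is
    analyzed).
    """
    seq = cds.upper().replace("-", "")
    flagged = len(seq) % 3 != 0
    n = len(seq) // 3
    # when flagged, the annotated terminal codon lies beyond the in-frame
    # prefix, so every prefix codon is strictly before it
    n_check = n if flagged else n - 1
    stops = []
    for i in range(n_check):
        c = codon_code(seq[3 * i:3 * i + 3])
        if c >= 0 and IS_STOP[c]:
            stops.append(i)
    return stops, flagged
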