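"""Independent NG86 oracle used by the unit and acceptance tests.

Implements the published counting rules directly from the genetic code
(via Biopython's translation), sharing no tables with the package: per-codon
synonymous site fractions, minimal-path enumeration for multi-substitution
codons (paths through stop codons excluded unless unavoidable; changes
into/out of stops nonsynonymous), Jukes-Cantor correction of the
proportions.
"""

import itertools
import math

from Bio.Seq import Seq

GENETIC_CODE = {"".join(c): str(Seq("".join(c)).translate())
                for c in itertools.product("ACGT", repeat=3)}


def oracle_sites(codon):
    """(syn, nonsyn) site counts of one codon."""
    syn = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if GENETIC_CODE[mut] != "*" and GENETIC_CODE[mut] == GENETIC_CODE[codon]:
                syn += 1 / 3
    return syn, 3 - syn


def oracle_path_counts(c1, c2):
    """(syn, nonsyn) substitution counts averaged over minimal paths."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur, s, n, bad = c1, 0.0, 0.0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if GENETIC_CODE[cur] == "*" or GENETIC_CODE[nxt] == "*":
                n += 1.0
            elif GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                s += 1.0
            else:
                n += 1.0
            if GENETIC_CODE[nxt] == "*" and nxt != c2:
                bad = True
            cur = nxt
        paths.append((s, n, bad))
    usable = [p for p in paths if not p[2]] or paths
    return (sum(p[0] for p in usable) / len(usable),
            sum(p[1] for p in usable) / len(usable))


def jc(p):
    return float("nan") if p >= 0.75 else max(-0.75 * math.log(1 - 4 * p / 3), 0.0)


def oracle_ng86(seq1, seq2):
    """(Ka, Ks, Nd, Sd, La, Ls, n_codons) for an ungapped in-frame pair;
    codons that are stops in either sequence are excluded."""
    Ls = La = Sd = Nd = 0.0
    n = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        if GENETIC_CODE.get(c1, "*") == "*" or GENETIC_CODE.get(c2, "*") == "*":
            continue
        n += 1
        s1, a1 = oracle_sites(c1)
        s2, a2 = oracle_sites(c2)
        Ls += (s1 + s2) / 2
        La += (a1 + a2) / 2
        ds, dn = oracle_path_counts(c1, c2)
        Sd += ds
        Nd += dn
    pS, pN = Sd / Ls, Nd / La
    return jc(pN), jc(pS), Nd, Sd, La, Ls, n
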