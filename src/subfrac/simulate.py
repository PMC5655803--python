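"""Synthetic outgroup + two-subgenome system with known ground truth.

The generator emulates an allotetraploid with subgenomes L and S and a
diploid outgroup T. Each chromosome is built in a shared ancestral
coordinate space: backbone sequence common to all three genomes, into
which the generator implants

* deletions removed from one subgenome (a configurable fraction carries an
  NAHR signature: a long repeat-family copy inside the lost segment and
  identical copies in both flanks of the retained counterpart),
* private "zones" of novel sequence per subgenome (no alignment to either
  other genome) that host subgenome-specific enhancer peaks,
* protein-coding genes whose codon sequences evolve along the species tree
  ((L,S),T) under per-gene dN/dS, with optional loss of constraint at a
  known time on one branch (unitary pseudogenes),
* background repeats, assembly gaps (N-runs), promoter/enhancer peaks with
  known conservation labels, homeolog-correlated expression with an L
  bias, and coding SNPs with a controlled nonsense fraction.

Alignment blocks between every genome pair are exact by construction
except across implanted deletions and zones, so every downstream stage
can be scored against the truth ledger.
"""

from __future__ import annotations

import bisect
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .codonevol import AA, BASES, CODONS, IS_STOP, codon_code
from .intervals import GenomeInterval, IntervalSet
from .alignments import AlignmentBlock, AlignmentSet, write_block_tsv

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class PackingError(RuntimeError):
    """Feature placement does not fit on the configured chromosomes."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic system.

    Times are in My; rates in substitutions per site per My. Defaults give
    a 10-Mb, 5-chromosome system with a 2:1 S:L deletion bias, an L/S
    split 34 My ago, hybridization 17 My ago, and a neutral synonymous
    divergence of ~0.2 per branch.
    """

    seed: int = 0
    n_chroms: int = 5
    chrom_length: int = 2_000_000
    n_genes: int = 500
    cds_length_range: Tuple[int, int] = (300, 1200)  # multiple of 3 enforced
    repeat_density: float = 0.05
    repeat_length_mean: int = 150
    n_deletions_L: int = 150  # deleted from L (SdL)
    n_deletions_S: int = 300  # deleted from S (LdS)
    deletion_size_range: Tuple[int, int] = (200, 5000)  # log-uniform
    nahr_fraction: float = 0.5
    nahr_repeat_length: int = 800
    T_split: float = 34.0          # L/S progenitor divergence
    hybridization_time: float = 17.0
    outgroup_split: float = 48.0   # divergence of T from the (L,S) ancestor
    neutral_ks_rate: float = 0.2 / 34.0
    functional_omega_beta: Tuple[float, float] = (2.0, 8.0)  # mean 0.2
    pseudogene_fraction: float = 0.2
    pseudogene_s_bias: float = 2.3  # S:L odds of carrying the relaxed copy
    expr_log2_mean: float = 3.0
    expr_log2_sd: float = 2.0
    expr_correlation: float = 0.6
    expr_l_bias_log2: float = 0.08  # ~5.7% median L excess
    pseudogene_expr_factor: float = 1e-3
    nonsense_snp_rate: float = 0.02   # per coding kb
    coding_snp_rate: float = 3.5      # non-nonsense, per coding kb
    n_specific_peaks_per_subgenome: int = 30
    n_p300_per_chrom: int = 40
    p300_conserved_fraction: float = 0.13
    h3k4me3_conserved_fraction: float = 0.40
    peak_width: int = 400
    n_assembly_gaps_per_chrom: int = 2
    assembly_gap_length: int = 200

    def validate(self) -> None:
        for name in ("repeat_density", "nahr_fraction", "pseudogene_fraction",
                     "p300_conserved_fraction", "h3k4me3_conserved_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.T_split >= self.hybridization_time >= 0:
            raise ValueError("need T_split >= hybridization_time >= 0")
        if self.outgroup_split < self.T_split:
            raise ValueError("outgroup_split must be >= T_split")
        if self.chrom_length <= 0 or self.n_chroms <= 0 or self.n_genes <= 0:
            raise ValueError("sizes must be positive")


@dataclass
class TruthDeletion:
    del_id: str
    side: str                    # "LdS" (deleted from S) or "SdL"
    retained: GenomeInterval     # on the genome that kept the sequence
    deleted_genome: str
    gap_chrom: str
    gap_pos: int                 # coordinate of the join on the deleted genome
    size: int
    nahr: bool


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for parameter-recovery tests."""

    config: SimulationConfig
    deletions: List[TruthDeletion]
    relaxation: Dict[str, Tuple[str, float]]   # gene_id -> (branch, t_relax My)
    omega_true: Dict[str, float]               # gene_id -> functional omega
    peak_labels: Dict[str, str]                # peak_id -> conserved|specific|nonconserved
    nonsense: List[Tuple[str, str, int]]       # (gene_id, genome, cds codon index)
    expression: Dict[str, float]               # "gene.L"/"gene.S" -> TPM
    chrom_sizes: Dict[str, Dict[str, int]]     # genome -> chrom -> size
    paths: Dict[str, str]

    def deletions_for_side(self, side: str) -> List[TruthDeletion]:
        return [d for d in self.deletions if d.side == side]


# -- coding-sequence evolution ----------------------------------------------

def evolve_cds(ancestral: str, branch_time: float, omega: float,
               relaxation_time: Optional[float], rate: float,
               seed: int | np.random.Generator = 0) -> Tuple[str, List[Tuple]]:
    """Evolve a CDS along one branch under a Jukes-Cantor proposal process
    with an omega acceptance filter.

    Substitutions are proposed uniformly over positions and alternative
    bases at ``rate`` per site per My; synonymous proposals are always
    accepted (so realized Ks converges to rate x time), nonsynonymous
    proposals are accepted with probability ``omega`` while the gene is
    constrained and always once constraint is lost (``relaxation_time`` My
    before present; the branch ends at the present). Premature stops are
    rejected under constraint. The terminal codon is frozen. Returns the
    descendant sequence and a log of accepted events
    ``(time_before_present, position, ref, alt, kind)``.
    """
    if omega > 1.0:
        raise ValueError(f"constraint model assumes omega <= 1, got {omega}")
    if len(ancestral) % 3 != 0:
        raise ValueError("ancestral CDS length must be divisible by 3")
    seq = list(ancestral.upper())
    n_codons = len(seq) // 3
    for i in range(n_codons - 1):
        c = codon_code("".join(seq[3 * i:3 * i + 3]))
        if c >= 0 and IS_STOP[c]:
            raise ValueError(f"internal stop codon at codon {i}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sites = max(len(seq) - 3, 0)  # terminal codon frozen
    events: List[Tuple] = []
    if branch_time <= 0 or n_sites == 0:
        return "".join(seq), events
    n_prop = rng.poisson(rate * n_sites * branch_time)
    times = np.sort(rng.uniform(0.0, branch_time, size=n_prop))[::-1]  # before present
    positions = rng.integers(0, n_sites, size=n_prop)
    base_choices = rng.integers(0, 3, size=n_prop)
    accept_draws = rng.random(n_prop)
    for t, pos, bc, u in zip(times, positions, base_choices, accept_draws):
        pos = int(pos)
        ref = seq[pos]
        alts = [b for b in BASES if b != ref]
        alt = alts[int(bc)]
        ci = pos // 3
        old_codon = "".join(seq[3 * ci:3 * ci + 3])
        new_codon = old_codon[:pos % 3] + alt + old_codon[pos % 3 + 1:]
        oc, nc = codon_code(old_codon), codon_code(new_codon)
        if oc < 0 or nc < 0:
            continue
        syn = (not IS_STOP[nc]) and (not IS_STOP[oc]) and AA[oc] == AA[nc]
        relaxed = relaxation_time is not None and t <= relaxation_time
        if syn:
            accept = True
            kind = "syn"
        elif IS_STOP[nc]:
            accept = relaxed
            kind = "stop"
        else:
            accept = relaxed or (u < omega)
            kind = "nonsyn"
        if accept:
            seq[pos] = alt
            events.append((float(t), pos, ref, alt, kind))
    return "".join(seq), events


def simulate_expression(n_genes: int, cfg: SimulationConfig,
                        rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Correlated homeolog log2-TPM pairs (L, S) with the configured L bias."""
    a = rng.standard_normal(n_genes)
    b = rng.standard_normal(n_genes)
    rho = cfg.expr_correlation
    zl = cfg.expr_log2_mean + cfg.expr_l_bias_log2 + cfg.expr_log2_sd * a
    zs = cfg.expr_log2_mean + cfg.expr_log2_sd * (rho * a + math.sqrt(1 - rho ** 2) * b)
    return 2.0 ** zl, 2.0 ** zs


# -- placement ---------------------------------------------------------------

class _Packer:
    """Non-overlapping placement of padded features on one chromosome."""

    def __init__(self, size: int, rng: np.random.Generator):
        self.size = size
        self.rng = rng
        self._starts: List[int] = []
        self._ends: List[int] = []

    def place(self, length: int, pad: int, tries: int = 200) -> int:
        lo, hi = pad, self.size - length - pad
        if hi <= lo:
            raise PackingError(f"feature of length {length} cannot fit")
        for _ in range(tries):
            s = int(self.rng.integers(lo, hi))
            if self._free(s - pad, s + length + pad):
                self._insert(s - pad, s + length + pad)
                return s
        raise PackingError(
            f"could not place feature of length {length} after {tries} tries "
            f"(chromosome too crowded)")

    def _free(self, s: int, e: int) -> bool:
        i = bisect.bisect_left(self._starts, e)
        if i > 0 and self._ends[i - 1] > s:
            return False
        return True

    def _insert(self, s: int, e: int) -> None:
        i = bisect.bisect_left(self._starts, s)
        self._starts.insert(i, s)
        self._ends.insert(i, e)


def _random_seq_array(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASE_BYTES[rng.integers(0, 4, size=n)]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random codons without stops, terminated by TAA."""
    non_stop = [c for c in range(64) if not IS_STOP[c]]
    picks = rng.choice(len(non_stop), size=n_codons - 1)
    return "".join(CODONS[non_stop[int(i)]] for i in picks) + "TAA"


def _revcomp(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq))


# -- per-chromosome layout ---------------------------------------------------

@dataclass
class _Deletion:
    start: int  # ancestral coords
    end: int
    target: str  # genome it is deleted from ("L" or "S")
    nahr: bool


@dataclass
class _Gene:
    gene_id: str
    chrom_idx: int
    start: int  # ancestral coords of the CDS
    end: int
    strand: str
    root_cds: str
    cds: Dict[str, str] = field(default_factory=dict)  # per genome
    omega: float = 0.2
    pseudo_branch: Optional[str] = None
    t_relax: Optional[float] = None


@dataclass
class _ChromLayout:
    idx: int
    deletions: List[_Deletion] = field(default_factory=list)
    zones: Dict[str, List[Tuple[int, int]]] = field(default_factory=lambda: {"L": [], "S": []})
    nruns: List[Tuple[int, int]] = field(default_factory=list)
    repeats: List[Tuple[int, int, str]] = field(default_factory=list)  # ancestral
    genes: List[_Gene] = field(default_factory=list)
    p300_cons: List[Tuple[int, int, bool]] = field(default_factory=list)  # (start, end, conserved)
    p300_spec: Dict[str, List[Tuple[int, int]]] = field(default_factory=lambda: {"L": [], "S": []})


def _chrom_name(idx: int, genome: str) -> str:
    return f"chr{idx + 1}{genome}"


def _layout_chromosomes(cfg: SimulationConfig, rng: np.random.Generator,
                        ) -> List[_ChromLayout]:
    layouts = [_ChromLayout(i) for i in range(cfg.n_chroms)]
    packers = [_Packer(cfg.chrom_length, rng) for _ in range(cfg.n_chroms)]
    rl = cfg.nahr_repeat_length
    lo, hi = cfg.deletion_size_range

    def round_robin(n):
        return [i % cfg.n_chroms for i in range(n)]

    # deletions (largest structural footprint first)
    plan = ([("S", k) for k in range(cfg.n_deletions_S)]
            + [("L", k) for k in range(cfg.n_deletions_L)])
    chrom_of = round_robin(len(plan))
    for (target, k), ci in zip(plan, chrom_of):
        nahr = bool(rng.random() < cfg.nahr_fraction)
        size = int(round(10 ** rng.uniform(math.log10(lo), math.log10(hi))))
        if nahr:
            size = max(size, rl + 100)  # must contain the internal repeat copy
        # pad covers the two flank repeat copies and 1-kb flank windows
        pad = max(rl, 0) + 1100
        s = packers[ci].place(size, pad)
        layouts[ci].deletions.append(_Deletion(s, s + size, target, nahr))
        if nahr:
            # identical family copies: both flanks plus the left edge of the
            # lost segment (tandem geometry of an NAHR substrate)
            layouts[ci].repeats.append((s - rl, s, "NAHR_fam"))
            layouts[ci].repeats.append((s, s + rl, "NAHR_fam"))
            layouts[ci].repeats.append((s + size, s + size + rl, "NAHR_fam"))

    # private zones hosting subgenome-specific peaks
    zone_len = cfg.peak_width + 800
    for genome in ("L", "S"):
        for k in range(cfg.n_specific_peaks_per_subgenome):
            ci = k % cfg.n_chroms
            s = packers[ci].place(zone_len, 600)
            layouts[ci].zones[genome].append((s, s + zone_len))

    # genes (promoter window upstream needs clearance)
    lo_cds, hi_cds = cfg.cds_length_range
    for g in range(cfg.n_genes):
        ci = g % cfg.n_chroms
        n_codons = int(rng.integers(lo_cds // 3, hi_cds // 3 + 1))
        length = n_codons * 3
        s = packers[ci].place(length, 1100)
        strand = "+" if rng.random() < 0.5 else "-"
        layouts[ci].genes.append(_Gene(
            gene_id=f"g{g + 1:04d}", chrom_idx=ci, start=s, end=s + length,
            strand=strand, root_cds=_random_cds(rng, n_codons)))

    # assembly gaps
    for ci in range(cfg.n_chroms):
        for _ in range(cfg.n_assembly_gaps_per_chrom):
            s = packers[ci].place(cfg.assembly_gap_length, 300)
            layouts[ci].nruns.append((s, s + cfg.assembly_gap_length))

    # conserved/background p300 peaks
    for ci in range(cfg.n_chroms):
        for _ in range(cfg.n_p300_per_chrom):
            s = packers[ci].place(cfg.peak_width, 100)
            conserved = bool(rng.random() < cfg.p300_conserved_fraction)
            layouts[ci].p300_cons.append((s, s + cfg.peak_width, conserved))

    # background repeats
    n_bg = int(cfg.repeat_density * cfg.chrom_length / cfg.repeat_length_mean)
    for ci in range(cfg.n_chroms):
        for _ in range(n_bg):
            length = int(np.clip(rng.exponential(cfg.repeat_length_mean), 50, 1000))
            try:
                s = packers[ci].place(length, 20, tries=50)
            except PackingError:
                continue  # background repeats are best-effort filler
            layouts[ci].repeats.append((s, s + length, "bg_repeat"))

    # specific peaks centered in their zones
    for ci in range(cfg.n_chroms):
        for genome in ("L", "S"):
            for (zs, ze) in layouts[ci].zones[genome]:
                mid = (zs + ze) // 2
                half = cfg.peak_width // 2
                layouts[ci].p300_spec[genome].append((mid - half, mid + half))

    for lay in layouts:
        lay.deletions.sort(key=lambda d: d.start)
        lay.repeats.sort()
        lay.genes.sort(key=lambda g: g.start)
    return layouts


# -- coordinate mapping ------------------------------------------------------

class _AncestralMap:
    """Maps ancestral coordinates to a genome's own coordinates given the
    segments deleted from that genome."""

    def __init__(self, deleted: Sequence[Tuple[int, int]], length: int):
        self.deleted = sorted(deleted)
        self.length = length
        self._dstarts = np.array([d[0] for d in self.deleted], dtype=np.int64)
        self._dcum = np.concatenate([[0], np.cumsum([d[1] - d[0] for d in self.deleted])]) \
            if self.deleted else np.array([0])
        self._dends = np.array([d[1] for d in self.deleted], dtype=np.int64)

    def out_length(self) -> int:
        return self.length - int(self._dcum[-1])

    def pos(self, p: int) -> int:
        """Genome coordinate of ancestral position p (p must survive)."""
        i = int(np.searchsorted(self._dends, p, side="right"))
        return p - int(self._dcum[i])

    def keep_mask(self) -> np.ndarray:
        mask = np.ones(self.length, dtype=bool)
        for s, e in self.deleted:
            mask[s:e] = False
        return mask


# -- main entry point --------------------------------------------------------

def simulate_system(cfg: SimulationConfig, outdir: str) -> SyntheticTruth:
    """Generate the full synthetic system and write every on-disk format.

    Deterministic for a fixed config (a single seeded generator drives all
    randomness, consumed in a fixed order). Raises :class:`PackingError`
    before any file is written if the features cannot be packed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    layouts = _layout_chromosomes(cfg, rng)

    genomes = ("T", "L", "S")
    t_anc = cfg.outgroup_split - cfg.T_split  # root -> L/S ancestor

    # assign per-gene selection regimes
    all_genes = [g for lay in layouts for g in lay.genes]
    all_genes.sort(key=lambda g: g.gene_id)
    a_om, b_om = cfg.functional_omega_beta
    p_s = cfg.pseudogene_s_bias / (1.0 + cfg.pseudogene_s_bias)
    for g in all_genes:
        g.omega = float(np.clip(rng.beta(a_om, b_om), 0.0, 0.95))
        if rng.random() < cfg.pseudogene_fraction:
            g.pseudo_branch = "S" if rng.random() < p_s else "L"
            g.t_relax = float(rng.uniform(0.0, cfg.T_split))

    # evolve coding sequences: root -> T; root -> anc -> L and S
    rate = cfg.neutral_ks_rate
    for g in all_genes:
        g.cds["T"], _ = evolve_cds(g.root_cds, cfg.outgroup_split, g.omega, None, rate, rng)
        anc_cds, _ = evolve_cds(g.root_cds, t_anc, g.omega, None, rate, rng)
        g.cds["ancestor"] = anc_cds
        for sub in ("L", "S"):
            relax = g.t_relax if g.pseudo_branch == sub else None
            g.cds[sub], _ = evolve_cds(anc_cds, cfg.T_split, g.omega, relax, rate, rng)

    # build ancestral-space sequences per genome
    seqs: Dict[str, List[np.ndarray]] = {g: [] for g in genomes}
    nahr_family = _random_seq_array(rng, cfg.nahr_repeat_length)
    for lay in layouts:
        root = _random_seq_array(rng, cfg.chrom_length)
        for (rs, re, fam) in lay.repeats:
            if fam == "NAHR_fam":
                root[rs:re] = nahr_family[: re - rs]
        for (ns, ne) in lay.nruns:
            root[ns:ne] = ord("N")
        per_genome = {g: root.copy() for g in genomes}
        # zones: novel sequence in the owner only
        for genome in ("L", "S"):
            for (zs, ze) in lay.zones[genome]:
                per_genome[genome][zs:ze] = _random_seq_array(rng, ze - zs)
        # paste evolved CDS
        for gene in lay.genes:
            for genome in genomes:
                cds = gene.cds[genome]
                s = cds if gene.strand == "+" else _revcomp(cds)
                per_genome[genome][gene.start:gene.end] = np.frombuffer(
                    s.encode(), dtype=np.uint8)
        for genome in genomes:
            seqs[genome].append(per_genome[genome])

    # deletion maps per genome / chromosome
    maps: Dict[str, List[_AncestralMap]] = {}
    for genome in genomes:
        maps[genome] = []
        for lay in layouts:
            deleted = [(d.start, d.end) for d in lay.deletions if d.target == genome]
            maps[genome].append(_AncestralMap(deleted, cfg.chrom_length))

    chrom_sizes = {g: {_chrom_name(i, g): maps[g][i].out_length()
                       for i in range(cfg.n_chroms)} for g in genomes}

    os.makedirs(outdir, exist_ok=True)
    paths: Dict[str, str] = {}

    # -- genomes (FASTA) ----------------------------------------------------
    for genome in genomes:
        path = os.path.join(outdir, f"genome_{genome}.fa")
        with open(path, "w") as fh:
            for i in range(cfg.n_chroms):
                arr = seqs[genome][i][maps[genome][i].keep_mask()]
                fh.write(f">{_chrom_name(i, genome)}\n")
                raw = arr.tobytes().decode()
                for j in range(0, len(raw), 80):
                    fh.write(raw[j:j + 80] + "\n")
        paths[f"genome_{genome}"] = path

    # -- truth deletions + alignment blocks ---------------------------------
    truth_dels: List[TruthDeletion] = []
    counter = 0
    for i, lay in enumerate(layouts):
        for d in lay.deletions:
            counter += 1
            retained_genome = "L" if d.target == "S" else "S"
            side = "LdS" if d.target == "S" else "SdL"
            rmap = maps[retained_genome][i]
            dmap = maps[d.target][i]
            truth_dels.append(TruthDeletion(
                del_id=f"del{counter:05d}", side=side,
                retained=GenomeInterval(retained_genome,
                                        _chrom_name(i, retained_genome),
                                        rmap.pos(d.start), rmap.pos(d.end)),
                deleted_genome=d.target,
                gap_chrom=_chrom_name(i, d.target),
                gap_pos=dmap.pos(d.end),
                size=d.end - d.start, nahr=d.nahr))

    pairs = [("L", "T"), ("S", "T"), ("L", "S")]
    min_block = 30
    for ga, gb in pairs:
        blocks = []
        for i, lay in enumerate(layouts):
            excluded = [(d.start, d.end) for d in lay.deletions if d.target in (ga, gb)]
            for genome in (ga, gb):
                excluded.extend(lay.zones.get(genome, []))
            excluded.extend(lay.nruns)
            excluded.sort()
            pos = 0
            segments = []
            for (s, e) in excluded + [(cfg.chrom_length, cfg.chrom_length)]:
                if s - pos >= min_block:
                    segments.append((pos, s))
                pos = max(pos, e)
            for (s, e) in segments:
                ident = float((seqs[ga][i][s:e] == seqs[gb][i][s:e]).mean())
                blocks.append(AlignmentBlock(
                    GenomeInterval(ga, _chrom_name(i, ga),
                                   maps[ga][i].pos(s), maps[ga][i].pos(e)),
                    GenomeInterval(gb, _chrom_name(i, gb),
                                   maps[gb][i].pos(s), maps[gb][i].pos(e)),
                    identity=round(ident, 6), strand="+", reciprocal=True))
        aln = AlignmentSet(blocks, ga, gb)
        path = os.path.join(outdir, f"aln_{ga}_{gb}.tsv")
        write_block_tsv(aln, path, mirror=True)
        paths[f"aln_{ga}_{gb}"] = path

    # -- gene models (GFF3) --------------------------------------------------
    for genome in genomes:
        path = os.path.join(outdir, f"genes_{genome}.gff3")
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, lay in enumerate(layouts):
                chrom = _chrom_name(i, genome)
                gmap = maps[genome][i]
                for gene in lay.genes:
                    gid = f"{gene.gene_id}.{genome}"
                    s, e = gmap.pos(gene.start) + 1, gmap.pos(gene.end)  # 1-based closed
                    fh.write(f"{chrom}\tsynth\tgene\t{s}\t{e}\t.\t{gene.strand}\t.\tID={gid}\n")
                    fh.write(f"{chrom}\tsynth\tmRNA\t{s}\t{e}\t.\t{gene.strand}\t.\t"
                             f"ID={gid}.t1;Parent={gid}\n")
                    fh.write(f"{chrom}\tsynth\tCDS\t{s}\t{e}\t.\t{gene.strand}\t0\t"
                             f"ID={gid}.cds;Parent={gid}.t1\n")
        paths[f"genes_{genome}"] = path

    # -- per-gene codon alignments (FASTA; gap-free by construction) ---------
    genes_dir = os.path.join(outdir, "gene_alignments")
    os.makedirs(genes_dir, exist_ok=True)
    manifest_rows = []
    for gene in all_genes:
        path = os.path.join(genes_dir, f"{gene.gene_id}.fa")
        with open(path, "w") as fh:
            for taxon in ("T", "L", "S"):
                fh.write(f">{taxon}\n{gene.cds[taxon]}\n")
        manifest_rows.append((gene.gene_id, os.path.relpath(path, outdir)))
    gm_path = os.path.join(outdir, "gene_alignments.tsv")
    with open(gm_path, "w") as fh:
        fh.write("gene_id\tpath\n")
        for gid, rel in manifest_rows:
            fh.write(f"{gid}\t{rel}\n")
    paths["gene_alignments"] = gm_path

    # -- repeats (BED per genome) --------------------------------------------
    for genome in genomes:
        path = os.path.join(outdir, f"repeats_{genome}.bed")
        with open(path, "w") as fh:
            for i, lay in enumerate(layouts):
                gmap = maps[genome][i]
                deleted = maps[genome][i].deleted
                for (rs, re, fam) in lay.repeats:
                    if any(ds <= rs and re <= de for ds, de in deleted):
                        continue  # removed with the deletion in this genome
                    if any(rs < de and ds < re for ds, de in deleted):
                        continue  # partially deleted: skip the remnant
                    fh.write(f"{_chrom_name(i, genome)}\t{gmap.pos(rs)}\t"
                             f"{gmap.pos(re)}\t{fam}\t0\t.\n")
        paths[f"repeats_{genome}"] = path

    # -- expression ----------------------------------------------------------
    tpm_l, tpm_s = simulate_expression(len(all_genes), cfg, rng)
    expression: Dict[str, float] = {}
    for gene, tl, ts in zip(all_genes, tpm_l, tpm_s):
        tl, ts = float(tl), float(ts)
        if gene.pseudo_branch == "L":
            tl *= cfg.pseudogene_expr_factor
        elif gene.pseudo_branch == "S":
            ts *= cfg.pseudogene_expr_factor
        expression[f"{gene.gene_id}.L"] = tl
        expression[f"{gene.gene_id}.S"] = ts
    expr_path = os.path.join(outdir, "expression.tsv")
    with open(expr_path, "w") as fh:
        fh.write("gene_id\ttpm\n")
        for gid, tpm in expression.items():
            fh.write(f"{gid}\t{tpm:.6g}\n")
    paths["expression"] = expr_path

    # -- peaks ---------------------------------------------------------------
    peak_labels: Dict[str, str] = {}
    peak_files: Dict[Tuple[str, str], List[Tuple[str, int, int, str]]] = {
        (m, g): [] for m in ("h3k4me3", "p300") for g in genomes}
    pk = 0
    for i, lay in enumerate(layouts):
        for gene in lay.genes:  # promoter peaks on T; conserved ones mirrored
            pk += 1
            pid = f"pk{pk:05d}"
            if gene.strand == "+":
                ps, pe = gene.start - 500, gene.start + 200
            else:
                ps, pe = gene.end - 200, gene.end + 500
            conserved = bool(rng.random() < cfg.h3k4me3_conserved_fraction)
            peak_labels[pid] = "conserved" if conserved else "nonconserved"
            peak_files[("h3k4me3", "T")].append(
                (_chrom_name(i, "T"), maps["T"][i].pos(ps), maps["T"][i].pos(pe), pid))
            if conserved:
                for genome in ("L", "S"):
                    gmap = maps[genome][i]
                    peak_files[("h3k4me3", genome)].append(
                        (_chrom_name(i, genome), gmap.pos(ps), gmap.pos(pe), pid))
        for (ps, pe, conserved) in lay.p300_cons:
            pk += 1
            pid = f"pk{pk:05d}"
            peak_labels[pid] = "conserved" if conserved else "nonconserved"
            peak_files[("p300", "T")].append(
                (_chrom_name(i, "T"), maps["T"][i].pos(ps), maps["T"][i].pos(pe), pid))
            if conserved:
                for genome in ("L", "S"):
                    gmap = maps[genome][i]
                    peak_files[("p300", genome)].append(
                        (_chrom_name(i, genome), gmap.pos(ps), gmap.pos(pe), pid))
        for genome in ("L", "S"):
            for (ps, pe) in lay.p300_spec[genome]:
                pk += 1
                pid = f"pk{pk:05d}"
                peak_labels[pid] = "specific"
                gmap = maps[genome][i]
                peak_files[("p300", genome)].append(
                    (_chrom_name(i, genome), gmap.pos(ps), gmap.pos(pe), pid))
    for (mark, genome), rows in peak_files.items():
        path = os.path.join(outdir, f"{mark}_{genome}.bed")
        with open(path, "w") as fh:
            for chrom, s, e, pid in sorted(rows):
                fh.write(f"{chrom}\t{s}\t{e}\t{pid}\t0\t.\n")
        paths[f"{mark}_{genome}"] = path

    # -- variants (VCF per genome) -------------------------------------------
    nonsense_truth: List[Tuple[str, str, int]] = []
    for genome in genomes:
        path = os.path.join(outdir, f"variants_{genome}.vcf")
        records = []
        for i, lay in enumerate(layouts):
            gmap = maps[genome][i]
            chrom = _chrom_name(i, genome)
            for gene in lay.genes:
                cds = gene.cds[genome]
                kb = len(cds) / 1000.0
                n_non = rng.poisson(cfg.nonsense_snp_rate * kb)
                n_other = rng.poisson(cfg.coding_snp_rate * kb)
                recs, hits = _gene_snps(gene, cds, genome, chrom, gmap, rng,
                                        n_non, n_other)
                records.extend(recs)
                nonsense_truth.extend(hits)
        records.sort(key=lambda r: (r[0], r[1]))
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
            for c, size in chrom_sizes[genome].items():
                fh.write(f"##contig=<ID={c},length={size}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tind1\n")
            for chrom, pos, ref, alt, dp, ad in records:
                fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t50\tPASS\t.\t"
                         f"GT:DP:AD\t0/1:{dp}:{dp - ad},{ad}\n")
        paths[f"variants_{genome}"] = path

    # -- truth ledger --------------------------------------------------------
    relaxation = {g.gene_id: (g.pseudo_branch, g.t_relax)
                  for g in all_genes if g.pseudo_branch is not None}
    omega_true = {g.gene_id: g.omega for g in all_genes}

    td_path = os.path.join(outdir, "truth_deletions.tsv")
    with open(td_path, "w") as fh:
        fh.write("del_id\tside\tretained_genome\tretained_chrom\tretained_start\t"
                 "retained_end\tdeleted_genome\tgap_chrom\tgap_pos\tsize\tnahr\n")
        for d in truth_dels:
            fh.write(f"{d.del_id}\t{d.side}\t{d.retained.genome}\t{d.retained.chrom}\t"
                     f"{d.retained.start}\t{d.retained.end}\t{d.deleted_genome}\t"
                     f"{d.gap_chrom}\t{d.gap_pos}\t{d.size}\t{int(d.nahr)}\n")
    paths["truth_deletions"] = td_path

    tr_path = os.path.join(outdir, "truth_relaxation.tsv")
    with open(tr_path, "w") as fh:
        fh.write("gene_id\tbranch\tt_relax\tomega_functional\n")
        for gid, (branch, t) in relaxation.items():
            fh.write(f"{gid}\t{branch}\t{t:.4f}\t{omega_true[gid]:.4f}\n")
    paths["truth_relaxation"] = tr_path

    tp_path = os.path.join(outdir, "truth_peaks.tsv")
    with open(tp_path, "w") as fh:
        fh.write("peak_id\tlabel\n")
        for pid, label in peak_labels.items():
            fh.write(f"{pid}\t{label}\n")
    paths["truth_peaks"] = tp_path

    tn_path = os.path.join(outdir, "truth_nonsense.tsv")
    with open(tn_path, "w") as fh:
        fh.write("gene_id\tgenome\tcodon_index\n")
        for gid, genome, ci in nonsense_truth:
            fh.write(f"{gid}\t{genome}\t{ci}\n")
    paths["truth_nonsense"] = tn_path

    manifest = {
        "seed": cfg.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "chrom_sizes": chrom_sizes,
        "paths": {k: os.path.relpath(v, outdir) for k, v in paths.items()},
    }
    man_path = os.path.join(outdir, "manifest.yaml")
    with open(man_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    paths["manifest"] = man_path

    return SyntheticTruth(config=cfg, deletions=truth_dels, relaxation=relaxation,
                          omega_true=omega_true, peak_labels=peak_labels,
                          nonsense=nonsense_truth, expression=expression,
                          chrom_sizes=chrom_sizes, paths=paths)


def _gene_snps(gene: _Gene, cds: str, genome: str, chrom: str,
               gmap: _AncestralMap, rng: np.random.Generator,
               n_nonsense: int, n_other: int):
    """Implant coding SNPs for one gene; returns (vcf_records, nonsense_truth)."""
    records = []
    hits = []
    n_codons = len(cds) // 3

    def genome_pos_ref_alt(cds_pos: int, alt_base: str) -> Tuple[int, str, str]:
        if gene.strand == "+":
            apos = gene.start + cds_pos
            return gmap.pos(apos) + 1, cds[cds_pos], alt_base
        apos = gene.end - 1 - cds_pos
        return gmap.pos(apos) + 1, _COMP[cds[cds_pos]], _COMP[alt_base]

    used = set()
    for _ in range(n_nonsense):
        placed = False
        for _try in range(50):
            ci = int(rng.integers(1, max(n_codons - 1, 2)))
            codon = cds[3 * ci:3 * ci + 3]
            cc = codon_code(codon)
            if cc < 0 or IS_STOP[cc]:
                continue
            options = []
            for p in range(3):
                for b in BASES:
                    if b == codon[p]:
                        continue
                    mc = codon_code(codon[:p] + b + codon[p + 1:])
                    if IS_STOP[mc]:
                        options.append((p, b))
            if not options:
                continue
            p, b = options[int(rng.integers(0, len(options)))]
            cds_pos = 3 * ci + p
            if cds_pos in used:
                continue
            used.add(cds_pos)
            pos, ref, alt = genome_pos_ref_alt(cds_pos, b)
            dp = int(rng.integers(10, 61))
            ad = int(rng.integers(4, dp + 1))
            records.append((chrom, pos, ref, alt, dp, ad))
            hits.append((gene.gene_id, genome, ci))
            placed = True
            break
        if not placed:
            continue
    for _ in range(n_other):
        for _try in range(50):
            cds_pos = int(rng.integers(0, len(cds) - 3))  # keep terminal codon
            if cds_pos in used:
                continue
            ref_b = cds[cds_pos]
            if ref_b not in BASES:
                continue
            alts = [b for b in BASES if b != ref_b]
            b = alts[int(rng.integers(0, 3))]
            ci = cds_pos // 3
            codon = cds[3 * ci:3 * ci + 3]
            mc = codon_code(codon[:cds_pos % 3] + b + codon[cds_pos % 3 + 1:])
            if mc < 0 or IS_STOP[mc]:
                continue
            used.add(cds_pos)
            pos, ref, alt = genome_pos_ref_alt(cds_pos, b)
            dp = int(rng.integers(10, 61))
            ad = int(rng.integers(4, dp + 1))
            records.append((chrom, pos, ref, alt, dp, ad))
            break
    return records, hits
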