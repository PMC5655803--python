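"""Pseudogene feature classification, loss-of-function variant analysis and
protein-complex retention.

Four non-exclusive pseudogene feature classes per homeolog copy:
``premature_stop`` (in-frame stop before the terminal codon),
``truncated_50`` (CDS at least 50% shorter than both the homeolog and the
outgroup ortholog), ``promoter_loss_75`` (at least 75% of the homeolog's
H3K4me3-decorated promoter, projected through the subgenome alignment,
falls in called deletions or unaligned sequence) and ``frameshift`` (gap
run of length not divisible by 3 in the pairwise codon alignment). A
likely pseudogene additionally must be expressed at least tenfold lower
than its homeolog (or not expressed at all in the strict mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from . import codonevol
from .alignments import AlignmentSet, project
from .intervals import GenomeInterval, IntervalSet
from .randomization import chi_squared_2x2

logger = logging.getLogger(__name__)

FEATURES = ("premature_stop", "truncated_50", "promoter_loss_75", "frameshift")
DELETION_FEATURES = ("truncated_50", "promoter_loss_75")


@dataclass
class GeneTriangle:
    """Per-gene record tying the outgroup ortholog and both homeologs."""

    gene_id: str
    cds: Dict[str, Optional[str]] = field(default_factory=dict)       # taxon -> CDS
    expression: Dict[str, Optional[float]] = field(default_factory=dict)
    promoter: Dict[str, Optional[GenomeInterval]] = field(default_factory=dict)
    features: Dict[str, Set[str]] = field(default_factory=lambda: {"L": set(), "S": set()})
    rates: Dict[str, object] = field(default_factory=dict)            # branch -> EvolutionRates
    date: Optional[codonevol.PseudogeneDate] = None
    flags: List[str] = field(default_factory=list)


def promoter_interval(tss: GenomeInterval, h3k4me3: IntervalSet,
                      fallback_halfwidth: int = 500) -> GenomeInterval:
    """The H3K4me3 peak overlapping the TSS, else TSS +/- 500 bp."""
    point = GenomeInterval(tss.genome, tss.chrom, tss.start, tss.start + 1)
    for peak in h3k4me3:
        if peak.overlaps(point):
            return peak
    start = max(tss.start - fallback_halfwidth, 0)
    return GenomeInterval(tss.genome, tss.chrom, start,
                          tss.start + fallback_halfwidth)


def classify_pseudogene_features(
        triangle: GeneTriangle,
        deletions: Mapping[str, IntervalSet],
        aln_LS: Optional[AlignmentSet] = None,
        pair_alignments: Optional[Mapping[str, codonevol.CodonAlignment]] = None,
        ) -> GeneTriangle:
    """Evaluate the four feature booleans on each existing homeolog copy.

    ``deletions[sub]`` are deletion gap intervals on subgenome ``sub``;
    ``pair_alignments[sub]`` is the copy-vs-homeolog codon alignment used
    for frameshift detection (skipped when absent).
    """
    for sub, other in (("L", "S"), ("S", "L")):
        cds = triangle.cds.get(sub)
        if cds is None:
            triangle.features[sub] = set()
            continue
        feats = triangle.features.setdefault(sub, set())
        stops, flagged = codonevol.detect_premature_stop(cds)
        if flagged:
            triangle.flags.append(f"{sub}:cds_not_multiple_of_3")
        if stops:
            feats.add("premature_stop")
        ortho = triangle.cds.get("T")
        homeo = triangle.cds.get(other)
        if homeo is not None:
            own = len(cds.replace("-", ""))
            thr_h = 0.5 * len(homeo.replace("-", ""))
            if ortho is None:
                triangle.flags.append(f"{sub}:truncation_vs_homeolog_only")
                if own < thr_h:
                    feats.add("truncated_50")
            elif own < thr_h and own < 0.5 * len(ortho.replace("-", "")):
                feats.add("truncated_50")
        if _promoter_lost(triangle, sub, other, deletions, aln_LS):
            feats.add("promoter_loss_75")
        if pair_alignments and sub in pair_alignments:
            events = codonevol.detect_frameshift(pair_alignments[sub])
            if any(e.taxon == sub for e in events):
                feats.add("frameshift")
    return triangle


def _promoter_lost(triangle: GeneTriangle, sub: str, other: str,
                   deletions: Mapping[str, IntervalSet],
                   aln_LS: Optional[AlignmentSet],
                   threshold: float = 0.75) -> bool:
    """>= 75% of the homeolog's promoter projects into deletions or nothing."""
    promoter = triangle.promoter.get(other)
    if promoter is None or aln_LS is None:
        return False
    projected = project(promoter, aln_LS, sub)
    aligned_bp = projected.total_bp()
    lost = promoter.length - min(aligned_bp, promoter.length)
    dels = deletions.get(sub)
    if dels is not None:
        lost += sum(dels.covered_bp(iv) for iv in projected)
    return lost / promoter.length >= threshold


def call_likely_pseudogenes(triangles: Iterable[GeneTriangle],
                            expression_floor: float = 1.0,
                            fold: float = 10.0,
                            mode: str = "tenfold") -> Dict[str, List[str]]:
    """Genes with >= 1 feature whose expression is at least ``fold`` lower
    than the homeolog's, the homeolog being expressed (TPM >= floor).

    ``mode='no_expression'`` is the stricter variant: the candidate itself
    must fall below the expression floor.
    """
    out: Dict[str, List[str]] = {"L": [], "S": []}
    n_excluded = 0
    for tri in triangles:
        for sub, other in (("L", "S"), ("S", "L")):
            if not tri.features.get(sub):
                continue
            own = tri.expression.get(sub)
            homeo = tri.expression.get(other)
            if own is None or homeo is None:
                n_excluded += 1
                continue
            if homeo < expression_floor:
                continue
            if mode == "no_expression":
                if own < expression_floor:
                    out[sub].append(tri.gene_id)
            elif own < homeo / fold:
                out[sub].append(tri.gene_id)
    if n_excluded:
        logger.info("%d candidate copies lacked expression data", n_excluded)
    return out


def exclusive_class(features: Set[str]) -> str:
    """Deterministic partition into one cause class per gene.

    Deletion-associated features (truncation, promoter loss) take priority
    over point-mutation features; a gene with several point features and no
    deletion feature is 'multiple'.
    """
    if not features:
        raise ValueError("gene has no pseudogene feature")
    if features & set(DELETION_FEATURES):
        return "deletion-driven"
    if len(features) == 1:
        return {"premature_stop": "stop-only", "frameshift": "frameshift-only"}[
            next(iter(features))]
    return "multiple"


# -- nonsense (PTV) analysis -------------------------------------------------

@dataclass
class PtvRecord:
    gene_id: str
    chrom: str
    pos: int            # 1-based VCF coordinate
    ref: str
    alt: str
    codon_index: int    # 0-based within the CDS
    ref_codon: str
    alt_codon: str
    depth: int
    alt_reads: int


@dataclass
class CdsModel:
    gene_id: str
    chrom: str
    start: int   # 0-based half-open, genome coordinates
    end: int
    strand: str


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def read_cds_models(gff3_path: str, genome: str = "") -> List[CdsModel]:
    """Single-exon CDS models from a GFF3 (type CDS, gene id from Parent/ID)."""
    from .intervals import read_intervals

    ivs = read_intervals(gff3_path, "gff3", genome, feature_types=["CDS"])
    models = []
    for iv in ivs:
        attrs = dict(kv.split("=", 1) for kv in iv.label.split(";") if "=" in kv)
        gid = attrs.get("Parent", attrs.get("ID", "unknown"))
        for suffix in (".cds", ".t1"):
            if gid.endswith(suffix):
                gid = gid[: -len(suffix)]
        models.append(CdsModel(gid, iv.chrom, iv.start, iv.end, iv.strand))
    return models


def annotate_nonsense(vcf_path: str, models: Sequence[CdsModel], genome,
                      min_depth: int = 10, min_alt_reads: int = 4
                      ) -> Tuple[List[PtvRecord], Dict[str, bool], Dict[str, int]]:
    """Flag SNPs that introduce a premature stop codon inside annotated CDS.

    ``genome`` is a mapping chrom -> sequence (``pyfaidx.Fasta`` works).
    Returns (nonsense records, per-gene has-nonsense flags, counters).
    The depth filters mirror the variant post-filter: >= 10x coverage with
    >= 4 alternative-allele observations. Records whose REF disagrees with
    the genome sequence are skipped and counted.
    """
    import pysam

    by_chrom: Dict[str, List[CdsModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    flags = {m.gene_id: False for m in models}
    records: List[PtvRecord] = []
    counts = {"n_snps": 0, "n_coding": 0, "n_filtered": 0, "n_ref_mismatch": 0,
              "n_nonsense": 0}
    vcf = pysam.VariantFile(vcf_path)
    for rec in vcf:
        if rec.alts is None or len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            continue
        counts["n_snps"] += 1
        dp, ad_alt = _depths(rec)
        if dp is not None and (dp < min_depth or (ad_alt is not None
                                                  and ad_alt < min_alt_reads)):
            counts["n_filtered"] += 1
            continue
        pos0 = rec.pos - 1
        for m in by_chrom.get(rec.chrom, []):
            if not (m.start <= pos0 < m.end):
                continue
            counts["n_coding"] += 1
            genome_ref = str(genome[m.chrom][pos0:pos0 + 1]).upper()
            if genome_ref != rec.ref.upper():
                counts["n_ref_mismatch"] += 1
                logger.debug("REF mismatch at %s:%d", rec.chrom, rec.pos)
                continue
            if m.strand == "-":
                cds_pos = m.end - 1 - pos0
                ref_b = _COMP[rec.ref.upper()]
                alt_b = _COMP[rec.alts[0].upper()]
            else:
                cds_pos = pos0 - m.start
                ref_b = rec.ref.upper()
                alt_b = rec.alts[0].upper()
            ci = cds_pos // 3
            n_codons = (m.end - m.start) // 3
            if ci >= n_codons - 1:
                continue  # terminal codon: not premature
            codon = _cds_codon(genome, m, ci)
            if codon[cds_pos % 3] != ref_b:
                counts["n_ref_mismatch"] += 1
                continue
            alt_codon = codon[: cds_pos % 3] + alt_b + codon[cds_pos % 3 + 1:]
            cc = codonevol.codon_code(alt_codon)
            if cc >= 0 and codonevol.IS_STOP[cc]:
                counts["n_nonsense"] += 1
                flags[m.gene_id] = True
                records.append(PtvRecord(m.gene_id, rec.chrom, rec.pos,
                                         rec.ref, rec.alts[0], ci, codon,
                                         alt_codon, dp or 0, ad_alt or 0))
    return records, flags, counts


def _depths(rec) -> Tuple[Optional[int], Optional[int]]:
    for sample in rec.samples.values():
        dp = sample.get("DP")
        ad = sample.get("AD")
        alt = ad[1] if ad is not None and len(ad) > 1 else None
        return dp, alt
    return None, None


def _cds_codon(genome, m: CdsModel, codon_index: int) -> str:
    if m.strand == "+":
        s = m.start + 3 * codon_index
        return str(genome[m.chrom][s:s + 3]).upper()
    e = m.end - 3 * codon_index
    seq = str(genome[m.chrom][e - 3:e]).upper()
    return "".join(_COMP[b] for b in reversed(seq))


def lof_summary(gene_totals: Mapping[str, int],
                flagged_counts: Mapping[str, int],
                coding_snp_totals: Optional[Mapping[str, int]] = None,
                nonsense_counts: Optional[Mapping[str, int]] = None
                ) -> Dict[str, object]:
    """Per-genome LOF fractions and pairwise chi-squared comparisons.

    ``gene_totals``/``flagged_counts`` give annotated genes and genes with
    >= 1 nonsense variant; optional ``coding_snp_totals``/``nonsense_counts``
    yield the nonsense-per-coding-SNP rate.
    """
    out: Dict[str, object] = {"fractions": {}, "chi_squared": {},
                              "nonsense_rate": {}}
    for g, total in gene_totals.items():
        if total <= 0:
            raise ValueError(f"zero gene total for {g}")
        out["fractions"][g] = flagged_counts[g] / total
    if coding_snp_totals and nonsense_counts:
        for g in coding_snp_totals:
            out["nonsense_rate"][g] = nonsense_counts[g] / coding_snp_totals[g]
    names = sorted(gene_totals)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            try:
                stat, p = chi_squared_2x2(
                    flagged_counts[a], gene_totals[a] - flagged_counts[a],
                    flagged_counts[b], gene_totals[b] - flagged_counts[b])
            except ValueError:  # a zero margin (no flagged genes anywhere)
                stat, p = float("nan"), float("nan")
            out["chi_squared"][f"{a}_vs_{b}"] = {"statistic": stat, "p": p}
    return out


# -- protein-complex retention ------------------------------------------------

@dataclass
class ComplexLossSummary:
    n_total: int
    n_both_dual: int
    n_one_single: int
    n_both_single: int
    observed_fraction: float
    expected_fraction: float
    q: float


def complex_retention(dimers: Sequence[Tuple[str, str]],
                      copy_status: Mapping[str, str],
                      q: Optional[float] = None) -> ComplexLossSummary:
    """Classify fully represented heterodimers by homeolog copy status.

    A dimer is fully represented when both members are present (``dual`` or
    ``single``). ``observed_fraction`` is the share of dimers with both
    members single-copy; the expectation under independent loss is
    ``q**2`` with ``q`` either supplied (genome-wide single-copy rate) or
    estimated from the classified dimers.
    """
    n_dual = n_one = n_both = 0
    for a, b in dimers:
        sa, sb = copy_status.get(a, "absent"), copy_status.get(b, "absent")
        if sa == "absent" or sb == "absent":
            continue
        singles = (sa == "single") + (sb == "single")
        if singles == 0:
            n_dual += 1
        elif singles == 1:
            n_one += 1
        else:
            n_both += 1
    return summarize_complex_counts(n_dual, n_one, n_both, q)


def summarize_complex_counts(n_both_dual: int, n_one_single: int,
                             n_both_single: int,
                             q: Optional[float] = None) -> ComplexLossSummary:
    """Build the summary directly from the three printed counts."""
    n_total = n_both_dual + n_one_single + n_both_single
    observed = n_both_single / n_total if n_total else 0.0
    if q is None:
        q = ((n_one_single + 2 * n_both_single) / (2 * n_total)) if n_total else 0.0
    return ComplexLossSummary(n_total, n_both_dual, n_one_single, n_both_single,
                              observed_fraction=observed,
                              expected_fraction=q * q, q=q)
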