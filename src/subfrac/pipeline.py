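"""End-to-end orchestration: simulate -> deletion calling -> enrichment ->
NAHR -> codon evolution & dating -> gene loss -> regulatory statistics.

Every stage writes one TSV/JSON artifact into the run directory and the
final report collects its numbers from those files (no recomputation), so
a seeded run is byte-reproducible.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
from Bio import SeqIO
from pyfaidx import Fasta

from . import codonevol, deletions, geneloss, nahr, regulatory
from .alignments import AlignmentSet, read_alignment_blocks
from .intervals import GenomeInterval, IntervalSet, read_intervals
from .randomization import (FeatureClass, compare_fold_between_genomes,
                            deletion_enrichment)
from .simulate import SimulationConfig, SyntheticTruth, simulate_system


def _read_expression(path: str) -> Dict[str, float]:
    out = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            gid, tpm = line.split("\t")
            out[gid] = float(tpm)
    return out


def load_alignments(simdir: str) -> Dict[str, AlignmentSet]:
    return {
        "LT": read_alignment_blocks(os.path.join(simdir, "aln_L_T.tsv"), "block-tsv"),
        "ST": read_alignment_blocks(os.path.join(simdir, "aln_S_T.tsv"), "block-tsv"),
        "LS": read_alignment_blocks(os.path.join(simdir, "aln_L_S.tsv"), "block-tsv"),
    }


def call_all_deletions(simdir: str, alns: Mapping[str, AlignmentSet],
                       use_gap_filter: bool = True
                       ) -> Dict[str, object]:
    """Candidates + calls for both sides (LdS retained on L, SdL on S)."""
    out: Dict[str, object] = {}
    for retained, aln_xt in (("L", alns["LT"]), ("S", alns["ST"])):
        gaps = None
        if use_gap_filter:
            gaps = deletions.assembly_gaps(
                os.path.join(simdir, f"genome_{retained}.fa"), retained)
        cands = deletions.candidate_regions(aln_xt, alns["LS"], retained, gaps)
        calls, summary = deletions.call_deletions(cands, alns["LS"], retained)
        side = "LdS" if retained == "L" else "SdL"
        out[side] = {"candidates": cands, "calls": calls, "summary": summary}
    return out


def build_feature_classes(simdir: str, subgenome: str,
                          alns: Mapping[str, AlignmentSet],
                          chrom_sizes: Mapping[str, int]) -> List[FeatureClass]:
    """Feature classes on ``subgenome`` using the sister homeolog's
    annotation projected through the L<->S alignment as a proxy for the
    pre-deletion state (plus own-genome intergenic space)."""
    from .alignments import project

    sister = "S" if subgenome == "L" else "L"
    aln_ls = alns["LS"]
    classes = []
    sister_genes = read_intervals(os.path.join(simdir, f"genes_{sister}.gff3"),
                                  "gff3", sister, feature_types=["CDS"])
    projected = []
    for iv in sister_genes:
        projected.extend(project(iv, aln_ls, subgenome))
    exonic = IntervalSet(projected, genome=subgenome).merge()
    classes.append(FeatureClass("Exonic", exonic))
    # intergenic: >= 1 kb from any (projected) gene
    near_genes = IntervalSet(
        [GenomeInterval(subgenome, iv.chrom, max(iv.start - 1000, 0), iv.end + 1000)
         for iv in exonic], genome=subgenome).merge()
    whole = IntervalSet([GenomeInterval(subgenome, c, 0, size)
                         for c, size in chrom_sizes.items()], genome=subgenome)
    classes.append(FeatureClass("Intergenic", whole.subtract(near_genes)))
    for mark in ("h3k4me3", "p300"):
        sister_peaks = read_intervals(os.path.join(simdir, f"{mark}_{sister}.bed"),
                                      "bed", sister)
        proj = []
        for iv in sister_peaks:
            proj.extend(project(iv, aln_ls, subgenome))
        name = "H3K4me3" if mark == "h3k4me3" else "p300"
        classes.append(FeatureClass(name, IntervalSet(proj, genome=subgenome).merge()))
    return classes


def load_gene_triangles(simdir: str) -> Dict[str, codonevol.CodonAlignment]:
    """Per-gene codon alignments (taxa T, L, S) from the manifest."""
    out = {}
    man = os.path.join(simdir, "gene_alignments.tsv")
    with open(man) as fh:
        fh.readline()
        for line in fh:
            gid, rel = line.strip().split("\t")
            seqs = {rec.id: str(rec.seq)
                    for rec in SeqIO.parse(os.path.join(simdir, rel), "fasta")}
            out[gid] = codonevol.CodonAlignment(seqs)
    return out


def gene_evolution_table(alignments: Mapping[str, codonevol.CodonAlignment],
                         T_my: float) -> List[Dict[str, object]]:
    """Per-gene branch rates from the reconstructed split ancestor."""
    rows = []
    for gid in sorted(alignments):
        aln = alignments[gid]
        anc = codonevol.ancestral_at_split(aln)
        row: Dict[str, object] = {"gene_id": gid}
        for sub in ("L", "S"):
            pair = codonevol.CodonAlignment({"anc": anc, sub: aln.sequences[sub]})
            try:
                rates = codonevol.ng86_from_codes(pair.codon_codes("anc"),
                                                  pair.codon_codes(sub))
            except ValueError:
                rates = None
            row[f"Ka_{sub}"] = rates.Ka if rates else float("nan")
            row[f"Ks_{sub}"] = rates.Ks if rates else float("nan")
            row[f"omega_{sub}"] = (rates.omega if rates and rates.omega is not None
                                   else float("nan"))
        rows.append(row)
    return rows


def date_pseudogene_set(alignments: Mapping[str, codonevol.CodonAlignment],
                        candidates: Mapping[str, str], T_my: float,
                        n_boot: int, seed: int) -> List[Dict[str, object]]:
    """Bootstrap-dated loss-of-constraint times for candidate pseudogenes.

    ``candidates`` maps gene_id -> pseudogenized subgenome branch.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for gid in sorted(candidates):
        branch = candidates[gid]
        functional = "S" if branch == "L" else "L"
        aln = alignments.get(gid)
        if aln is None:
            continue
        try:
            date = codonevol.bootstrap_date(
                aln, pseudo_taxon=branch, functional_taxon=functional,
                outgroup="T", T=T_my, n_boot=n_boot,
                seed=int(rng.integers(0, 2 ** 31 - 1)))
        except ValueError:
            continue
        rows.append({"gene_id": gid, "branch": branch, "t_loss": date.t_loss,
                     "ci_low": date.ci_low, "ci_high": date.ci_high,
                     "omega_obs": date.omega_obs, "omega_f": date.omega_f,
                     "unreliable": date.unreliable})
    return rows


def run_pipeline(outdir: str, seed: int = 0,
                 config: Optional[SimulationConfig] = None,
                 n_rand: int = 200, n_boot: int = 100,
                 n_nahr_regions: int = 60) -> Dict[str, object]:
    """The simulate -> analyse happy path; returns the report dict and
    writes per-stage artifacts plus ``report.json`` under ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    cfg = config or SimulationConfig()
    cfg.seed = seed
    simdir = os.path.join(outdir, "sim")
    truth = simulate_system(cfg, simdir)
    report: Dict[str, object] = {"seed": seed}

    # -- deletion calling ----------------------------------------------------
    alns = load_alignments(simdir)
    delres = call_all_deletions(simdir, alns)
    calls_all = list(delres["LdS"]["calls"]) + list(delres["SdL"]["calls"])
    deletions.write_deletions_bed(calls_all, os.path.join(outdir, "deletions.bed"))
    n_lds = len(delres["LdS"]["calls"])
    n_sdl = len(delres["SdL"]["calls"])
    score = deletions.score_against_truth(calls_all, truth.deletions)
    report["deletions"] = {
        "n_LdS": n_lds, "n_SdL": n_sdl,
        "share_LdS_pct": round(100.0 * n_lds / max(n_lds + n_sdl, 1), 2),
        "precision": round(score["precision"], 4),
        "recall": round(score["recall"], 4),
    }

    # -- enrichment ----------------------------------------------------------
    enrich_results = {}
    for retained, side in (("L", "LdS"), ("S", "SdL")):
        dels = IntervalSet([c.retained_region for c in delres[side]["calls"]],
                           genome=retained)
        classes = build_feature_classes(simdir, retained, alns,
                                        truth.chrom_sizes[retained])
        enrich_results[retained] = deletion_enrichment(
            dels, classes, truth.chrom_sizes[retained],
            n_rand=n_rand, seed=seed + 1)
    with open(os.path.join(outdir, "enrichment.tsv"), "w") as fh:
        fh.write("genome\tfeature\tchrom\tobserved_bp\texpected_bp\tsd_bp\t"
                 "log2_fold\tz\tp\tq\n")
        for genome, results in sorted(enrich_results.items()):
            for r in results:
                fh.write(f"{genome}\t{r.feature}\t{r.chromosome}\t{r.observed_bp}\t"
                         f"{r.expected_bp:.2f}\t{r.sd_bp:.2f}\t{r.log2_fold:.4f}\t"
                         f"{r.z:.4f}\t{r.p:.3e}\t{r.q:.3e}\n")
    lvss = compare_fold_between_genomes(enrich_results["L"], enrich_results["S"])
    report["enrichment_L_vs_S"] = {k: {"p": round(v["p"], 6)} for k, v in lvss.items()}

    # -- NAHR ----------------------------------------------------------------
    retained_L = [c.retained_region for c in delres["LdS"]["calls"]][:n_nahr_regions]
    repeats_L = read_intervals(os.path.join(simdir, "repeats_L.bed"), "bed", "L")
    rep = nahr.repeat_length_ratio(retained_L, repeats_L,
                                   truth.chrom_sizes["L"], seed=seed + 2)
    genome_L = Fasta(os.path.join(simdir, "genome_L.fa"))
    flank = nahr.flank_similarity(retained_L, genome_L, truth.chrom_sizes["L"],
                                  n_random_pairs=n_nahr_regions, seed=seed + 3)
    report["nahr"] = {
        "repeat_length_ratio": round(rep.get("ratio", float("nan")), 3)
        if not rep.get("flagged") else None,
        "repeat_length_p": rep.get("mann_whitney_p"),
        "mean_flank_identity": round(float(np.mean(flank.similarities)), 4)
        if flank.similarities else None,
        "mean_random_identity": round(float(np.mean(flank.random_similarities)), 4),
        "flank_similarity_p": flank.mann_whitney_p,
    }

    # -- codon evolution and dating ------------------------------------------
    gene_alns = load_gene_triangles(simdir)
    evo_rows = gene_evolution_table(gene_alns, cfg.T_split)
    with open(os.path.join(outdir, "gene_rates.tsv"), "w") as fh:
        cols = ["gene_id", "Ka_L", "Ks_L", "omega_L", "Ka_S", "Ks_S", "omega_S"]
        fh.write("\t".join(cols) + "\n")
        for row in evo_rows:
            fh.write("\t".join(f"{row[c]:.5f}" if c != "gene_id" else row[c]
                               for c in cols) + "\n")

    # pseudogene candidates: feature + tenfold-lower expression
    expression = _read_expression(os.path.join(simdir, "expression.tsv"))
    candidates: Dict[str, str] = {}
    for gid, aln in gene_alns.items():
        for sub, other in (("L", "S"), ("S", "L")):
            cds = aln.sequences[sub].replace("-", "")
            stops, _ = codonevol.detect_premature_stop(cds)
            own = expression.get(f"{gid}.{sub}", 0.0)
            homeo = expression.get(f"{gid}.{other}", 0.0)
            if stops and homeo >= 1.0 and own < homeo / 10.0:
                candidates[gid] = sub
    dates = date_pseudogene_set(gene_alns, candidates, cfg.T_split,
                                n_boot=n_boot, seed=seed + 4)
    with open(os.path.join(outdir, "pseudogene_dates.tsv"), "w") as fh:
        fh.write("gene_id\tbranch\tt_loss\tci_low\tci_high\tomega_obs\tomega_f\n")
        for row in dates:
            fh.write(f"{row['gene_id']}\t{row['branch']}\t{row['t_loss']:.3f}\t"
                     f"{row['ci_low']:.3f}\t{row['ci_high']:.3f}\t"
                     f"{row['omega_obs']:.4f}\t{row['omega_f']:.4f}\n")
    by_branch = {"L": 0, "S": 0}
    for row in dates:
        by_branch[row["branch"]] += 1
    hist, edges = np.histogram([r["t_loss"] for r in dates],
                               bins=np.arange(0, cfg.T_split + 2, 2.0))
    report["pseudogenes"] = {
        "n_dated": len(dates),
        "n_on_L": by_branch["L"], "n_on_S": by_branch["S"],
        "date_histogram_2My_bins": hist.tolist(),
    }

    # -- LOF variants --------------------------------------------------------
    lof_totals, lof_flagged = {}, {}
    for genome in ("L", "S", "T"):
        models = geneloss.read_cds_models(
            os.path.join(simdir, f"genes_{genome}.gff3"), genome)
        fa = Fasta(os.path.join(simdir, f"genome_{genome}.fa"))
        _, flags, counts = geneloss.annotate_nonsense(
            os.path.join(simdir, f"variants_{genome}.vcf"), models, fa)
        lof_totals[genome] = len(models)
        lof_flagged[genome] = sum(flags.values())
    lof = geneloss.lof_summary(lof_totals, lof_flagged)
    report["lof"] = {
        "fraction_pct": {g: round(100.0 * f, 3) for g, f in lof["fractions"].items()},
    }

    # -- regulatory landscape ------------------------------------------------
    reg: Dict[str, object] = {}
    for mark in ("h3k4me3", "p300"):
        t_peaks = regulatory.PeakSet(
            read_intervals(os.path.join(simdir, f"{mark}_T.bed"), "bed", "T"), mark)
        l_peaks = regulatory.PeakSet(
            read_intervals(os.path.join(simdir, f"{mark}_L.bed"), "bed", "L"), mark)
        frac, _ = regulatory.peak_conservation(t_peaks, alns["LT"], l_peaks)
        reg[f"{mark}_conserved_fraction_T_to_L"] = round(frac, 4)
    n_spec = {}
    for sub, aln_xt in (("L", alns["LT"]), ("S", alns["ST"])):
        peaks = regulatory.PeakSet(
            read_intervals(os.path.join(simdir, f"p300_{sub}.bed"), "bed", sub), "p300")
        spec = regulatory.subgenome_specific_peaks(peaks, alns["LS"], aln_xt)
        n_spec[sub] = len(spec)
    reg["n_specific_p300"] = n_spec
    report["regulatory"] = reg

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
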