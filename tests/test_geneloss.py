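"""Pseudogene classification, nonsense annotation and complex retention."""

import numpy as np
import pytest
from Bio.Seq import Seq

from subfrac.alignments import AlignmentBlock, AlignmentSet
from subfrac.geneloss import (CdsModel, GeneTriangle, annotate_nonsense,
                              call_likely_pseudogenes,
                              classify_pseudogene_features, complex_retention,
                              exclusive_class, lof_summary, read_cds_models,
                              summarize_complex_counts)
from subfrac.intervals import GenomeInterval, IntervalSet


def triangle(**kw):
    t = GeneTriangle(gene_id="g1")
    t.cds = {"T": kw.get("T"), "L": kw.get("L"), "S": kw.get("S")}
    t.expression = kw.get("expression", {})
    t.promoter = kw.get("promoter", {})
    return t


NO_DELS = {"L": IntervalSet([], genome="L"), "S": IntervalSet([], genome="S")}


class TestClassification:
    def test_identical_intact_copies_have_no_features(self):
        cds = "ATGAAATTTGGGTAA"
        t = classify_pseudogene_features(triangle(T=cds, L=cds, S=cds), NO_DELS)
        assert t.features["L"] == set() and t.features["S"] == set()

    def test_truncation_needs_both_references(self):
        short = "ATG" + "AAA" * 20 + "TAA"        # 66 bp
        homeo = "ATG" + "AAA" * 60 + "TAA"        # 186 bp
        ortho = "ATG" + "AAA" * 55 + "TAA"        # 171 bp
        t = classify_pseudogene_features(
            triangle(T=ortho, L=homeo, S=short), NO_DELS)
        assert "truncated_50" in t.features["S"]
        assert "truncated_50" not in t.features["L"]
        # not truncated when longer than half of the ortholog
        mid = "ATG" + "AAA" * 40 + "TAA"
        t2 = classify_pseudogene_features(
            triangle(T=ortho, L=homeo, S=mid), NO_DELS)
        assert "truncated_50" not in t2.features["S"]

    def test_premature_stop_feature(self):
        bad = "ATGTAAGGGTTT"
        good = "ATGAAAGGGTTT"
        t = classify_pseudogene_features(triangle(T=good, L=good, S=bad), NO_DELS)
        assert t.features["S"] == {"premature_stop"}

    def test_promoter_loss_through_projection(self):
        # homeolog promoter on L 1000 bp; only 200 bp of it aligns to S,
        # so 80% falls in unaligned sequence: promoter_loss_75 on S
        aln = AlignmentSet([AlignmentBlock(
            GenomeInterval("L", "chr1L", 0, 200),
            GenomeInterval("S", "chr1S", 0, 200), 0.95, "+", True)], "L", "S")
        cds = "ATGAAATTTTAA"
        t = triangle(T=cds, L=cds, S=cds,
                     promoter={"L": GenomeInterval("L", "chr1L", 0, 1000)})
        t = classify_pseudogene_features(t, NO_DELS, aln_LS=aln)
        assert "promoter_loss_75" in t.features["S"]
        assert "promoter_loss_75" not in t.features["L"]

    def test_promoter_mostly_aligned_not_lost(self):
        aln = AlignmentSet([AlignmentBlock(
            GenomeInterval("L", "chr1L", 0, 900),
            GenomeInterval("S", "chr1S", 0, 900), 0.95, "+", True)], "L", "S")
        cds = "ATGAAATTTTAA"
        t = triangle(T=cds, L=cds, S=cds,
                     promoter={"L": GenomeInterval("L", "chr1L", 0, 1000)})
        t = classify_pseudogene_features(t, NO_DELS, aln_LS=aln)
        assert "promoter_loss_75" not in t.features["S"]

    def test_absent_copy_has_empty_features(self):
        t = classify_pseudogene_features(
            triangle(T="ATGTAA", L="ATGTAA", S=None), NO_DELS)
        assert t.features["S"] == set()


class TestLikelyPseudogenes:
    def _with_features(self, expr_l, expr_s, feats_s=frozenset({"premature_stop"})):
        t = triangle(T="ATGTAA", L="ATGTAA", S="ATGTAA",
                     expression={"L": expr_l, "S": expr_s})
        t.features = {"L": set(), "S": set(feats_s)}
        return t

    def test_tenfold_rule(self):
        called = call_likely_pseudogenes([self._with_features(5.0, 0.1)])
        assert called["S"] == ["g1"]
        # 4 vs 5 TPM: ratio < 10, not called
        called = call_likely_pseudogenes([self._with_features(5.0, 4.0)])
        assert called["S"] == []

    def test_no_features_never_called(self):
        called = call_likely_pseudogenes(
            [self._with_features(5.0, 0.0, frozenset())])
        assert called["S"] == []

    def test_homeolog_must_be_expressed(self):
        called = call_likely_pseudogenes([self._with_features(0.5, 0.0)])
        assert called["S"] == []

    def test_strict_no_expression_mode(self):
        t = self._with_features(5.0, 0.4)
        assert call_likely_pseudogenes([t], mode="no_expression")["S"] == ["g1"]
        t2 = self._with_features(5.0, 2.0)
        assert call_likely_pseudogenes([t2], mode="no_expression")["S"] == []


class TestExclusiveClass:
    @pytest.mark.parametrize("features,want", [
        ({"premature_stop"}, "stop-only"),
        ({"frameshift"}, "frameshift-only"),
        ({"truncated_50", "frameshift"}, "deletion-driven"),
        ({"promoter_loss_75"}, "deletion-driven"),
        ({"premature_stop", "frameshift"}, "multiple"),
    ])
    def test_partition(self, features, want):
        assert exclusive_class(set(features)) == want

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            exclusive_class(set())


def write_vcf(path, chrom, rows, contig_len=100000):
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n')
        fh.write(f"##contig=<ID={chrom},length={contig_len}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n")
        for pos, ref, alt, dp, ad in rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t50\tPASS\t.\t"
                     f"GT:DP:AD\t0/1:{dp}:{dp - ad},{ad}\n")


class TestAnnotateNonsense:
    def test_plus_strand_stop_gain(self, tmp_path):
        # genome: CDS ATG AAA TTT GGG TAA at offset 10
        cds = "ATGAAATTTGGGTAA"
        genome = {"c": "G" * 10 + cds + "G" * 20}
        model = CdsModel("g1", "c", 10, 10 + len(cds), "+")
        # codon 2 (AAA) position 1: A->T makes TAA; 1-based genome pos 14
        vcf = tmp_path / "a.vcf"
        write_vcf(str(vcf), "c", [(14, "A", "T", 30, 10),   # nonsense
                                  (16, "A", "T", 30, 10)])  # AAA->AAT = Asn
        recs, flags, counts = annotate_nonsense(str(vcf), [model], genome)
        assert flags["g1"]
        assert [(r.pos, r.alt_codon) for r in recs] == [(14, "TAA")]

    def test_minus_strand_stop_gain(self, tmp_path):
        cds = "ATGAAATTTGGGTAA"
        genome_seq = "G" * 10 + str(Seq(cds).reverse_complement()) + "G" * 20
        genome = {"c": genome_seq}
        model = CdsModel("g1", "c", 10, 10 + len(cds), "-")
        # same codon-2 pos-1 A->T: genome strand holds the complement at
        # genome position end - 1 - cds_pos = 25 - 3 = position 21 (0-based)
        vcf = tmp_path / "a.vcf"
        write_vcf(str(vcf), "c", [(22, "T", "A", 30, 10)])
        recs, flags, counts = annotate_nonsense(str(vcf), [model], genome)
        assert flags["g1"]
        assert recs[0].alt_codon == "TAA"

    def test_depth_filters(self, tmp_path):
        cds = "ATGAAATTTGGGTAA"
        genome = {"c": "G" * 10 + cds + "G" * 20}
        model = CdsModel("g1", "c", 10, 10 + len(cds), "+")
        vcf = tmp_path / "a.vcf"
        write_vcf(str(vcf), "c", [(14, "A", "T", 8, 4),    # depth too low
                                  (14, "A", "T", 30, 3)])  # too few alt reads
        recs, flags, counts = annotate_nonsense(str(vcf), [model], genome)
        assert not flags["g1"] and counts["n_filtered"] == 2

    def test_ref_mismatch_skipped(self, tmp_path):
        cds = "ATGAAATTTGGGTAA"
        genome = {"c": "G" * 10 + cds + "G" * 20}
        model = CdsModel("g1", "c", 10, 10 + len(cds), "+")
        vcf = tmp_path / "a.vcf"
        write_vcf(str(vcf), "c", [(14, "C", "T", 30, 10)])
        recs, flags, counts = annotate_nonsense(str(vcf), [model], genome)
        assert counts["n_ref_mismatch"] == 1 and not recs

    def test_agrees_with_translate_oracle(self, tmp_path):
        """Brute-force oracle: substitute the allele in the whole CDS,
        translate, and compare premature-stop status."""
        rng = np.random.default_rng(7)
        non_stop = [c for c in
                    ("".join(p) for p in __import__("itertools").product("ACGT", repeat=3))
                    if str(Seq(c).translate()) != "*"]
        n_codons = 30
        cds = "".join(rng.choice(non_stop, n_codons - 1)) + "TAA"
        for strand in ("+", "-"):
            gseq = ("A" * 50 + (cds if strand == "+"
                                else str(Seq(cds).reverse_complement())) + "A" * 50)
            genome = {"c": gseq}
            model = CdsModel("g1", "c", 50, 50 + len(cds), strand)
            rows = []
            for _ in range(100):
                pos0 = int(rng.integers(50, 50 + len(cds)))
                ref = gseq[pos0]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                rows.append((pos0 + 1, ref, alt, 30, 10))
            # oracle: substitute in the full CDS, translate, check the codon
            expected = []
            for (pos, ref, alt, dp, ad) in rows:
                pos0 = pos - 1
                cds_pos = (pos0 - 50) if strand == "+" else (50 + len(cds) - 1 - pos0)
                alt_cds = (alt if strand == "+" else str(Seq(alt).complement()))
                mutated = cds[:cds_pos] + alt_cds + cds[cds_pos + 1:]
                aa = str(Seq(mutated).translate())
                ci = cds_pos // 3
                expected.append(aa[ci] == "*" and ci < n_codons - 1)
            vcf = tmp_path / f"oracle_{strand}.vcf"
            write_vcf(str(vcf), "c", rows)
            recs, flags, counts = annotate_nonsense(str(vcf), [model], genome)
            got_positions = sorted(r.pos for r in recs)
            want_positions = sorted(r[0] for r, e in zip(rows, expected) if e)
            assert got_positions == want_positions


class TestLofSummary:
    def test_printed_fractions(self):
        out = lof_summary({"L": 23667, "S": 16939, "T": 26550},
                          {"L": 528, "S": 367, "T": 388})
        assert out["fractions"]["L"] == pytest.approx(0.0223, abs=5e-5)
        assert out["fractions"]["S"] == pytest.approx(0.0217, abs=5e-5)
        assert out["fractions"]["T"] == pytest.approx(0.0146, abs=5e-5)

    def test_equal_rates_p_one(self):
        out = lof_summary({"a": 1000, "b": 1000}, {"a": 20, "b": 20})
        assert out["chi_squared"]["a_vs_b"]["p"] == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            lof_summary({"a": 0}, {"a": 0})


class TestComplexRetention:
    def test_printed_counts(self):
        s = summarize_complex_counts(170, 124, 63)
        assert s.n_total == 357
        assert s.observed_fraction == pytest.approx(63 / 357)
        assert round(100 * s.observed_fraction, 1) == 17.6

    def test_all_dual(self):
        s = complex_retention([("a", "b")], {"a": "dual", "b": "dual"})
        assert s.observed_fraction == 0.0 and s.expected_fraction == 0.0

    def test_supplied_q(self):
        s = summarize_complex_counts(10, 5, 5, q=0.3)
        assert s.expected_fraction == pytest.approx(0.09)

    def test_absent_members_excluded(self):
        s = complex_retention([("a", "b"), ("a", "c")],
                              {"a": "single", "b": "single", "c": "absent"})
        assert s.n_total == 1 and s.n_both_single == 1


def test_read_cds_models_from_system(small_system):
    _, truth, simdir = small_system
    import os
    models = read_cds_models(os.path.join(simdir, "genes_L.gff3"), "L")
    assert len(models) == truth.config.n_genes
    assert all(m.gene_id.endswith(".L") for m in models)
    assert all((m.end - m.start) % 3 == 0 for m in models)
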