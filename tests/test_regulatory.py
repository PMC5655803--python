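"""Peak conservation, subgenome-specific peaks, enrichment, activity
thresholding and the proximity expression test."""

import numpy as np
import pytest

from subfrac.alignments import AlignmentBlock, AlignmentSet
from subfrac.intervals import GenomeInterval, IntervalSet
from subfrac.randomization import hypergeometric_tail
from subfrac.regulatory import (PeakSet, active_transcription_threshold,
                                annotation_enrichment, gene_tss,
                                is_actively_transcribed, peak_conservation,
                                proximity_expression_test,
                                repeats_per_megabase,
                                subgenome_specific_peaks)


def iv(start, end, chrom="c", genome="L", strand=".", label=""):
    return GenomeInterval(genome, chrom, start, end, strand, label)


def identity_alignment(length=10000, ga="T", gb="L", ca="cT", cb="cL"):
    return AlignmentSet([AlignmentBlock(
        GenomeInterval(ga, ca, 0, length), GenomeInterval(gb, cb, 0, length),
        1.0, "+", True)], ga, gb)


class TestPeakConservation:
    def test_identical_sets_fully_conserved(self):
        aln = identity_alignment()
        ref = PeakSet(IntervalSet([iv(100, 200, "cT", "T"),
                                   iv(500, 700, "cT", "T")]), "p300", "T")
        tgt = PeakSet(IntervalSet([iv(100, 200, "cL", "L"),
                                   iv(500, 700, "cL", "L")]), "p300", "L")
        frac, labels = peak_conservation(ref, aln, tgt)
        assert frac == 1.0

    def test_unaligned_peak_not_conserved(self):
        aln = identity_alignment(length=1000)
        ref = PeakSet(IntervalSet([iv(5000, 5200, "cT", "T")]), "p300", "T")
        tgt = PeakSet(IntervalSet([iv(5000, 5200, "cL", "L")]), "p300", "L")
        frac, _ = peak_conservation(ref, aln, tgt)
        assert frac == 0.0

    def test_recovers_configured_fraction(self, small_system):
        import os
        from subfrac import pipeline
        from subfrac.intervals import read_intervals
        cfg, truth, simdir = small_system
        alns = pipeline.load_alignments(simdir)
        t_peaks = PeakSet(read_intervals(os.path.join(simdir, "h3k4me3_T.bed"),
                                         "bed", "T"), "h3k4me3")
        l_peaks = PeakSet(read_intervals(os.path.join(simdir, "h3k4me3_L.bed"),
                                         "bed", "L"), "h3k4me3")
        frac, _ = peak_conservation(t_peaks, alns["LT"], l_peaks)
        n = len(t_peaks)
        se = np.sqrt(0.4 * 0.6 / n)
        assert abs(frac - cfg.h3k4me3_conserved_fraction) < 3 * se + 0.02


class TestSpecificPeaks:
    def test_aligned_peak_excluded(self):
        aln_s = identity_alignment(ga="L", gb="S", ca="cL", cb="cS")
        aln_t = identity_alignment(ga="L", gb="T", ca="cL", cb="cT")
        peaks = PeakSet(IntervalSet([iv(100, 200, "cL")]), "p300", "L")
        spec = subgenome_specific_peaks(peaks, aln_s, aln_t)
        assert len(spec) == 0

    def test_one_aligned_bp_excluded_under_strict_default(self):
        aln_s = AlignmentSet([AlignmentBlock(
            GenomeInterval("L", "cL", 199, 200),
            GenomeInterval("S", "cS", 0, 1), 1.0, "+", True)], "L", "S")
        aln_t = AlignmentSet([], "L", "T")
        peaks = PeakSet(IntervalSet([iv(100, 200, "cL")]), "p300", "L")
        assert len(subgenome_specific_peaks(peaks, aln_s, aln_t)) == 0
        assert len(subgenome_specific_peaks(peaks, aln_s, aln_t,
                                            max_aligned_bp=1)) == 1

    def test_disjoint_from_conserved_by_construction(self, small_system):
        import os
        from subfrac import pipeline
        from subfrac.intervals import read_intervals
        cfg, truth, simdir = small_system
        alns = pipeline.load_alignments(simdir)
        peaks = PeakSet(read_intervals(os.path.join(simdir, "p300_L.bed"),
                                       "bed", "L"), "p300", "L")
        spec = subgenome_specific_peaks(peaks, alns["LS"], alns["LT"])
        spec_ids = {p.label for p in spec.peaks}
        want = {pid for pid, lab in truth.peak_labels.items() if lab == "specific"}
        # all L-genome specific peaks recovered, no conserved peak misclassified
        l_ids = {p.label for p in peaks.peaks}
        assert spec_ids == want & l_ids
        assert all(truth.peak_labels[pid] == "specific" for pid in spec_ids)


class TestAnnotationEnrichment:
    def test_subset_equals_population_fold_one(self):
        peaks = IntervalSet([iv(i * 1000, i * 1000 + 100) for i in range(20)])
        ann = {"rep": IntervalSet([iv(0, 5100)])}
        res = annotation_enrichment(PeakSet(peaks), PeakSet(peaks), ann)
        assert res[0].fold == pytest.approx(1.0)

    def test_constructed_counts_closed_form(self):
        # annotation fully covers the 5 subset peaks and 1 of the 95 others
        all_ivs = [iv(i * 1000, i * 1000 + 100) for i in range(100)]
        subset = IntervalSet(all_ivs[:5])
        ann = {"rep": IntervalSet([iv(0, 4200), iv(50000, 50200)])}
        res = annotation_enrichment(PeakSet(subset), PeakSet(IntervalSet(all_ivs)),
                                    ann, p_max=1e-4, fold_min=2.0,
                                    prevalence_min=0.15)
        r = res[0]
        assert r.k == 5 and r.K == 6
        assert r.prevalence == 1.0
        assert r.fold == pytest.approx((5 / 5) / (6 / 100))
        assert r.p == pytest.approx(hypergeometric_tail(5, 6, 5, 100))
        assert r.passing

    def test_empty_subset_rejected(self):
        peaks = IntervalSet([iv(0, 10)])
        with pytest.raises(ValueError):
            annotation_enrichment(PeakSet(IntervalSet([], genome="L")),
                                  PeakSet(peaks), {})


class TestActivity:
    def test_mean_plus_two_sd(self):
        bg = {"H3K36me3": [1.0, 1.0, 1.0], "RNAPII": [0.0, 2.0]}
        thr = active_transcription_threshold(bg)
        assert thr["H3K36me3"] == pytest.approx(1.0)
        assert thr["RNAPII"] == pytest.approx(1.0 + 2.0)

    def test_both_marks_required_and_boundary_passes(self):
        thr = {"a": 2.0, "b": 2.0}
        assert is_actively_transcribed({"a": 2.0, "b": 2.0}, thr)
        assert not is_actively_transcribed({"a": 3.0, "b": 1.9}, thr)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        bg = {"m": rng.gamma(2.0, 1.0, 500).tolist()}
        regions = rng.gamma(2.0, 2.0, 50)
        thr1 = active_transcription_threshold(bg)
        labels1 = [r >= thr1["m"] for r in regions]
        c = 7.3
        thr2 = active_transcription_threshold({"m": [c * v for v in bg["m"]]})
        labels2 = [c * r >= thr2["m"] for r in regions]
        assert labels1 == labels2


class TestProximity:
    def test_boundary_inclusive_at_5kb(self):
        enh = PeakSet(IntervalSet([iv(0, 100, "c")]), "p300", "L")
        tss = IntervalSet([iv(5099, 5100, "c", label="g_near"),
                           iv(5101, 5102, "c", label="g_far"),
                           iv(9000, 9001, "c", label="g_far2")])
        # distance from enhancer end (exclusive) to 5099 is 5000
        expr = {"g_near": 10.0, "g_far": 1.0, "g_far2": 1.0}
        res = proximity_expression_test(enh, tss, expr, distance=5000)
        assert res["n_near"] == 1 and res["n_far"] == 2

    def test_enhancers_near_top_genes_give_positive_shift(self):
        rng = np.random.default_rng(1)
        tpm = np.sort(2.0 ** rng.normal(3, 2, 200))[::-1]
        tss_list, enh_list, expr = [], [], {}
        for i, t in enumerate(tpm):
            pos = 20000 * i + 10000
            gid = f"g{i}"
            expr[gid] = float(t)
            tss_list.append(iv(pos, pos + 1, "c", label=gid))
            if i < 40:  # enhancers adjacent to the top-expressed genes
                enh_list.append(iv(pos + 500, pos + 900, "c"))
        res = proximity_expression_test(
            PeakSet(IntervalSet(enh_list)), IntervalSet(tss_list), expr)
        assert res["p"] < 1e-6
        assert res["median_log2_near"] > res["median_log2_far"]

    def test_empty_group_reports_sizes(self):
        enh = PeakSet(IntervalSet([iv(0, 100, "c")]), "p300", "L")
        tss = IntervalSet([iv(50, 51, "c", label="g")])
        with pytest.raises(ValueError, match="near=1"):
            proximity_expression_test(enh, tss, {"g": 1.0})


def test_repeats_per_megabase():
    reps = IntervalSet([iv(i * 100, i * 100 + 50) for i in range(100)])
    assert repeats_per_megabase(reps, 10_000_000) == pytest.approx(10.0)
    assert repeats_per_megabase(IntervalSet([], genome="L"), 1_000_000) == 0.0


def test_gene_tss_strand_aware():
    plus = gene_tss(iv(100, 200, strand="+"))
    minus = gene_tss(iv(100, 200, strand="-"))
    assert (plus.start, plus.end) == (100, 101)
    assert (minus.start, minus.end) == (199, 200)
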