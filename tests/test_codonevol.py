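"""Codon evolution statistics: NG86 against an independent enumeration
oracle, 4D sites, parsimony ancestor, dating and feature detection."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ng86_oracle import GENETIC_CODE, oracle_ng86

from subfrac import codonevol as ce

NON_STOP = [c for c in ce.CODONS if GENETIC_CODE[c] != "*"]


class TestNg86:
    def test_identical_sequences(self):
        aln = ce.CodonAlignment({"a": "ATGAAATTTGGG", "b": "ATGAAATTTGGG"})
        r = ce.ng86_ka_ks(aln)
        assert r.Ka == 0.0 and r.Ks == 0.0 and r.omega is None

    def test_one_synonymous_difference(self):
        a = "ATGAAATTTGGGCCCTGGCATATA"
        b = a[:-1] + "G"  # ATA -> ATG is nonsyn; use GGG->GGA instead
        a = "ATGAAATTTGGGCCCTGGCATGGG"
        b = a[:-1] + "A"  # GGG -> GGA, Gly -> Gly
        r = ce.ng86_ka_ks(ce.CodonAlignment({"a": a, "b": b}))
        assert r.Ka == 0.0 and r.Ks > 0.0 and r.omega == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = "".join(rng.choice(NON_STOP, 40))
        b = "".join(rng.choice(NON_STOP, 40))
        r1 = ce.ng86_ka_ks(ce.CodonAlignment({"x": a, "y": b}), ("x", "y"))
        r2 = ce.ng86_ka_ks(ce.CodonAlignment({"x": a, "y": b}), ("y", "x"))
        assert r1.Na == pytest.approx(r2.Na)
        assert r1.Ns == pytest.approx(r2.Ns)
        assert r1.La == pytest.approx(r2.La)

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = "".join(rng.choice(NON_STOP, 30))
            # mutate a few positions
            b = list(a)
            for pos in rng.choice(len(a), 6, replace=False):
                b[pos] = "ACGT"[rng.integers(0, 4)]
            b = "".join(b)
            oka, oks, ond, osd, ola, ols = oracle_ng86(a, b)[:6]
            r = ce.ng86_from_codes(
                ce.CodonAlignment({"a": a, "b": b}).codon_codes("a"),
                ce.CodonAlignment({"a": a, "b": b}).codon_codes("b"))
            assert r.Ns == pytest.approx(osd, abs=1e-9)
            assert r.Na == pytest.approx(ond, abs=1e-9)
            assert r.Ls == pytest.approx(ols, abs=1e-9)
            if not (math.isnan(oks) or r.undefined):
                assert r.Ks == pytest.approx(oks, abs=1e-9)

    def test_gapped_and_stop_codons_excluded(self):
        aln = ce.CodonAlignment({"a": "ATG---TAAGGG", "b": "ATGAAATTTGGG"})
        r = ce.ng86_ka_ks(aln)
        assert r.n_codons == 2  # gap codon and stop codon dropped

    def test_no_comparable_codons_is_error(self):
        aln = ce.CodonAlignment({"a": "---", "b": "AAA"})
        with pytest.raises(ValueError):
            ce.ng86_ka_ks(aln)


class TestFourfold:
    def test_examples(self):
        assert ce.fourfold_degenerate_sites("GGA") == [2]   # Gly: GGN
        assert ce.fourfold_degenerate_sites("TTA") == []    # Leu/Phe split
        assert ce.fourfold_degenerate_sites("ATGGGATTA") == [5]

    def test_toy_gene_matches_hand_enumeration(self):
        # walk the genetic code: third positions of codons whose first two
        # bases determine the amino acid
        gene = "ATGGCTCGGAAATTTGGCCTGTCATAA"  # M A R K F G L S *
        hand = []
        for i in range(0, len(gene) - 3, 3):  # skip terminal stop
            codon = gene[i:i + 3]
            aas = {GENETIC_CODE[codon[:2] + b] for b in "ACGT"}
            if len(aas) == 1:
                hand.append(i + 2)
        assert ce.fourfold_degenerate_sites(gene) == hand
        assert hand == [5, 8, 17, 20, 23]  # GCT, CGG, GGC, CTG, TCA are 4D


class TestSiteConservation:
    def test_bounds(self):
        assert ce.site_conservation("ACGT", "ACGT", [0, 1, 2, 3]) == 1.0
        assert ce.site_conservation("AAAA", "TTTT", [0, 1]) == 0.0
        with pytest.raises(ValueError):
            ce.site_conservation("ACGT", "ACGT", [])

    def test_matches_jukes_cantor_expectation(self):
        # P(identical) = 1/4 + 3/4 * exp(-4 d / 3) under JC at distance d
        rng = np.random.default_rng(2)
        d = 0.2
        n = 30000
        p_change = 0.75 * (1 - math.exp(-4 * d / 3))
        a = rng.choice(list("ACGT"), n)
        b = a.copy()
        flip = rng.random(n) < p_change
        for i in np.where(flip)[0]:
            b[i] = rng.choice([x for x in "ACGT" if x != a[i]])
        cons = ce.site_conservation("".join(a), "".join(b), list(range(n)))
        expected = 1 - p_change
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(cons - expected) < 2.5 * se


class TestAncestor:
    @pytest.mark.parametrize("l,s,o,want", [
        ("A", "A", "G", "A"),   # child agreement wins
        ("A", "G", "G", "G"),   # outgroup arbitration
        ("A", "G", "C", "N"),   # three-way tie excluded
    ])
    def test_column_rules(self, l, s, o, want):
        tri = ce.CodonAlignment({"T": o * 3, "L": l * 3, "S": s * 3})
        assert ce.ancestral_at_split(tri) == want * 3

    def test_all_gap_column(self):
        tri = ce.CodonAlignment({"T": "---", "L": "---", "S": "---"})
        assert ce.ancestral_at_split(tri) == "---"


class TestDating:
    def test_closed_form(self):
        assert ce.date_pseudogene(0.2, 0.2, 34.0).t_loss == 0.0
        assert ce.date_pseudogene(1.0, 0.2, 34.0).t_loss == 34.0
        assert ce.date_pseudogene(0.6, 0.2, 34.0).t_loss == pytest.approx(17.0)

    def test_clamped_and_validated(self):
        assert ce.date_pseudogene(0.1, 0.2, 34.0).t_loss == 0.0
        with pytest.raises(ValueError):
            ce.date_pseudogene(0.5, 1.0, 34.0)

    @given(st.floats(0.0, 0.9), st.floats(0.0, 0.9), st.floats(0.0, 0.99))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_observed_omega(self, w1, w2, wf):
        lo, hi = sorted((w1, w2))
        t_lo = ce.date_pseudogene(lo, wf, 34.0).t_loss
        t_hi = ce.date_pseudogene(hi, wf, 34.0).t_loss
        assert t_hi >= t_lo


class TestBootstrap:
    @staticmethod
    def _triplet(seed=0, n=120, n_mut=25):
        rng = np.random.default_rng(seed)
        anc = "".join(rng.choice(NON_STOP, n))

        def mutate(seq, k):
            s = list(seq)
            for pos in rng.choice(len(s), k, replace=False):
                s[pos] = "ACGT"[rng.integers(0, 4)]
            return "".join(s)

        return ce.CodonAlignment({"T": mutate(anc, 2 * n_mut),
                                  "L": mutate(anc, 2 * n_mut),
                                  "S": mutate(anc, n_mut)})

    def test_seed_reproducibility(self):
        tri = self._triplet()
        d1 = ce.bootstrap_date(tri, "L", "S", "T", 34.0, n_boot=50, seed=3,
                               omega_f=0.2)
        d2 = ce.bootstrap_date(tri, "L", "S", "T", 34.0, n_boot=50, seed=3,
                               omega_f=0.2)
        assert (d1.ci_low, d1.ci_high, d1.t_loss) == (d2.ci_low, d2.ci_high, d2.t_loss)
        assert d1.ci_low <= d1.t_loss <= d1.ci_high or d1.unreliable

    def test_too_short_alignment_rejected(self):
        tri = ce.CodonAlignment({"T": "ATG" * 5, "L": "ATG" * 5, "S": "ATG" * 5})
        with pytest.raises(ValueError):
            ce.bootstrap_date(tri, "L", "S", "T", 34.0, n_boot=10, seed=0)

    def test_zero_variation_undatable(self):
        tri = ce.CodonAlignment({t: "ATGGCT" * 10 for t in "TLS"})
        with pytest.raises(ValueError, match="undatable"):
            ce.bootstrap_date(tri, "L", "S", "T", 34.0, n_boot=10, seed=0)


class TestFeatures:
    @pytest.mark.parametrize("a,b,n_events", [
        ("ATGAAATTT", "ATG---TTT", 0),   # 3-bp gap keeps frame
        ("ATGAAATTT", "ATGA-ATTT", 1),   # 1-bp gap shifts frame
    ])
    def test_frameshift_gap_runs(self, a, b, n_events):
        aln = ce.CodonAlignment({"x": a, "y": b})
        assert len(ce.detect_frameshift(aln)) == n_events

    def test_two_separate_events_reported_individually(self):
        # two gap runs of 1 and 2 bp in y
        x = "ATGAAATTTCCC"
        y = "ATG-AATT--CC"
        aln = ce.CodonAlignment({"x": x, "y": y})
        events = ce.detect_frameshift(aln)
        assert [(e.column, e.gap_length) for e in events] == [(3, 1), (8, 2)]

    def test_premature_stop(self):
        assert ce.detect_premature_stop("ATGTAATTT") == ([1], False)
        assert ce.detect_premature_stop("ATGAAATAA") == ([], False)
        stops, flagged = ce.detect_premature_stop("ATGTAATT")
        assert stops == [1] and flagged
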