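"""Composition, RSCU, representation classes, ENC and the expected curve."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codonuse.codon_stats import (
    CodonCounts,
    classify_representation,
    composition,
    count_codons,
    enc,
    expected_enc,
    gc_partition,
    rscu,
)
from codonuse.genetic_code import (
    AA_TO_CODONS,
    DEGENERACY,
    MULTI_CODON_AAS,
    SENSE_CODONS,
    SYNONYMOUS_CODONS,
)
from codonuse.seqio import CodingSequence

from conftest import brute_force_enc, random_count_table


def seq(s: str, sid: str = "s") -> CodingSequence:
    return CodingSequence(id=sid, sequence=s)


class TestCountCodons:
    def test_single_sequence(self):
        t = count_codons(seq("ATGATGATG"))
        assert t.counts["ATG"] == 3 and t.n_codons == 3

    def test_pooling(self):
        t = count_codons([seq("ATGAAA", "a"), seq("AAATTT", "b")],
                         pool=True)
        assert t.counts["ATG"] == 1
        assert t.counts["AAA"] == 2
        assert t.counts["TTT"] == 1
        assert t.n_codons == 4
        assert t.source_ids == ["a", "b"]

    def test_ambiguous_codons_not_counted(self):
        t = count_codons(seq("ATGNNNAAA"))
        assert t.n_codons == 2

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            count_codons([])

    def test_counts_sum_to_n_codons(self, rng):
        t = random_count_table(rng)
        assert sum(t.counts.values()) == t.n_codons


class TestComposition:
    def test_all_ala_gct(self):
        prof = composition(count_codons(seq("GCT" * 10)))
        assert prof.overall["G"] == pytest.approx(100 / 3)
        assert prof.overall["C"] == pytest.approx(100 / 3)
        assert prof.overall["T"] == pytest.approx(100 / 3)
        assert prof.overall["A"] == 0.0
        assert prof.third_syn["T"] == 100.0
        assert prof.gc3 == 0.0

    def test_all_atg_has_no_third_syn_pool(self):
        prof = composition(count_codons(seq("ATG" * 5)))
        assert prof.third_syn is None and prof.gc3 is None
        for b in "ATG":
            assert prof.overall[b] == pytest.approx(100 / 3)

    def test_stop_codons_never_counted(self):
        with_stop = composition(count_codons(seq("GCTGCTTAA")))
        without = composition(count_codons(seq("GCTGCT")))
        assert with_stop == without

    def test_percentages_sum_to_100(self, rng):
        for _ in range(20):
            prof = composition(random_count_table(rng))
            assert sum(prof.overall.values()) == pytest.approx(100.0)
            assert sum(prof.third_syn.values()) == pytest.approx(100.0)

    def test_pooled_composition_is_order_invariant(self):
        a, b = seq("GCTGCCAAATAA", "a"), seq("TTTGGGCCC", "b")
        p1 = composition(count_codons([a, b], pool=True))
        p2 = composition(count_codons([b, a], pool=True))
        assert p1.overall == p2.overall and p1.gc3 == p2.gc3

    def test_gc_partition_examples(self):
        # GCG: both first (G) and second (C) position slots are G+C
        assert gc_partition(count_codons(seq("GCG" * 4))) == (100.0, 100.0)
        assert gc_partition(count_codons(seq("ATA" * 4))) == (0.0, 0.0)
        gc12, gc3 = gc_partition(count_codons(seq("GCTGCC")))
        assert gc12 == 100.0 and gc3 == 50.0


class TestRSCU:
    def test_equal_usage_gives_all_ones(self):
        t = CodonCounts({c: 1 for c in SENSE_CODONS})
        v = rscu(t)
        assert not v.undefined
        assert all(val == pytest.approx(1.0) for val in v.values.values())

    def test_two_fold_family_split(self):
        v = rscu(CodonCounts({"TTT": 3, "TTC": 1}))
        assert v.values["TTT"] == pytest.approx(1.5)
        assert v.values["TTC"] == pytest.approx(0.5)

    def test_absent_families_undefined_not_zero(self):
        v = rscu(CodonCounts({"TTT": 3, "TTC": 1}))
        assert "GGT" in v.undefined
        assert math.isnan(v.values["GGT"])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_family_sums_equal_degeneracy(self, seed):
        t = random_count_table(np.random.default_rng(seed))
        v = rscu(t)
        for aa in MULTI_CODON_AAS:
            fam = AA_TO_CODONS[aa]
            if fam[0] in v.undefined:
                continue
            assert sum(v.values[c] for c in fam) == pytest.approx(
                DEGENERACY[aa], abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 50))
    def test_scale_invariance(self, seed, factor):
        t = random_count_table(np.random.default_rng(seed))
        scaled = CodonCounts({c: n * factor for c, n in t.counts.items()})
        v1, v2 = rscu(t), rscu(scaled)
        for c in SYNONYMOUS_CODONS:
            if c in v1.undefined:
                assert c in v2.undefined
            else:
                assert v1.values[c] == pytest.approx(v2.values[c], abs=1e-12)


class TestRepresentation:
    def test_thresholds_are_strict(self):
        v = rscu(CodonCounts({"TTT": 4, "TTC": 1,   # 1.6 / 0.4
                              "GAT": 1, "GAC": 1}))
        cls = classify_representation(v)
        assert cls["TTT"] == "normal"  # exactly 1.6: not over
        assert cls["TTC"] == "under"
        assert cls["GAT"] == "normal"
        assert cls["GGG"] == "undefined"

    def test_over_representation(self):
        v = rscu(CodonCounts({"TTT": 9, "TTC": 1}))  # 1.8 / 0.2
        cls = classify_representation(v)
        assert cls["TTT"] == "over" and cls["TTC"] == "under"


class TestENC:
    def one_codon_per_family_counts(self, per_family=10):
        return CodonCounts({AA_TO_CODONS[aa][0]: per_family
                            for aa in AA_TO_CODONS})

    def test_maximal_bias_gives_20(self):
        assert enc(self.one_codon_per_family_counts()).enc == \
            pytest.approx(20.0)

    def test_equal_usage_capped_at_61(self):
        res = enc(CodonCounts({c: 10_000 for c in SENSE_CODONS}))
        assert res.enc == pytest.approx(61.0)

    def test_worked_toy_table_against_hand_formulas(self):
        counts = {"TTT": 2, "TTC": 2,            # Phe: F = (4*0.5-1)/3
                  "GAT": 3, "GAC": 1,            # Asp: F = (4*0.625-1)/3
                  "ATT": 2, "ATC": 1, "ATA": 1,  # Ile: F = (4*0.375-1)/3
                  "GCT": 1, "GCC": 1, "GCA": 1, "GCG": 1,  # Ala F=0 -> out
                  "CTG": 4}                      # Leu: F = 1
        f2 = ((4 * 0.5 - 1) / 3 + (4 * 0.625 - 1) / 3) / 2
        f3 = (4 * 0.375 - 1) / 3
        f6 = 1.0
        # Ala's F is 0 (unusable), so no 4-fold mean exists -> ENC missing
        res = enc(CodonCounts(counts))
        assert res.enc is None
        assert res.f_bar[2] == pytest.approx(f2)
        assert res.f_bar[3] == pytest.approx(f3)
        assert res.f_bar[6] == pytest.approx(f6)
        assert 4 not in res.f_bar

        # adding a biased Ala family restores all four class means
        counts["GCT"] = 5
        res2 = enc(CodonCounts(counts))
        f4 = (8 * (25 + 1 + 1 + 1) / 64 - 1) / 7
        expected = 2 + 9 / f2 + 1 / f3 + 5 / f4 + 3 / f6
        assert res2.enc == pytest.approx(min(expected, 61.0), abs=1e-9)

    def test_f3_imputed_when_ile_absent(self):
        counts = {AA_TO_CODONS[aa][0]: 10 for aa in AA_TO_CODONS
                  if aa != "I"}
        res = enc(CodonCounts(counts))
        assert res.imputed_classes == (3,)
        assert res.enc == pytest.approx(20.0)

    def test_missing_required_class_reports_missing(self):
        res = enc(CodonCounts({"TTT": 5, "TTC": 5}))  # only a 2-fold family
        assert res.enc is None
        assert res.families_used[2] == 1
        assert res.families_used[4] == 0

    def test_sparse_families_excluded(self):
        # every family at n=1 is unusable -> missing, not an exception
        res = enc(CodonCounts({AA_TO_CODONS[aa][0]: 1
                               for aa in AA_TO_CODONS}))
        assert res.enc is None

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(100):
            t = random_count_table(rng)
            expected = brute_force_enc(t.counts)
            got = enc(t).enc
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-9)
                assert 20.0 <= got <= 61.0


class TestExpectedENC:
    @pytest.mark.parametrize("s,val", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
    def test_closed_form_values(self, s, val):
        assert expected_enc(s) == pytest.approx(val)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            expected_enc(1.5)
        with pytest.raises(ValueError):
            expected_enc(-0.1)
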