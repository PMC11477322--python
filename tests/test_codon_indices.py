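"""The per-sequence index battery: RSCU, composition, ENC, CAI, CBI, Fop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codonusage import (
    CdsSet,
    CaiReference,
    aromo,
    cai_sharp_li,
    cbi,
    count_codons,
    enc_wright,
    fop,
    gravy,
    rscu,
    silent_composition,
    summarize_indices,
    translate,
)
from codonusage.genetics import SINGLE_CODON_AA
from codonusage.indices import CodonCounts, IndexError_
from conftest import random_cds


def counts_of(**kw):
    return CodonCounts(counts=kw, source="test")


class TestCountCodons:
    def test_direct_count(self, make_record):
        cc = count_codons(make_record("ATGTTTTTCTAA"))
        assert dict(cc.counts) == {"AUG": 1, "UUU": 1, "UUC": 1}
        assert cc.total_codons == 3

    def test_stop_only_sequence_errors(self, make_record):
        with pytest.raises(IndexError_, match="no codons"):
            count_codons(make_record("TAA"))


class TestRscu:
    @pytest.mark.parametrize(
        "counts,codon,expected",
        [
            (dict(UUU=318, UUC=506), "UUC", 1.23),
            (dict(UUA=105, UUG=155, CUU=182, CUC=664, CUA=141, CUG=1368), "CUG", 3.14),
            (dict(CGU=95, CGC=428, CGA=127, CGG=630, AGA=62, AGG=277), "AGG", 1.03),
        ],
    )
    def test_published_pooled_cells(self, counts, codon, expected):
        table = rscu(counts_of(**counts))
        assert round(table.values[codon], 2) == expected

    def test_uniform_usage_gives_unit_rscu(self, uniform_counts, code):
        table = rscu(uniform_counts)
        assert all(
            abs(v - 1.0) < 1e-12 for v in table.values.values()
        )

    def test_absent_family_is_nan_not_zero(self):
        table = rscu(counts_of(UUU=4))
        assert math.isnan(table.values["GGG"])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 50), min_size=61, max_size=61))
    def test_family_sums_equal_family_size(self, code, raw):
        counts = CodonCounts(
            counts=dict(zip(code.sense_codons, raw)), source="hyp"
        )
        table = rscu(counts)
        for aa, family in code.degenerate_families.items():
            total = sum(counts.get(c) for c in family)
            fam_sum = sum(table.values[c] for c in family)
            if total > 0:
                assert fam_sum == pytest.approx(len(family), abs=1e-9)
            else:
                assert all(math.isnan(table.values[c]) for c in family)


class TestSilentComposition:
    def test_single_silent_site(self, make_record):
        comp = silent_composition(make_record("ATGTTTTAA"))
        assert comp.t3s == 1.0 and comp.gc3s == 0.0
        assert comp.n_silent_sites == 1

    def test_all_g_ending(self, make_record):
        comp = silent_composition(make_record("CTGCTG"))
        assert comp.g3s == 1.0 and comp.gc3s == 1.0

    def test_fractions_sum_to_one(self, make_record, code):
        rng = np.random.default_rng(0)
        rec = random_cds(rng, 200, code)
        comp = silent_composition(rec)
        assert comp.t3s + comp.c3s + comp.a3s + comp.g3s == pytest.approx(1, abs=1e-9)

    def test_met_trp_excluded_from_silent_sites(self, make_record):
        # AUG and UGG end in G but are not silent sites
        comp = silent_composition(make_record("ATGTGGTTT"))
        assert comp.n_silent_sites == 1
        assert comp.g3s == 0.0


class TestEncWright:
    def test_uniform_usage_hits_upper_limit(self, uniform_counts):
        assert enc_wright(uniform_counts).nc == 61.0

    def test_one_codon_per_family_hits_lower_limit(self, degenerate_counts):
        assert enc_wright(degenerate_counts).nc == 20.0

    def test_two_fold_homozygosity_hand_value(self, code):
        # every 2-fold family at 3:1 -> F = (4*0.625 - 1)/3 = 0.5
        counts = {}
        for aa, fam in code.degenerate_families.items():
            if len(fam) == 2:
                counts[fam[0]], counts[fam[1]] = 3, 1
            else:
                for c in fam:
                    counts[c] = 5
        bd = enc_wright(CodonCounts(counts=counts, source="t"))
        assert bd.f_bar[2] == pytest.approx(0.5)

    def test_monotone_decrease_under_concentration(self, code):
        # interpolate every family from uniform toward one-codon usage
        ncs = []
        for t in np.linspace(0, 1, 6):
            counts = {}
            for fam in code.degenerate_families.values():
                total = 600
                top = int(total / len(fam) + t * (total - total / len(fam)))
                rest = (total - top) // (len(fam) - 1)
                counts[fam[0]] = top
                for c in fam[1:]:
                    counts[c] = rest
            ncs.append(enc_wright(CodonCounts(counts=counts, source="t")).nc)
        assert all(a >= b - 1e-9 for a, b in zip(ncs, ncs[1:]))
        assert ncs[0] > ncs[-1]

    def test_undefined_without_observed_classes(self):
        with pytest.raises(IndexError_, match="enc_undefined"):
            enc_wright(counts_of(UUU=3, UUC=1))  # only a 2-fold family


class TestCai:
    def test_all_unit_weights(self, code, uniform_counts):
        ref = CaiReference.from_weights({c: 1.0 for c in code.sense_codons})
        assert cai_sharp_li(uniform_counts, ref) == pytest.approx(1.0)

    def test_hand_geometric_mean(self, code):
        ref = CaiReference.from_weights({"UUC": 1.0, "UUU": 0.5})
        assert cai_sharp_li(counts_of(UUC=1, UUU=1), ref) == pytest.approx(
            math.sqrt(0.5)
        )

    def test_invariant_to_codon_order(self, make_record):
        ref = CaiReference.from_counts(counts_of(UUC=9, UUU=1, GGC=9, GGG=3, GGA=1, GGU=1))
        a = count_codons(make_record("TTTTTCGGGGGC"))
        b = count_codons(make_record("GGCTTCGGGTTT"))
        assert cai_sharp_li(a, ref) == pytest.approx(cai_sharp_li(b, ref))

    def test_strictly_increases_toward_optimal(self):
        ref = CaiReference.from_counts(counts_of(UUC=10, UUU=2))
        worse = cai_sharp_li(counts_of(UUC=2, UUU=2), ref)
        better = cai_sharp_li(counts_of(UUC=3, UUU=1), ref)
        assert better > worse

    def test_reference_floor_keeps_cai_finite(self):
        ref = CaiReference.from_counts(counts_of(UUC=10))  # UUU unobserved
        v = cai_sharp_li(counts_of(UUU=5), ref)
        assert 0 < v <= 1


class TestCbiFop:
    def test_all_optimal_gives_one(self):
        opt = frozenset({"UUC"})
        assert cbi(counts_of(UUC=8), opt) == pytest.approx(1.0)
        assert fop(counts_of(UUC=8), opt) == pytest.approx(1.0)

    def test_random_expectation_gives_zero_cbi(self):
        assert cbi(counts_of(UUC=5, UUU=5), frozenset({"UUC"})) == pytest.approx(0.0)

    def test_hand_values_three_to_one(self):
        opt = frozenset({"UUC"})
        assert cbi(counts_of(UUC=3, UUU=1), opt) == pytest.approx(0.5)
        assert fop(counts_of(UUC=3, UUU=1), opt) == pytest.approx(0.75)

    def test_no_degenerate_codons_errors(self):
        with pytest.raises(IndexError_):
            fop(counts_of(AUG=3, UGG=2), frozenset({"UUC"}))


class TestProteinIndices:
    @pytest.mark.parametrize("protein,expected", [("III", 4.5), ("RRR", -4.5), ("IR", 0.0)])
    def test_gravy(self, protein, expected):
        assert gravy(protein) == pytest.approx(expected)

    @pytest.mark.parametrize("protein,expected", [("MFW", 2 / 3), ("MMM", 0.0), ("FYW", 1.0)])
    def test_aromo(self, protein, expected):
        assert aromo(protein) == pytest.approx(expected)

    def test_empty_protein_errors(self):
        with pytest.raises(IndexError_):
            gravy("*")


class TestSummarizeIndices:
    def test_single_record_bounds(self, make_record):
        rec = make_record("ATG" + "TTTTTTTTCGGAGGGGGGCTGCTGCTCATTCCACCGTAA")
        table = summarize_indices(CdsSet(gene="g", records=(rec,)))
        row = table.iloc[0]
        assert 0 < row["CAI"] <= 1
        assert -1 <= row["CBI"] <= 1
        assert 0 <= row["Fop"] <= 1
        assert 20 <= row["Nc"] <= 61 or math.isnan(row["Nc"])
        assert row["L_sym"] <= row["L_aa"]

    def test_rows_follow_input_order(self, small_synthetic_set):
        cds, _ = small_synthetic_set
        table = summarize_indices(cds)
        assert list(table.index) == cds.species
        assert (table["Nc"].between(20, 61)).all()
        # composition reported in percent
        assert table[["T3s", "C3s", "A3s", "G3s"]].sum(axis=1).round(6).eq(100).all()


class TestBruteForceOracle:
    """Independent per-position enumeration vs the implementations."""

    def test_rscu_gc3s_fop_match_enumeration(self, code):
        rng = np.random.default_rng(7)
        opt = frozenset(fam[0] for fam in code.degenerate_families.values())
        for _ in range(200):
            rec = random_cds(rng, 50, code)
            codons = [rec.sequence[i:i + 3].replace("T", "U")
                      for i in range(0, len(rec.sequence), 3)]
            cc = count_codons(rec)
            # oracle RSCU
            table = rscu(cc)
            for aa, fam in code.degenerate_families.items():
                fam_obs = [c for c in codons if c in fam]
                for c in fam:
                    if fam_obs:
                        exp = len(fam) * fam_obs.count(c) / len(fam_obs)
                        assert abs(table.values[c] - exp) < 1e-12
            # oracle GC3s
            silent = [c for c in codons if code.codon_to_aa[c] not in SINGLE_CODON_AA]
            exp_gc3 = sum(c[2] in "GC" for c in silent) / len(silent)
            assert abs(silent_composition(rec).gc3s - exp_gc3) < 1e-12
            # oracle Fop
            deg = [c for c in codons if len(code.family_of(c)) >= 2]
            exp_fop = sum(c in opt for c in deg) / len(deg)
            assert abs(fop(cc, opt) - exp_fop) < 1e-12
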