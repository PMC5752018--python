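"""CDS alignment, variant calling, translation, protein properties, primers."""

import numpy as np
import pytest

from sssltools.allele_diff import (
    AlignParams,
    AlleleSequence,
    PrimerParams,
    align_pair,
    call_variants,
    check_primer,
    compare_alleles,
    protein_consequence,
    protein_properties,
    translate_cds,
)
from sssltools.reported import (
    dth3_w05s2_pair,
    dth3_w08s3_pair,
    ehd2_w22s2_pair,
    rft1_w12s4_pair,
)
from sssltools.synthetic_data import simulate_allele_pair


def allele(seq, gene="G", line="L"):
    return AlleleSequence(gene=gene, line_id=line, seq=seq)


def gotoh_score(a: str, b: str, p: AlignParams) -> float:
    """Independent affine-gap global alignment score by dynamic programming."""
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (deletion from a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (insertion)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = p.gap_open + (i - 1) * p.gap_extend
    for j in range(1, m + 1):
        Y[0, j] = p.gap_open + (j - 1) * p.gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = p.match if a[i - 1] == b[j - 1] else p.mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + p.gap_open, X[i - 1, j] + p.gap_extend,
                          Y[i - 1, j] + p.gap_open)
            Y[i, j] = max(M[i, j - 1] + p.gap_open, Y[i, j - 1] + p.gap_extend,
                          X[i, j - 1] + p.gap_open)
    return float(max(M[n, m], X[n, m], Y[n, m]))


class TestAlignment:
    def test_identical_sequences(self):
        aln = align_pair(allele("ACGTACGT"), allele("ACGTACGT"))
        assert aln.identity == 1.0
        assert "-" not in aln.aligned_ref + aln.aligned_alt

    def test_single_deletion(self):
        rep = compare_alleles(allele("ACGT"), allele("AGT"))
        assert [v.kind for v in rep.variants] == ["deletion"]
        assert rep.variants[0].length == 1

    def test_score_matches_dp_oracle(self):
        rng = np.random.default_rng(42)
        params = AlignParams()
        for _ in range(20):
            n = int(rng.integers(10, 50))
            a = "".join(rng.choice(list("ACGT"), n))
            b = list(a)
            # random perturbation: substitutions and a small indel
            for pos in rng.integers(0, len(b), rng.integers(0, 4)):
                b[pos] = str(rng.choice(list("ACGT")))
            if rng.random() < 0.7 and len(b) > 6:
                cut = int(rng.integers(1, len(b) - 3))
                del b[cut : cut + int(rng.integers(1, 3))]
            b = "".join(b)
            aln = align_pair(allele(a), allele(b), params)
            assert aln.score == pytest.approx(gotoh_score(a, b, params))

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            allele("ACGX")


class TestVariantCalling:
    def test_self_comparison_empty(self):
        rng = np.random.default_rng(1)
        for n in (10, 100, 300):
            s = "".join(rng.choice(list("ACGT"), n))
            rep = compare_alleles(allele(s), allele(s))
            assert rep.variants == ()
            assert rep.alignment_identity == 1.0

    def test_swap_maps_deletions_to_insertions(self):
        ref, alt, _ = simulate_allele_pair(
            "G", 300, [("del", 40, 60), ("snp", 150, ""), ("ins", 200, "GATTC")], seed=5
        )
        fwd = compare_alleles(ref, alt)
        rev = compare_alleles(alt, ref)
        assert fwd.n_deletions == rev.n_insertions
        assert fwd.n_insertions == rev.n_deletions
        assert fwd.total_deleted_nt == rev.total_inserted_nt
        assert fwd.n_snps == rev.n_snps

    def test_length_conservation(self):
        rng = np.random.default_rng(11)
        for rep_i in range(10):
            plan = [("del", 30, 30 + int(rng.integers(0, 20))),
                    ("ins", 100, "".join(rng.choice(list("ACGT"), int(rng.integers(1, 8))))),
                    ("snp", 200, "")]
            ref, alt, _ = simulate_allele_pair("G", 300, plan, seed=100 + rep_i)
            rep = compare_alleles(ref, alt)
            assert len(alt.seq) == len(ref.seq) - rep.total_deleted_nt + rep.total_inserted_nt

    def test_planted_variants_recovered_exactly(self):
        rng = np.random.default_rng(23)
        for rep_i in range(20):
            plan = []
            pos = 20
            while pos < 270:
                # variants separated by >= 12 matching bases so no merged
                # representation can outscore the planted one
                kind = rng.choice(["snp", "del", "ins"])
                if kind == "snp":
                    plan.append(("snp", pos, ""))
                    pos += int(rng.integers(12, 30))
                elif kind == "del":
                    ln = int(rng.integers(1, 12))
                    plan.append(("del", pos, pos + ln - 1))
                    pos += ln + int(rng.integers(12, 30))
                else:
                    ins = "".join(rng.choice(list("ACGT"), int(rng.integers(1, 8))))
                    plan.append(("ins", pos, ins))
                    pos += int(rng.integers(12, 30))
            ref, alt, truth = simulate_allele_pair("G", 300, plan, seed=1000 + rep_i, orf=False)
            rep = compare_alleles(ref, alt)
            assert rep.variants == truth.planted_variants["G"]

    def test_adjacent_snps_stay_separate(self):
        ref, alt, _ = simulate_allele_pair(
            "G", 60, [("snp", 30, ""), ("snp", 31, "")], seed=3, orf=False
        )
        rep = compare_alleles(ref, alt)
        assert rep.n_snps == 2
        assert [v.ref_start for v in rep.snps] == [30, 31]


class TestPublishedAllelePairs:
    def test_dth3_w05s2(self):
        ref, alt, truth = dth3_w05s2_pair()
        rep = compare_alleles(ref, alt)
        assert len(ref.seq) == 693 and len(alt.seq) == 66
        assert rep.total_deleted_nt == 627
        assert rep.n_deletions == 2
        assert rep.variants == truth.planted_variants["DTH3"]

    def test_dth3_w08s3_totals(self):
        ref, alt, _ = dth3_w08s3_pair()
        rep = compare_alleles(ref, alt)
        assert len(alt.seq) == 81
        assert rep.total_deleted_nt == 612
        assert rep.total_inserted_nt == 0

    def test_ehd2_w22s2(self):
        ref, alt, truth = ehd2_w22s2_pair()
        rep = compare_alleles(ref, alt)
        assert len(alt.seq) == 816
        assert rep.n_deletions == 1
        assert rep.total_deleted_nt == 229
        assert rep.n_snps == 3
        assert rep.variants == truth.planted_variants["Ehd2"]
        cons = protein_consequence(ref, alt)
        assert cons.frameshift  # 229 is not a codon multiple

    def test_rft1_w12s4(self):
        from sssltools.reported import RFT1_SNPS

        ref, alt, _ = rft1_w12s4_pair()
        rep = compare_alleles(ref, alt)
        assert len(ref.seq) == len(alt.seq) == 537
        assert rep.n_snps == 12 and rep.n_deletions == rep.n_insertions == 0
        assert [(v.ref_start, v.ref_allele, v.alt_allele) for v in rep.snps] == list(RFT1_SNPS)


class TestTranslation:
    def test_minimal_orf(self):
        assert translate_cds(allele("ATGTAA")) == "M"

    @pytest.mark.parametrize("length, aa", [(693, 230), (540, 179), (2496, 831)])
    def test_stop_terminated_lengths(self, length, aa):
        ref, _, _ = simulate_allele_pair("G", length, [], seed=2)
        assert len(translate_cds(ref)) == aa

    def test_no_stop_translates_to_end_with_warning(self):
        # the 81-nt allele is a partial CDS: 27 codons, no stop
        _, alt, _ = dth3_w08s3_pair()
        with pytest.warns(UserWarning, match="no stop"):
            assert len(translate_cds(alt)) == 27

    def test_partial_codon_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="not a multiple of 3"):
            assert translate_cds(allele("ATGGCCTAAGC")) == "MA"

    def test_agrees_with_independent_codon_table(self):
        # enumerate all 64 codons against a literal standard-code lookup
        bases = "TCAG"
        aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
        table = {
            b1 + b2 + b3: aas[16 * i + 4 * j + k]
            for i, b1 in enumerate(bases)
            for j, b2 in enumerate(bases)
            for k, b3 in enumerate(bases)
        }
        for codon, aa in table.items():
            cds = "ATG" + codon + "TAA"
            expected = "M" if aa == "*" else "M" + aa
            assert translate_cds(allele(cds)) == expected


class TestProteinConsequence:
    def test_identical_pair(self):
        ref, alt, _ = simulate_allele_pair("G", 300, [], seed=4)
        cons = protein_consequence(ref, alt)
        assert cons.identical
        assert cons.n_substitutions == 0 and not cons.frameshift and not cons.premature_stop

    def test_in_frame_codon_deletion_is_not_frameshift(self):
        ref, alt, _ = simulate_allele_pair("G", 300, [("del", 10, 12)], seed=6)
        cons = protein_consequence(ref, alt)
        assert not cons.frameshift
        assert cons.ref_protein_length - cons.alt_protein_length == 1

    def test_net_one_mod_three_deletion_is_frameshift(self):
        ref, alt, _ = simulate_allele_pair("G", 600, [("del", 103, 331)], seed=8)
        cons = protein_consequence(ref, alt)
        assert cons.frameshift
        assert cons.frameshift_codon == 35  # first affected codon of position 103

    def test_substitution_count(self):
        ref, alt, _ = simulate_allele_pair(
            "G", 300, [("snp", 40, "", ), ("snp", 100, "")], seed=9
        )
        cons = protein_consequence(ref, alt)
        assert 0 <= cons.n_substitutions <= 2  # synonymous changes possible
        assert not cons.frameshift


class TestProteinProperties:
    def test_poly_alanine_gravy(self):
        prof = protein_properties("A" * 25)
        assert prof.gravy == pytest.approx(1.8)

    def test_gg_molecular_weight(self):
        prof = protein_properties("GG")
        assert prof.molecular_weight == pytest.approx(132.12, abs=0.01)

    def test_composition_sums_to_one(self):
        prof = protein_properties("ACDEFGHIKLMNPQRSTVWY")
        assert sum(prof.aa_composition.values()) == pytest.approx(1.0, abs=1e-9)

    def test_charge_at_pi_is_zero(self):
        from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

        rng = np.random.default_rng(13)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            pep = "".join(rng.choice(aas, int(rng.integers(5, 60))))
            prof = protein_properties(pep)
            assert abs(IsoelectricPoint(pep).charge_at_pH(prof.theoretical_pi)) < 1e-3

    def test_hydropathy_profile_window(self):
        prof = protein_properties("ACDEFGHIKLMNPQRSTVWY", window=9)
        assert len(prof.hydropathy_profile) == 20 - 9 + 1
        assert protein_properties("ACD", window=9).hydropathy_profile == ()

    def test_unknown_residue(self):
        with pytest.raises(ValueError, match="unknown residue"):
            protein_properties("ACDEB")


class TestPrimerChecks:
    def test_gc_pass_tm_fail(self):
        # 10 G/C out of 20 -> GC 50%; Wallace Tm = 2*10 + 4*10 = 60 C
        rep = check_primer("GGGGGAAAAACCCCCTTTTT")
        assert rep.gc_percent == 50.0
        assert rep.tm == 60.0
        assert not rep.passed
        assert len(rep.failures) == 1 and "Tm" in rep.failures[0]

    def test_short_primer_fails_length(self):
        rep = check_primer("ACGTACGTACGTACGTA")  # 17-mer
        assert any("length" in f for f in rep.failures)

    def test_hairpin_flagged(self):
        stem = "GACGATCC"
        primer = stem + "AAA" + "GGATCGTC"  # perfect 8-nt inverted repeat
        rep = check_primer(primer)
        assert rep.max_self_complementary_run >= 8
        assert any("hairpin" in f for f in rep.failures)

    def test_good_primer_passes(self):
        rep = check_primer("AGCTAGACCATAGACCAGA", PrimerParams(tm_tolerance=5.0))
        assert rep.length == 19
        assert rep.passed, rep.failures

    def test_nearest_neighbor_tm_available(self):
        rep = check_primer(
            "AGCTAGACCATAGACCAGA",
            PrimerParams(tm_method="nearest_neighbor", tm_tolerance=10.0),
        )
        assert 30.0 < rep.tm < 80.0

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError):
            check_primer("ACGTN")
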