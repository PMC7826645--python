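"""Mature products, theoretical masses, signal prediction, isoform groups."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pep2cds.cds_reconstruction import PutativeCDS
from pep2cds.evidence_io import EDMAN, MS, PeptideEvidence
from pep2cds.product_annotation import (EDMAN_START, FULL_ORF,
                                        SIGNAL_CLEAVAGE, ProductError,
                                        average_mass, derive_mature,
                                        group_isoforms, monoisotopic_mass,
                                        predict_signal_cleavage, round_kda)
from pep2cds.sequence_core import Transcript
from pep2cds.translated_search import find_hits

from conftest import oracle_average_mass, oracle_mono_mass

proteins = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60)


class TestMasses:
    def test_glycine_free_amino_acid(self):
        assert average_mass("G") == pytest.approx(75.07, abs=0.01)
        assert monoisotopic_mass("G") == pytest.approx(75.0320, abs=0.001)

    def test_tripeptide_against_residue_table(self):
        assert average_mass("MAK") == pytest.approx(348.46, abs=0.01)

    def test_empty_and_wildcard_rejected(self):
        for bad in ("", "AXK", "AbK"):
            with pytest.raises(ProductError):
                average_mass(bad)
            with pytest.raises(ProductError):
                monoisotopic_mass(bad)

    @settings(max_examples=60, derandomize=True)
    @given(proteins, proteins)
    def test_additivity_of_concatenation(self, a, b):
        assert average_mass(a + b) == pytest.approx(
            average_mass(a) + average_mass(b) - 18.0153, abs=1e-3)

    @settings(max_examples=40, derandomize=True)
    @given(proteins, st.sampled_from("ACDEFGHIKLMNPQRSTVWY"))
    def test_monotone_under_append(self, seq, extra):
        assert monoisotopic_mass(seq + extra) > monoisotopic_mass(seq)

    def test_dual_implementation_agreement(self):
        """Library masses agree with the independent residue-table oracle
        to well under the 0.005 kDa reporting tolerance."""
        rng = random.Random(4242)
        for _ in range(100):
            seq = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY")
                          for _ in range(rng.randint(1, 130)))
            assert average_mass(seq) == pytest.approx(
                oracle_average_mass(seq), abs=0.5)
            assert monoisotopic_mass(seq) == pytest.approx(
                oracle_mono_mass(seq), abs=0.05)
            assert average_mass(seq) > monoisotopic_mass(seq) > 0

    def test_kda_rounding_half_up(self):
        assert round_kda(12845.0) == 12.85
        assert round_kda(12844.9) == 12.84


class TestSignalPrediction:
    @staticmethod
    def _signal_protein(cleavage=18):
        n_region = "MKR" + "Q" * (cleavage - 14)
        protein = n_region + "LVLLAVFA" + "AQA" + "DTPEQTSIDLKWESNF" * 4
        assert len(n_region) + 11 == cleavage + 0  # layout sanity
        return protein

    def test_planted_axa_site_found(self):
        protein = self._signal_protein(18)
        assert predict_signal_cleavage(protein) == 18

    def test_no_hydrophobic_stretch_no_site(self):
        assert predict_signal_cleavage("S" * 80) is None

    def test_short_protein_no_site(self):
        assert predict_signal_cleavage("MKLLVLLAVFAATCDLLSK") is None


def _cds_with_edman(fraction="2.1"):
    #        signal (11 aa)        mature
    # protein MKLLVLLAVFA ATCDLLSK  ; Edman read ATXDLLSK matches at offset 11
    codons = {"M": "ATG", "K": "AAA", "L": "CTT", "V": "GTT", "A": "GCC",
              "F": "TTT", "T": "ACC", "C": "TGT", "D": "GAT", "S": "TCT"}
    protein = "MKLLVLLAVFAATCDLLSK"
    seq = "".join(codons[a] for a in protein) + "TAA"
    t = Transcript("JX1", seq)
    edman = PeptideEvidence(fraction, 1, "ATXDLLSK", EDMAN)
    hits = find_hits(edman, [t])
    hits = [h for h in hits if h.strand == "+"]
    assert len(hits) == 1
    from pep2cds.cds_reconstruction import extend_hit_to_cds
    cds = extend_hit_to_cds(hits[0], t)
    return cds, edman


class TestDeriveMature:
    def test_edman_start_rule(self):
        cds, edman = _cds_with_edman()
        product = derive_mature(cds, [edman])
        assert product.method == EDMAN_START
        assert product.start_offset == 11
        assert product.sequence == "ATCDLLSK"  # residues from CDS, never X

    def test_edman_not_supporting_cds_is_an_error(self):
        cds, _ = _cds_with_edman()
        stray = PeptideEvidence("2.1", 1, "WWWWW", EDMAN)
        with pytest.raises(ProductError, match="does not support"):
            derive_mature(cds, [stray])

    def test_ms_only_falls_back_to_predictor_then_full_orf(self):
        cds, _ = _cds_with_edman()
        ms = PeptideEvidence("3.2", 1, "CDLLSK", MS)
        # the toy protein is too short for the signal detector: full ORF
        product = derive_mature(cds, [ms], fraction_id="3.2")
        assert product.method == FULL_ORF and product.low_confidence
        assert product.sequence == cds.protein

    def test_signal_cleavage_method_when_detector_fires(self):
        cds, _ = _cds_with_edman()
        product = derive_mature(cds, [], fraction_id="9.9",
                                signal_detector=lambda p: 11)
        assert product.method == SIGNAL_CLEAVAGE
        assert product.start_offset == 11 and product.sequence == "ATCDLLSK"

    def test_edman_takes_precedence_over_detector(self):
        cds, edman = _cds_with_edman()
        exploding = lambda p: (_ for _ in ()).throw(AssertionError("called"))
        product = derive_mature(cds, [edman], signal_detector=exploding)
        assert product.method == EDMAN_START


class TestIsoformGroups:
    def _product(self, fraction, cds, offset=11):
        return derive_mature(cds, [], fraction_id=fraction,
                             signal_detector=lambda p: offset)

    def test_fractions_sharing_cds_and_start_form_one_group(self):
        cds, _ = _cds_with_edman()
        products = [self._product(f, cds) for f in
                    ("4.3", "4.4", "4.8", "4.9")]
        groups = group_isoforms(products)
        assert len(groups) == 1
        assert groups[0].fraction_ids == ("4.3", "4.4", "4.8", "4.9")

    def test_distinct_cds_distinct_groups(self):
        cds_a, _ = _cds_with_edman()
        other = PutativeCDS(accession="OTHER", strand="+", nt_start=0,
                            nt_end=9, start_codon="ATG", has_stop=False,
                            protein="MAK", supporting_hits=())
        products = [self._product("1.1", cds_a),
                    derive_mature(other, [], fraction_id="2.2",
                                  signal_detector=lambda p: None)]
        assert len(group_isoforms(products)) == 2

    def test_empty_input(self):
        assert group_isoforms([]) == []
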