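"""Synthetic-transcriptome generator: determinism, digestion, evidence."""

import random

import pytest
from scipy import stats

from pep2cds.sequence_core import six_frame
from pep2cds.synthetic_data import (GeneratorError, GeneratorParams,
                                    digest_trypsin, generate_transcriptome,
                                    independent_average_mass, simulate_edman,
                                    simulate_ms_evidence)
from pep2cds.translated_search import find_hits

from conftest import evidence_from_truth


class TestGenerator:
    def test_deterministic_per_seed(self):
        a_t, a_truth = generate_transcriptome(8, seed=42)
        b_t, b_truth = generate_transcriptome(8, seed=42)
        assert [(t.accession, t.sequence) for t in a_t] == \
            [(t.accession, t.sequence) for t in b_t]
        assert a_truth == b_truth
        c_t, _ = generate_transcriptome(8, seed=43)
        assert [t.sequence for t in a_t] != [t.sequence for t in c_t]

    def test_contradictory_params_rejected(self):
        with pytest.raises(GeneratorError, match="min"):
            GeneratorParams(mature_len_range=(100, 50)).validate()
        with pytest.raises(GeneratorError):
            generate_transcriptome(0)

    def test_trimmed_count_within_binomial_band(self):
        n, p = 200, 0.2
        params = GeneratorParams(trim_prob=p, n_decoys=0)
        _, truth = generate_transcriptome(n, params, seed=11)
        trimmed = sum(pl.trimmed for pl in truth.plants)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
        assert lo <= trimmed <= hi

    def test_decoys_contain_no_evidence_peptide(self, small_synthetic):
        transcripts, truth = small_synthetic
        decoys = [t for t in transcripts if t.accession.startswith("DEC")]
        assert decoys
        hits = find_hits(evidence_from_truth(truth), decoys)
        assert hits == []

    def test_planted_cds_obeys_reported_coordinates(self, small_synthetic):
        transcripts, truth = small_synthetic
        tmap = {t.accession: t for t in transcripts}
        for plant in truth.plants:
            t = tmap[plant.accession]
            assert 0 <= plant.cds_start < plant.cds_end <= len(t)
            assert (plant.cds_end - plant.cds_start) % 3 == 0
            frames = {(f.strand, f.offset): f for f in six_frame(t)}
            # the mature sequence is a suffix of the full CDS protein
            assert plant.cds_protein.endswith(plant.mature_sequence)
            if plant.start_codon is not None:
                assert plant.cds_protein[0] in "ML"
            else:
                assert plant.trimmed

    def test_mass_ledger_matches_its_own_table(self, small_synthetic):
        _, truth = small_synthetic
        for plant in truth.plants:
            assert plant.mature_average_mass_da == pytest.approx(
                independent_average_mass(plant.mature_sequence))


class TestTrypsinDigest:
    @pytest.mark.parametrize("protein,missed,expected", [
        ("MAKRPLK", 0, ["MAK", "RPLK"]),          # R|P cleavage suppressed
        ("MAKRPLK", 1, ["MAK", "RPLK", "MAKRPLK"]),
        ("AAAA", 0, ["AAAA"]),                     # no K/R at all
        ("MAKV", 0, ["MAK", "V"]),
        ("", 0, []),
    ])
    def test_rules(self, protein, missed, expected):
        assert digest_trypsin(protein, missed) == expected

    def test_agrees_with_pyteomics_cleave(self):
        from pyteomics import parser
        rng = random.Random(31)
        for _ in range(40):
            protein = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY")
                              for _ in range(rng.randint(5, 60)))
            ours = set(digest_trypsin(protein, 1))
            theirs = set(parser.cleave(protein, r"[KR](?!P)",
                                       missed_cleavages=1))
            assert theirs <= ours  # pyteomics dedups; semantics agree


class TestEdmanSimulation:
    def test_cys_always_reads_as_x(self):
        ev = simulate_edman("ATCDLLSFEVCKGFKLNDSAQQ", 19, dropout_rate=0.0)
        assert ev.residues == "ATXDLLSFEVXKGFKLNDS"
        assert ev.x_positions == (2, 10)

    def test_zero_dropout_no_cys_exact_prefix(self):
        ev = simulate_edman("ATKDLLSFEV", 5, dropout_rate=0.0)
        assert ev.residues == "ATKDL" and not ev.truncated

    def test_read_longer_than_mature_truncates_with_flag(self):
        ev = simulate_edman("ATKDL", 10, dropout_rate=0.0)
        assert ev.residues == "ATKDL" and ev.truncated

    def test_expected_x_count_under_dropout_model(self):
        mature = "ATKDLLSFEVNGFKLNDSAWQRPS"  # no Cys
        rate, n_cycles, draws = 0.2, 20, 1000
        rng = random.Random(5)
        total = sum(
            len(simulate_edman(mature, n_cycles, dropout_rate=rate,
                               rng=rng).x_positions)
            for _ in range(draws))
        expected = rate * n_cycles
        assert total / draws == pytest.approx(expected, rel=0.15)


class TestMsSimulation:
    def test_peptides_are_verbatim_substrings(self):
        mature = ("DTPEQTSIDLDACLRKHMLCMMQGIGAVTSDGHISQDGVKHVVSDESKVSHILK"
                  "DCAVAKIDEEVFQKLDQNEPVDLPPNFGKWESNDARTL")
        evs = simulate_ms_evidence(mature, 3, seed=9)
        assert 1 <= len(evs) <= 3
        for ev in evs:
            assert ev.residues in mature
            assert 12 <= len(ev.residues) <= 24

    def test_fixed_seed_reproducibility(self):
        m = "DTPEQTSIDLDACLRKHMLCMMQGIGAVTSDGHISQDGVKAAAAKWWWWR"
        assert simulate_ms_evidence(m, 2, seed=4) == \
            simulate_ms_evidence(m, 2, seed=4)

    def test_undigestible_mature_returns_fewer(self):
        evs = simulate_ms_evidence("A" * 50, 3, seed=1)
        assert evs == []  # single 50-mer fragment is outside 12-24

    def test_emitted_peptides_rediscovered_at_planted_locus(
            self, small_synthetic):
        transcripts, truth = small_synthetic
        tmap = {t.accession: t for t in transcripts}
        evidence = evidence_from_truth(truth)
        by_fraction = {}
        for h in find_hits(evidence, transcripts):
            by_fraction.setdefault(h.evidence.fraction_id, []).append(h)
        for plant in truth.plants:
            hits = by_fraction.get(plant.fraction_id, [])
            assert hits, f"evidence of {plant.fraction_id} not re-found"
            for h in hits:
                assert h.accession == plant.accession
                assert h.strand == plant.strand
                assert plant.cds_start <= h.nt_start < h.nt_end <= plant.cds_end
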