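"""Shared fixtures and independent oracles.

The oracles here deliberately take different routes from the package:
translation goes codon-by-codon through Biopython's Seq.translate, the
search oracle is a naive sliding window over independently built frame
translations, and the alignment oracle is an exhaustive affine-gap
(Gotoh) dynamic program.  They exist so the package's optimized paths can
be checked against brute force.
"""

from __future__ import annotations

import random

import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from pep2cds.evidence_io import PeptideEvidence
from pep2cds.sequence_core import Transcript

# ---------------------------------------------------------------- oracles


def oracle_translate(dna: str) -> str:
    """Codon-by-codon translation via Biopython; any N-codon gives X."""
    out = []
    for i in range(len(dna) // 3):
        codon = dna[3 * i: 3 * i + 3]
        out.append("X" if "N" in codon else str(Seq(codon).translate()))
    return "".join(out)


def oracle_revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def oracle_six_frames(seq: str) -> list[tuple[str, int, str]]:
    """(strand, offset, aa) for all six frames, built independently."""
    frames = []
    for strand, template in (("+", seq), ("-", oracle_revcomp(seq))):
        for offset in (0, 1, 2):
            frames.append((strand, offset, oracle_translate(template[offset:])))
    return frames


def oracle_find_occurrences(peptide: str, seq: str) -> set[tuple]:
    """Naive wildcard search over the six frames of one DNA sequence.

    Returns {(strand, offset, aa_start)}; pattern X matches anything,
    window X matches only pattern X, '*' windows never match.
    """
    found = set()
    k = len(peptide)
    for strand, offset, aa in oracle_six_frames(seq):
        for start in range(len(aa) - k + 1):
            window = aa[start:start + k]
            if "*" in window:
                continue
            if all(p == "X" or p == w for p, w in zip(peptide, window)):
                found.add((strand, offset, start))
    return found


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def oracle_sw_score(a: str, b: str, gap_open: int = 11,
                    gap_extend: int = 1) -> float:
    """Exhaustive affine-gap Smith-Waterman score (Gotoh recurrences).

    A gap of length k costs gap_open + k * gap_extend (BLAST accounting).
    """
    NEG = float("-inf")
    m, n = len(a), len(b)
    best = 0.0
    H = [[0.0] * (n + 1) for _ in range(m + 1)]   # match/mismatch state
    E = [[NEG] * (n + 1) for _ in range(m + 1)]   # gap in b (up)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]   # gap in a (left)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          F[i][j - 1] - gap_extend)
            diag = max(H[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1])
            H[i][j] = max(0.0, diag + _BLOSUM62[a[i - 1]][b[j - 1]])
            best = max(best, H[i][j], E[i][j], F[i][j])
    return best


# Hand-typed standard average residue masses (Da) for the mass oracle.
ORACLE_AVG_RESIDUE = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
ORACLE_MONO_RESIDUE = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}


def oracle_average_mass(seq: str) -> float:
    return sum(ORACLE_AVG_RESIDUE[c] for c in seq) + 18.0153


def oracle_mono_mass(seq: str) -> float:
    return sum(ORACLE_MONO_RESIDUE[c] for c in seq) + 18.0105646863


# --------------------------------------------------------------- fixtures


def random_dna(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def evidence_from_truth(truth) -> list[PeptideEvidence]:
    """Evidence records for a synthetic truth ledger."""
    out = []
    for plant in truth.plants:
        for i, ev in enumerate(plant.evidence, 1):
            out.append(PeptideEvidence(plant.fraction_id, i,
                                       ev.residues, ev.technique))
    return out


@pytest.fixture
def toy_transcript() -> Transcript:
    # frame offset 2 reads ATG GCC AAA TAA -> "MAK*"
    return Transcript("TOY1", "CCATGGCCAAATAAGG", "TOY1 toy")


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240913)


@pytest.fixture(scope="session")
def small_synthetic():
    """A 30-plant synthetic dataset shared across tests (seed fixed)."""
    from pep2cds.synthetic_data import GeneratorParams, generate_transcriptome
    params = GeneratorParams(trim_prob=0.2, non_atg_start_prob=0.25,
                             ms_only_prob=0.2)
    transcripts, truth = generate_transcriptome(30, params, seed=1234)
    return transcripts, truth
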