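"""Synthetic transcriptomes with planted, signal-peptide-bearing ORFs.

The generator emulates the evidence structure the pipeline consumes: cDNA
contigs carrying one secreted-protein ORF each (5'UTR, initiation codon,
signal peptide, mature region, stop, 3'UTR), on either strand, optionally
5'-truncated ("trimmed" assemblies), plus decoy contigs; and, per plant,
either an Edman N-terminal read (Cys read as X, extra cycle dropout) or a
set of internal tryptic peptides.  A ground-truth ledger records every
planted CDS and every issued evidence record, so each pipeline stage can
be scored exactly.

Construction guarantees (what makes the ground truth recoverable):

* an in-frame stop is placed immediately 5' of the initiation codon, so
  upstream extension can reach exactly the planted start;
* signal-region codons never use ATG/TTG/CTG (leucine is encoded by the
  other four Leu codons), so a 5'-trimmed plant cannot be silently
  "completed" by a chance in-frame start codon;
* the mature region never begins with Met, and plants with TTG/CTG starts
  carry no Met at all, so the planted start is always the furthest
  reachable initiation codon;
* trim points fall on codon boundaries inside the signal region (the
  mature region is never touched);
* MS-only evidence is only issued for untrimmed plants, and the signal
  region is built so the built-in cleavage-site heuristic fires exactly
  at the planted boundary (8/8 hydrophobic h-region, Ala at -3/-1).
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass
from typing import Sequence

from .sequence_core import Transcript, translate_dna

# Independent average residue-mass table (Da); deliberately *not* taken
# from the mass library the analysis modules use, so tests can require the
# two implementations to agree.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_AVERAGE = 18.0153

# Codons per residue, with ATG/TTG/CTG banned so signal regions (and the
# matures of non-ATG plants) can be encoded start-codon-free.
_SAFE_CODONS = {
    "G": ["GGT", "GGC", "GGA", "GGG"], "A": ["GCT", "GCC", "GCA", "GCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "C": ["TGT", "TGC"],
    "L": ["CTT", "CTC", "CTA", "TTA"], "I": ["ATT", "ATC", "ATA"],
    "N": ["AAT", "AAC"], "D": ["GAT", "GAC"], "Q": ["CAA", "CAG"],
    "K": ["AAA", "AAG"], "E": ["GAA", "GAG"], "M": ["ATG"],
    "H": ["CAT", "CAC"], "F": ["TTT", "TTC"], "R": ["CGT", "CGC", "CGA",
    "CGG", "AGA", "AGG"], "Y": ["TAT", "TAC"], "W": ["TGG"],
}

_N_REGION_AA = "DEKNQR"        # charged/polar, never hydrophobic
_H_REGION_AA = "AILFVW"        # hydrophobic core (Met excluded by design)
_MATURE_AA = "ACDEFGHIKLNPQRSTVWY"  # Met excluded from position 0 anyway
STOP_CHOICES = ("TAA", "TAG", "TGA")


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorParams:
    """Study-condition knobs for the synthetic transcriptome."""

    utr5_range: tuple[int, int] = (20, 120)
    utr3_range: tuple[int, int] = (20, 120)
    signal_len_range: tuple[int, int] = (15, 30)   # residues incl. initiator
    mature_len_range: tuple[int, int] = (40, 130)  # spans ~4-15 kDa products
    reverse_strand_prob: float = 0.5
    trim_prob: float = 0.15          # 3 of ~20 published CDS were trimmed
    non_atg_start_prob: float = 0.1  # TTG/CTG initiators
    ms_only_prob: float = 0.2        # blocked N-terminus -> MS evidence only
    edman_cycles_range: tuple[int, int] = (15, 25)
    edman_dropout_rate: float = 0.05
    ms_peptides_range: tuple[int, int] = (2, 5)
    ms_peptide_len_range: tuple[int, int] = (12, 24)
    n_decoys: int | None = None      # default: one decoy per plant

    def validate(self) -> None:
        for name in ("utr5_range", "utr3_range", "signal_len_range",
                     "mature_len_range", "edman_cycles_range",
                     "ms_peptides_range", "ms_peptide_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise GeneratorError(f"{name}: min {lo} > max {hi}")
        if self.signal_len_range[0] < 15:
            raise GeneratorError("signal length must be >= 15 (detector range)")


@dataclass(frozen=True)
class EvidenceIssued:
    technique: str   # "edman_nterm" or "ms_internal"
    residues: str
    x_positions: tuple[int, ...] = ()
    truncated: bool = False


@dataclass(frozen=True)
class PlantTruth:
    """Ground truth for one planted ORF (coordinates on the final, possibly
    trimmed, transcript; forward strand, half-open, stop codon included)."""

    accession: str
    fraction_id: str
    cds_start: int
    cds_end: int
    strand: str
    start_codon: str | None   # None once the start was trimmed away
    signal_len: int           # residues incl. initiator, before trimming
    mature_sequence: str
    mature_average_mass_da: float
    trimmed: bool
    cds_protein: str          # full translated CDS on the final transcript
    evidence: tuple[EvidenceIssued, ...]


@dataclass(frozen=True)
class SyntheticTruth:
    seed: int
    plants: tuple[PlantTruth, ...]

    def by_fraction(self) -> dict[str, PlantTruth]:
        return {p.fraction_id: p for p in self.plants}


def independent_average_mass(sequence: str) -> float:
    """Average mass from the generator's own residue table (test oracle)."""
    return sum(AVERAGE_RESIDUE_MASS[a] for a in sequence) + WATER_AVERAGE


def _encode(protein: str, rng: random.Random, *, allow_atg: bool) -> str:
    codons = []
    for aa in protein:
        if aa == "M":
            if not allow_atg:
                raise GeneratorError("Met not encodable without ATG")
            codons.append("ATG")
        else:
            codons.append(rng.choice(_SAFE_CODONS[aa]))
    return "".join(codons)


def _random_dna(n: int, rng: random.Random) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _signal_body(signal_len: int, rng: random.Random) -> str:
    """Signal-peptide residues after the initiator: n-, h-, c-regions.

    Layout (c = signal_len = cleavage position): n-region to c-12,
    8-residue hydrophobic h-region at [c-11, c-4], then Ala at -3, a polar
    residue at -2, Ala at -1.
    """
    n_len = signal_len - 12  # minus initiator(1), h(8), c-region(3)
    n_region = "".join(rng.choice(_N_REGION_AA) for _ in range(n_len))
    h_region = "".join(rng.choice(_H_REGION_AA) for _ in range(8))
    return n_region + h_region + "A" + rng.choice("DENQ") + "A"


def digest_trypsin(protein: str, max_missed: int = 0) -> list[str]:
    """In-silico tryptic digest: cleave after K/R except before P.

    With ``max_missed == 1`` every concatenation of adjacent fragments is
    appended after the fully cleaved peptides.
    """
    if max_missed not in (0, 1):
        raise ValueError("max_missed must be 0 or 1")
    if not protein:
        return []
    sites = [m.end() for m in re.finditer(r"[KR](?!P)", protein)]
    bounds = [0] + [s for s in sites if s < len(protein)] + [len(protein)]
    fragments = [protein[a:b] for a, b in zip(bounds, bounds[1:])]
    peptides = list(fragments)
    if max_missed == 1:
        peptides += [a + b for a, b in zip(fragments, fragments[1:])]
    return peptides


def simulate_edman(mature: str, n_cycles: int, *,
                   dropout_rate: float = 0.0,
                   rng: random.Random | None = None) -> EvidenceIssued:
    """Edman N-terminal read: a prefix of the mature sequence with every
    Cys read as X and further positions dropped to X at ``dropout_rate``."""
    rng = rng or random.Random(0)
    truncated = n_cycles > len(mature)
    prefix = mature[:n_cycles]
    out, xs = [], []
    for i, aa in enumerate(prefix):
        if aa == "C" or (dropout_rate > 0 and rng.random() < dropout_rate):
            out.append("X")
            xs.append(i)
        else:
            out.append(aa)
    return EvidenceIssued("edman_nterm", "".join(out), tuple(xs), truncated)


def simulate_ms_evidence(mature: str, k_peptides: int, seed: int, *,
                         length_range: tuple[int, int] = (12, 24),
                         max_missed: int = 1) -> list[EvidenceIssued]:
    """Sample internal tryptic peptides within the length window.

    Deterministic per seed.  If fewer than ``k_peptides`` distinct
    candidates exist, all of them are returned (documented give-up).
    """
    rng = random.Random(seed)
    lo, hi = length_range
    candidates = sorted({p for p in digest_trypsin(mature, max_missed)
                         if lo <= len(p) <= hi and p in mature})
    k = min(k_peptides, len(candidates))
    chosen = rng.sample(candidates, k)
    return [EvidenceIssued("ms_internal", p) for p in chosen]


def generate_transcriptome(
    n_plants: int,
    params: GeneratorParams | None = None,
    seed: int = 0,
) -> tuple[list[Transcript], SyntheticTruth]:
    """Generate plant + decoy transcripts and the ground-truth ledger.

    Deterministic for a fixed seed; decoys are rejection-checked to
    contain no issued evidence peptide in any frame.
    """
    if n_plants < 1:
        raise GeneratorError("n_plants must be >= 1")
    params = params or GeneratorParams()
    params.validate()
    rng = random.Random(seed)
    transcripts: list[Transcript] = []
    plants: list[PlantTruth] = []

    for i in range(n_plants):
        plant = None
        while plant is None:
            plant = _make_plant(i, params, rng)
        transcripts.append(plant[0])
        plants.append(plant[1])

    evidence_peptides = [ev.residues for p in plants for ev in p.evidence]
    n_decoys = params.n_decoys if params.n_decoys is not None else n_plants
    for j in range(n_decoys):
        transcripts.append(_make_decoy(j, evidence_peptides, params, rng))
    return transcripts, SyntheticTruth(seed=seed, plants=tuple(plants))


def _make_plant(index: int, params: GeneratorParams,
                rng: random.Random) -> tuple[Transcript, PlantTruth] | None:
    fraction_id = f"s{index + 1}"
    accession = f"SYN{index + 1:05d}.1"

    non_atg = rng.random() < params.non_atg_start_prob
    start_codon = rng.choice(("TTG", "CTG")) if non_atg else "ATG"
    signal_len = rng.randint(*params.signal_len_range)
    mature_len = rng.randint(*params.mature_len_range)
    mature_aa = _MATURE_AA.replace("M", "") if non_atg else _MATURE_AA + "M"
    mature = rng.choice(_MATURE_AA) + "".join(
        rng.choice(mature_aa) for _ in range(mature_len - 1))
    body = _signal_body(signal_len, rng)

    trimmed = rng.random() < params.trim_prob
    # MS-only evidence (a blocked N-terminus) is only simulated for
    # untrimmed plants; see the module docstring's construction guarantees.
    ms_only = (not trimmed) and rng.random() < params.ms_only_prob

    cds_nt = (start_codon
              + _encode(body, rng, allow_atg=False)
              + _encode(mature, rng, allow_atg=not non_atg)
              + rng.choice(STOP_CHOICES))
    utr5 = _random_dna(rng.randint(*params.utr5_range), rng) + "TAA"
    utr3 = _random_dna(rng.randint(*params.utr3_range), rng)
    forward = utr5 + cds_nt + utr3
    cds_start, cds_end = len(utr5), len(utr5) + len(cds_nt)
    final_start_codon: str | None = start_codon

    if trimmed:
        # Cut at a codon boundary inside the signal region: the start codon
        # is lost, at least one signal codon and the whole mature survive.
        k = rng.randint(1, signal_len - 1)
        cut = cds_start + 3 * k
        forward = forward[cut:]
        cds_start, cds_end = 0, cds_end - cut
        final_start_codon = None

    cds_protein = translate_dna(forward[cds_start:cds_end - 3])

    evidence: list[EvidenceIssued] = []
    if ms_only:
        k = rng.randint(*params.ms_peptides_range)
        evidence = simulate_ms_evidence(
            mature, k, rng.randrange(2**31),
            length_range=params.ms_peptide_len_range)
        if not evidence:
            return None  # mature not digestible into usable peptides; retry
    else:
        n_cycles = rng.randint(*params.edman_cycles_range)
        ev = simulate_edman(mature, n_cycles,
                            dropout_rate=params.edman_dropout_rate, rng=rng)
        if set(ev.residues) == {"X"}:
            return None  # unusable all-wildcard read; retry
        evidence = [ev]

    strand = "+"
    length = len(forward)
    if rng.random() < params.reverse_strand_prob:
        strand = "-"
        forward = _revcomp(forward)
        cds_start, cds_end = length - cds_end, length - cds_start

    transcript = Transcript(accession=accession, sequence=forward,
                            description=f"{accession} synthetic plant")
    mass = independent_average_mass(mature)
    truth = PlantTruth(
        accession=accession, fraction_id=fraction_id,
        cds_start=cds_start, cds_end=cds_end, strand=strand,
        start_codon=final_start_codon, signal_len=signal_len,
        mature_sequence=mature, mature_average_mass_da=mass,
        trimmed=trimmed, cds_protein=cds_protein, evidence=tuple(evidence),
    )
    return transcript, truth


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _contains_any_peptide(transcript_seq: str,
                          peptides: Sequence[str]) -> bool:
    frames = []
    for template in (transcript_seq, _revcomp(transcript_seq)):
        for off in (0, 1, 2):
            frames.append(translate_dna(template[off:]))
    return any(_wildcard_in(pep, frame)
               for pep in peptides for frame in frames)


def _wildcard_in(pattern: str, text: str) -> bool:
    if "X" not in pattern:
        return pattern in text
    k = len(pattern)
    for s in range(len(text) - k + 1):
        window = text[s:s + k]
        if all(p == "X" or p == w for p, w in zip(pattern, window)):
            return True
    return False


def _make_decoy(index: int, evidence_peptides: Sequence[str],
                params: GeneratorParams, rng: random.Random) -> Transcript:
    lo = params.utr5_range[0] + params.utr3_range[0] + 150
    hi = params.utr5_range[1] + params.utr3_range[1] + 450
    while True:
        seq = _random_dna(rng.randint(lo, hi), rng)
        if not _contains_any_peptide(seq, evidence_peptides):
            return Transcript(
                accession=f"DEC{index + 1:05d}.1", sequence=seq,
                description=f"DEC{index + 1:05d}.1 synthetic decoy")


def truth_to_evidence_rows(truth: SyntheticTruth) -> list[dict]:
    """Ground-truth evidence as rows for the evidence TSV dialect."""
    rows = []
    for plant in truth.plants:
        for ev in plant.evidence:
            rows.append({
                "fraction_id": plant.fraction_id,
                "technique": ev.technique,
                "sequences": ev.residues,
            })
    return rows
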