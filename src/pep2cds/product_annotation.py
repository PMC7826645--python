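"""Mature-product derivation, theoretical masses and isoform grouping.

The mature protein/peptide is the processed, secreted form whose
N-terminus was (when Edman sequencing succeeded) observed directly.  The
precedence for placing that N-terminus is therefore:

1. an Edman N-terminal read supporting the CDS fixes the start exactly
   (``edman_start``);
2. otherwise a signal-peptide cleavage-site predictor is consulted
   (``signal_cleavage``);
3. otherwise the full translated ORF is reported (``full_orf``), flagged
   low-confidence.

Masses follow the conventional "theoretical molecular mass" of sequence
tools: unmodified residues, free termini, cysteines reduced; the average
mass is reported in kDa rounded half-up to 2 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Sequence

from pyteomics import mass as _ptm_mass

from .cds_reconstruction import PutativeCDS
from .evidence_io import AA_ALPHABET, EDMAN, PeptideEvidence

EDMAN_START = "edman_start"
SIGNAL_CLEAVAGE = "signal_cleavage"
FULL_ORF = "full_orf"

WATER_AVERAGE = 18.0153
WATER_MONO = 18.0105646863

HYDROPHOBIC = frozenset("AILFVMWC")   # h-region residues of signal peptides
SMALL_POLAR = frozenset("AGSCT")      # allowed at the -3 and -1 positions


class ProductError(ValueError):
    pass


@dataclass(frozen=True)
class MatureProduct:
    """The mature protein/peptide inferred for one fraction on one CDS."""

    fraction_id: str
    cds: PutativeCDS
    method: str          # EDMAN_START, SIGNAL_CLEAVAGE or FULL_ORF
    start_offset: int    # 0-based residue index into the CDS protein
    sequence: str
    low_confidence: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def average_mass_da(self) -> float:
        return average_mass(self.sequence)

    @property
    def monoisotopic_mass_da(self) -> float:
        return monoisotopic_mass(self.sequence)

    @property
    def mass_kda(self) -> float:
        return round_kda(self.average_mass_da)


@dataclass(frozen=True)
class IsoformGroup:
    """Fractions whose products share one CDS and one mature N-terminus.

    Distinct chromatographic fractions in one group are isoforms of the
    same gene product, e.g. trimmed proteolytically at the C-terminus or
    carrying different post-translational modifications.
    """

    cds_key: tuple
    start_offset: int
    fraction_ids: tuple[str, ...]
    shared_nterm_evidence: bool

    @property
    def group_id(self) -> str:
        acc = self.cds_key[0]
        return f"{acc}@{self.start_offset}"


def _check_residues(sequence: str) -> None:
    if not sequence:
        raise ProductError("empty sequence has no mass")
    bad = set(sequence) - AA_ALPHABET
    if bad:
        raise ProductError(
            f"mass undefined for residues {sorted(bad)} (X or invalid); "
            "masses are computed only on CDS-derived sequences")


def average_mass(sequence: str) -> float:
    """Average (abundance-weighted) molecular mass in Daltons."""
    _check_residues(sequence)
    return _ptm_mass.calculate_mass(sequence=sequence, average=True)


def monoisotopic_mass(sequence: str) -> float:
    """Monoisotopic molecular mass in Daltons."""
    _check_residues(sequence)
    return _ptm_mass.calculate_mass(sequence=sequence, average=False)


def round_kda(mass_da: float, ndigits: int = 2) -> float:
    """Da -> kDa with half-up rounding (the reporting convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(mass_da / 1000.0)).quantize(q, ROUND_HALF_UP))


def predict_signal_cleavage(protein: str) -> int | None:
    """Built-in heuristic signal-peptide cleavage-site detector.

    Secretory signal peptides are ~15-35 residues: a charged n-region, a
    hydrophobic h-region, and small residues at the -3/-1 positions before
    the cleavage site (the A-X-A motif).  Candidate cleavage positions
    ``c`` (0-based index of the first mature residue) in 15..35 are scored;
    a site requires >=6 hydrophobic residues among the 8 preceding the -3
    position and small residues at -3 and -1.  Returns the best-scoring
    site or None.  Any external detector with the same
    ``protein -> optional position`` contract can replace this.
    """
    if len(protein) < 25:
        return None
    best: tuple[float, int] | None = None
    for c in range(15, min(36, len(protein) - 5 + 1)):
        if protein[c - 3] not in SMALL_POLAR or protein[c - 1] not in SMALL_POLAR:
            continue
        window = protein[c - 11:c - 3]
        n_hydro = sum(r in HYDROPHOBIC for r in window)
        if len(window) < 8 or n_hydro < 6:
            continue
        score = n_hydro + (protein[c - 3] == "A") + (protein[c - 1] == "A")
        if best is None or score > best[0]:
            best = (score, c)
    return None if best is None else best[1]


SignalDetector = Callable[[str], int | None]


def derive_mature(cds: PutativeCDS,
                  evidence_for_fraction: Sequence[PeptideEvidence],
                  *,
                  fraction_id: str | None = None,
                  signal_detector: SignalDetector = predict_signal_cleavage,
                  ) -> MatureProduct:
    """Derive the mature product for one fraction from its CDS.

    The mature sequence always comes from the CDS translation (never from
    the evidence, which may contain X), running from the chosen start to
    the stop-bounded end of the CDS protein.
    """
    if fraction_id is None:
        fraction_id = evidence_for_fraction[0].fraction_id if evidence_for_fraction \
            else cds.supporting_hits[0].evidence.fraction_id
    edman = {ev for ev in evidence_for_fraction if ev.technique == EDMAN}
    if edman:
        offsets = [
            cds.hit_offset_in_protein(hit)
            for hit in cds.supporting_hits
            if hit.evidence in edman
        ]
        if not offsets:
            raise ProductError(
                f"fraction {fraction_id}: Edman evidence does not support "
                f"CDS {cds.accession}")
        start = min(offsets)
        return MatureProduct(fraction_id, cds, EDMAN_START, start,
                             cds.protein[start:])
    site = signal_detector(cds.protein)
    if site is not None:
        return MatureProduct(fraction_id, cds, SIGNAL_CLEAVAGE, site,
                             cds.protein[site:])
    return MatureProduct(fraction_id, cds, FULL_ORF, 0, cds.protein,
                         low_confidence=True)


def group_isoforms(products: Iterable[MatureProduct]) -> list[IsoformGroup]:
    """Group products sharing (CDS, mature start) across fractions."""
    buckets: dict[tuple, list[MatureProduct]] = {}
    for product in products:
        buckets.setdefault((product.cds.key, product.start_offset),
                           []).append(product)
    groups = []
    for (cds_key, start), members in buckets.items():
        fractions = tuple(sorted({m.fraction_id for m in members}))
        shared = all(m.method == EDMAN_START for m in members)
        groups.append(IsoformGroup(cds_key, start, fractions, shared))
    groups.sort(key=lambda g: g.fraction_ids)
    return groups
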