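"""Parsing and validation of experimentally determined peptide evidence.

Two kinds of evidence are supported: N-terminal reads from Edman
degradation (one per chromatographic fraction, may contain X where a cycle
failed — typically unmodified cysteine) and internal tryptic peptides from
MS/MS.  Published evidence tables print peptides as numbered, space-blocked
runs such as ``1.ETKQLNWQPK DDNQP`` (10-residue blocks, several peptides
concatenated with ``2.``, ``3.`` ... enumerators); the parser normalizes
that formatting away.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

logger = logging.getLogger(__name__)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
EVIDENCE_ALPHABET = AA_ALPHABET | {"X"}

EDMAN = "edman_nterm"
MS = "ms_internal"
TECHNIQUES = (EDMAN, MS)

_ENUMERATOR = re.compile(r"\d+\.")


class EvidenceError(ValueError):
    """Raised for malformed or inconsistent evidence records."""


@dataclass(frozen=True)
class PeptideEvidence:
    """One determined peptide sequence from one fraction."""

    fraction_id: str
    peptide_index: int  # 1-based within the fraction
    residues: str       # uppercase, 20 amino acids plus X
    technique: str      # EDMAN or MS

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise EvidenceError(
                f"fraction {self.fraction_id}: unknown technique {self.technique!r}")
        if self.peptide_index < 1:
            raise EvidenceError(
                f"fraction {self.fraction_id}: peptide_index must be >= 1")
        if not self.residues:
            raise EvidenceError(f"fraction {self.fraction_id}: empty peptide")
        for pos, ch in enumerate(self.residues):
            if ch not in EVIDENCE_ALPHABET:
                raise EvidenceError(
                    f"fraction {self.fraction_id}: invalid residue {ch!r} "
                    f"at position {pos}"
                )

    @property
    def evidence_id(self) -> str:
        return f"{self.fraction_id}#{self.peptide_index}"

    def __len__(self) -> int:
        return len(self.residues)


def split_numbered_sequences(text: str) -> list[str]:
    """Split a table-style numbered run into individual normalized peptides.

    ``"1.DTPEQTSIDL DACLRK2.HMLCMMQGIG AVTSDGHISQ DGVK"`` yields two
    peptides; internal spaces (the 10-residue display blocks) are removed
    and residues uppercased.  A string without enumerators is a single
    peptide.
    """
    text = text.strip()
    if not text:
        return []
    parts = [p for p in _ENUMERATOR.split(text) if p.strip()]
    return [re.sub(r"\s+", "", p).upper() for p in parts]


def parse_evidence_table(path: str | Path) -> list[PeptideEvidence]:
    """Read a tab-separated evidence file into :class:`PeptideEvidence` records.

    Expected columns: ``fraction_id``, ``technique`` (``edman_nterm`` /
    ``ms_internal``, with ``N-terminal`` / ``MS`` accepted as synonyms) and
    ``sequences`` (table-style numbered string, or a single peptide — the
    one-peptide-per-row long format).  Lines starting with ``#`` and blank
    lines are ignored.
    """
    path = Path(path)
    records: list[PeptideEvidence] = []
    counters: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip().lower() == "fraction_id":
                continue  # header row
            if len(fields) < 3:
                raise EvidenceError(
                    f"{path}:{lineno}: expected 3 tab-separated columns")
            fraction_id, technique_raw, sequences = (f.strip() for f in fields[:3])
            technique = _normalize_technique(technique_raw, fraction_id)
            for residues in split_numbered_sequences(sequences):
                counters[fraction_id] = counters.get(fraction_id, 0) + 1
                try:
                    records.append(
                        PeptideEvidence(
                            fraction_id=fraction_id,
                            peptide_index=counters[fraction_id],
                            residues=residues,
                            technique=technique,
                        )
                    )
                except EvidenceError as exc:
                    raise EvidenceError(f"{path}:{lineno}: {exc}") from exc
    return validate_evidence(records)


_TECHNIQUE_SYNONYMS = {
    "edman_nterm": EDMAN,
    "n-terminal": EDMAN,
    "nterm": EDMAN,
    "edman": EDMAN,
    "ms_internal": MS,
    "ms": MS,
    "mass spectrometry": MS,
}


def _normalize_technique(raw: str, fraction_id: str) -> str:
    try:
        return _TECHNIQUE_SYNONYMS[raw.lower()]
    except KeyError:
        raise EvidenceError(
            f"fraction {fraction_id}: unrecognized technique {raw!r}") from None


def validate_evidence(records: list[PeptideEvidence]) -> list[PeptideEvidence]:
    """Enforce cross-record invariants; returns the (unmodified) list.

    At most one Edman N-terminal read is allowed per fraction (a fraction
    has a single N-terminus).  An MS peptide containing X is suspicious —
    MS identification reports concrete residues — and triggers a warning,
    not a failure.
    """
    edman_seen: set[str] = set()
    for rec in records:
        if rec.technique == EDMAN:
            if rec.fraction_id in edman_seen:
                raise EvidenceError(
                    f"fraction {rec.fraction_id}: more than one Edman "
                    "N-terminal read")
            edman_seen.add(rec.fraction_id)
        elif "X" in rec.residues:
            logger.warning(
                "fraction %s: MS peptide %d contains X", rec.fraction_id,
                rec.peptide_index)
    return records


def format_evidence(records: list[PeptideEvidence]) -> str:
    """Serialize records back to the tab-separated evidence dialect.

    Peptides of one (fraction, technique) are re-joined in the numbered
    style, so ``parse_evidence_table`` on the output reproduces the input
    records (parse o format == identity on normalized records).
    """
    lines = ["fraction_id\ttechnique\tsequences"]
    groups: dict[tuple[str, str], list[PeptideEvidence]] = {}
    for rec in records:
        groups.setdefault((rec.fraction_id, rec.technique), []).append(rec)
    for (fraction_id, technique), recs in groups.items():
        recs.sort(key=lambda r: r.peptide_index)
        joined = "".join(f"{i}.{r.residues}" for i, r in enumerate(recs, 1))
        lines.append(f"{fraction_id}\t{technique}\t{joined}")
    return "\n".join(lines) + "\n"


def load_builtin_evidence() -> list[PeptideEvidence]:
    """The package's bundled hemolymph-fraction evidence table."""
    return parse_evidence_table(builtin_evidence_path())


def builtin_evidence_path() -> Path:
    return Path(__file__).parent / "data" / "rpw_fractions_evidence.tsv"
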