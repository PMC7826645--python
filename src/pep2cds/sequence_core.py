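"""DNA sequence model, FASTA I/O and six-frame translation machinery.

Transcripts are cDNA contigs from an assembled transcriptome.  All
nucleotide intervals used throughout the package are 0-based half-open on
the *forward* strand of the transcript; reverse-strand features carry a
strand flag and still store forward-strand coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# IUPAC ambiguity codes beyond N are collapsed to N on input (assembled
# transcriptomes occasionally contain them); anything else is rejected.
_AMBIGUITY_CODES = frozenset("RYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Standard codon table (NCBI table 1).  Any codon containing N translates
# to X, a stricter rule than Biopython's ambiguity resolution (which would
# translate e.g. GGN to G): downstream matching treats X as "undetermined",
# so a partially ambiguous codon must never pretend to be a known residue.
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"


class FastaParseError(ValueError):
    """Raised when a FASTA file is structurally invalid."""


@dataclass(frozen=True)
class Transcript:
    """One cDNA contig: accession, normalized DNA sequence, description."""

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.accession!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"transcript {self.accession!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadingFrame:
    """One of the six translation frames of a transcript.

    ``offset`` is counted on the translated strand: for the reverse strand
    the transcript is reverse-complemented first and the same 5'->3' offset
    convention applies.
    """

    accession: str
    strand: str  # "+" or "-"
    offset: int  # 0, 1 or 2
    aa_sequence: str
    transcript_length: int = field(repr=False, default=0)

    def nt_interval(self, aa_start: int, aa_end: int) -> tuple[int, int]:
        """Forward-strand nucleotide interval encoding ``aa_sequence[aa_start:aa_end]``."""
        if not (0 <= aa_start <= aa_end <= len(self.aa_sequence)):
            raise ValueError("amino-acid interval out of frame bounds")
        lo = self.offset + 3 * aa_start
        hi = self.offset + 3 * aa_end
        if self.strand == "+":
            return lo, hi
        return self.transcript_length - hi, self.transcript_length - lo


def normalize_sequence(raw: str, *, accession: str = "?") -> str:
    """Uppercase, U->T, collapse non-N ambiguity codes to N (with a warning)."""
    seq = raw.upper().replace("U", "T")
    ambiguous = set(seq) & _AMBIGUITY_CODES
    if ambiguous:
        logger.warning(
            "transcript %s: ambiguity codes %s mapped to N",
            accession,
            "".join(sorted(ambiguous)),
        )
        seq = "".join("N" if c in _AMBIGUITY_CODES else c for c in seq)
    return seq


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read a multi-FASTA of cDNA contigs into normalized :class:`Transcript` s.

    Accessions are the first whitespace-delimited header token and must be
    unique.  Empty records and malformed headers raise :class:`FastaParseError`
    naming the offending line.
    """
    path = Path(path)
    _scan_fasta_structure(path)
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise FastaParseError(f"{path}: duplicate accession {record.id!r}")
        seen.add(record.id)
        transcripts.append(
            Transcript(
                accession=record.id,
                sequence=normalize_sequence(str(record.seq), accession=record.id),
                description=record.description,
            )
        )
    return transcripts


def _scan_fasta_structure(path: Path) -> None:
    """Line-level structural validation so errors can name a line number."""
    header_line: int | None = None
    body_seen = False
    any_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if header_line is not None and not body_seen:
                    raise FastaParseError(
                        f"{path}:{header_line}: record has no sequence"
                    )
                if stripped == ">":
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                header_line, body_seen, any_header = lineno, False, True
            else:
                if not any_header:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                body_seen = True
    if not any_header:
        raise FastaParseError(f"{path}: no FASTA records found")
    if header_line is not None and not body_seen:
        raise FastaParseError(f"{path}:{header_line}: record has no sequence")


def write_fasta(transcripts: Iterable[Transcript], path: str | Path) -> None:
    """Write transcripts as multi-FASTA, 60-column wrapped."""
    records = [
        SeqRecord(Seq(t.sequence), id=t.accession,
                  description=_strip_id(t.description, t.accession))
        for t in transcripts
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def _strip_id(description: str, accession: str) -> str:
    if description.startswith(accession):
        return description[len(accession):].strip()
    return description


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; involutive by construction."""
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"invalid DNA characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate_dna(dna: str) -> str:
    """Translate a DNA string codon by codon; trailing 1-2 nt are ignored.

    Codons containing N give X; stops give '*'.
    """
    n = len(dna) // 3
    out = []
    for i in range(n):
        codon = dna[3 * i: 3 * i + 3]
        out.append("X" if "N" in codon else CODON_TO_AA[codon])
    return "".join(out)


def translate_frame(transcript: Transcript, strand: str, offset: int) -> ReadingFrame:
    """Translate one frame of a transcript.

    Reverse-strand frames are translated from the reverse complement with
    the same offset convention.
    """
    if offset not in (0, 1, 2):
        raise ValueError(f"offset must be 0, 1 or 2, got {offset}")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    template = transcript.sequence if strand == "+" else reverse_complement(
        transcript.sequence)
    return ReadingFrame(
        accession=transcript.accession,
        strand=strand,
        offset=offset,
        aa_sequence=translate_dna(template[offset:]),
        transcript_length=len(transcript),
    )


def six_frame(transcript: Transcript) -> list[ReadingFrame]:
    """All six reading frames (3 forward, 3 reverse)."""
    return [
        translate_frame(transcript, strand, offset)
        for strand in ("+", "-")
        for offset in (0, 1, 2)
    ]


def suppress_ambiguity_warnings() -> None:  # pragma: no cover - convenience
    logging.getLogger(__name__).setLevel(logging.ERROR)
    warnings.filterwarnings("ignore", module=__name__)
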