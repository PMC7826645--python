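"""Homology annotation of CDS products against a reference protein set.

Each query (a reconstructed CDS product) is aligned protein-vs-protein to
every reference by optimal Smith-Waterman local alignment with affine
gaps (BLOSUM62, gap open 11 / extend 1 in BLAST accounting, i.e. a gap of
length k costs 11 + k).  The best hit is the one with the lowest
Karlin-Altschul E-value (equivalently, within one database, the highest
score); percent identity follows the BLAST convention — identical columns
over *all* alignment columns, gap columns included in the denominator.

Reference FASTA headers use the dialect ``>ACCESSION product name
[Organism]``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

# Ungapped Karlin-Altschul parameters for BLOSUM62.
KA_LAMBDA = 0.3176
KA_K = 0.134

GAP = "-"


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class Alignment:
    """A pairwise local alignment: gapped strings plus its score."""

    aligned_query: str
    aligned_subject: str
    score: float
    query_interval: tuple[int, int] = (0, 0)    # half-open, query coords
    subject_interval: tuple[int, int] = (0, 0)  # half-open, subject coords

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise AlignmentError("aligned strings differ in length")
        for q, s in zip(self.aligned_query, self.aligned_subject):
            if q == GAP and s == GAP:
                raise AlignmentError("column with two gaps")

    def __len__(self) -> int:
        return len(self.aligned_query)


@dataclass(frozen=True)
class Reference:
    accession: str
    sequence: str
    product_name: str = ""
    organism: str = ""


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_accession: str
    subject_product_name: str
    subject_organism: str
    score: float
    percent_identity: float
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    evalue: float | None = None


def _make_aligner(matrix: str = "BLOSUM62", gap_open: int = 11,
                  gap_extend: int = 1) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # BLAST accounting: a length-k gap costs open + k*extend, so the first
    # gapped position costs open+extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align(query: str, subject: str, *, matrix: str = "BLOSUM62",
                gap_open: int = 11, gap_extend: int = 1) -> Alignment:
    """Optimal affine-gap Smith-Waterman local alignment.

    Deterministic: among co-optimal alignments the engine's first
    traceback is reported.  A pair with no positive-scoring local match
    (e.g. disjoint alphabets under BLOSUM62) yields an empty alignment
    with score 0.
    """
    if not query or not subject:
        raise AlignmentError("empty sequence")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    if aligner.score(query, subject) <= 0:
        return Alignment("", "", 0.0)
    aln = aligner.align(query, subject)[0]
    q_blocks, s_blocks = aln.aligned
    return Alignment(
        aligned_query=str(aln[0]),
        aligned_subject=str(aln[1]),
        score=float(aln.score),
        query_interval=(int(q_blocks[0][0]), int(q_blocks[-1][1])),
        subject_interval=(int(s_blocks[0][0]), int(s_blocks[-1][1])),
    )


def percent_identity(alignment: Alignment) -> float:
    """Identical columns / all columns (gaps included), %, 2 dp half-up."""
    if len(alignment) == 0:
        raise AlignmentError("percent identity undefined for empty alignment")
    identical = sum(
        q == s and q != GAP
        for q, s in zip(alignment.aligned_query, alignment.aligned_subject))
    pct = 100.0 * identical / len(alignment)
    return float(Decimal(repr(pct)).quantize(Decimal("0.01"), ROUND_HALF_UP))


def approximate_evalue(score: float, query_len: int, subject_len: int,
                       db_size: int | None = None) -> float:
    """Karlin-Altschul expect value, used only for ranking.

    ``E = K * m * n * exp(-lambda * S)`` with ungapped BLOSUM62 constants;
    ``n`` is the total database residue count when ``db_size`` is given
    (database-search mode — within one database the E-ranking then equals
    the score ranking) or the subject length for a single pair.
    """
    if score <= 0:
        raise ValueError("E-value defined only for positive scores")
    n = db_size if db_size is not None else subject_len
    return KA_K * query_len * n * math.exp(-KA_LAMBDA * score)


_HEADER_RE = re.compile(r"^(?P<name>.*?)\s*(?:\[(?P<org>[^\]]+)\])?\s*$")


def read_reference_fasta(path: str | Path) -> list[Reference]:
    """Read references from ``>ACCESSION product name [Organism]`` FASTA."""
    refs = []
    for record in SeqIO.parse(str(path), "fasta"):
        rest = record.description[len(record.id):].strip()
        m = _HEADER_RE.match(rest)
        refs.append(
            Reference(
                accession=record.id,
                sequence=str(record.seq).upper(),
                product_name=(m.group("name") or "").strip(),
                organism=(m.group("org") or "").strip(),
            ))
    return refs


def best_hit(query: str, references: Sequence[Reference], *,
             query_id: str = "query", matrix: str = "BLOSUM62",
             gap_open: int = 11, gap_extend: int = 1,
             use_evalue: bool = True) -> HomologyHit | None:
    """Most significant reference match, or None.

    Ranking: lowest E-value (equivalently highest score within one
    reference set); ties broken by higher percent identity, then
    lexicographically smaller accession.  Zero-score queries and empty
    reference sets yield None.
    """
    if not references:
        return None
    db_size = sum(len(r.sequence) for r in references)
    candidates = []
    for ref in references:
        aln = local_align(query, ref.sequence, matrix=matrix,
                          gap_open=gap_open, gap_extend=gap_extend)
        if aln.score <= 0:
            continue
        pid = percent_identity(aln)
        ev = approximate_evalue(aln.score, len(query), len(ref.sequence),
                                db_size) if use_evalue else None
        candidates.append((ev if use_evalue else -aln.score, -pid,
                           ref.accession, aln, ref, pid, ev))
    if not candidates:
        return None
    candidates.sort(key=lambda c: c[:3])
    _, _, _, aln, ref, pid, ev = candidates[0]
    return HomologyHit(
        query_id=query_id,
        subject_accession=ref.accession,
        subject_product_name=ref.product_name,
        subject_organism=ref.organism,
        score=aln.score,
        percent_identity=pid,
        query_interval=aln.query_interval,
        subject_interval=aln.subject_interval,
        evalue=ev,
    )


# Keyword rules for assigning an antimicrobial-peptide / binding-protein
# family from a hit's product name.  The synonym table is configurable;
# by default "hypothetical antimicrobial peptide" maps to cecropin (the
# weevil hypothetical AMP matched by the cecropin-like fraction).
FAMILY_KEYWORDS = (
    ("defensin", "defensin"),
    ("cecropin", "cecropin"),
    ("attacin", "attacin"),
    ("pheromone-binding", "PBP"),
    ("odorant-binding", "OBP"),
)
DEFAULT_SYNONYMS = {"hypothetical antimicrobial peptide": "cecropin"}

FAMILIES = ("defensin", "cecropin", "attacin", "OBP", "PBP", "other")


def classify_family(product_name: str,
                    synonyms: dict[str, str] | None = None) -> str:
    """Case-insensitive keyword classification of a product name."""
    name = (product_name or "").lower()
    for keyword, family in FAMILY_KEYWORDS:
        if keyword in name:
            return family
    table = DEFAULT_SYNONYMS if synonyms is None else synonyms
    for keyword, family in table.items():
        if keyword.lower() in name:
            return family
    return "other"
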