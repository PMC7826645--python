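"""Wildcard-exact search of peptide evidence across six-frame translations.

The original identification used a translated BLAST search filtered to
hits of 100% identity.  For short evidence peptides that filter makes the
accepted-hit set identical to exact matching with X treated as a one-
position wildcard, which is what this module computes directly: simpler,
deterministic, and with no scoring heuristics.  X in a translated window
(from an N-containing codon) matches only an X in the query — an
undetermined codon must not be claimed as evidence for a concrete residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .evidence_io import PeptideEvidence
from .sequence_core import ReadingFrame, Transcript, six_frame


@dataclass(frozen=True)
class PeptideHit:
    """One wildcard-exact occurrence of an evidence peptide in one frame."""

    evidence: PeptideEvidence
    accession: str
    strand: str          # "+" or "-"
    offset: int          # frame offset 0/1/2 on the translated strand
    aa_start: int        # half-open interval in frame protein coordinates
    aa_end: int
    nt_start: int        # half-open interval on the forward transcript strand
    nt_end: int

    def __post_init__(self) -> None:
        if (self.aa_end - self.aa_start) * 3 != self.nt_end - self.nt_start:
            raise ValueError("nt interval must be 3x the aa interval")

    @property
    def sort_key(self) -> tuple:
        return (self.accession, self.strand, self.offset, self.aa_start,
                self.evidence.evidence_id)


def wildcard_match(pattern: str, window: str,
                   *, il_equivalent: bool = False) -> bool:
    """True iff ``window`` matches ``pattern`` under the X-wildcard rule.

    Pattern X matches any window residue; window X matches only pattern X.
    With ``il_equivalent`` (for MS evidence, where I and L are mass-
    indistinguishable) I and L compare equal.
    """
    if len(pattern) != len(window):
        raise ValueError(
            f"length mismatch: pattern {len(pattern)}, window {len(window)}")
    for p, w in zip(pattern, window):
        if p == "X":
            continue
        if p != w and not (il_equivalent and {p, w} == {"I", "L"}):
            return False
    return True


def find_hits_in_frame(evidence: PeptideEvidence, frame: ReadingFrame,
                       *, il_equivalent: bool = False) -> list[PeptideHit]:
    """All wildcard-exact occurrences of one peptide in one reading frame."""
    pattern = evidence.residues
    protein = frame.aa_sequence
    k = len(pattern)
    hits = []
    # Fast path: a pattern without wildcards (and no I/L folding) can only
    # match at plain-substring positions; '*' can then never be inside a
    # candidate window.
    if "X" not in pattern and not il_equivalent:
        starts, pos = [], protein.find(pattern)
        while pos != -1:
            starts.append(pos)
            pos = protein.find(pattern, pos + 1)
    else:
        starts = range(len(protein) - k + 1)
    for start in starts:
        window = protein[start:start + k]
        if "*" in window:  # a peptide cannot span a stop codon
            continue
        if wildcard_match(pattern, window, il_equivalent=il_equivalent):
            nt_start, nt_end = frame.nt_interval(start, start + k)
            hits.append(
                PeptideHit(
                    evidence=evidence,
                    accession=frame.accession,
                    strand=frame.strand,
                    offset=frame.offset,
                    aa_start=start,
                    aa_end=start + k,
                    nt_start=nt_start,
                    nt_end=nt_end,
                )
            )
    return hits


def find_hits(evidence: Sequence[PeptideEvidence] | PeptideEvidence,
              transcripts: Iterable[Transcript],
              *, il_equivalent: bool = False) -> list[PeptideHit]:
    """Every wildcard-exact occurrence of each peptide across all six
    frames of all transcripts.

    Overlapping and multiple occurrences are all reported; result order is
    deterministic (accession, strand, frame offset, position, evidence id).
    An absent peptide simply yields no hits.
    """
    if isinstance(evidence, PeptideEvidence):
        evidence = [evidence]
    hits: list[PeptideHit] = []
    for transcript in transcripts:
        frames = six_frame(transcript)
        for ev in evidence:
            # MS-internal I/L equivalence is opt-in and never applies to
            # Edman reads, which observe residues chemically.
            il = il_equivalent and ev.technique == "ms_internal"
            for frame in frames:
                hits.extend(find_hits_in_frame(ev, frame, il_equivalent=il))
    hits.sort(key=lambda h: h.sort_key)
    return hits


HIT_TSV_COLUMNS = ("evidence_id", "accession", "strand", "frame",
                   "aa_start", "aa_end", "nt_start", "nt_end")


def hits_to_rows(hits: Iterable[PeptideHit]) -> list[dict]:
    """Hits as plain dicts for TSV/DataFrame export."""
    return [
        {
            "evidence_id": h.evidence.evidence_id,
            "accession": h.accession,
            "strand": h.strand,
            "frame": h.offset,
            "aa_start": h.aa_start,
            "aa_end": h.aa_end,
            "nt_start": h.nt_start,
            "nt_end": h.nt_end,
        }
        for h in hits
    ]
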