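"""Extension of peptide hits to putative coding sequences (CDS).

A hit is extended downstream to the first in-frame stop codon (TAA, TAG,
TGA) and upstream to the furthest reachable initiation codon: the most 5'
in-frame ATG that can be reached without crossing an in-frame stop, or —
if no ATG exists in that stop-bounded region — the most 5' TTG or CTG.
When no initiation codon exists at all, the CDS starts at the region's
upstream boundary (the codon after the bounding stop, or the transcript
edge truncated to complete codons) and is flagged 5'-incomplete: the
typical signature of an assembly truncated at its 5' end.

The reported ``nt_interval`` includes the stop codon when present; the
reported protein never includes the stop.  Non-ATG initiators are
translated literally (TTG/CTG -> L), not forced to Met; mature-product
characterization downstream never depends on the initiator region.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .sequence_core import (STOP_CODONS, Transcript, reverse_complement,
                            translate_dna)
from .translated_search import PeptideHit

START_CODONS_PREFERRED = ("ATG",)
START_CODONS_FALLBACK = ("TTG", "CTG")


@dataclass(frozen=True)
class PutativeCDS:
    """A reconstructed coding region on one transcript.

    Coordinates are 0-based half-open on the forward strand; reverse-
    strand CDS store forward-strand coordinates plus ``strand == '-'``.
    """

    accession: str
    strand: str
    nt_start: int
    nt_end: int              # includes the stop codon when has_stop
    start_codon: str | None  # "ATG", "TTG", "CTG" or None
    has_stop: bool
    protein: str             # translated product, stop excluded
    supporting_hits: tuple[PeptideHit, ...]

    @property
    def five_prime_complete(self) -> bool:
        return self.start_codon is not None

    @property
    def three_prime_complete(self) -> bool:
        return self.has_stop

    @property
    def key(self) -> tuple:
        return (self.accession, self.strand, self.nt_start, self.nt_end)

    def hit_offset_in_protein(self, hit: PeptideHit) -> int:
        """0-based residue index of a supporting hit within ``protein``."""
        if hit.accession != self.accession or hit.strand != self.strand:
            raise ValueError("hit is not on this CDS's transcript/strand")
        if self.strand == "+":
            delta = hit.nt_start - self.nt_start
        else:
            # Oriented (reading-direction) coordinates: the CDS 5' end maps
            # to forward-strand nt_end; the stop codon sits at nt_start.
            delta = self.nt_end - hit.nt_end
        if delta < 0 or delta % 3:
            raise ValueError("hit is not in frame with this CDS")
        return delta // 3


class CdsError(ValueError):
    pass


def _oriented(transcript: Transcript, strand: str) -> str:
    return (transcript.sequence if strand == "+"
            else reverse_complement(transcript.sequence))


def _oriented_interval(hit: PeptideHit, length: int) -> tuple[int, int]:
    if hit.strand == "+":
        return hit.nt_start, hit.nt_end
    return length - hit.nt_end, length - hit.nt_start


def extend_hit_to_cds(hit: PeptideHit, transcript: Transcript) -> PutativeCDS:
    """Extend one peptide hit to its putative CDS on ``transcript``."""
    if hit.accession != transcript.accession:
        raise CdsError(
            f"hit is on {hit.accession!r}, not {transcript.accession!r}")
    length = len(transcript)
    if hit.nt_end > length:
        raise CdsError("hit interval exceeds transcript length")
    seq = _oriented(transcript, hit.strand)
    o_start, o_end = _oriented_interval(hit, length)

    # Downstream: first in-frame stop at or after the hit end closes the
    # CDS (stop included); otherwise run to the last complete codon.
    has_stop = False
    cds_o_end = o_end + ((length - o_end) // 3) * 3
    for p in range(o_end, length - 2, 3):
        if seq[p:p + 3] in STOP_CODONS:
            cds_o_end, has_stop = p + 3, True
            break

    # Upstream: candidate region runs from the hit start back to (but not
    # across) the nearest in-frame stop, else to the transcript edge
    # truncated to complete codons.
    region_start = o_start % 3
    for p in range(o_start - 3, -1, -3):
        if seq[p:p + 3] in STOP_CODONS:
            region_start = p + 3
            break
    start_codon: str | None = None
    cds_o_start = region_start
    for candidates in (START_CODONS_PREFERRED, START_CODONS_FALLBACK):
        positions = [p for p in range(region_start, o_start + 1, 3)
                     if seq[p:p + 3] in candidates]
        if positions:
            cds_o_start = positions[0]  # furthest upstream wins
            start_codon = seq[cds_o_start:cds_o_start + 3]
            break

    protein = translate_dna(
        seq[cds_o_start:cds_o_end - (3 if has_stop else 0)])
    if hit.strand == "+":
        nt_start, nt_end = cds_o_start, cds_o_end
    else:
        nt_start, nt_end = length - cds_o_end, length - cds_o_start
    return PutativeCDS(
        accession=transcript.accession,
        strand=hit.strand,
        nt_start=nt_start,
        nt_end=nt_end,
        start_codon=start_codon,
        has_stop=has_stop,
        protein=protein,
        supporting_hits=(hit,),
    )


def merge_hits(hits: Sequence[PeptideHit],
               transcripts: Mapping[str, Transcript] | Iterable[Transcript],
               ) -> list[PutativeCDS]:
    """Extend a fraction's hits and merge those that share one CDS.

    Hits on the same transcript, strand and frame whose extensions land in
    the same stop-bounded region reconstruct the identical CDS interval;
    such hits are merged into one :class:`PutativeCDS` listing all of them
    as supporting evidence.  Hits on other transcripts or frames yield
    separate CDS.  Output order is deterministic: completeness (both ends
    complete first), then protein length (longest first), then accession
    and coordinates.
    """
    if not isinstance(transcripts, Mapping):
        transcripts = {t.accession: t for t in transcripts}
    merged: dict[tuple, PutativeCDS] = {}
    for hit in hits:
        try:
            transcript = transcripts[hit.accession]
        except KeyError:
            raise CdsError(f"no transcript {hit.accession!r} provided") from None
        cds = extend_hit_to_cds(hit, transcript)
        if cds.key in merged:
            existing = merged[cds.key]
            merged[cds.key] = replace(
                existing,
                supporting_hits=existing.supporting_hits + (hit,))
        else:
            merged[cds.key] = cds
    return sorted(merged.values(), key=rank_key)


def rank_key(cds: PutativeCDS) -> tuple:
    """Ranking: complete CDS first, then longer products, then accession."""
    return (
        -(cds.five_prime_complete + cds.three_prime_complete),
        -len(cds.protein),
        cds.accession,
        cds.strand,
        cds.nt_start,
    )


def cds_to_gff_row(cds: PutativeCDS) -> dict:
    """GFF3-like record (1-based inclusive display coordinates)."""
    return {
        "seqid": cds.accession,
        "source": "pep2cds",
        "type": "CDS",
        "start": cds.nt_start + 1,
        "end": cds.nt_end,
        "strand": cds.strand,
        "frame": cds.nt_start % 3 if cds.strand == "+" else (-cds.nt_end) % 3,
        "attributes": (
            f"start_codon={cds.start_codon or 'none'};"
            f"five_prime_complete={str(cds.five_prime_complete).lower()};"
            f"three_prime_complete={str(cds.three_prime_complete).lower()};"
            f"n_supporting_hits={len(cds.supporting_hits)}"
        ),
    }
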