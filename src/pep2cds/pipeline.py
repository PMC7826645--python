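"""End-to-end orchestration: evidence -> search -> CDS -> products -> report.

The stages run in a fixed order (parse, wildcard search, CDS
reconstruction, mature-product characterization, homology annotation,
isoform grouping) and every evidence record is accounted for: it either
supports a reported CDS or is listed as unmatched (a warning, not a
failure).  Reports are written as TSV with a fixed column order and as
versioned JSON; two runs on identical inputs produce byte-identical
output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import product_annotation
from .cds_reconstruction import PutativeCDS, merge_hits
from .evidence_io import PeptideEvidence, parse_evidence_table, validate_evidence
from .homology_annotation import (HomologyHit, Reference, best_hit,
                                  classify_family, read_reference_fasta)
from .product_annotation import (MatureProduct, derive_mature, group_isoforms,
                                 predict_signal_cleavage)
from .sequence_core import Transcript, read_fasta
from .translated_search import PeptideHit, find_hits

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"

REPORT_COLUMNS = (
    "fraction_id", "technique", "evidence_sequences", "transcript_accession",
    "strand", "cds_start", "cds_end", "start_codon", "five_prime_complete",
    "three_prime_complete", "mature_method", "mature_start_offset",
    "mature_length", "mature_average_mass_da", "mature_mass_kda",
    "hit_accession", "percent_identity", "product_name", "organism",
    "family", "isoform_group",
)


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class ReportRow:
    """One Table-style output record: one (fraction, matched CDS) pair."""

    fraction_id: str
    technique: str
    evidence_sequences: str
    cds: PutativeCDS
    product: MatureProduct | None
    hit: HomologyHit | None
    family: str
    isoform_group: str

    def as_dict(self) -> dict:
        mature = self.product
        mass_da = mass_kda = None
        if mature is not None and "X" not in mature.sequence:
            mass_da = round(mature.average_mass_da, 2)
            mass_kda = mature.mass_kda
        return {
            "fraction_id": self.fraction_id,
            "technique": self.technique,
            "evidence_sequences": self.evidence_sequences,
            "transcript_accession": self.cds.accession,
            "strand": self.cds.strand,
            "cds_start": self.cds.nt_start,
            "cds_end": self.cds.nt_end,
            "start_codon": self.cds.start_codon or "none",
            "five_prime_complete": self.cds.five_prime_complete,
            "three_prime_complete": self.cds.three_prime_complete,
            "mature_method": mature.method if mature else "",
            "mature_start_offset": mature.start_offset if mature else "",
            "mature_length": mature.length if mature else "",
            "mature_average_mass_da": mass_da,
            "mature_mass_kda": mass_kda,
            "hit_accession": self.hit.subject_accession if self.hit else "",
            "percent_identity": self.hit.percent_identity if self.hit else "",
            "product_name": self.hit.subject_product_name if self.hit else "",
            "organism": self.hit.subject_organism if self.hit else "",
            "family": self.family,
            "isoform_group": self.isoform_group,
        }


@dataclass
class PipelineConfig:
    """Paths and options for a config-driven run."""

    transcriptome: str | Path
    evidence: str | Path
    references: str | Path | None = None
    output_dir: str | Path = "."
    il_equivalence: bool = False
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    annotate_mature: bool = False  # align the mature region, not the full CDS
    unassigned_fractions: tuple[str, ...] = ()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "unassigned_fractions" in raw:
            raw["unassigned_fractions"] = tuple(raw["unassigned_fractions"])
        return cls(**raw)


@dataclass
class PipelineResult:
    rows: list[ReportRow]
    unmatched: list[PeptideEvidence] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame([r.as_dict() for r in self.rows],
                             columns=list(REPORT_COLUMNS))
        return frame


def analyze(transcripts: Sequence[Transcript],
            evidence: Sequence[PeptideEvidence],
            references: Sequence[Reference] = (),
            *,
            il_equivalence: bool = False,
            matrix: str = "BLOSUM62",
            gap_open: int = 11,
            gap_extend: int = 1,
            annotate_mature: bool = False,
            signal_detector=predict_signal_cleavage,
            unassigned_fractions: Sequence[str] = (),
            ) -> PipelineResult:
    """Run the full identification pipeline on in-memory inputs.

    With an empty reference set the rows are still produced, with empty
    annotation columns (degraded mode).
    """
    if not transcripts:
        raise PipelineError("no transcripts provided")
    if not evidence:
        raise PipelineError("no evidence provided")
    validate_evidence(list(evidence))
    transcript_map: Mapping[str, Transcript] = {
        t.accession: t for t in transcripts}

    all_hits = find_hits(evidence, transcripts, il_equivalent=il_equivalence)
    logger.info("search: %d hits for %d evidence records",
                len(all_hits), len(evidence))
    hits_by_fraction: dict[str, list[PeptideHit]] = {}
    matched_ids = set()
    for hit in all_hits:
        hits_by_fraction.setdefault(hit.evidence.fraction_id, []).append(hit)
        matched_ids.add(hit.evidence.evidence_id)
    unmatched = [ev for ev in evidence if ev.evidence_id not in matched_ids]
    for ev in unmatched:
        logger.warning("evidence %s: no wildcard-exact hit", ev.evidence_id)

    fractions = sorted({ev.fraction_id for ev in evidence}
                       | set(unassigned_fractions), key=_fraction_key)
    evidence_by_fraction: dict[str, list[PeptideEvidence]] = {}
    for ev in evidence:
        evidence_by_fraction.setdefault(ev.fraction_id, []).append(ev)

    products: list[MatureProduct] = []
    cds_rows: list[tuple[str, PutativeCDS, MatureProduct | None]] = []
    for fraction_id in fractions:
        fraction_hits = hits_by_fraction.get(fraction_id, [])
        fraction_evidence = evidence_by_fraction.get(fraction_id, [])
        if not fraction_hits:
            logger.warning("fraction %s: unassigned", fraction_id)
            continue
        for cds in merge_hits(fraction_hits, transcript_map):
            supported = {h.evidence.evidence_id for h in cds.supporting_hits}
            relevant = [ev for ev in fraction_evidence
                        if ev.evidence_id in supported]
            try:
                product = derive_mature(cds, relevant,
                                        fraction_id=fraction_id,
                                        signal_detector=signal_detector)
            except product_annotation.ProductError as exc:
                logger.warning("fraction %s / %s: %s", fraction_id,
                               cds.accession, exc)
                product = None
            cds_rows.append((fraction_id, cds, product))
            if product is not None:
                products.append(product)
        logger.info("fraction %s: %d CDS", fraction_id,
                    sum(1 for f, _, _ in cds_rows if f == fraction_id))

    groups = group_isoforms(products)
    group_of: dict[tuple, str] = {}
    for group in groups:
        for fraction_id in group.fraction_ids:
            group_of[(fraction_id, group.cds_key, group.start_offset)] = \
                group.group_id

    rows: list[ReportRow] = []
    for fraction_id, cds, product in cds_rows:
        query = cds.protein
        if annotate_mature and product is not None:
            query = product.sequence
        hit = best_hit(query, references, query_id=f"{fraction_id}:{cds.accession}",
                       matrix=matrix, gap_open=gap_open,
                       gap_extend=gap_extend) if references else None
        family = classify_family(hit.subject_product_name) if hit else "other"
        group_id = ""
        if product is not None:
            group_id = group_of.get(
                (fraction_id, cds.key, product.start_offset), "")
        fraction_evidence = evidence_by_fraction.get(fraction_id, [])
        rows.append(ReportRow(
            fraction_id=fraction_id,
            technique="/".join(sorted({ev.technique
                                       for ev in fraction_evidence})),
            evidence_sequences=";".join(ev.residues
                                        for ev in fraction_evidence),
            cds=cds,
            product=product,
            hit=hit,
            family=family,
            isoform_group=group_id,
        ))
    return PipelineResult(rows=rows, unmatched=unmatched)


def _fraction_key(fraction_id: str) -> tuple:
    parts = fraction_id.replace("s", "").split(".")
    try:
        return (0, tuple(int(p) for p in parts))
    except ValueError:
        return (1, (fraction_id,))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Config-driven entry point: load inputs from paths and analyze."""
    transcripts = read_fasta(config.transcriptome)
    evidence = parse_evidence_table(config.evidence)
    references: list[Reference] = []
    if config.references:
        references = read_reference_fasta(config.references)
    return analyze(
        transcripts, evidence, references,
        il_equivalence=config.il_equivalence,
        matrix=config.matrix,
        gap_open=config.gap_open,
        gap_extend=config.gap_extend,
        annotate_mature=config.annotate_mature,
        unassigned_fractions=config.unassigned_fractions,
    )


def write_report(result: PipelineResult, path: str | Path,
                 fmt: str = "tsv") -> Path:
    """Write the report as TSV (fixed column order) or versioned JSON."""
    path = Path(path)
    if fmt == "tsv":
        frame = result.to_frame()
        frame.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        payload = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "rows": [r.as_dict() for r in result.rows],
            "unmatched_evidence": [ev.evidence_id for ev in result.unmatched],
        }
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    else:
        raise PipelineError(f"unknown report format {fmt!r}")
    return path


def read_report(path: str | Path) -> pd.DataFrame:
    """Read a TSV report back (round-trips with :func:`write_report`)."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


# --- optional, strictly opt-in NCBI fetch helper ------------------------

EUTILS_URL = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
              "?db={db}&id={acc}&rettype=fasta&retmode=text")


def fetch_accessions(accessions: Sequence[str], cache_dir: str | Path,
                     db: str = "nuccore") -> tuple[list[Path], dict[str, str]]:
    """Fetch FASTA records into a local cache via NCBI E-utilities.

    Never called implicitly by the pipeline.  Cached accessions are not
    re-fetched.  Returns (paths written or cached, per-accession errors);
    a partial cache is kept on failure.
    """
    import urllib.error
    import urllib.request

    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    errors: dict[str, str] = {}
    for acc in accessions:
        target = cache_dir / f"{acc}.fasta"
        if target.exists():
            paths.append(target)
            continue
        url = EUTILS_URL.format(db=db, acc=acc)
        try:
            with urllib.request.urlopen(url, timeout=30) as resp:
                text = resp.read().decode()
            if not text.startswith(">"):
                raise ValueError("response is not FASTA")
            target.write_text(text)
            paths.append(target)
        except (urllib.error.URLError, ValueError, OSError) as exc:
            errors[acc] = str(exc)
    return paths, errors


def load_cache(cache_dir: str | Path) -> list[Transcript]:
    """Load every FASTA record previously fetched into ``cache_dir``."""
    cache_dir = Path(cache_dir)
    transcripts: list[Transcript] = []
    for fasta in sorted(cache_dir.glob("*.fasta")):
        transcripts.extend(read_fasta(fasta))
    return transcripts
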