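# pep2cds

Proteogenomic identification of partially sequenced proteins against an
assembled cDNA transcriptome.

When a protein has been isolated biochemically — say, an antibacterial
peptide purified from insect hemolymph — the experiment typically yields
only *fragments* of its sequence: an N-terminal read of 15–25 residues
from Edman degradation (with undetermined cycles printed as `X`, commonly
unmodified cysteines), or a handful of internal tryptic peptides from
MS/MS. `pep2cds` turns such fragments into full gene-level
identifications using a transcriptome assembly of the same organism:

1. **Wildcard-exact translated search** — every evidence peptide is
   located in all six reading frames of every cDNA contig. `X` in the
   query matches any residue; a translated `X` (from an `N`-containing
   codon) matches only a query `X`; windows spanning a stop never match.
   This is the exact-match equivalent of a translated-BLAST search
   filtered to 100 %-identity hits, computed directly and
   deterministically.
2. **CDS reconstruction** — each hit is extended downstream to the first
   in-frame stop codon (TAA/TAG/TGA) and upstream to the furthest
   in-frame initiation codon reachable without crossing a stop
   (preferring ATG, falling back to TTG/CTG). A hit whose upstream region
   reaches the contig edge without a start codon is flagged 5′-incomplete
   — the signature of a trimmed assembly.
3. **Mature-product characterization** — the mature N-terminus is placed
   by the Edman read when one exists, otherwise by a pluggable
   signal-peptide cleavage-site detector; lengths and theoretical average
   and monoisotopic masses (unmodified residues, free termini, reduced
   cysteines) are computed, and fractions sharing one CDS and N-terminus
   are grouped as isoforms.
4. **Homology annotation** — each CDS product is aligned to a reference
   protein set by affine-gap Smith–Waterman (BLOSUM62, gap open 11 /
   extend 1); the best hit is ranked by Karlin–Altschul E-value, percent
   identity uses the BLAST convention (gap columns in the denominator),
   and a family label (defensin / cecropin / attacin / OBP / PBP) is
   assigned from the product name.

A synthetic-data module generates transcriptomes with planted
signal-peptide-bearing ORFs (both strands, 5′-truncation, TTG/CTG starts)
plus matching Edman/MS evidence and a ground-truth ledger, so every stage
is testable without downloads.

The package ships the printed evidence table of the study it reproduces
— 16 antibacterial hemolymph fractions of the red palm weevil
*Rhynchophorus ferrugineus* (24 peptides; attacin, defensins, a
cecropin-like peptide, and pheromone-/odorant-binding proteins) — as its
bundled example input.

## Worked example

```python
>>> import pep2cds as p
>>> transcripts, truth = p.generate_transcriptome(3, seed=42)
>>> evidence = [p.PeptideEvidence(pl.fraction_id, i, ev.residues, ev.technique)
...             for pl in truth.plants for i, ev in enumerate(pl.evidence, 1)]
>>> result = p.analyze(transcripts, evidence)
>>> for row in result.rows:
...     print(row.fraction_id, row.cds.accession, row.cds.strand,
...           row.cds.start_codon, row.product.method,
...           row.product.length, row.product.mass_kda)
s1 SYN00001.1 - ATG signal_cleavage 75 9.1
s2 SYN00002.1 + ATG signal_cleavage 98 11.98
s3 SYN00003.1 + ATG edman_start 99 11.84
```

Each line is one identified fraction. Plant `s3` carried an Edman read:
its peptide was found on the forward strand of `SYN00003.1`, the hit
extended to an ATG-initiated, stop-terminated CDS, and the mature
product (from the Edman-determined N-terminus to the stop) is 99
residues, theoretical average mass 11.84 kDa. Plants `s1` and `s2` were
simulated with MS-only evidence (a blocked N-terminus), so their mature
N-termini come from the signal-peptide cleavage detector instead — all
matching the generator's ledger (`truth.plants`).

The same run from the shell:

```bash
pep2cds simulate --n-plants 3 --seed 42 --out-prefix demo
pep2cds report --transcriptome demo.fasta --evidence demo.evidence.tsv \
               --out demo.report.tsv
```

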