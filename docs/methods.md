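# Methods

This note documents the model behind each stage, the defaults and why
they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Problem setting

The pipeline identifies partially sequenced proteins — fragments
determined by Edman N-terminal sequencing or by MS/MS of tryptic digests
— against an assembled cDNA transcriptome of the same organism. Because
the experimental evidence is exact (the accepted hits of the original
translated-BLAST workflow were filtered to 100 % identity), the search
problem reduces to deterministic wildcard-exact matching, and the
statistical machinery of alignment is needed only at the annotation
stage, where products are compared across species.

## Wildcard-exact translated search

Every contig is translated in all six frames (standard codon table;
codons containing `N` translate to `X`; trailing 1–2 nt are ignored).
An evidence peptide matches a frame window iff every position matches,
where query `X` (an undetermined Edman cycle) matches any residue but a
translated `X` matches only a query `X`: an undetermined codon must not
be claimed as support for a concrete residue. Windows containing a stop
never match — a physical peptide cannot span a stop codon. All
occurrences, overlapping or not and on either strand, are reported in a
fixed order, so the stage is a pure function of its inputs.

Equivalence with a naive sliding-window oracle over independently built
frame translations is asserted on 500 random cases per run of the
acceptance suite, including `X`-bearing queries, `N`-bearing contigs and
planted reverse-strand peptides.

An optional I≡L folding (off by default) exists for MS evidence, where
isoleucine and leucine are mass-indistinguishable; it never applies to
Edman reads, which observe residues chemically.

## CDS reconstruction

A hit is extended downstream to the first in-frame stop codon, which is
included in the reported nucleotide interval; if none exists before the
contig end the CDS runs to the last complete codon and is flagged
3′-incomplete. Upstream, the candidate region runs from the hit start
back to (but not across) the nearest in-frame stop, or to the contig
edge truncated to complete codons. Within that region the chosen
initiation codon is the most 5′ in-frame ATG; if no ATG exists, the most
5′ TTG or CTG ("furthest reachable start", i.e. the maximal open reading
frame). When both TTG and CTG exist the more upstream wins regardless of
which it is: the furthest-reach rule dominates the sub-preference, which
is only stated relative to ATG. If no initiation codon exists at all the
CDS begins at the region boundary, start-less and flagged 5′-incomplete
— the signature of an assembly truncated at its 5′ end ("trimmed").

Non-ATG initiators are translated literally (TTG/CTG → Leu) rather than
forced to Met; since mature products never include the initiator region,
this choice cannot affect any reported mature length or mass. Upstream
extension never crosses the contig edge mid-codon: partial codons are
truncated away.

Hits of one fraction that reconstruct the identical CDS interval are
merged into a single CDS listing all of them as supporting evidence;
hits on other contigs or frames yield separate CDS. All candidate CDS
are reported, ranked by completeness (both ends) then product length —
the pipeline ranks, it never picks, because expression cannot be decided
computationally when several contigs carry the same motif.

## Mature products and masses

The mature N-terminus is placed with a strict precedence: (1) an Edman
read supporting the CDS fixes it exactly — the experiment observed the
mature N-terminus directly; (2) otherwise a signal-peptide cleavage-site
detector is consulted; (3) otherwise the full ORF is reported with a
low-confidence flag. The mature sequence is always taken from the CDS
translation, never from the evidence (which may contain `X`), and runs
to the stop-bounded end of the CDS protein.

The built-in cleavage-site detector is a deliberately simple
von-Heijne-style heuristic: candidate sites at positions 15–35 require
≥ 6 hydrophobic residues (A/I/L/F/V/M/W/C) among the 8 preceding the −3
position and small residues (A/G/S/C/T) at −3 and −1 (the A-X-A motif);
the best-scoring site wins, earliest on ties. It is *not* a
re-implementation of a trained predictor such as SignalP; any external
detector can be plugged in through the same `protein -> optional
position` interface, and masses of detector-placed products should be
treated as convention-dependent.

Masses follow the conventional "theoretical molecular mass" of sequence
tools: sums of standard residue masses plus one water, unmodified
residues, free termini, cysteines reduced; average masses are reported
in kDa rounded half-up to two decimals, monoisotopic masses are used for
MS-oriented work. Masses are computed only on CDS-derived sequences (an
`X` is an error, not a zero). Two independent mass tables exist in the
codebase — the analysis modules use pyteomics, the generator carries its
own hand-typed residue table — and tests require them to agree well
within the 0.005 kDa reporting tolerance.

Fractions whose products share one CDS and one mature start are grouped
as isoforms (C-terminally trimmed or differently modified forms of one
gene product); the grouping deliberately ignores the C-terminus, which
chromatographic isoforms differ in.

## Homology annotation

CDS products are aligned protein-vs-protein to a reference set by
optimal Smith–Waterman local alignment with affine gaps (BLOSUM62, gap
open 11 / extend 1 in BLAST accounting: a length-k gap costs 11 + k).
Aligning the already-translated product, rather than re-running a
translated nucleotide search, yields the same accepted outcome with
simpler machinery. The engine is Biopython's `PairwiseAligner`; scores
are verified against an exhaustive affine-gap dynamic program on 1,000
random short pairs per acceptance run. Determinism among co-optimal
alignments comes from taking the engine's first traceback; only the
choice among equal-scoring alignments (not the score) can depend on
this.

Percent identity is identical columns over all alignment columns, gap
columns included in the denominator (the BLAST convention), rounded
half-up to two decimals. Best hits are ranked by a Karlin–Altschul
expect value `E = K·m·n·exp(−λS)` with ungapped BLOSUM62 constants
(λ = 0.3176, K = 0.134) and `n` the total database residue count, so
within one database the E-ranking equals the score ranking; ties break
by higher identity, then lexicographic accession. The E-value is a
ranking device, not a calibrated significance estimate. By default the
full CDS product is aligned; a flag switches to the mature region.

Family labels (defensin, cecropin, attacin, OBP, PBP, other) come from
case-insensitive keywords in the hit's product name plus a configurable
synonym table; by default "hypothetical antimicrobial peptide" maps to
cecropin, mirroring the attribution of the weevil hypothetical AMP that
the cecropin-like fraction matches.

## Synthetic data: what it emulates, and what it does not

Each plant is a contig `5'UTR + start codon + signal region + mature
region + stop + 3'UTR`, optionally reverse-complemented, optionally
5′-truncated at a codon boundary inside the signal region. Defaults are
the study conditions the pipeline is meant for: signal peptides of 15–30
residues, mature regions of 40–130 residues (~4–15 kDa products), both
strands equally likely, a 0.15 trim probability (matching the roughly
one-in-seven trimmed CDS of the motivating dataset; tests use 0.2 where
a larger trimmed count is needed), 0.1 TTG/CTG starts, 0.2 MS-only
fractions, Edman reads of 15–25 cycles with every Cys read as `X` plus a
5 % extra dropout, and 2–5 tryptic peptides of 12–24 residues with at
most one missed cleavage (`[KR]` not before `P`). One decoy contig of
uniform random nucleotides is generated per plant and rejection-checked
to contain no issued evidence peptide in any frame.

Construction guarantees make the ground truth exactly recoverable and
are part of the generator's contract: an in-frame stop immediately 5′ of
the start codon (so upstream extension recovers the planted start, not
an earlier UTR codon), no ATG/TTG/CTG codons inside the signal region
(so trimmed plants cannot be silently "completed"), no initial Met in
the mature region and no Met at all in non-ATG plants (so the planted
start is always the furthest reachable), and an 8/8-hydrophobic,
Ala−3/Ala−1 signal region that the built-in detector resolves uniquely
(MS-only plants depend on it). Trimming applies only to plants with
Edman evidence.

What the generator does **not** emulate: realistic codon usage or
nucleotide composition, sequencing errors other than 5′ truncation,
chimeric or multi-ORF contigs, PTMs, spectra or retention behaviour, and
homologous gene families (each plant is unrelated to every other).
Passing the recovery suite therefore demonstrates the correctness of the
search/extension/characterization logic under clean evidence — not
robustness to assembly noise or to paralogy, which real data may add.

## Numerical and degenerate-input conventions

* Coordinates: 0-based half-open on the forward strand everywhere;
  reverse-strand features carry a strand flag (GFF-style 1-based
  inclusive coordinates only in the display export).
* Rounding: kDa and percent identity use decimal half-up, not banker's
  rounding.
* IUPAC ambiguity codes beyond `N` are collapsed to `N` on input with a
  warning; `U` is rewritten to `T`; empty FASTA records and duplicate
  accessions are errors that name the offending line.
* An evidence peptide with no hit is a warning and is listed as
  unmatched; a fraction with two Edman reads is an error (a fraction has
  one N-terminus).
* The unidentifiable fraction of the bundled table (3.4) carries no
  computable evidence and yields no record; it can be listed in the
  config to appear as explicitly unassigned.
* Seeds: one integer seed drives a single documented random stream in
  the generator; the acceptance script derives all randomness from its
  `--seed` argument.

## Problem sizes

The acceptance script and recovery suite use 200 planted ORFs (plus 200
decoys), 500 random search-oracle cases and 1,000 random alignment
pairs; the whole test suite runs in well under five minutes on one CPU
core. These sizes were chosen so that binomial bands on generator rates
are tight and every code path (reverse strand, TTG/CTG, trimming,
MS-only) is exercised many times per run.

## Known limitations

* The 100 %-identity reading makes the search blind to polymorphisms
  between the sequenced individuals and the transcriptome; a
  substitution-tolerant mode is a deliberate non-goal at this stage.
* The built-in cleavage detector is a heuristic; mature masses for
  MS-only fractions are only as good as the plugged-in detector.
* E-values are ungapped-parameter approximations used for ranking only.
* Multi-contig identifications are ranked, never collapsed: deciding
  which of several near-identical contigs is expressed needs data the
  pipeline does not see.
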