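# Methods

## The annotation model

`polyorf` treats every transcript — mRNA and ncRNA alike — as potentially
polycistronic. Enumeration scans the spliced sequence in all three frames;
for each in-frame stop codon at most one ORF is emitted, anchored at the
5′-most AUG after the previous in-frame stop. This matches common ORF-caller
convention and avoids one accession per nested AUG sharing a stop. ORFs
whose transcript ends before an in-frame stop are not emitted: their protein
sequence would be indeterminate. The 30-codon minimum counts amino-acid
codons excluding the stop (protein ≥ 30 aa). Codons containing N never match
a start or a stop and translate to X. Selenocysteine recoding and
non-standard genetic codes are unsupported.

ORFs are deduplicated genome-wide on (contig, strand, genomic blocks), so
one CDS annotated in both input annotations becomes a single record whose
supporting transcripts span both sources. Identical protein sequences at
different loci remain distinct records — the key is coordinates, not
sequence.

### Coordinates

Everything internal is 0-based half-open. GTF/GFF3 (1-based inclusive) is
converted once at the parsing boundary; BED12 is written natively. Annotated
CDS spans are normalized to include the stop codon: when the annotation is
stop-exclusive and the next in-frame codon is a stop, the span is extended
by 3 nt. This makes annotated-CDS boundary coordinates directly comparable
with predicted ORFs for the isoform rule.

### Gene reconciliation

The unit for every "same gene" decision is a gene group: genes (from either
annotation) merge when they share contig and strand and either their spans
overlap by ≥ 1 bp or their names match case-insensitively. The pairing of
genes across annotation providers is genuinely underdetermined — providers
share no stable gene identifier — so this locus-overlap-or-name rule is a
deliberate, simple choice; antisense overlaps never merge because the rule
is strand-aware.

## Categorization

A predicted protein is a **RefProt** iff its sequence exactly equals a
reference entry (case- and I/L-sensitive; the I/L collapse belongs to
peptide unicity only, where isobaric indistinguishability is a property of
the measurement). Otherwise it is a **novel isoform** iff some same-gene
reference CDS shares its genomic 5′ and/or 3′ boundary coordinate and local
alignment yields identical positions > 20% of the candidate's length — the
denominator is the candidate, matching "identity over X% of the protein
length" conventions. Everything else is an **altProt**, including every
protein on a gene without any RefProt (ncRNA-only loci).

External (UniProt-like) reference entries are mapped to genes through the
cross-reference table, or by exact sequence match to an annotation protein;
entries that map to no gene are kept with gene unknown. External entries
carry no genomic coordinates, so they can never satisfy the shared-boundary
clause and never create novel isoforms; they still block novelty through
exact sequence match. Accessions are deterministic: RefProts keep their
source accession; II_/IP_ numbers are assigned after sorting by (contig,
genomic start, end, strand, protein sequence), so a rebuild of identical
input yields identical accessions.

## Related-protein edges and bit scores

Within each gene group every protein pair is aligned in both query
directions with Smith–Waterman (BLOSUM62, gap open 11 / extend 1, i.e. a
gap of length k costs 11 + k). Raw scores are converted to bit scores with
the standard gapped-BLOSUM62 Karlin–Altschul constants λ = 0.267 and
K = 0.041 (both configurable); using bit scores keeps edges independent of
any database size. An edge is emitted when either direction has bit score
> 40 with the aligned span covering > 50% of the queried sequence; the edge
stores the passing (or stronger) direction. "Coverage" is aligned query
span over query length. Self-contained dynamic programming is used rather
than an external BLAST process; a BLAST binary, when present, serves only
as a cross-check in the test suite (composition-based statistics disabled,
agreement within 10%). Protein trees are single-linkage clusters of the
edge set; around any focal protein, co-members are ordered by descending
bit score to the focal protein, ties broken by accession.

## MS detectability and peptide unicity

Digestion is tryptic: cleave C-terminal to K or R except before P; the
default theoretical digest allows 0 missed cleavages (configurable).
Masses are monoisotopic, unmodified, uncharged and include one water — the
conventional neutral peptide mass. Peptides containing X are never
assignable.

The unicity index keys peptides with every I replaced by L, keeping original
spellings, so isobaric spellings collide deliberately. Assignment of an
observed peptide follows, in order: (a) any RefProt match → assigned to all
matching RefProts, reported under the reference spelling; (b) otherwise
matches spanning several gene groups → discarded; (c) otherwise assigned to
all matching novel proteins of the single gene. Rule (a) is applied across
genes: a pseudogene-supported peptide that equals a parental-gene RefProt
peptide up to I/L belongs to the RefProt, not the pseudogene product. A
stricter mode (`PipelineConfig.literal_unicity_rules`) applies the
cross-gene discard first instead.

Possible coverage is the union of spans of tryptic peptides that are ≥ 7 aa,
≤ 4600 Da and whose assignment would include the protein, divided by protein
length; zero flags the protein "not MS-detectable". Detected coverage uses
only observed, assigned peptides and therefore cannot exceed possible
coverage for observation tables drawn from the same search criteria.

## Ribo-seq call reconciliation

An external call overlaps a predicted ORF only when it lies on a supporting
transcript, shares the reading frame and the stop position; the fraction is
shared in-frame codons over the longer of the two ORFs. This symmetric,
conservative denominator is a recorded choice — the overlap definition is
not fully determined by its source — and is configurable. "Above 70%" is a
strict inequality. Each call is matched to the ORF with maximal overlap on
its transcript; accepted events keep the initiating codon verbatim (CUG,
GUG, … — this is the only route by which non-AUG starts enter the catalog)
and the caller's generalized-binomial-test p-value is passed through
unchanged as the start-codon confidence; no p-value cutoff or
multiple-testing correction is applied. Per-ORF summaries report distinct
datasets, the minimum p-value and the sorted set of observed start codons.

## The synthetic fixture

`synthetic_fixtures.generate_fixture` emulates the five input classes
(genome FASTA, GTF + GFF3 annotations, reference FASTA with gene
cross-references, a PeptideShaker-like observation TSV, a PRICE-like
ORF-call TSV) at desk scale: two contigs of a few kilobases, ten scenario
loci. Each decision point of the pipeline is planted with a case on each
side of its threshold: ORFs of 30 and 29 codons plus an AUG with no in-frame
stop; a 100-codon CDS with an embedded +1-frame 32-codon altORF, duplicated
across both annotations; stop-sharing isoform candidates at 67% and 10%
identity; same-gene, cross-gene and isobaric (EIGNLISDAMK/EIGNIISDAMK-style)
shared peptides; an antisense mRNA overlapping a ncRNA gene; ribo calls at
overlaps 0.50–0.95 in 0.05 steps including both datasets and a CUG start.
Generation is deterministic per (spec, seed) and byte-identical across
reruns. Random filler is vetted by seeded rejection sampling so it cannot
contribute unplanned ≥ 30-codon ORFs, and planted alignments are verified to
fall on their intended side of the 20%-identity and edge thresholds before
the manifest is written; the manifest truths themselves are fixed by
construction. `truth_check` compares a pipeline run against the manifest
and returns human-readable discrepancies.

What the fixture does **not** emulate: realistic gene density, intron
lengths, codon usage, sequencing errors, assembly gaps (N runs appear only
in unit tests), decoy peptides from search-engine FDR, or noisy ribo-seq
call boundaries. Passing on fixtures therefore demonstrates correctness of
the rules and bookkeeping, not robustness to dirty annotations.

## Numerical and tie-breaking choices

* Alignment identities are counted on the single best local alignment
  returned by the aligner; among co-optimal alignments the aligner's first
  is used, which is deterministic for fixed input.
* Edges: when both directions pass, the higher-bit direction is stored,
  ties broken by query accession; output ordered by bit score descending.
* Zero-score alignments (no positive-scoring segment) report an empty query
  span and zero identities rather than an arbitrary cell.
* All TSV/FASTA/BED writers emit records in deterministic order; reruns on
  identical input are bitwise identical (timestamps only in the run
  manifest).
* Degenerate inputs: empty proteins cannot be digested or aligned
  (validation errors); observation rows with non-positive PSM counts and
  call rows with non-numeric or out-of-range fields are rejected with
  warnings; unknown transcripts in call tables are kept but flagged.

## Problem sizes

The default test suite runs the full pipeline on the generated fixture
(~15 transcripts, 13 proteins), sweeps 20 fixture seeds end-to-end,
checks ORF enumeration against a brute-force scanner on 200 random
transcripts of up to 1.2 kb, and alignment raw scores against a quadratic
DP on dozens of random pairs — a few seconds in total. These sizes were
chosen because every rule in the pipeline is exercised at its boundary by
construction; larger random worlds would add runtime, not coverage.

## Known limitations

* Non-AUG starts are never enumerated de novo; they only annotate existing
  AUG ORFs via ribo-seq reconciliation.
* The gene-pairing rule across annotation providers is heuristic; unusual
  loci (same-strand overlapping distinct genes) will merge.
* No UniProt isoform (dash-suffix) expansion; no conservation or
  functional-domain evidence; no spectral search or FDR modelling.
* `diff` compares catalogs from the same genome build only (contig sets
  must match).
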