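# polyorf

Polycistronic proteogenomic ORF annotation for eukaryotic transcriptomes.

Standard genome annotations enforce one coding sequence per transcript, an
AUG start and (historically) a 100-codon minimum, which hides a large part of
the translated proteome: proteins from ncRNAs, from UTRs, from overlapping
reading frames of mRNAs, and unannotated isoforms. `polyorf` drops the
one-CDS-per-transcript convention and annotates *every* ORF of at least 30
codons with an AUG start, in all three frames of every transcript from up to
two annotation sources (e.g. a RefSeq-flavor GTF and an Ensembl-flavor
GFF3). It is aimed at proteogenomics practitioners who need an exhaustive,
evidence-annotated protein search space rather than the curated minimum.

## What it computes

**Prediction.** Each predicted protein is classified against the reference
proteome (annotation CDSs plus an optional UniProt-like FASTA):

* **RefProt** — exact sequence already annotated;
* **novel isoform (II_ accessions)** — shares a genomic CDS start and/or
  stop coordinate with a same-gene RefProt and aligns with identical
  positions over 20% of its own length;
* **altProt (IP_ accessions)** — everything else, including all proteins on
  genes with no RefProt.

**Evidence layers.**

* *Related proteins*: all-versus-all Smith–Waterman (BLOSUM62, gap open 11 /
  extend 1) within each gene; raw scores *S* become database-size-independent
  bit scores *S′* = (λ·*S* − ln *K*) / ln 2 with gapped-BLOSUM62 constants
  λ = 0.267, *K* = 0.041. A pair is related when either direction reaches
  *S′* > 40 bits over > 50% of the queried sequence; related proteins are
  single-linkage clustered into per-gene protein trees.
* *MS detectability*: in-silico tryptic digestion (cleave after K/R, not
  before P), monoisotopic masses; a peptide is assignable when it is ≥ 7 aa,
  ≤ 4600 Da and passes the unicity rules with I and L treated as
  indistinguishable — a peptide matching any RefProt goes to the matching
  RefProt(s) only (re-spelled to the reference sequence); a peptide shared
  by novel proteins of several genes is discarded; otherwise it goes to all
  matching novel proteins of its single gene. Per protein the tool reports
  datasets, unique peptides, PSMs, and possible vs detected sequence
  coverage ("not MS-detectable" when no assignable peptide exists).
* *Translation evidence*: ORF calls from a ribosome-profiling caller
  (PRICE-like TSV) are matched to predicted ORFs; a call is accepted when it
  shares the prediction's frame and stop and the shared codons exceed 70% of
  the longer of the two. Initiating codons are recorded verbatim, so
  non-AUG starts enter the catalog here, with the caller's p-value passed
  through as the start-codon confidence.

**Release diffing.** Two catalog builds can be compared: transcripts and
reference proteins added / removed or sequence-changed, and novel proteins
whose sequence became annotated ("promoted to RefProt").

## Worked example

The package ships a seeded generator for a complete synthetic input world —
genome, two annotations, reference proteins, peptide observations, ribo-seq
ORF calls — with a ground-truth manifest:

```bash
polyorf --quiet fixture --out demo/inputs --seed 13
polyorf --quiet build \
    --genome demo/inputs/genome.fa \
    --annotation demo/inputs/annotA.gtf --annotation demo/inputs/annotB.gff3 \
    --reference-fasta demo/inputs/reference.fasta --xref demo/inputs/xref.tsv \
    --peptides demo/inputs/peptides.tsv --ribo-calls demo/inputs/ribo_calls.tsv \
    --out demo/catalog
polyorf classify --catalog demo/catalog
```

```
Total   13
AltProt 7
NovelIsoform    1
RefProt 5
```

Thirteen proteins: five reference CDSs, one novel isoform (a transcript
splicing into the 3′ end of a reference CDS, 67% identical to it), and seven
altProts — among them a 32-codon ORF overlapping an annotated CDS in the +1
frame and an ORF on a ncRNA. The isoform edge table shows the relationship
call behind the II_ record:

```
query  subject        raw_score  bit_score  query_coverage  identity_fraction
II_1   REF_GENE_ISO   233        94.360     0.6667          0.6667
```

Peptide assignment demonstrates the I/L isobar rule: the observed peptide
differs from a reference-protein peptide only by a leucine-for-isoleucine
substitution, so it is re-assigned to the RefProt under the reference
spelling rather than supporting the pseudogene-like altProt:

```
peptide      dataset  psms  canonical    rule              assigned
EIGNLISDAMK  ds_ms1   4     EIGNIISDAMK  refprot_priority  REF_HSPD1
```

The ribo-seq summary aggregates accepted translation events per ORF — here
the 100-codon CDS was called in two datasets, once with a CUG start:

```
orf_id              n_datasets  best_p_value  init_codons
chr1:+:1240-1540    2           1e-06         ATG;CTG
```

`polyorf --help` lists the remaining subcommands (`isoforms`,
`assign-peptides`, `digest-stats`, `ribo-filter`, `diff`, `export`).

## Layout

```
src/polyorf/
  models.py              shared dataclasses and the PipelineConfig defaults
  annotation_io.py       FASTA/GTF/GFF3 ingestion, gene reconciliation, exports
  orf_prediction.py      3-frame enumeration, translation, genome projection
  protein_catalog.py     reference merging, categorization, accessions, diffs
  isoform_graph.py       local alignment, bit scores, edges, protein trees
  ms_evidence.py         digestion, masses, peptide unicity, coverage stats
  ribo_evidence.py       ORF-call ingestion, overlap filter, aggregation
  synthetic_fixtures.py  seeded input generator + ground-truth checking
  pipeline.py / cli.py   end-to-end driver and the polyorf command
docs/methods.md          model assumptions, parameter choices, limitations
```
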