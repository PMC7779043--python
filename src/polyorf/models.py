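"""Shared domain types for the polycistronic ORF annotation pipeline.

Coordinate conventions: all internal genomic and transcript coordinates are
0-based, half-open. GTF/GFF3 input (1-based, inclusive) is converted at the
parsing boundary; BED output is natively 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

logger = logging.getLogger("polyorf")

MRNA = "mRNA"
NCRNA = "ncRNA"

REFPROT = "RefProt"
NOVEL_ISOFORM = "NovelIsoform"
ALTPROT = "AltProt"

# isoform reasons
SHARED_START = "shared_start"
SHARED_END = "shared_end"
IDENTITY_OVER_THRESHOLD = "identity_over_threshold"

# peptide assignment rules
DISCARDED_CROSS_GENE = "discarded_cross_gene"
REFPROT_PRIORITY = "refprot_priority"
SHARED_NOVEL_SAME_GENE = "shared_novel_same_gene"
UNIQUE = "unique"

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class InputError(ValueError):
    """Unreadable, empty or malformed input file."""


class ValidationError(ValueError):
    """A record violates a structural invariant."""


class CoordinateError(ValidationError):
    """A span falls outside its transcript or contig."""


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds of the pipeline, with the published defaults.

    min_orf_codons counts amino-acid codons excluding the stop; start_codons
    applies to de novo enumeration only (non-AUG starts enter via ribo-seq
    call reconciliation). bit_threshold/query_coverage_threshold gate
    within-gene related-protein edges; isoform_identity_threshold is the
    fraction of the candidate protein length that must be identical for a
    boundary-sharing candidate to be called a novel isoform.
    """

    min_orf_codons: int = 30
    start_codons: frozenset[str] = frozenset({"ATG"})
    min_pep_len: int = 7
    max_pep_mass: float = 4600.0
    bit_threshold: float = 40.0
    query_coverage_threshold: float = 0.5
    ribo_overlap_threshold: float = 0.7
    isoform_identity_threshold: float = 0.2
    missed_cleavages: int = 0
    # Karlin-Altschul parameters for gapped BLOSUM62 (open 11, extend 1)
    ka_lambda: float = 0.267
    ka_k: float = 0.041
    # When True, apply assignment rule (i) literally: any cross-gene shared
    # peptide is discarded even if one match is a RefProt.
    literal_unicity_rules: bool = False

    def __post_init__(self) -> None:
        if self.min_orf_codons < 1 or self.min_pep_len < 1 or self.missed_cleavages < 0:
            raise ValidationError("count thresholds must be positive")
        if self.max_pep_mass <= 0 or self.bit_threshold <= 0:
            raise ValidationError("mass/bit thresholds must be positive")
        for frac in (self.query_coverage_threshold, self.ribo_overlap_threshold,
                     self.isoform_identity_threshold):
            if not 0 < frac <= 1:
                raise ValidationError("fraction thresholds must lie in (0, 1]")
        if not self.start_codons:
            raise ValidationError("at least one start codon required")
        object.__setattr__(self, "start_codons", frozenset(c.upper() for c in self.start_codons))

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = sorted(v) if isinstance(v, frozenset) else v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "start_codons" in d:
            d["start_codons"] = frozenset(d["start_codons"])
        return cls(**d)


@dataclass
class TranscriptModel:
    """A spliced, stranded transcript with exon blocks.

    ``exons`` are genomic intervals sorted by genomic start; ``annotated_cds``
    is the genomic span of the declared CDS (stop codon included) when the
    source annotation carries one.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    biotype: str  # MRNA | NCRNA
    source: str   # annotation source tag, e.g. "annotA"
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    annotated_cds: tuple[int, int] | None = None
    protein_id: str | None = None

    def __post_init__(self) -> None:
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id}: no exons")
        prev_end = -1
        for s, e in self.exons:
            if e <= s:
                raise ValidationError(f"transcript {self.transcript_id}: empty exon {s}-{e}")
            if s < prev_end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: overlapping exons")
            prev_end = e
        if self.strand not in "+-":
            raise ValidationError(f"transcript {self.transcript_id}: bad strand")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class GeneGroup:
    """A cross-annotation gene: the unit within which 'same gene' is decided."""

    group_id: str
    member_gene_ids: set[tuple[str, str]]  # (source, gene_id)
    contig_id: str
    strand: str
    span: tuple[int, int]


@dataclass
class PredictedORF:
    """An enumerated coding region, deduplicated across transcripts.

    Transcript coordinates (tx_start, tx_end, 0-based half-open) include the
    stop codon and refer to the representative transcript; genomic_blocks are
    sorted in genomic order and are the deduplication key together with
    contig and strand.
    """

    orf_id: str
    transcript_ids: set[str]
    gene_group_id: str
    frame: int
    tx_start: int
    tx_end: int
    genomic_blocks: tuple[tuple[int, int], ...]
    contig_id: str
    strand: str
    start_codon: str
    protein: str

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the first base of the start codon."""
        if self.strand == "+":
            return self.genomic_blocks[0][0]
        return self.genomic_blocks[-1][1]

    @property
    def three_prime(self) -> int:
        """Genomic coordinate just past the last base of the stop codon."""
        if self.strand == "+":
            return self.genomic_blocks[-1][1]
        return self.genomic_blocks[0][0]


@dataclass
class ProteinRecord:
    """A catalogued protein with its category and isoform annotation trail."""

    accession: str
    category: str  # REFPROT | NOVEL_ISOFORM | ALTPROT
    orf_id: str
    gene_group_id: str
    protein: str
    isoform_reasons: list[tuple[str, str]] = field(default_factory=list)
    orf: PredictedORF | None = None


@dataclass
class RefEntry:
    """One reference-protein entry (annotation-derived or external)."""

    accession: str
    protein: str
    gene_group_id: str | None  # None = unknown gene
    source: str                # annotA | annotB | external
    five_prime: int | None = None
    three_prime: int | None = None
    contig_id: str | None = None
    strand: str | None = None


@dataclass
class ReferenceProteinSet:
    entries: list[RefEntry]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            if e.accession in seen:
                raise ValidationError(f"duplicate reference accession {e.accession}")
            seen.add(e.accession)
        self.by_sequence: dict[str, list[RefEntry]] = {}
        self.by_gene: dict[str, list[RefEntry]] = {}
        for e in self.entries:
            self.by_sequence.setdefault(e.protein, []).append(e)
            if e.gene_group_id is not None:
                self.by_gene.setdefault(e.gene_group_id, []).append(e)


@dataclass
class IsoformEdge:
    """A within-gene related-protein call (direction that passed the filter)."""

    query_accession: str
    subject_accession: str
    raw_score: float
    bit_score: float
    query_coverage: float
    identity_fraction: float
    gene_group_id: str = ""


@dataclass
class PeptideObservation:
    sequence: str
    dataset_id: str
    psm_count: int

    def __post_init__(self) -> None:
        if self.psm_count < 1:
            raise ValidationError("psm_count must be >= 1")


@dataclass
class AssignmentResult:
    observed_sequence: str
    canonical_sequence: str
    assigned_accessions: set[str]
    rule_applied: str
    matched: bool = True


@dataclass
class DetectabilityStats:
    accession: str
    n_datasets: int
    n_unique_peptides: int
    n_psms: int
    possible_coverage: float
    detected_coverage: float
    ms_detectable: bool


@dataclass
class RiboORFCall:
    dataset_id: str
    transcript_id: str
    tx_start: int
    tx_end: int
    init_codon: str
    p_value: float
    matched: bool = True

    def __post_init__(self) -> None:
        if (self.tx_end - self.tx_start) % 3 != 0:
            raise ValidationError(
                f"ribo call on {self.transcript_id}: span not divisible by 3")
        if not 0 < self.p_value <= 1:
            raise ValidationError("p_value must be in (0, 1]")


@dataclass
class TranslationEvidence:
    orf_id: str
    dataset_id: str
    init_codon: str
    overlap_fraction: float
    p_value: float


@dataclass
class Catalog:
    """A complete catalog build: transcripts, gene groups, ORFs and proteins."""

    config: PipelineConfig
    contig_lengths: dict[str, int]
    transcripts: list[TranscriptModel]
    gene_groups: list[GeneGroup]
    orfs: list[PredictedORF]
    proteins: list[ProteinRecord]
    spliced_sequences: dict[str, str] = field(default_factory=dict)

    @property
    def gene_group_of(self) -> dict[tuple[str, str], str]:
        mapping = {}
        for g in self.gene_groups:
            for member in g.member_gene_ids:
                mapping[member] = g.group_id
        return mapping

    def protein_by_accession(self, accession: str) -> ProteinRecord:
        for p in self.proteins:
            if p.accession == accession:
                return p
        raise KeyError(accession)


@dataclass
class ChangeReport:
    """Release-to-release catalog diff."""

    transcripts_added: dict[tuple[str, str], int]            # (source, biotype) -> n
    transcripts_removed_or_changed: dict[tuple[str, str], int]
    refprots_added: int
    refprots_removed_or_changed: int
    reclassified: list[tuple[str, str, str]]  # (old_accession, old_category, new_category)

    @property
    def total_transcripts_added(self) -> int:
        return sum(self.transcripts_added.values())

    @property
    def total_transcripts_removed_or_changed(self) -> int:
        return sum(self.transcripts_removed_or_changed.values())
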