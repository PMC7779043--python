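"""Polycistronic ORF enumeration, translation, transcript-to-genome block
projection, and cross-transcript deduplication.

Every transcript (mRNA and ncRNA alike) is scanned in all three frames. Per
(frame, in-frame stop) at most one ORF is emitted, anchored at the 5'-most
configured start codon after the previous in-frame stop; ORFs without a stop
inside the transcript are dropped (their protein would be indeterminate).
The minimum length counts amino-acid codons excluding the stop.
"""

from __future__ import annotations

from Bio.Data import CodonTable

from .models import (
    CoordinateError, GeneGroup, PipelineConfig, PredictedORF,
    STOP_CODONS, TranscriptModel, ValidationError, logger,
)
from .annotation_io import spliced_sequence

_TABLE = CodonTable.unambiguous_dna_by_id[1].forward_table


def translate(cds: str) -> str:
    """Translate a CDS under the standard genetic code.

    The trailing stop codon (if present) is dropped; a codon containing N
    yields 'X'; an internal stop is a validation error.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValidationError(f"CDS length {len(cds)} not divisible by 3")
    aas = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i:3 * i + 3]
        if codon in STOP_CODONS:
            if i == n_codons - 1:
                break
            raise ValidationError(f"internal stop codon at nucleotide offset {3 * i}")
        if "N" in codon:
            aas.append("X")
        else:
            try:
                aas.append(_TABLE[codon])
            except KeyError as exc:
                raise ValidationError(f"unrecognized codon {codon!r}") from exc
    return "".join(aas)


def enumerate_orfs(seq: str, cfg: PipelineConfig) -> list[tuple[int, int, int, str]]:
    """Enumerate ORFs in all 3 frames of a spliced transcript sequence.

    Returns (frame, tx_start, tx_end, start_codon) tuples; tx_end includes
    the stop codon. Codons containing N never match a start or stop.
    """
    seq = seq.upper()
    if len(seq) < 3:
        return []
    hits = []
    for frame in range(3):
        open_start: int | None = None  # 5'-most start since last stop
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos:pos + 3]
            if "N" in codon:
                continue
            if codon in STOP_CODONS:
                if open_start is not None:
                    n_aa = (pos - open_start) // 3
                    if n_aa >= cfg.min_orf_codons:
                        hits.append((frame, open_start, pos + 3,
                                     seq[open_start:open_start + 3]))
                    open_start = None
            elif open_start is None and codon in cfg.start_codons:
                open_start = pos
    hits.sort(key=lambda h: (h[1], h[2], h[0]))
    return hits


def genomic_blocks(orf_span: tuple[int, int],
                   t: TranscriptModel) -> tuple[tuple[int, int], ...]:
    """Project a transcript-coordinate span through the exon structure.

    Blocks come back sorted in genomic order; on the '-' strand the first
    transcript base maps into the genomically-last exon.
    """
    tx_start, tx_end = orf_span
    if tx_start < 0 or tx_end > t.length or tx_start >= tx_end:
        raise CoordinateError(
            f"span {orf_span} outside transcript {t.transcript_id} "
            f"(length {t.length})")
    # exons in transcript order
    if t.strand == "+":
        tx_exons = t.exons
    else:
        tx_exons = list(reversed(t.exons))
    blocks = []
    offset = 0
    for gs, ge in tx_exons:
        exon_len = ge - gs
        lo = max(tx_start, offset)
        hi = min(tx_end, offset + exon_len)
        if lo < hi:
            if t.strand == "+":
                blocks.append((gs + (lo - offset), gs + (hi - offset)))
            else:
                blocks.append((ge - (hi - offset), ge - (lo - offset)))
        offset += exon_len
    blocks.sort()
    assert sum(e - s for s, e in blocks) == tx_end - tx_start
    return tuple(blocks)


def orf_identifier(contig: str, strand: str,
                   blocks: tuple[tuple[int, int], ...]) -> str:
    return f"{contig}:{strand}:" + "|".join(f"{s}-{e}" for s, e in blocks)


def deduplicate(per_transcript_orfs: list[PredictedORF]) -> list[PredictedORF]:
    """Merge ORFs with identical (contig, strand, genomic blocks).

    The key is coordinates, not protein sequence: one protein at two loci
    stays two ORFs; one CDS shared by transcripts of both annotations merges.
    """
    merged: dict[tuple, PredictedORF] = {}
    for orf in per_transcript_orfs:
        key = (orf.contig_id, orf.strand, orf.genomic_blocks)
        if key in merged:
            kept = merged[key]
            kept.transcript_ids |= orf.transcript_ids
            if kept.gene_group_id != orf.gene_group_id:
                logger.warning("ORF %s supported by transcripts of distinct gene "
                               "groups %s/%s; keeping %s", kept.orf_id,
                               kept.gene_group_id, orf.gene_group_id,
                               kept.gene_group_id)
        else:
            merged[key] = orf
    out = sorted(merged.values(), key=lambda o: (
        o.contig_id, o.genomic_blocks[0][0], o.genomic_blocks[-1][1],
        o.strand, o.genomic_blocks))
    return out


def predict_orfs(transcripts: list[TranscriptModel], genome: dict[str, str],
                 gene_groups: list[GeneGroup], cfg: PipelineConfig,
                 spliced_cache: dict[str, str] | None = None) -> list[PredictedORF]:
    """Run enumeration over every transcript and deduplicate genome-wide."""
    group_of = {}
    for g in gene_groups:
        for member in g.member_gene_ids:
            group_of[member] = g.group_id
    raw: list[PredictedORF] = []
    for t in transcripts:
        seq = spliced_sequence(t, genome)
        if spliced_cache is not None:
            spliced_cache[t.transcript_id] = seq
        for frame, tx_start, tx_end, start_codon in enumerate_orfs(seq, cfg):
            blocks = genomic_blocks((tx_start, tx_end), t)
            raw.append(PredictedORF(
                orf_id=orf_identifier(t.contig_id, t.strand, blocks),
                transcript_ids={t.transcript_id},
                gene_group_id=group_of[(t.source, t.gene_id)],
                frame=frame,
                tx_start=tx_start,
                tx_end=tx_end,
                genomic_blocks=blocks,
                contig_id=t.contig_id,
                strand=t.strand,
                start_codon=start_codon,
                protein=translate(seq[tx_start:tx_end]),
            ))
    return deduplicate(raw)
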