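"""Reference-protein merging, protein categorization and catalog diffing.

Categories: RefProt (exact sequence already annotated), NovelIsoform (II_;
shares a genomic CDS start and/or end coordinate with a same-gene RefProt and
aligns with identical positions over 20% of its own length) and AltProt (IP_;
everything else, including every protein on a gene with no RefProt, e.g.
ncRNA-only loci). RefProt matching is exact and I/L-sensitive; the I/L
collapse applies only to peptide unicity.
"""

from __future__ import annotations

import csv
import os

from Bio import SeqIO

from .models import (
    ALTPROT, Catalog, ChangeReport, GeneGroup, IDENTITY_OVER_THRESHOLD,
    NOVEL_ISOFORM, PipelineConfig, PredictedORF, ProteinRecord, REFPROT,
    RefEntry, ReferenceProteinSet, SHARED_END, SHARED_START, TranscriptModel,
    ValidationError, logger, STOP_CODONS,
)
from .annotation_io import spliced_sequence
from .orf_prediction import genomic_blocks, translate
from .isoform_graph import local_align


# ---------------------------------------------------------------------------
# reference proteins from annotations

def _genomic_to_tx_span(t: TranscriptModel, span: tuple[int, int]) -> tuple[int, int]:
    """Transcript-coordinate interval covered by a genomic interval."""
    gs, ge = span
    lo, hi = None, None
    offset = 0
    exons = t.exons if t.strand == "+" else list(reversed(t.exons))
    for es, ee in exons:
        a, b = max(es, gs), min(ee, ge)
        if a < b:
            if t.strand == "+":
                tx_a, tx_b = offset + (a - es), offset + (b - es)
            else:
                tx_a, tx_b = offset + (ee - b), offset + (ee - a)
            lo = tx_a if lo is None else min(lo, tx_a)
            hi = tx_b if hi is None else max(hi, tx_b)
        offset += ee - es
    if lo is None:
        raise ValidationError(
            f"annotated CDS {span} of {t.transcript_id} overlaps no exon")
    return lo, hi


def annotation_reference_entries(transcripts: list[TranscriptModel],
                                 genome: dict[str, str],
                                 gene_groups: list[GeneGroup]) -> list[RefEntry]:
    """Translate every annotated CDS into a RefEntry with genomic boundaries.

    Stop-exclusive CDS annotations are normalized by extending 3 nt when the
    next in-frame codon is a stop, so boundary coordinates are comparable
    with predicted ORFs (which include their stop codon).
    """
    group_of = {}
    for g in gene_groups:
        for member in g.member_gene_ids:
            group_of[member] = g.group_id
    entries = []
    used_accessions: set[str] = set()
    for t in transcripts:
        if t.annotated_cds is None:
            continue
        seq = spliced_sequence(t, genome)
        tx_lo, tx_hi = _genomic_to_tx_span(t, t.annotated_cds)
        if (tx_hi - tx_lo) % 3 != 0:
            logger.warning("CDS of %s has length not divisible by 3; skipped",
                           t.transcript_id)
            continue
        if seq[tx_hi - 3:tx_hi] not in STOP_CODONS and seq[tx_hi:tx_hi + 3] in STOP_CODONS:
            tx_hi += 3  # stop-exclusive annotation style
        try:
            protein = translate(seq[tx_lo:tx_hi])
        except ValidationError as exc:
            logger.warning("CDS of %s does not translate (%s); skipped",
                           t.transcript_id, exc)
            continue
        if not protein:
            continue
        blocks = genomic_blocks((tx_lo, tx_hi), t)
        accession = t.protein_id or f"REF_{t.transcript_id}"
        if accession in used_accessions:
            accession = f"{accession}|{t.source}:{t.transcript_id}"
        used_accessions.add(accession)
        five = blocks[0][0] if t.strand == "+" else blocks[-1][1]
        three = blocks[-1][1] if t.strand == "+" else blocks[0][0]
        entries.append(RefEntry(
            accession=accession, protein=protein,
            gene_group_id=group_of[(t.source, t.gene_id)], source=t.source,
            five_prime=five, three_prime=three,
            contig_id=t.contig_id, strand=t.strand,
        ))
    return entries


def read_gene_xref(path: str | os.PathLike) -> dict[str, str]:
    """Accession -> gene name table (TSV: accession, gene_name)."""
    xref = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if i == 0 and parts[0].lower() in ("accession", "acc"):
                continue
            if len(parts) < 2 or not parts[0] or not parts[1]:
                logger.warning("xref row %d malformed; skipped", i + 1)
                continue
            xref[parts[0]] = parts[1]
    return xref


def build_reference_set(annot_entries: list[RefEntry],
                        external_fasta: str | os.PathLike | None = None,
                        gene_xref: str | os.PathLike | None = None,
                        name_to_group: dict[str, str] | None = None) -> ReferenceProteinSet:
    """Merge annotation-derived reference proteins with an external
    (UniProt-like) protein FASTA.

    External entries are mapped to gene groups via the cross-reference table
    when possible; failing that, an exact sequence match to an annotation
    protein lets the entry inherit that gene group; otherwise the entry is
    kept with gene unknown (it still blocks novelty through sequence
    identity, but cannot support same-gene isoform calls). Duplicate
    sequences across sources stay distinct accessions.
    """
    entries = list(annot_entries)
    by_seq = {}
    for e in annot_entries:
        by_seq.setdefault(e.protein, e)
    xref = read_gene_xref(gene_xref) if gene_xref else {}
    name_to_group = {k.lower(): v for k, v in (name_to_group or {}).items()}
    if external_fasta:
        for rec in SeqIO.parse(str(external_fasta), "fasta"):
            protein = str(rec.seq)
            gene_group = None
            if rec.id in xref:
                gene_group = name_to_group.get(xref[rec.id].lower())
                if gene_group is None:
                    logger.warning("xref gene %r for %s matches no gene group",
                                   xref[rec.id], rec.id)
            if gene_group is None and protein in by_seq:
                gene_group = by_seq[protein].gene_group_id
            if gene_group is None:
                logger.warning("external reference %s has unknown gene", rec.id)
            entries.append(RefEntry(accession=rec.id, protein=protein,
                                    gene_group_id=gene_group, source="external"))
    return ReferenceProteinSet(entries)


# ---------------------------------------------------------------------------
# categorization

def categorize(p: PredictedORF, refs: ReferenceProteinSet, cfg: PipelineConfig,
               aligner=local_align) -> tuple[str, list[tuple[str, str]], str | None]:
    """Category plus isoform reasons for one predicted protein.

    Returns (category, isoform_reasons, matched_ref_accession). The isoform
    rule requires a same-gene RefProt sharing the genomic CDS start and/or
    end coordinate AND identical aligned positions over the identity
    threshold times the candidate length.
    """
    exact = refs.by_sequence.get(p.protein)
    if exact:
        accession = sorted(e.accession for e in exact)[0]
        return REFPROT, [], accession
    reasons: list[tuple[str, str]] = []
    min_identical = cfg.isoform_identity_threshold * len(p.protein)
    for e in refs.by_gene.get(p.gene_group_id, []):
        if e.five_prime is None or e.contig_id != p.contig_id or e.strand != p.strand:
            continue
        shared = []
        if e.five_prime == p.five_prime:
            shared.append(SHARED_START)
        if e.three_prime == p.three_prime:
            shared.append(SHARED_END)
        if not shared:
            continue
        _, identical, _ = aligner(p.protein, e.protein)
        if identical > min_identical:
            for s in shared:
                reasons.append((e.accession, s))
            reasons.append((e.accession, IDENTITY_OVER_THRESHOLD))
    if reasons:
        return NOVEL_ISOFORM, reasons, None
    return ALTPROT, [], None


def assign_accessions(categorized: list[tuple[PredictedORF, str,
                                              list[tuple[str, str]], str | None]]
                      ) -> list[ProteinRecord]:
    """Deterministic accessions: RefProts keep their source accession; novel
    proteins are numbered sequentially within their prefix after sorting by
    (contig, genomic start, end, strand, protein)."""
    def sort_key(item):
        orf = item[0]
        return (orf.contig_id, orf.genomic_blocks[0][0],
                orf.genomic_blocks[-1][1], orf.strand, orf.protein)

    records = []
    counters = {NOVEL_ISOFORM: 0, ALTPROT: 0}
    prefixes = {NOVEL_ISOFORM: "II_", ALTPROT: "IP_"}
    used: set[str] = set()
    for orf, category, reasons, ref_acc in sorted(categorized, key=sort_key):
        if category == REFPROT:
            accession = ref_acc
            n = 2
            while accession in used:
                accession = f"{ref_acc}.{n}"
                n += 1
        else:
            counters[category] += 1
            accession = f"{prefixes[category]}{counters[category]}"
        used.add(accession)
        records.append(ProteinRecord(
            accession=accession, category=category, orf_id=orf.orf_id,
            gene_group_id=orf.gene_group_id, protein=orf.protein,
            isoform_reasons=reasons, orf=orf,
        ))
    return records


def categorize_catalog(orfs: list[PredictedORF], refs: ReferenceProteinSet,
                       cfg: PipelineConfig) -> list[ProteinRecord]:
    categorized = [(orf, *categorize(orf, refs, cfg)) for orf in orfs]
    return assign_accessions(categorized)


# ---------------------------------------------------------------------------
# catalog diffing

def diff_catalogs(old: Catalog, new: Catalog) -> ChangeReport:
    """Release-to-release comparison of two catalog builds.

    Transcripts match by (source, transcript_id); an id present in both with
    a different spliced sequence counts as removed_or_changed. A novel
    protein of the old build whose exact sequence is a RefProt in the new
    build is reported as reclassified.
    """
    if set(old.contig_lengths) != set(new.contig_lengths):
        raise ValidationError("catalogs come from different genome builds "
                              "(contig sets differ)")

    def tx_map(cat: Catalog):
        return {(t.source, t.transcript_id):
                (t, cat.spliced_sequences.get(t.transcript_id, "")) for t in cat.transcripts}

    old_tx, new_tx = tx_map(old), tx_map(new)
    added: dict[tuple[str, str], int] = {}
    removed: dict[tuple[str, str], int] = {}
    for key, (t, _) in new_tx.items():
        if key not in old_tx:
            k = (t.source, t.biotype)
            added[k] = added.get(k, 0) + 1
    for key, (t, seq) in old_tx.items():
        if key not in new_tx or new_tx[key][1] != seq:
            k = (t.source, t.biotype)
            removed[k] = removed.get(k, 0) + 1

    old_ref = {p.accession: p.protein for p in old.proteins if p.category == REFPROT}
    new_ref = {p.accession: p.protein for p in new.proteins if p.category == REFPROT}
    refprots_added = sum(1 for a in new_ref if a not in old_ref)
    refprots_removed = sum(1 for a, s in old_ref.items()
                           if a not in new_ref or new_ref[a] != s)

    new_ref_seqs = set(new_ref.values())
    reclassified = [(p.accession, p.category, REFPROT)
                    for p in old.proteins
                    if p.category != REFPROT and p.protein in new_ref_seqs]

    return ChangeReport(
        transcripts_added=added,
        transcripts_removed_or_changed=removed,
        refprots_added=refprots_added,
        refprots_removed_or_changed=refprots_removed,
        reclassified=sorted(reclassified),
    )


def write_change_report(report: ChangeReport, path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["metric", "source", "biotype", "count"])
        for (source, biotype), n in sorted(report.transcripts_added.items()):
            w.writerow(["transcripts_added", source, biotype, n])
        for (source, biotype), n in sorted(report.transcripts_removed_or_changed.items()):
            w.writerow(["transcripts_removed_or_changed", source, biotype, n])
        w.writerow(["refprots_added", "", "", report.refprots_added])
        w.writerow(["refprots_removed_or_changed", "", "",
                    report.refprots_removed_or_changed])
        for old_acc, old_cat, new_cat in report.reclassified:
            w.writerow(["reclassified", old_acc, old_cat, new_cat])


# ---------------------------------------------------------------------------
# catalog build driver

def build_catalog(genome: dict[str, str], transcripts: list[TranscriptModel],
                  cfg: PipelineConfig | None = None,
                  external_fasta: str | os.PathLike | None = None,
                  gene_xref: str | os.PathLike | None = None) -> Catalog:
    """Full prediction + categorization: transcripts in, protein catalog out."""
    from .annotation_io import reconcile_genes
    from .orf_prediction import predict_orfs

    cfg = cfg or PipelineConfig()
    gene_groups = reconcile_genes(transcripts)
    spliced: dict[str, str] = {}
    orfs = predict_orfs(transcripts, genome, gene_groups, cfg, spliced_cache=spliced)
    annot_entries = annotation_reference_entries(transcripts, genome, gene_groups)
    name_to_group = {}
    group_of = {}
    for g in gene_groups:
        for member in g.member_gene_ids:
            group_of[member] = g.group_id
    for t in transcripts:
        if t.gene_name:
            name_to_group.setdefault(t.gene_name.lower(),
                                     group_of[(t.source, t.gene_id)])
    refs = build_reference_set(annot_entries, external_fasta, gene_xref,
                               name_to_group)
    proteins = categorize_catalog(orfs, refs, cfg)
    return Catalog(
        config=cfg,
        contig_lengths={c: len(s) for c, s in genome.items()},
        transcripts=transcripts,
        gene_groups=gene_groups,
        orfs=orfs,
        proteins=proteins,
        spliced_sequences=spliced,
    )
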