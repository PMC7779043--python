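"""Genome/annotation ingestion, spliced-sequence extraction, gene
reconciliation across two annotation sources, and catalog export.

GTF and GFF3 dialects are auto-detected per file (column-9 syntax) via
gffutils; FASTA goes through Bio.SeqIO. All coordinates are converted to
0-based half-open at this boundary and never touched again.
"""

from __future__ import annotations

import csv
import json
import os
from pathlib import Path

import gffutils.iterators
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    MRNA, NCRNA, Catalog, CoordinateError, GeneGroup, InputError, PipelineConfig,
    PredictedORF, ProteinRecord, TranscriptModel, ValidationError, logger,
)

_VALID_DNA = set("ACGTN")
_TRANSCRIPT_TYPES = {
    "transcript", "mRNA", "ncRNA", "lnc_RNA", "lincRNA", "miRNA", "snoRNA",
    "snRNA", "rRNA", "tRNA", "pseudogenic_transcript",
}


# ---------------------------------------------------------------------------
# genome

def read_genome(path: str | os.PathLike) -> dict[str, str]:
    """Load a genome FASTA into {contig_id: uppercase DNA}.

    Characters outside {A,C,G,T,N} are masked to N with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"genome FASTA not found: {path}")
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise InputError(f"empty sequence for contig {rec.id} in {path}")
        if set(seq) - _VALID_DNA:
            n_masked = sum(c not in _VALID_DNA for c in seq)
            logger.warning("contig %s: masked %d non-ACGTN characters to N",
                           rec.id, n_masked)
            seq = "".join(c if c in _VALID_DNA else "N" for c in seq)
        genome[rec.id] = seq
    if not genome:
        raise InputError(f"no FASTA records in {path}")
    return genome


def write_genome(genome: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=c, description="") for c, s in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# annotations

def _first(attrs, *keys) -> str | None:
    for k in keys:
        if k in attrs and attrs[k]:
            return attrs[k][0]
    return None


def read_annotation(path: str | os.PathLike, source_tag: str) -> list[TranscriptModel]:
    """Parse a GTF or GFF3 file into TranscriptModels.

    A transcript is mRNA iff it has a CDS feature or a protein_coding biotype
    attribute, else ncRNA. The declared CDS span (stop codon included when the
    annotation is stop-inclusive; normalized later otherwise) is kept as a
    genomic interval.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation not found: {path}")

    tx_meta: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []

    def meta_for(tid: str) -> dict:
        if tid not in tx_meta:
            tx_meta[tid] = {}
            order.append(tid)
        return tx_meta[tid]

    for f in gffutils.iterators.DataIterator(str(path)):
        ftype = f.featuretype
        attrs = f.attributes
        start, end = f.start - 1, f.end  # 1-based inclusive -> 0-based half-open
        if ftype in _TRANSCRIPT_TYPES:
            tid = _first(attrs, "transcript_id", "ID")
            if tid is None:
                logger.warning("%s: transcript feature without id skipped", path.name)
                continue
            m = meta_for(tid)
            m.setdefault("gene_id", _first(attrs, "gene_id", "Parent") or tid)
            m.setdefault("gene_name", _first(attrs, "gene_name", "gene", "Name") or "")
            m.setdefault("contig", f.seqid)
            m.setdefault("strand", f.strand)
            if m.get("protein_id") is None:
                m["protein_id"] = _first(attrs, "protein_id")
            bio = _first(attrs, "transcript_biotype", "biotype", "gene_biotype")
            if bio is not None:
                m.setdefault("biotype_attr", bio)
            if ftype == "mRNA":
                m.setdefault("biotype_attr", "protein_coding")
        elif ftype in ("exon", "CDS", "stop_codon"):
            tid = _first(attrs, "transcript_id", "Parent")
            if tid is None:
                logger.warning("%s: %s feature without transcript id skipped",
                               path.name, ftype)
                continue
            m = meta_for(tid)
            m.setdefault("gene_id", _first(attrs, "gene_id") or "")
            m.setdefault("gene_name", _first(attrs, "gene_name", "gene") or "")
            m.setdefault("contig", f.seqid)
            m.setdefault("strand", f.strand)
            if ftype == "exon":
                exons.setdefault(tid, []).append((start, end))
            else:
                if ftype == "CDS" and m.get("protein_id") is None:
                    m["protein_id"] = _first(attrs, "protein_id")
                cds.setdefault(tid, []).append((start, end))

    transcripts = []
    for tid in order:
        m = tx_meta[tid]
        ex = sorted(exons.get(tid, []))
        if not ex:
            logger.warning("%s: transcript %s has no exons, skipped", path.name, tid)
            continue
        for (s1, e1), (s2, _) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"{path.name}: transcript {tid} has overlapping exons")
        annotated_cds = None
        if tid in cds:
            blocks = cds[tid]
            annotated_cds = (min(s for s, _ in blocks), max(e for _, e in blocks))
        biotype = MRNA if (tid in cds or m.get("biotype_attr") == "protein_coding") else NCRNA
        transcripts.append(TranscriptModel(
            transcript_id=tid,
            gene_id=m.get("gene_id") or tid,
            gene_name=m.get("gene_name", ""),
            biotype=biotype,
            source=source_tag,
            contig_id=m["contig"],
            strand=m["strand"],
            exons=ex,
            annotated_cds=annotated_cds,
            protein_id=m.get("protein_id"),
        ))
    return transcripts


# ---------------------------------------------------------------------------
# spliced sequence

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def spliced_sequence(t: TranscriptModel, genome: dict[str, str]) -> str:
    """Concatenate exon sequences in genomic order; reverse-complement the
    whole for '-' strand transcripts."""
    if t.contig_id not in genome:
        raise CoordinateError(f"transcript {t.transcript_id}: unknown contig {t.contig_id}")
    contig = genome[t.contig_id]
    for s, e in t.exons:
        if s < 0 or e > len(contig):
            raise CoordinateError(
                f"transcript {t.transcript_id}: exon {s}-{e} outside contig "
                f"{t.contig_id} (length {len(contig)})")
    seq = "".join(contig[s:e] for s, e in t.exons)
    if t.strand == "-":
        seq = reverse_complement(seq)
    return seq


# ---------------------------------------------------------------------------
# gene reconciliation

def reconcile_genes(transcripts_a: list[TranscriptModel],
                    transcripts_b: list[TranscriptModel] | None = None) -> list[GeneGroup]:
    """Merge genes across annotation sources into GeneGroups.

    Two genes join one group when they sit on the same contig and strand and
    either their genomic spans overlap by >= 1 bp or their gene names match
    case-insensitively. Group ids are deterministic, ordered by locus.
    """
    transcripts = list(transcripts_a) + list(transcripts_b or [])
    genes: dict[tuple[str, str], dict] = {}
    for t in transcripts:
        key = (t.source, t.gene_id)
        g = genes.setdefault(key, {
            "contig": t.contig_id, "strand": t.strand,
            "start": t.span[0], "end": t.span[1],
            "names": set(),
        })
        if g["contig"] != t.contig_id or g["strand"] != t.strand:
            raise ValidationError(
                f"gene {t.gene_id} ({t.source}) spans multiple contigs/strands")
        g["start"] = min(g["start"], t.span[0])
        g["end"] = max(g["end"], t.span[1])
        if t.gene_name:
            g["names"].add(t.gene_name.lower())

    keys = sorted(genes, key=lambda k: (genes[k]["contig"], genes[k]["strand"],
                                        genes[k]["start"], genes[k]["end"], k))
    parent = {k: k for k in keys}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    # sweep per (contig, strand) for span overlap; name index for name matches
    by_locus: dict[tuple[str, str], list] = {}
    by_name: dict[str, list] = {}
    for k in keys:
        g = genes[k]
        by_locus.setdefault((g["contig"], g["strand"]), []).append(k)
        for name in g["names"]:
            by_name.setdefault((g["contig"], g["strand"], name), []).append(k)

    for ks in by_locus.values():
        ks = sorted(ks, key=lambda k: genes[k]["start"])
        active: list = []
        for k in ks:
            g = genes[k]
            active = [a for a in active if genes[a]["end"] > g["start"]]
            for a in active:
                union(a, k)
            active.append(k)
    for ks in by_name.values():
        for other in ks[1:]:
            union(ks[0], other)

    clusters: dict[tuple[str, str], list] = {}
    for k in keys:
        clusters.setdefault(find(k), []).append(k)

    groups = []
    ordered = sorted(clusters.values(), key=lambda ms: (
        genes[ms[0]]["contig"],
        min(genes[m]["start"] for m in ms),
        max(genes[m]["end"] for m in ms),
        genes[ms[0]]["strand"],
    ))
    for i, members in enumerate(ordered, start=1):
        g0 = genes[members[0]]
        groups.append(GeneGroup(
            group_id=f"GG{i:05d}",
            member_gene_ids=set(members),
            contig_id=g0["contig"],
            strand=g0["strand"],
            span=(min(genes[m]["start"] for m in members),
                  max(genes[m]["end"] for m in members)),
        ))
    return groups


# ---------------------------------------------------------------------------
# catalog export / import

_TSV_COLUMNS = [
    "accession", "category", "orf_id", "gene_group_id", "contig", "strand",
    "tx_start", "tx_end", "blocks", "start_codon", "transcript_ids",
    "isoform_reasons", "protein",
]


def _blocks_str(blocks) -> str:
    return ",".join(f"{s}-{e}" for s, e in blocks)


def _parse_blocks(text: str) -> tuple[tuple[int, int], ...]:
    return tuple(tuple(int(x) for x in b.split("-")) for b in text.split(",")) if text else ()


def write_bed12(orfs: list[PredictedORF], path: str | os.PathLike,
                names: dict[str, str] | None = None) -> None:
    """One BED12 row per unique ORF; blocks become blockSizes/blockStarts."""
    with open(path, "w") as fh:
        for orf in orfs:
            chrom_start = orf.genomic_blocks[0][0]
            chrom_end = orf.genomic_blocks[-1][1]
            sizes = [e - s for s, e in orf.genomic_blocks]
            starts = [s - chrom_start for s, _ in orf.genomic_blocks]
            name = (names or {}).get(orf.orf_id, orf.orf_id)
            fh.write("\t".join(map(str, [
                orf.contig_id, chrom_start, chrom_end, name, 0, orf.strand,
                chrom_start, chrom_end, "0,0,0", len(sizes),
                ",".join(map(str, sizes)) + ",",
                ",".join(map(str, starts)) + ",",
            ])) + "\n")


def read_bed12(path: str | os.PathLike) -> list[dict]:
    """Read BED12 rows back into block structures (round-trip check support)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom_start = int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = tuple((chrom_start + st, chrom_start + st + sz)
                           for st, sz in zip(starts, sizes))
            rows.append({"contig": f[0], "start": chrom_start, "end": int(f[2]),
                         "name": f[3], "strand": f[5], "blocks": blocks})
    return rows


def write_protein_fasta(proteins: list[ProteinRecord], path: str | os.PathLike) -> None:
    records = []
    for p in proteins:
        desc = f"gene_group={p.gene_group_id} category={p.category} orf={p.orf_id}"
        records.append(SeqRecord(Seq(p.protein), id=p.accession, description=desc))
    SeqIO.write(records, str(path), "fasta")


def write_catalog_tsv(proteins: list[ProteinRecord], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TSV_COLUMNS)
        for p in proteins:
            orf = p.orf
            w.writerow([
                p.accession, p.category, p.orf_id, p.gene_group_id,
                orf.contig_id if orf else "", orf.strand if orf else "",
                orf.tx_start if orf else "", orf.tx_end if orf else "",
                _blocks_str(orf.genomic_blocks) if orf else "",
                orf.start_codon if orf else "",
                ";".join(sorted(orf.transcript_ids)) if orf else "",
                ";".join(f"{acc}:{reason}" for acc, reason in p.isoform_reasons),
                p.protein,
            ])


def write_orf_gff3(orfs: list[PredictedORF], path: str | os.PathLike,
                   names: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for orf in orfs:
            name = (names or {}).get(orf.orf_id, orf.orf_id)
            s, e = orf.genomic_blocks[0][0], orf.genomic_blocks[-1][1]
            fh.write(f"{orf.contig_id}\tpolyorf\tORF\t{s + 1}\t{e}\t.\t"
                     f"{orf.strand}\t.\tID={name}\n")
            for bs, be in orf.genomic_blocks:
                fh.write(f"{orf.contig_id}\tpolyorf\tCDS\t{bs + 1}\t{be}\t.\t"
                         f"{orf.strand}\t0\tParent={name}\n")


def export_catalog(catalog: Catalog, fmt: str, path: str | os.PathLike) -> None:
    """Write the catalog in one of: fasta (proteins), bed (BED12), gff3, tsv."""
    names = {p.orf_id: p.accession for p in catalog.proteins}
    try:
        if fmt == "fasta":
            write_protein_fasta(catalog.proteins, path)
        elif fmt == "bed":
            write_bed12(catalog.orfs, path, names)
        elif fmt == "gff3":
            write_orf_gff3(catalog.orfs, path, names)
        elif fmt == "tsv":
            write_catalog_tsv(catalog.proteins, path)
        else:
            raise ValidationError(f"unknown export format: {fmt}")
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc


# full catalog directory persistence ----------------------------------------

def save_catalog(catalog: Catalog, outdir: str | os.PathLike) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    export_catalog(catalog, "tsv", outdir / "proteins.tsv")
    export_catalog(catalog, "fasta", outdir / "proteins.fasta")
    export_catalog(catalog, "bed", outdir / "orfs.bed")
    export_catalog(catalog, "gff3", outdir / "orfs.gff3")
    with open(outdir / "transcripts.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["source", "transcript_id", "gene_id", "gene_name", "biotype",
                    "contig", "strand", "exons", "annotated_cds", "spliced_sequence"])
        for t in catalog.transcripts:
            w.writerow([
                t.source, t.transcript_id, t.gene_id, t.gene_name, t.biotype,
                t.contig_id, t.strand, _blocks_str(t.exons),
                f"{t.annotated_cds[0]}-{t.annotated_cds[1]}" if t.annotated_cds else "",
                catalog.spliced_sequences.get(t.transcript_id, ""),
            ])
    with open(outdir / "gene_groups.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["group_id", "contig", "strand", "start", "end", "members"])
        for g in catalog.gene_groups:
            w.writerow([g.group_id, g.contig_id, g.strand, g.span[0], g.span[1],
                        ";".join(f"{s}:{gid}" for s, gid in sorted(g.member_gene_ids))])
    with open(outdir / "catalog.json", "w") as fh:
        json.dump({"config": catalog.config.to_dict(),
                   "contig_lengths": catalog.contig_lengths}, fh, indent=1)


def load_catalog(indir: str | os.PathLike) -> Catalog:
    indir = Path(indir)
    with open(indir / "catalog.json") as fh:
        meta = json.load(fh)
    config = PipelineConfig.from_dict(meta["config"])

    transcripts, spliced = [], {}
    with open(indir / "transcripts.tsv", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            cds = row["annotated_cds"]
            transcripts.append(TranscriptModel(
                transcript_id=row["transcript_id"], gene_id=row["gene_id"],
                gene_name=row["gene_name"], biotype=row["biotype"],
                source=row["source"], contig_id=row["contig"], strand=row["strand"],
                exons=list(_parse_blocks(row["exons"])),
                annotated_cds=tuple(int(x) for x in cds.split("-")) if cds else None,
            ))
            spliced[row["transcript_id"]] = row["spliced_sequence"]

    groups = []
    with open(indir / "gene_groups.tsv", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            members = {tuple(m.split(":", 1)) for m in row["members"].split(";") if m}
            groups.append(GeneGroup(row["group_id"], members, row["contig"],
                                    row["strand"], (int(row["start"]), int(row["end"]))))

    proteins, orfs, seen_orfs = [], [], set()
    with open(indir / "proteins.tsv", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            orf = None
            if row["orf_id"]:
                orf = PredictedORF(
                    orf_id=row["orf_id"],
                    transcript_ids=set(row["transcript_ids"].split(";")) if row["transcript_ids"] else set(),
                    gene_group_id=row["gene_group_id"], frame=0,
                    tx_start=int(row["tx_start"]), tx_end=int(row["tx_end"]),
                    genomic_blocks=_parse_blocks(row["blocks"]),
                    contig_id=row["contig"], strand=row["strand"],
                    start_codon=row["start_codon"], protein=row["protein"],
                )
                if orf.orf_id not in seen_orfs:
                    seen_orfs.add(orf.orf_id)
                    orfs.append(orf)
            reasons = [tuple(r.rsplit(":", 1)) for r in row["isoform_reasons"].split(";") if r]
            proteins.append(ProteinRecord(
                accession=row["accession"], category=row["category"],
                orf_id=row["orf_id"], gene_group_id=row["gene_group_id"],
                protein=row["protein"], isoform_reasons=reasons, orf=orf,
            ))
    return Catalog(config=config, contig_lengths=meta["contig_lengths"],
                   transcripts=transcripts, gene_groups=groups, orfs=orfs,
                   proteins=proteins, spliced_sequences=spliced)
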