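"""Seeded synthetic inputs with a machine-readable ground-truth manifest.

One call to :func:`generate_fixture` writes a miniature but complete input
world: a two-contig genome FASTA, a GTF annotation ("annotA", RefSeq-flavor)
and a GFF3 annotation ("annotB", Ensembl-flavor), an external reference
protein FASTA with a gene cross-reference table, a peptide observation TSV
and a ribo-seq ORF-call TSV, plus ``manifest.json`` recording every planted
truth. The scenarios cover every decision point of the pipeline:

* AUG ORFs at 30 codons (kept) and 29 codons (dropped), and a start with no
  in-frame stop (decoy, never emitted);
* a polycistronic mRNA carrying an annotated 100-codon CDS plus an
  overlapping out-of-frame 32-codon altORF, duplicated in both annotations
  (deduplication + cross-annotation gene pairing);
* isoform candidates sharing the reference CDS stop coordinate with
  sequence identity above (novel isoform) and below (altProt) the 20% rule;
* same-gene and cross-gene shared tryptic peptides, and an I/L isobar pair
  mirroring a pseudogene peptide that re-assigns to the parental-gene
  RefProt;
* an antisense mRNA overlapping an ncRNA gene (strand-aware grouping);
* ribo-seq calls sharing the 100-codon ORF's stop at overlaps 0.50-0.95.

Construction is validated by seeded rejection sampling: random filler that
happens to create unplanned >= 30 codon ORFs, or planted identities that
land on the wrong side of a threshold, trigger a deterministic re-draw. The
manifest truths themselves are fixed by construction, not measured.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Data import CodonTable

from .models import MRNA, NCRNA, REFPROT, NOVEL_ISOFORM, ALTPROT, STOP_CODONS, ValidationError
from .annotation_io import reverse_complement
from .isoform_graph import bit_score, local_align
from .ms_evidence import collapse_il, digest

_TABLE = CodonTable.unambiguous_dna_by_id[1].forward_table
_AA_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_TABLE.items()):
    _AA_CODONS.setdefault(_aa, []).append(_codon)
_NONSTOP_CODONS = sorted(set(_TABLE) - STOP_CODONS)

_PEP_ALPHABET = "ACDEFGHMNQSTVWY"  # no K/R/P (cleavage), no I/L (isobars)
_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FixtureSpec:
    """Knobs for fixture size and content."""

    core_scenarios: bool = True
    n_extra_nc_genes: int = 0       # additional single-ORF ncRNA genes (AltProts)
    intergenic: int = 150           # bp of filler between gene loci
    max_attempts: int = 40

    def __post_init__(self) -> None:
        if self.n_extra_nc_genes < 0 or self.intergenic < 0:
            raise ValidationError("fixture spec counts must be non-negative")


# ---------------------------------------------------------------------------
# small construction helpers

def _rand_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _rand_aa(rng: random.Random, n: int, first_not_p: bool = False) -> str:
    out = [rng.choice(_AA_ALPHABET) for _ in range(n)]
    if first_not_p and out and out[0] == "P":
        out[0] = "A"
    return "".join(out)


def _rand_peptide(rng: random.Random, n: int = 10) -> str:
    return "".join(rng.choice(_PEP_ALPHABET) for _ in range(n - 1)) + "K"


def _revtrans(rng: random.Random, protein: str) -> str:
    return "".join(rng.choice(_AA_CODONS[aa]) for aa in protein)


def _stop(rng: random.Random) -> str:
    return rng.choice(sorted(STOP_CODONS))


def _scan_orfs(seq: str, min_codons: int = 30) -> set[tuple[int, int]]:
    """Independent minimal ORF scanner used only to vet construction."""
    found = set()
    for frame in range(3):
        open_start = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos:pos + 3]
            if codon in STOP_CODONS:
                if open_start is not None and (pos - open_start) // 3 >= min_codons:
                    found.add((open_start, pos + 3))
                open_start = None
            elif open_start is None and codon == "ATG":
                open_start = pos
    return found


def _splice(dna: str, exons: list[tuple[int, int]], strand: str) -> str:
    seq = "".join(dna[s:e] for s, e in sorted(exons))
    return reverse_complement(seq) if strand == "-" else seq


@dataclass
class _Locus:
    name: str
    dna: str
    transcripts: list[dict] = field(default_factory=list)   # rel coords
    planted: list[dict] = field(default_factory=list)       # rel blocks
    expected_scan: dict[str, set] = field(default_factory=dict)
    notes: dict = field(default_factory=dict)


def _check_locus(locus: _Locus) -> bool:
    for t in locus.transcripts:
        spliced = _splice(locus.dna, t["exons"], t["strand"])
        if _scan_orfs(spliced) != locus.expected_scan.get(t["tid"], set()):
            return False
    return True


def _build(name: str, seed, builder, max_attempts: int) -> _Locus:
    for attempt in range(max_attempts):
        rng = random.Random(f"{seed}:{name}:{attempt}")
        locus = builder(rng)
        if _check_locus(locus):
            return locus
    raise ValidationError(f"could not construct clean locus {name} "
                          f"after {max_attempts} attempts")


# ---------------------------------------------------------------------------
# scenario loci
#
# Each builder lays out DNA left to right and records transcripts, planted
# proteins (with genomic blocks relative to the locus) and the exact ORF set
# a default-threshold scan must find on each transcript.

def _locus_isoform(rng: random.Random, gene: str, tids: tuple[str, str],
                   labels: tuple[str, str], shared_suffix: int,
                   category: str, peptide: str | None) -> _Locus:
    """A reference CDS plus a candidate sharing its stop coordinate with a
    controlled number of identical C-terminal residues."""
    total = 60
    prefix_len = total - shared_suffix
    if peptide:
        head = "M" + _rand_aa(rng, prefix_len - 2 - len(peptide)) + "K" + peptide
        assert len(head) == prefix_len
    else:
        head = "M" + _rand_aa(rng, prefix_len - 1)
    suffix = _rand_aa(rng, shared_suffix, first_not_p=True)
    p_ref = head + suffix
    cand_prefix = "M" + _rand_aa(rng, prefix_len - 1)
    p_cand = cand_prefix + suffix

    cds_ref = _revtrans(rng, p_ref)
    stop = _stop(rng)
    split = prefix_len * 3  # CDS split point: prefix exon / suffix exon

    utr5b = _rand_dna(rng, 9)
    cand_exon1 = utr5b + _revtrans(rng, cand_prefix)
    gap = _rand_dna(rng, 20)
    utr5 = _rand_dna(rng, 12)
    part_a = cds_ref[:split]
    intron = _rand_dna(rng, 40)
    part_b = cds_ref[split:] + stop
    utr3 = _rand_dna(rng, 15)

    dna = cand_exon1 + gap + utr5 + part_a + intron + part_b + utr3
    o1 = len(cand_exon1) + len(gap)                      # T-ref region start
    e1 = (o1, o1 + len(utr5) + len(part_a))              # T-ref exon 1
    i_end = e1[1] + len(intron)
    e2 = (i_end, i_end + len(part_b) + len(utr3))        # T-ref exon 2
    cds_b1 = (o1 + len(utr5), e1[1])
    cds_b2 = (i_end, i_end + len(part_b))
    cand_e2 = cds_b2                                      # candidate splices in

    t_ref, t_cand = tids
    locus = _Locus(name=gene, dna=dna)
    locus.transcripts = [
        {"tid": t_ref, "gene_id": f"G_{gene}", "gene_name": gene,
         "biotype": MRNA, "source": "annotA", "strand": "+",
         "exons": [e1, e2], "cds_blocks": [cds_b1, cds_b2],
         "protein_id": f"REF_{gene}"},
        {"tid": t_cand, "gene_id": f"G_{gene}", "gene_name": gene,
         "biotype": MRNA, "source": "annotA", "strand": "+",
         "exons": [(0, len(cand_exon1)), cand_e2], "cds_blocks": None,
         "protein_id": None},
    ]
    locus.planted = [
        {"label": labels[0], "protein": p_ref, "category": REFPROT,
         "gene_name": gene, "transcripts": [t_ref], "strand": "+",
         "blocks": [cds_b1, cds_b2], "accession": f"REF_{gene}"},
        {"label": labels[1], "protein": p_cand, "category": category,
         "gene_name": gene, "transcripts": [t_cand], "strand": "+",
         "blocks": [(9, len(cand_exon1)), cand_e2]},
    ]
    locus.expected_scan = {
        t_ref: {(12, 12 + len(p_ref) * 3 + 3)},
        t_cand: {(9, 9 + len(p_cand) * 3 + 3)},
    }
    locus.notes["peptide_host"] = labels[0] if peptide else None
    return locus


def _locus_polycistronic(rng: random.Random) -> _Locus:
    """100-codon annotated CDS with an embedded +1 frame 32-codon altORF;
    present identically in both annotations."""
    alt_dna = "ATG" + "GCT" * 31 + "TAA"          # M + A*31
    tail = _rand_dna(rng, 2) + "".join(rng.choice(_NONSTOP_CODONS) for _ in range(64))
    cds = "ATG" + "A" + alt_dna + tail + _stop(rng)
    assert len(cds) == 300
    # the main frame must read through cleanly over the embedded altORF
    for pos in range(3, 297, 3):
        if cds[pos:pos + 3] in STOP_CODONS:
            return _locus_polycistronic(rng)  # resample tail boundary
    utr5, utr3 = _rand_dna(rng, 10), _rand_dna(rng, 12)
    dna = utr5 + cds + utr3
    p_main = "".join(_TABLE.get(cds[i:i + 3], "X") for i in range(0, 297, 3))
    p_alt = "M" + "A" * 31

    locus = _Locus(name="GENE_POLY", dna=dna)
    exons = [(0, len(dna))]
    cds_blocks = [(10, 310)]
    locus.transcripts = [
        {"tid": "TX_POLY", "gene_id": "G_POLY", "gene_name": "GENE_POLY",
         "biotype": MRNA, "source": "annotA", "strand": "+",
         "exons": exons, "cds_blocks": cds_blocks, "protein_id": "REF_POLY"},
        {"tid": "ENST_POLY_B", "gene_id": "ENSG_POLY", "gene_name": "GENE_POLY",
         "biotype": MRNA, "source": "annotB", "strand": "+",
         "exons": exons, "cds_blocks": cds_blocks, "protein_id": "ENSP_POLY"},
    ]
    locus.planted = [
        {"label": "R_POLY", "protein": p_main, "category": REFPROT,
         "gene_name": "GENE_POLY", "transcripts": ["TX_POLY", "ENST_POLY_B"],
         "strand": "+", "blocks": cds_blocks, "accession": "ENSP_POLY"},
        {"label": "ALT_FRAME", "protein": p_alt, "category": ALTPROT,
         "gene_name": "GENE_POLY", "transcripts": ["TX_POLY", "ENST_POLY_B"],
         "strand": "+", "blocks": [(14, 113)]},
    ]
    scan = {(10, 310), (14, 113)}
    locus.expected_scan = {"TX_POLY": scan, "ENST_POLY_B": scan}
    locus.notes["ribo_orf"] = {"transcript": "TX_POLY", "tx_start": 10,
                               "tx_end": 310, "orf_label": "R_POLY"}
    return locus


def _locus_nc_orf(rng: random.Random, gene: str, tid: str, label: str,
                  n_aa: int, protein: str | None = None) -> _Locus:
    """A ncRNA whose single AUG ORF encodes ``protein`` (or a random one)."""
    if protein is None:
        protein = "M" + _rand_aa(rng, n_aa - 1)
    assert len(protein) == n_aa and protein[0] == "M"
    utr, tail = _rand_dna(rng, 10 + (n_aa % 7)), _rand_dna(rng, 10)
    orf_dna = _revtrans(rng, protein) + _stop(rng)
    dna = utr + orf_dna + tail
    locus = _Locus(name=gene, dna=dna)
    locus.transcripts = [{
        "tid": tid, "gene_id": f"G_{gene}", "gene_name": gene,
        "biotype": NCRNA, "source": "annotA", "strand": "+",
        "exons": [(0, len(dna))], "cds_blocks": None, "protein_id": None,
    }]
    start = len(utr)
    locus.planted = [{
        "label": label, "protein": protein, "category": ALTPROT,
        "gene_name": gene, "transcripts": [tid], "strand": "+",
        "blocks": [(start, start + len(orf_dna))],
    }]
    locus.expected_scan = {tid: {(start, start + len(orf_dna))}}
    return locus


def _locus_short_orf(rng: random.Random) -> _Locus:
    """29-codon AUG ORF: below the length cutoff, never emitted."""
    protein = "M" + _rand_aa(rng, 28)
    utr, tail = _rand_dna(rng, 10), _rand_dna(rng, 10)
    dna = utr + _revtrans(rng, protein) + _stop(rng) + tail
    locus = _Locus(name="GENE_NC29", dna=dna)
    locus.transcripts = [{
        "tid": "TX_NC29", "gene_id": "G_NC29", "gene_name": "GENE_NC29",
        "biotype": NCRNA, "source": "annotA", "strand": "+",
        "exons": [(0, len(dna))], "cds_blocks": None, "protein_id": None,
    }]
    locus.expected_scan = {"TX_NC29": set()}
    locus.notes["absent"] = {"label": "SHORT29", "transcript": "TX_NC29",
                             "reason": "28 aa < 30-codon minimum",
                             "protein": protein}
    return locus


def _locus_decoy(rng: random.Random) -> _Locus:
    """AUG with no in-frame stop before the transcript end (indeterminate)."""
    body = "".join(rng.choice(_NONSTOP_CODONS) for _ in range(50))
    dna = _rand_dna(rng, 10) + "ATG" + body
    locus = _Locus(name="GENE_DECOY", dna=dna)
    locus.transcripts = [{
        "tid": "TX_DECOY", "gene_id": "G_DECOY", "gene_name": "GENE_DECOY",
        "biotype": NCRNA, "source": "annotA", "strand": "+",
        "exons": [(0, len(dna))], "cds_blocks": None, "protein_id": None,
    }]
    locus.expected_scan = {"TX_DECOY": set()}
    locus.notes["absent"] = {"label": "DECOY", "transcript": "TX_DECOY",
                             "reason": "no in-frame stop within transcript",
                             "protein": None}
    return locus


def _locus_hsp(rng: random.Random, gene: str, tid: str, label: str,
               peptide: str, n_aa: int, refprot: bool) -> _Locus:
    """A protein embedding one designed tryptic peptide; either an annotated
    mRNA CDS (parental gene) or a ncRNA ORF (pseudogene-like)."""
    head_len = n_aa - len(peptide) - 2
    protein = "M" + _rand_aa(rng, head_len) + "K" + peptide
    assert len(protein) == n_aa and peptide in protein
    utr5, utr3 = _rand_dna(rng, 9), _rand_dna(rng, 9)
    orf_dna = _revtrans(rng, protein) + _stop(rng)
    dna = utr5 + orf_dna + utr3
    start = len(utr5)
    blocks = [(start, start + len(orf_dna))]
    locus = _Locus(name=gene, dna=dna)
    locus.transcripts = [{
        "tid": tid, "gene_id": f"G_{gene}", "gene_name": gene,
        "biotype": MRNA if refprot else NCRNA, "source": "annotA",
        "strand": "+", "exons": [(0, len(dna))],
        "cds_blocks": blocks if refprot else None,
        "protein_id": f"REF_{gene}" if refprot else None,
    }]
    entry = {"label": label, "protein": protein,
             "category": REFPROT if refprot else ALTPROT,
             "gene_name": gene, "transcripts": [tid], "strand": "+",
             "blocks": blocks}
    if refprot:
        entry["accession"] = f"REF_{gene}"
    locus.planted = [entry]
    locus.expected_scan = {tid: {(start, start + len(orf_dna))}}
    return locus


def _locus_twin(rng: random.Random, pep_twin: str, pep_cross: str) -> _Locus:
    """One gene, two ncRNA transcripts whose ORFs share a tryptic peptide;
    the first also carries the cross-gene peptide."""
    p_a = ("M" + _rand_aa(rng, 3) + "K" + pep_twin +
           _rand_aa(rng, 4, first_not_p=True) + "K" + pep_cross +
           _rand_aa(rng, 10, first_not_p=True))
    p_b = "M" + _rand_aa(rng, 5) + "K" + pep_twin + _rand_aa(rng, 21, first_not_p=True)
    assert len(p_a) == 40 and len(p_b) == 38
    utr_a, tail_a = _rand_dna(rng, 8), _rand_dna(rng, 8)
    utr_b, tail_b = _rand_dna(rng, 8), _rand_dna(rng, 8)
    dna_a = utr_a + _revtrans(rng, p_a) + _stop(rng) + tail_a
    dna_b = utr_b + _revtrans(rng, p_b) + _stop(rng) + tail_b
    gap = _rand_dna(rng, 30)
    dna = dna_a + gap + dna_b
    off_b = len(dna_a) + len(gap)
    locus = _Locus(name="GENE_TWIN", dna=dna)
    locus.transcripts = [
        {"tid": "TX_TWIN_A", "gene_id": "G_TWIN", "gene_name": "GENE_TWIN",
         "biotype": NCRNA, "source": "annotA", "strand": "+",
         "exons": [(0, len(dna_a))], "cds_blocks": None, "protein_id": None},
        {"tid": "TX_TWIN_B", "gene_id": "G_TWIN", "gene_name": "GENE_TWIN",
         "biotype": NCRNA, "source": "annotA", "strand": "+",
         "exons": [(off_b, off_b + len(dna_b))], "cds_blocks": None,
         "protein_id": None},
    ]
    locus.planted = [
        {"label": "TWIN_A", "protein": p_a, "category": ALTPROT,
         "gene_name": "GENE_TWIN", "transcripts": ["TX_TWIN_A"], "strand": "+",
         "blocks": [(8, 8 + len(p_a) * 3 + 3)]},
        {"label": "TWIN_B", "protein": p_b, "category": ALTPROT,
         "gene_name": "GENE_TWIN", "transcripts": ["TX_TWIN_B"], "strand": "+",
         "blocks": [(off_b + 8, off_b + 8 + len(p_b) * 3 + 3)]},
    ]
    locus.expected_scan = {
        "TX_TWIN_A": {(8, 8 + len(p_a) * 3 + 3)},
        "TX_TWIN_B": {(8, 8 + len(p_b) * 3 + 3)},
    }
    return locus


def _locus_antisense(rng: random.Random, pep_cross: str) -> _Locus:
    """An annotA ncRNA ORF carrying the cross-gene peptide, overlapped by an
    annotB minus-strand mRNA (separate strand-aware gene group)."""
    p_c = "M" + _rand_aa(rng, 4) + "K" + pep_cross + _rand_aa(rng, 20, first_not_p=True)
    assert len(p_c) == 36
    utr = _rand_dna(rng, 10)
    orf_dna = _revtrans(rng, p_c) + _stop(rng)
    part1 = utr + orf_dna + _rand_dna(rng, 9)      # [0, 130)
    # antisense mRNA occupies [130, 280); T12's exon stretches into it
    p_anti = "M" + _rand_aa(rng, 44)
    s13 = _rand_dna(rng, 6) + _revtrans(rng, p_anti) + _stop(rng) + _rand_dna(rng, 6)
    anti_genomic = reverse_complement(s13)          # 150 nt
    dna = part1 + anti_genomic
    anti_off = len(part1)
    anti_len = len(anti_genomic)
    locus = _Locus(name="GENE_XG", dna=dna)
    t12_exon = (0, len(part1) + 11)                 # overlaps the antisense gene
    # antisense CDS (stop included) in transcript coords is [6, 144); flip
    cds_g = (anti_off + anti_len - 144, anti_off + anti_len - 6)
    locus.transcripts = [
        {"tid": "TX_XG", "gene_id": "G_XG", "gene_name": "GENE_XG",
         "biotype": NCRNA, "source": "annotA", "strand": "+",
         "exons": [t12_exon], "cds_blocks": None, "protein_id": None},
        {"tid": "ENST_ANTI", "gene_id": "ENSG_ANTI", "gene_name": "GENE_ANTI",
         "biotype": MRNA, "source": "annotB", "strand": "-",
         "exons": [(anti_off, anti_off + anti_len)],
         "cds_blocks": [cds_g], "protein_id": "REF_ANTI"},
    ]
    start = len(utr)
    locus.planted = [
        {"label": "XG_C", "protein": p_c, "category": ALTPROT,
         "gene_name": "GENE_XG", "transcripts": ["TX_XG"], "strand": "+",
         "blocks": [(start, start + len(orf_dna))]},
        {"label": "R_ANTI", "protein": p_anti, "category": REFPROT,
         "gene_name": "GENE_ANTI", "transcripts": ["ENST_ANTI"], "strand": "-",
         "blocks": [cds_g], "accession": "REF_ANTI"},
    ]
    locus.expected_scan = {
        "TX_XG": {(start, start + len(orf_dna))},
        "ENST_ANTI": {(6, 144)},
    }
    locus.notes["antisense_pair"] = [["annotA", "G_XG"], ["annotB", "ENSG_ANTI"]]
    return locus


# ---------------------------------------------------------------------------
# cross-locus validation

def _peptide_matches(peptide: str, planted: list[dict]) -> set[str]:
    hits = set()
    collapsed = collapse_il(peptide)
    for entry in planted:
        for frag in digest(entry["protein"]):
            if collapse_il(frag.sequence) == collapsed:
                hits.add(entry["label"])
    return hits


def _edge_passes(pa: str, pb: str) -> bool:
    for q, s in ((pa, pb), (pb, pa)):
        raw, _, (qs, qe) = local_align(q, s)
        if bit_score(raw) > 40.0 and (qe - qs) / len(q) > 0.5:
            return True
    return False


def _validate_world(planted: list[dict], peptides: dict[str, dict]) -> bool:
    proteins = [e["protein"] for e in planted]
    if len(set(proteins)) != len(proteins):
        return False
    for pep, expect in peptides.items():
        if _peptide_matches(pep, planted) != set(expect["expected_labels"]):
            return False
    by_label = {e["label"]: e for e in planted}
    # isoform identity sides of the 20% rule (12 identical aa on 60-aa query)
    _, ident_hi, _ = local_align(by_label["II_CAND"]["protein"],
                                 by_label["R_ISO"]["protein"])
    _, ident_lo, _ = local_align(by_label["ALT_SUFFIX"]["protein"],
                                 by_label["R_LOWID"]["protein"])
    if not (ident_hi > 12 and ident_lo <= 12):
        return False
    if not _edge_passes(by_label["II_CAND"]["protein"], by_label["R_ISO"]["protein"]):
        return False
    for a, b in (("TWIN_A", "TWIN_B"), ("R_POLY", "ALT_FRAME")):
        if _edge_passes(by_label[a]["protein"], by_label[b]["protein"]):
            return False
    return True


# ---------------------------------------------------------------------------
# file writers

def _write_gtf(path: Path, transcripts: list[dict], contig_of: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            contig = contig_of[t["tid"]]
            base = [f'gene_id "{t["gene_id"]}"', f'transcript_id "{t["tid"]}"',
                    f'gene_name "{t["gene_name"]}"']
            bio = "protein_coding" if t["biotype"] == MRNA else "lncRNA"
            span = (t["exons"][0][0] + 1, t["exons"][-1][1])
            tx_attrs = "; ".join(base + [f'transcript_biotype "{bio}"']) + ";"
            fh.write(f"{contig}\tpolyorf_fixture\ttranscript\t{span[0]}\t{span[1]}"
                     f"\t.\t{t['strand']}\t.\t{tx_attrs}\n")
            attrs = "; ".join(base) + ";"
            for s, e in t["exons"]:
                fh.write(f"{contig}\tpolyorf_fixture\texon\t{s + 1}\t{e}\t.\t"
                         f"{t['strand']}\t.\t{attrs}\n")
            if t["cds_blocks"]:
                cds_attrs = "; ".join(base + [f'protein_id "{t["protein_id"]}"']) + ";"
                for s, e in t["cds_blocks"]:
                    fh.write(f"{contig}\tpolyorf_fixture\tCDS\t{s + 1}\t{e}\t.\t"
                             f"{t['strand']}\t0\t{cds_attrs}\n")


def _write_gff3(path: Path, transcripts: list[dict], contig_of: dict[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            contig = contig_of[t["tid"]]
            ftype = "mRNA" if t["biotype"] == MRNA else "ncRNA"
            span = (t["exons"][0][0] + 1, t["exons"][-1][1])
            fh.write(f"{contig}\tpolyorf_fixture\t{ftype}\t{span[0]}\t{span[1]}\t.\t"
                     f"{t['strand']}\t.\tID={t['tid']};Parent={t['gene_id']};"
                     f"gene_name={t['gene_name']}\n")
            for s, e in t["exons"]:
                fh.write(f"{contig}\tpolyorf_fixture\texon\t{s + 1}\t{e}\t.\t"
                         f"{t['strand']}\t.\tParent={t['tid']}\n")
            if t["cds_blocks"]:
                for s, e in t["cds_blocks"]:
                    fh.write(f"{contig}\tpolyorf_fixture\tCDS\t{s + 1}\t{e}\t.\t"
                             f"{t['strand']}\t0\tParent={t['tid']};"
                             f"protein_id={t['protein_id']}\n")


# ---------------------------------------------------------------------------
# the generator

def generate_fixture(outdir: str | Path, seed: int,
                     spec: FixtureSpec | None = None) -> dict:
    """Write the full synthetic input set plus manifest.json; returns the
    manifest. Deterministic (byte-identical files) for fixed (spec, seed)."""
    spec = spec or FixtureSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = None
    for world_attempt in range(spec.max_attempts):
        world_seed = f"{seed}:{world_attempt}"
        rng = random.Random(f"{world_seed}:peptides")
        pep_r1 = _rand_peptide(rng)
        pep_nc = _rand_peptide(rng)
        pep_twin = _rand_peptide(rng)
        pep_cross = _rand_peptide(rng)
        pep_none = _rand_peptide(rng)
        # the two EIGN spellings collapse to one key by design; every other
        # planted peptide must stay distinct under the I/L collapse
        peps = [pep_r1, pep_nc, pep_twin, pep_cross, pep_none, "EIGNLISDAMK"]
        if len({collapse_il(p) for p in peps}) != len(peps):
            continue

        loci_chr1: list[_Locus] = []
        loci_chr2: list[_Locus] = []
        if spec.core_scenarios:
            loci_chr1 = [
                _build("iso_hi", world_seed, lambda r: _locus_isoform(
                    r, "GENE_ISO", ("TX_ISO_REF", "TX_ISO_CAND"),
                    ("R_ISO", "II_CAND"), shared_suffix=40,
                    category=NOVEL_ISOFORM, peptide=pep_r1), spec.max_attempts),
                _build("iso_lo", world_seed, lambda r: _locus_isoform(
                    r, "GENE_LOWID", ("TX_LOW_REF", "TX_LOW_CAND"),
                    ("R_LOWID", "ALT_SUFFIX"), shared_suffix=6,
                    category=ALTPROT, peptide=None), spec.max_attempts),
                _build("poly", world_seed, _locus_polycistronic, spec.max_attempts),
                _build("nc30", world_seed, lambda r: _locus_nc_orf(
                    r, "GENE_NC30", "TX_NC30", "NC30", 30,
                    protein="M" + _rand_aa(r, 8) + "K" + pep_nc +
                            _rand_aa(r, 10, first_not_p=True)), spec.max_attempts),
                _build("nc29", world_seed, _locus_short_orf, spec.max_attempts),
            ]
            loci_chr2 = [
                _build("hspd1", world_seed, lambda r: _locus_hsp(
                    r, "HSPD1", "TX_HSPD1", "R_HSP", "EIGNIISDAMK", 50,
                    refprot=True), spec.max_attempts),
                _build("hspd1p7", world_seed, lambda r: _locus_hsp(
                    r, "HSPD1P7", "TX_HSPD1P7", "HSP_ALT", "EIGNLISDAMK", 35,
                    refprot=False), spec.max_attempts),
                _build("twin", world_seed, lambda r: _locus_twin(
                    r, pep_twin, pep_cross), spec.max_attempts),
                _build("xg", world_seed, lambda r: _locus_antisense(
                    r, pep_cross), spec.max_attempts),
                _build("decoy", world_seed, _locus_decoy, spec.max_attempts),
            ]
        for i in range(spec.n_extra_nc_genes):
            loci_chr2.append(_build(f"extra{i}", world_seed, lambda r, i=i: _locus_nc_orf(
                r, f"GENE_EXTRA{i + 1}", f"TX_EXTRA{i + 1}", f"EXTRA{i + 1}",
                31 + i), spec.max_attempts))

        # place loci on contigs with intergenic filler
        place_rng = random.Random(f"{world_seed}:placement")
        contigs: dict[str, str] = {}
        transcripts: list[dict] = []
        planted: list[dict] = []
        absent: list[dict] = []
        contig_of: dict[str, str] = {}
        expected_scan: dict[str, set] = {}
        notes: dict = {}
        for contig, loci in (("chr1", loci_chr1), ("chr2", loci_chr2)):
            parts = [_rand_dna(place_rng, spec.intergenic)]
            offset = len(parts[0])
            for locus in loci:
                for t in locus.transcripts:
                    t = dict(t)
                    t["exons"] = [(s + offset, e + offset) for s, e in t["exons"]]
                    if t["cds_blocks"]:
                        t["cds_blocks"] = [(s + offset, e + offset)
                                           for s, e in t["cds_blocks"]]
                    t["contig"] = contig
                    contig_of[t["tid"]] = contig
                    transcripts.append(t)
                for p in locus.planted:
                    p = dict(p)
                    p["blocks"] = [(s + offset, e + offset) for s, e in p["blocks"]]
                    p["contig"] = contig
                    planted.append(p)
                if "absent" in locus.notes:
                    absent.append(locus.notes["absent"])
                if "ribo_orf" in locus.notes:
                    notes["ribo_orf"] = locus.notes["ribo_orf"]
                if "antisense_pair" in locus.notes:
                    notes["antisense_pair"] = locus.notes["antisense_pair"]
                expected_scan.update(locus.expected_scan)
                parts.append(locus.dna)
                parts.append(_rand_dna(place_rng, spec.intergenic))
                offset += len(locus.dna) + spec.intergenic
            contigs[contig] = "".join(parts)

        peptide_expect = {}
        if spec.core_scenarios:
            peptide_expect = {
                "EIGNLISDAMK": {"expected_labels": ["HSP_ALT", "R_HSP"],
                                "expected_rule": "refprot_priority",
                                "expected_assigned": ["R_HSP"],
                                "expected_canonical": "EIGNIISDAMK",
                                "rows": [("ds_ms1", 4)]},
                pep_r1: {"expected_labels": ["R_ISO"],
                         "expected_rule": "unique",
                         "expected_assigned": ["R_ISO"],
                         "expected_canonical": pep_r1,
                         "rows": [("ds_ms1", 3), ("ds_ms2", 2)]},
                pep_nc: {"expected_labels": ["NC30"],
                         "expected_rule": "unique",
                         "expected_assigned": ["NC30"],
                         "expected_canonical": pep_nc,
                         "rows": [("ds_ms2", 1)]},
                pep_twin: {"expected_labels": ["TWIN_A", "TWIN_B"],
                           "expected_rule": "shared_novel_same_gene",
                           "expected_assigned": ["TWIN_A", "TWIN_B"],
                           "expected_canonical": pep_twin,
                           "rows": [("ds_ms1", 2)]},
                pep_cross: {"expected_labels": ["TWIN_A", "XG_C"],
                            "expected_rule": "discarded_cross_gene",
                            "expected_assigned": [],
                            "expected_canonical": pep_cross,
                            "rows": [("ds_ms2", 3)]},
                pep_none: {"expected_labels": [],
                           "expected_rule": "unique",
                           "expected_assigned": [],
                           "expected_canonical": pep_none,
                           "rows": [("ds_ms1", 1)]},
            }
            # EIGNLISDAMK also requires its own matching: observed spelling is
            # the pseudogene one, matching both genes after I/L collapse
            peptide_expect["EIGNLISDAMK"]["expected_labels"] = ["HSP_ALT", "R_HSP"]

        if spec.core_scenarios and not _validate_world(planted, peptide_expect):
            continue

        # --- ribo calls -----------------------------------------------------
        ribo_rows: list[dict] = []
        if spec.core_scenarios:
            orf = notes["ribo_orf"]
            p_values = ["0.0050", "0.0040", "0.0030", "0.0025", "0.0020",
                        "0.0010", "0.0008", "0.0005", "1e-04", "1e-06"]
            for i, n_codons in enumerate(range(50, 100, 5)):
                overlap = n_codons / 100.0
                ribo_rows.append({
                    "dataset_id": "ds_riboB" if n_codons == 85 else "ds_riboA",
                    "transcript_id": orf["transcript"],
                    "start": orf["tx_end"] - 3 * n_codons, "stop": orf["tx_end"],
                    "codon": "CTG" if n_codons == 90 else "ATG",
                    "p_value": p_values[i],
                    "expected_accepted": overlap > 0.7,
                    "expected_overlap": overlap,
                    "orf_label": orf["orf_label"], "parses": True,
                })
            ribo_rows.append({  # out of frame / different stop
                "dataset_id": "ds_riboA", "transcript_id": orf["transcript"],
                "start": 13, "stop": 313, "codon": "ATG", "p_value": "0.5",
                "expected_accepted": False, "expected_overlap": 0.0,
                "orf_label": None, "parses": True,
            })
            ribo_rows.append({  # unknown transcript
                "dataset_id": "ds_riboA", "transcript_id": "TX_GHOST",
                "start": 0, "stop": 90, "codon": "ATG", "p_value": "0.01",
                "expected_accepted": False, "expected_overlap": 0.0,
                "orf_label": None, "parses": True,
            })
            ribo_rows.append({  # unparsable p-value
                "dataset_id": "ds_riboA", "transcript_id": orf["transcript"],
                "start": 10, "stop": 310, "codon": "ATG", "p_value": "NA",
                "expected_accepted": False, "expected_overlap": None,
                "orf_label": None, "parses": False,
            })

        # --- write files ----------------------------------------------------
        with open(outdir / "genome.fa", "w") as fh:
            for contig in sorted(contigs):
                fh.write(f">{contig}\n")
                seq = contigs[contig]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
        _write_gtf(outdir / "annotA.gtf",
                   [t for t in transcripts if t["source"] == "annotA"], contig_of)
        _write_gff3(outdir / "annotB.gff3",
                    [t for t in transcripts if t["source"] == "annotB"], contig_of)

        by_label = {e["label"]: e for e in planted}
        with open(outdir / "reference.fasta", "w") as fh:
            if spec.core_scenarios:
                fh.write(f">SP_HSPD1\n{by_label['R_HSP']['protein']}\n")
                orphan_rng = random.Random(f"{world_seed}:orphan")
                orphan = "M" + _rand_aa(orphan_rng, 49)
                while orphan in {e["protein"] for e in planted}:
                    orphan = "M" + _rand_aa(orphan_rng, 49)
                fh.write(f">SP_ORPHAN\n{orphan}\n")
        with open(outdir / "xref.tsv", "w") as fh:
            fh.write("accession\tgene_name\n")
            if spec.core_scenarios:
                fh.write("SP_HSPD1\tHSPD1\n")
                fh.write("MALFORMED_ROW_WITHOUT_GENE\n")

        with open(outdir / "peptides.tsv", "w") as fh:
            fh.write("peptide\tdataset_id\tpsm_count\tconfidence\n")
            for pep in peptide_expect:
                for ds, psm in peptide_expect[pep]["rows"]:
                    fh.write(f"{pep}\t{ds}\t{psm}\t0.99\n")

        with open(outdir / "ribo_calls.tsv", "w") as fh:
            fh.write("dataset_id\ttranscript_id\tstart\tstop\tcodon\tp_value\n")
            for row in ribo_rows:
                fh.write(f"{row['dataset_id']}\t{row['transcript_id']}\t"
                         f"{row['start']}\t{row['stop']}\t{row['codon']}\t"
                         f"{row['p_value']}\n")

        counts = {REFPROT: 0, NOVEL_ISOFORM: 0, ALTPROT: 0}
        for e in planted:
            counts[e["category"]] += 1
        manifest = {
            "seed": seed,
            "contigs": {c: len(s) for c, s in sorted(contigs.items())},
            "transcript_counts": {
                "annotA": sum(t["source"] == "annotA" for t in transcripts),
                "annotB": sum(t["source"] == "annotB" for t in transcripts),
            },
            "planted_proteins": [
                {k: (list(map(list, v)) if k == "blocks" else v)
                 for k, v in e.items()} for e in planted],
            "absent_orfs": absent,
            "expected_counts": counts,
            "expected_scan": {tid: sorted(map(list, s))
                              for tid, s in sorted(expected_scan.items())},
            "isoform_pairs": ([
                {"a": "R_ISO", "b": "II_CAND", "edge": True},
                {"a": "R_LOWID", "b": "ALT_SUFFIX", "edge": False},
                {"a": "TWIN_A", "b": "TWIN_B", "edge": False},
                {"a": "R_POLY", "b": "ALT_FRAME", "edge": False},
            ] if spec.core_scenarios else []),
            "peptides": [
                {"sequence": pep, **{k: v for k, v in exp.items() if k != "rows"},
                 "rows": [list(r) for r in exp["rows"]]}
                for pep, exp in peptide_expect.items()],
            "ribo_calls": ribo_rows,
            "ribo_summary": ({
                "orf_label": "R_POLY", "n_datasets": 2,
                "best_p_value": 1e-06, "init_codons": ["ATG", "CTG"],
            } if spec.core_scenarios else None),
            "gene_pairs_merged": ([["annotA", "G_POLY"], ["annotB", "ENSG_POLY"]]
                                  if spec.core_scenarios else None),
            "gene_pairs_distinct": (notes.get("antisense_pair")
                                    if spec.core_scenarios else None),
            "dedup": ({"orf_label": "R_POLY",
                       "expected_transcripts": ["ENST_POLY_B", "TX_POLY"]}
                      if spec.core_scenarios else None),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        break

    if manifest is None:
        raise ValidationError("fixture generation failed for every attempt")
    return manifest


# ---------------------------------------------------------------------------
# truth checking

def truth_check(catalog, manifest: dict, edges=None, assignments=None,
                ribo_events=None) -> list[str]:
    """Compare pipeline outputs against the fixture manifest.

    ``assignments`` maps observed peptide sequence -> AssignmentResult;
    ``edges`` and ``ribo_events`` are the isoform edge list and accepted
    translation-evidence list. Returns a list of human-readable
    discrepancies; empty means the run recovered every planted truth.
    """
    problems: list[str] = []
    by_protein = {p.protein: p for p in catalog.proteins}

    label_to_acc: dict[str, str] = {}
    for entry in manifest["planted_proteins"]:
        rec = by_protein.get(entry["protein"])
        if rec is None:
            problems.append(f"planted protein {entry['label']} missing from catalog")
            continue
        label_to_acc[entry["label"]] = rec.accession
        if rec.category != entry["category"]:
            problems.append(f"{entry['label']}: category {rec.category} != "
                            f"{entry['category']}")
        blocks = tuple(tuple(b) for b in entry["blocks"])
        if rec.orf is not None and rec.orf.genomic_blocks != blocks:
            problems.append(f"{entry['label']}: genomic blocks "
                            f"{rec.orf.genomic_blocks} != {blocks}")

    counts = {REFPROT: 0, NOVEL_ISOFORM: 0, ALTPROT: 0}
    for p in catalog.proteins:
        counts[p.category] += 1
    for cat, n in manifest["expected_counts"].items():
        if counts.get(cat, 0) != n:
            problems.append(f"category count {cat}: {counts.get(cat, 0)} != {n}")

    for entry in manifest["absent_orfs"]:
        tid = entry["transcript"]
        offenders = [o.orf_id for o in catalog.orfs if tid in o.transcript_ids]
        if offenders:
            problems.append(f"unexpected ORFs on {tid}: {offenders}")

    if manifest.get("dedup") and "R_POLY" in label_to_acc:
        rec = catalog.protein_by_accession(label_to_acc["R_POLY"])
        expected = set(manifest["dedup"]["expected_transcripts"])
        if rec.orf is None or not expected <= rec.orf.transcript_ids:
            problems.append("deduplicated ORF lost a supporting transcript")

    if manifest.get("gene_pairs_merged"):
        mapping = catalog.gene_group_of
        a, b = (tuple(x) for x in manifest["gene_pairs_merged"])
        if mapping.get(a) != mapping.get(b):
            problems.append(f"genes {a} and {b} not merged into one group")
    if manifest.get("gene_pairs_distinct"):
        mapping = catalog.gene_group_of
        a, b = (tuple(x) for x in manifest["gene_pairs_distinct"])
        if mapping.get(a) == mapping.get(b):
            problems.append(f"antisense genes {a} and {b} wrongly merged")

    if edges is not None:
        edge_pairs = {frozenset((e.query_accession, e.subject_accession))
                      for e in edges}
        for pair in manifest["isoform_pairs"]:
            accs = frozenset((label_to_acc.get(pair["a"], "?"),
                              label_to_acc.get(pair["b"], "?")))
            if pair["edge"] and accs not in edge_pairs:
                problems.append(f"expected isoform edge {pair} missing")
            if not pair["edge"] and accs in edge_pairs:
                problems.append(f"unexpected isoform edge {pair}")

    if assignments is not None:
        for entry in manifest["peptides"]:
            res = assignments.get(entry["sequence"])
            if res is None:
                problems.append(f"peptide {entry['sequence']} never assigned")
                continue
            expect_accs = {label_to_acc.get(lbl, "?")
                           for lbl in entry["expected_assigned"]}
            if res.assigned_accessions != expect_accs:
                problems.append(f"peptide {entry['sequence']}: assigned "
                                f"{sorted(res.assigned_accessions)} != "
                                f"{sorted(expect_accs)}")
            if res.rule_applied != entry["expected_rule"]:
                problems.append(f"peptide {entry['sequence']}: rule "
                                f"{res.rule_applied} != {entry['expected_rule']}")
            if res.assigned_accessions and \
                    res.canonical_sequence != entry["expected_canonical"]:
                problems.append(f"peptide {entry['sequence']}: canonical "
                                f"{res.canonical_sequence} != "
                                f"{entry['expected_canonical']}")

    if ribo_events is not None:
        accepted = {(e.dataset_id, round(e.overlap_fraction, 6))
                    for e in ribo_events}
        expected = {(r["dataset_id"], round(r["expected_overlap"], 6))
                    for r in manifest["ribo_calls"] if r["expected_accepted"]}
        if accepted != expected:
            problems.append(f"accepted ribo events {sorted(accepted)} != "
                            f"{sorted(expected)}")
    return problems
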