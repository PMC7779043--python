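"""Reference-set merging, categorization, accessions, catalog diffing."""

import copy

import pytest

from polyorf.models import (
    ALTPROT, IDENTITY_OVER_THRESHOLD, NOVEL_ISOFORM, PipelineConfig, REFPROT,
    RefEntry, SHARED_END, ValidationError,
)
from polyorf.protein_catalog import (
    build_catalog, build_reference_set, diff_catalogs,
)
from polyorf.annotation_io import read_annotation, read_genome


@pytest.fixture(scope="module")
def inputs(fixture_dir):
    d, manifest = fixture_dir
    genome = read_genome(d / "genome.fa")
    txs = (read_annotation(d / "annotA.gtf", "annotA")
           + read_annotation(d / "annotB.gff3", "annotB"))
    return d, manifest, genome, txs


class TestReferenceSet:
    def test_external_entry_with_xref_shares_gene_group(self, run):
        d = run.dir
        from polyorf.protein_catalog import annotation_reference_entries
        from polyorf.annotation_io import read_genome, reconcile_genes
        genome = read_genome(d / "genome.fa")
        groups = reconcile_genes(run.catalog.transcripts)
        entries = annotation_reference_entries(run.catalog.transcripts, genome, groups)
        name_to_group = {}
        mapping = {}
        for g in groups:
            for m in g.member_gene_ids:
                mapping[m] = g.group_id
        for t in run.catalog.transcripts:
            if t.gene_name:
                name_to_group.setdefault(t.gene_name.lower(),
                                         mapping[(t.source, t.gene_id)])
        refs = build_reference_set(entries, d / "reference.fasta",
                                   d / "xref.tsv", name_to_group)
        by_acc = {e.accession: e for e in refs.entries}
        annot_hsp = by_acc["REF_HSPD1"]
        assert by_acc["SP_HSPD1"].gene_group_id == annot_hsp.gene_group_id
        assert by_acc["SP_HSPD1"].protein == annot_hsp.protein  # duplicates kept
        assert by_acc["SP_ORPHAN"].gene_group_id is None

    def test_sequence_match_inherits_gene_without_xref(self, tmp_path):
        annot = [RefEntry("A1", "MSEQPROTEIN", "GG7", "annotA")]
        fasta = tmp_path / "ext.fa"
        fasta.write_text(">E1\nMSEQPROTEIN\n")
        refs = build_reference_set(annot, fasta)
        by_acc = {e.accession: e for e in refs.entries}
        assert by_acc["E1"].gene_group_id == "GG7"


class TestCategorize:
    def test_planted_categories(self, run, label_to_record):
        for entry in run.manifest["planted_proteins"]:
            assert label_to_record[entry["label"]].category == entry["category"]

    def test_exact_match_is_refprot_even_cross_gene(self, run, label_to_record):
        assert label_to_record["R_HSP"].category == REFPROT
        assert label_to_record["R_HSP"].isoform_reasons == []

    def test_novel_isoform_reasons_recorded(self, run, label_to_record):
        rec = label_to_record["II_CAND"]
        reasons = {r for _, r in rec.isoform_reasons}
        assert SHARED_END in reasons and IDENTITY_OVER_THRESHOLD in reasons
        ref_accs = {acc for acc, _ in rec.isoform_reasons}
        assert label_to_record["R_ISO"].accession in ref_accs

    def test_shared_boundary_low_identity_stays_altprot(self, run, label_to_record):
        rec = label_to_record["ALT_SUFFIX"]
        assert rec.category == ALTPROT and rec.isoform_reasons == []

    def test_ncrna_orf_without_refprot_is_altprot(self, run, label_to_record):
        assert label_to_record["NC30"].category == ALTPROT

    def test_category_partition(self, run):
        cats = [p.category for p in run.catalog.proteins]
        assert all(c in (REFPROT, NOVEL_ISOFORM, ALTPROT) for c in cats)
        assert (cats.count(REFPROT) + cats.count(NOVEL_ISOFORM)
                + cats.count(ALTPROT)) == len(run.catalog.proteins)

    def test_raising_identity_threshold_is_monotone(self, inputs):
        """Raising the isoform identity threshold never converts an AltProt
        into a NovelIsoform."""
        d, manifest, genome, txs = inputs
        lo = build_catalog(genome, txs, PipelineConfig(isoform_identity_threshold=0.05),
                           external_fasta=d / "reference.fasta",
                           gene_xref=d / "xref.tsv")
        hi = build_catalog(genome, txs, PipelineConfig(isoform_identity_threshold=0.9),
                           external_fasta=d / "reference.fasta",
                           gene_xref=d / "xref.tsv")
        lo_iso = {p.protein for p in lo.proteins if p.category == NOVEL_ISOFORM}
        hi_iso = {p.protein for p in hi.proteins if p.category == NOVEL_ISOFORM}
        assert hi_iso <= lo_iso

    def test_input_order_invariance(self, inputs):
        d, manifest, genome, txs = inputs
        cfg = PipelineConfig()
        a = build_catalog(genome, txs, cfg, external_fasta=d / "reference.fasta",
                          gene_xref=d / "xref.tsv")
        b = build_catalog(genome, list(reversed(txs)), cfg,
                          external_fasta=d / "reference.fasta",
                          gene_xref=d / "xref.tsv")
        key = lambda c: sorted((p.accession, p.category, p.protein)
                               for p in c.proteins)
        assert key(a) == key(b)


class TestAccessions:
    def test_prefixes_match_categories(self, run):
        for p in run.catalog.proteins:
            if p.category == NOVEL_ISOFORM:
                assert p.accession.startswith("II_")
            elif p.category == ALTPROT:
                assert p.accession.startswith("IP_")
            else:
                assert not p.accession.startswith(("II_", "IP_"))

    def test_numbering_follows_genomic_order(self, run):
        ip = [p for p in run.catalog.proteins if p.accession.startswith("IP_")]
        ordered = sorted(ip, key=lambda p: int(p.accession[3:]))
        keys = [(p.orf.contig_id, p.orf.genomic_blocks[0][0],
                 p.orf.genomic_blocks[-1][1], p.orf.strand, p.protein)
                for p in ordered]
        assert keys == sorted(keys)

    def test_rerun_identical(self, inputs):
        d, manifest, genome, txs = inputs
        cfg = PipelineConfig()
        a = build_catalog(genome, txs, cfg)
        b = build_catalog(genome, txs, cfg)
        assert [p.accession for p in a.proteins] == [p.accession for p in b.proteins]

    def test_counts_match_manifest(self, run):
        counts = {REFPROT: 0, NOVEL_ISOFORM: 0, ALTPROT: 0}
        for p in run.catalog.proteins:
            counts[p.category] += 1
        assert counts == run.manifest["expected_counts"]


class TestDiffCatalogs:
    def test_identical_catalogs_all_zero(self, run):
        report = diff_catalogs(run.catalog, run.catalog)
        assert report.total_transcripts_added == 0
        assert report.total_transcripts_removed_or_changed == 0
        assert report.refprots_added == 0
        assert report.refprots_removed_or_changed == 0
        assert report.reclassified == []

    def test_shortened_exon_counts_as_changed(self, run):
        new = copy.deepcopy(run.catalog)
        t = next(t for t in new.transcripts if t.biotype == "ncRNA")
        s, e = t.exons[-1]
        t.exons[-1] = (s, e - 3)
        new.spliced_sequences[t.transcript_id] = \
            new.spliced_sequences[t.transcript_id][:-3]
        report = diff_catalogs(run.catalog, new)
        assert report.total_transcripts_removed_or_changed == 1
        assert report.total_transcripts_added == 0

    def test_altprot_promoted_to_refprot(self, run, label_to_record):
        """An AltProt of the old build whose sequence becomes annotated in
        the new build is reported as reclassified."""
        new = copy.deepcopy(run.catalog)
        promoted = label_to_record["NC30"]
        rec = next(p for p in new.proteins if p.protein == promoted.protein)
        rec.category = REFPROT
        rec.accession = "NEWREF_1"
        report = diff_catalogs(run.catalog, new)
        assert (promoted.accession, ALTPROT, REFPROT) in report.reclassified
        assert report.refprots_added >= 1

    def test_contig_mismatch_rejected(self, run):
        new = copy.deepcopy(run.catalog)
        new.contig_lengths = {"other": 10}
        with pytest.raises(ValidationError):
            diff_catalogs(run.catalog, new)
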