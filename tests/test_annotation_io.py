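"""Genome/annotation parsing, spliced extraction, gene grouping, exports."""

import random

import pytest

from polyorf.models import InputError, MRNA, NCRNA, TranscriptModel, ValidationError
from polyorf.annotation_io import (
    read_annotation, read_bed12, read_genome, reconcile_genes, spliced_sequence,
    write_bed12, write_genome,
)

from oracles import random_transcript


def _tx(tid="t1", gene="g1", name="", contig="c1", strand="+",
        exons=((0, 10),), source="annotA", biotype=NCRNA):
    return TranscriptModel(transcript_id=tid, gene_id=gene, gene_name=name,
                           biotype=biotype, source=source, contig_id=contig,
                           strand=strand, exons=list(exons))


class TestReadGenome:
    def test_basic_and_masking(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1\nACGT\n>c2\nacgry\n")
        g = read_genome(p)
        assert g["c1"] == "ACGT"
        # lowercase upcased, non-ACGTN masked to N
        assert g["c2"] == "ACGNN"

    def test_missing_and_empty_file(self, tmp_path):
        with pytest.raises(InputError):
            read_genome(tmp_path / "absent.fa")
        empty = tmp_path / "empty.fa"
        empty.write_text("")
        with pytest.raises(InputError):
            read_genome(empty)

    def test_write_read_round_trip(self, tmp_path):
        rng = random.Random(7)
        genome = {f"ctg{i}": random_transcript(rng, rng.randint(50, 400))
                  for i in range(100)}
        path = tmp_path / "rt.fa"
        write_genome(genome, path)
        assert read_genome(path) == genome


class TestReadAnnotation:
    def test_gtf_two_exon_mrna(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'c1\tx\ttranscript\t11\t100\t.\t+\t.\tgene_id "g"; transcript_id "t"; gene_name "GN";\n'
            'c1\tx\texon\t11\t40\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'c1\tx\texon\t61\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'c1\tx\tCDS\t15\t35\t.\t+\t0\tgene_id "g"; transcript_id "t"; protein_id "p1";\n')
        (t,) = read_annotation(p, "annotA")
        assert t.biotype == MRNA
        assert t.exons == [(10, 40), (60, 100)]  # 1-based inclusive -> 0-based
        assert t.annotated_cds == (14, 35)
        assert t.protein_id == "p1" and t.gene_name == "GN"

    def test_gff3_ncrna_without_cds(self, tmp_path):
        p = tmp_path / "b.gff3"
        p.write_text("##gff-version 3\n"
                     "c1\tx\tncRNA\t5\t64\t.\t-\t.\tID=t2;Parent=g2\n"
                     "c1\tx\texon\t5\t64\t.\t-\t.\tParent=t2\n")
        (t,) = read_annotation(p, "annotB")
        assert t.biotype == NCRNA and t.strand == "-"
        assert t.exons == [(4, 64)]

    def test_overlapping_exons_rejected(self, tmp_path):
        p = tmp_path / "c.gtf"
        p.write_text('c1\tx\texon\t1\t30\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
                     'c1\tx\texon\t20\t50\t.\t+\t.\tgene_id "g"; transcript_id "t";\n')
        with pytest.raises(ValidationError):
            read_annotation(p, "annotA")

    def test_fixture_transcript_counts_match_manifest(self, fixture_dir):
        d, manifest = fixture_dir
        for path, tag in (("annotA.gtf", "annotA"), ("annotB.gff3", "annotB")):
            txs = read_annotation(d / path, tag)
            assert len(txs) == manifest["transcript_counts"][tag]

    def test_coordinate_round_trip_is_identity(self, tmp_path):
        """1-based inclusive -> internal half-open -> 1-based is a bijection."""
        rng = random.Random(3)
        lines = []
        records = []
        for i in range(50):
            s = rng.randint(1, 5000)
            e = s + rng.randint(0, 300)
            records.append((s, e))
            lines.append(f'c1\tx\texon\t{s}\t{e}\t.\t+\t.\t'
                         f'gene_id "g{i}"; transcript_id "t{i}";\n')
        p = tmp_path / "rt.gtf"
        p.write_text("".join(lines))
        txs = read_annotation(p, "annotA")
        back = [(t.exons[0][0] + 1, t.exons[0][1]) for t in txs]
        assert sorted(back) == sorted(records)


class TestSplicedSequence:
    def test_plus_strand_concatenation(self):
        t = _tx(exons=[(0, 3), (6, 9)])
        assert spliced_sequence(t, {"c1": "AAATTTCCC"}) == "AAACCC"

    def test_minus_strand_reverse_complement(self):
        t = _tx(strand="-", exons=[(0, 6)])
        assert spliced_sequence(t, {"c1": "AAACGT"}) == "ACGTTT"

    def test_out_of_bounds(self):
        t = _tx(exons=[(0, 50)])
        with pytest.raises(ValidationError):
            spliced_sequence(t, {"c1": "ACGT"})

    @pytest.mark.parametrize("strand", "+-")
    def test_per_base_oracle_on_random_spliced_transcripts(self, strand):
        rng = random.Random(3)
        contig = random_transcript(rng, 2000)
        for _ in range(30):
            pos, exons = 0, []
            for _ in range(10):
                pos += rng.randint(1, 50)
                end = pos + rng.randint(1, 60)
                exons.append((pos, end))
                pos = end
            t = _tx(strand=strand, exons=exons)
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            bases = [contig[i] for s, e in exons for i in range(s, e)]
            expected = "".join(bases)
            if strand == "-":
                expected = "".join(comp[b] for b in reversed(bases))
            assert spliced_sequence(t, {"c1": contig}) == expected
            assert len(expected) == t.length

    def test_length_equals_exon_sum_many(self):
        rng = random.Random(17)
        contig = random_transcript(rng, 5000)
        for _ in range(1000):
            s = rng.randint(0, 4000)
            mid = s + rng.randint(1, 400)
            e = min(mid + 1 + rng.randint(1, 500), 5000)
            strand = rng.choice("+-")
            t = _tx(strand=strand, exons=[(s, mid), (mid + 1, e)])
            assert len(spliced_sequence(t, {"c1": contig})) == t.length


class TestReconcileGenes:
    def test_overlap_and_name_merge(self):
        a = _tx(tid="t1", gene="gA", name="FOO", exons=[(100, 200)], source="annotA")
        b = _tx(tid="t2", gene="gB", name="foo", exons=[(150, 260)], source="annotB")
        (g,) = reconcile_genes([a], [b])
        assert g.member_gene_ids == {("annotA", "gA"), ("annotB", "gB")}

    def test_antisense_overlap_stays_separate(self):
        a = _tx(tid="t1", gene="gA", exons=[(100, 200)], strand="+")
        b = _tx(tid="t2", gene="gB", exons=[(150, 260)], strand="-", source="annotB")
        groups = reconcile_genes([a], [b])
        assert len(groups) == 2

    def test_name_match_requires_same_contig_strand(self):
        a = _tx(tid="t1", gene="gA", name="FOO", exons=[(0, 50)], contig="c1")
        b = _tx(tid="t2", gene="gB", name="FOO", exons=[(0, 50)], contig="c2",
                source="annotB")
        assert len(reconcile_genes([a], [b])) == 2

    def test_partition_property(self):
        rng = random.Random(5)
        txs = []
        for i in range(120):
            s = rng.randint(0, 3000)
            txs.append(_tx(tid=f"t{i}", gene=f"g{i}",
                           name=rng.choice(["", f"N{i % 17}"]),
                           strand=rng.choice("+-"),
                           exons=[(s, s + rng.randint(10, 200))],
                           source=rng.choice(["annotA", "annotB"])))
        groups = reconcile_genes(txs)
        seen = [m for g in groups for m in g.member_gene_ids]
        assert len(seen) == len(set(seen))
        assert set(seen) == {(t.source, t.gene_id) for t in txs}

    def test_empty_inputs(self):
        assert reconcile_genes([], []) == []


class TestBedExport:
    def test_single_exon_row(self, tmp_path, run):
        single = [o for o in run.catalog.orfs if len(o.genomic_blocks) == 1][0]
        path = tmp_path / "one.bed"
        write_bed12([single], path)
        (row,) = read_bed12(path)
        assert row["blocks"] == single.genomic_blocks
        s, e = single.genomic_blocks[0]
        assert row["start"] == s and row["end"] == e

    def test_round_trip_identity_on_catalog(self, tmp_path, run):
        path = tmp_path / "all.bed"
        write_bed12(run.catalog.orfs, path)
        rows = read_bed12(path)
        assert len(rows) == len(run.catalog.orfs)
        for row, orf in zip(rows, run.catalog.orfs):
            assert row["blocks"] == orf.genomic_blocks
            assert row["strand"] == orf.strand
            assert row["contig"] == orf.contig_id

    def test_spliced_orf_block_arithmetic(self, run):
        spliced = [o for o in run.catalog.orfs if len(o.genomic_blocks) == 2]
        assert spliced
        for orf in spliced:
            total = sum(e - s for s, e in orf.genomic_blocks)
            assert total == 3 * len(orf.protein) + 3
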