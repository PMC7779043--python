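"""Digestion, masses, I/L-collapsed indexing, assignment rules, coverage."""

import random

import pytest

from polyorf.models import (
    ALTPROT, DISCARDED_CROSS_GENE, NOVEL_ISOFORM, PeptideObservation,
    PipelineConfig, ProteinRecord, REFPROT, REFPROT_PRIORITY,
    SHARED_NOVEL_SAME_GENE, UNIQUE, ValidationError,
)
from polyorf.ms_evidence import (
    assign_peptide, build_peptide_index, collapse_il, detectability_stats,
    digest, peptide_mass, possible_coverage, read_peptide_observations,
)

from oracles import MONO_RESIDUE, WATER_MONO, regex_digest, table_mass

CFG = PipelineConfig()


def _rec(acc, protein, gene="GG1", category=ALTPROT):
    return ProteinRecord(accession=acc, category=category, orf_id=acc,
                         gene_group_id=gene, protein=protein)


class TestDigest:
    def test_no_cleavage_before_proline(self):
        peps = [p.sequence for p in digest("MAAAKAAAARPAAAK")]
        assert peps == ["MAAAK", "AAAARPAAAK"]

    def test_missed_cleavage_expansion(self):
        seqs = {p.sequence for p in digest("KKK", missed_cleavages=1)}
        assert "KK" in seqs and "K" in seqs

    def test_positions_tile_protein_at_zero_missed(self):
        rng = random.Random(1)
        protein = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(80))
        peps = digest(protein)
        covered = sorted((p.start, p.end) for p in peps)
        assert covered[0][0] == 0 and covered[-1][1] == len(protein)
        for (s1, e1), (s2, e2) in zip(covered, covered[1:]):
            assert s2 == e1

    @pytest.mark.parametrize("missed", [0, 1, 2])
    def test_regex_oracle_random_proteins(self, missed):
        rng = random.Random(31)
        for _ in range(100):
            protein = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY")
                              for _ in range(rng.randint(5, 120)))
            got = {(p.start, p.sequence) for p in digest(protein, missed)}
            assert got == regex_digest(protein, missed)

    def test_empty_protein_rejected(self):
        with pytest.raises(ValidationError):
            digest("")


class TestPeptideMass:
    def test_glycine_against_residue_table(self):
        assert peptide_mass("G") == pytest.approx(
            MONO_RESIDUE["G"] + WATER_MONO, abs=1e-3)

    def test_random_peptides_against_residue_table(self):
        rng = random.Random(2)
        for _ in range(50):
            pep = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY")
                          for _ in range(rng.randint(1, 30)))
            assert peptide_mass(pep) == pytest.approx(table_mass(pep), abs=1e-2)

    def test_monotone_and_il_invariant(self):
        assert peptide_mass("AK") > peptide_mass("A")
        assert peptide_mass("EIGNLISDAMK") == peptide_mass("EIGNIISDAMK")

    def test_x_and_unknown_rejected(self):
        for bad in ("AXA", "AB", ""):
            with pytest.raises(ValidationError):
                peptide_mass(bad)


class TestPeptideIndex:
    def test_il_collapse_merges_isobaric_spellings(self):
        recs = [_rec("P1", "MKEIGNIISDAMK", gene="GG1", category=REFPROT),
                _rec("P2", "MKEIGNLISDAMK", gene="GG2")]
        index = build_peptide_index(recs)
        hits = index[collapse_il("EIGNLISDAMK")]
        assert {h.accession for h in hits} == {"P1", "P2"}
        assert {h.spelling for h in hits} == {"EIGNIISDAMK", "EIGNLISDAMK"}

    def test_singleton_catalog_all_keys_single(self):
        recs = [_rec("ONLY", "MAAAKCCCDDDKEEEK")]
        index = build_peptide_index(recs)
        for hits in index.values():
            assert {h.accession for h in hits} == {"ONLY"}

    def test_brute_force_substring_oracle(self, run):
        """Every indexed hit really is a tryptic fragment at that position."""
        proteins = {p.accession: p.protein for p in run.catalog.proteins}
        for collapsed, hits in run.index.items():
            for h in hits:
                assert collapse_il(h.spelling) == collapsed
                assert proteins[h.accession][h.start:h.end] == h.spelling
                expected = {(p.start, p.sequence)
                            for p in digest(proteins[h.accession])}
                assert (h.start, h.spelling) in expected


class TestAssignmentRules:
    def _index(self):
        recs = [
            _rec("P10809", "MVVTDKEIGNIISDAMKK", gene="HSPD1", category=REFPROT),
            _rec("IP_ps", "MAAGWKEIGNLISDAMK", gene="HSPD1P7"),
            _rec("IP_a", "MCCWWKSHAQEDPEPK", gene="GENEX"),
            _rec("IP_b", "MDDFFKSHAQEDPEPKW", gene="GENEX"),
            _rec("IP_c", "MEEYYKSHAQEDPEPKW", gene="GENEY"),
        ]
        return build_peptide_index(recs)

    def test_cross_gene_refprot_priority_with_respelling(self):
        """A pseudogene-supported peptide re-assigns to the parental RefProt
        under I/L collapse, reported under the reference spelling."""
        res = assign_peptide(PeptideObservation("EIGNLISDAMK", "ds1", 3),
                             self._index())
        assert res.assigned_accessions == {"P10809"}
        assert res.rule_applied == REFPROT_PRIORITY
        assert res.canonical_sequence == "EIGNIISDAMK"

    def test_shared_novel_same_gene(self):
        recs = [_rec("IP_a", "MCCWWKSHAQEDPEPK", gene="GENEX"),
                _rec("IP_b", "MDDFFKSHAQEDPEPKW", gene="GENEX")]
        res = assign_peptide(PeptideObservation("SHAQEDPEPK", "ds1", 1),
                             build_peptide_index(recs))
        assert res.assigned_accessions == {"IP_a", "IP_b"}
        assert res.rule_applied == SHARED_NOVEL_SAME_GENE

    def test_cross_gene_novel_discarded(self):
        recs = [_rec("IP_a", "MCCWWKSHAQEDPEPK", gene="GENEX"),
                _rec("IP_c", "MEEYYKSHAQEDPEPKW", gene="GENEY")]
        res = assign_peptide(PeptideObservation("SHAQEDPEPK", "ds1", 1),
                             build_peptide_index(recs))
        assert res.assigned_accessions == set()
        assert res.rule_applied == DISCARDED_CROSS_GENE

    def test_literal_rules_mode_discards_cross_gene_refprot(self):
        cfg = PipelineConfig(literal_unicity_rules=True)
        res = assign_peptide(PeptideObservation("EIGNLISDAMK", "ds1", 3),
                             self._index(), cfg)
        assert res.rule_applied == DISCARDED_CROSS_GENE
        assert res.assigned_accessions == set()

    def test_unique_and_no_match(self):
        index = self._index()
        res = assign_peptide(PeptideObservation("MVVTDK", "ds1", 1), index)
        assert res.rule_applied == UNIQUE and res.assigned_accessions == {"P10809"}
        res = assign_peptide(PeptideObservation("WWWWYYYK", "ds1", 1), index)
        assert not res.matched and res.assigned_accessions == set()

    def test_assignment_invariant_to_il_respelling(self):
        index = self._index()
        a = assign_peptide(PeptideObservation("EIGNLISDAMK", "ds1", 1), index)
        b = assign_peptide(PeptideObservation("EIGNIISDAMK", "ds1", 1), index)
        assert a.assigned_accessions == b.assigned_accessions
        assert a.canonical_sequence == b.canonical_sequence

    def test_never_coassigned_refprot_and_novel(self, run):
        novel = {p.accession for p in run.catalog.proteins
                 if p.category in (NOVEL_ISOFORM, ALTPROT)}
        refs = {p.accession for p in run.catalog.proteins
                if p.category == REFPROT}
        for res in run.assignments.values():
            assert not (res.assigned_accessions & novel
                        and res.assigned_accessions & refs)


class TestCoverage:
    def test_all_short_peptides_not_detectable(self):
        rec = _rec("P", "MAKCCKDDKEEKFFK")  # every tryptic peptide < 7 aa
        index = build_peptide_index([rec])
        assert possible_coverage(rec, index) == 0.0
        stats = detectability_stats(rec, index, [])
        assert not stats.ms_detectable

    def test_single_assignable_peptide_fraction(self):
        # 50 aa protein, one 10-aa assignable peptide -> 0.2
        pep = "CDEFGHMNW"  # + K = 10 aa
        protein = "M" + "K" * 39 + pep + "K"
        assert len(protein) == 50
        rec = _rec("P", protein)
        index = build_peptide_index([rec])
        assert possible_coverage(rec, index) == pytest.approx(0.2)

    def test_brute_force_recomputation_on_fixture(self, run):
        cfg = run.catalog.config
        for p in run.catalog.proteins:
            spans = []
            for start, pep in sorted((t.start, t.sequence)
                                     for t in digest(p.protein)):
                if len(pep) < cfg.min_pep_len or "X" in pep:
                    continue
                if peptide_mass(pep) > cfg.max_pep_mass:
                    continue
                res = assign_peptide(PeptideObservation(pep, "oracle", 1),
                                     run.index, cfg)
                if p.accession in res.assigned_accessions:
                    spans.append((start, start + len(pep)))
            covered = set()
            for s, e in spans:
                covered.update(range(s, e))
            expected = len(covered) / len(p.protein)
            assert possible_coverage(p, run.index, cfg) == pytest.approx(expected)

    def test_detected_not_above_possible(self, run):
        for p in run.catalog.proteins:
            s = detectability_stats(p, run.index, run.observations,
                                    run.catalog.config)
            assert 0 <= s.detected_coverage <= s.possible_coverage <= 1


class TestDetectabilityStats:
    def test_no_observations(self, run):
        p = run.catalog.proteins[0]
        s = detectability_stats(p, run.index, [], run.catalog.config)
        assert (s.n_datasets, s.n_unique_peptides, s.n_psms) == (0, 0, 0)
        assert s.detected_coverage == 0.0

    def test_two_datasets_aggregation(self, run, label_to_record):
        """The unique isoform-gene peptide is seen in two datasets (3+2 PSMs)."""
        rec = label_to_record["R_ISO"]
        s = detectability_stats(rec, run.index, run.observations,
                                run.catalog.config)
        assert s.n_datasets == 2 and s.n_unique_peptides == 1 and s.n_psms == 5

    def test_brute_force_aggregation_oracle(self, run):
        for p in run.catalog.proteins:
            datasets, seqs, psms = set(), set(), 0
            for obs in run.observations:
                res = run.assignments[obs.sequence]
                if p.accession in res.assigned_accessions:
                    datasets.add(obs.dataset_id)
                    seqs.add(res.canonical_sequence)
                    psms += obs.psm_count
            s = detectability_stats(p, run.index, run.observations,
                                    run.catalog.config)
            assert (s.n_datasets, s.n_unique_peptides, s.n_psms) == \
                   (len(datasets), len(seqs), psms)

    def test_order_invariance(self, run, label_to_record):
        rec = label_to_record["R_ISO"]
        fwd = detectability_stats(rec, run.index, run.observations)
        rev = detectability_stats(rec, run.index, run.observations[::-1])
        assert fwd == rev

    def test_psm_accounting(self, run):
        """Per-protein PSM totals add up to each observation's PSMs times the
        number of proteins it was assigned to; discarded and unmatched
        peptides contribute nothing."""
        total_assigned = 0
        for p in run.catalog.proteins:
            s = detectability_stats(p, run.index, run.observations,
                                    run.catalog.config)
            total_assigned += s.n_psms
        expected = sum(
            o.psm_count * len(run.assignments[o.sequence].assigned_accessions)
            for o in run.observations)
        assert total_assigned == expected
        total = sum(o.psm_count for o in run.observations)
        assert expected < total * max(
            len(r.assigned_accessions) for r in run.assignments.values()) + 1


class TestObservationIO:
    def test_reader_tolerates_extra_columns(self, fixture_dir):
        d, manifest = fixture_dir
        obs = read_peptide_observations(d / "peptides.tsv")
        expected_rows = sum(len(p["rows"]) for p in manifest["peptides"])
        assert len(obs) == expected_rows
        assert all(o.psm_count >= 1 for o in obs)

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("peptide\tcount\nAAA\t1\n")
        with pytest.raises(ValidationError):
            read_peptide_observations(p)
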