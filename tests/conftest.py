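from __future__ import annotations

import logging
from types import SimpleNamespace

import pytest

import polyorf as po
from polyorf.ms_evidence import (
    assign_peptide, build_peptide_index, read_peptide_observations,
)
from polyorf.pipeline import compute_isoform_edges
from polyorf.ribo_evidence import filter_calls, read_orf_calls

logging.getLogger("polyorf").setLevel(logging.ERROR)

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A generated synthetic input directory plus its manifest."""
    d = tmp_path_factory.mktemp("fixture")
    manifest = po.generate_fixture(d, seed=FIXTURE_SEED)
    return d, manifest


@pytest.fixture(scope="session")
def run(fixture_dir):
    """The default-config pipeline executed on the session fixture."""
    d, manifest = fixture_dir
    outdir = d / "catalog"
    catalog = po.run_pipeline(
        d / "genome.fa",
        [(d / "annotA.gtf", "annotA"), (d / "annotB.gff3", "annotB")],
        outdir,
        reference_fasta=d / "reference.fasta", gene_xref=d / "xref.tsv",
        peptides_path=d / "peptides.tsv", ribo_calls_path=d / "ribo_calls.tsv",
    )
    edges, trees = compute_isoform_edges(catalog)
    index = build_peptide_index(catalog.proteins, catalog.config)
    observations = read_peptide_observations(d / "peptides.tsv")
    assignments = {o.sequence: assign_peptide(o, index, catalog.config)
                   for o in observations}
    calls = read_orf_calls(d / "ribo_calls.tsv",
                           {t.transcript_id for t in catalog.transcripts})
    events = filter_calls(calls, catalog, catalog.config)
    return SimpleNamespace(
        dir=d, outdir=outdir, manifest=manifest, catalog=catalog, edges=edges,
        trees=trees, index=index, observations=observations,
        assignments=assignments, calls=calls, events=events,
    )


@pytest.fixture()
def label_to_record(run):
    by_protein = {p.protein: p for p in run.catalog.proteins}
    return {e["label"]: by_protein[e["protein"]]
            for e in run.manifest["planted_proteins"]}
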