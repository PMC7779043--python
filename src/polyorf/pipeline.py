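"""End-to-end run: ingest -> predict -> categorize -> isoforms -> MS
evidence -> ribo evidence -> export, with a run manifest echoing every
configuration value, input digests and per-stage record counts. Evidence
stages are skipped when their input table is absent. The whole pipeline is
deterministic: identical inputs and config give bitwise-identical outputs
(timestamps live only in the run manifest)."""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

from . import __version__
from .models import Catalog, PipelineConfig, logger
from .annotation_io import read_annotation, read_genome, save_catalog
from .protein_catalog import build_catalog
from .isoform_graph import related_proteins, isoform_tree, write_edges_tsv, write_trees_json
from .ms_evidence import (
    build_peptide_index, assign_peptide, detectability_stats,
    read_peptide_observations, write_assignments_tsv, write_stats_tsv,
)
from .ribo_evidence import (
    aggregate_translation_evidence, filter_calls, read_orf_calls,
    write_events_tsv, write_summary_tsv,
)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def compute_isoform_edges(catalog: Catalog):
    """All-versus-all related-protein calling, gene group by gene group."""
    by_group: dict[str, list] = {}
    for p in catalog.proteins:
        by_group.setdefault(p.gene_group_id, []).append(p)
    edges, trees = [], {}
    for group_id in sorted(by_group):
        group_edges = related_proteins(by_group[group_id], catalog.config)
        edges.extend(group_edges)
        trees[group_id] = isoform_tree(group_edges, by_group[group_id])
    return edges, trees


def run_pipeline(genome_path, annotation_paths: list[tuple[str, str]],
                 outdir, config: PipelineConfig | None = None,
                 reference_fasta=None, gene_xref=None,
                 peptides_path=None, ribo_calls_path=None) -> Catalog:
    """Execute every stage and write the catalog directory.

    ``annotation_paths`` is a list of (path, source_tag) with one or two
    entries. Returns the built Catalog.
    """
    cfg = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()

    genome = read_genome(genome_path)
    transcripts = []
    for path, tag in annotation_paths:
        transcripts.extend(read_annotation(path, tag))
    logger.info("loaded %d transcripts from %d annotation(s)",
                len(transcripts), len(annotation_paths))

    catalog = build_catalog(genome, transcripts, cfg,
                            external_fasta=reference_fasta, gene_xref=gene_xref)
    save_catalog(catalog, outdir)

    edges, trees = compute_isoform_edges(catalog)
    write_edges_tsv(edges, outdir / "isoform_edges.tsv")
    write_trees_json(trees, outdir / "isoform_trees.json")

    counts = {
        "transcripts": len(catalog.transcripts),
        "gene_groups": len(catalog.gene_groups),
        "orfs": len(catalog.orfs),
        "proteins": len(catalog.proteins),
        "isoform_edges": len(edges),
    }

    index = build_peptide_index(catalog.proteins, cfg)
    if peptides_path:
        observations = read_peptide_observations(peptides_path)
        results = [assign_peptide(o, index, cfg) for o in observations]
        for res in results:
            if not res.matched:
                logger.warning("observed peptide %s matches no catalogued "
                               "protein (dropped by no-match filter)",
                               res.observed_sequence)
        write_assignments_tsv(results, observations, outdir / "peptide_assignments.tsv")
        counts["peptide_observations"] = len(observations)
    else:
        observations = []
        logger.info("no peptide table given; MS assignment stage skipped")
    stats = [detectability_stats(p, index, observations, cfg)
             for p in catalog.proteins]
    write_stats_tsv(stats, outdir / "protein_stats.tsv")

    if ribo_calls_path:
        known = {t.transcript_id for t in catalog.transcripts}
        calls = read_orf_calls(ribo_calls_path, known)
        events = filter_calls(calls, catalog, cfg)
        write_events_tsv(events, outdir / "ribo_events.tsv")
        write_summary_tsv(aggregate_translation_evidence(events),
                          outdir / "ribo_summary.tsv")
        counts["ribo_calls"] = len(calls)
        counts["ribo_events_accepted"] = len(events)
    else:
        logger.info("no ribo-call table given; translation stage skipped")

    inputs = {"genome": str(genome_path)}
    for i, (path, tag) in enumerate(annotation_paths):
        inputs[f"annotation_{tag}"] = str(path)
    for name, path in (("reference_fasta", reference_fasta),
                       ("gene_xref", gene_xref),
                       ("peptides", peptides_path),
                       ("ribo_calls", ribo_calls_path)):
        if path:
            inputs[name] = str(path)
    run_manifest = {
        "tool_version": __version__,
        "config": cfg.to_dict(),
        "inputs": {k: {"path": v, "sha256": _sha256(v)} for k, v in inputs.items()},
        "started": started,
        "finished": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "record_counts": counts,
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return catalog
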