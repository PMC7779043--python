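"""Within-gene protein relationships by local alignment.

All-versus-all Smith–Waterman (BLOSUM62, gap open 11 / extend 1) between the
proteins of one gene group; raw scores are rescaled to bit scores with fixed
Karlin–Altschul constants for gapped BLOSUM62 (lambda = 0.267, K = 0.041), so
edges are database-size independent. A pair is related when either query
direction reaches bit score > 40 with the alignment spanning > 50% of the
queried sequence. Related proteins are then single-linkage clustered into
per-gene protein trees.
"""

from __future__ import annotations

import json
import math
import os
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .models import IsoformEdge, PipelineConfig, ProteinRecord, ValidationError


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST-style affine gap of length k costs 11 + k
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


def local_align(query: str, subject: str) -> tuple[float, int, tuple[int, int]]:
    """Best local alignment of query vs subject.

    Returns (raw_score, identical_positions, (query_span_start, query_span_end)).
    A pair with no positive-scoring segment gets score 0 and an empty span.
    """
    if not query or not subject:
        raise ValidationError("local_align requires non-empty sequences")
    aligner = _aligner()
    score = aligner.score(query, subject)
    if score <= 0:
        return 0.0, 0, (0, 0)
    best = aligner.align(query, subject)[0]
    q_segments, s_segments = best.aligned
    identical = 0
    for (qs, qe), (ss, _) in zip(q_segments, s_segments):
        for k in range(qe - qs):
            if query[qs + k] == subject[ss + k]:
                identical += 1
    span = (int(q_segments[0][0]), int(q_segments[-1][1]))
    return float(best.score), identical, span


def bit_score(raw_score: float, cfg: PipelineConfig | None = None) -> float:
    """Karlin–Altschul rescaling: bits = (lambda * S - ln K) / ln 2."""
    cfg = cfg or PipelineConfig()
    return (cfg.ka_lambda * raw_score - math.log(cfg.ka_k)) / math.log(2)


def related_proteins(gene_proteins: list[ProteinRecord],
                     cfg: PipelineConfig | None = None) -> list[IsoformEdge]:
    """Emit related-protein edges for one gene group.

    Both query directions are evaluated per unordered pair; the edge records
    the passing direction (the stronger one when both pass). Output order is
    deterministic: bit score descending, then query/subject accession.
    """
    cfg = cfg or PipelineConfig()
    groups = {p.gene_group_id for p in gene_proteins}
    if len(groups) > 1:
        raise ValidationError(f"related_proteins spans gene groups {groups}")
    edges = []
    recs = sorted(gene_proteins, key=lambda p: p.accession)
    for i, a in enumerate(recs):
        for b in recs[i + 1:]:
            candidates = []
            for q, s in ((a, b), (b, a)):
                raw, ident, (qs, qe) = local_align(q.protein, s.protein)
                bits = bit_score(raw, cfg)
                coverage = (qe - qs) / len(q.protein)
                if bits > cfg.bit_threshold and coverage > cfg.query_coverage_threshold:
                    candidates.append(IsoformEdge(
                        query_accession=q.accession,
                        subject_accession=s.accession,
                        raw_score=raw, bit_score=bits,
                        query_coverage=coverage,
                        identity_fraction=ident / len(q.protein),
                        gene_group_id=q.gene_group_id,
                    ))
            if candidates:
                candidates.sort(key=lambda e: (-e.bit_score, e.query_accession))
                edges.append(candidates[0])
    edges.sort(key=lambda e: (-e.bit_score, e.query_accession, e.subject_accession))
    return edges


def isoform_tree(edges: list[IsoformEdge],
                 gene_proteins: list[ProteinRecord]) -> dict:
    """Single-linkage protein tree for one gene.

    Clusters are the connected components of the edge set. For every protein
    (focal node) its cluster co-members are ordered by descending bit score
    to the focal protein, ties by accession; unrelated proteins are
    singletons.
    """
    accs = sorted(p.accession for p in gene_proteins)
    parent = {a: a for a in accs}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    best_bits: dict[tuple[str, str], float] = {}
    for e in edges:
        ra, rb = find(e.query_accession), find(e.subject_accession)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
        for key in ((e.query_accession, e.subject_accession),
                    (e.subject_accession, e.query_accession)):
            best_bits[key] = max(best_bits.get(key, 0.0), e.bit_score)

    clusters: dict[str, list[str]] = {}
    for a in accs:
        clusters.setdefault(find(a), []).append(a)

    tree = {"clusters": [], "singletons": [], "nodes": {}}
    for members in sorted(clusters.values()):
        if len(members) == 1:
            tree["singletons"].append(members[0])
            continue
        tree["clusters"].append(sorted(members))
        for focal in members:
            children = sorted(
                (m for m in members if m != focal),
                key=lambda m: (-best_bits.get((focal, m), 0.0), m))
            tree["nodes"][focal] = children
    return tree


def write_edges_tsv(edges: list[IsoformEdge], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("query\tsubject\traw_score\tbit_score\tquery_coverage\t"
                 "identity_fraction\tgene_group\n")
        for e in edges:
            fh.write(f"{e.query_accession}\t{e.subject_accession}\t{e.raw_score:g}\t"
                     f"{e.bit_score:.3f}\t{e.query_coverage:.4f}\t"
                     f"{e.identity_fraction:.4f}\t{e.gene_group_id}\n")


def write_trees_json(trees: dict[str, dict], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(trees, fh, indent=1, sort_keys=True)
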