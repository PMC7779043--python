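"""In-silico tryptic digestion, peptide unicity and detectability statistics.

Digestion cleaves C-terminal to K or R except before P (pyteomics). Peptide
masses are monoisotopic, unmodified, uncharged, water included. Peptide
matching treats the isobaric residues I and L as indistinguishable: the
index key collapses every I to L, while original spellings are kept so a
re-assigned peptide can be reported under the matched reference spelling
(e.g. an observed EIGNLISDAMK supported only by a pseudogene product is
re-assigned as EIGNIISDAMK to the parental-gene RefProt).

Assignment rules for a peptide matching multiple proteins: a match to any
RefProt hands the peptide to the matching RefProt(s) only; otherwise matches
spanning several genes discard the peptide; otherwise the peptide goes to
all matching novel proteins of the single gene. (A literal mode discarding
every cross-gene peptide first is available via
PipelineConfig.literal_unicity_rules.)
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd
from pyteomics import mass as pyt_mass
from pyteomics import parser as pyt_parser

from .models import (
    AssignmentResult, DISCARDED_CROSS_GENE, DetectabilityStats,
    PeptideObservation, PipelineConfig, ProteinRecord, REFPROT,
    REFPROT_PRIORITY, SHARED_NOVEL_SAME_GENE, UNIQUE, ValidationError, logger,
)

TRYPSIN_RULE = r"[KR](?!P)"
_CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class TrypticPeptide:
    sequence: str
    start: int
    end: int
    mass: float | None = None
    assignable: bool = False


@dataclass(frozen=True)
class IndexHit:
    accession: str
    category: str
    gene_group_id: str
    spelling: str
    start: int
    end: int


def digest(protein: str, missed_cleavages: int = 0) -> list[TrypticPeptide]:
    """Tryptic peptides of a protein with positions (0-based half-open)."""
    if not protein:
        raise ValidationError("cannot digest an empty protein")
    seen = set()
    peptides = []
    for start, pep in pyt_parser.icleave(protein, TRYPSIN_RULE,
                                         missed_cleavages=missed_cleavages):
        key = (start, len(pep))
        if pep and key not in seen:
            seen.add(key)
            peptides.append(TrypticPeptide(sequence=pep, start=start,
                                           end=start + len(pep)))
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def peptide_mass(sequence: str) -> float:
    """Monoisotopic, unmodified, uncharged peptide mass in Da."""
    if not sequence or set(sequence) - _CANONICAL:
        raise ValidationError(
            f"peptide {sequence!r} contains non-canonical residues")
    return pyt_mass.fast_mass(sequence)


def collapse_il(sequence: str) -> str:
    return sequence.replace("I", "L")


def build_peptide_index(proteins: list[ProteinRecord],
                        cfg: PipelineConfig | None = None) -> dict[str, list[IndexHit]]:
    """I/L-collapsed peptide -> every protein carrying it as a tryptic
    fragment at the configured missed cleavages, with the original spelling
    and position."""
    cfg = cfg or PipelineConfig()
    index: dict[str, list[IndexHit]] = {}
    for p in sorted(proteins, key=lambda r: r.accession):
        for pep in digest(p.protein, cfg.missed_cleavages):
            index.setdefault(collapse_il(pep.sequence), []).append(IndexHit(
                accession=p.accession, category=p.category,
                gene_group_id=p.gene_group_id, spelling=pep.sequence,
                start=pep.start, end=pep.end,
            ))
    return index


def _resolve(collapsed: str, index: dict[str, list[IndexHit]],
             cfg: PipelineConfig) -> tuple[set[str], str, str | None]:
    """Shared assignment logic: (accessions, rule, canonical spelling)."""
    hits = index.get(collapsed, [])
    if not hits:
        return set(), UNIQUE, None
    gene_groups = {h.gene_group_id for h in hits}
    ref_hits = [h for h in hits if h.category == REFPROT]

    if cfg.literal_unicity_rules and len(gene_groups) > 1:
        return set(), DISCARDED_CROSS_GENE, None
    if ref_hits:
        accs = {h.accession for h in ref_hits}
        canonical = sorted(ref_hits, key=lambda h: h.accession)[0].spelling
        rule = UNIQUE if len(hits) == 1 else REFPROT_PRIORITY
        return accs, rule, canonical
    if len(gene_groups) > 1:
        return set(), DISCARDED_CROSS_GENE, None
    accs = {h.accession for h in hits}
    canonical = sorted(hits, key=lambda h: h.accession)[0].spelling
    rule = UNIQUE if len(accs) == 1 else SHARED_NOVEL_SAME_GENE
    return accs, rule, canonical


def assign_peptide(obs: PeptideObservation, index: dict[str, list[IndexHit]],
                   cfg: PipelineConfig | None = None) -> AssignmentResult:
    """Apply the unicity rules to one observed peptide (I/L collapsed)."""
    cfg = cfg or PipelineConfig()
    collapsed = collapse_il(obs.sequence.upper())
    accs, rule, canonical = _resolve(collapsed, index, cfg)
    if not accs and rule == UNIQUE:
        logger.debug("observed peptide %s matches no catalogued protein",
                     obs.sequence)
        return AssignmentResult(observed_sequence=obs.sequence,
                                canonical_sequence=obs.sequence,
                                assigned_accessions=set(),
                                rule_applied=UNIQUE, matched=False)
    return AssignmentResult(
        observed_sequence=obs.sequence,
        canonical_sequence=canonical if canonical is not None else obs.sequence,
        assigned_accessions=accs,
        rule_applied=rule,
        matched=True,
    )


def assignable_peptides(p: ProteinRecord, index: dict[str, list[IndexHit]],
                        cfg: PipelineConfig | None = None) -> list[TrypticPeptide]:
    """Tryptic peptides of p that satisfy length/mass limits and whose
    assignment under the unicity rules would include p."""
    cfg = cfg or PipelineConfig()
    out = []
    for pep in digest(p.protein, cfg.missed_cleavages):
        if len(pep.sequence) < cfg.min_pep_len:
            continue
        if set(pep.sequence) - _CANONICAL:  # X etc. never assignable
            continue
        m = peptide_mass(pep.sequence)
        if m > cfg.max_pep_mass:
            continue
        accs, _, _ = _resolve(collapse_il(pep.sequence), index, cfg)
        if p.accession in accs:
            out.append(TrypticPeptide(pep.sequence, pep.start, pep.end,
                                      mass=m, assignable=True))
    return out


def _span_union(spans: list[tuple[int, int]]) -> int:
    total, prev_end = 0, -1
    for s, e in sorted(spans):
        s = max(s, prev_end)
        if e > s:
            total += e - s
            prev_end = e
        prev_end = max(prev_end, e)
    return total


def possible_coverage(p: ProteinRecord, index: dict[str, list[IndexHit]],
                      cfg: PipelineConfig | None = None) -> float:
    """Theoretical MS coverage: union of assignable tryptic peptide spans
    over the protein length; 0.0 means not MS-detectable."""
    peps = assignable_peptides(p, index, cfg)
    return _span_union([(pep.start, pep.end) for pep in peps]) / len(p.protein)


def detectability_stats(p: ProteinRecord, index: dict[str, list[IndexHit]],
                        observations: list[PeptideObservation],
                        cfg: PipelineConfig | None = None) -> DetectabilityStats:
    """Per-protein detection summary from an observation table."""
    cfg = cfg or PipelineConfig()
    possible = possible_coverage(p, index, cfg)
    datasets: set[str] = set()
    canonical_seqs: set[str] = set()
    n_psms = 0
    spans: list[tuple[int, int]] = []
    for obs in observations:
        res = assign_peptide(obs, index, cfg)
        if p.accession not in res.assigned_accessions:
            continue
        datasets.add(obs.dataset_id)
        canonical_seqs.add(res.canonical_sequence)
        n_psms += obs.psm_count
        collapsed = collapse_il(obs.sequence.upper())
        for hit in index.get(collapsed, []):
            if hit.accession == p.accession:
                spans.append((hit.start, hit.end))
    detected = _span_union(spans) / len(p.protein)
    return DetectabilityStats(
        accession=p.accession, n_datasets=len(datasets),
        n_unique_peptides=len(canonical_seqs), n_psms=n_psms,
        possible_coverage=possible, detected_coverage=detected,
        ms_detectable=possible > 0,
    )


# ---------------------------------------------------------------------------
# I/O

def read_peptide_observations(path: str | os.PathLike) -> list[PeptideObservation]:
    """Peptide observation TSV: columns peptide, dataset_id, psm_count
    (extra columns from PeptideShaker-style reports are ignored)."""
    df = pd.read_csv(path, sep="\t")
    required = {"peptide", "dataset_id", "psm_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"peptide table missing columns: {sorted(missing)}")
    observations = []
    for row in df.itertuples(index=False):
        try:
            observations.append(PeptideObservation(
                sequence=str(row.peptide), dataset_id=str(row.dataset_id),
                psm_count=int(row.psm_count)))
        except (ValueError, ValidationError) as exc:
            logger.warning("peptide row %r rejected: %s", tuple(row), exc)
    return observations


def write_assignments_tsv(results: list[AssignmentResult],
                          observations: list[PeptideObservation],
                          path: str | os.PathLike) -> None:
    rows = []
    for obs, res in zip(observations, results):
        rows.append({
            "peptide": obs.sequence, "dataset_id": obs.dataset_id,
            "psm_count": obs.psm_count, "canonical_sequence": res.canonical_sequence,
            "rule": res.rule_applied, "matched": res.matched,
            "assigned_accessions": ";".join(sorted(res.assigned_accessions)),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_stats_tsv(stats: list[DetectabilityStats], path: str | os.PathLike) -> None:
    pd.DataFrame([{
        "accession": s.accession, "n_datasets": s.n_datasets,
        "n_unique_peptides": s.n_unique_peptides, "n_psms": s.n_psms,
        "possible_coverage": round(s.possible_coverage, 6),
        "detected_coverage": round(s.detected_coverage, 6),
        "ms_detectable": s.ms_detectable,
    } for s in stats]).to_csv(path, sep="\t", index=False)
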