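"""Ribosome-profiling ORF-call reconciliation.

External ORF calls (PRICE-like rows: transcript, span, initiating codon,
generalized-binomial-test p-value) are matched to predicted ORFs on the same
transcript. Overlap requires the same frame and the same stop position; the
fraction is shared in-frame codons over the longer of the two ORFs, and a
call is accepted when the fraction strictly exceeds the 70% threshold. The
initiating codon is recorded verbatim — non-AUG starts enter the catalog
here, with the call p-value passed through as the start-codon confidence.
"""

from __future__ import annotations

import os

import pandas as pd

from .models import (
    Catalog, PipelineConfig, PredictedORF, RiboORFCall, TranslationEvidence,
    ValidationError, logger,
)


def read_orf_calls(path: str | os.PathLike,
                   known_transcripts: set[str] | None = None) -> list[RiboORFCall]:
    """Read an ORF-call TSV (dataset_id, transcript_id, start, stop, codon,
    p_value). Rows with non-numeric coordinates or p-values are rejected
    with a warning; rows naming unknown transcripts are kept but flagged."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"dataset_id", "transcript_id", "start", "stop", "codon", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"ORF-call table missing columns: {sorted(missing)}")
    calls = []
    for row in df.itertuples(index=False):
        try:
            call = RiboORFCall(
                dataset_id=str(row.dataset_id),
                transcript_id=str(row.transcript_id),
                tx_start=int(row.start), tx_end=int(row.stop),
                init_codon=str(row.codon).upper(),
                p_value=float(row.p_value),
            )
        except (TypeError, ValueError, ValidationError) as exc:
            logger.warning("ORF-call row %r rejected: %s", tuple(row), exc)
            continue
        if known_transcripts is not None and call.transcript_id not in known_transcripts:
            call.matched = False
            logger.warning("ORF call on unknown transcript %s flagged unmatched",
                           call.transcript_id)
        calls.append(call)
    return calls


def overlap_fraction(call: RiboORFCall, orf: PredictedORF) -> float:
    """Shared in-frame codons over max(call codons, ORF codons); zero unless
    the call shares the ORF's frame and stop position."""
    if call.transcript_id not in orf.transcript_ids:
        return 0.0
    if call.tx_end != orf.tx_end:
        return 0.0
    if (call.tx_start - orf.tx_start) % 3 != 0:
        return 0.0
    call_codons = (call.tx_end - call.tx_start) // 3
    orf_codons = (orf.tx_end - orf.tx_start) // 3
    if call_codons <= 0 or orf_codons <= 0:
        return 0.0
    shared = min(call_codons, orf_codons)
    return shared / max(call_codons, orf_codons)


def filter_calls(calls: list[RiboORFCall], catalog: Catalog,
                 cfg: PipelineConfig | None = None) -> list[TranslationEvidence]:
    """Match each call to the predicted ORF with maximal overlap on its
    transcript and accept it when the overlap strictly exceeds the
    threshold."""
    cfg = cfg or PipelineConfig()
    by_transcript: dict[str, list[PredictedORF]] = {}
    for orf in catalog.orfs:
        for tid in orf.transcript_ids:
            by_transcript.setdefault(tid, []).append(orf)
    events = []
    for call in calls:
        candidates = by_transcript.get(call.transcript_id, [])
        best, best_frac = None, 0.0
        for orf in candidates:
            frac = overlap_fraction(call, orf)
            if frac > best_frac:
                best, best_frac = orf, frac
        if best is None or best_frac <= cfg.ribo_overlap_threshold:
            logger.info("ribo call %s:%d-%d rejected by overlap filter (%.3f)",
                        call.transcript_id, call.tx_start, call.tx_end, best_frac)
            continue
        events.append(TranslationEvidence(
            orf_id=best.orf_id, dataset_id=call.dataset_id,
            init_codon=call.init_codon, overlap_fraction=best_frac,
            p_value=call.p_value,
        ))
    return events


def aggregate_translation_evidence(events: list[TranslationEvidence]) -> dict[str, dict]:
    """Per-ORF summary: distinct datasets, best (minimum) p-value, sorted
    deduplicated initiating codons. ORFs without events are absent."""
    summary: dict[str, dict] = {}
    for e in events:
        s = summary.setdefault(e.orf_id, {"datasets": set(), "best_p_value": 1.0,
                                          "init_codons": set()})
        s["datasets"].add(e.dataset_id)
        s["best_p_value"] = min(s["best_p_value"], e.p_value)
        s["init_codons"].add(e.init_codon)
    return {
        orf_id: {
            "n_datasets": len(s["datasets"]),
            "best_p_value": s["best_p_value"],
            "init_codons": sorted(s["init_codons"]),
        }
        for orf_id, s in summary.items()
    }


def write_events_tsv(events: list[TranslationEvidence], path: str | os.PathLike) -> None:
    pd.DataFrame([{
        "orf_id": e.orf_id, "dataset_id": e.dataset_id, "init_codon": e.init_codon,
        "overlap_fraction": round(e.overlap_fraction, 6), "p_value": e.p_value,
    } for e in events]).to_csv(path, sep="\t", index=False)


def write_summary_tsv(summary: dict[str, dict], path: str | os.PathLike) -> None:
    pd.DataFrame([{
        "orf_id": orf_id, "n_datasets": s["n_datasets"],
        "best_p_value": s["best_p_value"],
        "init_codons": ";".join(s["init_codons"]),
    } for orf_id, s in sorted(summary.items())]).to_csv(path, sep="\t", index=False)
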