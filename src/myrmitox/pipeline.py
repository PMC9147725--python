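"""End-to-end venom-component triage over one dataset.

Steps, mirroring the analysis workflow: exact-redundancy removal of the
transcripts, six-frame ORF extraction, local-alignment annotation against the
labeled toxin panel with E-value filtering and similarity/coverage ranking,
proteomic verification from the PSM table, TPM quantification with colony
averaging and gland-enrichment flagging, per-family composition summaries,
EGF-like toxin mining and characterization, and barcode-based species
verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import barcode as bc
from .annotate import AlignmentHit, ScoringScheme, annotate_orfs
from .egf import EgfPrecursor, characterize, mine_egf, parse_hormone_panel
from .evidence import summaries_to_frame, verified_set, verify_candidates
from .quantify import (
    CompositionRow,
    composition_summary,
    compute_tpm,
    enrichment_table,
    mean_tpm,
)
from .sequence import dedupe_exact, find_orfs
from .simulate import Dataset


@dataclass(frozen=True)
class VenomCandidate:
    """An annotated ORF with its family, proteomic evidence and expression."""

    orf_id: str
    transcript_id: str
    family: str
    top_hit: AlignmentHit
    proteome_verified: bool
    mean_gland_tpm: float
    mean_body_tpm: float
    enrichment: str


@dataclass
class PipelineResult:
    candidates: list[VenomCandidate]
    composition: list[CompositionRow]
    egf_precursors: list[EgfPrecursor]
    species_tally: dict[str, int]
    tpm: pd.DataFrame
    means: pd.DataFrame
    evidence: pd.DataFrame
    n_orfs: int = 0
    n_transcripts: int = 0
    n_duplicates_removed: int = 0


def run_pipeline(
    dataset: Dataset,
    min_aa: int = 10,
    scheme: ScoringScheme | None = None,
    min_score: float = 30.0,
    min_peptides: int = 2,
    fdr_q: float = 0.01,
    require_verified: bool = False,
    predicted_signal_len: int = 28,
) -> PipelineResult:
    """Run the full triage on a dataset and return all intermediate products.

    ``require_verified`` restricts the candidate list (and composition) to
    proteome-verified ORFs, the rule used for the species-level inventories;
    the default keeps all annotated candidates so transcriptome-only toxins
    (such as most EGF precursors) stay visible.
    """
    scheme = scheme or ScoringScheme()

    records, removed = dedupe_exact(dataset.transcripts)
    orfs = [o for rec in records for o in find_orfs(rec, min_aa=min_aa)]

    annotations = annotate_orfs(orfs, dataset.panel, scheme)

    if len(dataset.psm_table):
        summaries = verify_candidates(
            dataset.psm_table, min_score=min_score, min_peptides=min_peptides, q=fdr_q
        )
    else:
        summaries = {}
    verified = verified_set(summaries)

    tpm = compute_tpm(dataset.count_table) if len(dataset.count_table) else pd.DataFrame()
    means = mean_tpm(tpm) if len(tpm) else pd.DataFrame(columns=["mean_gland", "mean_body"])
    enriched = enrichment_table(means) if len(means) else means

    candidates: list[VenomCandidate] = []
    for orf in orfs:
        ann = annotations[orf.orf_id]
        if ann["top"] is None:
            continue
        g = float(means.at[orf.transcript_id, "mean_gland"]) if orf.transcript_id in means.index else 0.0
        b = float(means.at[orf.transcript_id, "mean_body"]) if orf.transcript_id in means.index else 0.0
        cat = (
            str(enriched.at[orf.transcript_id, "category"])
            if len(enriched) and orf.transcript_id in enriched.index
            else "not_enriched"
        )
        candidates.append(
            VenomCandidate(
                orf_id=orf.orf_id,
                transcript_id=orf.transcript_id,
                family=ann["family"],
                top_hit=ann["top"],
                proteome_verified=orf.orf_id in verified,
                mean_gland_tpm=g,
                mean_body_tpm=b,
                enrichment=cat,
            )
        )
    if require_verified:
        candidates = [c for c in candidates if c.proteome_verified]

    if candidates:
        composition = composition_summary(
            {c.orf_id: c.family for c in candidates},
            {c.orf_id: c.mean_gland_tpm for c in candidates},
        )
    else:
        composition = []

    egf_precursors: list[EgfPrecursor] = []
    if dataset.egf_seeds:
        mined = mine_egf(orfs, dataset.egf_seeds)
        reference_signal = None
        for seed in dataset.egf_seeds:
            for token in seed.description.split():
                if token.startswith("signal="):
                    reference_signal = int(token.split("=", 1)[1])
        hormones = (
            parse_hormone_panel(dataset.hormone_panel) if dataset.hormone_panel else None
        )
        abundance = (
            {tid: float(means.at[tid, "mean_gland"]) for tid in means.index}
            if len(means)
            else None
        )
        egf_precursors = characterize(
            mined,
            species_tag=dataset.manifest.species_tag,
            predicted_signal_len=predicted_signal_len,
            reference_signal_len=reference_signal,
            hormone_panel=hormones,
            verified_orfs=verified,
            abundance=abundance,
        )

    species_tally: dict[str, int] = {}
    if dataset.barcode_reads:
        over = bc.extract_overrepresented(dataset.barcode_reads)
        derep = bc.derep_prefix(over)
        queries = [(f"OVR{i:03d}", seq) for i, seq in enumerate(sorted(derep))]
        _, species_tally = bc.species_call(queries, dataset.barcode_db)

    return PipelineResult(
        candidates=candidates,
        composition=composition,
        egf_precursors=egf_precursors,
        species_tally=species_tally,
        tpm=tpm,
        means=means,
        evidence=summaries_to_frame(summaries),
        n_orfs=len(orfs),
        n_transcripts=len(records),
        n_duplicates_removed=len(removed),
    )


def recovery_metrics(dataset: Dataset, result: PipelineResult) -> dict:
    """Score pipeline output against the generator's ground truth."""
    manifest = dataset.manifest
    toxins = manifest.toxin_ids()
    by_transcript: dict[str, set[str]] = {}
    for c in result.candidates:
        by_transcript.setdefault(c.transcript_id, set()).add(c.family)
    recovered = [t for t in toxins if manifest.entries[t].family in by_transcript.get(t, set())]
    planted_egf = {
        manifest.entries[t].orf_id for t in toxins if manifest.entries[t].family == "EGF"
    }
    mined_egf = {p.source_orf for p in result.egf_precursors}
    return {
        "n_planted": len(toxins),
        "n_recovered": len(recovered),
        "recovery_pct": 100.0 * len(recovered) / len(toxins) if toxins else float("nan"),
        "egf_planted": len(planted_egf),
        "egf_mined": len(mined_egf),
        "egf_true_positives": len(planted_egf & mined_egf),
        "egf_false_positives": len(mined_egf - planted_egf),
        "majority_species": max(result.species_tally, key=result.species_tally.get)
        if result.species_tally
        else None,
    }
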