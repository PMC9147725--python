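"""Decoy-FDR filtering of peptide-spectrum matches and candidate verification.

PSMs carry an explicit decoy flag, so the FDR estimate at a score threshold t
is simply (#decoys >= t) / (#targets >= t).  Verification applies, in order:
drop decoys, drop PSMs below max(min_score, FDR cutoff), then require at
least ``min_peptides`` distinct peptide sequences per ORF.  Peptides mapping
to several ORFs count for each (no parsimony grouping).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

PSM_COLUMNS = ["peptide", "orf_id", "score", "is_decoy"]


@dataclass(frozen=True)
class EvidenceSummary:
    orf_id: str
    n_distinct_peptides: int
    best_score: float
    verified: bool


def _as_frame(psms) -> pd.DataFrame:
    df = pd.DataFrame(psms, columns=PSM_COLUMNS) if not isinstance(psms, pd.DataFrame) else psms.copy()
    missing = set(PSM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")
    df["is_decoy"] = df["is_decoy"].astype(bool)
    return df


def fdr_threshold(psms, q: float = 0.01) -> float | None:
    """Smallest score t with decoy/target ratio above t at most ``q``.

    Candidate thresholds are the observed scores (the FDR is a step function
    that only changes there); at least one target must survive the cutoff.
    ``None`` when no threshold attains the requested FDR.
    """
    df = _as_frame(psms)
    targets = df.loc[~df["is_decoy"], "score"].to_numpy()
    decoys = df.loc[df["is_decoy"], "score"].to_numpy()
    if targets.size == 0:
        raise ValueError("PSM table contains no target PSMs")
    for t in sorted(set(df["score"].tolist())):
        n_t = int((targets >= t).sum())
        n_d = int((decoys >= t).sum())
        if n_t > 0 and n_d / n_t <= q:
            return float(t)
    return None


def verify_candidates(
    psms,
    min_score: float = 30.0,
    min_peptides: int = 2,
    q: float = 0.01,
) -> dict[str, EvidenceSummary]:
    """Per-ORF evidence summaries after decoy, FDR/score and peptide-count filters.

    A summary is emitted for every ORF with at least one surviving PSM;
    ``verified`` additionally requires ``min_peptides`` distinct peptides.
    """
    df = _as_frame(psms)
    cutoff = fdr_threshold(df, q=q)
    effective = max(min_score, cutoff) if cutoff is not None else float("inf")
    surviving = df[(~df["is_decoy"]) & (df["score"] >= effective)]
    summaries: dict[str, EvidenceSummary] = {}
    for orf_id, grp in surviving.groupby("orf_id", sort=True):
        n_pep = int(grp["peptide"].nunique())
        summaries[str(orf_id)] = EvidenceSummary(
            orf_id=str(orf_id),
            n_distinct_peptides=n_pep,
            best_score=float(grp["score"].max()),
            verified=n_pep >= min_peptides,
        )
    return summaries


def verified_set(summaries: dict[str, EvidenceSummary]) -> set[str]:
    return {orf_id for orf_id, s in summaries.items() if s.verified}


def summaries_to_frame(summaries: dict[str, EvidenceSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "orf_id": s.orf_id,
                "n_distinct_peptides": s.n_distinct_peptides,
                "best_score": s.best_score,
                "verified": s.verified,
            }
            for s in summaries.values()
        ],
        columns=["orf_id", "n_distinct_peptides", "best_score", "verified"],
    )
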