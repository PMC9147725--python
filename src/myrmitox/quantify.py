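"""TPM computation, colony averaging, gland-enrichment flags and composition.

Counts arrive as a long table (transcript_id, length, sample_id, count) over
the four samples gland_c1, gland_c2, body_c1, body_c2 (venom gland and
remaining body tissue from two colonies).  TPM uses the transcript length as
effective length:  TPM_i = 1e6 * (c_i / l_i) / sum_j (c_j / l_j), per sample.
Species-level expression is the arithmetic mean TPM of the two colonies per
tissue.  A transcript is gland-enriched when its mean gland TPM exceeds its
mean body TPM, or when it is detected only in gland samples.

Composition summaries report, per venom family, the share of candidate count
(diversity %) and the share of summed mean gland TPM (abundance %) among the
venom candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

SAMPLES = ("gland_c1", "gland_c2", "body_c1", "body_c2")
GLAND_SAMPLES = ("gland_c1", "gland_c2")
BODY_SAMPLES = ("body_c1", "body_c2")

COUNT_COLUMNS = ["transcript_id", "length", "sample_id", "count"]


@dataclass(frozen=True)
class CompositionRow:
    family: str
    n_candidates: int
    diversity_pct: float  # rounded half-up to one decimal
    abundance_pct: float


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding for reported percentages."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def compute_tpm(count_table: pd.DataFrame) -> pd.DataFrame:
    """Per-transcript TPM for every sample in the long count table.

    Returns a wide frame indexed by transcript_id with one TPM column per
    sample.  A sample with zero total count yields all-zero TPM.
    """
    df = count_table.copy()
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if df["length"].isna().any() or (df["length"] <= 0).any():
        raise ValueError("every transcript needs a positive length")
    if (df["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    df["rate"] = df["count"] / df["length"]
    wide = df.pivot_table(
        index="transcript_id", columns="sample_id", values="rate", aggfunc="sum"
    ).fillna(0.0)
    totals = wide.sum(axis=0)
    tpm = wide.div(totals.where(totals > 0, np.nan), axis=1).fillna(0.0) * 1e6
    tpm.columns.name = None
    return tpm


def mean_tpm(tpm: pd.DataFrame) -> pd.DataFrame:
    """Mean TPM of the two colonies per tissue: columns mean_gland, mean_body."""
    for s in SAMPLES:
        if s not in tpm.columns:
            raise ValueError(f"missing sample {s!r} in expression table")
    out = pd.DataFrame(index=tpm.index)
    out["mean_gland"] = tpm[list(GLAND_SAMPLES)].mean(axis=1)
    out["mean_body"] = tpm[list(BODY_SAMPLES)].mean(axis=1)
    return out


def gland_enrichment(mean_gland: float, mean_body: float) -> str:
    """'gland_only', 'gland_higher' or 'not_enriched' (strict inequalities)."""
    if mean_body == 0 and mean_gland > 0:
        return "gland_only"
    if mean_gland > mean_body > 0:
        return "gland_higher"
    return "not_enriched"


def enrichment_table(means: pd.DataFrame) -> pd.DataFrame:
    out = means.copy()
    out["category"] = [
        gland_enrichment(g, b) for g, b in zip(out["mean_gland"], out["mean_body"])
    ]
    out["enriched"] = out["category"] != "not_enriched"
    return out


def composition_summary(
    families: dict[str, str],
    mean_gland_tpm: dict[str, float] | None = None,
) -> list[CompositionRow]:
    """Per-family diversity % (of candidate count) and abundance % (of gland TPM).

    ``families`` maps candidate id -> family label; ``mean_gland_tpm`` maps
    candidate id -> mean venom-gland TPM (abundance is NaN when omitted).
    Percentages use half-up rounding to one decimal for reporting; rows are
    ordered by descending candidate count then family name.
    """
    if not families:
        raise ValueError("empty candidate set")
    fam_series = pd.Series(families, name="family")
    n_total = len(fam_series)
    counts = fam_series.value_counts()
    if mean_gland_tpm is not None:
        tpm_series = pd.Series(mean_gland_tpm).reindex(fam_series.index).fillna(0.0)
        fam_tpm = tpm_series.groupby(fam_series).sum()
        total_tpm = float(fam_tpm.sum())
    else:
        fam_tpm, total_tpm = None, 0.0
    rows = []
    for family in sorted(counts.index, key=lambda f: (-counts[f], f)):
        n = int(counts[family])
        if fam_tpm is not None and total_tpm > 0:
            ab = round_half_up(100.0 * float(fam_tpm[family]) / total_tpm)
        else:
            ab = float("nan")
        rows.append(
            CompositionRow(
                family=family,
                n_candidates=n,
                diversity_pct=round_half_up(100.0 * n / n_total),
                abundance_pct=ab,
            )
        )
    return rows


def composition_to_frame(rows: list[CompositionRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family": r.family,
                "n": r.n_candidates,
                "diversity_pct": r.diversity_pct,
                "abundance_pct": r.abundance_pct,
            }
            for r in rows
        ],
        columns=["family", "n", "diversity_pct", "abundance_pct"],
    )
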