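#!/usr/bin/env python
"""TPM quantification, gland enrichment and venom composition.

Computes per-sample TPM, colony means per tissue, enrichment categories, and
the per-family diversity/abundance composition of the annotated candidates.
Writes expression.tsv and composition.tsv under results/.
"""

from pathlib import Path

import pandas as pd

from myrmitox.quantify import (
    composition_summary,
    composition_to_frame,
    compute_tpm,
    enrichment_table,
    mean_tpm,
)

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts = pd.read_csv(BASE / "data" / "counts.tsv", sep="\t")
    tpm = compute_tpm(counts)
    means = mean_tpm(tpm)
    expr = tpm.join(means)
    expr = enrichment_table(expr)
    expr.to_csv(BASE / "expression.tsv", sep="\t")

    ann = pd.read_csv(BASE / "annotations.tsv", sep="\t")
    families = dict(zip(ann["query"], ann["family"]))
    gland = {
        q: float(means.at[q.split("|")[0], "mean_gland"])
        for q in ann["query"]
        if q.split("|")[0] in means.index
    }
    rows = composition_summary(families, gland)
    composition_to_frame(rows).to_csv(BASE / "composition.tsv", sep="\t", index=False)

    print(f"TPM computed for {len(tpm)} transcripts; per-sample sums:")
    print(tpm.sum(axis=0).round(3).to_string())
    print(f"\nenrichment categories:\n{expr['category'].value_counts().to_string()}")
    print("\nvenom composition (diversity % / abundance % of candidate gland TPM):")
    for r in rows:
        print(f"  {r.family:8s} n={r.n_candidates:3d}  {r.diversity_pct:5.1f}%  {r.abundance_pct:5.1f}%")


if __name__ == "__main__":
    main()
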