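#!/usr/bin/env python
"""Extract ORFs and annotate them against the toxin reference panel.

Dedupe transcripts, scan all six frames for ORFs of >= 10 residues, align
each against the labeled panel (BLOSUM62, E <= 1e-3), rank hits by
similarity and coverage, and assign venom families from the top hits.
Writes orfs.tsv and annotations.tsv under results/.
"""

from pathlib import Path

import pandas as pd

from myrmitox.annotate import annotate_orfs, hit_to_row
from myrmitox.sequence import dedupe_exact, find_orfs, orfs_to_rows, parse_fasta

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = parse_fasta(BASE / "data" / "transcripts.fasta")
    records, removed = dedupe_exact(records)
    orfs = [o for rec in records for o in find_orfs(rec, min_aa=10)]
    pd.DataFrame(orfs_to_rows(orfs)).to_csv(BASE / "orfs.tsv", sep="\t", index=False)

    panel = parse_fasta(BASE / "data" / "panel.fasta", alphabet="aa")
    annotations = annotate_orfs(orfs, panel)
    rows = []
    for orf_id, entry in annotations.items():
        if entry["top"] is None:
            continue
        row = hit_to_row(entry["top"])
        row["family"] = entry["family"]
        rows.append(row)
    ann = pd.DataFrame(rows)
    ann.to_csv(BASE / "annotations.tsv", sep="\t", index=False)

    print(f"{len(records)} transcripts ({len(removed)} exact duplicates removed)")
    print(f"{len(orfs)} ORFs scanned, {len(ann)} with a panel hit at E<=1e-3")
    if len(ann):
        print("family counts among annotated ORFs:")
        print(ann["family"].value_counts().to_string())


if __name__ == "__main__":
    main()
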