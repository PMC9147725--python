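#!/usr/bin/env python
"""Verify the dataset's species from overrepresented reads.

Exact-duplicate reads above 0.1% frequency are prefix-dereplicated and
matched as exact substrings (both strands) against the CO1 barcode
references.  Writes species_calls.tsv under results/.
"""

from pathlib import Path

import pandas as pd

from myrmitox import barcode as bc
from myrmitox.sequence import parse_fasta

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    reads = parse_fasta(BASE / "data" / "barcode_reads.fasta")
    db = parse_fasta(BASE / "data" / "barcode_db.fasta")
    over = bc.extract_overrepresented(reads, frac_threshold=0.001)
    derep = bc.derep_prefix(over)
    queries = [(f"OVR{i:03d}", seq) for i, seq in enumerate(sorted(derep))]
    calls, tally = bc.species_call(queries, db)
    pd.DataFrame(
        [
            {"query": c.query_id, "reference": c.matched_reference_id, "species": c.species}
            for c in calls
        ]
    ).to_csv(BASE / "species_calls.tsv", sep="\t", index=False)
    print(f"{len(over)} overrepresented sequences, {len(derep)} after prefix derep")
    print(f"species tally: {tally}")
    if tally:
        print(f"majority species: {max(tally, key=tally.get)}")


if __name__ == "__main__":
    main()
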