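#!/usr/bin/env python
"""Filter the PSM table and mark proteome-verified ORFs.

Decoy PSMs are removed, the score cutoff is the larger of 30 and the 1%
decoy-FDR threshold, and verification requires two distinct peptides.
Writes evidence.tsv under results/.
"""

from pathlib import Path

import pandas as pd

from myrmitox.evidence import fdr_threshold, summaries_to_frame, verify_candidates

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    psms = pd.read_csv(BASE / "data" / "psms.tsv", sep="\t")
    cutoff = fdr_threshold(psms, q=0.01)
    summaries = verify_candidates(psms, min_score=30.0, min_peptides=2, q=0.01)
    frame = summaries_to_frame(summaries)
    frame.to_csv(BASE / "evidence.tsv", sep="\t", index=False)
    print(f"{len(psms)} PSMs ({int(psms.is_decoy.sum())} decoys)")
    print(f"1% decoy-FDR score cutoff: {cutoff}; effective cutoff: {max(30.0, cutoff)}")
    print(f"{int(frame.verified.sum())} of {len(frame)} ORFs with surviving PSMs are verified")


if __name__ == "__main__":
    main()
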