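#!/usr/bin/env python
"""Generate the synthetic venom-gland dataset used by the downstream steps.

One species ("M. rubra"-tagged), two colonies, venom-gland and body samples:
23 planted toxin transcripts across eight families (including four EGF-like
precursors), 60 background transcripts, negative-binomial counts with 10x
gland enrichment, a target/decoy PSM table, and CO1 barcode reads.
"""

from pathlib import Path

from myrmitox.simulate import SimConfig, generate_dataset

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 2022


def main() -> None:
    config = SimConfig(n_background=60, n_reads=1000, seed=SEED)
    dataset = generate_dataset(config)
    dataset.write(OUTDIR)
    tally = dataset.manifest.family_tally()
    print(f"dataset written to {OUTDIR}")
    print(f"transcripts: {len(dataset.transcripts)} "
          f"({sum(tally.values())} toxins, {config.n_background} background)")
    print(f"planted family tally: {tally}")
    print(f"PSM rows: {len(dataset.psm_table)} "
          f"({int(dataset.psm_table.is_decoy.sum())} decoys)")


if __name__ == "__main__":
    main()
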