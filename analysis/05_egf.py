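#!/usr/bin/env python
"""Mine and characterize EGF-like toxin precursors.

ORFs hit by a seed toxin at 100% query coverage are kept, dereplicated,
cleaved at the reference-adjusted signal position (28 -> 30), and the mature
peptides characterized: six-cysteine scaffold, average MW, pI, MYRTX name,
and nearest verified EGF-hormone type.  Writes egf_report.tsv under results/.
"""

from pathlib import Path

import pandas as pd

from myrmitox.egf import characterize, mine_egf, parse_hormone_panel, report_rows
from myrmitox.sequence import parse_fasta
from myrmitox.simulate import TruthManifest

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    from myrmitox.cli import _read_orfs

    orfs = _read_orfs(BASE / "orfs.tsv")
    seeds = parse_fasta(BASE / "data" / "egf_seeds.fasta", alphabet="aa")
    hormones = parse_hormone_panel(
        parse_fasta(BASE / "data" / "hormone_panel.fasta", alphabet="aa")
    )
    evidence = pd.read_csv(BASE / "evidence.tsv", sep="\t")
    verified = set(evidence[evidence["verified"]]["orf_id"])
    expr = pd.read_csv(BASE / "expression.tsv", sep="\t", index_col=0)
    abundance = expr["mean_gland"].to_dict()
    manifest = TruthManifest.from_json(BASE / "data" / "manifest.json")

    reference_signal = None
    for rec in seeds:
        for token in rec.description.split():
            if token.startswith("signal="):
                reference_signal = int(token.split("=", 1)[1])

    mined = mine_egf(orfs, seeds)
    precursors = characterize(
        mined,
        species_tag=manifest.species_tag,
        predicted_signal_len=28,
        reference_signal_len=reference_signal,
        hormone_panel=hormones,
        verified_orfs=verified,
        abundance=abundance,
    )
    pd.DataFrame(report_rows(precursors)).to_csv(
        BASE / "egf_report.tsv", sep="\t", index=False
    )
    print(f"{len(mined)} precursors pass the 100%-coverage mining filter")
    print(f"{'name':16s} {'pre':>4s} {'mat':>4s} {'MW':>5s} {'pI':>5s}  type")
    for p in precursors:
        print(
            f"{p.name:16s} {len(p.precursor_seq):4d} {len(p.mature_seq):4d} "
            f"{p.mw_kda:5.1f} {p.pi:5.2f}  {p.egf_type}"
        )


if __name__ == "__main__":
    main()
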