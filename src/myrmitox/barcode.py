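"""Species verification from overrepresented reads and CO1 barcode references.

Overrepresented reads (exact duplicates above a frequency threshold) are
prefix-dereplicated and matched against a CO1 barcode reference set.  Because
only 100%-identity, 100%-query-coverage hits are meaningful for species
verification, matching is exact substring search on both strands, which is
provably equivalent to a heuristic nucleotide search followed by that filter.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .sequence import reverse_complement


@dataclass(frozen=True)
class BarcodeCall:
    query_id: str
    matched_reference_id: str
    species: str
    identity: float = 100.0
    q_cov: float = 100.0


def extract_overrepresented(reads, frac_threshold: float = 0.001):
    """Sequences whose exact-duplicate frequency is >= the threshold (inclusive).

    ``reads`` is an iterable of sequence strings (or records with ``.seq``).
    Returns a list of (sequence, count) sorted by descending count then
    sequence, so the output is order-invariant.
    """
    if not 0 < frac_threshold < 1:
        raise ValueError("frac_threshold must be in (0, 1)")
    seqs = [r if isinstance(r, str) else r.seq for r in reads]
    if not seqs:
        raise ValueError("no reads supplied")
    total = len(seqs)
    counts = Counter(seqs)
    over = [
        (seq, n) for seq, n in counts.items() if n >= 2 and n / total >= frac_threshold
    ]
    over.sort(key=lambda t: (-t[1], t[0]))
    return over


def derep_prefix(sequences):
    """Merge exact duplicates and strict prefixes into the longest sequence.

    ``sequences`` is an iterable of strings or (string, count) pairs.  Returns
    a dict sequence -> summed count; any sequence that is a prefix of another
    retained sequence contributes its count to that sequence.  Longest-first
    processing makes the result order-invariant.
    """
    pairs = [(s, 1) if isinstance(s, str) else (s[0], s[1]) for s in sequences]
    merged: Counter[str] = Counter()
    for seq, n in pairs:
        merged[seq] += n
    # longest first: every prefix folds into an already-retained superstring
    kept: dict[str, int] = {}
    for seq in sorted(merged, key=lambda s: (-len(s), s)):
        target = None
        for existing in kept:
            if existing.startswith(seq):
                target = existing
                break
        if target is None:
            kept[seq] = merged[seq]
        else:
            kept[target] += merged[seq]
    return kept


def parse_species(record) -> str:
    """Species label from a ``species=`` description key (underscores -> spaces)."""
    for token in record.description.split():
        if token.startswith("species="):
            return token.split("=", 1)[1].replace("_", " ")
    raise ValueError(f"barcode reference {record.id!r} lacks a species= key")


def species_call(queries, barcode_db):
    """Exact-substring barcode lookup on both strands.

    ``queries``: iterable of (query_id, sequence); ``barcode_db``: FASTA
    records with ``species=`` description keys.  Emits one call per
    (query, reference) pair where the query (either orientation) is an exact
    substring of the reference.  Returns ``(calls, tally)`` where ``tally``
    maps species -> number of calls.
    """
    db = list(barcode_db)
    if not db:
        raise ValueError("empty barcode database")
    species_of = {rec.id: parse_species(rec) for rec in db}
    calls: list[BarcodeCall] = []
    for query_id, seq in queries:
        rc = reverse_complement(seq)
        for rec in db:
            if seq in rec.seq or rc in rec.seq:
                calls.append(
                    BarcodeCall(
                        query_id=query_id,
                        matched_reference_id=rec.id,
                        species=species_of[rec.id],
                    )
                )
    tally: Counter[str] = Counter(c.species for c in calls)
    return calls, dict(tally)
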