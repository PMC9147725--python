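"""FASTA I/O, exact-redundancy removal and six-frame ORF extraction.

Transcripts arrive as assembled contigs without reliable start codons, so ORFs
are defined permissively: every maximal stop-free span between stop codons (or
sequence ends) in each of the six reading frames, reported whole, without
requiring an initiator methionine.  Coordinates are 1-based inclusive on the
forward strand; the strand is stored separately.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqIO.FastaIO import SimpleFastaParser

_CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NT_RE = re.compile(r"^[ACGTN]+$")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (duplicate ids, empty sequences)."""


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside the expected alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single FASTA record; ``alphabet`` is 'nt' or 'aa'."""

    id: str
    seq: str
    description: str = ""
    alphabet: str = "nt"

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("record id must be non-empty")
        if not self.seq:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class OrfRecord:
    """A translated open reading frame located on its source transcript."""

    orf_id: str
    transcript_id: str
    strand: str  # '+' or '-'
    frame: int  # 0..2, offset within the strand read
    start: int  # 1-based inclusive, forward strand
    end: int
    protein: str

    def __post_init__(self) -> None:
        if (self.end - self.start + 1) % 3:
            raise ValueError("ORF span must be a multiple of 3")
        if "*" in self.protein:
            raise ValueError("ORF protein must be stop-free")


def parse_fasta(path, alphabet: str = "nt") -> list[SequenceRecord]:
    """Read a FASTA file into records, preserving order.

    Line-wrapped sequences are concatenated.  Duplicate ids and empty
    sequences raise :class:`FastaFormatError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            parts = title.split(None, 1)
            rec_id = parts[0] if parts else ""
            desc = parts[1] if len(parts) > 1 else ""
            if rec_id in seen:
                raise FastaFormatError(f"duplicate record id {rec_id!r}")
            seen.add(rec_id)
            records.append(
                SequenceRecord(rec_id, seq.upper(), desc, alphabet=alphabet)
            )
    return records


def write_fasta(records, path, width: int = 60) -> None:
    """Write records to FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as handle:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            handle.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i : i + width] + "\n")


def dedupe_exact(records):
    """Remove exact-duplicate sequences, keeping the first occurrence.

    Returns ``(kept_records, removed)`` where ``removed`` maps each dropped
    record id to the id of the identical record that was kept.
    """
    kept: list[SequenceRecord] = []
    removed: dict[str, str] = {}
    by_seq: dict[str, str] = {}
    for rec in records:
        if rec.seq in by_seq:
            removed[rec.id] = by_seq[rec.seq]
        else:
            by_seq[rec.seq] = rec.id
            kept.append(rec)
    return kept, removed


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str) -> str:
    """Translate a nucleotide string codon-by-codon; trailing partial codon ignored.

    Codons containing N translate to X; X never terminates a span.
    """
    aa = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        aa.append(_CODON_TABLE.get(codon, "X"))
    return "".join(aa)


def find_orfs(record: SequenceRecord, min_aa: int = 10) -> list[OrfRecord]:
    """Scan all six frames for maximal stop-free ORFs of >= ``min_aa`` residues.

    The reported span always maps back to the forward strand, so for minus-
    strand ORFs ``start`` is the 5' end of the reverse-complement read's last
    codon.  ORF ids encode transcript, strand, frame and span and are stable
    across runs.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = record.seq.upper()
    if not _NT_RE.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise AlphabetError(f"non-nucleotide characters in {record.id!r}: {bad}")
    n = len(seq)
    orfs: list[OrfRecord] = []
    for strand in "+-":
        read = seq if strand == "+" else reverse_complement(seq)
        for frame in range(3):
            prot = translate(read[frame:])
            # maximal stop-free spans
            start_aa = 0
            for m in list(re.finditer(r"\*", prot)) + [None]:
                end_aa = m.start() if m is not None else len(prot)
                if end_aa - start_aa >= min_aa:
                    pep = prot[start_aa:end_aa]
                    # nt coords on the strand read, 0-based half-open
                    s_read = frame + 3 * start_aa
                    e_read = frame + 3 * end_aa
                    if strand == "+":
                        start, end = s_read + 1, e_read
                    else:
                        start, end = n - e_read + 1, n - s_read
                    orfs.append(
                        OrfRecord(
                            orf_id=f"{record.id}|{strand}{frame}|{start}-{end}",
                            transcript_id=record.id,
                            strand=strand,
                            frame=frame,
                            start=start,
                            end=end,
                            protein=pep,
                        )
                    )
                start_aa = end_aa + 1 if m is not None else end_aa
    return orfs


def orf_table_columns() -> list[str]:
    return ["orf_id", "transcript_id", "strand", "frame", "start", "end", "protein"]


def orfs_to_rows(orfs) -> list[dict]:
    return [
        {
            "orf_id": o.orf_id,
            "transcript_id": o.transcript_id,
            "strand": o.strand,
            "frame": o.frame,
            "start": o.start,
            "end": o.end,
            "protein": o.protein,
        }
        for o in orfs
    ]
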