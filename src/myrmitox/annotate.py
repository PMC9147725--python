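"""Local protein alignment of ORFs against a labeled toxin reference panel.

Candidate ORFs are aligned to every panel entry with Smith-Waterman affine-gap
alignment under BLOSUM62.  Each hit carries three report metrics:

* similarity  = 100 * positives / alignment columns (gap columns count in the
  denominator and are never positive),
* q_cov, s_cov = 100 * aligned span / full sequence length.

Hits passing the E-value cutoff are sorted by (similarity desc, q_cov desc,
s_cov desc, subject id asc) and the top hit assigns the venom family.
E-values follow the Karlin-Altschul form E = K * m * n * exp(-lambda * S)
with the published gapped BLOSUM62 constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

from .sequence import AlphabetError, SequenceRecord

BLOSUM62 = substitution_matrices.load("BLOSUM62")
_BLOSUM62_ALPHA = set(str(a) for a in BLOSUM62.alphabet)


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters.

    A gap of length k costs ``gap_open + k * gap_extend``.  ``karlin_lambda``
    and ``karlin_k`` are the gapped Karlin-Altschul constants for the scheme;
    the defaults are the published values for BLOSUM62 with open 11 / extend 1.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    max_evalue: float = 1e-3

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    score: float
    evalue: float
    q_start: int  # 1-based inclusive residue coordinates
    q_end: int
    s_start: int
    s_end: int
    aln_len: int  # columns including gaps
    n_identical: int
    n_positive: int
    similarity: float = float("nan")  # %
    q_cov: float = float("nan")  # %
    s_cov: float = float("nan")  # %


def _check_alphabet(seq: str, label: str) -> None:
    bad = sorted(set(seq) - _BLOSUM62_ALPHA)
    if bad:
        raise AlphabetError(f"residues not in matrix in {label}: {bad}")


@lru_cache(maxsize=8)
def _make_aligner(scheme: ScoringScheme) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = scheme.matrix
    # biopython charges open_gap_score for the first gapped column and
    # extend_gap_score for each further one; our convention is open + k*extend
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def local_align(
    query: str,
    subject: str,
    scheme: ScoringScheme | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
    skip_above_evalue: float | None = None,
) -> AlignmentHit | None:
    """Optimal affine-gap local alignment; ``None`` if no positive-scoring one exists.

    ``skip_above_evalue`` is a speed gate: when the E-value computed from the
    optimal score already exceeds it, the hit would be discarded downstream
    anyway, so ``None`` is returned without tracing back the alignment.
    """
    scheme = scheme or ScoringScheme()
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    _check_alphabet(query, query_id)
    _check_alphabet(subject, subject_id)
    aligner = _make_aligner(scheme)
    score = aligner.score(query, subject)
    if score <= 0:
        return None
    if (
        skip_above_evalue is not None
        and karlin_evalue(score, len(query), len(subject), scheme) > skip_above_evalue
    ):
        return None
    aln = next(iter(aligner.align(query, subject)))
    matrix = scheme.matrix
    q_aln, s_aln = str(aln[0]), str(aln[1])
    # local alignments are reported padded to full length; trim to the span
    (q_spans, s_spans) = aln.aligned
    q_start, q_end = int(q_spans[0][0]), int(q_spans[-1][1])
    s_start, s_end = int(s_spans[0][0]), int(s_spans[-1][1])
    cols = _alignment_columns(aln)
    n_ident = sum(1 for a, b in cols if a == b and a != "-")
    n_pos = sum(
        1 for a, b in cols if a != "-" and b != "-" and matrix[a, b] > 0
    )
    evalue = karlin_evalue(score, len(query), len(subject), scheme)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        score=float(score),
        evalue=evalue,
        q_start=q_start + 1,
        q_end=q_end,
        s_start=s_start + 1,
        s_end=s_end,
        aln_len=len(cols),
        n_identical=n_ident,
        n_positive=n_pos,
    )


def _alignment_columns(aln):
    """Yield (query_char, subject_char) per column of the local alignment core."""
    q, s = aln.sequences
    cols = []
    (q_spans, s_spans) = aln.aligned
    qi_prev, si_prev = None, None
    for (qs, qe), (ss, se) in zip(q_spans, s_spans):
        if qi_prev is not None:
            for i in range(qi_prev, qs):  # gap in subject
                cols.append((q[i], "-"))
            for j in range(si_prev, ss):  # gap in query
                cols.append(("-", s[j]))
        for i, j in zip(range(qs, qe), range(ss, se)):
            cols.append((q[i], s[j]))
        qi_prev, si_prev = qe, se
    return cols


def karlin_evalue(score: float, m: int, n: int, scheme: ScoringScheme) -> float:
    return scheme.karlin_k * m * n * math.exp(-scheme.karlin_lambda * score)


def hit_metrics(hit: AlignmentHit, query_len: int, subject_len: int) -> AlignmentHit:
    """Fill similarity and coverage percentages from spans and counts."""
    if hit.aln_len <= 0:
        raise ValueError("zero-length alignment")
    return replace(
        hit,
        similarity=100.0 * hit.n_positive / hit.aln_len,
        q_cov=100.0 * (hit.q_end - hit.q_start + 1) / query_len,
        s_cov=100.0 * (hit.s_end - hit.s_start + 1) / subject_len,
    )


def rank_and_select(hits):
    """Sort hits (similarity desc, q_cov desc, s_cov desc, subject_id asc).

    Returns ``(ordered_hits, top_hit_or_None)``.  The output order does not
    depend on the input order.
    """
    ordered = sorted(
        hits,
        key=lambda h: (-h.similarity, -h.q_cov, -h.s_cov, h.subject_id),
    )
    return ordered, (ordered[0] if ordered else None)


def filter_hits(hits, scheme: ScoringScheme | None = None):
    """Keep hits with evalue <= scheme.max_evalue, preserving order."""
    scheme = scheme or ScoringScheme()
    passing = [h for h in hits if h.evalue <= scheme.max_evalue]
    return passing, len(hits) - len(passing)


class ReferenceError_(KeyError):
    """Top-hit subject missing from the reference panel."""


def panel_families(panel_records) -> dict[str, str]:
    """Map panel record id -> family label parsed from a ``family=`` description key."""
    families = {}
    for rec in panel_records:
        label = None
        for token in rec.description.split():
            if token.startswith("family="):
                label = token.split("=", 1)[1]
        if label is None:
            raise ValueError(f"panel entry {rec.id!r} lacks a family= key")
        families[rec.id] = label
    return families


def assign_family(top_hit: AlignmentHit | None, families: dict[str, str]) -> str:
    """Family label of the top hit's subject; 'unannotated' when there is no hit."""
    if top_hit is None:
        return "unannotated"
    try:
        return families[top_hit.subject_id]
    except KeyError as exc:
        raise ReferenceError_(
            f"subject {top_hit.subject_id!r} not in reference panel"
        ) from exc


def annotate_orfs(orfs, panel_records, scheme: ScoringScheme | None = None):
    """Align every ORF against the panel; return per-ORF (ordered hits, family).

    A dict keyed by orf_id with values ``{"hits": [...], "top": hit_or_None,
    "family": label}``.  Hits are E-value filtered then ranked.
    """
    scheme = scheme or ScoringScheme()
    families = panel_families(panel_records)
    out = {}
    for orf in orfs:
        hits = []
        for ref in panel_records:
            hit = local_align(
                orf.protein,
                ref.seq,
                scheme,
                query_id=orf.orf_id,
                subject_id=ref.id,
                skip_above_evalue=scheme.max_evalue,
            )
            if hit is not None:
                hits.append(hit_metrics(hit, len(orf.protein), len(ref.seq)))
        hits, _ = filter_hits(hits, scheme)
        ordered, top = rank_and_select(hits)
        out[orf.orf_id] = {
            "hits": ordered,
            "top": top,
            "family": assign_family(top, families),
        }
    return out


HIT_COLUMNS = [
    "query",
    "subject",
    "score",
    "evalue",
    "identities",
    "positives",
    "aln_len",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "similarity",
    "q_cov",
    "s_cov",
]


def hit_to_row(h: AlignmentHit) -> dict:
    return {
        "query": h.query_id,
        "subject": h.subject_id,
        "score": h.score,
        "evalue": h.evalue,
        "identities": h.n_identical,
        "positives": h.n_positive,
        "aln_len": h.aln_len,
        "q_start": h.q_start,
        "q_end": h.q_end,
        "s_start": h.s_start,
        "s_end": h.s_end,
        "similarity": h.similarity,
        "q_cov": h.q_cov,
        "s_cov": h.s_cov,
    }
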