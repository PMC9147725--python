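"""Independent brute-force oracles used to validate the library's algorithms.

Everything here is deliberately naive: full dynamic-programming tables,
exhaustive enumeration, grid search.  Nothing imports the code paths it
checks (translation goes through Bio.Seq, alignment is a hand-rolled Gotoh
table, ORF scanning re-derives spans from scratch).
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq


def gotoh_local_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Brute-force affine-gap local alignment score.

    A gap of length k costs ``gap_open + k * gap_extend``.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), neg)  # gap in b (a aligned to gap)
    Iy = np.full((n + 1, m + 1), neg)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(
                0.0,
                M[i - 1][j - 1] + s,
                Ix[i - 1][j - 1] + s,
                Iy[i - 1][j - 1] + s,
            )
            Ix[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend, Ix[i - 1][j] - gap_extend
            )
            Iy[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend, Iy[i][j - 1] - gap_extend
            )
            best = max(best, M[i][j])
    return best


def six_frame_orfs(seq: str, min_aa: int):
    """All maximal stop-free translated spans in all six frames.

    Returns a set of (strand, frame, start, end, protein) with 1-based
    inclusive forward-strand coordinates.  Translation goes through Bio.Seq.
    """
    out = set()
    n = len(seq)
    for strand in "+-":
        read = seq if strand == "+" else str(Seq(seq).reverse_complement())
        for frame in range(3):
            trimmed = read[frame:]
            trimmed = trimmed[: len(trimmed) - len(trimmed) % 3]
            prot = str(Seq(trimmed).translate())
            for chunk_start, chunk in _stop_free_chunks(prot):
                if len(chunk) >= min_aa:
                    s_read = frame + 3 * chunk_start
                    e_read = frame + 3 * (chunk_start + len(chunk))
                    if strand == "+":
                        start, end = s_read + 1, e_read
                    else:
                        start, end = n - e_read + 1, n - s_read
                    out.add((strand, frame, start, end, chunk))
    return out


def _stop_free_chunks(prot: str):
    start = 0
    for i, aa in enumerate(prot):
        if aa == "*":
            if i > start:
                yield start, prot[start:i]
            start = i + 1
    if len(prot) > start:
        yield start, prot[start:]


def fdr_cutoff_exhaustive(scores, decoy_flags, q: float):
    """Exhaustive scan over every observed score as candidate cutoff."""
    scores = np.asarray(scores, dtype=float)
    decoy = np.asarray(decoy_flags, dtype=bool)
    best = None
    for t in sorted(set(scores.tolist())):
        keep = scores >= t
        n_t = int((keep & ~decoy).sum())
        n_d = int((keep & decoy).sum())
        if n_t > 0 and n_d / n_t <= q:
            if best is None or t < best:
                best = t
    return best


def pi_grid_search(charge_fn, seq: str, step: float = 1e-3) -> float:
    """pH minimizing |net charge| over a regular grid on [0, 14]."""
    grid = np.arange(0.0, 14.0 + step, step)
    charges = np.array([abs(charge_fn(seq, ph)) for ph in grid])
    return float(grid[int(np.argmin(charges))])
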