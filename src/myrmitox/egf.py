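"""Mining and characterization of EGF-like venom toxin precursors.

EGF-like ant toxins (myrmicitoxins, MYRTX) are secreted prepeptides: an
N-terminal signal peptide directly followed by the mature toxin, which is
built on the epidermal-growth-factor fold with a conserved six-cysteine
scaffold.  This module

* mines candidate precursors from ORFs by local alignment against seed
  toxins, keeping only hits that cover the seed query completely,
* adjusts predicted signal-peptide lengths against a reference cleavage
  position taken from alignment to known toxins,
* derives the mature peptide, its cysteine scaffold, average molecular
  weight and isoelectric point,
* assigns U-MYRTX-<species>1<letter> names, and
* classifies each mature toxin by its most similar empirically verified EGF
  hormone of comparable length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .annotate import ScoringScheme, hit_metrics, local_align
from .sequence import AlphabetError

# average (not monoisotopic) residue masses, Da
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

# Bjellqvist pKa values, the set used by the common proteomics servers.
# Kept as module-level data so an alternative scale can be substituted.
PKA_POSITIVE = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PKA_NTERM_BY_RESIDUE = {
    "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7,
}
PKA_CTERM_BY_RESIDUE = {"D": 4.55, "E": 4.75}

# permissive search context for seed mining (the decisive filter is full
# query coverage, not the E-value)
MINING_SCHEME = ScoringScheme(max_evalue=10.0)


@dataclass(frozen=True)
class EgfPrecursor:
    """A characterized EGF-like toxin precursor."""

    name: str
    precursor_seq: str
    signal_len: int
    mature_seq: str
    cys_positions: tuple[int, ...]  # 1-based in mature
    spacing: tuple[int, ...]  # 5 inter-cysteine gaps when canonical
    mw_kda: float  # average mass of the mature peptide
    pi: float
    proteome_verified: bool = False
    egf_type: str = "unclassified"
    source_orf: str = ""
    seed_id: str = ""


@dataclass(frozen=True)
class EgfCandidate:
    """A mined precursor before characterization."""

    orf_id: str
    seed_id: str
    precursor_seq: str
    transcript_id: str = ""


def mine_egf(orfs, seed_records, scheme: ScoringScheme = MINING_SCHEME):
    """ORFs hit by a seed toxin at 100% query (seed) coverage.

    The candidate precursor is the ORF-protein span aligned to the seed.
    Exact-duplicate precursor sequences are collapsed, keeping the first in
    ORF-id order; the matching seed is kept as provenance.
    """
    if not seed_records:
        raise ValueError("empty seed set")
    candidates: list[EgfCandidate] = []
    for orf in sorted(orfs, key=lambda o: o.orf_id):
        best = None
        for seed in seed_records:
            hit = local_align(
                seed.seq,
                orf.protein,
                scheme,
                query_id=seed.id,
                subject_id=orf.orf_id,
                skip_above_evalue=scheme.max_evalue,
            )
            if hit is None:
                continue
            hit = hit_metrics(hit, len(seed.seq), len(orf.protein))
            if hit.q_cov < 100.0:
                continue
            if best is None or (hit.score, hit.query_id) > (best.score, best.query_id):
                best = hit
        if best is not None:
            precursor = orf.protein[best.s_start - 1 : best.s_end]
            candidates.append(
                EgfCandidate(
                    orf_id=orf.orf_id,
                    seed_id=best.query_id,
                    precursor_seq=precursor,
                    transcript_id=orf.transcript_id,
                )
            )
    seen: set[str] = set()
    unique = []
    for cand in candidates:
        if cand.precursor_seq not in seen:
            seen.add(cand.precursor_seq)
            unique.append(cand)
    return unique


def adjust_signal(predicted_len: int, reference_len: int | None, precursor_len: int) -> int:
    """Adopt the reference-aligned cleavage position when one is available.

    Signal-peptide predictors systematically call the cleavage site two
    residues early on these precursors; alignment to reference toxins with a
    known cleavage column overrides the prediction.
    """
    if predicted_len < 0:
        raise ValueError("predicted signal length must be >= 0")
    adopted = reference_len if reference_len is not None else predicted_len
    if adopted >= precursor_len:
        raise ValueError(
            f"signal length {adopted} not smaller than precursor length {precursor_len}"
        )
    return adopted


def derive_mature(precursor_seq: str, signal_len: int) -> str:
    """Mature peptide = precursor suffix after the signal peptide."""
    if not 0 <= signal_len < len(precursor_seq):
        raise ValueError(
            f"signal length {signal_len} out of range for precursor of "
            f"{len(precursor_seq)} residues"
        )
    return precursor_seq[signal_len:]


def molecular_weight(seq: str) -> float:
    """Average molecular mass in Da: residue masses plus one water."""
    try:
        return sum(AVERAGE_RESIDUE_MASS[aa] for aa in seq) + WATER_MASS
    except KeyError as exc:
        raise AlphabetError(f"unknown residue {exc.args[0]!r}") from exc


def net_charge(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge of the peptide at the given pH."""
    unknown = set(seq) - set(AVERAGE_RESIDUE_MASS)
    if unknown:
        raise AlphabetError(f"unknown residues {sorted(unknown)}")
    pos: list[float] = [PKA_NTERM_BY_RESIDUE.get(seq[0], PKA_POSITIVE["Nterm"])]
    neg: list[float] = [PKA_CTERM_BY_RESIDUE.get(seq[-1], PKA_NEGATIVE["Cterm"])]
    for aa in seq:
        if aa in ("K", "R", "H"):
            pos.append(PKA_POSITIVE[aa])
        elif aa in ("D", "E", "C", "Y"):
            neg.append(PKA_NEGATIVE[aa])
    charge = sum(1.0 / (1.0 + 10 ** (ph - pk)) for pk in pos)
    charge -= sum(1.0 / (1.0 + 10 ** (pk - ph)) for pk in neg)
    return charge


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    The charge is strictly decreasing in pH, so the zero is unique.
    """
    lo, hi = 0.0, 14.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        c = net_charge(seq, mid)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def cysteine_scaffold(mature_seq: str):
    """Cysteine positions (1-based), inter-cysteine gaps, and canonical flag.

    The canonical EGF-like scaffold has exactly six cysteines.
    """
    positions = tuple(i + 1 for i, aa in enumerate(mature_seq) if aa == "C")
    spacing = tuple(
        positions[i + 1] - positions[i] - 1 for i in range(len(positions) - 1)
    )
    return positions, spacing, len(positions) == 6


class NamingOverflowError(ValueError):
    """More candidates in one family number than letters available."""


def assign_names(matures: list[str], species_tag: str, order_key=None) -> dict[str, str]:
    """Assign U-MYRTX-<tag>1<letter> names to unique mature sequences.

    ``matures`` are mature peptide sequences in the desired naming order
    (descending venom-gland abundance, ties broken lexicographically, is the
    pipeline's convention).  Identical sequences share one name.  Returns a
    mapping mature_seq -> name.
    """
    unique: list[str] = []
    for seq in matures:
        if seq not in unique:
            unique.append(seq)
    if len(unique) > 26:
        raise NamingOverflowError(
            f"{len(unique)} candidates exceed one family number's 26 letters"
        )
    return {
        seq: f"U-MYRTX-{species_tag}1{chr(ord('a') + i)}"
        for i, seq in enumerate(unique)
    }


def parse_hormone_panel(panel_records):
    """Extract ``type=`` and ``verified=`` keys from hormone panel descriptions."""
    panel = []
    for rec in panel_records:
        meta = dict(
            token.split("=", 1) for token in rec.description.split() if "=" in token
        )
        if "type" not in meta:
            raise ValueError(f"hormone panel entry {rec.id!r} lacks a type= key")
        panel.append(
            {
                "id": rec.id,
                "seq": rec.seq,
                "type": meta["type"].replace("_", " "),
                "verified": meta.get("verified", "false").lower() == "true",
            }
        )
    return panel


def classify_egf_type(
    mature_seq: str,
    panel,
    scheme: ScoringScheme = MINING_SCHEME,
    length_window: float = 0.5,
):
    """Nearest empirically verified EGF hormone of comparable length.

    Panel hits are sorted by similarity descending (ties by panel id); the
    first verified entry whose length is within ±``length_window`` of the
    query length is chosen.  Returns ``(panel_id, similarity_pct, type_label)``
    or ``(None, nan, 'unclassified')``.
    """
    if not panel:
        raise ValueError("empty hormone panel")
    hits = []
    for entry in panel:
        hit = local_align(
            mature_seq, entry["seq"], scheme, subject_id=entry["id"]
        )
        if hit is None:
            continue
        hits.append((hit_metrics(hit, len(mature_seq), len(entry["seq"])), entry))
    hits.sort(key=lambda t: (-t[0].similarity, t[1]["id"]))
    lo = len(mature_seq) * (1.0 - length_window)
    hi = len(mature_seq) * (1.0 + length_window)
    for hit, entry in hits:
        if entry["verified"] and lo <= len(entry["seq"]) <= hi:
            return entry["id"], hit.similarity, entry["type"]
    return None, float("nan"), "unclassified"


def characterize(
    candidates: list[EgfCandidate],
    species_tag: str,
    predicted_signal_len: int = 28,
    reference_signal_len: int | None = 30,
    hormone_panel=None,
    verified_orfs: set[str] | None = None,
    abundance: dict[str, float] | None = None,
) -> list[EgfPrecursor]:
    """Full characterization of mined candidates, in naming order.

    ``abundance`` maps transcript_id -> mean venom-gland TPM and fixes the
    naming order (descending, ties by mature sequence).
    """
    rows = []
    for cand in candidates:
        signal_len = adjust_signal(
            predicted_signal_len, reference_signal_len, len(cand.precursor_seq)
        )
        mature = derive_mature(cand.precursor_seq, signal_len)
        rows.append((cand, signal_len, mature))
    def sort_key(row):
        cand, _, mature = row
        tpm = (abundance or {}).get(cand.transcript_id, 0.0)
        return (-tpm, mature)
    rows.sort(key=sort_key)
    names = assign_names([mature for _, _, mature in rows], species_tag)
    out = []
    emitted: set[str] = set()
    for cand, signal_len, mature in rows:
        if mature in emitted:
            continue
        emitted.add(mature)
        positions, spacing, canonical = cysteine_scaffold(mature)
        if hormone_panel:
            _, _, egf_type = classify_egf_type(mature, hormone_panel)
        else:
            egf_type = "unclassified"
        out.append(
            EgfPrecursor(
                name=names[mature],
                precursor_seq=cand.precursor_seq,
                signal_len=signal_len,
                mature_seq=mature,
                cys_positions=positions,
                spacing=spacing if canonical else spacing,
                mw_kda=round(molecular_weight(mature) / 1000.0, 1),
                pi=round(isoelectric_point(mature), 2),
                proteome_verified=bool(verified_orfs and cand.orf_id in verified_orfs),
                egf_type=egf_type,
                source_orf=cand.orf_id,
                seed_id=cand.seed_id,
            )
        )
    return out


EGF_REPORT_COLUMNS = [
    "name",
    "precursor_len",
    "mature_len",
    "mw_kda",
    "pi",
    "spacing",
    "canonical_scaffold",
    "egf_type",
    "proteome_verified",
    "source_orf",
]


def report_rows(precursors: list[EgfPrecursor]) -> list[dict]:
    return [
        {
            "name": p.name,
            "precursor_len": len(p.precursor_seq),
            "mature_len": len(p.mature_seq),
            "mw_kda": p.mw_kda,
            "pi": p.pi,
            "spacing": "-".join(map(str, p.spacing)),
            "canonical_scaffold": len(p.cys_positions) == 6,
            "egf_type": p.egf_type,
            "proteome_verified": p.proteome_verified,
            "source_orf": p.source_orf,
        }
        for p in precursors
    ]
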