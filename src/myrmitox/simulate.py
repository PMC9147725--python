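"""Synthetic venomics datasets with known ground truth.

The generator emulates the study design the analysis assumes: a venom-gland /
body-tissue RNA-seq experiment on two colonies of one myrmicine ant species,
yielding one assembled transcriptome with per-sample counts, a labeled toxin
reference panel, a peptide-spectrum-match table with decoys, EGF-like toxin
seeds and a hormone panel, and CO1 barcode reads with a reference set.  A
TruthManifest records every planted toxin (family, ORF coordinates, protein,
enrichment and verification status) so recovery can be scored exactly.

Design choices (documented in the methods note): background transcripts are
uniform-random nucleotide sequences; toxin proteins are family templates
mutated at a per-site substitution rate that never touches the terminal
residues (nor cysteines of EGF templates); counts are negative binomial with
a gland/body mean ratio for enriched toxins; PSM scores are truncated
Gaussians for targets and decoys.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .sequence import SequenceRecord, find_orfs, reverse_complement, write_fasta

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# fixed, unrelated random protein templates, one per venom protein family
FAMILY_TEMPLATES = {
    "VSP": "YVTRANSPIGTERPYWNVASAGRMAGVQLRLLADMLLSNGLKRQVGIQLRRIQPLPKAEIGTDKLNCDITYERFYRGVTKTQAMLEYTEKNNKARADVTGSRLANTKNLEAQDIEKNNDE",
    "CAP": "GAEAGPSGKLDRYHLFRFGNSEKPRYRYVQKECQQNQRMYLHELGIQMEMKILEANLDKDKQSIVLEDLACESAPRSMPKFDVRFHAQGMAH",
    "PLA": "DYSSNLKKRVGGENKQLHVGFLRSQFNMAMSCDHRSRKKRNSKELGAAWDAWRSCFKQRYRVIMFKEFITLEGDASFGLVIRERVSVRHSFLSTGLSGRS",
    "Kunitz": "LFVFIMPKLDTKQTNLVWFSSHITQAYYTGVQEPYIIAFFEESELGDDLCGDLCYRNN",
    "ACP": "QPRRFSGKGLAIEGLLVPPQIDVISGWGVDTDKAEGLRSIFPQDPAMDTSVVLKYYITMSYSAPFDTTVFNVARGDNETIYEDELPEPPEAVLLRCMMDVCSLEEIEADD",
    "M12": "EPKLYGHLIYLESSGLFWTREPQLFAGFKKGMERAGETVVALTAVSEENIATSTMGGKAGDVLDNLRIAVQPIHGSDLARPDTSHVEQMTIPLSE",
    "S9": "RSGPSEPLQPVYALHAHISKFFGWMDVMDQRLFVLAIEKQEVGCKHSNIFSYPSIHYLTLAYSLQMCDVSTGKLIRDGIALGDAGQAASDMDSGEYFAIP",
}

EGF_TYPES = (
    "Vertebrate TGF-like",
    "Vertebrate epiregulin-like",
    "Vertebrate HBEGF-like",
    "Insect Spitz-like",
    "Vertebrate betacellulin-like",
)

SPECIES_BY_TAG = {"Mrub": "Myrmica rubra", "Mrug": "Myrmica ruginodis"}

BARCODE_SPECIES = (
    "Myrmica rubra",
    "Myrmica ruginodis",
    "Myrmica sulcinodis",
    "Manica rubida",
    "Lasius niger",
    "Formica rufa",
)

_CODONS_BY_AA: dict[str, list[str]] = {}
from Bio.Data.CodonTable import standard_dna_table as _tbl

for _codon, _aa in sorted(_tbl.forward_table.items()):
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset (one species, two colonies)."""

    n_toxins_per_family: dict[str, int] = field(
        default_factory=lambda: {
            "VSP": 8, "CAP": 3, "PLA": 2, "ACP": 2, "Kunitz": 2, "M12": 1, "S9": 1,
        }
    )
    families: dict[str, str] = field(default_factory=lambda: dict(FAMILY_TEMPLATES))
    n_background: int = 150
    n_egf: int = 4
    signal_len: int = 30  # residues
    mature_len_range: tuple[int, int] = (46, 56)
    enrichment_factor: float = 10.0  # gland/body mean ratio for enriched toxins
    gland_only_frac: float = 0.3
    nb_dispersion: float = 10.0  # NB size; variance = mu + mu^2/dispersion
    mutation_rate: float = 0.10  # per-site template substitution
    psm_target_mean: float = 60.0
    psm_target_sd: float = 15.0
    psm_decoy_mean: float = 15.0
    psm_decoy_sd: float = 8.0
    n_decoy_psms: int | None = None  # default: one per target PSM
    psm_verified_frac: float = 1.0
    n_reads: int = 2000
    species_tag: str = "Mrub"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in self.n_toxins_per_family.items():
            if value < 0:
                raise ConfigError(f"n_toxins_per_family[{name!r}] must be >= 0")
            if value and name not in self.families:
                raise ConfigError(f"n_toxins_per_family has unknown family {name!r}")
        for fname in ("n_background", "n_egf", "n_reads"):
            if getattr(self, fname) < 0:
                raise ConfigError(f"{fname} must be >= 0")
        if self.enrichment_factor <= 0:
            raise ConfigError("enrichment_factor must be > 0")
        lo, hi = self.mature_len_range
        if not (20 <= lo <= hi <= 200):
            raise ConfigError("mature_len_range must lie within [20, 200]")
        if not 1 <= self.signal_len < self.signal_len + lo:
            raise ConfigError("signal_len must be >= 1")
        if not 0 < self.mutation_rate < 1:
            raise ConfigError("mutation_rate must be in (0, 1)")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if not 0 <= self.psm_verified_frac <= 1:
            raise ConfigError("psm_verified_frac must be in [0, 1]")
        if not 0 <= self.gland_only_frac <= 1:
            raise ConfigError("gland_only_frac must be in [0, 1]")
        if self.species_tag not in SPECIES_BY_TAG:
            raise ConfigError(
                f"species_tag must be one of {sorted(SPECIES_BY_TAG)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if "mature_len_range" in raw:
            raw["mature_len_range"] = tuple(raw["mature_len_range"])
        return cls(**raw)


@dataclass
class ManifestEntry:
    transcript_id: str
    length: int
    is_toxin: bool
    family: str  # '' for background
    strand: str = "+"
    frame: int = 0
    start: int = 0  # 1-based inclusive forward-strand CDS coordinates
    end: int = 0
    protein: str = ""
    gland_enriched: bool = False
    gland_only: bool = False
    proteome_verified: bool = False
    orf_id: str = ""  # id of the maximal ORF containing the planted protein
    base_mean: float = 0.0  # body-tissue NB mean used for count simulation


@dataclass
class TruthManifest:
    species_tag: str
    barcode_species: str
    entries: dict[str, ManifestEntry] = field(default_factory=dict)

    def family_tally(self) -> dict[str, int]:
        tally: dict[str, int] = {}
        for e in self.entries.values():
            if e.is_toxin:
                tally[e.family] = tally.get(e.family, 0) + 1
        return tally

    def toxin_ids(self) -> list[str]:
        return [t for t, e in self.entries.items() if e.is_toxin]

    def to_json(self, path) -> None:
        payload = {
            "species_tag": self.species_tag,
            "barcode_species": self.barcode_species,
            "entries": {t: dataclasses.asdict(e) for t, e in self.entries.items()},
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as handle:
            payload = json.load(handle)
        return cls(
            species_tag=payload["species_tag"],
            barcode_species=payload["barcode_species"],
            entries={
                t: ManifestEntry(**e) for t, e in payload["entries"].items()
            },
        )


@dataclass
class Dataset:
    """All artifacts of one synthetic dataset, in memory."""

    config: SimConfig
    transcripts: list[SequenceRecord]
    panel: list[SequenceRecord]
    egf_seeds: list[SequenceRecord]
    hormone_panel: list[SequenceRecord]
    count_table: pd.DataFrame
    psm_table: pd.DataFrame
    barcode_reads: list[SequenceRecord]
    barcode_db: list[SequenceRecord]
    manifest: TruthManifest

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.transcripts, outdir / "transcripts.fasta")
        write_fasta(self.panel, outdir / "panel.fasta")
        write_fasta(self.egf_seeds, outdir / "egf_seeds.fasta")
        write_fasta(self.hormone_panel, outdir / "hormone_panel.fasta")
        write_fasta(self.barcode_reads, outdir / "barcode_reads.fasta")
        write_fasta(self.barcode_db, outdir / "barcode_db.fasta")
        self.count_table.to_csv(outdir / "counts.tsv", sep="\t", index=False)
        self.psm_table.to_csv(outdir / "psms.tsv", sep="\t", index=False)
        self.manifest.to_json(outdir / "manifest.json")


def _random_protein(rng, length: int, alphabet: str = AA_ALPHABET) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def mutate_template(
    protein: str,
    rate: float,
    rng: np.random.Generator,
    freeze_cys: bool = False,
) -> str:
    """Per-site substitution of a template; terminal residues are never touched.

    With ``freeze_cys`` cysteines are neither replaced nor introduced, which
    preserves disulfide scaffolds.
    """
    out = list(protein)
    replacement_pool = AA_ALPHABET.replace("C", "") if freeze_cys else AA_ALPHABET
    for i in range(1, len(out) - 1):
        if freeze_cys and out[i] == "C":
            continue
        if rng.random() < rate:
            choices = replacement_pool.replace(out[i], "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def encode_protein(protein: str, rng: np.random.Generator) -> str:
    """Nucleotide CDS with uniformly random synonymous codons."""
    return "".join(
        _CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))] for aa in protein
    )


def _random_nt(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def generate_egf_precursor(
    signal_len: int,
    mature_len: int,
    spacing,
    seed,
) -> tuple[str, str]:
    """An EGF-like prepeptide: cysteine-free signal + six-cysteine mature.

    ``spacing`` gives the five inter-cysteine gaps; the scaffold is centred in
    the mature peptide.  Returns ``(protein, encoding_nucleotides)``.
    """
    if signal_len < 1:
        raise ValueError("signal_len must be >= 1")
    spacing = tuple(int(g) for g in spacing)
    if len(spacing) != 5 or any(g < 0 for g in spacing):
        raise ValueError("spacing must be 5 non-negative inter-cysteine gaps")
    occupied = 6 + sum(spacing)
    if occupied > mature_len:
        raise ValueError(
            f"spacing needs {occupied} residues but mature_len is {mature_len}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    no_cys = AA_ALPHABET.replace("C", "")
    signal = _random_protein(rng, signal_len, no_cys)
    head = (mature_len - occupied) // 2
    positions = [head + 1]
    for gap in spacing:
        positions.append(positions[-1] + gap + 1)
    mature = list(_random_protein(rng, mature_len, no_cys))
    for pos in positions:
        mature[pos - 1] = "C"
    protein = signal + "".join(mature)
    return protein, encode_protein(protein, rng)


def _plant_transcript(protein: str, tid: str, rng) -> tuple[SequenceRecord, dict]:
    """Embed a CDS for ``protein`` in UTR flanks on a random strand."""
    cds = encode_protein(protein, rng)
    u5 = _random_nt(rng, int(rng.integers(30, 121)))
    u3 = _random_nt(rng, int(rng.integers(30, 121)))
    forward = u5 + cds + u3
    strand = "+" if rng.random() < 0.5 else "-"
    n = len(forward)
    if strand == "+":
        seq = forward
        start, end = len(u5) + 1, len(u5) + len(cds)
        frame = (start - 1) % 3
    else:
        seq = reverse_complement(forward)
        start, end = n - (len(u5) + len(cds)) + 1, n - len(u5)
        frame = (n - end) % 3
    rec = SequenceRecord(tid, seq, alphabet="nt")
    return rec, {"strand": strand, "frame": frame, "start": start, "end": end}


def _containing_orf_id(rec: SequenceRecord, strand: str, protein: str) -> str:
    for orf in find_orfs(rec, min_aa=10):
        if orf.strand == strand and protein in orf.protein:
            return orf.orf_id
    raise RuntimeError(f"planted protein not recovered in {rec.id}")


def generate_counts(
    manifest: TruthManifest,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Negative-binomial count table (transcript × 4 samples), long format.

    Gland samples of enriched toxins use mean = enrichment_factor × body mean;
    gland-only toxins have body mean 0.  Two colonies are independent draws.
    ``nb_dispersion = inf`` falls back to Poisson sampling.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)

    def draw(mean: float) -> int:
        if mean <= 0:
            return 0
        if np.isinf(config.nb_dispersion):
            return int(rng.poisson(mean))
        size = config.nb_dispersion
        return int(rng.negative_binomial(size, size / (size + mean)))

    rows = []
    for tid in sorted(manifest.entries):
        e = manifest.entries[tid]
        body_mean = 0.0 if e.gland_only else e.base_mean
        gland_mean = (
            config.enrichment_factor * e.base_mean if e.gland_enriched else e.base_mean
        )
        for sample, mean in (
            ("gland_c1", gland_mean),
            ("gland_c2", gland_mean),
            ("body_c1", body_mean),
            ("body_c2", body_mean),
        ):
            rows.append(
                {
                    "transcript_id": tid,
                    "length": e.length,
                    "sample_id": sample,
                    "count": draw(mean),
                }
            )
    return pd.DataFrame(rows, columns=["transcript_id", "length", "sample_id", "count"])


def _distinct_peptides(protein: str, k: int, rng) -> list[str]:
    peptides: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(peptides) < k and attempts < 200:
        attempts += 1
        length = int(rng.integers(8, 16))
        if length >= len(protein):
            length = max(4, len(protein) - 1)
        start = int(rng.integers(0, len(protein) - length + 1))
        pep = protein[start : start + length]
        if pep not in seen:
            seen.add(pep)
            peptides.append(pep)
    return peptides


def generate_psm_table(
    manifest: TruthManifest,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Target/decoy PSM table keyed by the planted ORF ids.

    Every proteome-verified toxin receives at least two distinct target
    peptides with scores above ``psm_target_mean − 2·psm_target_sd``; decoy
    scores come from the lower-mean Gaussian.  Both are truncated at 0.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    rows = []
    floor = max(0.0, config.psm_target_mean - 2 * config.psm_target_sd)
    for tid in sorted(manifest.entries):
        e = manifest.entries[tid]
        if not (e.is_toxin and e.proteome_verified):
            continue
        k = int(rng.integers(2, 5))
        for i, pep in enumerate(_distinct_peptides(e.protein, k, rng)):
            score = rng.normal(config.psm_target_mean, config.psm_target_sd)
            if i < 2:
                # the two guaranteeing peptides stay clear of the cutoff region
                while score <= floor:
                    score = rng.normal(config.psm_target_mean, config.psm_target_sd)
            score = max(0.0, score)
            rows.append(
                {
                    "peptide": pep,
                    "orf_id": e.orf_id,
                    "score": round(float(score), 2),
                    "is_decoy": False,
                }
            )
    n_decoys = config.n_decoy_psms if config.n_decoy_psms is not None else len(rows)
    for i in range(n_decoys):
        pep = _random_protein(rng, int(rng.integers(8, 16)))
        score = max(0.0, rng.normal(config.psm_decoy_mean, config.psm_decoy_sd))
        rows.append(
            {
                "peptide": pep,
                "orf_id": f"DECOY_{i:05d}",
                "score": round(float(score), 2),
                "is_decoy": True,
            }
        )
    return pd.DataFrame(rows, columns=["peptide", "orf_id", "score", "is_decoy"])


def _make_egf_seeds(config: SimConfig, rng) -> list[tuple[str, str, int]]:
    """(seed_id, precursor, signal_len) triples spanning the mature-length range."""
    if config.n_egf == 0:
        return []
    lo, hi = config.mature_len_range
    n_seeds = min(3, config.n_egf)
    lengths = sorted({lo, hi, (lo + hi) // 2})[:n_seeds]
    seeds = []
    for i, mature_len in enumerate(lengths):
        budget = mature_len - 6 - 8  # head + tail of 4 residues each
        gaps = rng.multinomial(budget, [0.2] * 5)
        protein, _ = generate_egf_precursor(
            config.signal_len, mature_len, tuple(int(g) for g in gaps), rng
        )
        seeds.append((f"EGF_SEED_{i + 1}", protein, config.signal_len))
    return seeds


def _make_barcodes(config: SimConfig, rng):
    """Barcode reference records and raw-read records with a planted species."""
    db = []
    refs = {}
    for i, species in enumerate(BARCODE_SPECIES):
        seq = _random_nt(rng, 658)
        refs[species] = seq
        db.append(
            SequenceRecord(
                f"BOLD{i + 1:04d}",
                seq,
                description=f"species={species.replace(' ', '_')}",
                alphabet="nt",
            )
        )
    reads = []
    species = SPECIES_BY_TAG[config.species_tag]
    if config.n_reads > 0:
        n_over = max(4, config.n_reads // 100)  # ~1% overrepresented
        slice_start = int(rng.integers(0, 658 - 100))
        over = refs[species][slice_start : slice_start + 100]
        for i in range(n_over):
            reads.append(SequenceRecord(f"R{len(reads):06d}", over, alphabet="nt"))
        for i in range(n_over // 2):  # truncated copies exercise prefix derep
            reads.append(SequenceRecord(f"R{len(reads):06d}", over[:90], alphabet="nt"))
        while len(reads) < config.n_reads:
            reads.append(
                SequenceRecord(
                    f"R{len(reads):06d}", _random_nt(rng, 100), alphabet="nt"
                )
            )
    return db, reads, species


def generate_dataset(config: SimConfig) -> Dataset:
    """One complete synthetic dataset, deterministic in ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    manifest = TruthManifest(
        species_tag=config.species_tag,
        barcode_species=SPECIES_BY_TAG[config.species_tag],
    )

    # reference panel: the family templates themselves
    panel = [
        SequenceRecord(f"REF_{fam}", template, description=f"family={fam}", alphabet="aa")
        for fam, template in sorted(config.families.items())
    ]
    seeds = _make_egf_seeds(config, rng)
    panel += [
        SequenceRecord(sid, prot, description="family=EGF", alphabet="aa")
        for sid, prot, _ in seeds
    ]

    # planted toxins: mutated family templates, then mutated EGF seeds
    planted: list[tuple[str, str]] = []  # (family, protein)
    for fam in sorted(config.n_toxins_per_family):
        template = config.families[fam]
        for _ in range(config.n_toxins_per_family[fam]):
            planted.append((fam, mutate_template(template, config.mutation_rate, rng)))
    for i in range(config.n_egf):
        _, seed_prot, _ = seeds[i % len(seeds)]
        planted.append(
            (
                "EGF",
                mutate_template(seed_prot, config.mutation_rate, rng, freeze_cys=True),
            )
        )

    transcripts: list[SequenceRecord] = []
    n_total = len(planted) + config.n_background
    order = rng.permutation(n_total)
    slots: list[tuple[str, str] | None] = list(planted) + [None] * config.n_background
    for idx, slot_i in enumerate(order):
        slot = slots[slot_i]
        tid = f"TX{idx:05d}"
        if slot is None:
            length = int(rng.integers(300, 901))
            rec = SequenceRecord(tid, _random_nt(rng, length), alphabet="nt")
            transcripts.append(rec)
            manifest.entries[tid] = ManifestEntry(
                transcript_id=tid,
                length=length,
                is_toxin=False,
                family="",
                base_mean=float(rng.lognormal(3.5, 1.2)),
            )
        else:
            fam, protein = slot
            rec, coords = _plant_transcript(protein, tid, rng)
            transcripts.append(rec)
            gland_only = bool(rng.random() < config.gland_only_frac)
            verified = bool(rng.random() < config.psm_verified_frac)
            manifest.entries[tid] = ManifestEntry(
                transcript_id=tid,
                length=len(rec.seq),
                is_toxin=True,
                family=fam,
                strand=coords["strand"],
                frame=coords["frame"],
                start=coords["start"],
                end=coords["end"],
                protein=protein,
                gland_enriched=True,
                gland_only=gland_only,
                proteome_verified=verified,
                orf_id=_containing_orf_id(rec, coords["strand"], protein),
                base_mean=float(rng.lognormal(3.5, 1.2)),
            )

    count_table = generate_counts(manifest, config, rng)
    psm_table = generate_psm_table(manifest, config, rng)

    # hormone panel: per seed one verified mutated relative (the intended
    # nearest neighbour) plus one closer but unverified decoy
    hormones: list[SequenceRecord] = []
    for i, (sid, prot, signal_len) in enumerate(seeds):
        mature = prot[signal_len:]
        egf_type = EGF_TYPES[i % len(EGF_TYPES)].replace(" ", "_")
        verified_rel = mutate_template(mature, 0.15, rng, freeze_cys=True)
        decoy = mutate_template(mature, 0.05, rng, freeze_cys=True)
        hormones.append(
            SequenceRecord(
                f"HORM{i + 1:03d}",
                verified_rel,
                description=f"type={egf_type} verified=true",
                alphabet="aa",
            )
        )
        hormones.append(
            SequenceRecord(
                f"PRED{i + 1:03d}",
                decoy,
                description="type=predicted_only verified=false",
                alphabet="aa",
            )
        )

    barcode_db, barcode_reads, _ = _make_barcodes(config, rng)

    egf_seed_records = [
        SequenceRecord(
            sid, prot, description=f"family=EGF signal={slen}", alphabet="aa"
        )
        for sid, prot, slen in seeds
    ]
    return Dataset(
        config=config,
        transcripts=transcripts,
        panel=panel,
        egf_seeds=egf_seed_records,
        hormone_panel=hormones,
        count_table=count_table,
        psm_table=psm_table,
        barcode_reads=barcode_reads,
        barcode_db=barcode_db,
        manifest=manifest,
    )
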