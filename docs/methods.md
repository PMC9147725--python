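# Methods

This note documents the models, rules and numerical choices behind
`myrmitox`, and what the synthetic-data experiments do and do not show.

## ORF model

Assembled transcripts are fragments without reliable start codons, so an ORF
is any maximal stop-free span between stop codons (or the sequence ends) in
any of the six reading frames, translated with the standard codon table and
reported whole if it reaches the minimum length (default 10 residues).  No
initiator methionine is required.  Ambiguity codes (N) translate to X; X
never terminates a span.  Coordinates are 1-based inclusive on the forward
strand with the strand stored separately, so every reported protein
re-translates from its cited coordinates (for minus-strand ORFs, from the
reverse complement of the cited span).

## Annotation

Each ORF is aligned locally (Smith–Waterman with affine gaps) against every
entry of a family-labeled reference panel under BLOSUM62.  Gap costs follow
the convention cost(k) = open + k·extend with open 11, extend 1, the common
default for protein search with this matrix.  E-values use the
Karlin–Altschul form E = K·m·n·exp(−λS) with the published gapped constants
for this scheme, λ = 0.267 and K = 0.041; hits with E > 10⁻³ are discarded.

Three report metrics drive ranking:

* similarity = 100 · positives / alignment columns.  A "positive" column
  aligns two residues with a positive BLOSUM62 score; gap columns count in
  the denominator and are never positive.  This positives-fraction reading
  of "similarity" is the standard one; it is isolated in one function
  (`hit_metrics`) so an alternative normalization could be substituted.
* query and subject coverage = 100 · aligned span / full sequence length.

Hits are sorted by similarity, query coverage and subject coverage, all
descending, with subject id (ascending) as a deterministic tie-break, and
the top hit assigns the family.  No heuristic seeding or word indexing is
used — panels are small enough that exact alignment of every pair is cheap;
an E-value gate computed from the optimal score skips the traceback for
hits that would be discarded anyway, without changing any reported hit.

## Proteomic verification

PSMs carry explicit decoy flags, so the FDR at a score threshold t is
estimated as (#decoys ≥ t)/(#targets ≥ t).  The adopted cutoff is the
smallest observed score with FDR ≤ q (default q = 0.01); candidate cutoffs
are the observed scores because the estimate is a step function that only
changes there.  Verification then applies, in order: decoy removal, a score
floor of max(30, FDR cutoff), and a requirement of at least two distinct
peptide sequences per ORF.  "Two peptides" means two distinct sequences, not
two spectra of one peptide — the stricter, standard reading of protein-level
evidence.  Peptides shared between ORFs count for each; no parsimony
grouping is attempted.

## Quantification

TPM uses the transcript length as effective length: TPM_i = 10⁶·(c_i/l_i) /
Σ_j (c_j/l_j) per sample.  No fragment-length correction is applied — the
count tables carry no fragment model, and the divergence from
assembler-internal TPM is deliberate and documented here.  Species-level
expression is the arithmetic mean of the two colony TPMs per tissue.
Enrichment categories use strict inequalities: `gland_only` (body mean
exactly 0, gland mean > 0), `gland_higher` (gland > body > 0), otherwise
`not_enriched`.

Composition summaries report per family the diversity share
(100·n_family/n_total) and abundance share (100·family gland TPM / total
candidate gland TPM).  The abundance denominator is the summed mean gland
TPM of the venom candidates only: the three published M. rubra family
abundances sum to exactly 100.0, which identifies candidate-relative shares
as the intended quantity.  Gland samples only are used, since venom-gland
composition is the object described.  Reported percentages are rounded
half-up to one decimal; full precision is kept internally, so the rounded
shares can sum to 100 ± 0.2 at most.

## EGF-like toxins

Seeds (known EGF-like precursors) are aligned against every ORF with a
permissive E ≤ 10; the decisive filter is full seed coverage (q_cov = 100%),
which only a genuine homolog spanning the whole precursor can reach.  The
candidate precursor is the ORF span aligned to the seed; exact duplicates
are collapsed deterministically.  Signal-peptide lengths are inputs (from an
external predictor); when a reference cleavage column from alignment to
known toxins is available and differs, it overrides the prediction — in the
shipped pipeline a 28-residue prediction is corrected to the 30-residue
reference position.  The mature peptide is the precursor suffix.

Characterization:

* Scaffold: positions of all cysteines in the mature peptide and the five
  inter-cysteine gaps; the canonical EGF fold has exactly six cysteines.
* Molecular weight: sum of average (not monoisotopic) residue masses plus
  one water, reported in kDa to one decimal — the precision appropriate for
  a ~5–6 kDa peptide.
* Isoelectric point: pH at which the Henderson–Hasselbalch net charge of
  termini plus D, E, C, Y, K, R, H side chains crosses zero, found by
  bisection on [0, 14] to |charge| < 10⁻⁴.  The pKa set is the Bjellqvist
  table used by the common proteomics servers, including its
  residue-specific terminal overrides; the table is module-level data so an
  alternative scale can be substituted.  The charge is strictly decreasing
  in pH, so the zero is unique.
* Naming: `U-MYRTX-<species tag>1<letter>` with letters assigned in
  descending mean gland TPM (ties broken by mature sequence), identical
  mature sequences sharing one name.  The "U" prefix designates toxins
  without a known molecular target; naming is injective per species and
  stable across runs.
* Type classification: panel hits sorted by similarity descending (panel id
  breaks ties); the first *empirically verified* entry whose length is
  within ±50% of the query's is chosen and contributes its type label
  (TGF-like, epiregulin-like, HBEGF-like, Spitz-like, betacellulin-like).
  The ±50% window parameterizes "similar sequence length", for which no
  published number exists.

## Species verification

Reads duplicated at ≥ 0.1% frequency (the usual QC overrepresentation
convention; inclusive bound) are prefix-dereplicated — a sequence that is a
strict prefix of another merges into the longer one, counts summed,
processed longest-first so the result is order-invariant — and then matched
against CO1 barcode references by exact substring search on both strands.
Exact search replaces a heuristic aligner because only 100%-identity,
100%-coverage hits are retained anyway, making the two provably equivalent.
Multiple matches per read are kept and a per-species tally is reported; no
single-species decision is forced when references conflict.

## Synthetic data

The generator emulates one species sampled as in the study design: two
colonies, venom-gland and body tissue, one assembled transcriptome.

* Toxins are fixed family templates mutated at a per-site substitution rate
  (default 10%), giving controllable similarity to the panel.  The first and
  last residues of a template are never mutated, and cysteines of EGF
  templates are neither replaced nor introduced: this keeps full-coverage
  seed alignment and scaffold recovery well-defined (a terminal mismatch
  would be clipped by any local aligner, and coverage would drop below 100%
  for reasons unrelated to homology).
* EGF precursors have a cysteine-free signal (default 30 residues) and a
  mature peptide of 46–56 residues with six cysteines at configurable
  spacing, matching the published length band for these toxins.
* Background transcripts are uniform-random nucleotide sequences, which
  avoids accidental homology with the templates.
* Counts are negative binomial with mean μ and dispersion k
  (variance μ + μ²/k, default k = 10; k = ∞ degrades to Poisson); per-
  transcript base means are log-normal.  Gland means of enriched toxins are
  enrichment_factor × base (default 10×); a configurable fraction of toxins
  (default 0.3) is gland-only with body mean 0.  Colonies are independent
  draws.  The published work reports no per-colony variability, so the
  dispersion default is a free, documented choice.
* PSM scores are truncated Gaussians — targets N(60, 15), decoys N(15, 8) —
  which places the 1% decoy-FDR crossing near the score-30 floor and makes
  the floor meaningful.  Every verified toxin gets ≥ 2 distinct peptides
  drawn from its protein with scores above mean − 2 SD.
* Barcode reads are slices of the planted species' reference at ~1%
  frequency (plus truncated copies to exercise prefix dereplication) among
  unique random reads; references are 658-nt random sequences for six ant
  species.

The default problem sizes used by the analysis scripts, tests and the
acceptance script — 23 planted toxins, 60 background transcripts, 1000
barcode reads — were chosen to mirror the scale of a plausible venom
inventory while keeping a full pipeline run in the tens of seconds.

What passing recovery tests shows: the triage rules (E-value filter,
ranking, FDR/score/peptide filters, 100%-coverage mining, TPM bookkeeping)
are implemented correctly and are mutually consistent at realistic
signal-to-noise.  What it does not show: robustness to assembly artifacts,
chimeras, sequencing error, incomplete ORFs, paralog ambiguity or biased
peptide detectability — none of which the generator models (deliberately;
they are properties of upstream tools that this package consumes).

## Degenerate inputs and tie-breaks

Empty hit lists annotate as `unannotated`; an all-zero count sample has TPM
0 everywhere (not NaN); FDR may be unattainable (no cutoff exists), in which
case no PSM passes; equal gland and body means are `not_enriched` (strict
inequality); identical sort keys fall back to lexicographic ids everywhere a
deterministic order is needed.  More than 26 distinct mature EGF sequences
in one family number is a naming overflow error rather than silent
wrap-around.
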