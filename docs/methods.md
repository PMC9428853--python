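# Methods

## Model and assumptions

The package treats candidate nomination as a deterministic filter cascade
over reported O-GlcNAc sites. A *site* is identified by
`(protein_accession, position)` with 1-based, inclusive numbering throughout
the public API; the reported residue letter is data, not part of the key.
Each stage is a pure predicate on a site (given its protein and auxiliary
evidence), so the funnel is monotone by construction: every stage's retained
set is a subset of the previous stage's, and every excluded site carries
exactly one reason code naming the stage that dropped it.

Key modelling choices, where the underlying decision rule left room:

- **QC rule order.** The three published exclusion rules plus the Ser/Thr
  sanity rule are applied in a fixed order (`n_linked` →
  `misannotated_peptide` → `extracellular` → `not_ser_thr`) so exclusion
  logs are deterministic. Peptide matching is exact and case-insensitive,
  with no I/L equivalence and no missed-cleavage expansion, and the
  peptide's modified offset must land on the claimed position.
  "Exclusively extracellular" means every known localization term is in
  {extracellular, secreted}; an empty localization set is *unknown*, passes
  the rule, and is logged with a warning.
- **Per-site filtering.** Sites are filtered individually; a protein remains
  a candidate while at least one of its sites survives.
- **Conservation equivalence.** The default test is S/T-interchangeability
  (both residues are O-GlcNAc-competent); `strict_identity` is a
  configuration switch. A site aligned to a gap in any panel species counts
  as absent, hence not conserved. The verdict is a conjunction over
  species, so it is invariant to panel iteration order and monotone under
  panel growth.
- **Fallback species.** A missing rat/rabbit/sheep ortholog is replaced by
  the first available fallback (bovine, then porcine, then chimpanzee) not
  already serving another slot, with the substitution recorded.

## Pairwise alignment

The external multiple-alignment step is replaced by an in-package global
pairwise aligner (Needleman–Wunsch with Gotoh affine-gap states): each
ortholog is aligned to the human reference and site coordinates are mapped
through the alignment. Scoring defaults are BLOSUM62 with gap open 10 and
gap extend 1; a gap run of length L costs `open + (L−1)·extend`. Traceback
tie-breaking is fixed — prefer diagonal, then up, then left — so the chosen
alignment, and therefore every mapped coordinate, is identical across
platforms. Direct switches between the two gap states are allowed at
gap-open cost, which makes the optimum agree with unrestricted enumeration
over all gapped alignments; with protein matrices and these penalties such
columns never appear in an optimal path. The row recurrences are
numpy-vectorised; the within-row horizontal-gap state is resolved with a
running-maximum scan, giving O(nm) time with small constants. Precomputed
alignments (aligned FASTA or Clustal, read with Biopython) can be supplied
and take precedence over the internal aligner.

Correctness is checked two independent ways: exhaustive enumeration of all
gapped alignments on random instances with lengths ≤ 8, and Biopython's
`PairwiseAligner` scores on realistic protein pairs.

## Accessibility

Two evidence routes, with structure taking precedence when both are
available:

- **Disorder profiles.** IUPred2A-style per-residue scores in [0, 1].
  Default semantics follow the predictor's convention: score strictly above
  0.5 means disordered, hence accessible to the OGT active site. Because
  published protocol text sometimes states the inverse mapping, the literal
  behaviour is available behind `paper_literal_disorder`; flipping the flag
  inverts every label exactly, so either convention can be reproduced
  without guessing intent.
- **Structures.** Standard PDB files are read with gemmi. A residue absent
  from the resolved set is taken as disordered in the crystal, hence
  accessible. A resolved residue is ordered when its backbone dihedrals
  fall in canonical secondary-structure boxes — helix φ ∈ [−180°, −30°],
  ψ ∈ [−80°, 40°]; strand φ ∈ [−180°, −40°], ψ ∈ [60°, 180°] — a simple
  region heuristic standing in for manual molecular-graphics inspection.
  Resolved coil defaults to accessible (configurable). Dihedrals follow the
  IUPAC convention, reported in (−180°, 180°], and are cross-checked against
  gemmi's torsion routine; they are invariant under rigid motions to below
  1e−6° and flip sign under mirror reflection. Reported values are rounded
  to integer degrees.

Accessible/disordered sites are labelled post-translationally modified;
ordered sites are candidates for co-translational modification on the
nascent chain; a protein with both kinds is labelled `both`.

Because deposited coordinate files cannot be bundled, the worked structural
examples use synthetic fragments built by internal-coordinate (NeRF)
placement with ideal bond geometry and trans peptide bonds: a three-residue
loop planted at φ = −57°, ψ = 147° (the reference conformation of the
β-tubulin O-GlcNAc site S172) and a serine-hydroxyl/glutamate-carboxylate
contact planted at 3.3 Å (the actin S365–E364 arrangement). Construction
(rotation about an axis from internal coordinates) and measurement (torsion
from four points) are independent algebra, so recovery of the planted values
is a genuine two-route check of the measurement utilities — but it validates
the utilities, not the deposited structures themselves.

## Variant screen

Protein-level missense variants (HGVS p. three-letter or compact one-letter
form; synonymous and stop changes rejected) are intersected with O-GlcNAc
sites on the same protein within a ±5-residue window, inclusive at both
ends; a variant may hit several sites, one hit each. PolyPhen-2 HumVar
scores are consumed, never computed, and banded with strict inequalities:
score > 0.85 probably damaging, score < 0.15 likely benign, otherwise
possibly damaging, missing unscored. Triage retains
pathogenic/likely-pathogenic hits outright and uncertain-significance hits
banded probably damaging. Aggregate significance labels
("Pathogenic/Likely pathogenic") normalise to the stronger token. The same
triage applies at exact and proximal positions; the hit table labels the
relation so stricter conventions for proximal hits can be recovered
downstream. A reference-residue mismatch between a variant and the supplied
sequence is logged as a warning, never silently dropped. Variants arrive as
TSV or as VCF 4.x with the consequence carried in INFO (read with cyvcf2).

## Synthetic cohort and what passing it shows

`SyntheticConfig` defaults define the cohort used by the test suite and the
acceptance script: 50 proteins of 240–400 residues (residues i.i.d. from a
fixed Swiss-Prot-like frequency table), three true sites per protein on
planted S/T positions, ten QC decoys per class (sites on asparagine,
corrupted evidence peptides, sites on exclusively extracellular proteins),
40% of genes ID/DD-flagged, 70% of sites conserved, 80% inside functional
intervals, 60% accessible, orthologs at 5% substitution and 1% indel
divergence, one of rat/rabbit/sheep withheld for 3.84% of proteins (bovine
standing in), and 100 planted variants split across exact/proximal/distant
relations and significance classes. Damaging predictor scores are drawn in
(0.85, 1] and benign scores in [0, 0.15) (scaled Beta draws with means
≈ 0.95 and 0.05), so score class determines band deterministically.
Site positions are at least 13 residues apart and variants planted as
"distant" are more than 5 residues from every site, so each planted variant
resolves to exactly one intended hit. Alignment-critical neighbourhoods
(site ± 3) are protected from substitutions and indels (length 1–3) never
touch site ± 6, keeping ground-truth coordinate mapping well defined. All
randomness flows from a single numpy PCG64 generator, making every bundle
byte-identical for a given (config, seed).

The generator plants *separable* truth: conserved sites keep their exact
residue in every species, non-conserved sites are forcibly substituted in
exactly one species, and disorder means (0.9 vs 0.1) are far from the 0.5
threshold. Perfect precision/recall on this cohort therefore shows that the
cascade's logic, coordinate mapping and bookkeeping are correct — not that
the method would be error-free on real data, where conservation is graded,
disorder scores hover near threshold, site tables carry coordinate-transfer
errors, and the ID/DD flag reflects curation noise. The no-signal disorder
configuration (both means 0.5) is exercised in tests as the degenerate case
where recovery collapses toward chance.

## Numerical and degenerate-input choices

- Alignment DP uses float64 with an exact-tie tolerance of 1e−9; integer
  matrices and penalties make comparisons exact in practice.
- Disorder threshold comparisons are strict (`>`), so a score of exactly
  0.5 is ordered under default semantics; band cut-offs are likewise strict
  at 0.85 and 0.15.
- Torsions of near-collinear atom quadruples raise `degenerate_geometry`;
  missing neighbour atoms raise `undefined_dihedral`; a structure with no
  coverage of the queried position raises `no_coverage` and the caller
  falls back to the disorder profile.
- Ambiguous amino-acid letters (B, Z, X, U, O) are rejected at load with the
  offending position named, keeping substitution scoring total.
- An empty localization set, an unscored variant and an empty variant table
  are all legal inputs with defined behaviour (pass-with-warning, band
  `unscored`, empty summary).

## Problem sizes

The default cohort (50 proteins, ~180 site reports, 200 ortholog
alignments of ~300×300, 100 variants) runs the full cascade in about one
second; the brute-force oracle comparisons use 200 random instances with
sequence lengths ≤ 8, where exhaustive enumeration is tractable. These
sizes make the planted-truth checks exact while keeping the whole suite
fast to rerun.

## Known limitations

- Orthology is taken as given; the package neither infers orthologs nor
  scores conservation phylogenetically.
- Site coordinates must already be expressed on the supplied reference
  sequence; cross-species coordinate transfer is logged as
  `residue_mismatch`, never guessed.
- The functional-region filter and the ID/DD flag are curated inputs; the
  pipeline is honest that these judgments are data.
- The dihedral-box classifier is a heuristic stand-in for expert structural
  inspection and ignores side-chain packing and quaternary context.
- Percentage tallies by protein class depend on the annotation's coverage;
  the denominator convention (annotated candidates only) is fixed and
  documented in `tally_classes`.
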