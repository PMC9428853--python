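# glycofunnel

Missense variants in *OGT*, the enzyme that attaches O-GlcNAc to serine and
threonine residues of nucleocytoplasmic proteins, cause a congenital disorder
of glycosylation (OGT-CDG) presenting as X-linked intellectual disability.
Which OGT substrates actually *convey* the phenotype when they lose their
O-GlcNAc is unknown. `glycofunnel` implements a filter-based discovery
cascade that nominates candidate conveyer proteins from pooled O-GlcNAc
site-mapping data, together with a ClinVar-style screen for pathogenic
missense variants at or near O-GlcNAc sites. It is aimed at glycobiology and
neurodevelopmental-genetics groups who want to run, audit or extend this kind
of candidate triage on their own compilations.

## The cascade

Reported O-GlcNAc sites from per-study tables are pooled by
`(accession, position)` and pushed through five filters, in fixed order:

1. **Quality control** — a site is dropped if the reported residue is
   asparagine (an N-linked misassignment), if the evidence peptide is absent
   from the full-length sequence or places the modified residue elsewhere
   (misannotation), or if the protein is exclusively extracellular.
2. **Disease association** — the encoding gene must have been reported as
   the sole pathogenic variant in a patient with intellectual disability or
   developmental delay (ID/DD), supplied as a precomputed gene–disease table.
3. **Conservation** — the site must be an O-GlcNAc-competent residue
   (Ser/Thr by default) at the aligned position in every species of an
   ortholog panel (human, mouse, rat, rabbit, sheep; bovine, porcine and
   chimpanzee stand in, in that order of preference, when a species is
   missing). Orthologs are aligned to the human reference by global
   Needleman–Wunsch alignment with affine gaps (BLOSUM62, gap open 10,
   extend 1); precomputed alignments can be ingested instead. A site aligned
   to a gap is absent, hence not conserved.
4. **Functional region** — the site must fall inside a user-supplied
   annotated interval (domains, motifs, active sites); this judgment is
   literature curation, so it enters as data, not computation.
5. **Accessibility split** — surviving sites are classed as
   accessible/disordered (post-translationally modified) or
   inaccessible/ordered (candidates for co-translational modification),
   from a deposited structure when one covers the site (backbone φ/ψ
   dihedral regions) or else from IUPred2A-style disorder profiles
   (score > 0.5 ⇒ disordered). A protein with sites of both kinds is
   labelled `both`.

The companion variant screen intersects protein-level missense variants with
O-GlcNAc sites exactly and within ±5 residues, bands PolyPhen-2 HumVar
scores (> 0.85 probably damaging, < 0.15 likely benign) and retains
pathogenic/likely-pathogenic hits plus uncertain-significance hits predicted
probably damaging.

A fully deterministic synthetic-cohort generator (`glycofunnel.synthetic`)
emulates every input with planted truth — QC decoys, ID/DD flags, conserved
and non-conserved sites, withheld orthologs, disorder profiles, and on-site,
proximal and distant variants — so the whole cascade is testable without
any database download.

## Worked example

```python
from glycofunnel.datasets import load_id_dd_variant_table, id_dd_variant_sites
from glycofunnel.variants import screen

variants = load_id_dd_variant_table()   # 8 published ClinVar variants
result = screen(variants, id_dd_variant_sites())
print(result.summary)
```

prints

```
{'n_variants': 8, 'n_sites': 6, 'n_hits': 8, 'n_exact': 8, 'n_proximal': 0,
 'n_retained': 8, 'n_retained_pathogenic': 2, 'n_retained_predicted': 6}
```

All eight variants sit exactly on an O-GlcNAc site; the two TUBB2B S172
alleles are retained as (likely) pathogenic and the six
uncertain-significance variants are retained because their HumVar scores
(0.855–0.995) all clear the 0.85 probably-damaging cut-off.

The full cascade on a synthetic cohort, from the shell:

```bash
glycofunnel simulate --seed 1 --outdir bundle/
glycofunnel run-all --bundle bundle/ --outdir out/
```

The second command prints the funnel counts, e.g.

```
{"pooled": 180, "qc": 150, "id_dd": 48, "conserved": 31, "functional_region": 24}
```

— 180 pooled site reports, 150 surviving quality control (30 planted decoys
removed), 48 on ID/DD-associated proteins, 31 conserved across the panel and
24 inside annotated functional regions — and writes the candidate table,
funnel/exclusion JSON, low-confidence rescue scan and a plain gene list
under `out/`.

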