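"""Bundled reference tables.

``id_dd_variant_table.tsv`` lists the eight published ClinVar missense
variants that fall exactly on conserved O-GlcNAc sites in patients with
intellectual disability / developmental delay, with their reported clinical
significance and, for the variants of uncertain significance, PolyPhen-2
HumVar scores.  It serves as the worked example for the banding and triage
rules.
"""

from __future__ import annotations

from importlib import resources

from .model import GlycoSite
from .variants import VariantRecord, load_variant_table


def load_id_dd_variant_table() -> list[VariantRecord]:
    """The eight ClinVar missense variants at conserved O-GlcNAc sites."""
    ref = resources.files("glycofunnel") / "data" / "id_dd_variant_table.tsv"
    with resources.as_file(ref) as path:
        return load_variant_table(path)


def id_dd_variant_sites() -> list[GlycoSite]:
    """O-GlcNAc sites at each bundled variant position (the site database
    row each of those variants intersects exactly)."""
    variants = load_id_dd_variant_table()
    seen = set()
    sites = []
    for v in variants:
        key = (v.protein_accession, v.position)
        if key in seen:
            continue
        seen.add(key)
        sites.append(
            GlycoSite(
                protein_accession=v.protein_accession,
                position=v.position,
                residue=v.ref_aa,
            )
        )
    return sites
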