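"""Cross-species conservation of O-GlcNAc sites over an ortholog panel.

The panel is human plus four further species (default mouse, rat, rabbit,
sheep).  When one of the non-human species lacks an ortholog, bovine,
porcine or chimpanzee sequences stand in, in descending order of preference,
with the substitution recorded.  A site is conserved when the aligned residue
in every non-human panel member is O-GlcNAc-competent: by default Ser and Thr
are interchangeable (``st_equivalent``); ``strict_identity`` demands the
exact reference letter.  A site aligned against a gap in any species is not
conserved — the residue is absent in that species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .alignment import GAP, PairAlignment, ScoringParams, align_pair, map_position
from .model import GlycoFunnelError, GlycoSite, PipelineConfig, ProteinRecord


@dataclass
class OrthologPanel:
    """Human reference plus per-species orthologs with fallback provenance."""

    reference: ProteinRecord
    members: dict[str, ProteinRecord]  # panel species slot -> record used
    substitutions: dict[str, str] = field(default_factory=dict)  # slot -> species used

    def __post_init__(self):
        if self.reference.species != "human":
            raise GlycoFunnelError(
                "bad_reference", "panel reference must be the human sequence"
            )

    @property
    def size(self) -> int:
        return 1 + len(self.members)


@dataclass(frozen=True)
class ConservationVerdict:
    conserved: bool
    per_species: Mapping[str, str]  # species slot -> aligned residue or '-'
    mode: str


def index_ortholog_pool(
    records, key: str = "gene_symbol"
) -> dict[tuple[str, str], ProteinRecord]:
    """Index ortholog records by ``(gene, species)`` for panel assembly."""
    pool: dict[tuple[str, str], ProteinRecord] = {}
    for rec in records.values() if isinstance(records, dict) else records:
        pool[(getattr(rec, key), rec.species)] = rec
    return pool


def assemble_panel(
    reference: ProteinRecord,
    ortholog_pool: Mapping[tuple[str, str], ProteinRecord],
    config: PipelineConfig | None = None,
) -> OrthologPanel:
    """Fill the species panel for one protein, using fallbacks for gaps.

    Each missing panel species is replaced by the first fallback species
    (in configured preference order) that is available in the pool and not
    already serving another slot.  If a slot cannot be filled the panel is
    incomplete and a structured error lists the missing slots.
    """
    config = config or PipelineConfig()
    gene = reference.gene_symbol
    members: dict[str, ProteinRecord] = {}
    substitutions: dict[str, str] = {}
    used_fallbacks: set[str] = set()
    missing: list[str] = []
    for species in config.species_panel:
        if species == "human":
            continue
        rec = ortholog_pool.get((gene, species))
        if rec is not None:
            members[species] = rec
            continue
        for fb in config.fallback_order:
            if fb in used_fallbacks:
                continue
            fb_rec = ortholog_pool.get((gene, fb))
            if fb_rec is not None:
                members[species] = fb_rec
                substitutions[species] = fb
                used_fallbacks.add(fb)
                break
        else:
            missing.append(species)
    if missing:
        raise GlycoFunnelError(
            "incomplete_panel",
            f"{gene}: no ortholog or fallback for panel slots {missing}",
        )
    return OrthologPanel(reference=reference, members=members, substitutions=substitutions)


def _residue_ok(aligned: str, reference_residue: str, mode: str) -> bool:
    if aligned == "-":
        return False
    if mode == "st_equivalent":
        return aligned in ("S", "T")
    return aligned == reference_residue


def assess_conservation(
    site: GlycoSite,
    panel: OrthologPanel,
    config: PipelineConfig | None = None,
    alignments: Optional[Mapping[str, PairAlignment]] = None,
) -> ConservationVerdict:
    """Judge one validated site across the panel.

    ``alignments`` may supply precomputed reference-to-member alignments
    (e.g. projected from an external MSA), keyed by panel slot; they take
    precedence over the internal aligner.  The verdict is independent of
    member iteration order (the rule is a conjunction over species).
    """
    config = config or PipelineConfig()
    params = ScoringParams(
        matrix_name=config.substitution_matrix,
        gap_open=config.gap_open,
        gap_extend=config.gap_extend,
    )
    per_species: dict[str, str] = {}
    conserved = True
    for species in sorted(panel.members):
        member = panel.members[species]
        if alignments is not None and species in alignments:
            aln = alignments[species]
        else:
            aln = align_pair(panel.reference.sequence, member.sequence, params)
        mapped = map_position(aln, site.position)
        residue = "-" if mapped is GAP else member.sequence[mapped - 1]
        per_species[species] = residue
        if not _residue_ok(residue, site.residue, config.conservation_mode):
            conserved = False
    return ConservationVerdict(
        conserved=conserved, per_species=per_species, mode=config.conservation_mode
    )


def filter_conservation(
    sites,
    proteome: Mapping[str, ProteinRecord],
    panels: Mapping[str, OrthologPanel],
    config: PipelineConfig | None = None,
) -> tuple[list[GlycoSite], list[GlycoSite], dict[tuple[str, int], ConservationVerdict]]:
    """Apply the conservation filter to a site collection.

    Returns retained sites, excluded sites (reason ``not_conserved``) and the
    per-site verdicts.  Alignments are computed once per (protein, species)
    pair and reused across sites via caching in the panel loop.
    """
    config = config or PipelineConfig()
    params = ScoringParams(
        matrix_name=config.substitution_matrix,
        gap_open=config.gap_open,
        gap_extend=config.gap_extend,
    )
    retained, excluded = [], []
    verdicts: dict[tuple[str, int], ConservationVerdict] = {}
    aln_cache: dict[str, dict[str, PairAlignment]] = {}
    for site in sites:
        panel = panels.get(site.protein_accession)
        if panel is None:
            raise GlycoFunnelError(
                "missing_panel",
                f"no ortholog panel for {site.protein_accession!r}",
            )
        if site.protein_accession not in aln_cache:
            aln_cache[site.protein_accession] = {
                sp: align_pair(panel.reference.sequence, rec.sequence, params)
                for sp, rec in panel.members.items()
            }
        verdict = assess_conservation(
            site, panel, config, alignments=aln_cache[site.protein_accession]
        )
        verdicts[site.key] = verdict
        if verdict.conserved:
            retained.append(site.mark("conserved", "retained", "pass"))
        else:
            excluded.append(site.mark("conserved", "excluded", "not_conserved"))
    return retained, excluded, verdicts
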