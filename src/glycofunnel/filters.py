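"""Stage-1 pooling/quality control of O-GlcNAc sites and stage-2 ID/DD
disease filtering.

QC drops a reported site when (in fixed rule order) the reported residue is
asparagine (an N-linked glycosylation misassignment), the evidence peptide is
absent from the full-length sequence or does not place the modified residue at
the claimed position (misannotation), the protein is exclusively
extracellular, or the residue is not Ser/Thr.  The fixed order makes
exclusion logs deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import GlycoFunnelError, GlycoSite, ProteinRecord

#: QC rules in the order they are applied; ``pass`` means retained.
QC_REASONS = ("n_linked", "misannotated_peptide", "extracellular", "not_ser_thr")


@dataclass(frozen=True)
class QCVerdict:
    retained: bool
    reason: str  # pass | n_linked | misannotated_peptide | extracellular | not_ser_thr

    def __post_init__(self):
        if self.retained != (self.reason == "pass"):
            raise GlycoFunnelError(
                "bad_verdict", "retained must be true iff reason is 'pass'"
            )


def pool_sites(per_study_tables: Sequence[Iterable[GlycoSite]]) -> list[GlycoSite]:
    """Merge per-study site tables into one deduplicated collection.

    Rows sharing ``(accession, position)`` collapse to a single site whose
    ``source_studies`` is the union over studies; distinct evidence peptides
    are all kept (the first becomes the primary evidence, the rest stay in
    provenance order via the study tags).  The result is independent of input
    order: sites are sorted by key and study tags are sorted.
    """
    pooled: dict[tuple[str, int], GlycoSite] = {}
    peptides: dict[tuple[str, int], list[tuple[str, int]]] = {}
    for table in per_study_tables:
        for site in table:
            key = site.key
            if key not in pooled:
                pooled[key] = site
                peptides[key] = []
                if site.evidence_peptide:
                    peptides[key].append(
                        (site.evidence_peptide, site.peptide_site_offset)
                    )
                continue
            prev = pooled[key]
            if prev.residue != site.residue:
                raise GlycoFunnelError(
                    "residue_conflict",
                    f"site {key}: studies disagree on the residue letter "
                    f"({prev.residue!r} vs {site.residue!r})",
                )
            ev = peptides[key]
            if site.evidence_peptide and (
                (site.evidence_peptide, site.peptide_site_offset) not in ev
            ):
                ev.append((site.evidence_peptide, site.peptide_site_offset))
            pooled[key] = prev.evolve(
                source_studies=prev.source_studies + site.source_studies
            )
    out = []
    for key in sorted(pooled):
        site = pooled[key]
        ev = peptides[key]
        primary_pep, primary_off = ev[0] if ev else ("", 1)
        out.append(
            site.evolve(
                source_studies=tuple(sorted(set(site.source_studies))),
                evidence_peptide=primary_pep,
                peptide_site_offset=primary_off,
            ).mark("pooled", "retained", "pass")
        )
    return out


def _peptide_matches(site: GlycoSite, protein: ProteinRecord) -> bool:
    """True when the evidence peptide is an exact contiguous substring of the
    full-length sequence *and* its modified offset lands on the claimed
    position.

    Matching is exact and case-insensitive with no I/L equivalence and no
    missed-cleavage expansion.  An occurrence anywhere consistent with the
    claimed position counts.
    """
    pep = site.evidence_peptide
    if not pep:
        # No peptide reported: nothing to contradict the annotation.
        return True
    # Expected 0-based start such that the peptide offset hits the site.
    start = site.position - site.peptide_site_offset  # 0-based
    if start < 0:
        return False
    return protein.sequence[start : start + len(pep)] == pep


def qc_site(site: GlycoSite, protein: ProteinRecord) -> QCVerdict:
    """Apply the pooled-site quality-control rules in fixed order.

    Pure function: identical inputs always yield the identical verdict.
    """
    if site.residue == "N":
        return QCVerdict(False, "n_linked")
    if (
        site.position > len(protein.sequence)
        or protein.sequence[site.position - 1] != site.residue
        or not _peptide_matches(site, protein)
    ):
        return QCVerdict(False, "misannotated_peptide")
    if protein.exclusively_extracellular:
        return QCVerdict(False, "extracellular")
    if site.residue not in ("S", "T"):
        return QCVerdict(False, "not_ser_thr")
    if not protein.localization_terms:
        warnings.warn(
            f"site {site.key}: protein has no localization annotation; "
            "treating as not exclusively extracellular",
            stacklevel=2,
        )
    return QCVerdict(True, "pass")


def apply_qc(
    sites: Iterable[GlycoSite], proteome: Mapping[str, ProteinRecord]
) -> tuple[list[GlycoSite], list[GlycoSite]]:
    """Run :func:`qc_site` over a pooled collection.

    Returns ``(retained, excluded)``; every excluded site carries exactly one
    reason code in ``status_reason``.
    """
    retained, excluded = [], []
    for site in sites:
        protein = proteome.get(site.protein_accession)
        if protein is None:
            raise GlycoFunnelError(
                "unknown_protein",
                f"site {site.key} references unknown accession "
                f"{site.protein_accession!r}",
            )
        verdict = qc_site(site, protein)
        if verdict.retained:
            retained.append(site.mark("qc", "retained", "pass"))
        else:
            excluded.append(site.mark("qc", "excluded", verdict.reason))
    return retained, excluded


def filter_disease(
    sites: Iterable[GlycoSite], proteome: Mapping[str, ProteinRecord]
) -> tuple[list[GlycoSite], list[GlycoSite]]:
    """Keep sites on proteins whose gene is ID/DD associated.

    A protein passes when its gene was reported as the sole pathogenic
    variant in a patient with intellectual disability or developmental delay
    (precomputed ``id_dd_flag``).  Sites are filtered individually; a protein
    survives while at least one of its sites survives downstream.
    """
    retained, excluded = [], []
    for site in sites:
        protein = proteome.get(site.protein_accession)
        if protein is None:
            raise GlycoFunnelError(
                "unknown_protein",
                f"site {site.key} references unknown accession "
                f"{site.protein_accession!r}",
            )
        if protein.id_dd_flag:
            retained.append(site.mark("id_dd", "retained", "pass"))
        else:
            excluded.append(site.mark("id_dd", "excluded", "not_id_dd"))
    return retained, excluded
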