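"""Domain types, identifier conventions and validation shared by all stages.

Residue numbering is 1-based and inclusive everywhere in the public API; the
only 0-based arithmetic happens inside alignment internals.  A site is keyed
by ``(protein_accession, position)``; the reported residue letter is data, not
part of the key.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard one-letter amino-acid codes.  Ambiguity codes (B, Z, X)
#: and the rare translated letters (U, O) are rejected at load time so that
#: downstream alignment scoring stays well defined.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Species tokens accepted for ortholog panels.
SPECIES_TOKENS = (
    "human",
    "mouse",
    "rat",
    "rabbit",
    "sheep",
    "bovine",
    "porcine",
    "chimpanzee",
)

#: Localization tokens treated as "outside the cell" for the QC rule that
#: drops exclusively extracellular proteins.
EXTRACELLULAR_TOKENS = frozenset({"extracellular", "secreted"})


class GlycoFunnelError(ValueError):
    """Base class for structured validation/pipeline errors."""

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


@dataclass
class ProteinRecord:
    """A protein sequence with the annotations the funnel filters consume.

    Parameters
    ----------
    accession:
        Stable identifier, unique within a proteome.
    gene_symbol:
        HGNC-style gene symbol.
    species:
        One of :data:`SPECIES_TOKENS`.
    sequence:
        Amino-acid string over the 20 standard letters, positions 1-based.
    localization_terms:
        Subcellular localization tokens (``nucleus``, ``cytoplasm``,
        ``extracellular`` ...). Empty means unknown.
    id_dd_flag:
        True when the encoding gene has been reported as the sole pathogenic
        variant in a patient with intellectual disability or developmental
        delay.
    """

    accession: str
    gene_symbol: str = ""
    species: str = "human"
    sequence: str = ""
    localization_terms: frozenset[str] = frozenset()
    id_dd_flag: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GlycoFunnelError(
                "empty_sequence", f"{self.accession}: empty sequence"
            )
        if self.species not in SPECIES_TOKENS:
            raise GlycoFunnelError(
                "bad_species", f"{self.accession}: unknown species {self.species!r}"
            )
        self.sequence = self.sequence.upper()
        bad = [
            (i + 1, c) for i, c in enumerate(self.sequence) if c not in STANDARD_AA
        ]
        if bad:
            pos, letter = bad[0]
            raise GlycoFunnelError(
                "nonstandard_residue",
                f"{self.accession}: non-standard residue {letter!r} at position "
                f"{pos} (and {len(bad) - 1} more)" if len(bad) > 1 else
                f"{self.accession}: non-standard residue {letter!r} at position {pos}",
            )
        self.localization_terms = frozenset(
            t.strip().lower() for t in self.localization_terms if t.strip()
        )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """One-letter residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise GlycoFunnelError(
                "out_of_range",
                f"{self.accession}: position {position} outside 1..{len(self.sequence)}",
            )
        return self.sequence[position - 1]

    @property
    def exclusively_extracellular(self) -> bool:
        """True when every known localization term is extracellular/secreted.

        An empty localization set means *unknown* and does not count as
        extracellular.
        """
        return bool(self.localization_terms) and self.localization_terms <= EXTRACELLULAR_TOKENS


@dataclass
class GlycoSite:
    """One reported O-GlcNAc site with provenance and rolling filter status."""

    protein_accession: str
    position: int
    residue: str
    evidence_peptide: str = ""
    peptide_site_offset: int = 1
    source_studies: tuple[str, ...] = ()
    status: str = "pending"
    status_reason: str = ""
    #: Names of the stages that have acted on this site, in order.
    status_trail: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.position < 1:
            raise GlycoFunnelError(
                "bad_position",
                f"{self.key}: position must be >= 1, got {self.position}",
            )
        self.residue = self.residue.upper()
        self.evidence_peptide = self.evidence_peptide.upper()
        if self.evidence_peptide and not (
            1 <= self.peptide_site_offset <= len(self.evidence_peptide)
        ):
            raise GlycoFunnelError(
                "bad_peptide_offset",
                f"{self.key}: peptide offset {self.peptide_site_offset} outside "
                f"evidence peptide of length {len(self.evidence_peptide)}",
            )
        self.source_studies = tuple(self.source_studies)

    @property
    def key(self) -> tuple[str, int]:
        return (self.protein_accession, self.position)

    def evolve(self, **changes) -> "GlycoSite":
        return dataclasses.replace(self, **changes)

    def mark(self, stage: str, status: str, reason: str = "") -> "GlycoSite":
        """Return a copy with status set by *stage* and the trail extended."""
        return self.evolve(
            status=status,
            status_reason=reason,
            status_trail=self.status_trail + (stage,),
        )


@dataclass
class PipelineConfig:
    """Every numeric rule of the cascade and screen in one place.

    Defaults encode the published decision rules: a +/-5-residue variant
    window, an intrinsic-disorder threshold of 0.5, PolyPhen-2 HumVar
    cut-offs of 0.85 (probably damaging) and 0.15 (likely benign), a
    five-species conservation panel (human, mouse, rat, rabbit, sheep) with
    bovine, porcine and chimpanzee fallbacks in descending order of
    preference.
    """

    window: int = 5
    disorder_threshold: float = 0.5
    paper_literal_disorder: bool = False
    conservation_mode: str = "st_equivalent"
    species_panel: tuple[str, ...] = ("human", "mouse", "rat", "rabbit", "sheep")
    fallback_order: tuple[str, ...] = ("bovine", "porcine", "chimpanzee")
    polyphen_damaging_cutoff: float = 0.85
    polyphen_benign_cutoff: float = 0.15
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    coil_is_accessible: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 0:
            raise GlycoFunnelError("bad_window", "window must be >= 0")
        if not self.polyphen_benign_cutoff < self.polyphen_damaging_cutoff:
            raise GlycoFunnelError(
                "bad_cutoffs", "benign cutoff must be below damaging cutoff"
            )
        if "human" not in self.species_panel:
            raise GlycoFunnelError("bad_panel", "species panel must contain human")
        if self.conservation_mode not in ("st_equivalent", "strict_identity"):
            raise GlycoFunnelError(
                "bad_mode", f"unknown conservation mode {self.conservation_mode!r}"
            )
        self.species_panel = tuple(self.species_panel)
        self.fallback_order = tuple(self.fallback_order)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - names
        if unknown:
            raise GlycoFunnelError(
                "unknown_config_key", f"unknown config keys: {sorted(unknown)}"
            )
        return cls(**dict(mapping))


# ---------------------------------------------------------------------------
# FASTA / TSV I/O
# ---------------------------------------------------------------------------

def _parse_header(description: str) -> dict:
    """Pull accession / gene / species / localization / flag tokens from a
    UniProt-style or ``key=value``-annotated FASTA header."""
    parts = description.split()
    first = parts[0]
    # UniProt style: db|ACCESSION|ENTRY_NAME
    if "|" in first:
        bits = first.split("|")
        accession = bits[1] if len(bits) >= 2 and bits[1] else bits[0]
    else:
        accession = first
    meta = {"accession": accession, "gene_symbol": "", "species": "human",
            "localization_terms": frozenset(), "id_dd_flag": False}
    for token in parts[1:]:
        if "=" not in token:
            continue
        key, _, value = token.partition("=")
        key = key.lower()
        if key in ("gn", "gene"):
            meta["gene_symbol"] = value
        elif key in ("os", "species"):
            meta["species"] = value.lower()
        elif key in ("loc", "localization"):
            meta["localization_terms"] = frozenset(
                v for v in value.lower().split(",") if v
            )
        elif key in ("id_dd", "iddd"):
            meta["id_dd_flag"] = value.lower() in ("1", "true", "yes")
    return meta


def load_proteome(fasta_source) -> dict[str, ProteinRecord]:
    """Read a FASTA file (path or handle) into accession-keyed records.

    Raises on an empty file, duplicate accessions (naming the accession) and
    non-standard residue letters (naming the first offending position).
    """
    records: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(fasta_source, "fasta"):
        meta = _parse_header(rec.description)
        if meta["accession"] in records:
            raise GlycoFunnelError(
                "duplicate_accession",
                f"duplicate accession {meta['accession']!r} in proteome",
            )
        records[meta["accession"]] = ProteinRecord(sequence=str(rec.seq), **meta)
    if not records:
        raise GlycoFunnelError("empty_proteome", f"no FASTA entries in {fasta_source}")
    return records


def write_proteome(records: Iterable[ProteinRecord], path) -> None:
    """Export records as FASTA with ``key=value`` annotation tokens."""
    seq_records = []
    for r in records:
        desc_parts = []
        if r.gene_symbol:
            desc_parts.append(f"gene={r.gene_symbol}")
        desc_parts.append(f"species={r.species}")
        if r.localization_terms:
            desc_parts.append("loc=" + ",".join(sorted(r.localization_terms)))
        if r.id_dd_flag:
            desc_parts.append("id_dd=1")
        seq_records.append(
            SeqRecord(Seq(r.sequence), id=r.accession, description=" ".join(desc_parts))
        )
    SeqIO.write(seq_records, path, "fasta")


SITE_TSV_COLUMNS = [
    "study",
    "protein_accession",
    "position",
    "residue",
    "evidence_peptide",
    "peptide_site_offset",
]


def load_site_table(path_or_buf) -> list[GlycoSite]:
    """Read one per-study site table (TSV, header row, '.' for missing)."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    missing = [c for c in SITE_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise GlycoFunnelError(
            "bad_site_table", f"site table missing columns: {missing}"
        )
    sites = []
    for row in df.itertuples(index=False):
        peptide = row.evidence_peptide if isinstance(row.evidence_peptide, str) else ""
        offset = row.peptide_site_offset
        sites.append(
            GlycoSite(
                protein_accession=row.protein_accession,
                position=int(row.position),
                residue=row.residue,
                evidence_peptide=peptide,
                peptide_site_offset=int(offset) if isinstance(offset, str) and offset else 1,
                source_studies=(row.study,),
            )
        )
    return sites


def write_site_table(sites: Iterable[GlycoSite], path) -> None:
    rows = []
    for s in sites:
        studies = s.source_studies or ("",)
        for study in studies:
            rows.append(
                {
                    "study": study,
                    "protein_accession": s.protein_accession,
                    "position": s.position,
                    "residue": s.residue,
                    "evidence_peptide": s.evidence_peptide or ".",
                    "peptide_site_offset": s.peptide_site_offset,
                }
            )
    pd.DataFrame(rows, columns=SITE_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def load_gene_disease_table(path_or_buf) -> dict[str, bool]:
    """Read the gene-disease TSV mapping accession -> ID/DD flag.

    The flag stands in for manual clinical-database inspection: true when the
    gene was the sole pathogenic variant in an ID/DD patient.
    """
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str)
    for col in ("protein_accession", "id_dd_flag"):
        if col not in df.columns:
            raise GlycoFunnelError(
                "bad_disease_table", f"gene-disease table missing column {col!r}"
            )
    return {
        row.protein_accession: str(row.id_dd_flag).lower() in ("1", "true", "yes")
        for row in df.itertuples(index=False)
    }


def apply_disease_flags(
    proteome: Mapping[str, ProteinRecord], flags: Mapping[str, bool]
) -> dict[str, ProteinRecord]:
    """Return a proteome copy with id_dd_flag set from a gene-disease table."""
    out = {}
    for acc, rec in proteome.items():
        out[acc] = dataclasses.replace(rec, id_dd_flag=bool(flags.get(acc, rec.id_dd_flag)))
    return out


def validate_site_record(site: GlycoSite, protein: ProteinRecord) -> None:
    """Check a site against its protein; raise a structured error on corrupt
    input.

    ``out_of_range``: the claimed position exceeds the sequence length.
    ``residue_mismatch``: the sequence letter differs from the reported
    residue.  Both signal corrupt input and are distinct from QC exclusion.
    """
    if protein.accession != site.protein_accession:
        raise GlycoFunnelError(
            "accession_mismatch",
            f"site {site.key} checked against protein {protein.accession}",
        )
    if site.position > len(protein.sequence):
        raise GlycoFunnelError(
            "out_of_range",
            f"site {site.key}: position {site.position} beyond sequence "
            f"length {len(protein.sequence)}",
        )
    actual = protein.sequence[site.position - 1]
    if actual != site.residue:
        raise GlycoFunnelError(
            "residue_mismatch",
            f"site {site.key}: reported residue {site.residue} but sequence "
            f"has {actual}",
        )
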