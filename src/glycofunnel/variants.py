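"""ClinVar-style screen: intersect protein missense variants with O-GlcNAc
sites exactly and within a ±window, then triage by clinical significance and
PolyPhen-2 HumVar bands.

Triage rule: pathogenic / likely-pathogenic hits are retained outright;
uncertain-significance hits are retained when HumVar predicts them probably
damaging (score > 0.85); everything else is excluded.  Likely-benign is
score < 0.15; scores in between are possibly damaging.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import GlycoFunnelError, GlycoSite, PipelineConfig, ProteinRecord

SIGNIFICANCE_TOKENS = (
    "pathogenic",
    "likely_pathogenic",
    "uncertain",
    "likely_benign",
    "benign",
    "other",
)

#: Condition substrings treated as ID/DD phenotypes (lower-cased matching).
ID_DD_TERMS = (
    "intellectual disability",
    "mental retardation",
    "developmental",
    "spinocerebellar ataxia",
    "cortical dysplasia",
    "epileptic encephalopathy",
    "alpha thalassemia-x-linked",
    "wiedemann",
)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "TER": "*", "SEC": "U", "PYL": "O",
}

_HGVS_RE = re.compile(
    r"^(?:p\.)?(?:\()?"
    r"(?P<ref>[A-Z][a-z]{2}|[A-Z*])"
    r"(?P<pos>\d+)"
    r"(?P<alt>[A-Z][a-z]{2}|[A-Z*])"
    r"(?:\))?$"
)


def parse_hgvs_p(text: str) -> tuple[str, int, str]:
    """Parse a protein substitution in HGVS p. or compact one-letter form.

    Accepts ``p.Ser172Pro``, ``Ser172Pro``, ``S172P`` (and a parenthesised
    ``p.(Ser172Pro)``).  Synonymous changes and stop gains are rejected as
    non-missense.
    """
    m = _HGVS_RE.match(text.strip())
    if not m:
        raise GlycoFunnelError("parse_error", f"cannot parse substitution {text!r}")

    def to_one(token: str) -> str:
        if len(token) == 1:
            return token
        try:
            return AA3_TO_1[token.upper()]
        except KeyError:
            raise GlycoFunnelError(
                "parse_error", f"unknown amino-acid code {token!r} in {text!r}"
            ) from None

    ref, alt = to_one(m.group("ref")), to_one(m.group("alt"))
    pos = int(m.group("pos"))
    if alt == "*" or ref == "*":
        raise GlycoFunnelError("not_missense", f"{text!r} is a stop change")
    if ref == alt:
        raise GlycoFunnelError("not_missense", f"{text!r} is synonymous")
    return ref, pos, alt


def normalize_significance(raw: str) -> str:
    """Map free-text clinical significance to a controlled token.

    Aggregate labels such as "Pathogenic/Likely pathogenic" normalise to the
    stronger token.
    """
    low = raw.strip().lower().replace("_", " ")
    if "conflicting" in low:
        return "other"
    parts = [p.strip() for p in low.split("/")]
    if "pathogenic" in low and "benign" not in low:
        return "pathogenic" if "pathogenic" in parts else "likely_pathogenic"
    if "uncertain" in low or low == "vus":
        return "uncertain"
    if "benign" in low:
        return "benign" if "benign" in parts else "likely_benign"
    return "other"


@dataclass
class VariantRecord:
    """A protein-level missense variant with clinical annotation."""

    gene_symbol: str
    protein_accession: str
    ref_aa: str
    position: int
    alt_aa: str
    clinical_significance: str = "other"
    polyphen_humvar: Optional[float] = None
    condition: str = ""

    def __post_init__(self):
        if self.position < 1:
            raise GlycoFunnelError("bad_position", "variant position must be >= 1")
        if self.ref_aa == self.alt_aa:
            raise GlycoFunnelError(
                "not_missense", f"{self.gene_symbol} {self.ref_aa}{self.position}"
                f"{self.alt_aa}: not a missense change"
            )
        if self.clinical_significance not in SIGNIFICANCE_TOKENS:
            self.clinical_significance = normalize_significance(
                self.clinical_significance
            )
        if self.polyphen_humvar is not None and not (
            0.0 <= self.polyphen_humvar <= 1.0
        ):
            raise GlycoFunnelError(
                "bad_score", f"PolyPhen score {self.polyphen_humvar} outside [0, 1]"
            )

    @property
    def label(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"

    @property
    def is_id_dd(self) -> bool:
        low = self.condition.lower()
        return any(term in low for term in ID_DD_TERMS)


@dataclass(frozen=True)
class VariantHit:
    """A variant intersecting an O-GlcNAc site exactly or within the window."""

    variant: VariantRecord
    site: GlycoSite
    relation: str  # exact | proximal
    distance: int
    band: str = "unscored"
    triage: str = "excluded"

    def __post_init__(self):
        if (self.relation == "exact") != (self.distance == 0):
            raise GlycoFunnelError(
                "bad_hit", "relation must be exact iff distance is 0"
            )


def classify_polyphen(
    score: Optional[float], config: PipelineConfig | None = None
) -> str:
    """Band a HumVar score: > damaging cutoff ⇒ probably damaging, < benign
    cutoff ⇒ likely benign, between ⇒ possibly damaging, missing ⇒ unscored."""
    config = config or PipelineConfig()
    if score is None:
        return "unscored"
    if not 0.0 <= score <= 1.0:
        raise GlycoFunnelError("bad_score", f"score {score} outside [0, 1]")
    if score > config.polyphen_damaging_cutoff:
        return "probably_damaging"
    if score < config.polyphen_benign_cutoff:
        return "likely_benign"
    return "possibly_damaging"


def triage_hit(significance: str, band: str) -> str:
    """Compose clinical significance with the predictor band."""
    if significance in ("pathogenic", "likely_pathogenic"):
        return "retained_pathogenic"
    if significance == "uncertain" and band == "probably_damaging":
        return "retained_predicted"
    return "excluded"


def intersect_sites(
    variants: Iterable[VariantRecord],
    sites: Iterable[GlycoSite],
    window: int = 5,
    config: PipelineConfig | None = None,
) -> list[VariantHit]:
    """All (variant, site) pairs on the same protein within the window.

    Inclusive at both ends; a variant may hit several sites, producing one
    hit per site.  Hits come back banded and triaged.
    """
    config = config or PipelineConfig()
    by_protein: dict[str, list[GlycoSite]] = {}
    for site in sites:
        by_protein.setdefault(site.protein_accession, []).append(site)
    hits: list[VariantHit] = []
    for variant in variants:
        for site in by_protein.get(variant.protein_accession, ()):
            dist = abs(variant.position - site.position)
            if dist > window:
                continue
            band = classify_polyphen(variant.polyphen_humvar, config)
            hits.append(
                VariantHit(
                    variant=variant,
                    site=site,
                    relation="exact" if dist == 0 else "proximal",
                    distance=dist,
                    band=band,
                    triage=triage_hit(variant.clinical_significance, band),
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Input readers
# ---------------------------------------------------------------------------

VARIANT_TSV_COLUMNS = [
    "gene_symbol",
    "protein_accession",
    "hgvs_p",
    "clinical_significance",
    "polyphen_humvar",
    "condition",
]


def load_variant_table(path_or_buf) -> list[VariantRecord]:
    """Read a variant TSV ('.' for missing scores); skips non-missense rows
    with a warning, as a screen of a substitution dump would."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    missing = [c for c in VARIANT_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise GlycoFunnelError(
            "bad_variant_table", f"variant table missing columns: {missing}"
        )
    out = []
    for row in df.itertuples(index=False):
        try:
            ref, pos, alt = parse_hgvs_p(row.hgvs_p)
        except GlycoFunnelError as err:
            warnings.warn(f"skipping variant {row.hgvs_p!r}: {err}", stacklevel=2)
            continue
        score = row.polyphen_humvar
        out.append(
            VariantRecord(
                gene_symbol=row.gene_symbol,
                protein_accession=row.protein_accession,
                ref_aa=ref,
                position=pos,
                alt_aa=alt,
                clinical_significance=row.clinical_significance,
                polyphen_humvar=float(score) if isinstance(score, str) and score else None,
                condition=row.condition if isinstance(row.condition, str) else "",
            )
        )
    return out


def load_variant_vcf(path, accession_map: Mapping[str, str] | None = None) -> list[VariantRecord]:
    """Read variants from a VCF 4.x file whose INFO field carries gene,
    HGVS p. consequence, clinical significance and optional HumVar score
    (keys GENE, HGVSP, CLNSIG, HUMVAR, CONDITION).

    ``accession_map`` translates gene symbols to protein accessions; without
    it the gene symbol doubles as the accession.  Malformed records are
    skipped with a warning and counted by the caller.
    """
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        info = dict(rec.INFO)
        gene = info.get("GENE")
        hgvs = info.get("HGVSP")
        if not gene or not hgvs:
            warnings.warn(f"VCF record {rec.CHROM}:{rec.POS} lacks GENE/HGVSP; skipped", stacklevel=2)
            continue
        try:
            ref, pos, alt = parse_hgvs_p(str(hgvs))
        except GlycoFunnelError as err:
            warnings.warn(f"VCF record {rec.CHROM}:{rec.POS}: {err}; skipped", stacklevel=2)
            continue
        score = info.get("HUMVAR")
        out.append(
            VariantRecord(
                gene_symbol=str(gene),
                protein_accession=(accession_map or {}).get(str(gene), str(gene)),
                ref_aa=ref,
                position=pos,
                alt_aa=alt,
                clinical_significance=str(info.get("CLNSIG", "other")),
                polyphen_humvar=float(score) if score is not None else None,
                condition=str(info.get("CONDITION", "")).replace("_", " "),
            )
        )
    return out


@dataclass
class ScreenResult:
    hits: list[VariantHit]
    summary: dict
    hit_table: pd.DataFrame = field(repr=False, default=None)


def check_reference_residues(
    variants: Sequence[VariantRecord], proteome: Mapping[str, ProteinRecord]
) -> list[str]:
    """Warn (do not drop) when a variant's reference residue disagrees with
    the supplied protein sequence; returns the warning messages."""
    messages = []
    for v in variants:
        protein = proteome.get(v.protein_accession)
        if protein is None or v.position > len(protein.sequence):
            continue
        actual = protein.sequence[v.position - 1]
        if actual != v.ref_aa:
            msg = (
                f"{v.gene_symbol} {v.label}: reference residue {v.ref_aa} "
                f"disagrees with sequence ({actual})"
            )
            messages.append(msg)
            warnings.warn(msg, stacklevel=2)
    return messages


def screen(
    variants: Sequence[VariantRecord],
    sites: Sequence[GlycoSite],
    config: PipelineConfig | None = None,
    proteome: Mapping[str, ProteinRecord] | None = None,
) -> ScreenResult:
    """End-to-end screen: missense-only input → window intersection →
    HumVar banding → triage, with summary counts."""
    config = config or PipelineConfig()
    if proteome:
        check_reference_residues(variants, proteome)
    hits = intersect_sites(variants, sites, window=config.window, config=config)
    rows = [
        {
            "gene_symbol": h.variant.gene_symbol,
            "protein_accession": h.variant.protein_accession,
            "variant": h.variant.label,
            "site_position": h.site.position,
            "relation": h.relation,
            "distance": h.distance,
            "clinical_significance": h.variant.clinical_significance,
            "polyphen_humvar": h.variant.polyphen_humvar,
            "band": h.band,
            "triage": h.triage,
            "condition": h.variant.condition,
        }
        for h in hits
    ]
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_symbol", "protein_accession", "variant", "site_position",
            "relation", "distance", "clinical_significance", "polyphen_humvar",
            "band", "triage", "condition",
        ],
    )
    summary = {
        "n_variants": len(variants),
        "n_sites": len(sites),
        "n_hits": len(hits),
        "n_exact": sum(1 for h in hits if h.relation == "exact"),
        "n_proximal": sum(1 for h in hits if h.relation == "proximal"),
        "n_retained": sum(1 for h in hits if h.triage != "excluded"),
        "n_retained_pathogenic": sum(
            1 for h in hits if h.triage == "retained_pathogenic"
        ),
        "n_retained_predicted": sum(
            1 for h in hits if h.triage == "retained_predicted"
        ),
    }
    return ScreenResult(hits=hits, summary=summary, hit_table=table)
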