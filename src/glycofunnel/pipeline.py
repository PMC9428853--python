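"""End-to-end orchestration of the filter cascade.

Stage order is fixed: pool → quality control → ID/DD disease filter →
cross-species conservation → functional-region filter → accessibility
split.  The functional-region judgment (does the site sit in a functionally
important domain or motif?) is literature curation, not computation, so it
enters as a user-supplied interval annotation table.  Each stage is also
callable on its own through the underlying modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from . import accessibility as acc_mod
from .accessibility import DisorderProfile, StructureModel, classify_site, protein_mode
from .conservation import (
    ConservationVerdict,
    assemble_panel,
    filter_conservation,
    index_ortholog_pool,
)
from .filters import apply_qc, filter_disease, pool_sites
from .model import (
    GlycoFunnelError,
    GlycoSite,
    PipelineConfig,
    ProteinRecord,
    apply_disease_flags,
    load_gene_disease_table,
    load_proteome,
    load_site_table,
)

FUNNEL_STAGES = ("pooled", "qc", "id_dd", "conserved", "functional_region")


@dataclass
class FunnelReport:
    """Retained counts and site keys after each stage of the cascade."""

    stages: tuple[str, ...] = FUNNEL_STAGES
    counts: dict[str, int] = field(default_factory=dict)
    retained_keys: dict[str, list] = field(default_factory=dict)
    accessible_split: dict[str, int] = field(default_factory=dict)

    def record(self, stage: str, sites: Sequence[GlycoSite]) -> None:
        self.counts[stage] = len(sites)
        self.retained_keys[stage] = sorted([list(s.key) for s in sites])

    def check_monotone(self) -> None:
        prev = None
        for stage in self.stages:
            if stage not in self.counts:
                continue
            keys = {tuple(k) for k in self.retained_keys[stage]}
            if prev is not None and not keys <= prev:
                raise GlycoFunnelError(
                    "funnel_violation", f"stage {stage} gained sites"
                )
            prev = keys

    def to_dict(self) -> dict:
        return {
            "stages": list(self.stages),
            "counts": dict(self.counts),
            "retained_keys": {k: list(v) for k, v in self.retained_keys.items()},
            "accessible_split": dict(self.accessible_split),
        }


@dataclass
class PipelineResult:
    candidates: pd.DataFrame
    funnel: FunnelReport
    exclusions: list[dict]
    verdicts: dict
    calls: dict
    low_confidence: pd.DataFrame
    sites_by_stage: dict[str, list[GlycoSite]]


def load_functional_regions(path_or_buf) -> list[tuple[str, int, int, str]]:
    df = pd.read_csv(path_or_buf, sep="\t")
    for col in ("protein_accession", "start", "end"):
        if col not in df.columns:
            raise GlycoFunnelError(
                "bad_region_table", f"functional-region table missing {col!r}"
            )
    out = []
    for row in df.itertuples(index=False):
        label = getattr(row, "label", "")
        out.append((row.protein_accession, int(row.start), int(row.end), str(label)))
    return out


def site_in_regions(
    site: GlycoSite, regions: Iterable[tuple[str, int, int, str]]
) -> Optional[str]:
    """Label of the first annotated interval containing the site, else None."""
    for acc, start, end, label in regions:
        if acc == site.protein_accession and start <= site.position <= end:
            return label or "annotated_region"
    return None


def filter_functional(
    sites: Iterable[GlycoSite], regions
) -> tuple[list[GlycoSite], list[GlycoSite], dict]:
    retained, excluded, labels = [], [], {}
    for site in sites:
        label = site_in_regions(site, regions)
        if label is None:
            excluded.append(site.mark("functional_region", "excluded", "not_functional"))
        else:
            labels[site.key] = label
            retained.append(site.mark("functional_region", "retained", "pass"))
    return retained, excluded, labels


def low_confidence_scan(
    non_conserved_sites: Iterable[GlycoSite], regions
) -> pd.DataFrame:
    """Sites that failed conservation but sit inside an annotated functional
    interval — low-confidence hits worth manual follow-up (e.g. sites in
    mitochondrial targeting sequences)."""
    rows = []
    for site in non_conserved_sites:
        label = site_in_regions(site, regions)
        if label is not None:
            rows.append(
                {
                    "protein_accession": site.protein_accession,
                    "position": site.position,
                    "residue": site.residue,
                    "region_label": label,
                    "flag": "low_confidence",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["protein_accession", "position", "residue", "region_label", "flag"],
    ).sort_values(["protein_accession", "position"]).reset_index(drop=True)


def tally_classes(
    candidate_accessions: Sequence[str], annotation: Mapping[str, str]
) -> tuple[pd.DataFrame, int]:
    """Count candidates per protein class.

    Percentages are taken over candidates *with* a class annotation and
    rounded to integers; the unannotated count is returned separately.
    """
    annotated = [a for a in candidate_accessions if annotation.get(a)]
    unannotated = len(candidate_accessions) - len(annotated)
    counts: dict[str, int] = {}
    for a in annotated:
        counts[annotation[a]] = counts.get(annotation[a], 0) + 1
    rows = [
        {
            "protein_class": cls,
            "count": cnt,
            "percentage": round(100 * cnt / len(annotated)),
        }
        for cls, cnt in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return (
        pd.DataFrame(rows, columns=["protein_class", "count", "percentage"]),
        unannotated,
    )


def run_pipeline(
    proteome: Mapping[str, ProteinRecord] | str | Path,
    site_tables: Sequence,
    gene_disease: Mapping[str, bool] | str | Path | None,
    ortholog_sources: Sequence,
    disorder_profiles: Mapping[str, DisorderProfile] | str | Path,
    functional_regions,
    config: PipelineConfig | None = None,
    structures: Mapping[str, tuple[StructureModel, Optional[str]]] | None = None,
) -> PipelineResult:
    """Run the whole cascade.

    Accepts in-memory objects or file paths for every input.  Returns the
    candidate table, the funnel report (with monotonicity checked), the
    exclusion log and the per-site conservation verdicts and accessibility
    calls.
    """
    config = config or PipelineConfig()

    if isinstance(proteome, (str, Path)):
        proteome = load_proteome(str(proteome))
    if gene_disease is not None:
        if isinstance(gene_disease, (str, Path)):
            gene_disease = load_gene_disease_table(str(gene_disease))
        proteome = apply_disease_flags(proteome, gene_disease)
    tables = []
    for t in site_tables:
        tables.append(load_site_table(str(t)) if isinstance(t, (str, Path)) else t)
    if isinstance(disorder_profiles, (str, Path)):
        disorder_profiles = acc_mod.load_disorder_profiles(str(disorder_profiles))
    if isinstance(functional_regions, (str, Path)):
        functional_regions = load_functional_regions(str(functional_regions))

    ortholog_records: list[ProteinRecord] = []
    for src in ortholog_sources:
        if isinstance(src, (str, Path)):
            ortholog_records.extend(load_proteome(str(src)).values())
        else:
            ortholog_records.extend(
                src.values() if isinstance(src, dict) else list(src)
            )
    pool = index_ortholog_pool(ortholog_records)

    funnel = FunnelReport()
    exclusions: list[dict] = []
    sites_by_stage: dict[str, list[GlycoSite]] = {}

    def log_exclusions(stage: str, excluded: Sequence[GlycoSite]) -> None:
        for s in excluded:
            exclusions.append(
                {
                    "protein_accession": s.protein_accession,
                    "position": s.position,
                    "stage": stage,
                    "reason": s.status_reason,
                }
            )

    pooled = pool_sites(tables)
    funnel.record("pooled", pooled)
    sites_by_stage["pooled"] = pooled

    qc_kept, qc_dropped = apply_qc(pooled, proteome)
    funnel.record("qc", qc_kept)
    sites_by_stage["qc"] = qc_kept
    log_exclusions("qc", qc_dropped)

    dd_kept, dd_dropped = filter_disease(qc_kept, proteome)
    funnel.record("id_dd", dd_kept)
    sites_by_stage["id_dd"] = dd_kept
    log_exclusions("id_dd", dd_dropped)

    panels = {}
    for accn in sorted({s.protein_accession for s in dd_kept}):
        panels[accn] = assemble_panel(proteome[accn], pool, config)
    cons_kept, cons_dropped, verdicts = filter_conservation(
        dd_kept, proteome, panels, config
    )
    funnel.record("conserved", cons_kept)
    sites_by_stage["conserved"] = cons_kept
    log_exclusions("conserved", cons_dropped)

    func_kept, func_dropped, region_labels = filter_functional(
        cons_kept, functional_regions
    )
    funnel.record("functional_region", func_kept)
    sites_by_stage["functional_region"] = func_kept
    log_exclusions("functional_region", func_dropped)

    calls = {}
    for site in func_kept:
        model, chain = (structures or {}).get(site.protein_accession, (None, None))
        calls[site.key] = classify_site(
            site.position,
            disorder_profiles.get(site.protein_accession),
            model=model,
            chain=chain,
            config=config,
        )
    funnel.accessible_split = {
        "accessible_disordered": sum(
            1 for c in calls.values() if c.label == acc_mod.ACCESSIBLE
        ),
        "inaccessible_ordered": sum(
            1 for c in calls.values() if c.label == acc_mod.ORDERED
        ),
    }
    funnel.check_monotone()

    rows = []
    by_protein: dict[str, list[GlycoSite]] = {}
    for site in func_kept:
        by_protein.setdefault(site.protein_accession, []).append(site)
    for accn in sorted(by_protein):
        protein = proteome[accn]
        protein_sites = sorted(by_protein[accn], key=lambda s: s.position)
        mode = protein_mode([calls[s.key] for s in protein_sites])
        panel = panels[accn]
        for site in protein_sites:
            call = calls[site.key]
            verdict = verdicts[site.key]
            rows.append(
                {
                    "gene_symbol": protein.gene_symbol,
                    "protein_accession": accn,
                    "position": site.position,
                    "residue": site.residue,
                    "conserved": verdict.conserved,
                    "per_species": ";".join(
                        f"{sp}={r}" for sp, r in sorted(verdict.per_species.items())
                    ),
                    "accessibility": call.label,
                    "basis": call.basis,
                    "modification_mode": (
                        "posttranslational"
                        if call.label == acc_mod.ACCESSIBLE
                        else "cotranslational_candidate"
                    ),
                    "protein_mode": mode,
                    "region_label": region_labels.get(site.key, ""),
                    "panel_substitutions": ";".join(
                        f"{k}->{v}" for k, v in sorted(panel.substitutions.items())
                    ),
                    "source_studies": ",".join(site.source_studies),
                }
            )
    candidates = pd.DataFrame(
        rows,
        columns=[
            "gene_symbol", "protein_accession", "position", "residue",
            "conserved", "per_species", "accessibility", "basis",
            "modification_mode", "protein_mode", "region_label",
            "panel_substitutions", "source_studies",
        ],
    )

    low_conf = low_confidence_scan(cons_dropped, functional_regions)

    return PipelineResult(
        candidates=candidates,
        funnel=funnel,
        exclusions=exclusions,
        verdicts=verdicts,
        calls=calls,
        low_confidence=low_conf,
        sites_by_stage=sites_by_stage,
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

#: Structural requirements on an exported funnel JSON document.
FUNNEL_SCHEMA = {
    "required": ["stages", "counts", "retained_keys", "accessible_split"],
    "types": {
        "stages": list,
        "counts": dict,
        "retained_keys": dict,
        "accessible_split": dict,
    },
}


def validate_funnel_json(document: dict) -> None:
    """Check an exported funnel document against :data:`FUNNEL_SCHEMA` and
    the monotonicity invariant."""
    for key in FUNNEL_SCHEMA["required"]:
        if key not in document:
            raise GlycoFunnelError("schema_violation", f"funnel JSON missing {key!r}")
        if not isinstance(document[key], FUNNEL_SCHEMA["types"][key]):
            raise GlycoFunnelError(
                "schema_violation",
                f"funnel JSON field {key!r} has wrong type",
            )
    counts = [document["counts"][s] for s in document["stages"] if s in document["counts"]]
    if any(b > a for a, b in zip(counts, counts[1:])):
        raise GlycoFunnelError("schema_violation", "funnel counts increase")


def export_results(result: PipelineResult, outdir) -> dict[str, Path]:
    """Write candidate TSV, funnel/exclusion JSON, low-confidence TSV and a
    plain gene list (one symbol per line, ready for enrichment submission)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["candidates"] = outdir / "candidates.tsv"
    result.candidates.to_csv(paths["candidates"], sep="\t", index=False)

    paths["funnel"] = outdir / "funnel.json"
    doc = result.funnel.to_dict()
    validate_funnel_json(doc)
    with open(paths["funnel"], "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")

    paths["exclusions"] = outdir / "exclusions.json"
    with open(paths["exclusions"], "w") as fh:
        json.dump(result.exclusions, fh, indent=1)
        fh.write("\n")

    paths["low_confidence"] = outdir / "low_confidence.tsv"
    result.low_confidence.to_csv(paths["low_confidence"], sep="\t", index=False)

    paths["gene_list"] = outdir / "candidate_genes.txt"
    genes = sorted(result.candidates["gene_symbol"].unique())
    with open(paths["gene_list"], "w") as fh:
        for g in genes:
            fh.write(g + "\n")
    return paths
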