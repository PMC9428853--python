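"""Self-contained synthetic cohort generator with a planted-truth manifest.

Emulates the statistical structure of the study inputs the funnel consumes —
a pooled multi-study O-GlcNAc site table with QC decoys, a human proteome
with localization and ID/DD disease flags, ortholog panels with withheld
species to exercise fallbacks, IUPred-style disorder profiles, functional
region annotations, and a ClinVar-style variant table — so that every stage
and the full cascade are testable without any download.  Every byte of the
bundle is a deterministic function of ``(config, seed)`` (a single numpy
PCG64 generator drives all randomness).

It does not attempt to mimic real mutational signatures, real gene names, or
real O-GlcNAcome composition.

The module also provides internal-coordinate (NeRF) builders for *synthetic*
peptide fragments with planted backbone dihedrals and side-chain contact
distances, used to exercise the structural measurement utilities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .accessibility import DisorderProfile, StructureModel, write_disorder_profiles
from .model import (
    GlycoFunnelError,
    GlycoSite,
    ProteinRecord,
    write_proteome,
    write_site_table,
)

#: Swiss-Prot-like background amino-acid frequencies (percent, fixed table).
AA_FREQ = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.64, "T": 5.35, "W": 1.10, "Y": 2.92, "V": 6.86,
}
_AA = np.array(sorted(AA_FREQ))
_AA_P = np.array([AA_FREQ[a] for a in _AA])
_AA_P = _AA_P / _AA_P.sum()

PANEL_SPECIES = ("mouse", "rat", "rabbit", "sheep")

ID_DD_CONDITIONS = (
    "intellectual disability, autosomal dominant",
    "developmental delay with seizures",
    "early infantile epileptic encephalopathy",
    "syndromic intellectual disability",
)
OTHER_CONDITIONS = (
    "familial hypertrophic cardiomyopathy",
    "hereditary hearing loss",
    "autosomal recessive polycystic kidney disease",
)

#: Default plant: (relation, significance, score class or None, count).
DEFAULT_VARIANT_PLAN = (
    ("exact", "pathogenic", None, 10),
    ("exact", "likely_pathogenic", None, 5),
    ("exact", "uncertain", "damaging", 10),
    ("exact", "uncertain", "benign", 10),
    ("exact", "benign", None, 5),
    ("proximal", "pathogenic", None, 10),
    ("proximal", "likely_pathogenic", None, 5),
    ("proximal", "uncertain", "damaging", 10),
    ("distant", "pathogenic", None, 20),
    ("distant", "uncertain", "damaging", 15),
)

#: Minimum spacing between planted positions on one protein; keeps every
#: ±5-residue variant window and every alignment-protection neighbourhood
#: attached to exactly one site.
MIN_SITE_SPACING = 13
PEPTIDE_FLANK = 4  # evidence peptides are 9-mers, site at offset 5


@dataclass
class SyntheticConfig:
    """Study conditions the generator emulates.

    The defaults are the cohort used throughout the test suite: 50 proteins
    of 240–400 residues with three true sites each, ten QC decoys per class,
    40% of genes ID/DD-flagged, 70% of sites conserved across the panel,
    orthologs at 5% substitution / 1% indel divergence with 3.84% of
    proteins lacking one of rat/rabbit/sheep (bovine standing in), and 100
    planted variants whose damaging scores concentrate above 0.85 and benign
    scores below 0.15 (means ≈0.95 / 0.05).
    """

    n_proteins: int = 50
    protein_length_range: tuple[int, int] = (240, 400)
    n_sites_per_protein: tuple[int, int] = (3, 3)
    fraction_id_dd: float = 0.4
    fraction_conserved_sites: float = 0.7
    fraction_functional_sites: float = 0.8
    fraction_accessible_sites: float = 0.6
    ortholog_substitution_rate: float = 0.05
    ortholog_indel_rate: float = 0.01
    withheld_ortholog_rate: float = 0.0384
    duplicate_study_fraction: float = 0.3
    n_studies: int = 14
    decoy_counts: dict = field(
        default_factory=lambda: {
            "n_linked": 10,
            "misannotated_peptide": 10,
            "extracellular": 10,
        }
    )
    variant_plan: tuple = DEFAULT_VARIANT_PLAN
    damaging_score_range: tuple[float, float] = (0.85, 1.0)
    benign_score_range: tuple[float, float] = (0.0, 0.15)
    disorder_means: tuple[float, float] = (0.9, 0.1)  # accessible, ordered
    disorder_sd: float = 0.04
    seed: int = 0

    def __post_init__(self):
        for name in (
            "fraction_id_dd",
            "fraction_conserved_sites",
            "fraction_functional_sites",
            "fraction_accessible_sites",
            "ortholog_substitution_rate",
            "ortholog_indel_rate",
            "withheld_ortholog_rate",
            "duplicate_study_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GlycoFunnelError("bad_config", f"{name}={v} outside [0, 1]")
        lo, hi = self.protein_length_range
        if not (0 < lo <= hi):
            raise GlycoFunnelError("bad_config", "degenerate protein length range")


@dataclass
class PlantedSite:
    protein_accession: str
    position: int
    residue: str
    planted_class: str  # candidate | n_linked | misannotated_peptide |
    #                     extracellular | not_id_dd | not_conserved | not_functional
    conserved: bool
    functional: bool
    accessible: bool
    studies: tuple[str, ...]


@dataclass
class PlantedVariant:
    gene_symbol: str
    protein_accession: str
    hgvs_p: str
    position: int
    relation: str  # exact | proximal | distant
    distance: int
    target_site_position: int
    significance: str
    score_class: str  # damaging | benign | none
    polyphen_humvar: float | None
    condition: str
    expected_triage: str  # retained_pathogenic | retained_predicted | excluded | no_hit


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(_AA, size=length, p=_AA_P))


def _pick_positions(
    rng: np.random.Generator, length: int, count: int, spacing: int = MIN_SITE_SPACING
) -> list[int]:
    """Well-separated 1-based positions away from the termini."""
    lo, hi = 20, length - 20
    chosen: list[int] = []
    for _ in range(2000):
        if len(chosen) == count:
            break
        pos = int(rng.integers(lo, hi + 1))
        if all(abs(pos - c) >= spacing for c in chosen):
            chosen.append(pos)
    if len(chosen) < count:
        raise GlycoFunnelError(
            "insufficient_positions",
            f"could not place {count} separated sites on a protein of length "
            f"{length}; use longer proteins",
        )
    return sorted(chosen)


class SyntheticBundle:
    """In-memory cohort plus manifest; ``write`` serialises the file bundle."""

    def __init__(self, config: SyntheticConfig, seed: int | None = None):
        self.config = config
        self.seed = config.seed if seed is None else seed
        self.proteome: dict[str, ProteinRecord] = {}
        self.orthologs: dict[str, list[ProteinRecord]] = {}  # species -> records
        self.sites: list[PlantedSite] = []
        self.site_rows: list[GlycoSite] = []  # per-study rows incl. duplicates
        self.variants: list[PlantedVariant] = []
        self.disorder: dict[str, DisorderProfile] = {}
        self.functional_regions: list[tuple[str, int, int, str]] = []
        self.withheld: list[tuple[str, str]] = []  # (gene, species slot)
        self.expected_substitutions: dict[str, dict[str, str]] = {}
        self.manifest: dict = {}
        self._generate()

    # -- generation -----------------------------------------------------

    def _generate(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(self.seed)
        n = cfg.n_proteins
        lo, hi = cfg.protein_length_range
        slo, shi = cfg.n_sites_per_protein

        id_dd_flags = rng.random(n) < cfg.fraction_id_dd
        seqs: dict[str, list[str]] = {}
        site_positions: dict[str, list[int]] = {}

        decoys = dict(cfg.decoy_counts)
        n_nlinked = int(decoys.get("n_linked", 0))
        n_misann = int(decoys.get("misannotated_peptide", 0))
        n_extl = int(decoys.get("extracellular", 0))

        # --- normal proteins with true + decoy site slots ---------------
        for i in range(n):
            acc, gene = f"SYNP{i:04d}", f"GENE{i:04d}"
            length = int(rng.integers(lo, hi + 1))
            seq = _random_sequence(rng, length)
            n_true = int(rng.integers(slo, shi + 1))
            extra = (1 if i < n_nlinked else 0) + (1 if i < n_misann else 0)
            positions = _pick_positions(rng, length, n_true + extra)
            order = list(rng.permutation(len(positions)))
            true_pos = sorted(positions[k] for k in order[:n_true])
            decoy_pos = [positions[k] for k in order[n_true:]]
            seqs[acc] = seq
            site_positions[acc] = sorted(positions)

            for pos in true_pos:
                residue = "S" if rng.random() < 0.55 else "T"
                seq[pos - 1] = residue
                self.sites.append(
                    PlantedSite(
                        protein_accession=acc,
                        position=pos,
                        residue=residue,
                        planted_class="pending",
                        conserved=bool(rng.random() < cfg.fraction_conserved_sites),
                        functional=bool(rng.random() < cfg.fraction_functional_sites),
                        accessible=bool(rng.random() < cfg.fraction_accessible_sites),
                        studies=(),
                    )
                )
            di = 0
            if i < n_nlinked:
                pos = decoy_pos[di]; di += 1
                seq[pos - 1] = "N"
                self.sites.append(
                    PlantedSite(acc, pos, "N", "n_linked", False, False, False, ())
                )
            if i < n_misann:
                pos = decoy_pos[di]; di += 1
                residue = "S" if rng.random() < 0.5 else "T"
                seq[pos - 1] = residue
                self.sites.append(
                    PlantedSite(
                        acc, pos, residue, "misannotated_peptide",
                        False, False, False, (),
                    )
                )
            self.proteome[acc] = ProteinRecord(
                accession=acc,
                gene_symbol=gene,
                species="human",
                sequence="".join(seq),
                localization_terms=frozenset(
                    {"nucleus", "cytoplasm"} if rng.random() < 0.7 else {"cytoplasm"}
                ),
                id_dd_flag=bool(id_dd_flags[i]),
            )

        # --- exclusively extracellular decoy proteins -------------------
        for j in range(n_extl):
            acc, gene = f"SYNX{j:04d}", f"GENX{j:04d}"
            length = int(rng.integers(lo, hi + 1))
            seq = _random_sequence(rng, length)
            pos = _pick_positions(rng, length, 1)[0]
            residue = "S" if rng.random() < 0.5 else "T"
            seq[pos - 1] = residue
            seqs[acc] = seq
            site_positions[acc] = [pos]
            self.sites.append(
                PlantedSite(acc, pos, residue, "extracellular", False, False, False, ())
            )
            self.proteome[acc] = ProteinRecord(
                accession=acc,
                gene_symbol=gene,
                species="human",
                sequence="".join(seq),
                localization_terms=frozenset({"extracellular", "secreted"}),
                id_dd_flag=False,
            )

        # --- resolve planted fates in cascade order ---------------------
        for site in self.sites:
            if site.planted_class != "pending":
                continue
            protein = self.proteome[site.protein_accession]
            if not protein.id_dd_flag:
                site.planted_class = "not_id_dd"
            elif not site.conserved:
                site.planted_class = "not_conserved"
            elif not site.functional:
                site.planted_class = "not_functional"
            else:
                site.planted_class = "candidate"

        # --- per-study site rows (pooling exercise) ---------------------
        studies = [f"study{k + 1:02d}" for k in range(self.config.n_studies)]
        for site in self.sites:
            k = 2 if rng.random() < cfg.duplicate_study_fraction else 1
            tags = sorted(rng.choice(studies, size=k, replace=False))
            site.studies = tuple(tags)
            protein_seq = self.proteome[site.protein_accession].sequence
            start = site.position - 1 - PEPTIDE_FLANK
            peptide = protein_seq[start : start + 2 * PEPTIDE_FLANK + 1]
            offset = PEPTIDE_FLANK + 1
            if site.planted_class == "misannotated_peptide":
                # corrupt one flanking letter so the peptide is absent from
                # the full-length sequence
                plist = list(peptide)
                idx = 0 if plist[0] != "W" else 1
                plist[idx] = "W" if plist[idx] != "W" else "Y"
                peptide = "".join(plist)
            for tag in tags:
                self.site_rows.append(
                    GlycoSite(
                        protein_accession=site.protein_accession,
                        position=site.position,
                        residue=site.residue,
                        evidence_peptide=peptide,
                        peptide_site_offset=offset,
                        source_studies=(tag,),
                    )
                )

        # --- orthologs ---------------------------------------------------
        normal_accs = [a for a in sorted(self.proteome) if a.startswith("SYNP")]
        n_withheld = int(round(cfg.withheld_ortholog_rate * len(normal_accs)))
        withheld_accs = set(
            rng.choice(normal_accs, size=n_withheld, replace=False)
        ) if n_withheld else set()
        self.orthologs = {sp: [] for sp in PANEL_SPECIES}
        self.orthologs["bovine"] = []
        for acc in normal_accs:
            protein = self.proteome[acc]
            protected = set()
            for pos in site_positions[acc]:
                protected.update(range(pos - 3, pos + 4))
            withheld_slot = None
            if acc in withheld_accs:
                withheld_slot = ("rat", "rabbit", "sheep")[int(rng.integers(0, 3))]
                self.withheld.append((protein.gene_symbol, withheld_slot))
                self.expected_substitutions[acc] = {withheld_slot: "bovine"}
            # species that will actually form this protein's panel
            effective = [sp for sp in PANEL_SPECIES if sp != withheld_slot]
            if withheld_slot:
                effective.append("bovine")
            # every planted non-conserved Ser/Thr site loses the residue in
            # exactly one species of the effective panel
            planted_flips: dict[tuple[int, str], bool] = {}
            for site in self.sites:
                if (
                    site.protein_accession == acc
                    and not site.conserved
                    and site.residue in "ST"
                    and site.planted_class
                    not in ("n_linked", "misannotated_peptide", "extracellular")
                ):
                    flip_species = effective[int(rng.integers(0, len(effective)))]
                    planted_flips[(site.position, flip_species)] = True
            for sp in effective:
                seq = self._derive_ortholog(
                    rng, protein.sequence, protected, site_positions[acc],
                    planted_flips, sp, cfg,
                )
                self.orthologs[sp].append(
                    ProteinRecord(
                        accession=f"{acc}_{sp.upper()[:3]}",
                        gene_symbol=protein.gene_symbol,
                        species=sp,
                        sequence=seq,
                    )
                )

        # --- disorder profiles -------------------------------------------
        mean_acc, mean_ord = cfg.disorder_means
        for acc in sorted(self.proteome):
            length = len(self.proteome[acc].sequence)
            scores = rng.uniform(0.2, 0.8, size=length)
            for site in self.sites:
                if site.protein_accession != acc:
                    continue
                mean = mean_acc if site.accessible else mean_ord
                lo_i = max(0, site.position - 8)
                hi_i = min(length, site.position + 7)
                scores[lo_i:hi_i] = rng.normal(
                    mean, cfg.disorder_sd, size=hi_i - lo_i
                )
            self.disorder[acc] = DisorderProfile(acc, np.clip(scores, 0.01, 0.99))

        # --- functional region annotations --------------------------------
        for site in self.sites:
            if site.functional:
                self.functional_regions.append(
                    (
                        site.protein_accession,
                        site.position - 3,
                        site.position + 3,
                        "interaction_motif",
                    )
                )
        self.functional_regions.sort()

        # --- variants ------------------------------------------------------
        candidate_targets = [
            s for s in self.sites if s.planted_class not in (
                "n_linked", "misannotated_peptide", "extracellular",
            )
        ]
        vi = 0
        for relation, significance, score_class, count in cfg.variant_plan:
            for _ in range(count):
                target = candidate_targets[vi % len(candidate_targets)]
                vi += 1
                acc = target.protein_accession
                protein = self.proteome[acc]
                if relation == "exact":
                    pos = target.position
                    distance = 0
                elif relation == "proximal":
                    distance = int(rng.integers(1, 6))
                    sign = 1 if rng.random() < 0.5 else -1
                    pos = target.position + sign * distance
                else:
                    distance = int(rng.integers(6, 8))
                    pos = target.position + distance
                ref = protein.sequence[pos - 1]
                alt_choices = [a for a in _AA if a != ref]
                alt = str(rng.choice(alt_choices))
                if score_class == "damaging":
                    s_lo, s_hi = cfg.damaging_score_range
                    score = float(s_lo + (s_hi - s_lo) * rng.beta(2.0, 1.0))
                elif score_class == "benign":
                    s_lo, s_hi = cfg.benign_score_range
                    score = float(s_lo + (s_hi - s_lo) * rng.beta(1.0, 2.0))
                else:
                    score = None
                if relation == "distant":
                    expected = "no_hit"
                elif significance in ("pathogenic", "likely_pathogenic"):
                    expected = "retained_pathogenic"
                elif significance == "uncertain" and score_class == "damaging":
                    expected = "retained_predicted"
                else:
                    expected = "excluded"
                retained = expected in ("retained_pathogenic", "retained_predicted")
                condition = (
                    ID_DD_CONDITIONS[vi % len(ID_DD_CONDITIONS)]
                    if retained
                    else OTHER_CONDITIONS[vi % len(OTHER_CONDITIONS)]
                )
                self.variants.append(
                    PlantedVariant(
                        gene_symbol=protein.gene_symbol,
                        protein_accession=acc,
                        hgvs_p=f"{ref}{pos}{alt}",
                        position=pos,
                        relation=relation,
                        distance=distance,
                        target_site_position=target.position,
                        significance=significance,
                        score_class=score_class or "none",
                        polyphen_humvar=round(score, 6) if score is not None else None,
                        condition=condition,
                        expected_triage=expected,
                    )
                )

        self.manifest = self._build_manifest()

    def _derive_ortholog(
        self,
        rng: np.random.Generator,
        human_seq: str,
        protected: set[int],
        positions: list[int],
        planted_flips: dict[str, int],
        species: str,
        cfg: SyntheticConfig,
    ) -> str:
        seq = list(human_seq)
        length = len(seq)
        # substitutions outside protected neighbourhoods
        mask = rng.random(length) < cfg.ortholog_substitution_rate
        for idx in np.nonzero(mask)[0]:
            if (idx + 1) in protected:
                continue
            choices = [a for a in _AA if a != seq[idx]]
            seq[idx] = str(rng.choice(choices))
        # forced non-conservation flips at the site position
        for (site_pos, flip_sp) in planted_flips:
            if flip_sp == species:
                seq[site_pos - 1] = "A"
        # short indels (1–3 residues) clear of any site neighbourhood
        n_indels = int(rng.binomial(length, cfg.ortholog_indel_rate))
        events = []
        for _ in range(n_indels):
            idx = int(rng.integers(10, length - 10))
            if any(abs(idx + 1 - p) <= PEPTIDE_FLANK + 2 for p in positions):
                continue
            size = int(rng.integers(1, 4))
            kind = "del" if rng.random() < 0.5 else "ins"
            events.append((idx, kind, size))
        for idx, kind, size in sorted(events, reverse=True):
            if kind == "del":
                if any(
                    abs(j + 1 - p) <= PEPTIDE_FLANK + 2
                    for p in positions
                    for j in range(idx, idx + size)
                ):
                    continue
                del seq[idx : idx + size]
            else:
                insert = [str(a) for a in rng.choice(_AA, size=size)]
                seq[idx:idx] = insert
        return "".join(seq)

    # -- manifest --------------------------------------------------------

    def _build_manifest(self) -> dict:
        order = ("pooled", "qc", "id_dd", "conserved", "functional_region")
        surviving = {stage: [] for stage in order}
        for s in self.sites:
            key = [s.protein_accession, s.position]
            surviving["pooled"].append(key)
            if s.planted_class in ("n_linked", "misannotated_peptide", "extracellular"):
                continue
            surviving["qc"].append(key)
            if s.planted_class == "not_id_dd":
                continue
            surviving["id_dd"].append(key)
            if s.planted_class == "not_conserved":
                continue
            surviving["conserved"].append(key)
            if s.planted_class == "not_functional":
                continue
            surviving["functional_region"].append(key)
        accessible = [
            [s.protein_accession, s.position]
            for s in self.sites
            if s.planted_class == "candidate" and s.accessible
        ]
        ordered = [
            [s.protein_accession, s.position]
            for s in self.sites
            if s.planted_class == "candidate" and not s.accessible
        ]
        candidates: dict[str, str] = {}
        for s in self.sites:
            if s.planted_class != "candidate":
                continue
            mode = "posttranslational" if s.accessible else "cotranslational_candidate"
            prev = candidates.get(s.protein_accession)
            if prev is None:
                candidates[s.protein_accession] = mode
            elif prev != mode:
                candidates[s.protein_accession] = "both"
        low_confidence = [
            [s.protein_accession, s.position]
            for s in self.sites
            if s.planted_class == "not_conserved" and s.functional
        ]
        return {
            "seed": self.seed,
            "n_proteins": self.config.n_proteins,
            "sites": [asdict(s) for s in self.sites],
            "variants": [asdict(v) for v in self.variants],
            "expected_funnel": {stage: len(keys) for stage, keys in surviving.items()},
            "surviving_keys": {stage: keys for stage, keys in surviving.items()},
            "expected_accessible": accessible,
            "expected_ordered": ordered,
            "expected_candidates": candidates,
            "expected_low_confidence": low_confidence,
            "expected_retained_variants": [
                [v.protein_accession, v.hgvs_p]
                for v in self.variants
                if v.expected_triage in ("retained_pathogenic", "retained_predicted")
            ],
            "withheld": [list(w) for w in self.withheld],
            "expected_substitutions": self.expected_substitutions,
        }

    # -- serialisation ----------------------------------------------------

    def write(self, outdir) -> dict[str, Path]:
        """Write the complete bundle; returns the path of each artifact."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        paths["proteome"] = outdir / "proteome.fasta"
        write_proteome(
            [self.proteome[a] for a in sorted(self.proteome)], paths["proteome"]
        )

        for sp in sorted(self.orthologs):
            if not self.orthologs[sp]:
                continue
            p = outdir / f"orthologs_{sp}.fasta"
            write_proteome(self.orthologs[sp], p)
            paths[f"orthologs_{sp}"] = p

        paths["sites"] = outdir / "sites.tsv"
        write_site_table(self.site_rows, paths["sites"])

        paths["gene_disease"] = outdir / "gene_disease.tsv"
        with open(paths["gene_disease"], "w") as fh:
            fh.write("protein_accession\tgene_symbol\tid_dd_flag\n")
            for acc in sorted(self.proteome):
                rec = self.proteome[acc]
                fh.write(f"{acc}\t{rec.gene_symbol}\t{int(rec.id_dd_flag)}\n")

        paths["disorder"] = outdir / "disorder.tsv"
        write_disorder_profiles(self.disorder, paths["disorder"])

        paths["functional_regions"] = outdir / "functional_regions.tsv"
        with open(paths["functional_regions"], "w") as fh:
            fh.write("protein_accession\tstart\tend\tlabel\n")
            for acc, start, end, label in self.functional_regions:
                fh.write(f"{acc}\t{start}\t{end}\t{label}\n")

        paths["variants"] = outdir / "variants.tsv"
        with open(paths["variants"], "w") as fh:
            fh.write(
                "gene_symbol\tprotein_accession\thgvs_p\tclinical_significance"
                "\tpolyphen_humvar\tcondition\n"
            )
            for v in self.variants:
                score = "." if v.polyphen_humvar is None else f"{v.polyphen_humvar:.6f}"
                fh.write(
                    f"{v.gene_symbol}\t{v.protein_accession}\t{v.hgvs_p}"
                    f"\t{v.significance}\t{score}\t{v.condition}\n"
                )

        paths["variants_vcf"] = outdir / "variants.vcf"
        self._write_vcf(paths["variants_vcf"])

        paths["manifest"] = outdir / "manifest.json"
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths

    def _write_vcf(self, path) -> None:
        lines = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=1,length=248956422>",
            '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
            '##INFO=<ID=HGVSP,Number=1,Type=String,Description="Protein consequence">',
            '##INFO=<ID=CLNSIG,Number=1,Type=String,Description="Clinical significance">',
            '##INFO=<ID=HUMVAR,Number=1,Type=Float,Description="PolyPhen-2 HumVar score">',
            '##INFO=<ID=CONDITION,Number=1,Type=String,Description="Reported condition">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        ]
        for i, v in enumerate(self.variants, start=1):
            info = [
                f"GENE={v.gene_symbol}",
                f"HGVSP=p.{v.hgvs_p}",
                f"CLNSIG={v.significance}",
            ]
            if v.polyphen_humvar is not None:
                info.append(f"HUMVAR={v.polyphen_humvar:.6f}")
            info.append("CONDITION=" + v.condition.replace(" ", "_"))
            lines.append(
                f"1\t{1000 + i}\t.\tA\tC\t.\tPASS\t" + ";".join(info)
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def generate_bundle(config: SyntheticConfig | None = None, seed: int | None = None,
                    outdir=None) -> SyntheticBundle:
    """Generate a cohort; optionally write it to ``outdir``."""
    bundle = SyntheticBundle(config or SyntheticConfig(), seed=seed)
    if outdir is not None:
        bundle.write(outdir)
    return bundle


# ---------------------------------------------------------------------------
# Synthetic structure fragments (internal-coordinate construction)
# ---------------------------------------------------------------------------

# Idealised backbone geometry (Å / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position atom D so that |C−D| = bond, the B−C−D angle
    and the A−B−C−D torsion take the requested values."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone_fragment(
    phi_psi: list[tuple[float, float]],
    chain: str = "A",
    start_residue: int = 1,
    numbering_offset: int = 0,
) -> StructureModel:
    """Synthetic peptide backbone with planted (phi, psi) per residue.

    Builds N/CA/C atoms for ``len(phi_psi)`` residues with ideal bond
    geometry and trans peptide bonds (omega = 180°); the first residue's phi
    and the last residue's psi are unused.  The returned model is a synthetic
    stand-in fragment, not a deposited structure.
    """
    if len(phi_psi) < 2:
        raise GlycoFunnelError("bad_fragment", "need at least two residues")
    atoms: dict[tuple[str, int, str], np.ndarray] = {}
    r0 = start_residue
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    angle = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(angle), math.sin(angle), 0.0])
    atoms[(chain, r0, "N")] = n0
    atoms[(chain, r0, "CA")] = ca0
    atoms[(chain, r0, "C")] = c0
    prev_n, prev_ca, prev_c = n0, ca0, c0
    for k in range(1, len(phi_psi)):
        psi_prev = phi_psi[k - 1][1]
        phi_k = phi_psi[k][0]
        n_k = place_atom(prev_n, prev_ca, prev_c, BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_k = place_atom(prev_ca, prev_c, n_k, BOND_N_CA, ANGLE_C_N_CA, 180.0)
        c_k = place_atom(prev_c, n_k, ca_k, BOND_CA_C, ANGLE_N_CA_C, phi_k)
        res = r0 + k
        atoms[(chain, res, "N")] = n_k
        atoms[(chain, res, "CA")] = ca_k
        atoms[(chain, res, "C")] = c_k
        prev_n, prev_ca, prev_c = n_k, ca_k, c_k
    return StructureModel(atoms=atoms, numbering_offset=numbering_offset)


def build_contact_fragment(distance: float = 3.3, chain: str = "A") -> StructureModel:
    """Synthetic two-residue fragment: a glutamate carboxylate next to a
    serine hydroxyl at a planted minimum oxygen–oxygen distance (Å).

    Stand-in for a deposited side-chain contact; the measurement utilities
    recover the planted distance from the coordinates.
    """
    atoms = {
        # Glu 364 carboxylate oxygens plus nearby carbons
        (chain, 364, "CD"): np.array([0.0, 1.25, 0.0]),
        (chain, 364, "OE1"): np.array([0.0, 0.0, 0.0]),
        (chain, 364, "OE2"): np.array([1.1, 1.9, 0.0]),
        (chain, 364, "CA"): np.array([-2.5, 2.6, 1.2]),
        # Ser 365 hydroxyl oxygen pointing at OE1
        (chain, 365, "OG"): np.array([0.0, 0.0, distance]),
        (chain, 365, "CB"): np.array([0.9, 0.4, distance + 1.2]),
        (chain, 365, "CA"): np.array([1.1, 1.6, distance + 2.1]),
    }
    return StructureModel(atoms=atoms)
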