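"""Site accessibility: disordered (OGT-accessible, post-translational) versus
ordered (candidate for co-translational modification).

Two evidence routes, with structure taking precedence when both exist:

* per-residue intrinsic-disorder profiles (IUPred2A-style scores in [0, 1]);
* deposited structures, judged through backbone phi/psi dihedral regions.

The disorder threshold is 0.5.  Under the standard IUPred convention a score
strictly above the threshold means disordered, hence accessible.  Because the
source protocol sentence states the opposite mapping ("ordered if scores were
higher than 0.5"), the literal behaviour is available behind
``config.paper_literal_disorder``; flipping the flag exactly inverts every
label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import GlycoFunnelError, PipelineConfig

ACCESSIBLE = "accessible_disordered"
ORDERED = "inaccessible_ordered"

#: Dihedral boxes (degrees) treated as ordered secondary structure — a simple
#: region heuristic standing in for manual structure inspection.
HELIX_BOX = ((-180.0, -30.0), (-80.0, 40.0))
STRAND_BOX = ((-180.0, -40.0), (60.0, 180.0))


@dataclass
class DisorderProfile:
    """Per-residue disorder scores for one protein, index 1-based."""

    protein_accession: str
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or len(self.scores) == 0:
            raise GlycoFunnelError("bad_profile", "scores must be a non-empty vector")
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise GlycoFunnelError(
                "bad_profile",
                f"{self.protein_accession}: disorder scores outside [0, 1]",
            )

    def __len__(self) -> int:
        return len(self.scores)

    def score_at(self, position: int) -> float:
        if not 1 <= position <= len(self.scores):
            raise GlycoFunnelError(
                "out_of_range",
                f"{self.protein_accession}: position {position} outside profile",
            )
        return float(self.scores[position - 1])


def load_disorder_profiles(path_or_buf) -> dict[str, DisorderProfile]:
    """Read a TSV of (protein_accession, position, score) into profiles."""
    df = pd.read_csv(path_or_buf, sep="\t")
    profiles = {}
    for acc, grp in df.groupby("protein_accession", sort=True):
        grp = grp.sort_values("position")
        positions = grp["position"].to_numpy()
        if not np.array_equal(positions, np.arange(1, len(positions) + 1)):
            raise GlycoFunnelError(
                "bad_profile", f"{acc}: positions must run 1..n without holes"
            )
        profiles[str(acc)] = DisorderProfile(str(acc), grp["score"].to_numpy())
    return profiles


def write_disorder_profiles(profiles: Mapping[str, DisorderProfile], path) -> None:
    rows = []
    for acc in sorted(profiles):
        for i, s in enumerate(profiles[acc].scores, start=1):
            rows.append({"protein_accession": acc, "position": i, "score": round(float(s), 6)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class AccessibilityCall:
    label: str  # ACCESSIBLE | ORDERED
    basis: str  # "structure" | "disorder_profile"
    detail: str = ""


def classify_disorder(
    profile: DisorderProfile, position: int, config: PipelineConfig | None = None
) -> AccessibilityCall:
    """Label one residue from its disorder score.

    Default semantics: score strictly above the threshold means disordered,
    hence accessible; at or below means ordered.  With
    ``paper_literal_disorder`` the mapping is inverted wholesale.
    """
    config = config or PipelineConfig()
    score = profile.score_at(position)
    disordered = score > config.disorder_threshold
    if config.paper_literal_disorder:
        disordered = not disordered
    return AccessibilityCall(
        label=ACCESSIBLE if disordered else ORDERED,
        basis="disorder_profile",
        detail=f"score={score:.3f} threshold={config.disorder_threshold}",
    )


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

@dataclass
class StructureModel:
    """A minimal coordinate model: atoms keyed by (chain, residue number,
    atom name), plus the offset mapping structure numbering to reference
    protein numbering (protein position + offset = structure residue
    number)."""

    atoms: dict[tuple[str, int, str], np.ndarray] = field(default_factory=dict)
    numbering_offset: int = 0

    def __post_init__(self):
        for key, xyz in list(self.atoms.items()):
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise GlycoFunnelError("bad_atom", f"non-finite coordinates at {key}")
            self.atoms[key] = arr

    @property
    def resolved_residues(self) -> set[tuple[str, int]]:
        return {(c, r) for (c, r, _a) in self.atoms}

    def chains(self) -> set[str]:
        return {c for (c, _r, _a) in self.atoms}

    def atom(self, chain: str, residue: int, name: str) -> Optional[np.ndarray]:
        return self.atoms.get((chain, residue, name))

    @classmethod
    def from_pdb(cls, path, numbering_offset: int = 0) -> "StructureModel":
        """Read standard ATOM records (first model) with gemmi."""
        import gemmi

        st = gemmi.read_structure(str(path))
        atoms: dict[tuple[str, int, str], np.ndarray] = {}
        if len(st) == 0:
            raise GlycoFunnelError("empty_structure", f"no models in {path}")
        for chain in st[0]:
            for residue in chain:
                for atom in residue:
                    key = (chain.name, residue.seqid.num, atom.name)
                    atoms.setdefault(
                        key, np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    )
        if not atoms:
            raise GlycoFunnelError("empty_structure", f"no atoms in {path}")
        return cls(atoms=atoms, numbering_offset=numbering_offset)


def write_pdb(model: StructureModel, path, residue_names: Mapping[tuple[str, int], str] | None = None) -> None:
    """Write fixed-width ATOM records (enough for round-tripping tests)."""
    residue_names = residue_names or {}
    lines = []
    serial = 1
    for (chain, resnum, name) in sorted(model.atoms):
        x, y, z = model.atoms[(chain, resnum, name)]
        resname = residue_names.get((chain, resnum), "GLY")
        element = name[0]
        lines.append(
            f"ATOM  {serial:>5} {name:<4.4}{'':1}{resname:<3} {chain:1}"
            f"{resnum:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2}"
        )
        serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion of four points, IUPAC convention, degrees in (−180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GlycoFunnelError(
            "degenerate_geometry", "near-collinear atoms: torsion undefined"
        )
    b2_unit = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2_unit))
    angle = math.degrees(math.atan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return angle


def compute_dihedrals(
    model: StructureModel, chain: str, residue_number: int
) -> tuple[float, float]:
    """Backbone (phi, psi) in degrees for one residue.

    phi = C(i−1)–N(i)–CA(i)–C(i); psi = N(i)–CA(i)–C(i)–N(i+1).
    """
    needed = {
        "C_prev": model.atom(chain, residue_number - 1, "C"),
        "N": model.atom(chain, residue_number, "N"),
        "CA": model.atom(chain, residue_number, "CA"),
        "C": model.atom(chain, residue_number, "C"),
        "N_next": model.atom(chain, residue_number + 1, "N"),
    }
    missing = [k for k, v in needed.items() if v is None]
    if missing:
        raise GlycoFunnelError(
            "undefined_dihedral",
            f"{chain}/{residue_number}: missing atoms {missing}",
        )
    phi = dihedral_angle(needed["C_prev"], needed["N"], needed["CA"], needed["C"])
    psi = dihedral_angle(needed["N"], needed["CA"], needed["C"], needed["N_next"])
    return phi, psi


def min_atom_distance(
    model: StructureModel,
    selection_a: Sequence[tuple[str, int, Optional[Iterable[str]]]] | tuple,
    selection_b: Sequence[tuple[str, int, Optional[Iterable[str]]]] | tuple,
    ndigits: int | None = None,
) -> float:
    """Minimum Euclidean distance (Å) over the product of two selections.

    A selection is one or more ``(chain, residue_number, atom_names)``
    triples; ``atom_names=None`` selects every atom of the residue.
    """

    def resolve(selection):
        if selection and isinstance(selection[0], str):
            selection = [selection]
        coords = []
        labels = []
        for chain, resnum, names in selection:
            wanted = None if names is None else set(names)
            for (c, r, a), xyz in model.atoms.items():
                if c == chain and r == resnum and (wanted is None or a in wanted):
                    coords.append(xyz)
                    labels.append((c, r, a))
            if not any(l[0] == chain and l[1] == resnum for l in labels):
                raise GlycoFunnelError(
                    "empty_selection",
                    f"no atoms for {chain}/{resnum}"
                    + ("" if wanted is None else f" named {sorted(wanted)}"),
                )
        return np.array(coords)

    ca = resolve(selection_a)
    cb = resolve(selection_b)
    d = np.sqrt(((ca[:, None, :] - cb[None, :, :]) ** 2).sum(axis=2))
    best = float(d.min())
    return round(best, ndigits) if ndigits is not None else best


def classify_from_structure(
    model: StructureModel, position: int, chain: str | None = None,
    config: PipelineConfig | None = None,
) -> AccessibilityCall:
    """Label one reference-protein position from a structure.

    The residue number in the structure is ``position + numbering_offset``.
    A residue absent from the resolved set is taken as disordered in the
    crystal, hence accessible.  A resolved residue whose phi/psi fall in the
    canonical helix or strand boxes is ordered; resolved coil defaults to
    accessible (configurable).  Dihedrals undefined at chain termini are
    treated as coil.
    """
    config = config or PipelineConfig()
    if not model.atoms:
        raise GlycoFunnelError("no_coverage", "empty structure model")
    if chain is None:
        chain = sorted(model.chains())[0]
    resnum = position + model.numbering_offset
    chain_residues = {r for (c, r) in model.resolved_residues if c == chain}
    if not chain_residues:
        raise GlycoFunnelError("no_coverage", f"chain {chain!r} not in structure")
    if resnum < min(chain_residues) or resnum > max(chain_residues):
        raise GlycoFunnelError(
            "no_coverage",
            f"position {position} (residue {resnum}) outside structure coverage",
        )
    if resnum not in chain_residues:
        return AccessibilityCall(
            ACCESSIBLE, "structure", f"residue {resnum} unresolved in density"
        )
    try:
        phi, psi = compute_dihedrals(model, chain, resnum)
    except GlycoFunnelError:
        phi = psi = None
    if phi is not None:
        for (phi_lo, phi_hi), (psi_lo, psi_hi) in (HELIX_BOX, STRAND_BOX):
            if phi_lo <= phi <= phi_hi and psi_lo <= psi <= psi_hi:
                return AccessibilityCall(
                    ORDERED, "structure", f"phi={phi:.1f} psi={psi:.1f}"
                )
    label = ACCESSIBLE if config.coil_is_accessible else ORDERED
    return AccessibilityCall(label, "structure", "resolved coil")


def assign_modification_mode(call: AccessibilityCall) -> str:
    """Accessible/disordered sites are modified post-translationally; ordered
    sites are candidates for co-translational modification on the nascent
    chain."""
    return "posttranslational" if call.label == ACCESSIBLE else "cotranslational_candidate"


def protein_mode(calls: Iterable[AccessibilityCall]) -> str:
    """Aggregate site-level modes to a protein label; mixed kinds give
    ``both``."""
    modes = {assign_modification_mode(c) for c in calls}
    if not modes:
        raise GlycoFunnelError("no_calls", "no accessibility calls for protein")
    if len(modes) == 2:
        return "both"
    return modes.pop()


def classify_site(
    position: int,
    profile: Optional[DisorderProfile],
    model: Optional[StructureModel] = None,
    chain: str | None = None,
    config: PipelineConfig | None = None,
) -> AccessibilityCall:
    """Resolve the evidence precedence for one site: structure first, disorder
    profile as fallback when the structure is absent or lacks coverage."""
    if model is not None:
        try:
            return classify_from_structure(model, position, chain=chain, config=config)
        except GlycoFunnelError as err:
            if err.code != "no_coverage":
                raise
    if profile is None:
        raise GlycoFunnelError(
            "no_evidence", f"no structure coverage and no disorder profile at {position}"
        )
    return classify_disorder(profile, position, config)
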