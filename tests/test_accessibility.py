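import math

import gemmi
import numpy as np
import pytest

from glycofunnel.accessibility import (
    ACCESSIBLE,
    ORDERED,
    DisorderProfile,
    StructureModel,
    assign_modification_mode,
    classify_disorder,
    classify_from_structure,
    classify_site,
    compute_dihedrals,
    dihedral_angle,
    load_disorder_profiles,
    min_atom_distance,
    protein_mode,
    write_disorder_profiles,
    write_pdb,
)
from glycofunnel.model import GlycoFunnelError, PipelineConfig
from glycofunnel.synthetic import (
    build_backbone_fragment,
    build_contact_fragment,
    place_atom,
)


class TestDisorder:
    def test_high_score_is_accessible_by_default(self):
        profile = DisorderProfile("P1", [0.1, 0.8, 0.3])
        call = classify_disorder(profile, 2)
        assert call.label == ACCESSIBLE
        assert call.basis == "disorder_profile"

    def test_literal_protocol_mode_inverts_the_call(self):
        profile = DisorderProfile("P1", [0.1, 0.8, 0.3])
        call = classify_disorder(
            profile, 2, PipelineConfig(paper_literal_disorder=True)
        )
        assert call.label == ORDERED

    def test_threshold_is_strictly_greater_than(self):
        profile = DisorderProfile("P1", [0.5])
        assert classify_disorder(profile, 1).label == ORDERED

    def test_flipping_the_flag_inverts_every_label(self):
        rng = np.random.default_rng(0)
        profile = DisorderProfile("P1", rng.uniform(0, 1, size=60))
        default = [classify_disorder(profile, i).label for i in range(1, 61)]
        literal = [
            classify_disorder(profile, i, PipelineConfig(paper_literal_disorder=True)).label
            for i in range(1, 61)
        ]
        assert all(a != b for a, b in zip(default, literal))

    def test_out_of_range_position_rejected(self):
        with pytest.raises(GlycoFunnelError):
            classify_disorder(DisorderProfile("P1", [0.5]), 2)

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(GlycoFunnelError):
            DisorderProfile("P1", [0.5, 1.2])

    def test_profile_tsv_round_trip(self, tmp_path):
        profiles = {
            "P1": DisorderProfile("P1", [0.1, 0.9, 0.5]),
            "P2": DisorderProfile("P2", [0.4, 0.6]),
        }
        path = tmp_path / "disorder.tsv"
        write_disorder_profiles(profiles, path)
        loaded = load_disorder_profiles(str(path))
        assert set(loaded) == {"P1", "P2"}
        assert np.allclose(loaded["P1"].scores, profiles["P1"].scores)


def rigid_transform(model: StructureModel, rng) -> StructureModel:
    # random rotation (QR of a Gaussian matrix) + translation
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(scale=20.0, size=3)
    return StructureModel(
        atoms={k: q @ v + t for k, v in model.atoms.items()},
        numbering_offset=model.numbering_offset,
    )


class TestDihedrals:
    def test_planted_backbone_angles_are_recovered(self):
        for phi, psi in [(-57, 147), (-60, -45), (-120, 130), (60, 40)]:
            frag = build_backbone_fragment([(0, 10), (phi, psi), (0, 0)])
            got_phi, got_psi = compute_dihedrals(frag, "A", 2)
            assert got_phi == pytest.approx(phi, abs=1e-6)
            assert got_psi == pytest.approx(psi, abs=1e-6)

    def test_trans_planar_chain_has_torsion_180(self):
        # zig-zag in a plane: torsion of an ideal trans arrangement
        p1, p2, p3 = [0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0]
        p4 = place_atom(p1, p2, p3, 1.5, 109.5, 180.0)
        assert dihedral_angle(p1, p2, p3, p4) == pytest.approx(180.0, abs=1e-9)

    def test_rigid_motion_leaves_torsions_unchanged(self):
        rng = np.random.default_rng(3)
        frag = build_backbone_fragment([(0, 30), (-57, 147), (-80, 60), (0, 0)])
        ref = [compute_dihedrals(frag, "A", r) for r in (2, 3)]
        for _ in range(5):
            moved = rigid_transform(frag, rng)
            got = [compute_dihedrals(moved, "A", r) for r in (2, 3)]
            for (p0, s0), (p1, s1) in zip(ref, got):
                assert p1 == pytest.approx(p0, abs=1e-6)
                assert s1 == pytest.approx(s0, abs=1e-6)

    def test_mirror_reflection_flips_torsion_sign(self):
        frag = build_backbone_fragment([(0, 30), (-57, 147), (0, 0)])
        mirrored = StructureModel(
            atoms={k: v * np.array([1, 1, -1]) for k, v in frag.atoms.items()}
        )
        phi, psi = compute_dihedrals(frag, "A", 2)
        mphi, mpsi = compute_dihedrals(mirrored, "A", 2)
        assert mphi == pytest.approx(-phi, abs=1e-6)
        assert mpsi == pytest.approx(-psi, abs=1e-6)

    def test_agrees_with_gemmi_reference(self):
        frag = build_backbone_fragment([(0, 30), (-57, 147), (-80, 60), (0, 0)])
        for res in (2, 3):
            pts = [
                frag.atom("A", res - 1, "C"),
                frag.atom("A", res, "N"),
                frag.atom("A", res, "CA"),
                frag.atom("A", res, "C"),
            ]
            expected = math.degrees(
                gemmi.calculate_dihedral(*[gemmi.Position(*p) for p in pts])
            )
            assert compute_dihedrals(frag, "A", res)[0] == pytest.approx(
                expected, abs=1e-9
            )

    def test_missing_neighbor_gives_undefined_dihedral(self):
        frag = build_backbone_fragment([(0, 30), (-57, 147)])
        with pytest.raises(GlycoFunnelError) as err:
            compute_dihedrals(frag, "A", 1)  # no residue 0
        assert err.value.code == "undefined_dihedral"

    def test_collinear_atoms_are_degenerate(self):
        with pytest.raises(GlycoFunnelError) as err:
            dihedral_angle([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])
        assert err.value.code == "degenerate_geometry"


class TestDistances:
    def test_planted_hydroxyl_carboxylate_contact(self):
        frag = build_contact_fragment(3.3)
        d = min_atom_distance(
            frag, ("A", 365, ["OG"]), ("A", 364, ["OE1", "OE2"]), ndigits=1
        )
        assert d == 3.3

    def test_shared_atom_position_gives_zero(self):
        frag = build_contact_fragment()
        assert min_atom_distance(frag, ("A", 365, ["OG"]), ("A", 365, ["OG"])) == 0.0

    def test_matches_exhaustive_all_pairs_scan(self):
        rng = np.random.default_rng(9)
        atoms = {
            ("A", r, f"X{i}"): rng.normal(scale=8.0, size=3)
            for r in (1, 2) for i in range(6)
        }
        model = StructureModel(atoms=atoms)
        got = min_atom_distance(model, ("A", 1, None), ("A", 2, None))
        expected = min(
            float(np.linalg.norm(atoms[("A", 1, f"X{i}")] - atoms[("A", 2, f"X{j}")]))
            for i in range(6) for j in range(6)
        )
        assert got == pytest.approx(expected)
        # symmetry and non-negativity
        assert got == pytest.approx(
            min_atom_distance(model, ("A", 2, None), ("A", 1, None))
        )
        assert got >= 0

    def test_empty_selection_names_missing_atoms(self):
        frag = build_contact_fragment()
        with pytest.raises(GlycoFunnelError) as err:
            min_atom_distance(frag, ("A", 999, ["OG"]), ("A", 364, None))
        assert err.value.code == "empty_selection"


class TestStructureClassification:
    def test_unresolved_residue_is_accessible(self):
        frag = build_backbone_fragment([(0, 30), (-57, 147), (0, 0)])
        # residue 10 inside coverage... build a gap by shifting numbering
        atoms = dict(frag.atoms)
        model = StructureModel(atoms=atoms)
        # density gap: drop residue 2 entirely but keep 1 and 3
        for name in ("N", "CA", "C"):
            del atoms[("A", 2, name)]
        model = StructureModel(atoms=atoms)
        call = classify_from_structure(model, 2)
        assert call.label == ACCESSIBLE
        assert call.basis == "structure"

    def test_helical_dihedrals_are_ordered(self):
        frag = build_backbone_fragment([(-60, -45)] * 5)
        call = classify_from_structure(frag, 3)
        assert call.label == ORDERED

    def test_helix_planted_site_is_cotranslational_candidate(self):
        # an AHCY-like site buried in an alpha-helix
        frag = build_backbone_fragment([(-60, -45)] * 7, start_residue=133)
        call = classify_from_structure(frag, 136)
        assert call.label == ORDERED
        assert assign_modification_mode(call) == "cotranslational_candidate"

    def test_extended_strand_dihedrals_are_ordered(self):
        frag = build_backbone_fragment([(-120, 130)] * 5)
        assert classify_from_structure(frag, 3).label == ORDERED

    def test_position_outside_coverage_raises_no_coverage(self):
        frag = build_backbone_fragment([(-60, -45)] * 3)
        with pytest.raises(GlycoFunnelError) as err:
            classify_from_structure(frag, 50)
        assert err.value.code == "no_coverage"

    def test_numbering_offset_maps_protein_to_structure(self):
        frag = build_backbone_fragment([(-60, -45)] * 5, start_residue=101)
        frag.numbering_offset = 100
        assert classify_from_structure(frag, 3).label == ORDERED

    def test_structure_takes_precedence_over_disorder(self):
        frag = build_backbone_fragment([(-60, -45)] * 5)
        profile = DisorderProfile("P1", [0.9] * 10)
        call = classify_site(3, profile, model=frag)
        assert call.basis == "structure"
        assert call.label == ORDERED
        # without coverage the profile decides
        fallback = classify_site(9, profile, model=frag)
        assert fallback.basis == "disorder_profile"
        assert fallback.label == ACCESSIBLE

    def test_pdb_round_trip_through_gemmi(self, tmp_path):
        frag = build_backbone_fragment([(0, 30), (-57, 147), (0, 0)])
        path = tmp_path / "frag.pdb"
        write_pdb(frag, path, residue_names={("A", 2): "SER"})
        loaded = StructureModel.from_pdb(path)
        assert loaded.resolved_residues == frag.resolved_residues
        phi0, psi0 = compute_dihedrals(frag, "A", 2)
        phi1, psi1 = compute_dihedrals(loaded, "A", 2)
        # PDB stores 3 decimals; on a short fragment that allows a few
        # hundredths of a degree of drift
        assert phi1 == pytest.approx(phi0, abs=0.05)
        assert psi1 == pytest.approx(psi0, abs=0.05)


class TestModes:
    def test_accessible_site_is_posttranslational(self):
        assert assign_modification_mode(
            classify_disorder(DisorderProfile("P", [0.9]), 1)
        ) == "posttranslational"

    def test_mixed_sites_give_protein_label_both(self):
        calls = [
            classify_disorder(DisorderProfile("P", [0.9, 0.1]), 1),
            classify_disorder(DisorderProfile("P", [0.9, 0.1]), 2),
        ]
        assert protein_mode(calls) == "both"
        assert protein_mode(calls[:1]) == "posttranslational"
        assert protein_mode(calls[1:]) == "cotranslational_candidate"
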