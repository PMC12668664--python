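"""Footprints, cross-complex overlap, receptor transplantation, clash scan."""

import numpy as np
import pytest

from abepitope.footprints import (
    clash_scan,
    compare_footprints,
    epitope_footprint,
    peptide_contact_profile,
    transplant_receptor,
)
from abepitope.geometry import Transform, kabsch_superpose
from abepitope.structure import Atom, ChainRoleMap, Residue, StructureModel
from abepitope.synthetic import HelixSpec, ProbePlacement, ToyComplexSpec, build_toy_complex
from tests.conftest import atom_entries, single_atom_residues
from tests.test_geometry import random_rotation


def rigid_move(model, rng, scale=15.0):
    T = Transform(random_rotation(rng), rng.normal(size=3) * scale)
    moved = model.copy()
    for res in moved.iter_residues():
        for atom in res.atoms:
            atom.position = T.apply(atom.position)
    return moved


def footprint_of(model, roles, binder=("ab_heavy",), cutoff=4.0):
    return epitope_footprint(model, roles, binder_roles=binder, cutoff=cutoff)


def test_designed_epitope_residues_recovered(toy_complex):
    model, roles, truth = toy_complex
    fp = footprint_of(model, roles)
    designed_within_cutoff = {
        t["antigen_residue"] for t in truth if t["distance"] <= 4.0
    }
    assert designed_within_cutoff <= set(fp.residues)
    # the 4.1 Å probe contributes no contact at 4.0
    assert ("A", 153, "") not in fp.residues


def test_tiny_cutoff_empties_footprint(toy_complex):
    model, roles, _ = toy_complex
    assert footprint_of(model, roles, cutoff=0.1).residues == {}


def test_missing_role_raises(toy_complex):
    model, roles, _ = toy_complex
    with pytest.raises(KeyError):
        epitope_footprint(model, roles, binder_roles=("receptor",))


def _fp(cid, numbers):
    from abepitope.footprints import Footprint

    return Footprint(
        complex_id=cid, target_role="mhc_heavy", binder_role="x",
        residues={("A", n, ""): 1 for n in numbers},
    )


def test_self_comparison_gives_jaccard_one():
    fp = _fp("one", [145, 146, 149])
    report = compare_footprints([fp, fp])
    assert report.jaccard == 1.0
    assert report.shared == {145, 146, 149}
    assert all(not u for u in report.unique.values())


def test_disjoint_footprints_give_jaccard_zero():
    report = compare_footprints([_fp("a", [1, 2]), _fp("b", [10, 11])])
    assert report.jaccard == 0.0
    assert report.shared == set()
    assert report.unique["a"] == {1, 2}


def test_three_way_overlap_and_order_invariance():
    a = _fp("a", [141, 145, 146, 149, 150, 151])
    b = _fp("b", [145, 146, 148, 149, 150, 151])
    c = _fp("c", [144, 145, 146, 149, 150, 151, 155])
    expected_shared = {145, 146, 149, 150, 151}
    for order in ([a, b, c], [c, a, b], [b, c, a]):
        report = compare_footprints(order)
        assert report.shared == expected_shared
    report = compare_footprints([a, b, c])
    assert report.union == {141, 144, 145, 146, 148, 149, 150, 151, 155}
    assert report.jaccard == pytest.approx(5 / 9)
    # partition property: shared and uniques are disjoint subsets of the union
    assert report.shared <= report.union
    for u in report.unique.values():
        assert u <= report.union and not (u & report.shared)


def test_segment_restriction():
    a = _fp("a", [50, 145, 146])
    b = _fp("b", [50, 145, 170])
    report = compare_footprints([a, b], restricted_segment=(141, 155),
                                segment_name="alpha2_1")
    assert report.shared == {145}
    assert report.restricted_segment == "alpha2_1"


def test_unmappable_residues_are_reported_not_dropped():
    from abepitope.geometry import Correspondence

    a = _fp("ref", [145, 146])
    b = _fp("mov", [145, 199])
    corr = Correspondence(pairs=[(("A", 145, ""), ("A", 145, ""))], mode="by_number")
    report = compare_footprints([a, b], correspondences={"mov": corr})
    assert report.unmapped["mov"] == {199}


def make_reference_complex():
    """MHC-like helix (mhc_heavy) + a 'receptor' chain near it."""
    spec = ToyComplexSpec(
        antigen=HelixSpec("A" * 60, start_number=120, with_backbone=True),
        placements=[
            ProbePlacement(145, [1.0, 0, 0], 3.5, probe_atom="CB"),
            ProbePlacement(149, [0.8, 0.6, 0], 3.2, probe_atom="CB"),
        ],
        probe_chain_id="R",
        probe_role="receptor",
    )
    model, roles, truth = build_toy_complex(spec)
    roles.segments[("mhc_heavy", "alpha1_alpha2")] = (120, 179)
    return model, roles, truth


def test_transplant_self_lands_on_original_pose(rng):
    ref_model, ref_roles, _ = make_reference_complex()
    donor = rigid_move(ref_model, rng)
    moved, transform, fit = transplant_receptor(
        ref_model, ref_roles, donor, ref_roles, min_pairs=30
    )
    assert fit == pytest.approx(0.0, abs=1e-8)
    orig = np.array([a.position for _, a in ref_model.iter_atoms()])
    back = np.array([a.position for _, a in moved.iter_atoms()])
    np.testing.assert_allclose(back, orig, atol=1e-8)


def test_transplant_transform_matches_kabsch_on_same_subset(rng):
    ref_model, ref_roles, _ = make_reference_complex()
    donor = rigid_move(ref_model, rng)
    moved, transform, fit = transplant_receptor(
        ref_model, ref_roles, donor, ref_roles, min_pairs=30
    )
    lo, hi = ref_roles.segment("mhc_heavy", "alpha1_alpha2")
    ref_ca = np.array([
        r.atom("CA").position for r in ref_model.chain("A") if lo <= r.seq_number <= hi
    ])
    don_ca = np.array([
        r.atom("CA").position for r in donor.chain("A") if lo <= r.seq_number <= hi
    ])
    expected, expected_rmsd = kabsch_superpose(ref_ca, don_ca)
    np.testing.assert_allclose(transform.rotation, expected.rotation, atol=1e-9)
    np.testing.assert_allclose(transform.translation, expected.translation, atol=1e-8)
    assert fit == pytest.approx(expected_rmsd, abs=1e-10)


def test_transplant_requires_enough_pairs(rng):
    ref_model, ref_roles, _ = make_reference_complex()
    donor = rigid_move(ref_model, rng)
    with pytest.raises(ValueError, match="unreliable"):
        transplant_receptor(ref_model, ref_roles, donor, ref_roles, min_pairs=500)


def test_clash_scan_closed_form_two_carbons():
    a = atom_entries(single_atom_residues([[0.0, 0, 0]], chain_id="P"))
    b = atom_entries(single_atom_residues([[2.0, 0, 0]], chain_id="T"))
    report = clash_scan(a, b, overlap_threshold=0.4)
    assert report.total == 1
    (_, _, distance, overlap) = report.clash_pairs[0]
    assert distance == pytest.approx(2.0)
    assert overlap == pytest.approx(1.4)  # 1.70 + 1.70 − 2.0


def test_clash_scan_far_apart_is_empty():
    a = atom_entries(single_atom_residues([[0.0, 0, 0]], chain_id="P"))
    b = atom_entries(single_atom_residues([[20.0, 0, 0]], chain_id="T"))
    report = clash_scan(a, b)
    assert report.total == 0 and report.dominant is None


def test_clash_scan_threshold_semantics():
    # carbons: clash iff d < 3.4 − threshold
    a = atom_entries(single_atom_residues([[0.0, 0, 0]], chain_id="P"))
    for d, expected in ((2.99, 1), (3.01, 0)):
        b = atom_entries(single_atom_residues([[d, 0, 0]], chain_id="T"))
        assert clash_scan(a, b, overlap_threshold=0.4).total == expected


def test_clash_matrix_segments_and_dominant():
    probe = atom_entries(
        single_atom_residues([[0.0, 0, 0], [0.0, 0, 2.0], [50, 0, 0]], chain_id="R")
    )
    target = atom_entries(
        single_atom_residues([[1.8, 0, 0], [0.0, 0, 3.6]], chain_id="L")
    )
    report = clash_scan(
        probe, target,
        probe_segments={"D1": (1, 1), "D2": (2, 3)},
        target_segments={"VL": (1, 2)},
    )
    assert report.total >= 2
    assert report.dominant is not None
    assert sum(report.by_segment.values()) == report.total


def test_self_image_antibody_clashes_everywhere(rng):
    # receptor = exact copy of the antibody: every atom clashes with its image
    positions = rng.normal(size=(20, 3)) * 6
    ab = atom_entries(single_atom_residues(positions, chain_id="H"))
    image = atom_entries(single_atom_residues(positions, chain_id="R"))
    report = clash_scan(image, ab, overlap_threshold=0.4)
    self_pairs = {(i, j) for i, j, _, _ in report.clash_pairs if i == j}
    assert len(self_pairs) == 20


def test_transplant_then_clash_invariant_under_donor_rigid_motion(rng):
    ref_model, ref_roles, _ = make_reference_complex()
    # an "antibody" chain near the receptor site of the reference
    ab = single_atom_residues(
        [[6.0, 1.0, 36.0], [7.0, 0.0, 37.5], [5.5, 2.0, 39.0]], chain_id="H"
    )
    donor0 = rigid_move(ref_model, rng)
    donor1 = rigid_move(donor0, rng)

    def clash_count(donor):
        moved, _, _ = transplant_receptor(ref_model, ref_roles, donor, ref_roles,
                                          min_pairs=30)
        rec_atoms = [(r, a) for r in moved.chain("R") for a in r.atoms]
        return clash_scan(rec_atoms, atom_entries(ab)).total

    assert clash_count(donor0) == clash_count(donor1)


def peptide_model():
    """Nonamer peptide + binder contacting only P3."""
    pep = single_atom_residues(
        [[float(i) * 3.8, 0, 0] for i in range(9)], chain_id="C"
    )
    binder = single_atom_residues([[2 * 3.8, 3.0, 0]], chain_id="H")
    model = StructureModel(id="pep_toy", chains=[("C", pep), ("H", binder)])
    roles = ChainRoleMap(role_of={"C": "peptide", "H": "ab_heavy"})
    return model, roles


def test_peptide_profile_designed_p3_contact():
    model, roles = peptide_model()
    profile = peptide_contact_profile(model, roles)
    flags = [p["contacted"] for p in profile]
    assert flags == [False, False, True, False, False, False, False, False, False]
    assert profile[2]["partners"] == [(("H", 1, ""), "ALA")]


def test_peptide_profile_requires_peptide_role():
    model, _ = peptide_model()
    roles = ChainRoleMap(role_of={"C": "other", "H": "ab_heavy"})
    with pytest.raises(KeyError):
        peptide_contact_profile(model, roles)
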