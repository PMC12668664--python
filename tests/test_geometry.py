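"""Kabsch superposition, residue correspondence, and RMSD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abepitope.geometry import (
    Transform,
    apply_transform,
    kabsch_superpose,
    map_residues,
    rmsd,
)
from abepitope.structure import Atom, Residue


def random_rotation(rng):
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def test_identical_sets_give_identity_and_zero_rmsd(rng):
    pts = rng.normal(size=(10, 3))
    transform, value = kabsch_superpose(pts, pts)
    np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(transform.translation, 0.0, atol=1e-12)
    assert value == pytest.approx(0.0, abs=1e-12)


def test_known_rigid_motion_is_recovered(rng):
    pts = rng.normal(size=(25, 3)) * 5
    R = random_rotation(rng)
    t = rng.normal(size=3) * 10
    moved = (R @ pts.T).T + t
    # superposing `moved` back onto `pts` must recover the inverse motion
    transform, value = kabsch_superpose(pts, moved)
    assert value < 1e-8
    np.testing.assert_allclose(transform.rotation @ R, np.eye(3), atol=1e-8)
    np.testing.assert_allclose(transform.apply(moved), pts, atol=1e-8)


def test_reflection_is_suppressed(rng):
    pts = rng.normal(size=(12, 3))
    mirrored = pts * np.array([-1.0, 1.0, 1.0])
    transform, _ = kabsch_superpose(pts, mirrored)
    assert np.linalg.det(transform.rotation) == pytest.approx(1.0, abs=1e-9)


def test_degenerate_inputs_raise():
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(ValueError, match="collinear"):
        kabsch_superpose(line, line + 1.0)
    with pytest.raises(ValueError, match="3 paired points"):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def brute_force_min_rmsd(P, Q, coarse_deg=5.0):
    """Grid search over ZYZ Euler rotations, then local refinement."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)

    def value(angles):
        R = Rotation.from_euler("zyz", angles, degrees=True).as_matrix()
        return np.sqrt(np.mean(np.sum(((R @ Q0.T).T - P0) ** 2, axis=1)))

    grid = np.arange(0.0, 360.0, coarse_deg)
    mid = np.arange(0.0, 180.0 + coarse_deg, coarse_deg)
    best, best_angles = np.inf, None
    for a in grid[::4]:
        for b in mid[::4]:
            for c in grid[::4]:
                v = value((a, b, c))
                if v < best:
                    best, best_angles = v, (a, b, c)
    res = minimize(value, best_angles, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12})
    return min(best, res.fun)


def test_kabsch_matches_brute_force_rotation_search(rng):
    for n in (4, 5, 6):
        P = rng.normal(size=(n, 3)) * 3
        Q = rng.normal(size=(n, 3)) * 3
        _, kabsch_value = kabsch_superpose(P, Q)
        brute = brute_force_min_rmsd(P, Q)
        assert kabsch_value <= brute + 1e-6
        assert abs(kabsch_value - brute) < 0.05  # grid+refine tolerance


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_kabsch_invariant_under_rigid_motion_of_moving_set(seed):
    rng = np.random.default_rng(seed)
    P = rng.normal(size=(8, 3)) * 4
    Q = rng.normal(size=(8, 3)) * 4
    _, base = kabsch_superpose(P, Q)
    R = random_rotation(rng)
    t = rng.normal(size=3) * 7
    _, moved = kabsch_superpose(P, (R @ Q.T).T + t)
    assert moved == pytest.approx(base, abs=1e-6)
    # and superposition never increases the RMSD
    assert base <= rmsd(P, Q) + 1e-12


def test_rmsd_closed_forms():
    a = np.array([[0.0, 0, 0], [10, 0, 0]])
    b = np.array([[0.0, 0, 2], [10, 0, 2]])
    assert rmsd(a, a) == 0.0
    assert rmsd(a, b) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        rmsd(np.zeros((0, 3)), np.zeros((0, 3)))


def test_rmsd_superpose_first_equals_kabsch(rng):
    A = rng.normal(size=(9, 3))
    B = rng.normal(size=(9, 3))
    assert rmsd(A, B, superpose_first=True) == pytest.approx(
        kabsch_superpose(A, B)[1]
    )


def test_apply_transform_identity_composition_inverse(rng):
    pts = rng.normal(size=(6, 3))
    ident = Transform.identity()
    np.testing.assert_allclose(apply_transform(ident, pts), pts)
    R1, R2 = random_rotation(rng), random_rotation(rng)
    t1, t2 = rng.normal(size=3), rng.normal(size=3)
    T1, T2 = Transform(R1, t1), Transform(R2, t2)
    composed = T1.compose(T2)
    np.testing.assert_allclose(
        apply_transform(composed, pts),
        apply_transform(T1, apply_transform(T2, pts)),
        atol=1e-12,
    )
    np.testing.assert_allclose(
        apply_transform(T1.inverse(), apply_transform(T1, pts)), pts, atol=1e-9
    )


def test_known_rotation_maps_unit_vectors_analytically():
    Rz90 = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
    T = Transform(Rz90, np.zeros(3))
    np.testing.assert_allclose(T.apply(np.array([1.0, 0, 0])), [0, 1, 0], atol=1e-15)
    np.testing.assert_allclose(T.apply(np.array([0.0, 1, 0])), [-1, 0, 0], atol=1e-15)


def _chain(seq, start=1, chain_id="A"):
    three = {"A": "ALA", "G": "GLY", "V": "VAL", "L": "LEU", "S": "SER",
             "T": "THR", "K": "LYS", "R": "ARG", "Q": "GLN", "E": "GLU",
             "H": "HIS", "D": "ASP", "N": "ASN", "F": "PHE", "Y": "TYR",
             "W": "TRP", "I": "ILE", "M": "MET", "P": "PRO", "C": "CYS"}
    return [
        Residue(chain_id, start + i, three[c],
                [Atom("CA", "C", np.array([float(i), 0, 0]))])
        for i, c in enumerate(seq)
    ]


def test_map_residues_by_number_identical_chains():
    a = _chain("AGVLSTKRQE")
    b = _chain("AGVLSTKRQE", chain_id="B")
    corr = map_residues(a, b, "by_number")
    assert len(corr.pairs) == 10
    assert all(ra[1] == rb[1] for ra, rb in corr.pairs)


def test_map_residues_by_number_respects_numbering_offset():
    a = _chain("AGVLS", start=141)
    b = _chain("AGVLS", start=143, chain_id="B")
    corr = map_residues(a, b, "by_number")
    assert sorted(ra[1] for ra, _ in corr.pairs) == [143, 144, 145]


def test_map_residues_alpha21_segment_full_pairing():
    # 15 positions, 141–155: allelomorph helix sequences differ in sequence
    # but share mature numbering, so by_number pairs all 15
    a = _chain("AGVLSTKRQEAGVLS", start=141)
    b = _chain("TGVKSHRRQHAGVHS", start=141, chain_id="B")
    corr = map_residues(a, b, "by_number")
    assert len(corr.pairs) == 15


def test_map_residues_by_alignment_skips_deletions():
    full = _chain("AGVLSTKRQE")
    # delete residues 4-6 (VLS... positions 3..5) — alignment must skip the gap
    deleted = [r for r in _chain("AGVLSTKRQE", chain_id="B") if r.seq_number not in (4, 5, 6)]
    corr = map_residues(full, deleted, "by_alignment")
    paired_ref = sorted(ra[1] for ra, _ in corr.pairs)
    assert len(corr.pairs) == 7
    assert paired_ref == [1, 2, 3, 7, 8, 9, 10]
    # brute-force expectation: the surviving letters pair with their originals
    for (ra, rb) in corr.pairs:
        assert ra[1] == rb[1]


def test_map_residues_empty_intersection_raises():
    a = _chain("AGVLS", start=1)
    b = _chain("AGVLS", start=100, chain_id="B")
    with pytest.raises(ValueError):
        map_residues(a, b, "by_number")
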