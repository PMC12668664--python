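"""Rigid-body superposition and residue correspondence.

Kabsch superposition finds the proper rotation + translation minimizing the
RMSD between paired point sets; reflections are always suppressed (the
determinant is forced to +1) because mirror images are not physical poses.
Residue correspondence between homologous chains is either by shared author
numbering (HLA allelomorphs share mature-protein numbering) or by global
pairwise sequence alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from Bio import Align
from Bio.Data.IUPACData import protein_letters_3to1

from .structure import Residue

__all__ = [
    "Transform",
    "Correspondence",
    "kabsch_superpose",
    "map_residues",
    "rmsd",
    "apply_transform",
]


@dataclass
class Transform:
    """Proper rigid motion x' = R·x + t (rotation R, translation t in Å)."""

    rotation: np.ndarray  # 3×3, orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("Transform needs a 3×3 rotation and a 3-vector translation")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation determinant is not +1 (reflection?)")

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return apply_transform(self, coords)

    def inverse(self) -> "Transform":
        rt = self.rotation.T
        return Transform(rt, -rt @ self.translation)

    def compose(self, other: "Transform") -> "Transform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return Transform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def as_flat(self) -> list[float]:
        """12 numbers: row-major rotation then translation (for JSON reports)."""
        return [*self.rotation.reshape(9).tolist(), *self.translation.tolist()]


@dataclass
class Correspondence:
    """Ordered one-to-one pairing of residues between two chains."""

    pairs: list[tuple[tuple, tuple]]  # (reference residue id, moving residue id)
    mode: Literal["by_number", "by_alignment"]

    def __post_init__(self) -> None:
        refs = [p[0] for p in self.pairs]
        movs = [p[1] for p in self.pairs]
        if len(set(refs)) != len(refs) or len(set(movs)) != len(movs):
            raise ValueError("correspondence is not one-to-one")


def kabsch_superpose(
    reference: np.ndarray, moving: np.ndarray
) -> tuple[Transform, float]:
    """Least-squares proper superposition of ``moving`` onto ``reference``.

    Returns the optimal :class:`Transform` and the minimized RMSD in Å.
    Requires N ≥ 3 non-collinear paired points; reflections are forbidden.
    """
    P = np.asarray(reference, dtype=float)
    Q = np.asarray(moving, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching N×3 arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 paired points, got {n}")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    # collinearity: centered points must span at least a plane
    if np.linalg.matrix_rank(Q0, tol=1e-8) < 2 or np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = Q0.T @ P0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    moved = (R @ Q.T).T + t
    value = float(np.sqrt(np.mean(np.sum((moved - P) ** 2, axis=1))))
    return Transform(R, t), value


def rmsd(
    coords_a: np.ndarray, coords_b: np.ndarray, superpose_first: bool = False
) -> float:
    """Root-mean-square deviation between paired coordinate sets, in Å."""
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("coordinate sets must have equal shapes")
    if A.shape[0] == 0:
        raise ValueError("empty coordinate sets")
    if superpose_first:
        return kabsch_superpose(A, B)[1]
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


def apply_transform(transform: Transform, coords: np.ndarray) -> np.ndarray:
    """Apply x' = R·x + t to an N×3 (or (3,)) coordinate array."""
    c = np.asarray(coords, dtype=float)
    if c.ndim == 1:
        return transform.rotation @ c + transform.translation
    return (transform.rotation @ c.T).T + transform.translation


def _one_letter(res_name: str) -> str:
    return protein_letters_3to1.get(res_name.capitalize(), "X")


def map_residues(
    chain_a: Sequence[Residue],
    chain_b: Sequence[Residue],
    mode: Literal["by_number", "by_alignment"] = "by_number",
) -> Correspondence:
    """Pair residues of two protein chains.

    ``by_number`` pairs residues with equal (author seq_number, insertion
    code). ``by_alignment`` runs a global pairwise sequence alignment
    (match +1, mismatch −1, gap open −2, gap extend −1) and pairs residues
    from aligned columns where both are present.
    """
    a = [r for r in chain_a if r.is_protein]
    b = [r for r in chain_b if r.is_protein]
    if not a or not b:
        raise ValueError("both chains must contain protein residues")

    pairs: list[tuple[tuple, tuple]] = []
    if mode == "by_number":
        index_b = {(r.seq_number, r.insertion_code): r for r in b}
        for r in a:
            other = index_b.get((r.seq_number, r.insertion_code))
            if other is not None:
                pairs.append((r.id, other.id))
    elif mode == "by_alignment":
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -1
        seq_a = "".join(_one_letter(r.res_name) for r in a)
        seq_b = "".join(_one_letter(r.res_name) for r in b)
        alignment = aligner.align(seq_a, seq_b)[0]
        for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
            for i, j in zip(range(a_start, a_end), range(b_start, b_end)):
                pairs.append((a[i].id, b[j].id))
    else:
        raise ValueError(f"unknown mapping mode {mode!r}")

    if not pairs:
        raise ValueError("no residues could be paired between the chains")
    return Correspondence(pairs=pairs, mode=mode)
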