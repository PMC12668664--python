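"""Footprints, cross-complex overlap, receptor transplantation, and clashes.

These are the computations behind the blocking argument: the antibody's
contact footprint on the MHC-I α2₁ helix is compared with the footprints of
inhibitory KIR receptors from their own complexes (mapped onto a shared
reference numbering), and a KIR receptor is "transplanted" into the antibody
complex by superposing the MHC heavy chains — steric clashes between the
transplanted receptor and the antibody then demonstrate mutual exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .contacts import find_contacts
from .geometry import Correspondence, Transform, kabsch_superpose, map_residues
from .structure import (
    ChainRoleMap,
    RadiusSet,
    Residue,
    StructureModel,
    select_atoms,
)

__all__ = [
    "Footprint",
    "OverlapReport",
    "ClashReport",
    "epitope_footprint",
    "compare_footprints",
    "transplant_receptor",
    "clash_scan",
    "peptide_contact_profile",
]


@dataclass
class Footprint:
    """Contact-based footprint: residues of ``target_role`` touched by ``binder_role``."""

    complex_id: str
    target_role: str
    binder_role: str
    residues: dict[tuple, int]  # residue id → number of partner residues
    res_names: dict[tuple, str] = field(default_factory=dict)
    cutoff: float = 4.0

    def residue_numbers(self) -> set[int]:
        return {rid[1] for rid in self.residues}


@dataclass
class OverlapReport:
    """Multi-way footprint comparison on a shared reference numbering."""

    complex_ids: list[str]
    mapping_mode: str
    shared: set[int]  # reference residue numbers contacted in every complex
    unique: dict[str, set[int]]  # complex id → numbers contacted only there
    union: set[int]
    jaccard: float  # |shared| / |union|
    unmapped: dict[str, set[int]] = field(default_factory=dict)
    restricted_segment: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.jaccard <= 1.0:
            raise ValueError("jaccard must lie in [0, 1]")


@dataclass
class ClashReport:
    """Steric clashes between a probe atom set and a target atom set."""

    transform: Transform | None
    fit_rmsd: float | None
    clash_pairs: list[tuple[int, int, float, float]]  # (probe idx, target idx, distance, overlap)
    total: int
    by_segment: dict[tuple[str, str], int]  # (probe segment, target segment) → count
    overlap_threshold: float = 0.4

    @property
    def dominant(self) -> tuple[str, str] | None:
        """(probe segment, target segment) cell with the most clashes."""
        if not self.by_segment:
            return None
        return max(self.by_segment.items(), key=lambda kv: (kv[1], kv[0]))[0]


def epitope_footprint(
    model: StructureModel,
    roles: ChainRoleMap,
    target_role: str = "mhc_heavy",
    binder_roles: Sequence[str] = ("ab_heavy", "ab_light"),
    cutoff: float = 4.0,
) -> Footprint:
    """Residues of the target role with ≥ 1 heavy-atom contact to the binder.

    Per-residue values count distinct partner residues on the binder side.
    """
    target_atoms = select_atoms(model, roles, target_role)
    present = [r for r in binder_roles if roles.chains_with_role(r)]
    if not present:
        raise KeyError(f"no binder chains among roles {tuple(binder_roles)}")
    binder_atoms: list = []
    for role in present:
        binder_atoms.extend(select_atoms(model, roles, role))
    table = find_contacts(target_atoms, binder_atoms, cutoff=cutoff)
    residues: dict[tuple, int] = {}
    names: dict[tuple, str] = {}
    partners: dict[tuple, set] = {}
    for rec in table.records:
        partners.setdefault(rec.residue_a, set()).add(rec.residue_b)
        names[rec.residue_a] = rec.res_name_a
    for rid, ps in partners.items():
        residues[rid] = len(ps)
    return Footprint(
        complex_id=model.id,
        target_role=target_role,
        binder_role="+".join(binder_roles),
        residues=residues,
        res_names=names,
        cutoff=cutoff,
    )


def compare_footprints(
    footprints: Sequence[Footprint],
    correspondences: Mapping[str, Correspondence] | None = None,
    restricted_segment: tuple[int, int] | None = None,
    segment_name: str | None = None,
) -> OverlapReport:
    """Intersect/union ≥ 2 footprints mapped onto a shared reference numbering.

    ``correspondences`` maps a complex id to the residue correspondence from
    that complex's ligand chain onto the reference ligand; complexes without
    an entry are assumed to share the reference numbering already (the HLA
    mature-numbering convention). Footprint residues that cannot be mapped
    are reported in ``unmapped``, never silently dropped. The optional
    ``restricted_segment`` (inclusive number range) restricts the comparison,
    e.g. to the α2₁ helix.
    """
    if len(footprints) < 2:
        raise ValueError("need at least two footprints to compare")
    mapped: dict[str, set[int]] = {}
    unmapped: dict[str, set[int]] = {}
    mode = "by_number"
    for fp in footprints:
        corr = correspondences.get(fp.complex_id) if correspondences else None
        if corr is None:
            nums = fp.residue_numbers()
            miss: set[int] = set()
        else:
            mode = corr.mode
            to_ref = {mov: ref for ref, mov in corr.pairs}
            nums, miss = set(), set()
            for rid in fp.residues:
                ref_id = to_ref.get(rid)
                if ref_id is None:
                    miss.add(rid[1])
                else:
                    nums.add(ref_id[1])
        if restricted_segment is not None:
            lo, hi = restricted_segment
            nums = {n for n in nums if lo <= n <= hi}
        mapped[fp.complex_id] = nums
        if miss:
            unmapped[fp.complex_id] = miss

    sets = list(mapped.values())
    shared = set.intersection(*sets)
    union = set.union(*sets)
    unique = {}
    for cid, nums in mapped.items():
        others = [s for c, s in mapped.items() if c != cid]
        unique[cid] = nums - set.union(*others) if others else set()
    jaccard = len(shared) / len(union) if union else 1.0
    return OverlapReport(
        complex_ids=[fp.complex_id for fp in footprints],
        mapping_mode=mode,
        shared=shared,
        unique=unique,
        union=union,
        jaccard=jaccard,
        unmapped=unmapped,
        restricted_segment=segment_name,
    )


def transplant_receptor(
    reference_model: StructureModel,
    reference_roles: ChainRoleMap,
    donor_model: StructureModel,
    donor_roles: ChainRoleMap,
    align_segment: str = "alpha1_alpha2",
    mapping_mode: str = "by_number",
    min_pairs: int = 30,
) -> tuple[StructureModel, Transform, float]:
    """Superpose a donor complex onto the reference via the MHC heavy chains.

    The donor MHC heavy chain Cα atoms of ``align_segment`` are Kabsch-fit
    onto the corresponding reference atoms; the resulting transform is applied
    to the donor's receptor chain(s). Returns (transformed donor copy,
    transform, fit RMSD in Å). Fewer than ``min_pairs`` paired Cα atoms is an
    error (unreliable fit).
    """
    ref_chain = reference_model.chain(reference_roles.chain_for("mhc_heavy"))
    don_chain = donor_model.chain(donor_roles.chain_for("mhc_heavy"))
    lo, hi = reference_roles.segment("mhc_heavy", align_segment)

    corr = map_residues(ref_chain, don_chain, mode=mapping_mode)
    ref_by_id = {r.id: r for r in ref_chain}
    don_by_id = {r.id: r for r in don_chain}
    ref_pts, don_pts = [], []
    for ref_id, don_id in corr.pairs:
        if not (lo <= ref_id[1] <= hi):
            continue
        ra, da = ref_by_id[ref_id], don_by_id[don_id]
        if ra.has_atom("CA") and da.has_atom("CA"):
            ref_pts.append(ra.atom("CA").position)
            don_pts.append(da.atom("CA").position)
    if len(ref_pts) < min_pairs:
        raise ValueError(
            f"only {len(ref_pts)} paired Cα atoms in segment {align_segment!r} "
            f"(need ≥ {min_pairs}); fit would be unreliable"
        )
    transform, fit_rmsd = kabsch_superpose(np.array(ref_pts), np.array(don_pts))

    moved = donor_model.copy()
    for _, residues in moved.chains:
        for res in residues:
            for atom in res.atoms:
                atom.position = transform.apply(atom.position)
    return moved, transform, fit_rmsd


def clash_scan(
    probe_atoms: Sequence[tuple[Residue, "object"]],
    target_atoms: Sequence[tuple[Residue, "object"]],
    radius_set: RadiusSet | None = None,
    overlap_threshold: float = 0.4,
    probe_segments: Mapping[str, tuple[int, int]] | None = None,
    target_segments: Mapping[str, tuple[int, int]] | None = None,
) -> ClashReport:
    """Count van der Waals overlaps between two heavy-atom sets.

    A pair clashes iff distance < r_i + r_j − overlap_threshold (the 0.4 Å
    default is the usual "clash" convention; 1.5 Å flags severe overlap).
    Counts are binned by (probe segment, target segment) when segment ranges
    (inclusive residue-number ranges) are given; atoms outside any named
    segment fall in the "other" bin.
    """
    rs = radius_set or RadiusSet()
    if not probe_atoms or not target_atoms:
        return ClashReport(None, None, [], 0, {}, overlap_threshold)
    from scipy.spatial import cKDTree

    pc = np.array([a.position for _, a in probe_atoms])
    tc = np.array([a.position for _, a in target_atoms])
    pr = rs.radii(a.element for _, a in probe_atoms)
    tr = rs.radii(a.element for _, a in target_atoms)

    def seg_of(res: Residue, segments) -> str:
        if segments:
            for name, (lo, hi) in segments.items():
                if lo <= res.seq_number <= hi:
                    return name
        return "other"

    max_cut = pr.max() + tr.max() - overlap_threshold
    pairs = cKDTree(pc).query_ball_tree(cKDTree(tc), max_cut)
    clash_pairs: list[tuple[int, int, float, float]] = []
    by_segment: dict[tuple[str, str], int] = {}
    for i, hits in enumerate(pairs):
        for j in hits:
            d = float(np.linalg.norm(pc[i] - tc[j]))
            limit = pr[i] + tr[j] - overlap_threshold
            if d < limit:
                overlap = float(pr[i] + tr[j] - d)
                clash_pairs.append((i, j, d, overlap))
                key = (
                    seg_of(probe_atoms[i][0], probe_segments),
                    seg_of(target_atoms[j][0], target_segments),
                )
                by_segment[key] = by_segment.get(key, 0) + 1
    return ClashReport(
        transform=None,
        fit_rmsd=None,
        clash_pairs=clash_pairs,
        total=len(clash_pairs),
        by_segment=by_segment,
        overlap_threshold=overlap_threshold,
    )


def peptide_contact_profile(
    model: StructureModel,
    roles: ChainRoleMap,
    binder_roles: Sequence[str] = ("ab_heavy", "ab_light"),
    cutoff: float = 4.0,
) -> list[dict]:
    """Per-position contact flags for the bound peptide (P1..Pn).

    For each peptide position, reports whether any heavy-atom contact to the
    binder exists within the cutoff, along with the partner residues.
    """
    pep_chain_id = roles.chain_for("peptide")
    peptide = model.chain(pep_chain_id)
    pep_atoms = select_atoms(model, roles, "peptide")
    present = [r for r in binder_roles if roles.chains_with_role(r)]
    if not present:
        raise KeyError(f"no binder chains among roles {tuple(binder_roles)}")
    binder_atoms: list = []
    for role in present:
        binder_atoms.extend(select_atoms(model, roles, role))
    table = find_contacts(pep_atoms, binder_atoms, cutoff=cutoff)
    partners: dict[tuple, set] = {}
    for rec in table.records:
        partners.setdefault(rec.residue_a, set()).add((rec.residue_b, rec.res_name_b))
    profile = []
    for pos, res in enumerate(peptide, start=1):
        plist = sorted(partners.get(res.id, set()))
        profile.append(
            {
                "position": pos,
                "residue": res.res_name,
                "seq_number": res.seq_number,
                "contacted": bool(plist),
                "partners": plist,
            }
        )
    return profile
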