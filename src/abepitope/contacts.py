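"""Heavy-atom interface contacts at a distance cutoff.

A contact is any inter-group heavy-atom pair within the cutoff (default
4.0 Å, the standard criterion for antibody/antigen contact tables). Contact
classification (hydrogen bond / salt bridge / nonbonded) is advisory metadata
layered on top of the pure distance criterion — deposited models carry no
hydrogens, so no angular hydrogen-bond geometry is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import Atom, Residue

__all__ = [
    "ContactRecord",
    "ContactTable",
    "find_contacts",
    "classify_contact",
    "reduce_closest",
    "contact_partners",
    "export_contact_map",
]

AtomEntry = tuple[Residue, Atom]

# side-chain atoms defining carboxylates and basic nitrogens for salt bridges
_ACIDIC = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_BASIC = {
    ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}


@dataclass(frozen=True)
class ContactRecord:
    """One inter-group atom pair within the cutoff."""

    residue_a: tuple  # (chain_id, seq_number, insertion_code)
    res_name_a: str
    atom_a: str
    residue_b: tuple
    res_name_b: str
    atom_b: str
    distance: float  # Å
    contact_class: str = "nonbonded"  # {hbond, salt_bridge, nonbonded}


@dataclass
class ContactTable:
    """Contacts at a stated cutoff, optionally reduced to closest-per-pair."""

    records: list[ContactRecord]
    cutoff: float
    reduction: str = "all"  # {"all", "closest_per_residue_pair"}

    def __len__(self) -> int:
        return len(self.records)

    def residue_pairs(self) -> set[tuple[tuple, tuple]]:
        return {(r.residue_a, r.residue_b) for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chain_a": r.residue_a[0],
                "resnum_a": r.residue_a[1],
                "icode_a": r.residue_a[2],
                "resname_a": r.res_name_a,
                "atom_a": r.atom_a,
                "chain_b": r.residue_b[0],
                "resnum_b": r.residue_b[1],
                "icode_b": r.residue_b[2],
                "resname_b": r.res_name_b,
                "atom_b": r.atom_b,
                "distance_A": round(r.distance, 3),
                "class": r.contact_class,
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "chain_a", "resnum_a", "icode_a", "resname_a", "atom_a",
                "chain_b", "resnum_b", "icode_b", "resname_b", "atom_b",
                "distance_A", "class",
            ],
        )


def classify_contact(
    res_name_a: str, atom_a: str, element_a: str,
    res_name_b: str, atom_b: str, element_b: str,
    distance: float,
) -> str:
    """Advisory contact class from atom chemistry and distance.

    salt_bridge: carboxylate O (Asp/Glu) vs basic N (Lys/Arg/His) at ≤ 4.0 Å;
    hbond: both atoms N or O at ≤ 3.5 Å; otherwise nonbonded. Salt bridge
    takes precedence over hydrogen bond.
    """
    key_a, key_b = (res_name_a, atom_a), (res_name_b, atom_b)
    if distance <= 4.0 and (
        (key_a in _ACIDIC and key_b in _BASIC) or (key_b in _ACIDIC and key_a in _BASIC)
    ):
        return "salt_bridge"
    if distance <= 3.5 and element_a in ("N", "O") and element_b in ("N", "O"):
        return "hbond"
    return "nonbonded"


def find_contacts(
    group_a: Sequence[AtomEntry],
    group_b: Sequence[AtomEntry],
    cutoff: float = 4.0,
) -> ContactTable:
    """All inter-group heavy-atom pairs with distance ≤ cutoff.

    Uses a spatial grid (k-d tree); the result is identical to the all-pairs
    search. Empty groups yield an empty table.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not group_a or not group_b:
        return ContactTable([], cutoff)
    ca = np.array([a.position for _, a in group_a])
    cb = np.array([a.position for _, a in group_b])
    tree_b = cKDTree(cb)
    pairs = cKDTree(ca).query_ball_tree(tree_b, cutoff)
    records: list[ContactRecord] = []
    for i, hits in enumerate(pairs):
        res_a, atom_a = group_a[i]
        for j in sorted(hits):
            res_b, atom_b = group_b[j]
            d = float(np.linalg.norm(atom_a.position - atom_b.position))
            if d > cutoff:  # query_ball_tree is inclusive; keep explicit
                continue
            records.append(
                ContactRecord(
                    residue_a=res_a.id,
                    res_name_a=res_a.res_name,
                    atom_a=atom_a.name,
                    residue_b=res_b.id,
                    res_name_b=res_b.res_name,
                    atom_b=atom_b.name,
                    distance=d,
                    contact_class=classify_contact(
                        res_a.res_name, atom_a.name, atom_a.element,
                        res_b.res_name, atom_b.name, atom_b.element,
                        d,
                    ),
                )
            )
    return ContactTable(records, cutoff)


def reduce_closest(table: ContactTable) -> ContactTable:
    """Keep the single closest atom contact per residue pair.

    Ties are broken deterministically by the (atom_a, atom_b) name pair.
    """
    best: dict[tuple[tuple, tuple], ContactRecord] = {}
    for rec in table.records:
        key = (rec.residue_a, rec.residue_b)
        cur = best.get(key)
        if cur is None or (rec.distance, rec.atom_a, rec.atom_b) < (
            cur.distance, cur.atom_a, cur.atom_b
        ):
            best[key] = rec
    return ContactTable(
        records=list(best.values()),
        cutoff=table.cutoff,
        reduction="closest_per_residue_pair",
    )


def contact_partners(table: ContactTable, focal_residue: tuple) -> dict[tuple, int]:
    """Distinct partner residues of a focal residue, with atom-contact counts.

    The focal residue may appear on either side of the table. An absent focal
    residue yields an empty dict.
    """
    partners: dict[tuple, int] = {}
    for rec in table.records:
        if rec.residue_a == focal_residue:
            partners[rec.residue_b] = partners.get(rec.residue_b, 0) + 1
        elif rec.residue_b == focal_residue:
            partners[rec.residue_a] = partners.get(rec.residue_a, 0) + 1
    return partners


def export_contact_map(
    table: ContactTable,
    row_residues: Sequence[Residue] | None = None,
    col_residues: Sequence[Residue] | None = None,
) -> pd.DataFrame:
    """Residue-by-residue contact incidence matrix (rows: group A; cols: B).

    Cell values count atom contacts between the residue pair. Explicit row or
    column residue orders may be supplied (e.g. antigen residues in sequence
    order, antibody residues grouped by CDR loop); otherwise the orders are
    taken from the table.
    """

    def _label(rid: tuple, name: str) -> str:
        icode = rid[2] or ""
        return f"{rid[0]}:{name}{rid[1]}{icode}"

    names_a = {r.residue_a: r.res_name_a for r in table.records}
    names_b = {r.residue_b: r.res_name_b for r in table.records}
    if row_residues is not None:
        rows = [(_label(r.id, r.res_name)) for r in row_residues]
        row_index = {r.id: _label(r.id, r.res_name) for r in row_residues}
    else:
        ordered = sorted(names_a)
        rows = [_label(rid, names_a[rid]) for rid in ordered]
        row_index = {rid: _label(rid, names_a[rid]) for rid in ordered}
    if col_residues is not None:
        cols = [(_label(r.id, r.res_name)) for r in col_residues]
        col_index = {r.id: _label(r.id, r.res_name) for r in col_residues}
    else:
        ordered = sorted(names_b)
        cols = [_label(rid, names_b[rid]) for rid in ordered]
        col_index = {rid: _label(rid, names_b[rid]) for rid in ordered}

    matrix = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for rec in table.records:
        ra = row_index.get(rec.residue_a)
        cb = col_index.get(rec.residue_b)
        if ra is not None and cb is not None:
            matrix.loc[ra, cb] += 1
    return matrix
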