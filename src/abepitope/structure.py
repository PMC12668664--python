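"""Macromolecular coordinate model, PDB/mmCIF I/O, and chain-role assignment.

The hierarchy is deliberately small: a :class:`StructureModel` holds ordered
chains of :class:`Residue` objects, each an ordered list of :class:`Atom`.
Author residue numbering is the coordinate convention throughout the package,
because HLA epitope residues (K146, R145, ...) are cited by mature-protein
numbers in the structural literature.

Parsing and writing are delegated to :mod:`gemmi`; this module owns the
in-memory model, the altloc/water policies, and the semantic chain roles
(MHC heavy chain, β2-microglobulin, peptide, antibody heavy/light chain,
NK receptor) that every downstream analysis consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "ChainRoleMap",
    "RadiusSet",
    "STANDARD_AMINO_ACIDS",
    "ROLES",
    "ParseError",
    "EmptyStructureError",
    "AmbiguousRolesError",
    "parse_structure",
    "write_pdb",
    "count_protein_residues",
    "assign_roles",
    "select_atoms",
]

#: Three-letter codes of the 20 standard amino acids (protein-residue counting).
STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Semantic chain roles used across the package.
ROLES = ("mhc_heavy", "beta2m", "peptide", "ab_heavy", "ab_light", "receptor", "other")

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class ParseError(ValueError):
    """Raised when a coordinate file cannot be read."""


class EmptyStructureError(ParseError):
    """Raised when a coordinate file contains no ATOM records."""


class AmbiguousRolesError(ValueError):
    """Raised when heuristic role assignment cannot decide between chains."""


@dataclass
class Atom:
    """One atom: PDB atom name, normalized element, position in Å."""

    name: str
    element: str
    position: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        self.element = self.element.strip().capitalize()

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    """One residue addressed by (chain_id, author seq_number, insertion_code)."""

    chain_id: str
    seq_number: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def is_protein(self) -> bool:
        return self.res_name in STANDARD_AMINO_ACIDS

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.id} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class StructureModel:
    """A single coordinate model: ordered chains of residues."""

    id: str
    chains: list[tuple[str, list[Residue]]]
    model_number: int = 1

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("StructureModel needs at least one chain")

    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]

    def chain(self, chain_id: str) -> list[Residue]:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise KeyError(f"no chain {chain_id!r} in model {self.id}")

    def iter_residues(self) -> Iterator[Residue]:
        for _, residues in self.chains:
            yield from residues

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.iter_residues():
            for atom in res.atoms:
                yield res, atom

    def copy(self) -> "StructureModel":
        chains = [
            (
                cid,
                [
                    Residue(
                        r.chain_id,
                        r.seq_number,
                        r.res_name,
                        [replace(a, position=a.position.copy()) for a in r.atoms],
                        r.insertion_code,
                    )
                    for r in residues
                ],
            )
            for cid, residues in self.chains
        ]
        return StructureModel(self.id, chains, self.model_number)


# Default named segments on the MHC heavy chain (author/mature numbering).
# Three α2₁ helix definitions circulate in the structural literature for this
# epitope; all three are registered so reports can state which one was used.
DEFAULT_MHC_SEGMENTS: dict[str, tuple[int, int]] = {
    "alpha1_alpha2": (1, 180),
    "alpha2_1": (141, 155),
    "alpha2_1_ext": (131, 155),
    "md_fragment": (127, 158),
}


@dataclass
class ChainRoleMap:
    """Maps chain ids to semantic roles and names residue segments.

    ``segments`` keys are (role, segment_name); values are inclusive author
    residue-number ranges on that role's chain.
    """

    role_of: dict[str, str]
    segments: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, role in self.role_of.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for chain {cid!r}")

    def chains_with_role(self, role: str) -> list[str]:
        return [cid for cid, r in self.role_of.items() if r == role]

    def chain_for(self, role: str) -> str:
        hits = self.chains_with_role(role)
        if not hits:
            raise KeyError(f"no chain assigned role {role!r}")
        if len(hits) > 1:
            raise AmbiguousRolesError(f"role {role!r} assigned to several chains: {hits}")
        return hits[0]

    def segment(self, role: str, name: str) -> tuple[int, int]:
        try:
            return self.segments[(role, name)]
        except KeyError:
            raise KeyError(f"no segment {name!r} registered for role {role!r}") from None


@dataclass
class RadiusSet:
    """Van der Waals radii by element, plus the solvent probe radius.

    Defaults are Chothia-type values (C 1.70, N 1.55, O 1.52, S 1.80 Å) with a
    1.4 Å water probe. Unknown elements fall back to 1.70 Å with a warning
    unless ``strict`` is requested at lookup time.
    """

    lookup: dict[str, float] = field(
        default_factory=lambda: {
            "C": 1.70,
            "N": 1.55,
            "O": 1.52,
            "S": 1.80,
            "P": 1.80,
            "H": 1.20,
            "D": 1.20,
        }
    )
    probe_radius: float = 1.4
    default_radius: float = 1.70

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.lookup.values()) or self.default_radius <= 0:
            raise ValueError("van der Waals radii must be positive")

    def radius(self, element: str, strict: bool = False) -> float:
        el = element.strip().capitalize()
        if el in self.lookup:
            return self.lookup[el]
        if strict:
            raise KeyError(f"no van der Waals radius for element {element!r}")
        warnings.warn(
            f"no van der Waals radius for element {element!r}; using {self.default_radius} Å",
            stacklevel=2,
        )
        return self.default_radius

    def radii(self, elements: Iterable[str], strict: bool = False) -> np.ndarray:
        return np.array([self.radius(e, strict=strict) for e in elements], dtype=float)


# ---------------------------------------------------------------------------
# Parsing / writing


def _best_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # Highest occupancy wins; ties resolved toward altloc 'A' (lexicographic).
    return min(atoms, key=lambda a: (-a.occ, a.altloc or "A"))


def parse_structure(
    path: str | Path,
    format: str | None = None,
    *,
    keep_waters: bool = False,
) -> StructureModel:
    """Read the first model of a PDB or mmCIF file into a :class:`StructureModel`.

    HETATM records are retained with ``is_hetero`` set; waters are excluded by
    default. For alternate locations the highest-occupancy conformer is kept
    (ties resolved toward altloc 'A').

    Parameters
    ----------
    path : file path
    format : {"pdb", "mmcif"}, optional
        Detected from the extension when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown format {format!r} (expected 'pdb' or 'mmcif')")
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]

    chains: list[tuple[str, list[Residue]]] = []
    n_atoms = 0
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if not keep_waters and (res.name in _WATER_NAMES or res.is_water()):
                continue
            icode = res.seqid.icode.strip()
            is_het = res.het_flag == "H"
            # group alternate locations by atom name
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            atoms = []
            for name, group in by_name.items():
                g = _best_altloc(group)
                atoms.append(
                    Atom(
                        name=name,
                        element=g.element.name,
                        position=np.array([g.pos.x, g.pos.y, g.pos.z]),
                        occupancy=g.occ,
                        b_factor=g.b_iso,
                        altloc=(g.altloc or "").strip(),
                        is_hetero=is_het,
                    )
                )
            if atoms:
                residues.append(
                    Residue(chain.name, res.seqid.num, res.name, atoms, icode)
                )
                n_atoms += len(atoms)
        if residues:
            chains.append((chain.name, residues))

    if n_atoms == 0:
        raise EmptyStructureError(f"{path}: no ATOM records")
    return StructureModel(id=path.stem, chains=chains, model_number=1)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write standard fixed-column PDB records (coordinates to 3 decimals)."""
    for cid in model.chain_ids():
        if len(cid) > 1:
            raise ValueError(
                f"chain id {cid!r} does not fit the single-character PDB dialect; "
                "write mmCIF instead"
            )
    st = gemmi.Structure()
    st.name = model.id
    gm = gemmi.Model(model.model_number)
    for cid, residues in model.chains:
        gc = gemmi.Chain(cid)
        for res in residues:
            gr = gemmi.Residue()
            gr.name = res.res_name
            gr.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
            gr.het_flag = "H" if all(a.is_hetero for a in res.atoms) else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_factor
                ga.altloc = atom.altloc[:1] if atom.altloc else "\0"
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def count_protein_residues(model: StructureModel) -> int:
    """Number of residues whose name is one of the 20 standard amino acids."""
    return sum(1 for r in model.iter_residues() if r.is_protein)


# ---------------------------------------------------------------------------
# Role assignment


def assign_roles(
    model: StructureModel,
    hints: Mapping[str, str] | None = None,
    segments: Mapping[tuple[str, str], tuple[int, int]] | None = None,
) -> ChainRoleMap:
    """Assign semantic roles to chains, by explicit hints or by heuristic.

    Heuristic (protein-residue chain lengths): ≤ 15 → peptide; 95–105 → β2m;
    the longest chain spanning the MHC α1–α3 region (~275 residues) →
    mhc_heavy; of the remaining two chains, the longer → ab_heavy, the other
    → ab_light. Any rule matched by more than one chain raises
    :class:`AmbiguousRolesError` naming the candidates, so callers can pass
    explicit hints instead.
    """
    lengths = {
        cid: sum(1 for r in residues if r.is_protein) for cid, residues in model.chains
    }
    role_of: dict[str, str] = {}

    if hints:
        unknown = set(hints) - set(lengths)
        if unknown:
            raise KeyError(f"hinted chains not in model: {sorted(unknown)}")
        role_of.update({cid: role for cid, role in hints.items()})
        for cid, role in role_of.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for chain {cid!r}")
        for cid in lengths:
            role_of.setdefault(cid, "other")
    else:
        unassigned = dict(lengths)

        def take(role: str, candidates: list[str]) -> None:
            if len(candidates) > 1:
                raise AmbiguousRolesError(
                    f"role {role!r}: several candidate chains {sorted(candidates)} "
                    f"(lengths {[lengths[c] for c in sorted(candidates)]}); "
                    "pass explicit hints"
                )
            if candidates:
                role_of[candidates[0]] = role
                del unassigned[candidates[0]]

        take("peptide", [c for c, n in unassigned.items() if 0 < n <= 15])
        take("beta2m", [c for c, n in unassigned.items() if 95 <= n <= 105])
        mhc_candidates = [c for c, n in unassigned.items() if n >= 250]
        if mhc_candidates:
            longest = max(mhc_candidates, key=lambda c: lengths[c])
            if sum(1 for c in mhc_candidates if lengths[c] == lengths[longest]) > 1:
                raise AmbiguousRolesError(
                    f"role 'mhc_heavy': several chains of maximal length "
                    f"{lengths[longest]}; pass explicit hints"
                )
            role_of[longest] = "mhc_heavy"
            del unassigned[longest]
        remaining = sorted(unassigned, key=lambda c: (-lengths[c], c))
        if len(remaining) == 2:
            role_of[remaining[0]] = "ab_heavy"
            role_of[remaining[1]] = "ab_light"
        else:
            for cid in remaining:
                role_of[cid] = "other"

    seg: dict[tuple[str, str], tuple[int, int]] = {}
    if "mhc_heavy" in role_of.values():
        for name, rng in DEFAULT_MHC_SEGMENTS.items():
            seg[("mhc_heavy", name)] = rng
    if segments:
        seg.update({tuple(k): tuple(v) for k, v in segments.items()})
    return ChainRoleMap(role_of=role_of, segments=seg)


def select_atoms(
    model: StructureModel,
    roles: ChainRoleMap,
    role: str,
    segment: str | None = None,
    heavy_only: bool = True,
    include_hetero: bool = False,
) -> list[tuple[Residue, Atom]]:
    """Atoms of all chains holding ``role``, optionally restricted to a segment.

    Returns (residue, atom) pairs in model order. ``heavy_only`` drops
    hydrogens/deuteriums; HETATM atoms are dropped unless ``include_hetero``.
    """
    chain_ids = roles.chains_with_role(role)
    if not chain_ids:
        raise KeyError(f"role {role!r} not present in role map")
    lo, hi = (None, None)
    if segment is not None:
        lo, hi = roles.segment(role, segment)
    out: list[tuple[Residue, Atom]] = []
    for cid in chain_ids:
        for res in model.chain(cid):
            if segment is not None and not (lo <= res.seq_number <= hi):
                continue
            for atom in res.atoms:
                if heavy_only and atom.is_hydrogen:
                    continue
                if atom.is_hetero and not include_hetero:
                    continue
                out.append((res, atom))
    return out


def coordinates(pairs: Sequence[tuple[Residue, Atom]]) -> np.ndarray:
    """Stack the positions of (residue, atom) pairs into an N×3 array."""
    if not pairs:
        return np.zeros((0, 3))
    return np.array([a.position for _, a in pairs])
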