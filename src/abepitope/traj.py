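"""Post-hoc MD-trajectory statistics: aligned RMSD series, P(d), and RMSF.

This module analyzes pre-computed trajectories (it is not a simulation
engine). Frames are Kabsch-aligned to a reference on a stated atom
selection; the per-frame backbone RMSD series is summarized as a normalized
conformational probability distribution P(d) with its mean ± SD, and
per-residue RMSF is computed about the mean structure with a two-pass
alignment protocol (align to frame 1, compute the mean, re-align to the
mean). The SD and all moments are population (ddof = 0) moments of the raw
series, never of the histogram.

Trajectory input formats are text only: multi-model PDB, and a plain
whitespace XYZ-per-frame dialect (blocks of "x y z" lines, one per selected
atom, frames separated by blank lines or ``FRAME`` header lines).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry
from .structure import StructureModel, parse_structure

__all__ = [
    "Trajectory",
    "RmsdSeries",
    "DistributionSummary",
    "RmsfProfile",
    "BACKBONE_ATOMS",
    "align_frames",
    "rmsd_series",
    "distribution",
    "rmsf",
    "read_multimodel_pdb",
    "read_xyz_frames",
    "write_xyz_frames",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Trajectory:
    """T × N × 3 coordinate stack with per-atom labels.

    ``labels`` aligns with the atom axis: (chain_id, seq_number, insertion
    code, res_name, atom_name).
    """

    coords: np.ndarray  # (T, N, 3), Å
    labels: list[tuple[str, int, str, str, str]]
    frame_interval: float | None = None  # metadata only (e.g. ns/frame)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be a (T, N, 3) array")
        if self.coords.shape[1] != len(self.labels):
            raise ValueError("labels must align with the atom axis")
        if self.coords.shape[0] < 1:
            raise ValueError("need at least one frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_indices(
        self,
        atom_names: tuple[str, ...] | None = BACKBONE_ATOMS,
        residue_range: tuple[int, int] | None = None,
        chain_id: str | None = None,
    ) -> np.ndarray:
        """Indices of atoms matching a simple name/residue/chain selection."""
        idx = []
        for i, (cid, num, _icode, _rn, aname) in enumerate(self.labels):
            if atom_names is not None and aname not in atom_names:
                continue
            if residue_range is not None and not (residue_range[0] <= num <= residue_range[1]):
                continue
            if chain_id is not None and cid != chain_id:
                continue
            idx.append(i)
        return np.array(idx, dtype=int)


@dataclass
class RmsdSeries:
    """Per-frame RMSD (Å) versus a stated reference over a stated selection."""

    values: np.ndarray
    reference: str
    selection: str
    alignment_selection: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("RMSD values must be ≥ 0")


@dataclass
class DistributionSummary:
    """Density-normalized histogram of an RMSD series with raw-series moments."""

    bin_edges: np.ndarray
    density: np.ndarray  # P(d); Σ P·Δd = 1
    mean: float  # Å, from the raw series
    sd: float  # Å, population SD of the raw series

    def normalization(self) -> float:
        return float(np.sum(self.density * np.diff(self.bin_edges)))


@dataclass
class RmsfProfile:
    """Per-residue RMSF (Å) over a stated selection."""

    residues: list[tuple[str, int, str]]  # (chain_id, seq_number, icode) in input order
    values: np.ndarray
    selection: str = "backbone"
    alignment: str = "two-pass mean structure"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("RMSF values must be ≥ 0")


def align_frames(
    traj: Trajectory,
    reference: np.ndarray | int = 0,
    selection: np.ndarray | None = None,
) -> Trajectory:
    """Kabsch-fit every frame to a reference on the selection; carry all atoms.

    ``reference`` is either a frame index or an explicit (N_sel, 3) reference
    coordinate array for the selected atoms. The selection must contain at
    least 3 atoms.
    """
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection, dtype=int)
    if len(sel) < 3:
        raise ValueError("alignment selection needs ≥ 3 atoms")
    if isinstance(reference, (int, np.integer)):
        ref = traj.coords[int(reference)][sel]
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (len(sel), 3):
            raise ValueError("reference must match the selection shape")
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        transform, _ = geometry.kabsch_superpose(ref, traj.coords[f][sel])
        out[f] = geometry.apply_transform(transform, traj.coords[f])
    return Trajectory(out, list(traj.labels), traj.frame_interval)


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray | int = 0,
    selection: np.ndarray | None = None,
    align_first: bool = True,
    align_selection: np.ndarray | None = None,
) -> RmsdSeries:
    """Per-frame RMSD over the selection versus a reference frame/coordinates."""
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection, dtype=int)
    if len(sel) == 0:
        raise ValueError("empty selection")
    work = traj
    if align_first:
        work = align_frames(traj, reference, align_selection if align_selection is not None else sel)
    if isinstance(reference, (int, np.integer)):
        ref = work.coords[int(reference)][sel]
    else:
        ref = np.asarray(reference, dtype=float)
    diffs = work.coords[:, sel, :] - ref[None, :, :]
    values = np.sqrt(np.mean(np.sum(diffs**2, axis=2), axis=1))
    return RmsdSeries(
        values=values,
        reference="frame" if isinstance(reference, (int, np.integer)) else "explicit",
        selection=f"{len(sel)} atoms",
        alignment_selection="same as selection" if align_first else "none",
    )


def distribution(series: RmsdSeries | np.ndarray, bins: int = 50) -> DistributionSummary:
    """Normalized P(d) histogram; mean and SD come from the raw series."""
    values = series.values if isinstance(series, RmsdSeries) else np.asarray(series, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 samples for a distribution summary")
    density, edges = np.histogram(values, bins=bins, density=True)
    return DistributionSummary(
        bin_edges=edges,
        density=density,
        mean=float(np.mean(values)),
        sd=float(np.std(values)),
    )


def rmsf(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    align_selection: np.ndarray | None = None,
) -> RmsfProfile:
    """Per-residue RMSF about the mean structure (two-pass alignment).

    Frames are aligned to frame 1 on ``align_selection``, the mean structure
    is computed, frames are re-aligned to the mean, and
    RMSF = sqrt(⟨|r − ⟨r⟩|²⟩) is averaged (as mean square fluctuation) over
    each residue's selected atoms.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection, dtype=int)
    if len(sel) == 0:
        raise ValueError("empty selection")
    align_sel = sel if align_selection is None else np.asarray(align_selection, dtype=int)

    pass1 = align_frames(traj, 0, align_sel)
    mean_ref = pass1.coords[:, align_sel, :].mean(axis=0)
    pass2 = align_frames(pass1, mean_ref, align_sel)

    coords = pass2.coords[:, sel, :]
    mean = coords.mean(axis=0)
    msf_atom = np.mean(np.sum((coords - mean[None]) ** 2, axis=2), axis=0)

    residues: list[tuple[str, int, str]] = []
    msf_by_res: dict[tuple[str, int, str], list[float]] = {}
    for k, i in enumerate(sel):
        cid, num, icode, _rn, _an = traj.labels[i]
        rid = (cid, num, icode)
        if rid not in msf_by_res:
            residues.append(rid)
            msf_by_res[rid] = []
        msf_by_res[rid].append(float(msf_atom[k]))
    values = np.array([np.sqrt(np.mean(msf_by_res[rid])) for rid in residues])
    return RmsfProfile(residues=residues, values=values)


# ---------------------------------------------------------------------------
# Trajectory I/O (text formats only)


def _labels_of(model: StructureModel) -> list[tuple[str, int, str, str, str]]:
    return [
        (res.chain_id, res.seq_number, res.insertion_code, res.res_name, atom.name)
        for res, atom in model.iter_atoms()
    ]


def trajectory_from_models(models: list[StructureModel]) -> Trajectory:
    """Stack structure models with identical atom layouts into a Trajectory."""
    if not models:
        raise ValueError("no models")
    labels = _labels_of(models[0])
    frames = []
    for m in models:
        if _labels_of(m) != labels:
            raise ValueError("all frames must share the same atoms in the same order")
        frames.append(np.array([a.position for _, a in m.iter_atoms()]))
    return Trajectory(np.stack(frames), labels)


def read_multimodel_pdb(path: str | Path) -> Trajectory:
    """Read every MODEL of a PDB file as one trajectory frame."""
    import gemmi

    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    labels: list[tuple[str, int, str, str, str]] | None = None
    frames = []
    for model in st:
        frame_labels = []
        coords = []
        for chain in model:
            for res in chain:
                for atom in res:
                    frame_labels.append(
                        (chain.name, res.seqid.num, res.seqid.icode.strip(),
                         res.name, atom.name)
                    )
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        if labels is None:
            labels = frame_labels
        elif frame_labels != labels:
            raise ValueError(f"{path}: models differ in atom content")
        frames.append(np.array(coords))
    return Trajectory(np.stack(frames), labels)


def read_xyz_frames(
    path: str | Path, labels: list[tuple[str, int, str, str, str]] | None = None
) -> Trajectory:
    """Read the plain XYZ-per-frame dialect.

    Frames are blocks of whitespace-separated ``x y z`` lines; blank lines or
    lines starting with ``FRAME`` separate frames; ``#`` lines are comments.
    When no labels are supplied, synthetic per-atom labels are generated
    (one pseudo-residue per atom, chain "X").
    """
    frames: list[list[list[float]]] = []
    current: list[list[float]] = []
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if not stripped or stripped.upper().startswith("FRAME"):
            if current:
                frames.append(current)
                current = []
            continue
        if stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != 3:
            raise ValueError(f"{path}: expected 'x y z', got {line!r}")
        current.append([float(p) for p in parts])
    if current:
        frames.append(current)
    if not frames:
        raise ValueError(f"{path}: no frames")
    coords = np.array(frames, dtype=float)
    if labels is None:
        labels = [("X", i + 1, "", "UNK", "CA") for i in range(coords.shape[1])]
    return Trajectory(coords, labels)


def write_xyz_frames(traj: Trajectory, path: str | Path) -> None:
    """Write the plain XYZ-per-frame dialect read by :func:`read_xyz_frames`."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"FRAME {f + 1}\n")
            for x, y, z in traj.coords[f]:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
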