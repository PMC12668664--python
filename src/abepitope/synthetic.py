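"""Synthetic structures, trajectories, and analytic oracles.

Generators here produce inputs with exactly the geometric/statistical
structure the analysis modules assume, so every stage of the pipeline is
testable without downloading deposited coordinates: ideal α-helices standing
in for the MHC-I α2₁ helix, toy antibody/antigen complexes with contacts
placed at designed distances, and harmonic-jitter trajectories with known
per-residue fluctuation amplitudes. The two-sphere solvent-accessible-area
closed form serves as an independent oracle for the Shrake–Rupley
implementation.

Each generator consumes a single seeded RNG, and records its seed in the
returned object's metadata where applicable, so fixtures are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import Atom, ChainRoleMap, Residue, StructureModel, DEFAULT_MHC_SEGMENTS
from .traj import Trajectory, trajectory_from_models

__all__ = [
    "HelixSpec",
    "ProbePlacement",
    "ToyComplexSpec",
    "JitterSpec",
    "build_ideal_helix",
    "build_toy_complex",
    "gen_jitter_trajectory",
    "two_sphere_sasa",
]


@dataclass
class HelixSpec:
    """Ideal α-helix: canonical rise 1.5 Å, twist 100°, Cα radius 2.3 Å."""

    sequence: str = "A" * 15
    rise: float = 1.5  # Å per residue
    twist: float = 100.0  # degrees per residue
    ca_radius: float = 2.3  # Å
    start_number: int = 1
    chain_id: str = "A"
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    with_backbone: bool = False

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if not self.sequence:
            raise ValueError("sequence must be non-empty")


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def build_ideal_helix(spec: HelixSpec) -> StructureModel:
    """Cα-trace ideal helix (optionally with an alanine-like pseudo-backbone).

    Cα of residue k sits at (r·cos kθ, r·sin kθ, k·rise) + origin. With the
    canonical parameters the consecutive Cα–Cα distance is ≈ 3.8 Å. The
    pseudo-backbone places N, C, O, CB at fixed small offsets from Cα —
    geometrically plausible, not Ramachandran-valid.
    """
    theta = np.deg2rad(spec.twist)
    residues = []
    # fixed local offsets for the pseudo-backbone (Å), alanine-like
    offsets = {
        "N": np.array([-0.8, -0.9, -0.6]),
        "C": np.array([0.9, 0.7, 0.6]),
        "O": np.array([1.4, 1.5, 0.9]),
        "CB": np.array([0.6, -1.2, 0.8]),
    }
    for k, letter in enumerate(spec.sequence):
        ang = k * theta
        ca = spec.origin + np.array(
            [spec.ca_radius * np.cos(ang), spec.ca_radius * np.sin(ang), k * spec.rise]
        )
        res_name = _ONE_TO_THREE.get(letter.upper(), "ALA")
        atoms = [Atom("CA", "C", ca)]
        if spec.with_backbone:
            for name, off in offsets.items():
                element = name[0]
                atoms.append(Atom(name, element, ca + off))
            # keep PDB-conventional atom order: N, CA, C, O, CB
            order = {"N": 0, "CA": 1, "C": 2, "O": 3, "CB": 4}
            atoms.sort(key=lambda a: order.get(a.name, 9))
        residues.append(
            Residue(spec.chain_id, spec.start_number + k, res_name, atoms)
        )
    return StructureModel(id="ideal_helix", chains=[(spec.chain_id, residues)])


@dataclass
class ProbePlacement:
    """One probe residue placed at an exact distance from a target atom."""

    target_residue_number: int
    direction: np.ndarray  # offset direction from the target atom
    distance: float  # Å, probe contact atom to target atom
    probe_res_name: str = "ALA"
    probe_atom: str = "CB"  # the probe-side atom placed at the exact distance
    target_atom: str = "CA"

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("placement distance must be positive")
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if norm == 0:
            raise ValueError("direction must be nonzero")
        self.direction = self.direction / norm


@dataclass
class ToyComplexSpec:
    """Antigen helix plus designed probe residues at exact contact distances."""

    antigen: HelixSpec = field(default_factory=lambda: HelixSpec("A" * 15, with_backbone=True))
    placements: list[ProbePlacement] = field(default_factory=list)
    antigen_role: str = "mhc_heavy"
    probe_chain_id: str = "P"
    probe_role: str = "ab_heavy"


def build_toy_complex(spec: ToyComplexSpec) -> tuple[StructureModel, ChainRoleMap, list[dict]]:
    """Build a toy antigen/probe complex with a derivable contact ground truth.

    Each placement puts one single-atom-of-interest probe residue with its
    contact atom exactly ``distance`` Å from the chosen target atom along
    ``direction``. Returns (model, role map, ground truth), where the ground
    truth lists each designed pair with its exact distance — the expected
    contact table at any cutoff follows directly.
    """
    helix = build_ideal_helix(spec.antigen)
    antigen_chain = helix.chains[0][1]
    by_number = {r.seq_number: r for r in antigen_chain}

    probe_residues = []
    truth = []
    for k, pl in enumerate(spec.placements):
        target = by_number.get(pl.target_residue_number)
        if target is None:
            raise KeyError(f"antigen has no residue {pl.target_residue_number}")
        anchor = target.atom(pl.target_atom).position
        pos = anchor + pl.direction * pl.distance
        element = pl.probe_atom[0]
        probe_residues.append(
            Residue(spec.probe_chain_id, k + 1, pl.probe_res_name,
                    [Atom(pl.probe_atom, element, pos)])
        )
        truth.append(
            {
                "antigen_residue": target.id,
                "probe_residue": (spec.probe_chain_id, k + 1, ""),
                "distance": pl.distance,
            }
        )
    chains = [(spec.antigen.chain_id, antigen_chain)]
    if probe_residues:
        chains.append((spec.probe_chain_id, probe_residues))
    model = StructureModel(id="toy_complex", chains=chains)
    role_of = {spec.antigen.chain_id: spec.antigen_role}
    if probe_residues:
        role_of[spec.probe_chain_id] = spec.probe_role
    segments = {}
    if spec.antigen_role == "mhc_heavy":
        segments = {("mhc_heavy", k): v for k, v in DEFAULT_MHC_SEGMENTS.items()}
    roles = ChainRoleMap(role_of=role_of, segments=segments)
    return model, roles, truth


@dataclass
class JitterSpec:
    """Gaussian-jitter trajectory around a reference model."""

    reference: StructureModel
    sigma_per_residue: dict[tuple, float] | float = 0.1  # Å per coordinate
    n_frames: int = 100
    seed: int = 0
    rigid_motion: bool = False  # add a random global rigid motion per frame

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        sig = self.sigma_per_residue
        if isinstance(sig, (int, float)):
            if sig < 0:
                raise ValueError("sigma must be ≥ 0")
        elif any(s < 0 for s in sig.values()):
            raise ValueError("sigma must be ≥ 0")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # uniform random proper rotation via QR of a Gaussian matrix
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def gen_jitter_trajectory(spec: JitterSpec) -> Trajectory:
    """Reference + per-frame isotropic Gaussian displacement, seeded.

    Residue i's atoms get independent Gaussian jitter of per-coordinate SD
    σ_i, so its expected RMSF is σ_i·√3. An optional random global rigid
    motion per frame exercises trajectory alignment.
    """
    # independent child streams so the jitter draw is identical whether or
    # not the rigid-motion flag is set
    jitter_rng, rigid_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(2)
    )
    ref = spec.reference
    labels = [
        (res.chain_id, res.seq_number, res.insertion_code, res.res_name, atom.name)
        for res, atom in ref.iter_atoms()
    ]
    base = np.array([atom.position for _, atom in ref.iter_atoms()])
    if isinstance(spec.sigma_per_residue, dict):
        sigma = np.array(
            [spec.sigma_per_residue.get(res.id, 0.0) for res, _ in ref.iter_atoms()]
        )
    else:
        sigma = np.full(len(labels), float(spec.sigma_per_residue))

    frames = np.empty((spec.n_frames, len(labels), 3))
    for f in range(spec.n_frames):
        jitter = jitter_rng.normal(size=(len(labels), 3)) * sigma[:, None]
        frame = base + jitter
        if spec.rigid_motion:
            R = _random_rotation(rigid_rng)
            t = rigid_rng.uniform(-20, 20, size=3)
            frame = (R @ frame.T).T + t
        frames[f] = frame
    return Trajectory(frames, labels)


def two_sphere_sasa(
    r1: float, r2: float, d: float, probe: float = 1.4
) -> tuple[float, float]:
    """Exact accessible areas (Å²) of two spheres of vdW radii r1, r2 at
    center distance d, probed by a solvent sphere of radius ``probe``.

    Each accessible area is the full expanded-sphere area 4π(rᵢ+probe)² minus
    the spherical cap occluded by the other expanded sphere. When the
    expanded spheres do not intersect, both areas are full; when one expanded
    sphere is engulfed by the other, its area is 0 and the larger sphere is
    fully accessible.
    """
    if r1 <= 0 or r2 <= 0 or d <= 0:
        raise ValueError("radii and distance must be positive")
    R1, R2 = r1 + probe, r2 + probe

    if d >= R1 + R2:
        return 4 * np.pi * R1**2, 4 * np.pi * R2**2
    if d <= abs(R1 - R2):
        # engulfed: smaller expanded sphere entirely inside the larger
        if R1 >= R2:
            return 4 * np.pi * R1**2, 0.0
        return 0.0, 4 * np.pi * R2**2

    # spherical-cap heights from the two-sphere intersection plane
    h1 = R1 - (d**2 + R1**2 - R2**2) / (2 * d)
    h2 = R2 - (d**2 + R2**2 - R1**2) / (2 * d)
    area1 = 4 * np.pi * R1**2 - 2 * np.pi * R1 * h1
    area2 = 4 * np.pi * R2**2 - 2 * np.pi * R2 * h2
    return float(area1), float(area2)
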