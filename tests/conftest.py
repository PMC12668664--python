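import numpy as np
import pytest

from abepitope.structure import Atom, ChainRoleMap, Residue, StructureModel
from abepitope.synthetic import (
    HelixSpec,
    ProbePlacement,
    ToyComplexSpec,
    build_ideal_helix,
    build_toy_complex,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_complex():
    """Antigen helix + three probes at designed distances 3.5 / 3.9 / 4.1 Å."""
    spec = ToyComplexSpec(
        antigen=HelixSpec("A" * 15, start_number=141, with_backbone=False),
        placements=[
            ProbePlacement(145, [1.0, 0.3, 0.0], 3.5),
            ProbePlacement(149, [0.2, 1.0, 0.1], 3.9),
            ProbePlacement(153, [-0.5, 1.0, 0.3], 4.1),
        ],
    )
    return build_toy_complex(spec)


def _poly_ala_chain(chain_id: str, n: int, origin, start_number: int = 1):
    helix = build_ideal_helix(
        HelixSpec("A" * n, chain_id=chain_id, start_number=start_number,
                  origin=np.asarray(origin, dtype=float), with_backbone=True)
    )
    return helix.chains[0][1]


@pytest.fixture
def five_chain_model():
    """Synthetic complex with the designed chain lengths 275/99/9/220/214."""
    chains = [
        ("A", _poly_ala_chain("A", 275, [0, 0, 0])),
        ("B", _poly_ala_chain("B", 99, [40, 0, 0])),
        ("C", _poly_ala_chain("C", 9, [80, 0, 0])),
        ("H", _poly_ala_chain("H", 220, [120, 0, 0])),
        ("L", _poly_ala_chain("L", 214, [160, 0, 0])),
    ]
    return StructureModel(id="five_chain", chains=chains)


def make_atom(name, element, pos, **kw):
    return Atom(name, element, np.asarray(pos, dtype=float), **kw)


def single_atom_residues(positions, elements=None, chain_id="X", res_name="ALA",
                         atom_name="CA"):
    """One single-atom residue per position — handy for geometric fixtures."""
    elements = elements or ["C"] * len(positions)
    return [
        Residue(chain_id, i + 1, res_name, [make_atom(atom_name, el, p)])
        for i, (p, el) in enumerate(zip(positions, elements))
    ]


def atom_entries(residues):
    return [(r, a) for r in residues for a in r.atoms]
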