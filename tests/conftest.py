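import math

import numpy as np
import pytest

from ffcondense.assignment import assign_direct
from ffcondense.energy import EngineConfig
from ffcondense.fixtures import (
    make_toy_molecule,
    nonbonded_for,
    perturb_conformer,
    records_for_molecule,
)
from ffcondense.topology import Atom, Conformer, MoleculeTopology, enumerate_internals


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def carbon_chain(n: int, ff_class: str = "I", perturb: float = 0.0, seed: int = 0):
    """United-atom n-carbon chain (types all 1), fully parametrized from the
    fixture tables; planar zigzag geometry, optionally perturbed."""
    th = math.radians(68.0)
    coords = [[0.0, 0.0, 0.0]]
    direction = 0
    for _ in range(n - 1):
        ang = th if direction else 0.0
        last = coords[-1]
        coords.append([last[0] + 1.53 * math.cos(ang), last[1] + 1.53 * math.sin(ang), 0.0])
        direction ^= 1
    mol = MoleculeTopology(
        [Atom("C", 0, 1) for _ in range(n)],
        [(i, i + 1, 1) for i in range(n - 1)],
        name=f"chain{n}",
    )
    conf = Conformer(np.array(coords))
    if perturb > 0:
        conf = perturb_conformer(conf, perturb, seed)
    internals = enumerate_internals(mol)
    ps, _ = assign_direct(
        mol,
        internals,
        list(records_for_molecule(mol, internals, ff_class)),
        nonbonded_for(mol, ff_class),
        EngineConfig.for_class(ff_class),
    )
    return mol, conf, internals, ps


@pytest.fixture
def toy():
    def _toy(kind: str, ff_class: str = "I"):
        mol, conf, ps = make_toy_molecule(kind, ff_class)
        return mol, conf, enumerate_internals(mol), ps

    return _toy
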