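"""Synthetic data with known ground truth.

This module stands in for the upstream machine-learning force field and the
quantum-chemistry corpus: it provides small, fully parametrized toy
molecules, streams of per-molecule parameter records with Normal noise
around type-keyed true values, and perturbed conformers for optimization
starts and mock reference minima.

The mini-typer covers the C/H/N/O subset with MMFF94-flavoured integer ids
(alkyl C = 1, trigonal C = 2, H on C = 5, divalent O = 6, trigonal N = 8,
H on O = 21, H on N = 23); it is a fixture convenience, not a chemical
perception model.  Every stochastic operation takes an explicit seed; there
is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .assignment import NonbondedParams, PARAM_UNITS, assign_direct
from .condensation import InteractionKey, ParameterRecord, canonical_type_tuple
from .energy import EngineConfig, ParameterSet
from .errors import ConfigurationError
from .topology import (
    Atom,
    Conformer,
    InternalCoordinateIndex,
    MoleculeTopology,
    enumerate_internals,
)

__all__ = [
    "mini_typer",
    "make_toy_molecule",
    "records_for_molecule",
    "nonbonded_for",
    "SyntheticCorpusSpec",
    "synth_parameter_records",
    "corpus_spec_for_kinds",
    "perturb_conformer",
    "TOY_KINDS",
    "TRUE_TABLE_I",
    "TRUE_TABLE_II",
]

TOY_KINDS = ("diatomic", "water_like", "ethane", "butane", "trigonal_center")

_TYPE_BY_ELEMENT = {"C": 1, "O": 6, "N": 8}
_H_TYPE_BY_NEIGHBOR = {"C": 5, "O": 21, "N": 23}


def mini_typer(mol: MoleculeTopology) -> MoleculeTopology:
    """Assign fixture atom-type ids to a C/H/N/O molecule."""
    nb = mol.neighbors()
    ids = []
    for i, a in enumerate(mol.atoms):
        if a.element == "H":
            if not nb[i]:
                raise ConfigurationError(f"isolated hydrogen at index {i}")
            heavy = mol.atoms[nb[i][0]].element
            ids.append(_H_TYPE_BY_NEIGHBOR.get(heavy, 5))
        elif a.element == "C":
            ids.append(2 if len(nb[i]) == 3 else 1)
        elif a.element in _TYPE_BY_ELEMENT:
            ids.append(_TYPE_BY_ELEMENT[a.element])
        else:
            raise ConfigurationError(f"mini-typer covers C/H/N/O only, got {a.element}")
    return mol.with_types(ids)


# ---------------------------------------------------------------------------
# type-keyed ground-truth parameter tables (internal units)
#
# Values are keyed by canonical atom-type tuples so that interactions sharing
# a key share true values exactly; magnitudes follow common small-molecule
# force-field scales (bond k ~ 2000-4500 kJ/mol/A^2, angle k ~ 300-500
# kJ/mol/rad^2, torsion barriers of a few kJ/mol).

TRUE_TABLE_I: dict[tuple[str, tuple[int, ...]], dict[str, float]] = {
    ("bond", (1, 1)): {"k_r": 2000.0, "r0": 1.53},
    ("bond", (1, 5)): {"k_r": 2900.0, "r0": 1.09},
    ("bond", (6, 21)): {"k_r": 4500.0, "r0": 0.96},
    ("bond", (8, 23)): {"k_r": 4000.0, "r0": 1.01},
    ("angle", (1, 1, 1)): {"k_theta": 500.0, "theta0": 1.9548},
    ("angle", (1, 1, 5)): {"k_theta": 400.0, "theta0": 1.9111},
    ("angle", (5, 1, 5)): {"k_theta": 350.0, "theta0": 1.8815},
    ("angle", (21, 6, 21)): {"k_theta": 380.0, "theta0": 1.8239},
    ("angle", (23, 8, 23)): {"k_theta": 300.0, "theta0": 2.0944},
    ("proper", (1, 1, 1, 1)): {"phi0": 0.0, "k_phi_3": 2.5},
    ("proper", (5, 1, 1, 5)): {"phi0": 0.0, "k_phi_3": 1.2},
    ("proper", (1, 1, 1, 5)): {"phi0": 0.0, "k_phi_3": 1.5},
    ("improper", (8, 23, 23, 23)): {"k_oop": 50.0},
}


def _cls2_angle(k_theta, theta0, r1, r2):
    return {
        "k_theta": k_theta,
        "theta0": theta0,
        "cb": -0.4,
        "k_sb_ijk": 25.0,
        "k_sb_kji": 25.0,
        "r_ij0": r1,
        "r_jk0": r2,
    }


TRUE_TABLE_II: dict[tuple[str, tuple[int, ...]], dict[str, float]] = {
    ("bond", (1, 1)): {"k_r": 2000.0, "r0": 1.53, "cs": -2.0},
    ("bond", (1, 5)): {"k_r": 2900.0, "r0": 1.09, "cs": -2.0},
    ("bond", (6, 21)): {"k_r": 4500.0, "r0": 0.96, "cs": -2.0},
    ("bond", (8, 23)): {"k_r": 4000.0, "r0": 1.01, "cs": -2.0},
    ("angle", (1, 1, 1)): _cls2_angle(500.0, 1.9548, 1.53, 1.53),
    ("angle", (1, 1, 5)): _cls2_angle(400.0, 1.9111, 1.53, 1.09),
    ("angle", (5, 1, 5)): _cls2_angle(350.0, 1.8815, 1.09, 1.09),
    ("angle", (21, 6, 21)): _cls2_angle(380.0, 1.8239, 0.96, 0.96),
    ("angle", (23, 8, 23)): _cls2_angle(300.0, 2.0944, 1.01, 1.01),
    ("proper", (1, 1, 1, 1)): {"phi0": 0.0, "k1": 0.8, "k2": 0.5, "k3": 2.0},
    ("proper", (5, 1, 1, 5)): {"phi0": 0.0, "k1": 0.0, "k2": 0.0, "k3": 1.2},
    ("proper", (1, 1, 1, 5)): {"phi0": 0.0, "k1": 0.0, "k2": 0.0, "k3": 1.5},
    ("improper", (8, 23, 23, 23)): {"k_oop": 50.0},
}

# per-element non-bonded parameters (fixture values on OpenFF/MMFF94 scales)
_LJ_SIGMA = {"C": 3.40, "H": 2.60, "O": 3.12, "N": 3.25}
_LJ_EPSILON = {"C": 0.45, "H": 0.07, "O": 0.65, "N": 0.70}
_B147_RSTAR = {"C": 3.85, "H": 3.00, "O": 3.45, "N": 3.60}
_B147_EPS = {"C": 0.30, "H": 0.10, "O": 0.40, "N": 0.35}
_CHARGES = {
    "diatomic": [0.0, 0.0],
    "water_like": [-0.8, 0.4, 0.4],
    "ethane": [-0.18, -0.18, 0.06, 0.06, 0.06, 0.06, 0.06, 0.06],
    "butane": [0.0, 0.0, 0.0, 0.0],
    "trigonal_center": [-0.9, 0.3, 0.3, 0.3],
}


def nonbonded_for(mol: MoleculeTopology, ff_class: str, charges=None) -> NonbondedParams:
    """Per-atom non-bonded parameters from the fixture element tables."""
    els = [a.element for a in mol.atoms]
    nb = NonbondedParams(
        charges=np.zeros(len(els)) if charges is None else np.asarray(charges, dtype=float)
    )
    if ff_class == "I":
        nb.sigma = np.array([_LJ_SIGMA[e] for e in els])
        nb.epsilon = np.array([_LJ_EPSILON[e] for e in els])
    else:
        nb.rstar = np.array([_B147_RSTAR[e] for e in els])
        nb.eps = np.array([_B147_EPS[e] for e in els])
    return nb


# ---------------------------------------------------------------------------
# toy geometries


def _geometry(kind: str) -> tuple[list[Atom], list[tuple[int, int, int]], np.ndarray]:
    A = Atom
    if kind == "diatomic":
        atoms = [A("C"), A("C")]
        bonds = [(0, 1, 1)]
        coords = [[0.0, 0.0, 0.0], [0.0, 0.0, 1.53]]
    elif kind == "water_like":
        th = 1.8239  # 104.5 deg
        atoms = [A("O"), A("H"), A("H")]
        bonds = [(0, 1, 1), (0, 2, 1)]
        coords = [
            [0.0, 0.0, 0.0],
            [0.96, 0.0, 0.0],
            [0.96 * math.cos(th), 0.96 * math.sin(th), 0.0],
        ]
    elif kind == "ethane":
        atoms = [A("C"), A("C")] + [A("H")] * 6
        bonds = [(0, 1, 1)] + [(0, h, 1) for h in (2, 3, 4)] + [(1, h, 1) for h in (5, 6, 7)]
        ct = -1.0 / 3.0  # cos(109.47 deg)
        st = math.sqrt(1.0 - ct * ct)
        coords = [[0.0, 0.0, 0.0], [1.53, 0.0, 0.0]]
        for az in (90.0, 210.0, 330.0):  # staggered
            a = math.radians(az)
            coords.append([1.09 * ct, 1.09 * st * math.cos(a), 1.09 * st * math.sin(a)])
        for az in (30.0, 150.0, 270.0):
            a = math.radians(az)
            coords.append([1.53 - 1.09 * ct, 1.09 * st * math.cos(a), 1.09 * st * math.sin(a)])
    elif kind == "butane":
        # united-atom 4-carbon chain, planar anti (dihedral = pi)
        th = math.radians(68.0)  # pi - 112 deg
        atoms = [A("C")] * 4
        bonds = [(0, 1, 1), (1, 2, 1), (2, 3, 1)]
        c2 = [1.53 + 1.53 * math.cos(th), 1.53 * math.sin(th), 0.0]
        coords = [
            [0.0, 0.0, 0.0],
            [1.53, 0.0, 0.0],
            c2,
            [c2[0] + 1.53, c2[1], c2[2]],
        ]
    elif kind == "trigonal_center":
        atoms = [A("N"), A("H"), A("H"), A("H")]
        bonds = [(0, 1, 1), (0, 2, 1), (0, 3, 1)]
        coords = [[0.0, 0.0, 0.0]]
        for az in (0.0, 120.0, 240.0):
            a = math.radians(az)
            coords.append([1.01 * math.cos(a), 1.01 * math.sin(a), 0.0])
    else:
        raise ConfigurationError(f"unknown toy molecule kind {kind!r}")
    return atoms, bonds, np.array(coords, dtype=float)


def records_for_molecule(
    mol: MoleculeTopology,
    internals: InternalCoordinateIndex,
    ff_class: str = "I",
    molecule_id: str | None = None,
    sigma: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """One ParameterRecord per (interaction key, parameter name) of ``mol``,
    drawn from the fixture ground-truth table with optional Normal noise.

    Records are emitted once per distinct key (as an upstream predictor
    would: one value per parameter per molecule), in canonical orientation.
    """
    if sigma > 0 and rng is None:
        raise ConfigurationError("sigma > 0 requires an rng")
    table = TRUE_TABLE_I if ff_class == "I" else TRUE_TABLE_II
    types = mol.atom_types()
    mol_id = molecule_id or mol.name
    seen: set[tuple[str, tuple[int, ...]]] = set()
    for category, tuples in (
        ("bond", internals.bonds),
        ("angle", internals.angles),
        ("proper", internals.propers),
        ("improper", internals.impropers),
    ):
        for t in tuples:
            tt = tuple(types[a] for a in t)
            ct, _ = canonical_type_tuple(category, tt)
            if (category, ct) in seen:
                continue
            seen.add((category, ct))
            true = table.get((category, ct))
            if true is None:
                continue  # unparametrized key: downstream drop policy applies
            for pname in sorted(true):
                val = true[pname]
                if sigma > 0:
                    val += sigma * float(rng.standard_normal())
                yield ParameterRecord(
                    molecule_id=mol_id,
                    category=category,
                    atom_type_tuple=ct,
                    parameter_name=pname,
                    value=val,
                    unit=PARAM_UNITS[pname],
                )


def make_toy_molecule(
    kind: str, ff_class: str = "I"
) -> tuple[MoleculeTopology, Conformer, ParameterSet]:
    """A fully typed, fully parametrized toy system.

    diatomic: 1 bond; water_like: 2 bonds, 1 angle; ethane: 7 bonds;
    butane (united-atom): 3 bonds, 2 angles, 1 three-fold proper torsion;
    trigonal_center: planar center with exactly 1 improper.
    """
    atoms, bonds, coords = _geometry(kind)
    mol = mini_typer(MoleculeTopology(atoms, bonds, name=kind))
    conf = Conformer(coords)
    internals = enumerate_internals(mol)
    records = list(records_for_molecule(mol, internals, ff_class))
    nb = nonbonded_for(mol, ff_class, charges=_CHARGES[kind])
    ps, _report = assign_direct(
        mol, internals, records, nb, EngineConfig.for_class(ff_class)
    )
    return mol, conf, ps


# ---------------------------------------------------------------------------
# synthetic corpora


@dataclass
class SyntheticCorpusSpec:
    """A corpus of per-molecule predictions: for every molecule and every
    key, each parameter value is drawn Normal(true value, sigma_key)."""

    true_params: dict[InteractionKey, dict[str, float]]
    sigma: float | dict[InteractionKey, float]
    n_molecules: int
    seed: int

    def sigma_for(self, key: InteractionKey) -> float:
        s = self.sigma if isinstance(self.sigma, float) else self.sigma.get(key, 0.0)
        if s < 0:
            raise ConfigurationError("sigma must be >= 0")
        return s


def corpus_spec_for_kinds(
    kinds,
    ff_class: str = "I",
    sigma: float = 0.0,
    n_molecules: int = 50,
    seed: int = 0,
) -> SyntheticCorpusSpec:
    """Corpus spec whose key space is the union of the fixture keys of the
    given toy-molecule kinds, with fixture true values."""
    true: dict[InteractionKey, dict[str, float]] = {}
    table = TRUE_TABLE_I if ff_class == "I" else TRUE_TABLE_II
    for kind in kinds:
        atoms, bonds, _ = _geometry(kind)
        mol = mini_typer(MoleculeTopology(atoms, bonds, name=kind))
        internals = enumerate_internals(mol)
        types = mol.atom_types()
        for category, tuples in (
            ("bond", internals.bonds),
            ("angle", internals.angles),
            ("proper", internals.propers),
            ("improper", internals.impropers),
        ):
            for t in tuples:
                ct, _r = canonical_type_tuple(category, tuple(types[a] for a in t))
                entry = table.get((category, ct))
                if entry is not None:
                    true[InteractionKey(category, ct)] = dict(entry)
    return SyntheticCorpusSpec(true, float(sigma), n_molecules, seed)


def synth_parameter_records(spec: SyntheticCorpusSpec):
    """Reproducible stream of noisy ParameterRecords over the spec's key
    space: one record per molecule, key and parameter name."""
    rng = np.random.default_rng(spec.seed)
    keys = sorted(spec.true_params)
    for m in range(spec.n_molecules):
        mol_id = f"synth-{m:05d}"
        for key in keys:
            s = spec.sigma_for(key)
            params = spec.true_params[key]
            for pname in sorted(params):
                val = params[pname] + (s * float(rng.standard_normal()) if s > 0 else 0.0)
                yield ParameterRecord(
                    molecule_id=mol_id,
                    category=key.category,
                    atom_type_tuple=key.types,
                    parameter_name=pname,
                    value=val,
                    unit=PARAM_UNITS[pname],
                )


def perturb_conformer(conf: Conformer, magnitude: float, seed: int) -> Conformer:
    """Seeded isotropic Gaussian displacement of every coordinate with
    standard deviation ``magnitude`` (Å); magnitude 0 is the identity."""
    if magnitude < 0:
        raise ConfigurationError("magnitude must be >= 0")
    if magnitude == 0:
        return conf.copy()
    rng = np.random.default_rng(seed)
    return Conformer(conf.coords + magnitude * rng.standard_normal(conf.coords.shape))
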