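"""Per-molecule parameter assignment from a condensation table.

Every enumerated interaction is keyed by its atoms' type ids (canonical
orientation) and filled from the table with a plain lookup.  There is no
step-down or wildcard fallback: an interaction whose key — or any required
parameter name under that key — is absent is *dropped*, i.e. recorded in the
AssignmentReport and excluded from the molecular energy entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .condensation import (
    CondensationTable,
    InteractionKey,
    accumulate,
    condense,
    canonical_type_tuple,
)
from .energy import (
    ClassIAngleParam,
    ClassIBondParam,
    ClassITorsionParam,
    ClassIIBendParam,
    ClassIIStretchBendParam,
    ClassIIStretchParam,
    ClassIITorsionParam,
    DroppedInteraction,
    EngineConfig,
    OutOfPlaneParam,
    ParameterSet,
)
from .errors import AssignmentError
from .topology import InternalCoordinateIndex, MoleculeTopology

__all__ = [
    "NonbondedParams",
    "AssignmentReport",
    "assign_parameters",
    "assign_direct",
    "PARAM_UNITS",
    "TORSION_N_MAX",
]

#: internal-unit tags for every parameter name the record schema uses
PARAM_UNITS = {
    "k_r": "kJ/mol/A^2",
    "r0": "A",
    "cs": "1/A",
    "k_theta": "kJ/mol/rad^2",
    "theta0": "rad",
    "cb": "1/rad",
    "phi0": "rad",
    "k1": "kJ/mol",
    "k2": "kJ/mol",
    "k3": "kJ/mol",
    "k_oop": "kJ/mol/rad^2",
    "k_sb_ijk": "kJ/mol/A/rad",
    "k_sb_kji": "kJ/mol/A/rad",
    "r_ij0": "A",
    "r_jk0": "A",
}
TORSION_N_MAX = 6
PARAM_UNITS.update({f"k_phi_{n}": "kJ/mol" for n in range(1, TORSION_N_MAX + 1)})

_SB_NAMES = ("k_sb_ijk", "k_sb_kji", "r_ij0", "r_jk0")


@dataclass
class NonbondedParams:
    """Per-atom non-bonded parameters, passed through from their source
    (a transferable force field and/or the charge-equilibration module)."""

    charges: np.ndarray | None = None
    sigma: np.ndarray | None = None  # Class I LJ
    epsilon: np.ndarray | None = None
    eps: np.ndarray | None = None  # Class II buffered 14-7
    rstar: np.ndarray | None = None
    vdw_pairs: dict = field(default_factory=dict)


@dataclass
class AssignmentReport:
    """Bookkeeping: per category, assigned + dropped = enumerated."""

    n_assigned: dict[str, int]
    n_enumerated: dict[str, int]
    dropped_interactions: list[DroppedInteraction]
    table_source: str = ""

    def n_dropped(self, category: str | None = None) -> int:
        if category is None:
            return len(self.dropped_interactions)
        return sum(1 for d in self.dropped_interactions if d.category == category)


def _values(entry: dict | None, names: tuple[str, ...]) -> dict | None:
    """Extract required parameter values; None if the entry or any name is
    missing (partial entries count as fully missing)."""
    if entry is None:
        return None
    out = {}
    for name in names:
        cv = entry.get(name)
        if cv is None:
            return None
        out[name] = cv.value
    return out


def assign_parameters(
    mol: MoleculeTopology,
    internals: InternalCoordinateIndex,
    table: CondensationTable,
    nonbonded: NonbondedParams | None = None,
    config: EngineConfig | None = None,
) -> tuple[ParameterSet, AssignmentReport]:
    """Build a ParameterSet for ``mol`` by table lookup.

    Each interaction's atom-type tuple is canonicalized and looked up in
    ``table``; missing (or partially present) entries send the interaction
    to the dropped list.  Non-bonded per-atom values come from ``nonbonded``.
    """
    if not table.entries:
        raise AssignmentError("condensation table is empty")
    types = mol.atom_types()  # raises on untyped atoms
    if config is None:
        config = EngineConfig.for_class("I")
    ps = ParameterSet(config=config)
    if nonbonded is not None:
        ps.charges = nonbonded.charges
        ps.sigma = nonbonded.sigma
        ps.epsilon = nonbonded.epsilon
        ps.eps = nonbonded.eps
        ps.rstar = nonbonded.rstar
        ps.vdw_pairs = dict(nonbonded.vdw_pairs)

    cls2 = config.ff_class == "II"
    n_assigned = {c: 0 for c in ("bond", "angle", "proper", "improper")}

    def drop(category, t, key, reason="missing table entry"):
        ps.dropped.append(DroppedInteraction(category, tuple(t), str(key), reason))

    def lookup(category, type_tuple):
        ct, reversed_ = canonical_type_tuple(category, type_tuple)
        key = InteractionKey(category, ct)
        return key, table.get(key), reversed_

    for t in internals.bonds:
        key, entry, _ = lookup("bond", (types[t[0]], types[t[1]]))
        names = ("k_r", "r0", "cs") if cls2 else ("k_r", "r0")
        v = _values(entry, names)
        if v is None:
            drop("bond", t, key, "missing table entry" if entry is None else "partial entry")
            continue
        ps.bond[t] = ClassIIStretchParam(**v) if cls2 else ClassIBondParam(**v)
        n_assigned["bond"] += 1

    for t in internals.angles:
        i, j, k = t
        key, entry, reversed_ = lookup("angle", (types[i], types[j], types[k]))
        names = ("k_theta", "theta0", "cb") if cls2 else ("k_theta", "theta0")
        v = _values(entry, names)
        if v is None:
            drop("angle", t, key, "missing table entry" if entry is None else "partial entry")
            continue
        ps.angle[t] = ClassIIBendParam(**v) if cls2 else ClassIAngleParam(**v)
        n_assigned["angle"] += 1
        if cls2:
            sb = _values(entry, _SB_NAMES)
            if sb is not None:
                if reversed_:
                    sb["k_sb_ijk"], sb["k_sb_kji"] = sb["k_sb_kji"], sb["k_sb_ijk"]
                    sb["r_ij0"], sb["r_jk0"] = sb["r_jk0"], sb["r_ij0"]
                ps.stretch_bend[t] = ClassIIStretchBendParam(theta0=v["theta0"], **sb)

    for t in internals.propers:
        tt = tuple(types[a] for a in t)
        key, entry, _ = lookup("proper", tt)
        if cls2:
            v = _values(entry, ("k1", "k2", "k3", "phi0"))
            if v is None:
                drop("proper", t, key, "missing table entry" if entry is None else "partial entry")
                continue
            ps.torsion[t] = ClassIITorsionParam(**v)
        else:
            v = _values(entry, ("phi0",))
            ks = []
            if entry is not None:
                for n in range(1, TORSION_N_MAX + 1):
                    cv = entry.get(f"k_phi_{n}")
                    ks.append(0.0 if cv is None else cv.value)
                while ks and ks[-1] == 0.0:
                    ks.pop()
            if v is None or not ks:
                drop("proper", t, key, "missing table entry" if entry is None else "partial entry")
                continue
            ps.torsion[t] = ClassITorsionParam(k_phi=tuple(ks), phi0=v["phi0"])
        n_assigned["proper"] += 1

    for t in internals.impropers:
        tt = tuple(types[a] for a in t)
        key, entry, _ = lookup("improper", tt)
        v = _values(entry, ("k_oop",))
        if v is None:
            drop("improper", t, key, "missing table entry" if entry is None else "partial entry")
            continue
        ps.oop[t] = OutOfPlaneParam(**v)
        n_assigned["improper"] += 1

    report = AssignmentReport(
        n_assigned=n_assigned,
        n_enumerated={
            "bond": len(internals.bonds),
            "angle": len(internals.angles),
            "proper": len(internals.propers),
            "improper": len(internals.impropers),
        },
        dropped_interactions=list(ps.dropped),
        table_source=table.source,
    )
    return ps, report


def assign_direct(
    mol: MoleculeTopology,
    internals: InternalCoordinateIndex,
    records,
    nonbonded: NonbondedParams | None = None,
    config: EngineConfig | None = None,
) -> tuple[ParameterSet, AssignmentReport]:
    """Molecule-specific parametrization from this molecule's own predicted
    records, without a shared table — the runtime-inference baseline against
    which condensed tables are compared.

    Implemented as a single-molecule condensation (mean statistic): with one
    record per interaction parameter this is exact pass-through, and missing
    records fall under the same drop policy as table assignment.
    """
    table = condense(accumulate(records), statistic="mean", source=f"direct:{mol.name}")
    return assign_parameters(mol, internals, table, nonbonded, config)
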