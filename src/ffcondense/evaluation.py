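"""Force-field predictive accuracy: RMSD, torsion fingerprint deviation,
nearest-reference selection and cohort summaries.

A force-field-optimized conformer is compared against a set of reference
minima (e.g. QM-optimized geometries).  Because an optimizer may legitimately
relax into a neighbouring basin, the reference minimizing each metric is
selected independently per metric, and that minimal value is reported.

RMSD is computed over heavy atoms by default after optimal rigid
superposition (Kabsch, SVD with reflection correction); no graph-automorphism
symmetry correction is applied (a documented limitation for symmetric
molecules).  TFD is the weighted mean of normalized dihedral deviations over
rotatable-bond torsions, in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ModelError, StructureError
from .topology import Conformer, InternalCoordinateIndex, MoleculeTopology, measure

__all__ = [
    "ReferenceSet",
    "EvalResult",
    "kabsch_rmsd",
    "tfd",
    "rotatable_torsions",
    "select_reference",
    "evaluate_conformer",
    "summarize",
    "cumulative_density",
]


@dataclass
class ReferenceSet:
    """Reference conformers sharing one topology (e.g. PES local minima)."""

    conformers: list[Conformer]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.conformers:
            n = self.conformers[0].n_atoms
            if any(c.n_atoms != n for c in self.conformers):
                raise StructureError("reference conformers differ in atom count")
        if not self.labels:
            self.labels = [f"ref{i}" for i in range(len(self.conformers))]

    def __len__(self) -> int:
        return len(self.conformers)


@dataclass
class EvalResult:
    rmsd: float
    tfd: float
    selected_reference_rmsd: int
    selected_reference_tfd: int
    tfd_defined: bool = True


def kabsch_rmsd(X: Conformer, Y: Conformer, atom_mask: np.ndarray | None = None) -> float:
    """Minimal RMSD (Å) over rigid superpositions of Y onto X.

    Centroids are aligned, then the optimal rotation comes from the SVD of
    the covariance matrix with the usual determinant (reflection) correction.
    ``atom_mask`` selects the atoms entering both the fit and the deviation;
    fewer than 3 non-collinear atoms leave the rotation non-unique but the
    minimal RMSD is still well-defined.
    """
    if X.n_atoms != Y.n_atoms:
        raise StructureError(f"atom-count mismatch: {X.n_atoms} vs {Y.n_atoms}")
    x = X.coords
    y = Y.coords
    if atom_mask is not None:
        mask = np.asarray(atom_mask, dtype=bool)
        x = x[mask]
        y = y[mask]
    if x.shape[0] == 0:
        raise StructureError("atom mask selects no atoms")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    h = yc.T @ xc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])
    rot = u @ corr @ vt
    diff = yc @ rot - xc
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def heavy_atom_mask(mol: MoleculeTopology) -> np.ndarray:
    return np.array([a.element != "H" for a in mol.atoms], dtype=bool)


def rotatable_torsions(
    mol: MoleculeTopology, internals: InternalCoordinateIndex
) -> list[tuple[int, int, int, int]]:
    """One representative proper torsion per rotatable central bond.

    A bond is rotatable when it is not in a ring and neither end is terminal.
    The lexicographically smallest proper over each such bond is chosen, so
    the torsion list is deterministic.
    """
    g = mol.graph()
    ring_edges = set()
    for cycle in nx.cycle_basis(g):
        m = len(cycle)
        for idx in range(m):
            a, b = cycle[idx], cycle[(idx + 1) % m]
            ring_edges.add((min(a, b), max(a, b)))
    deg = dict(g.degree())
    chosen: dict[tuple[int, int], tuple[int, int, int, int]] = {}
    for t in sorted(internals.propers):
        j, k = t[1], t[2]
        bond = (min(j, k), max(j, k))
        if bond in ring_edges or deg[j] < 2 or deg[k] < 2:
            continue
        chosen.setdefault(bond, t)
    return [chosen[b] for b in sorted(chosen)]


def tfd(
    X: Conformer,
    Y: Conformer,
    torsions: list[tuple[int, int, int, int]],
    weights: np.ndarray | None = None,
) -> tuple[float, bool]:
    """Torsion fingerprint deviation between two conformers of one molecule.

    Each torsion contributes d_i = min(|dphi|, 2 pi - |dphi|) / pi in [0, 1];
    the result is the weighted mean sum(w_i d_i) / sum(w_i).  Weights default
    to uniform.  With no torsions the deviation is defined-empty: (0.0, False).
    """
    if not torsions:
        return 0.0, False
    if weights is None:
        w = np.ones(len(torsions))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(torsions),) or np.any(w < 0) or float(np.sum(w)) == 0.0:
            raise ModelError("weights must be non-negative, one per torsion, not all zero")
    devs = np.empty(len(torsions))
    for i, t in enumerate(torsions):
        dphi = abs(measure(X, "dihedral", t) - measure(Y, "dihedral", t))
        devs[i] = min(dphi, 2.0 * np.pi - dphi) / np.pi
    return float(np.sum(w * devs) / np.sum(w)), True


def select_reference(
    candidate: Conformer,
    refs: ReferenceSet,
    metric,
) -> tuple[int, float]:
    """Index and value of the reference minimizing ``metric(candidate, ref)``;
    ties break toward the lowest index."""
    if len(refs) == 0:
        raise ModelError("reference set is empty")
    values = [metric(candidate, r) for r in refs.conformers]
    idx = int(np.argmin(values))
    return idx, float(values[idx])


def evaluate_conformer(
    mol: MoleculeTopology,
    candidate: Conformer,
    refs: ReferenceSet,
    internals: InternalCoordinateIndex,
    heavy_only: bool = True,
) -> EvalResult:
    """Full per-molecule evaluation: nearest-basin RMSD and TFD, with the
    reference selected independently per metric."""
    mask = heavy_atom_mask(mol) if heavy_only else None
    torsions = rotatable_torsions(mol, internals)

    idx_r, val_r = select_reference(candidate, refs, lambda c, r: kabsch_rmsd(c, r, mask))
    if torsions:
        idx_t, val_t = select_reference(candidate, refs, lambda c, r: tfd(c, r, torsions)[0])
        defined = True
    else:
        idx_t, val_t, defined = idx_r, 0.0, False
    return EvalResult(
        rmsd=val_r,
        tfd=val_t,
        selected_reference_rmsd=idx_r,
        selected_reference_tfd=idx_t,
        tfd_defined=defined,
    )


def summarize(values) -> dict[str, float]:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ModelError("summarize needs at least one value")
    return {"mean": float(np.mean(arr)), "median": float(np.median(arr)), "n": int(arr.size)}


def cumulative_density(values, bin_edges) -> np.ndarray:
    """Empirical CDF evaluated at the right edge of each bin: the fraction of
    values <= edge.  Non-decreasing; reaches 1.0 once the last edge covers the
    sample; flat 0 for empty input."""
    edges = np.asarray(bin_edges, dtype=float)
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return np.zeros(edges.size)
    return np.array([float(np.mean(arr <= e)) for e in edges])
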