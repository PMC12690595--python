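"""Class I and Class II (MMFF94-style) molecular-mechanics energy engines.

Class I uses uncoupled harmonic bond/angle terms, a cosine-series proper
torsion, point-charge Coulomb and 12-6 Lennard-Jones non-bonded terms.
Class II adds anharmonic corrections (cubic-quartic stretch, cubic bend),
a stretch-bend cross term, a three-fold phased torsion, a harmonic Wilson
out-of-plane term at trigonal centers, buffered Coulomb and the buffered
14-7 van der Waals form.

Internal units: Angstrom, radian, kJ/mol, elementary charge.  All term
functions are scalar; :func:`total_energy` and :func:`analytic_gradient`
assemble them over an :class:`~ffcondense.topology.InternalCoordinateIndex`
with 1-2/1-3 exclusions and scaled 1-4 non-bonded pairs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigurationError, ConsistencyError, FormatError, ModelError
from .topology import Conformer, InternalCoordinateIndex

__all__ = [
    "ClassIBondParam",
    "ClassIAngleParam",
    "ClassITorsionParam",
    "ClassIIStretchParam",
    "ClassIIBendParam",
    "ClassIIStretchBendParam",
    "ClassIITorsionParam",
    "OutOfPlaneParam",
    "EngineConfig",
    "ParameterSet",
    "EnergyBreakdown",
    "u_bond_I",
    "u_angle_I",
    "u_torsion_I",
    "u_coulomb_I",
    "u_lj",
    "u_stretch_II",
    "u_bend_II",
    "u_stretch_bend",
    "u_torsion_II",
    "u_oop",
    "u_coulomb_II",
    "u_buf_14_7",
    "total_energy",
    "analytic_gradient",
    "nonbonded_pairs",
]

#: Coulomb constant 1/(4 pi eps0) in kJ mol^-1 Angstrom e^-2 (CODATA).
COULOMB_CONSTANT = 138.935458

_GUARD = 1e-8  # small-angle guard in gradient denominators (rad)


# ---------------------------------------------------------------------------
# parameter records


@dataclass(frozen=True)
class ClassIBondParam:
    k_r: float  # kJ mol^-1 A^-2
    r0: float  # A

    def __post_init__(self):
        if self.k_r < 0 or self.r0 <= 0:
            raise ConfigurationError(f"invalid bond parameters {self}")


@dataclass(frozen=True)
class ClassIAngleParam:
    k_theta: float  # kJ mol^-1 rad^-2
    theta0: float  # rad

    def __post_init__(self):
        if self.k_theta < 0 or not (0 < self.theta0 <= math.pi):
            raise ConfigurationError(f"invalid angle parameters {self}")


@dataclass(frozen=True)
class ClassITorsionParam:
    """Cosine series sum_n k_n [1 + cos n(phi - phi0)], n = 1..n_max."""

    k_phi: tuple[float, ...]  # kJ mol^-1, index n-1 holds k_n
    phi0: float = 0.0  # rad

    def __post_init__(self):
        if len(self.k_phi) < 1:
            raise ConfigurationError("torsion needs at least one force constant")
        object.__setattr__(self, "k_phi", tuple(float(k) for k in self.k_phi))

    @property
    def n_max(self) -> int:
        return len(self.k_phi)


@dataclass(frozen=True)
class ClassIIStretchParam:
    k_r: float
    r0: float
    cs: float = 0.0  # cubic-stretch constant, A^-1

    def __post_init__(self):
        if self.k_r < 0 or self.r0 <= 0:
            raise ConfigurationError(f"invalid stretch parameters {self}")


@dataclass(frozen=True)
class ClassIIBendParam:
    k_theta: float
    theta0: float
    cb: float = 0.0  # bend correction constant, rad^-1

    def __post_init__(self):
        if self.k_theta < 0 or not (0 < self.theta0 <= math.pi):
            raise ConfigurationError(f"invalid bend parameters {self}")


@dataclass(frozen=True)
class ClassIIStretchBendParam:
    k_sb_ijk: float  # kJ mol^-1 A^-1 rad^-1
    k_sb_kji: float
    r_ij0: float
    r_jk0: float
    theta0: float


@dataclass(frozen=True)
class ClassIITorsionParam:
    k1: float
    k2: float
    k3: float
    phi0: float = 0.0


@dataclass(frozen=True)
class OutOfPlaneParam:
    k_oop: float  # kJ mol^-1 rad^-2

    def __post_init__(self):
        if self.k_oop < 0:
            raise ConfigurationError(f"invalid out-of-plane parameter {self}")


@dataclass(frozen=True)
class EngineConfig:
    """Engine-level constants: Coulomb prefactor, buffering delta, 1-4
    scalings and the Class II stretch functional form.

    The 1-2 and 1-3 pairs are always excluded from non-bonded sums; 1-4
    pairs are scaled.  Defaults follow common Class I (AMBER-style) and
    Class II (MMFF94-style) conventions and are fully configurable.
    """

    ff_class: str = "I"
    coulomb_constant: float = COULOMB_CONSTANT
    delta: float = 0.0  # Coulomb buffering, A (Class II)
    scale14_coulomb: float = 0.8333
    scale14_vdw: float = 0.5
    stretch_form: str = "mmff94"  # or "literal" (squared-polynomial variant)

    def __post_init__(self):
        if self.ff_class not in ("I", "II"):
            raise ConfigurationError(f"ff_class must be 'I' or 'II', got {self.ff_class!r}")
        if self.delta < 0:
            raise ConfigurationError("delta must be >= 0")
        for s in (self.scale14_coulomb, self.scale14_vdw):
            if not (0.0 <= s <= 1.0):
                raise ConfigurationError("1-4 scale factors must lie in [0, 1]")
        if self.stretch_form not in ("mmff94", "literal"):
            raise ConfigurationError(f"unknown stretch_form {self.stretch_form!r}")

    @classmethod
    def for_class(cls, ff_class: str, **overrides) -> "EngineConfig":
        if ff_class == "I":
            base = dict(ff_class="I", delta=0.0, scale14_coulomb=0.8333, scale14_vdw=0.5)
        else:
            base = dict(ff_class="II", delta=0.05, scale14_coulomb=0.75, scale14_vdw=1.0)
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# scalar term functions (value and d/d(internal coordinate))


def u_bond_I(r: float, p: ClassIBondParam) -> float:
    """Harmonic bond: k_r/2 (r - r0)^2."""
    d = r - p.r0
    return 0.5 * p.k_r * d * d


def _du_bond_I(r: float, p: ClassIBondParam) -> float:
    return p.k_r * (r - p.r0)


def u_angle_I(theta: float, p: ClassIAngleParam) -> float:
    """Harmonic valence angle: k_theta/2 (theta - theta0)^2."""
    d = theta - p.theta0
    return 0.5 * p.k_theta * d * d


def _du_angle_I(theta: float, p: ClassIAngleParam) -> float:
    return p.k_theta * (theta - p.theta0)


def u_torsion_I(phi: float, p: ClassITorsionParam) -> float:
    """Cosine series sum_n k_n [1 + cos n(phi - phi0)]; 2 pi periodic."""
    d = phi - p.phi0
    return sum(k * (1.0 + math.cos((n + 1) * d)) for n, k in enumerate(p.k_phi))


def _du_torsion_I(phi: float, p: ClassITorsionParam) -> float:
    d = phi - p.phi0
    return sum(-k * (n + 1) * math.sin((n + 1) * d) for n, k in enumerate(p.k_phi))


def u_coulomb_I(r: float, qi: float, qj: float, config: EngineConfig) -> float:
    """Point-charge Coulomb: k_C qi qj / r."""
    return config.coulomb_constant * qi * qj / r


def u_lj(r: float, sigma: float, epsilon: float) -> float:
    """12-6 Lennard-Jones: 4 eps [(sigma/r)^12 - (sigma/r)^6]."""
    s6 = (sigma / r) ** 6
    return 4.0 * epsilon * (s6 * s6 - s6)


def _du_lj(r: float, sigma: float, epsilon: float) -> float:
    s6 = (sigma / r) ** 6
    return 4.0 * epsilon * (-12.0 * s6 * s6 + 6.0 * s6) / r


def u_stretch_II(r: float, p: ClassIIStretchParam, form: str = "mmff94") -> float:
    """Anharmonic bond stretch.

    ``mmff94`` (default): the canonical cubic-quartic expansion
    k_r/2 D^2 (1 + cs D + 7/12 cs^2 D^2), D = r - r0.
    ``literal``: the squared-polynomial variant
    k_r/2 D^2 (1 + cs D + 7/12 cs D)^2, kept for comparison.
    """
    d = r - p.r0
    if form == "mmff94":
        return 0.5 * p.k_r * d * d * (1.0 + p.cs * d + (7.0 / 12.0) * p.cs * p.cs * d * d)
    if form == "literal":
        a = 1.0 + (19.0 / 12.0) * p.cs * d
        return 0.5 * p.k_r * d * d * a * a
    raise ConfigurationError(f"unknown stretch form {form!r}")


def _du_stretch_II(r: float, p: ClassIIStretchParam, form: str = "mmff94") -> float:
    d = r - p.r0
    if form == "mmff94":
        return 0.5 * p.k_r * (2.0 * d + 3.0 * p.cs * d * d + (7.0 / 3.0) * p.cs * p.cs * d ** 3)
    a = (19.0 / 12.0) * p.cs
    return p.k_r * d * (1.0 + a * d) * (1.0 + 2.0 * a * d)


def u_bend_II(theta: float, p: ClassIIBendParam) -> float:
    """Cubic-corrected bend: k_theta/2 Dt^2 (1 + cb Dt)."""
    d = theta - p.theta0
    return 0.5 * p.k_theta * d * d * (1.0 + p.cb * d)


def _du_bend_II(theta: float, p: ClassIIBendParam) -> float:
    d = theta - p.theta0
    return 0.5 * p.k_theta * (2.0 * d + 3.0 * p.cb * d * d)


def u_stretch_bend(r_ij: float, r_jk: float, theta: float, p: ClassIIStretchBendParam) -> float:
    """Stretch-bend coupling: (k_ijk Dr_ij + k_kji Dr_jk) Dtheta."""
    return (p.k_sb_ijk * (r_ij - p.r_ij0) + p.k_sb_kji * (r_jk - p.r_jk0)) * (theta - p.theta0)


def u_torsion_II(phi: float, p: ClassIITorsionParam) -> float:
    """Three-fold phased torsion:
    k1(1+cos D) + k2(1-cos 2D) + k3(1+cos 3D), D = phi - phi0."""
    d = phi - p.phi0
    return (
        p.k1 * (1.0 + math.cos(d))
        + p.k2 * (1.0 - math.cos(2.0 * d))
        + p.k3 * (1.0 + math.cos(3.0 * d))
    )


def _du_torsion_II(phi: float, p: ClassIITorsionParam) -> float:
    d = phi - p.phi0
    return -p.k1 * math.sin(d) + 2.0 * p.k2 * math.sin(2.0 * d) - 3.0 * p.k3 * math.sin(3.0 * d)


def u_oop(chi: float, p: OutOfPlaneParam) -> float:
    """Harmonic out-of-plane (Wilson angle) term: k_oop/2 chi^2."""
    return 0.5 * p.k_oop * chi * chi


def _du_oop(chi: float, p: OutOfPlaneParam) -> float:
    return p.k_oop * chi


def u_coulomb_II(r: float, qi: float, qj: float, config: EngineConfig) -> float:
    """Buffered Coulomb: k_C qi qj / (r + delta)."""
    return config.coulomb_constant * qi * qj / (r + config.delta)


def u_buf_14_7(r: float, eps_ij: float, rstar_ij: float) -> float:
    """MMFF94 buffered 14-7 van der Waals potential; minimum -eps at r = r*."""
    a = 1.07 * rstar_ij / (r + 0.07 * rstar_ij)
    r7 = r ** 7
    rs7 = rstar_ij ** 7
    b = 1.12 * rs7 / (r7 + 0.12 * rs7)
    return eps_ij * a ** 7 * (b - 2.0)


def _du_buf_14_7(r: float, eps_ij: float, rstar_ij: float) -> float:
    a = 1.07 * rstar_ij / (r + 0.07 * rstar_ij)
    da = -1.07 * rstar_ij / (r + 0.07 * rstar_ij) ** 2
    r7 = r ** 7
    rs7 = rstar_ij ** 7
    b = 1.12 * rs7 / (r7 + 0.12 * rs7)
    db = -1.12 * rs7 * 7.0 * r ** 6 / (r7 + 0.12 * rs7) ** 2
    return eps_ij * (7.0 * a ** 6 * da * (b - 2.0) + a ** 7 * db)


# ---------------------------------------------------------------------------
# parameter set


@dataclass(frozen=True)
class DroppedInteraction:
    category: str
    atom_indices: tuple[int, ...]
    key: str = ""
    reason: str = "missing table entry"


@dataclass
class ParameterSet:
    """Per-molecule parameters keyed by the index tuples of the molecule's
    InternalCoordinateIndex, plus per-atom non-bonded parameters.

    Every enumerated interaction must either carry a parameter record here
    or be listed in ``dropped``; :func:`total_energy` enforces this and
    silently skips dropped interactions (their contribution is disregarded).
    """

    config: EngineConfig
    bond: dict = field(default_factory=dict)
    angle: dict = field(default_factory=dict)
    stretch_bend: dict = field(default_factory=dict)  # Class II, optional per angle
    torsion: dict = field(default_factory=dict)
    oop: dict = field(default_factory=dict)
    charges: np.ndarray | None = None
    sigma: np.ndarray | None = None  # Class I per-atom LJ
    epsilon: np.ndarray | None = None
    eps: np.ndarray | None = None  # Class II per-atom well depth
    rstar: np.ndarray | None = None  # Class II per-atom minimum distance
    vdw_pairs: dict = field(default_factory=dict)  # Class II explicit (eps_ij, rstar_ij)
    dropped: list = field(default_factory=list)

    @property
    def ff_class(self) -> str:
        return self.config.ff_class

    def dropped_set(self) -> set[tuple[str, tuple[int, ...]]]:
        return {(d.category, tuple(d.atom_indices)) for d in self.dropped}

    # -- serialization ------------------------------------------------------

    _UNITS_HEADER = {
        "length": "angstrom",
        "angle": "radian",
        "energy": "kJ/mol",
        "charge": "e",
    }

    def to_json(self, path: str) -> None:
        def enc(d):
            return {
                "-".join(map(str, k)): asdict(v) | {"_type": type(v).__name__}
                for k, v in d.items()
            }

        doc = {
            "format": "ffcondense-parameterset",
            "version": 1,
            "units": self._UNITS_HEADER,
            "config": asdict(self.config),
            "bond": enc(self.bond),
            "angle": enc(self.angle),
            "stretch_bend": enc(self.stretch_bend),
            "torsion": enc(self.torsion),
            "oop": enc(self.oop),
            "charges": None if self.charges is None else list(map(float, self.charges)),
            "sigma": None if self.sigma is None else list(map(float, self.sigma)),
            "epsilon": None if self.epsilon is None else list(map(float, self.epsilon)),
            "eps": None if self.eps is None else list(map(float, self.eps)),
            "rstar": None if self.rstar is None else list(map(float, self.rstar)),
            "vdw_pairs": {
                "-".join(map(str, k)): [float(v[0]), float(v[1])]
                for k, v in self.vdw_pairs.items()
            },
            "dropped": [asdict(d) for d in self.dropped],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "ParameterSet":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "ffcondense-parameterset" or doc.get("version") != 1:
            raise FormatError(f"{path}: not a version-1 ffcondense parameter set")
        types = {
            c.__name__: c
            for c in (
                ClassIBondParam,
                ClassIAngleParam,
                ClassITorsionParam,
                ClassIIStretchParam,
                ClassIIBendParam,
                ClassIIStretchBendParam,
                ClassIITorsionParam,
                OutOfPlaneParam,
            )
        }

        def dec(d):
            out = {}
            for ks, v in d.items():
                k = tuple(int(x) for x in ks.split("-"))
                tname = v.pop("_type")
                if "k_phi" in v:
                    v["k_phi"] = tuple(v["k_phi"])
                out[k] = types[tname](**v)
            return out

        def arr(v):
            return None if v is None else np.asarray(v, dtype=float)

        return cls(
            config=EngineConfig(**doc["config"]),
            bond=dec(doc["bond"]),
            angle=dec(doc["angle"]),
            stretch_bend=dec(doc["stretch_bend"]),
            torsion=dec(doc["torsion"]),
            oop=dec(doc["oop"]),
            charges=arr(doc["charges"]),
            sigma=arr(doc["sigma"]),
            epsilon=arr(doc["epsilon"]),
            eps=arr(doc["eps"]),
            rstar=arr(doc["rstar"]),
            vdw_pairs={
                tuple(int(x) for x in ks.split("-")): (v[0], v[1])
                for ks, v in doc["vdw_pairs"].items()
            },
            dropped=[DroppedInteraction(**d) for d in doc["dropped"]],
        )


def nonbonded_pairs(
    n_atoms: int, bonds: list[tuple[int, int]]
) -> list[tuple[int, int, int]]:
    """All unordered atom pairs with their bond-graph separation class.

    Returns (i, j, sep) for i < j where sep = 4 for 1-4 pairs and 5 for
    more distant pairs; 1-2 and 1-3 pairs are omitted (always excluded).
    """
    adj: list[set[int]] = [set() for _ in range(n_atoms)]
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    # BFS distances up to 3 bonds
    pairs = []
    for i in range(n_atoms):
        dist = {i: 0}
        frontier = [i]
        for d in (1, 2, 3):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = d
                        nxt.append(v)
            frontier = nxt
        for j in range(i + 1, n_atoms):
            d = dist.get(j)
            if d is None:
                pairs.append((i, j, 5))
            elif d == 3:
                pairs.append((i, j, 4))
    return pairs


# ---------------------------------------------------------------------------
# internal-coordinate values and Cartesian gradients


def _dist_wg(x, i, j):
    d = x[i] - x[j]
    r = float(np.linalg.norm(d))
    u = d / r
    return r, ((i, u), (j, -u))


def _angle_wg(x, i, j, k):
    a = x[i] - x[j]
    b = x[k] - x[j]
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    c = float(np.dot(a, b) / (na * nb))
    c = min(1.0, max(-1.0, c))
    theta = math.acos(c)
    s = max(math.sqrt(max(0.0, 1.0 - c * c)), _GUARD)
    gi = (c * a / na - b / nb) / (na * s)
    gk = (c * b / nb - a / na) / (nb * s)
    return theta, ((i, gi), (k, gk), (j, -(gi + gk)))


def _dihedral_wg(x, i, j, k, l):
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = float(np.linalg.norm(b2))
    n1sq = float(np.dot(n1, n1))
    n2sq = float(np.dot(n2, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / nb2))
    c = float(np.dot(n1, n2))
    phi = math.atan2(y, c)
    n1sq = max(n1sq, _GUARD * _GUARD)
    n2sq = max(n2sq, _GUARD * _GUARD)
    gi = -(nb2 / n1sq) * n1
    gl = (nb2 / n2sq) * n2
    f1 = float(np.dot(b1, b2)) / (nb2 * nb2)
    f3 = float(np.dot(b3, b2)) / (nb2 * nb2)
    gj = -(1.0 + f1) * gi + f3 * gl
    gk = f1 * gi - (1.0 + f3) * gl
    return phi, ((i, gi), (j, gj), (k, gk), (l, gl))


def _oop_wg(x, i, j, k, l):
    """Wilson angle of atom l against plane i-j-k (vertex j), with gradient."""
    a = x[i] - x[j]
    b = x[k] - x[j]
    c = x[l] - x[j]
    n = np.cross(a, b)
    nn = float(np.linalg.norm(n))
    nc = float(np.linalg.norm(c))
    s = float(np.dot(n, c) / (nn * nc))
    s = min(1.0, max(-1.0, s))
    chi = math.asin(s)
    dchi_ds = 1.0 / max(math.sqrt(max(0.0, 1.0 - s * s)), _GUARD)
    g_n = c / (nn * nc) - s * n / (nn * nn)
    g_c = n / (nn * nc) - s * c / (nc * nc)
    ga = np.cross(b, g_n) * dchi_ds
    gb = np.cross(g_n, a) * dchi_ds
    gc = g_c * dchi_ds
    return chi, ((i, ga), (k, gb), (l, gc), (j, -(ga + gb + gc)))


# ---------------------------------------------------------------------------
# total energy and gradient


@dataclass
class EnergyBreakdown:
    """Per-category energies (kJ/mol) and the count of dropped interactions.

    ``total()`` accumulates the categories in a fixed order so the sum is
    bitwise reproducible and exactly equals the engine's reported total.
    """

    terms: dict[str, float]
    n_dropped: int = 0

    CATEGORIES = ("bond", "angle", "stretch_bend", "torsion", "oop", "coulomb", "vdw")

    def total(self) -> float:
        t = 0.0
        for c in self.CATEGORIES:
            t += self.terms.get(c, 0.0)
        return t


def _check_complete(ps: ParameterSet, internals: InternalCoordinateIndex) -> None:
    dropped = ps.dropped_set()
    for cat, tuples, table in (
        ("bond", internals.bonds, ps.bond),
        ("angle", internals.angles, ps.angle),
        ("proper", internals.propers, ps.torsion),
        ("improper", internals.impropers, ps.oop),
    ):
        for t in tuples:
            if t not in table and (cat, t) not in dropped:
                raise ConsistencyError(
                    f"{cat} interaction {t} is neither parametrized nor dropped"
                )


def _vdw_pair_params(ps: ParameterSet, i: int, j: int):
    """Resolve per-pair vdW parameters.

    Class I: Lorentz-Berthelot combination of per-atom (sigma, epsilon).
    Class II: explicit pair override if present, else arithmetic r* and
    geometric eps combination of per-atom values.
    """
    if ps.ff_class == "I":
        sigma = 0.5 * (ps.sigma[i] + ps.sigma[j])
        epsilon = math.sqrt(ps.epsilon[i] * ps.epsilon[j])
        return sigma, epsilon
    key = (min(i, j), max(i, j))
    if key in ps.vdw_pairs:
        return ps.vdw_pairs[key]
    eps_ij = math.sqrt(ps.eps[i] * ps.eps[j])
    rstar_ij = 0.5 * (ps.rstar[i] + ps.rstar[j])
    return eps_ij, rstar_ij


def _iter_oop_wags(imp: tuple[int, int, int, int]):
    """The three Wilson wag angles of one trigonal improper center
    (center j; neighbors n1, n2, n3): each neighbor out of the plane of the
    center and the other two (MMFF94 convention)."""
    j, n1, n2, n3 = imp
    yield (n1, j, n2, n3)
    yield (n2, j, n3, n1)
    yield (n3, j, n1, n2)


def total_energy(
    conf: Conformer, ps: ParameterSet, internals: InternalCoordinateIndex
) -> tuple[float, EnergyBreakdown]:
    """Total potential energy and its per-category breakdown (kJ/mol).

    Bonded terms run over the enumerated interactions, skipping those in
    ``ps.dropped`` (their contribution is disregarded entirely).  Non-bonded
    sums exclude 1-2/1-3 pairs and scale 1-4 pairs per the engine config.
    """
    _check_complete(ps, internals)
    x = conf.coords
    cfg = ps.config
    dropped = ps.dropped_set()
    terms = {c: 0.0 for c in EnergyBreakdown.CATEGORIES}

    from .topology import _distance, _angle, _dihedral, _oop  # value-only paths

    for t in internals.bonds:
        if ("bond", t) in dropped:
            continue
        r = _distance(x, *t)
        p = ps.bond[t]
        if cfg.ff_class == "I":
            terms["bond"] += u_bond_I(r, p)
        else:
            terms["bond"] += u_stretch_II(r, p, cfg.stretch_form)

    for t in internals.angles:
        if ("angle", t) in dropped:
            continue
        theta = _angle(x, *t)
        p = ps.angle[t]
        if cfg.ff_class == "I":
            terms["angle"] += u_angle_I(theta, p)
        else:
            terms["angle"] += u_bend_II(theta, p)
            sb = ps.stretch_bend.get(t)
            if sb is not None:
                i, j, k = t
                terms["stretch_bend"] += u_stretch_bend(
                    _distance(x, i, j), _distance(x, j, k), theta, sb
                )

    for t in internals.propers:
        if ("proper", t) in dropped:
            continue
        phi = _dihedral(x, *t)
        p = ps.torsion[t]
        if cfg.ff_class == "I":
            terms["torsion"] += u_torsion_I(phi, p)
        else:
            terms["torsion"] += u_torsion_II(phi, p)

    for t in internals.impropers:
        if ("improper", t) in dropped:
            continue
        p = ps.oop[t]
        for (a, b, c, d) in _iter_oop_wags(t):
            terms["oop"] += u_oop(_oop(x, a, b, c, d), p)

    q = ps.charges
    for i, j, sep in nonbonded_pairs(conf.n_atoms, internals.bonds):
        sc = cfg.scale14_coulomb if sep == 4 else 1.0
        sv = cfg.scale14_vdw if sep == 4 else 1.0
        r = _distance(x, i, j)
        if q is not None and q[i] != 0.0 and q[j] != 0.0:
            if cfg.ff_class == "I":
                terms["coulomb"] += sc * u_coulomb_I(r, q[i], q[j], cfg)
            else:
                terms["coulomb"] += sc * u_coulomb_II(r, q[i], q[j], cfg)
        if cfg.ff_class == "I":
            if ps.sigma is not None and ps.epsilon is not None:
                sigma, epsilon = _vdw_pair_params(ps, i, j)
                if epsilon > 0.0:
                    terms["vdw"] += sv * u_lj(r, sigma, epsilon)
        else:
            if (ps.eps is not None and ps.rstar is not None) or (min(i, j), max(i, j)) in ps.vdw_pairs:
                eps_ij, rstar_ij = _vdw_pair_params(ps, i, j)
                if eps_ij > 0.0:
                    terms["vdw"] += sv * u_buf_14_7(r, eps_ij, rstar_ij)

    bd = EnergyBreakdown(terms=terms, n_dropped=len(ps.dropped))
    return bd.total(), bd


def analytic_gradient(
    conf: Conformer, ps: ParameterSet, internals: InternalCoordinateIndex
) -> np.ndarray:
    """Cartesian gradient of :func:`total_energy`, shape (n_atoms, 3),
    kJ mol^-1 A^-1.  Internal terms exert zero net force and zero net torque;
    near-linear angles are regularized with a small-angle guard."""
    _check_complete(ps, internals)
    x = conf.coords
    cfg = ps.config
    dropped = ps.dropped_set()
    g = np.zeros_like(x)

    def add(wgrads, du):
        for idx, vec in wgrads:
            g[idx] += du * vec

    for t in internals.bonds:
        if ("bond", t) in dropped:
            continue
        r, wg = _dist_wg(x, *t)
        p = ps.bond[t]
        du = _du_bond_I(r, p) if cfg.ff_class == "I" else _du_stretch_II(r, p, cfg.stretch_form)
        add(wg, du)

    for t in internals.angles:
        if ("angle", t) in dropped:
            continue
        theta, wg = _angle_wg(x, *t)
        p = ps.angle[t]
        if cfg.ff_class == "I":
            add(wg, _du_angle_I(theta, p))
        else:
            add(wg, _du_bend_II(theta, p))
            sb = ps.stretch_bend.get(t)
            if sb is not None:
                i, j, k = t
                rij, wgij = _dist_wg(x, i, j)
                rjk, wgjk = _dist_wg(x, j, k)
                dth = theta - sb.theta0
                add(wgij, sb.k_sb_ijk * dth)
                add(wgjk, sb.k_sb_kji * dth)
                du_dtheta = sb.k_sb_ijk * (rij - sb.r_ij0) + sb.k_sb_kji * (rjk - sb.r_jk0)
                add(wg, du_dtheta)

    for t in internals.propers:
        if ("proper", t) in dropped:
            continue
        phi, wg = _dihedral_wg(x, *t)
        p = ps.torsion[t]
        du = _du_torsion_I(phi, p) if cfg.ff_class == "I" else _du_torsion_II(phi, p)
        add(wg, du)

    for t in internals.impropers:
        if ("improper", t) in dropped:
            continue
        p = ps.oop[t]
        for (a, b, c, d) in _iter_oop_wags(t):
            chi, wg = _oop_wg(x, a, b, c, d)
            add(wg, _du_oop(chi, p))

    q = ps.charges
    kc = cfg.coulomb_constant
    for i, j, sep in nonbonded_pairs(conf.n_atoms, internals.bonds):
        sc = cfg.scale14_coulomb if sep == 4 else 1.0
        sv = cfg.scale14_vdw if sep == 4 else 1.0
        r, wg = _dist_wg(x, i, j)
        du = 0.0
        if q is not None and q[i] != 0.0 and q[j] != 0.0:
            if cfg.ff_class == "I":
                du += sc * (-kc * q[i] * q[j] / (r * r))
            else:
                du += sc * (-kc * q[i] * q[j] / (r + cfg.delta) ** 2)
        if cfg.ff_class == "I":
            if ps.sigma is not None and ps.epsilon is not None:
                sigma, epsilon = _vdw_pair_params(ps, i, j)
                if epsilon > 0.0:
                    du += sv * _du_lj(r, sigma, epsilon)
        else:
            if (ps.eps is not None and ps.rstar is not None) or (min(i, j), max(i, j)) in ps.vdw_pairs:
                eps_ij, rstar_ij = _vdw_pair_params(ps, i, j)
                if eps_ij > 0.0:
                    du += sv * _du_buf_14_7(r, eps_ij, rstar_ij)
        if du != 0.0:
            add(wg, du)

    return g
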