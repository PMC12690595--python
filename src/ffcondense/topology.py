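"""Molecular graph representation, structure I/O and internal coordinates.

The topology layer is deliberately chemistry-light: atoms carry an element
symbol, a formal charge and an integer atom-type id (MMFF94-style, or any
user scheme).  Atom typing itself is treated as a pluggable chemical-sensing
model: types arrive from the structure file, from a JSON sidecar, or from
the mini-typer in :mod:`ffcondense.fixtures`.

Units are Angstrom and radians throughout.  Indices are 0-based internally;
the 1-based indices of MOL2/SDF files are converted at the boundary.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    ParseError,
    StructureError,
)

__all__ = [
    "Atom",
    "MoleculeTopology",
    "Conformer",
    "InternalCoordinateIndex",
    "ImproperPattern",
    "DEFAULT_IMPROPER_PATTERNS",
    "read_structure",
    "write_mol2",
    "write_sdf",
    "enumerate_internals",
    "detect_impropers",
    "measure",
]

_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Hf Ta W Re Os Ir Pt Au Hg Tl Pb Bi".split()
)


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol, formal charge (e) and integer atom-type id.

    ``atom_type_id`` is ``None`` while the atom is untyped; assigned ids are
    ≥ 1 (MMFF94-style schemes use 1–100, user schemes may use any positive
    integers).
    """

    element: str
    formal_charge: int = 0
    atom_type_id: int | None = None

    def __post_init__(self) -> None:
        if self.element not in _ELEMENTS:
            raise StructureError(f"unknown element symbol {self.element!r}")
        if self.atom_type_id is not None and self.atom_type_id < 1:
            raise StructureError(
                f"atom_type_id must be >= 1 when assigned, got {self.atom_type_id}"
            )


@dataclass
class MoleculeTopology:
    """Molecular graph: ordered atoms plus bonds ``(i, j, order)``.

    The graph must be connected: this package targets single-ligand
    preparation for virtual screening, where multi-fragment inputs indicate
    an upstream error and are rejected.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, int]]
    name: str = "mol"
    total_charge: int = 0

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        norm_bonds: list[tuple[int, int, int]] = []
        for b in self.bonds:
            i, j, order = b
            if not (0 <= i < n and 0 <= j < n):
                raise StructureError(f"bond {b} references an atom out of range (n={n})")
            if i == j:
                raise StructureError(f"self-bond on atom {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise StructureError(f"duplicate bond between atoms {i} and {j}")
            seen.add(key)
            norm_bonds.append((key[0], key[1], order))
        self.bonds = norm_bonds
        if n > 1:
            g = self.graph()
            if not nx.is_connected(g):
                raise StructureError(
                    f"molecule {self.name!r} is disconnected "
                    f"({nx.number_connected_components(g)} fragments)"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from((i, j) for i, j, _ in self.bonds)
        return g

    def neighbors(self) -> list[list[int]]:
        nb: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for i, j, _ in self.bonds:
            nb[i].append(j)
            nb[j].append(i)
        return [sorted(x) for x in nb]

    def atom_types(self) -> list[int]:
        """Atom-type ids for all atoms; raises if any atom is untyped."""
        ids = []
        for idx, a in enumerate(self.atoms):
            if a.atom_type_id is None:
                raise StructureError(f"atom {idx} ({a.element}) is untyped")
            ids.append(a.atom_type_id)
        return ids

    def with_types(self, type_ids: list[int]) -> "MoleculeTopology":
        if len(type_ids) != self.n_atoms:
            raise StructureError(
                f"{len(type_ids)} type ids for {self.n_atoms} atoms"
            )
        atoms = [
            Atom(a.element, a.formal_charge, int(t))
            for a, t in zip(self.atoms, type_ids)
        ]
        return MoleculeTopology(atoms, list(self.bonds), self.name, self.total_charge)


@dataclass
class Conformer:
    """Cartesian coordinates, one (x, y, z) triple per atom, in Angstrom."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError(f"coords must be (n, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("coords contain non-finite values")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Conformer":
        return Conformer(self.coords.copy())


@dataclass
class InternalCoordinateIndex:
    """Canonical listing of every bonded internal coordinate of a molecule.

    * ``bonds``: (i, j) with i < j
    * ``angles``: (i, j, k), j the vertex, i < k
    * ``propers``: (i, j, k, l) over central bond j–k, one canonical
      direction per dihedral
    * ``impropers``: (center, n1, n2, n3) with neighbors in ascending order
    """

    bonds: list[tuple[int, int]] = field(default_factory=list)
    angles: list[tuple[int, int, int]] = field(default_factory=list)
    propers: list[tuple[int, int, int, int]] = field(default_factory=list)
    impropers: list[tuple[int, int, int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# internal-coordinate enumeration


def canonical_angle(i: int, j: int, k: int) -> tuple[int, int, int]:
    return (i, j, k) if i < k else (k, j, i)


def canonical_proper(i: int, j: int, k: int, l: int) -> tuple[int, int, int, int]:
    # keep if the (j, k, i, l) comparison tuple is lexicographically <= its
    # reverse counterpart (k, j, l, i); deterministic single listing
    return (i, j, k, l) if (j, k, i, l) <= (k, j, l, i) else (l, k, j, i)


def enumerate_internals(
    mol: MoleculeTopology,
    improper_patterns: "list[ImproperPattern] | None" = None,
) -> InternalCoordinateIndex:
    """Enumerate bonds, angles, proper torsions and impropers of ``mol``.

    Angles are all bonded triples with distinct ends; propers all bonded
    quadruples with four distinct atoms.  Each appears exactly once, in the
    canonical direction.
    """
    if mol.n_atoms < 1:
        raise StructureError("empty molecule")
    nb = mol.neighbors()
    bonds = sorted((i, j) for i, j, _ in mol.bonds)

    angles = []
    for j in range(mol.n_atoms):
        ns = nb[j]
        for a in range(len(ns)):
            for b in range(a + 1, len(ns)):
                angles.append(canonical_angle(ns[a], j, ns[b]))
    angles.sort()

    propers_set = set()
    for j, k in bonds:
        for i in nb[j]:
            if i == k:
                continue
            for l in nb[k]:
                if l == j or l == i:
                    continue
                propers_set.add(canonical_proper(i, j, k, l))
    propers = sorted(propers_set)

    impropers = detect_impropers(mol, improper_patterns)
    return InternalCoordinateIndex(bonds, angles, propers, impropers)


@dataclass(frozen=True)
class ImproperPattern:
    """Element + neighbor-count predicate selecting improper (out-of-plane)
    centers, e.g. ``ImproperPattern("N", 3)`` for trigonal nitrogen.

    Only degree-3 centers define a Wilson out-of-plane coordinate, so the
    neighbor count must be 3.
    """

    element: str
    degree: int = 3

    def __post_init__(self) -> None:
        if self.element not in _ELEMENTS:
            raise ConfigurationError(f"pattern element {self.element!r} unknown")
        if self.degree != 3:
            raise ConfigurationError(
                "improper centers must have exactly 3 bonded neighbors; "
                f"got degree={self.degree}"
            )

    @classmethod
    def parse(cls, text: str) -> "ImproperPattern":
        """Parse ``"N:3"`` / ``"C:3"`` style pattern strings."""
        m = re.fullmatch(r"([A-Z][a-z]?):(\d+)", text.strip())
        if not m:
            raise ConfigurationError(f"invalid improper pattern {text!r}")
        return cls(m.group(1), int(m.group(2)))


#: Artifact defaults: trigonal nitrogen and trigonal (sp2-like) carbon.
DEFAULT_IMPROPER_PATTERNS = (ImproperPattern("N", 3), ImproperPattern("C", 3))


def detect_impropers(
    mol: MoleculeTopology,
    patterns: "list[ImproperPattern] | None" = None,
) -> list[tuple[int, int, int, int]]:
    """Match improper centers: atoms whose element and neighbor count match a
    pattern.  Each match yields (center, n1, n2, n3) with neighbors ascending;
    results sorted by center index."""
    if patterns is None:
        patterns = list(DEFAULT_IMPROPER_PATTERNS)
    nb = mol.neighbors()
    out = []
    for j, atom in enumerate(mol.atoms):
        deg = len(nb[j])
        for p in patterns:
            if atom.element == p.element and deg == p.degree:
                n1, n2, n3 = nb[j]
                out.append((j, n1, n2, n3))
                break
    return sorted(out)


# ---------------------------------------------------------------------------
# geometric measurement

_EPS = 1e-12


def _distance(x: np.ndarray, i: int, j: int) -> float:
    return float(np.linalg.norm(x[i] - x[j]))


def _angle(x: np.ndarray, i: int, j: int, k: int) -> float:
    a = x[i] - x[j]
    b = x[k] - x[j]
    na = np.linalg.norm(a)
    nbn = np.linalg.norm(b)
    if na < _EPS or nbn < _EPS:
        raise DegenerateGeometryError(f"coincident atoms in angle ({i},{j},{k})")
    c = float(np.dot(a, b) / (na * nbn))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def _dihedral(x: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < _EPS or np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS:
        raise DegenerateGeometryError(
            f"dihedral ({i},{j},{k},{l}) undefined (collinear atoms)"
        )
    # IUPAC convention: cis (eclipsed) = 0, trans (anti) = pi
    y = float(np.dot(np.cross(n1, n2), b2 / nb2))
    c = float(np.dot(n1, n2))
    phi = float(np.arctan2(y, c))
    if phi <= -np.pi:  # map to (-pi, pi]
        phi += 2 * np.pi
    return phi


def _oop(x: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Wilson out-of-plane angle of atom ``l`` against the i–j–k plane, with
    j the central atom; in [-pi/2, pi/2], zero for coplanar atoms."""
    a = x[i] - x[j]
    b = x[k] - x[j]
    c = x[l] - x[j]
    n = np.cross(a, b)
    nn = np.linalg.norm(n)
    nc = np.linalg.norm(c)
    if nn < _EPS or nc < _EPS:
        raise DegenerateGeometryError(
            f"out-of-plane angle ({i},{j},{k},{l}) undefined"
        )
    s = float(np.dot(n, c) / (nn * nc))
    return float(np.arcsin(np.clip(s, -1.0, 1.0)))


def measure(conf: Conformer, kind: str, indices: tuple[int, ...]) -> float:
    """Measure an internal coordinate on a conformer.

    kind: ``distance`` (Å), ``angle`` ([0, π]), ``dihedral`` ((−π, π],
    trans = π), or ``oop`` (Wilson angle, [−π/2, π/2]); all angles in radians.
    """
    x = conf.coords
    n = conf.n_atoms
    if any(not (0 <= ix < n) for ix in indices):
        raise StructureError(f"indices {indices} out of range (n={n})")
    if kind == "distance":
        return _distance(x, *indices)
    if kind == "angle":
        return _angle(x, *indices)
    if kind == "dihedral":
        return _dihedral(x, *indices)
    if kind == "oop":
        return _oop(x, *indices)
    raise ConfigurationError(f"unknown measurement kind {kind!r}")


# ---------------------------------------------------------------------------
# structure file I/O

_MOL2_TYPE_INT = re.compile(r"^\d+$")


def _element_from_name(name: str) -> str:
    sym = re.sub(r"[^A-Za-z]", "", name)
    for cand in (sym[:2].capitalize(), sym[:1].upper()):
        if cand in _ELEMENTS:
            return cand
    raise ValueError(name)


def _read_sidecar_types(path: str, n_atoms: int) -> list[int]:
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list) or len(data) != n_atoms:
        raise ParseError(
            f"sidecar must be a JSON list of {n_atoms} integers", path=path
        )
    return [int(t) for t in data]


def _parse_mol2(path: str) -> tuple[list[Atom], list[tuple[int, int, int]], np.ndarray, str]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    section = None
    name = "mol"
    atoms: list[Atom] = []
    coords: list[list[float]] = []
    raw_types: list[str] = []
    bonds: list[tuple[int, int, int]] = []
    n_atoms_decl = n_bonds_decl = None
    mol_lines = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("@<TRIPOS>"):
            section = line[9:].strip().upper()
            mol_lines = 0
            continue
        if section == "MOLECULE":
            mol_lines += 1
            if mol_lines == 1:
                name = line
            elif mol_lines == 2:
                counts = line.split()
                try:
                    n_atoms_decl = int(counts[0])
                    n_bonds_decl = int(counts[1]) if len(counts) > 1 else 0
                except (ValueError, IndexError):
                    raise ParseError("malformed MOLECULE counts line", path, lineno)
        elif section == "ATOM":
            parts = line.split()
            if len(parts) < 6:
                raise ParseError("malformed ATOM record (need >= 6 fields)", path, lineno)
            try:
                x, y, z = float(parts[2]), float(parts[3]), float(parts[4])
            except ValueError:
                raise ParseError("non-numeric coordinates in ATOM record", path, lineno)
            atom_name, type_str = parts[1], parts[5]
            charge = 0
            if len(parts) >= 9:
                try:
                    charge = int(round(float(parts[8])))
                except ValueError:
                    raise ParseError("non-numeric charge in ATOM record", path, lineno)
            try:
                if _MOL2_TYPE_INT.match(type_str):
                    element = _element_from_name(atom_name)
                else:
                    element = _element_from_name(type_str.split(".")[0])
            except ValueError:
                raise ParseError(
                    f"cannot infer element from ATOM record ({atom_name!r}/{type_str!r})",
                    path,
                    lineno,
                )
            raw_types.append(type_str)
            atoms.append(Atom(element, charge))
            coords.append([x, y, z])
        elif section == "BOND":
            parts = line.split()
            if len(parts) < 4:
                raise ParseError("malformed BOND record (need 4 fields)", path, lineno)
            try:
                i, j = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError("non-integer atom index in BOND record", path, lineno)
            order_str = parts[3]
            order = {"ar": 2, "am": 1}.get(order_str) or (
                int(order_str) if order_str.isdigit() else 1
            )
            if i < 1 or j < 1 or i > len(atoms) or j > len(atoms):
                raise StructureError(
                    f"{path}:{lineno}: bond references atom {i if i < 1 or i > len(atoms) else j} "
                    f"outside 1..{len(atoms)}"
                )
            bonds.append((i - 1, j - 1, order))
    if n_atoms_decl is not None and n_atoms_decl != len(atoms):
        raise StructureError(
            f"{path}: MOLECULE declares {n_atoms_decl} atoms, ATOM block has {len(atoms)}"
        )
    if n_bonds_decl is not None and n_bonds_decl != len(bonds):
        raise StructureError(
            f"{path}: MOLECULE declares {n_bonds_decl} bonds, BOND block has {len(bonds)}"
        )
    # in-file integer atom types (artifact dialect)
    typed = []
    for a, t in zip(atoms, raw_types):
        if _MOL2_TYPE_INT.match(t):
            typed.append(Atom(a.element, a.formal_charge, int(t)))
        else:
            typed.append(a)
    return typed, bonds, np.array(coords, dtype=float), name


def _parse_sdf(path: str) -> tuple[list[Atom], list[tuple[int, int, int]], np.ndarray, str]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 4:
        raise ParseError("SDF file too short for a V2000 header", path, len(lines))
    name = lines[0].strip() or "mol"
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except ValueError:
        raise ParseError("malformed V2000 counts line", path, 4)
    atoms: list[Atom] = []
    coords: list[list[float]] = []
    for idx in range(n_atoms):
        lineno = 5 + idx
        if lineno > len(lines):
            raise StructureError(f"{path}: atom block truncated at atom {idx + 1}")
        line = lines[lineno - 1]
        try:
            x, y, z = float(line[0:10]), float(line[10:20]), float(line[20:30])
            element = line[31:34].strip()
        except (ValueError, IndexError):
            raise ParseError("malformed atom record", path, lineno)
        atoms.append(Atom(element, 0))
        coords.append([x, y, z])
    bonds: list[tuple[int, int, int]] = []
    for idx in range(n_bonds):
        lineno = 5 + n_atoms + idx
        if lineno > len(lines):
            raise StructureError(f"{path}: bond block truncated at bond {idx + 1}")
        line = lines[lineno - 1]
        try:
            i, j, order = int(line[0:3]), int(line[3:6]), int(line[6:9])
        except (ValueError, IndexError):
            raise ParseError("malformed bond record", path, lineno)
        if i < 1 or j < 1 or i > n_atoms or j > n_atoms:
            raise StructureError(
                f"{path}:{lineno}: bond references atom outside 1..{n_atoms}"
            )
        bonds.append((i - 1, j - 1, order))
    return atoms, bonds, np.array(coords, dtype=float), name


def read_structure(
    path: str,
    format: str = "mol2",
    types_source: str = "in_file",
    sidecar_path: str | None = None,
) -> tuple[MoleculeTopology, Conformer]:
    """Read a structure file into a topology + conformer pair.

    ``format``: ``mol2`` (TRIPOS @<TRIPOS>ATOM/BOND records) or ``sdf``
    (V2000).  Atom types come from the file's atom-type column when
    ``types_source="in_file"`` (MOL2 dialect with integer ids), or from a
    JSON sidecar — a list of integers, one per atom, in file order — when
    ``types_source="sidecar"``.  Atom order and coordinates (Å) are
    preserved from the file.
    """
    if format == "mol2":
        atoms, bonds, coords, name = _parse_mol2(path)
    elif format == "sdf":
        atoms, bonds, coords, name = _parse_sdf(path)
    else:
        raise ConfigurationError(f"unknown structure format {format!r}")

    if types_source == "sidecar":
        if sidecar_path is None:
            raise ConfigurationError("types_source='sidecar' requires sidecar_path")
        type_ids = _read_sidecar_types(sidecar_path, len(atoms))
        atoms = [Atom(a.element, a.formal_charge, t) for a, t in zip(atoms, type_ids)]
    elif types_source != "in_file":
        raise ConfigurationError(f"unknown types_source {types_source!r}")

    total_charge = sum(a.formal_charge for a in atoms)
    mol = MoleculeTopology(atoms, bonds, name=name, total_charge=total_charge)
    return mol, Conformer(coords)


def write_mol2(mol: MoleculeTopology, conf: Conformer, path: str) -> None:
    """Write the artifact MOL2 dialect: the atom-type column carries the
    integer atom-type id when assigned, else the element symbol."""
    with open(path, "w") as fh:
        fh.write("@<TRIPOS>MOLECULE\n")
        fh.write(f"{mol.name}\n")
        fh.write(f"{mol.n_atoms} {len(mol.bonds)} 0 0 0\n")
        fh.write("SMALL\nUSER_CHARGES\n")
        fh.write("@<TRIPOS>ATOM\n")
        for i, (a, xyz) in enumerate(zip(mol.atoms, conf.coords), start=1):
            t = str(a.atom_type_id) if a.atom_type_id is not None else a.element
            fh.write(
                f"{i:>4} {a.element}{i:<3} {xyz[0]:>10.4f} {xyz[1]:>10.4f} "
                f"{xyz[2]:>10.4f} {t} 1 {mol.name} {float(a.formal_charge):.4f}\n"
            )
        fh.write("@<TRIPOS>BOND\n")
        for bi, (i, j, order) in enumerate(mol.bonds, start=1):
            fh.write(f"{bi:>4} {i + 1:>4} {j + 1:>4} {order}\n")


def write_sdf(mol: MoleculeTopology, conf: Conformer, path: str, append: bool = False) -> None:
    """Write a minimal V2000 SDF record (atom types go to a sidecar)."""
    with open(path, "a" if append else "w") as fh:
        fh.write(f"{mol.name}\n  ffcondense\n\n")
        fh.write(f"{mol.n_atoms:>3}{len(mol.bonds):>3}  0  0  0  0  0  0  0  0999 V2000\n")
        for a, xyz in zip(mol.atoms, conf.coords):
            fh.write(
                f"{xyz[0]:>10.4f}{xyz[1]:>10.4f}{xyz[2]:>10.4f} {a.element:<3} 0  0  0  0  0  0  0  0  0  0  0  0\n"
            )
        for i, j, order in mol.bonds:
            fh.write(f"{i + 1:>3}{j + 1:>3}{order:>3}  0\n")
        fh.write("M  END\n$$$$\n")
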