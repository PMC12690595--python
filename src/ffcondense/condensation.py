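"""Condensation of per-molecule parameter predictions into lookup tables.

A machine-learned force field predicts valence parameters per molecule; many
molecules share the same atom-type environment, so each (category, atom-type
tuple, parameter name) accumulates a numerical distribution of predicted
values.  Condensation collapses each distribution into one representative
value (mean, median or mode) stored in an atom-type-keyed lookup table,
trading the per-molecule inference cost for a constant-time table lookup.

Only bonded categories (bond, angle, proper, improper) are condensed;
non-bonded parameters pass through from their source unchanged.
"""

from __future__ import annotations

import datetime
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, UnitError

__all__ = [
    "ParameterRecord",
    "InteractionKey",
    "ParameterDistribution",
    "CondensationTable",
    "canonical_key",
    "canonical_type_tuple",
    "accumulate",
    "AccumulationResult",
    "condense",
    "write_table",
    "read_table",
    "read_records_jsonl",
    "write_records_jsonl",
]

CATEGORIES = ("bond", "angle", "proper", "improper")
_ARITY = {"bond": 2, "angle": 3, "proper": 4, "improper": 4}

# unit registry: tag -> (dimension, factor to internal units)
_BOHR = 0.529177210903
_HARTREE = 2625.4996394799
_KCAL = 4.184
UNITS: dict[str, tuple[str, float]] = {
    "A": ("length", 1.0),
    "angstrom": ("length", 1.0),
    "nm": ("length", 10.0),
    "bohr": ("length", _BOHR),
    "rad": ("angle", 1.0),
    "radian": ("angle", 1.0),
    "deg": ("angle", math.pi / 180.0),
    "degree": ("angle", math.pi / 180.0),
    "kJ/mol": ("energy", 1.0),
    "kcal/mol": ("energy", _KCAL),
    "hartree": ("energy", _HARTREE),
    "kJ/mol/A^2": ("energy/length^2", 1.0),
    "kcal/mol/A^2": ("energy/length^2", _KCAL),
    "kJ/mol/rad^2": ("energy/angle^2", 1.0),
    "kcal/mol/rad^2": ("energy/angle^2", _KCAL),
    "kJ/mol/A/rad": ("energy/length/angle", 1.0),
    "kcal/mol/A/rad": ("energy/length/angle", _KCAL),
    "1/A": ("1/length", 1.0),
    "1/rad": ("1/angle", 1.0),
    "e": ("charge", 1.0),
    "dimensionless": ("1", 1.0),
}


@dataclass(frozen=True)
class ParameterRecord:
    """One predicted parameter value for one interaction of one molecule."""

    molecule_id: str
    category: str
    atom_type_tuple: tuple[int, ...]
    parameter_name: str
    value: float
    unit: str

    def validate(self) -> None:
        if self.category not in CATEGORIES:
            raise SchemaError(f"unknown category {self.category!r}")
        if len(self.atom_type_tuple) != _ARITY[self.category]:
            raise SchemaError(
                f"{self.category} key must have {_ARITY[self.category]} atom types, "
                f"got {self.atom_type_tuple}"
            )
        if self.unit not in UNITS:
            raise UnitError(f"unknown unit tag {self.unit!r}")
        if not math.isfinite(self.value):
            raise SchemaError(f"non-finite value for {self.parameter_name}")


@dataclass(frozen=True, order=True)
class InteractionKey:
    """Group-by key of the condensation table: category + canonical
    atom-type tuple."""

    category: str
    types: tuple[int, ...]

    def __str__(self) -> str:
        return f"{self.category}:{'-'.join(map(str, self.types))}"


def canonical_type_tuple(category: str, t: tuple[int, ...]) -> tuple[tuple[int, ...], bool]:
    """Canonical orientation of an atom-type tuple; the flag reports whether
    the tuple was reversed (orientation-sensitive parameters must swap)."""
    t = tuple(int(x) for x in t)
    if category == "bond":
        return (t, False) if t[0] <= t[1] else ((t[1], t[0]), True)
    if category == "angle":
        return (t, False) if t[0] <= t[2] else ((t[2], t[1], t[0]), True)
    if category == "proper":
        rev = t[::-1]
        return (t, False) if t <= rev else (rev, True)
    if category == "improper":
        return ((t[0],) + tuple(sorted(t[1:])), False)
    raise SchemaError(f"unknown category {category!r}")


def canonical_key(category: str, atom_type_tuple: tuple[int, ...]) -> InteractionKey:
    if category not in CATEGORIES:
        raise SchemaError(f"unknown category {category!r}")
    if len(atom_type_tuple) != _ARITY[category]:
        raise SchemaError(
            f"{category} key needs {_ARITY[category]} atom types, got {atom_type_tuple}"
        )
    ct, _ = canonical_type_tuple(category, atom_type_tuple)
    return InteractionKey(category, ct)


@dataclass
class ParameterDistribution:
    """All accumulated values for one (key, parameter name)."""

    key: InteractionKey
    parameter_name: str
    values: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class AccumulationResult:
    distributions: dict[tuple[InteractionKey, str], ParameterDistribution]
    n_accepted: int = 0
    n_skipped: int = 0


def accumulate(records) -> AccumulationResult:
    """Pool a stream of ParameterRecords into per-key distributions.

    Values are converted to internal units on ingest.  Malformed records
    (bad arity, category or non-finite value) are counted and skipped;
    a unit-dimension clash within one parameter name is a hard error.
    """
    out = AccumulationResult(distributions={})
    dims: dict[str, str] = {}
    for rec in records:
        try:
            rec.validate()
        except (SchemaError,) as _:
            out.n_skipped += 1
            continue
        dim, factor = UNITS[rec.unit]
        prev = dims.setdefault(rec.parameter_name, dim)
        if prev != dim:
            raise UnitError(
                f"unit clash for {rec.parameter_name!r}: {prev} vs {dim}"
            )
        key = canonical_key(rec.category, rec.atom_type_tuple)
        dk = (key, rec.parameter_name)
        dist = out.distributions.get(dk)
        if dist is None:
            dist = out.distributions[dk] = ParameterDistribution(key, rec.parameter_name)
        dist.values.append(rec.value * factor)
        out.n_accepted += 1
    return out


@dataclass
class CondensedValue:
    value: float
    n: int
    statistic: str


@dataclass
class CondensationTable:
    """InteractionKey -> {parameter_name -> condensed value with count}."""

    entries: dict[InteractionKey, dict[str, CondensedValue]]
    statistic: str
    source: str = ""
    created: str = ""
    version: int = 1

    def get(self, key: InteractionKey) -> dict[str, CondensedValue] | None:
        return self.entries.get(key)

    @property
    def n_entries(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def total_count(self) -> int:
        return sum(cv.n for params in self.entries.values() for cv in params.values())


def _mode_fd(values: np.ndarray) -> float:
    """Mode estimate: midpoint of the most populated Freedman-Diaconis
    histogram bin, ties broken toward the lower bin."""
    if values.size == 1 or float(np.ptp(values)) == 0.0:
        return float(values[0])
    q75, q25 = np.percentile(values, [75, 25])
    width = 2.0 * (q75 - q25) / values.size ** (1.0 / 3.0)
    if width <= 0.0:
        # degenerate IQR; fall back to Sturges bin count
        nbins = max(1, int(np.ceil(np.log2(values.size) + 1)))
    else:
        nbins = max(1, int(np.ceil(float(np.ptp(values)) / width)))
    counts, edges = np.histogram(values, bins=nbins)
    imax = int(np.argmax(counts))  # argmax takes the first (lower) maximal bin
    return float(0.5 * (edges[imax] + edges[imax + 1]))


def _condense_one(values: list[float], statistic: str) -> float:
    arr = np.asarray(values, dtype=float)
    if float(arr.min()) == float(arr.max()):
        # delta distribution: every statistic reproduces the value exactly,
        # without accumulation rounding
        return float(arr[0])
    if statistic == "mean":
        return float(np.mean(arr))
    if statistic == "median":
        return float(np.median(arr))
    if statistic == "mode":
        return _mode_fd(arr)
    raise SchemaError(f"unknown statistic {statistic!r}")


def condense(
    acc: AccumulationResult | dict,
    statistic: str = "mean",
    min_count: int = 1,
    source: str = "",
) -> CondensationTable:
    """Collapse each distribution to its representative value.

    ``statistic``: mean (default — the representative value), median, or
    mode (Freedman-Diaconis histogram bin midpoint).  Distributions with
    fewer than ``min_count`` values are excluded from the table.
    """
    dists = acc.distributions if isinstance(acc, AccumulationResult) else acc
    entries: dict[InteractionKey, dict[str, CondensedValue]] = {}
    for (key, pname), dist in sorted(dists.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        if dist.n < max(1, min_count):
            continue
        entries.setdefault(key, {})[pname] = CondensedValue(
            _condense_one(dist.values, statistic), dist.n, statistic
        )
    return CondensationTable(
        entries=entries,
        statistic=statistic,
        source=source,
        created=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )


# ---------------------------------------------------------------------------
# serialization

_CSV_COLUMNS = ["category", "types", "parameter", "value", "n", "statistic"]


def _meta_path(path: str) -> str:
    return str(path) + ".meta.json"


def write_table(table: CondensationTable, path: str) -> None:
    """CSV table (category, dash-joined type tuple, parameter, value, n,
    statistic) plus a JSON metadata sidecar at ``<path>.meta.json``."""
    rows = []
    for key in sorted(table.entries):
        for pname in sorted(table.entries[key]):
            cv = table.entries[key][pname]
            rows.append(
                {
                    "category": key.category,
                    "types": "-".join(map(str, key.types)),
                    "parameter": pname,
                    "value": cv.value,
                    "n": cv.n,
                    "statistic": cv.statistic,
                }
            )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False, float_format="%.12g")
    with open(_meta_path(path), "w") as fh:
        json.dump(
            {
                "format": "ffcondense-table",
                "version": table.version,
                "statistic": table.statistic,
                "source": table.source,
                "created": table.created,
                "units": {"length": "angstrom", "angle": "radian", "energy": "kJ/mol"},
            },
            fh,
            indent=1,
        )


def read_table(path: str) -> CondensationTable:
    try:
        with open(_meta_path(path)) as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        raise FormatError(f"missing metadata sidecar {_meta_path(path)}")
    if meta.get("format") != "ffcondense-table" or meta.get("version") != 1:
        raise FormatError(f"{path}: unsupported table format/version")
    df = pd.read_csv(path)
    if list(df.columns) != _CSV_COLUMNS:
        raise FormatError(f"{path}: unexpected columns {list(df.columns)}")
    entries: dict[InteractionKey, dict[str, CondensedValue]] = {}
    for row in df.itertuples(index=False):
        key = InteractionKey(row.category, tuple(int(x) for x in str(row.types).split("-")))
        params = entries.setdefault(key, {})
        if row.parameter in params:
            raise FormatError(
                f"{path}: duplicate row for key {key} parameter {row.parameter}"
            )
        params[row.parameter] = CondensedValue(float(row.value), int(row.n), str(row.statistic))
    return CondensationTable(
        entries=entries,
        statistic=meta["statistic"],
        source=meta.get("source", ""),
        created=meta.get("created", ""),
        version=meta["version"],
    )


def write_records_jsonl(records, path: str) -> int:
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                json.dumps(
                    {
                        "molecule_id": rec.molecule_id,
                        "category": rec.category,
                        "atom_type_tuple": list(rec.atom_type_tuple),
                        "parameter_name": rec.parameter_name,
                        "value": rec.value,
                        "unit": rec.unit,
                    }
                )
                + "\n"
            )
            n += 1
    return n


def read_records_jsonl(path: str):
    """Yield ParameterRecords from a JSON-lines file."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                doc = json.loads(line)
                yield ParameterRecord(
                    molecule_id=str(doc["molecule_id"]),
                    category=str(doc["category"]),
                    atom_type_tuple=tuple(int(x) for x in doc["atom_type_tuple"]),
                    parameter_name=str(doc["parameter_name"]),
                    value=float(doc["value"]),
                    unit=str(doc["unit"]),
                )
            except (KeyError, ValueError, json.JSONDecodeError) as exc:
                raise FormatError(f"{path}:{lineno}: bad record ({exc})")
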