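"""Nano-descriptor construction.

Three descriptor families are built from the exposure table:

* **raw** — diameter, concentration and the parsed doping percent;
* **onehot** — per-level binary indicators for core, doping and coating;
* **elemental** — constants of the core's "active metal" (the metallic
  element of the formula) looked up in an embedded element table, plus
  simple formula counts;
* **combined** — arithmetic combinations of existing columns, by default
  the two products/ratios that drive the dose response: concentration ×
  PMAA-coating indicator and concentration / diameter.
"""

from __future__ import annotations

import hashlib
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import OneHotEncoder as _SkOneHot

from .data import ENMDataset, NO_DOPING
from .errors import ElementLookupError, FormulaParseError, SchemaError

#: Provenance tags a descriptor column may carry.
PROVENANCE_TAGS = ("raw", "onehot", "elemental", "combined")

#: Column-name prefixes used for the one-hot indicator columns.
ONEHOT_PREFIX = {"Core": "core", "Doping": "dop", "Surface_Coating": "coat"}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_DOPING = re.compile(r"^\s*([A-Z][a-z]?)\s*\(\s*([0-9.]+)\s*%\s*\)\s*$")


# ---------------------------------------------------------------------------
# Element table

@dataclass(frozen=True)
class ElementTable:
    """Per-element constants backing the elemental descriptors."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if (f["atomic_number"] <= 0).any() or (f["vdw_radius_pm"] <= 0).any():
            raise ValueError("element table contains non-positive constants")

    @classmethod
    def load(cls, path: str | Path | None = None) -> "ElementTable":
        """Load the embedded (or a user-supplied) element constants CSV."""
        if path is None:
            ref = resources.files("nanoqstr.resources") / "element_table.csv"
            with resources.as_file(ref) as p:
                frame = pd.read_csv(p, comment="#")
        else:
            frame = pd.read_csv(path, comment="#")
        return cls(frame=frame.set_index("symbol", drop=False))

    def lookup(self, symbol: str) -> pd.Series:
        try:
            return self.frame.loc[symbol]
        except KeyError:
            raise ElementLookupError(
                f"element {symbol!r} is not in the embedded element table"
            ) from None

    def is_metal(self, symbol: str) -> bool:
        return str(self.lookup(symbol)["classification"]) == "metal"

    @staticmethod
    def checksum() -> str:
        """SHA-256 of the shipped element table file (version pin)."""
        ref = resources.files("nanoqstr.resources") / "element_table.csv"
        with resources.as_file(ref) as p:
            return hashlib.sha256(Path(p).read_bytes()).hexdigest()


def parse_formula(core: str) -> dict[str, int]:
    """Parse a composition label like ``"Fe3O4"`` into element counts."""
    core = core.strip()
    if not core:
        raise FormulaParseError("empty composition label")
    pos = 0
    counts: dict[str, int] = {}
    for m in _FORMULA_TOKEN.finditer(core):
        if m.start() != pos:
            raise FormulaParseError(
                f"unparseable token {core[pos:m.start()]!r} in formula {core!r}"
            )
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(core) or not counts:
        raise FormulaParseError(f"unparseable token {core[pos:]!r} in formula {core!r}")
    return counts


def parse_doping(doping: str) -> tuple[str | None, float]:
    """Split a doping label into (element symbol, percent); ``"ND"`` -> (None, 0)."""
    if doping.strip().upper() == NO_DOPING:
        return None, 0.0
    m = _DOPING.match(doping)
    if not m:
        raise FormulaParseError(f"unparseable doping label {doping!r}")
    return m.group(1), float(m.group(2))


def active_metal(counts: Mapping[str, int], table: ElementTable) -> str | None:
    """The metallic element of a core formula.

    When several metals occur, the one with the largest stoichiometric
    count wins; ties break toward the higher atomic number. Returns
    ``None`` for metal-free cores (semimetals such as Si do not count).
    """
    metals = [s for s in counts if table.is_metal(s)]
    if not metals:
        return None
    return max(metals, key=lambda s: (counts[s], int(table.lookup(s)["atomic_number"])))


#: Order of the elemental descriptor vector.
ELEMENTAL_NAMES = (
    "n_metallic_elements",
    "active_metal_electrons",
    "active_metal_vdw_radius",
    "active_metal_electronegativity",
    "active_metal_ionization_energy",
    "n_oxygen_atoms",
    "n_atoms",
    "doping_percent",
)


def elemental_descriptors(
    core: str, doping: str = NO_DOPING, table: ElementTable | None = None
) -> dict[str, float]:
    """Elemental descriptor vector for one (core, doping) pair.

    A pure function of its inputs: the number of metallic elements
    (core plus dopant), constants of the active metal (electron count,
    van der Waals radius, Pauling electronegativity, first ionization
    energy), the oxygen and total atom counts of the core formula, and
    the parsed doping percent. For a metal-free core the active-metal
    constants are 0 (the semimetal/nonmetal core carries no active metal).
    """
    table = table or ElementTable.load()
    counts = parse_formula(core)
    dop_el, dop_pct = parse_doping(doping)
    for sym in counts:
        table.lookup(sym)
    n_metals = sum(1 for s in counts if table.is_metal(s))
    if dop_el is not None and table.is_metal(dop_el):
        n_metals += 1
    am = active_metal(counts, table)
    if am is None:
        electrons = radius = chi = ion = 0.0
    else:
        row = table.lookup(am)
        electrons = float(row["atomic_number"])  # neutral atom: electrons == Z
        radius = float(row["vdw_radius_pm"])
        chi = float(row["electronegativity_pauling"])
        ion = float(row["ionization_energy_ev"])
    return {
        "n_metallic_elements": float(n_metals),
        "active_metal_electrons": electrons,
        "active_metal_vdw_radius": radius,
        "active_metal_electronegativity": chi,
        "active_metal_ionization_energy": ion,
        "n_oxygen_atoms": float(counts.get("O", 0)),
        "n_atoms": float(sum(counts.values())),
        "doping_percent": dop_pct,
    }


def sphere_surface_area(diameter: float) -> float:
    """Surface area (nm²) of a perfect sphere of the given diameter (nm)."""
    if diameter <= 0:
        raise ValueError(f"diameter must be > 0, got {diameter}")
    return float(np.pi * diameter**2)


# ---------------------------------------------------------------------------
# Descriptor matrix

@dataclass
class DescriptorMatrix:
    """Named numeric feature columns aligned to dataset rows.

    ``provenance`` maps every column to one of :data:`PROVENANCE_TAGS`.
    """

    frame: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame.columns.duplicated().any():
            dup = self.frame.columns[self.frame.columns.duplicated()].tolist()
            raise SchemaError(f"duplicate descriptor columns: {dup}")
        missing = set(self.frame.columns) - set(self.provenance)
        if missing:
            raise SchemaError(f"columns without provenance tag: {sorted(missing)}")
        bad = {c: t for c, t in self.provenance.items() if t not in PROVENANCE_TAGS}
        if bad:
            raise SchemaError(f"unknown provenance tags: {bad}")
        if self.frame.isna().any().any():
            cols = self.frame.columns[self.frame.isna().any()].tolist()
            raise ValueError(f"descriptor matrix has missing values in {cols}")
        self.frame = self.frame.astype(float)
        self.provenance = {c: self.provenance[c] for c in self.frame.columns}

    # -- views ------------------------------------------------------------
    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def select(self, columns: Sequence[str]) -> "DescriptorMatrix":
        missing = [c for c in columns if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"columns absent from matrix: {missing}")
        return DescriptorMatrix(
            frame=self.frame.loc[:, list(columns)].copy(),
            provenance={c: self.provenance[c] for c in columns},
        )

    def rows(self, indices) -> "DescriptorMatrix":
        return DescriptorMatrix(
            frame=self.frame.iloc[list(indices)].reset_index(drop=True),
            provenance=dict(self.provenance),
        )

    def hstack(self, other: "DescriptorMatrix") -> "DescriptorMatrix":
        if other.n_rows != self.n_rows:
            raise SchemaError("row counts differ in hstack")
        overlap = set(self.columns) & set(other.columns)
        if overlap:
            raise SchemaError(f"duplicate columns in hstack: {sorted(overlap)}")
        return DescriptorMatrix(
            frame=pd.concat(
                [self.frame.reset_index(drop=True), other.frame.reset_index(drop=True)],
                axis=1,
            ),
            provenance={**self.provenance, **other.provenance},
        )

    def columns_by_tag(self, *tags: str) -> list[str]:
        return [c for c in self.columns if self.provenance[c] in tags]

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path: str | Path) -> Path:
        """Write the matrix with a commented provenance header row."""
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#provenance," + ",".join(self.provenance[c] for c in self.columns) + "\n")
            self.frame.to_csv(fh, index=False, float_format="%.12g")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorMatrix":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            first = fh.readline().rstrip("\n")
            if not first.startswith("#provenance,"):
                raise SchemaError(f"{path.name} lacks the provenance header row")
            tags = first.split(",")[1:]
            frame = pd.read_csv(fh)
        if len(tags) != len(frame.columns):
            raise SchemaError("provenance row length does not match the header")
        return cls(frame=frame, provenance=dict(zip(frame.columns, tags)))


# ---------------------------------------------------------------------------
# One-hot encoding

class FrozenOneHot:
    """One-hot encoder with a level -> column mapping frozen at fit time.

    Thin wrapper over scikit-learn's ``OneHotEncoder`` that names the
    indicator columns ``{prefix}_{level}`` and either raises on levels
    unseen at fit time (default) or maps them to all-zero rows
    (``unseen="zeros"``).
    """

    def __init__(self, columns: Sequence[str] = ("Core", "Doping", "Surface_Coating"),
                 unseen: str = "error"):
        if unseen not in ("error", "zeros"):
            raise ValueError("unseen must be 'error' or 'zeros'")
        self.columns = tuple(columns)
        self.unseen = unseen
        self._enc: _SkOneHot | None = None

    def fit(self, ds: ENMDataset) -> "FrozenOneHot":
        df = ds.to_frame()[list(self.columns)]
        if any(df[c].nunique() < 1 for c in self.columns):
            raise ValueError("every categorical column needs at least one level")
        handle = "error" if self.unseen == "error" else "ignore"
        self._enc = _SkOneHot(handle_unknown=handle, sparse_output=False, dtype=float)
        self._enc.fit(df)
        return self

    @property
    def output_columns(self) -> list[str]:
        if self._enc is None:
            raise RuntimeError("encoder is not fitted")
        out = []
        for col, cats in zip(self.columns, self._enc.categories_):
            prefix = ONEHOT_PREFIX.get(col, col.lower())
            out.extend(f"{prefix}_{c}" for c in cats)
        return out

    def transform(self, ds: ENMDataset) -> DescriptorMatrix:
        if self._enc is None:
            raise RuntimeError("encoder is not fitted")
        df = ds.to_frame()[list(self.columns)]
        values = self._enc.transform(df)
        frame = pd.DataFrame(values, columns=self.output_columns)
        return DescriptorMatrix(frame=frame, provenance={c: "onehot" for c in frame.columns})


def one_hot_encode(
    ds: ENMDataset,
    columns: Sequence[str] = ("Core", "Doping", "Surface_Coating"),
    unseen: str = "error",
) -> tuple[DescriptorMatrix, FrozenOneHot]:
    """Fit a frozen one-hot encoding on ``ds`` and return (matrix, encoder)."""
    enc = FrozenOneHot(columns=columns, unseen=unseen).fit(ds)
    return enc.transform(ds), enc


# ---------------------------------------------------------------------------
# Combined descriptors

#: Default pairs combined into new columns: the concentration × PMAA-coating
#: product and the concentration / diameter ratio.
DEFAULT_COMBINE_WHITELIST = (
    ("Concentration_ug_mL", "coat_PMAA", "product"),
    ("Concentration_ug_mL", "Diameter_nm", "ratio"),
)

_OP_SYMBOL = {"product": "*", "sum": "+", "ratio": "/"}


def combine_descriptors(
    m: DescriptorMatrix,
    operators: Iterable[str] = ("product",),
    whitelist: Sequence[tuple[str, str, str]] | None = None,
) -> DescriptorMatrix:
    """Append arithmetic combination columns to a descriptor matrix.

    With ``whitelist=None`` every unordered column pair is combined with
    every requested operator; otherwise only the listed
    ``(left, right, operator)`` triples are built. Combined columns are
    named ``left{op}right`` (e.g. ``"Concentration_ug_mL*coat_PMAA"``).
    Ratio pairs whose denominator contains zeros are skipped with a
    warning. Parent columns are retained.
    """
    if len(m.columns) < 2:
        raise ValueError("need at least 2 columns to combine")
    operators = tuple(operators)
    unknown = [op for op in operators if op not in _OP_SYMBOL]
    if unknown:
        raise ValueError(f"unknown operators: {unknown}")
    if whitelist is None:
        cols = m.columns
        pairs = [
            (cols[i], cols[j], op)
            for i in range(len(cols))
            for j in range(i + 1, len(cols))
            for op in operators
        ]
    else:
        pairs = [(a, b, op) for a, b, op in whitelist]

    new_cols: dict[str, np.ndarray] = {}
    for left, right, op in pairs:
        for c in (left, right):
            if c not in m.frame.columns:
                raise SchemaError(f"combine references unknown column {c!r}")
        x, y = m.frame[left].to_numpy(), m.frame[right].to_numpy()
        name = f"{left}{_OP_SYMBOL[op]}{right}"
        if op == "product":
            new_cols[name] = x * y
        elif op == "sum":
            new_cols[name] = x + y
        else:  # ratio
            if np.any(y == 0):
                warnings.warn(f"skipping ratio {name}: zero denominator", stacklevel=2)
                continue
            new_cols[name] = x / y
    add = DescriptorMatrix(
        frame=pd.DataFrame(new_cols, index=m.frame.index),
        provenance={c: "combined" for c in new_cols},
    )
    return m.hstack(add) if new_cols else m


# ---------------------------------------------------------------------------
# Full feature build

def build_feature_matrix(
    ds: ENMDataset,
    encoder: FrozenOneHot | None = None,
    element_table: ElementTable | None = None,
    include_elemental: bool = True,
    combine_whitelist: Sequence[tuple[str, str, str]] | None = DEFAULT_COMBINE_WHITELIST,
) -> tuple[DescriptorMatrix, FrozenOneHot]:
    """Assemble the full descriptor matrix for a dataset.

    Raw columns, one-hot indicators (using ``encoder`` if given, else
    fitting a fresh one on ``ds``), elemental descriptors, and the
    default combined columns. Combination pairs whose parents are absent
    (e.g. no PMAA-coated ENM in the data) are dropped with a warning.
    """
    df = ds.to_frame()
    raw = DescriptorMatrix(
        frame=df[["Diameter_nm", "Concentration_ug_mL"]].copy(),
        provenance={"Diameter_nm": "raw", "Concentration_ug_mL": "raw"},
    )
    if encoder is None:
        onehot, encoder = one_hot_encode(ds)
    else:
        onehot = encoder.transform(ds)
    m = raw.hstack(onehot)
    if include_elemental:
        table = element_table or ElementTable.load()
        rows = [elemental_descriptors(r.core, r.doping, table) for r in ds]
        elem = DescriptorMatrix(
            frame=pd.DataFrame(rows, columns=list(ELEMENTAL_NAMES)),
            provenance={c: "elemental" for c in ELEMENTAL_NAMES},
        )
        m = m.hstack(elem)
    if combine_whitelist:
        usable = []
        for left, right, op in combine_whitelist:
            if left in m.frame.columns and right in m.frame.columns:
                usable.append((left, right, op))
            else:
                warnings.warn(
                    f"combination {left}/{right} skipped: parent column missing",
                    stacklevel=2,
                )
        if usable:
            m = combine_descriptors(m, operators=("product", "ratio"), whitelist=usable)
    return m, encoder
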