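"""Data model and delimited-file I/O for ENM exposure datasets.

One row of the dataset is a single exposure observation: an engineered
nanomaterial (ENM) described by its core composition, doping, surface
coating and diameter, exposed to A549 cells at one concentration, with
the measured cell viability in percent of untreated control. Viability
is stored as printed percent (e.g. ``96.0``), never as a fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import EmptyDatasetError, RowParseError, SchemaError

#: Canonical CSV header, in column order.
CANONICAL_COLUMNS = (
    "ENM_ID",
    "Core",
    "Doping",
    "Surface_Coating",
    "Diameter_nm",
    "Concentration_ug_mL",
    "Cell_Viability_pct",
)

#: Sentinel for an undoped ENM ("no doping").
NO_DOPING = "ND"
#: Sentinel for an uncoated ENM ("no surface coating").
NO_COATING = "NSC"


def _normalize_sentinel(value: str, sentinel: str) -> str:
    value = str(value).strip()
    return sentinel if value.upper() == sentinel else value


@dataclass(frozen=True)
class ENMRecord:
    """One exposure observation.

    Parameters
    ----------
    enm_id : str
        Identifier of the nanomaterial the observation belongs to.
    core : str
        Core composition label, e.g. ``"ZnO"`` or ``"Fe3O4"``.
    diameter : float
        Particle diameter in nm (> 0).
    concentration : float
        Exposure dose in µg/mL (>= 0).
    viability : float
        Cell viability in percent of control (>= 0; values above 100
        occur and are kept).
    doping : str
        Dopant label with percent, e.g. ``"Na (1.5%)"``, or ``"ND"``.
    coating : str
        Surface-coating label, e.g. ``"PEG"``, or ``"NSC"``.
    """

    enm_id: str
    core: str
    diameter: float
    concentration: float
    viability: float
    doping: str = NO_DOPING
    coating: str = NO_COATING

    def __post_init__(self) -> None:
        object.__setattr__(self, "enm_id", str(self.enm_id).strip())
        object.__setattr__(self, "core", str(self.core).strip())
        object.__setattr__(self, "doping", _normalize_sentinel(self.doping, NO_DOPING))
        object.__setattr__(self, "coating", _normalize_sentinel(self.coating, NO_COATING))
        if not self.enm_id:
            raise ValueError("enm_id must be non-empty")
        if not self.core:
            raise ValueError("core label must be non-empty")
        if not self.doping or not self.coating:
            raise ValueError("doping/coating must use explicit sentinels, not empty strings")
        for name in ("diameter", "concentration", "viability"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            object.__setattr__(self, name, v)
        if self.diameter <= 0:
            raise ValueError(f"diameter must be > 0, got {self.diameter}")
        if self.concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration}")
        if self.viability < 0:
            raise ValueError(f"viability must be >= 0, got {self.viability}")


@dataclass(frozen=True)
class ENMDataset:
    """Ordered collection of :class:`ENMRecord` with a provenance tag."""

    records: tuple[ENMRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[tuple[str, float]] = set()
        for rec in self.records:
            key = (rec.enm_id, rec.concentration)
            if key in seen:
                raise ValueError(f"duplicate (enm_id, concentration) pair: {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ENMRecord]:
        return iter(self.records)

    @property
    def enm_ids(self) -> tuple[str, ...]:
        """Distinct ENM ids in first-appearance order."""
        out: list[str] = []
        for rec in self.records:
            if rec.enm_id not in out:
                out.append(rec.enm_id)
        return tuple(out)

    @property
    def viability(self):
        import numpy as np

        return np.array([r.viability for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Render the dataset as a DataFrame with the canonical header."""
        return pd.DataFrame(
            {
                "ENM_ID": [r.enm_id for r in self.records],
                "Core": [r.core for r in self.records],
                "Doping": [r.doping for r in self.records],
                "Surface_Coating": [r.coating for r in self.records],
                "Diameter_nm": [r.diameter for r in self.records],
                "Concentration_ug_mL": [r.concentration for r in self.records],
                "Cell_Viability_pct": [r.viability for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "ENMDataset":
        records = []
        for i, row in enumerate(df.itertuples(index=False)):
            try:
                records.append(
                    ENMRecord(
                        enm_id=row.ENM_ID,
                        core=row.Core,
                        doping=row.Doping,
                        coating=row.Surface_Coating,
                        diameter=row.Diameter_nm,
                        concentration=row.Concentration_ug_mL,
                        viability=row.Cell_Viability_pct,
                    )
                )
            except (TypeError, ValueError) as exc:
                raise RowParseError(f"row {i}: {exc}", row=i) from exc
        return cls(records=tuple(records), provenance=provenance)

    def subset(self, indices: Iterable[int], provenance: str | None = None) -> "ENMDataset":
        recs = tuple(self.records[i] for i in indices)
        return ENMDataset(records=recs, provenance=provenance or self.provenance)


def read_dataset(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> ENMDataset:
    """Read an ENM exposure dataset from a delimited (CSV) file.

    Parameters
    ----------
    path : path-like
        CSV file with one observation per row.
    dialect : mapping, optional
        Maps canonical column names (:data:`CANONICAL_COLUMNS`) to the
        column names used in the file, for supplementary spreadsheets
        exported with different headers. Identity by default.

    Raises
    ------
    SchemaError
        If a mapped column is absent.
    RowParseError
        If a numeric cell cannot be parsed (reports the row index).
    EmptyDatasetError
        If the file holds a header but no data rows.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    mapping = {c: c for c in CANONICAL_COLUMNS}
    if dialect:
        mapping.update({k: v for k, v in dialect.items() if k in mapping})
    missing = [src for src in mapping.values() if src not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) in {path.name}: {', '.join(missing)}")
    if len(df) == 0:
        raise EmptyDatasetError(f"{path.name} contains a header but no data rows")
    out = pd.DataFrame({canon: df[src] for canon, src in mapping.items()})
    for col in ("Diameter_nm", "Concentration_ug_mL", "Cell_Viability_pct"):
        values = []
        for i, cell in enumerate(out[col]):
            try:
                values.append(float(cell))  # correctly-rounded, bit-exact
            except ValueError:
                raise RowParseError(
                    f"unparseable numeric value {cell!r} in column {col}, row {i}",
                    row=i,
                ) from None
        out[col] = values
    return ENMDataset.from_frame(out, provenance=str(path))


def write_dataset(ds: ENMDataset, path: str | Path) -> Path:
    """Write a dataset as CSV with the canonical header.

    Floats are written with the shortest round-trip representation, so
    the printed form ("104.79") is preserved and a read-back yields
    bit-identical values. The dataset must be non-empty.
    """
    if len(ds) == 0:
        raise EmptyDatasetError("refusing to write an empty dataset")
    path = Path(path)
    ds.to_frame().to_csv(path, index=False)
    return path
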