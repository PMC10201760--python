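"""Pre-processing: diameter filter, z-score standardization, Yeo-Johnson.

The pipeline's pre-processing order is fixed: diameter filter ->
categorical encoding -> descriptor build -> z-score -> Yeo-Johnson.
Transform parameters are fitted on a designated subset (normally the
training rows) and frozen into an immutable :class:`TransformState`;
applying a state never recomputes statistics, so a single new row can
always be transformed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import ENMDataset
from .errors import ConfigError, ConstantColumnError, SchemaError
from .descriptors import DescriptorMatrix

#: The only admissible ordering of the two numeric transforms.
CANONICAL_TRANSFORM_ORDER = ("zscore", "yeojohnson")


def validate_transform_order(order: Sequence[str]) -> tuple[str, ...]:
    """Reject any transform ordering other than z-score then Yeo-Johnson."""
    order = tuple(order)
    if order != CANONICAL_TRANSFORM_ORDER:
        raise ConfigError(
            f"transform order must be {CANONICAL_TRANSFORM_ORDER}, got {order}: "
            "standardization precedes the Yeo-Johnson transformation"
        )
    return order


@dataclass(frozen=True)
class FilterResult:
    """Outcome of the diameter filter."""

    dataset: ENMDataset
    n_kept: int
    n_dropped: int
    enms_kept: tuple[str, ...]
    enms_dropped: tuple[str, ...]
    threshold: float


def filter_by_diameter(ds: ENMDataset, threshold: float = 200.0) -> FilterResult:
    """Keep the records with diameter strictly below ``threshold`` (nm).

    Row order is preserved; an empty result is allowed.
    """
    if threshold <= 0 and threshold != 0:
        raise ValueError("threshold must be >= 0")
    kept = [i for i, r in enumerate(ds) if r.diameter < threshold]
    dropped_ids = tuple(
        eid for eid in ds.enm_ids
        if eid not in {ds.records[i].enm_id for i in kept}
    )
    sub = ds.subset(kept, provenance=f"{ds.provenance}|diameter<{threshold:g}nm")
    return FilterResult(
        dataset=sub,
        n_kept=len(kept),
        n_dropped=len(ds) - len(kept),
        enms_kept=sub.enm_ids,
        enms_dropped=dropped_ids,
        threshold=threshold,
    )


@dataclass(frozen=True)
class TransformState:
    """Frozen per-column transform parameters.

    ``kind`` is ``"zscore"`` (stores mean/SD per Eq. X' = (X - µ)/σ) or
    ``"yeojohnson"`` (stores the maximum-likelihood λ per column).
    """

    kind: str
    columns: tuple[str, ...]
    mean: dict[str, float] | None = None
    sd: dict[str, float] | None = None
    lmbda: dict[str, float] | None = None
    ddof: int = 0
    fit_subset: str = "train"

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kind": self.kind,
            "columns": list(self.columns),
            "mean": self.mean,
            "sd": self.sd,
            "lmbda": self.lmbda,
            "ddof": self.ddof,
            "fit_subset": self.fit_subset,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TransformState":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            kind=d["kind"],
            columns=tuple(d["columns"]),
            mean=d.get("mean"),
            sd=d.get("sd"),
            lmbda=d.get("lmbda"),
            ddof=int(d.get("ddof", 0)),
            fit_subset=d.get("fit_subset", "train"),
        )


def _transform_columns(m: DescriptorMatrix, columns: Sequence[str] | None) -> list[str]:
    """Default transform targets: every non-indicator numeric column."""
    if columns is not None:
        missing = [c for c in columns if c not in m.frame.columns]
        if missing:
            raise SchemaError(f"columns absent from matrix: {missing}")
        return list(columns)
    return [c for c in m.columns if m.provenance[c] != "onehot"]


def zscore_fit(
    m: DescriptorMatrix,
    columns: Sequence[str] | None = None,
    ddof: int = 0,
    fit_subset: str = "train",
) -> TransformState:
    """Fit per-column mean and SD for z-score standardization.

    Population SD (``ddof=0``) by default. One-hot indicator columns are
    excluded unless explicitly listed. Constant columns are an error —
    remove them (variance filter) before standardizing.
    """
    cols = _transform_columns(m, columns)
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for c in cols:
        x = m.frame[c].to_numpy()
        if not np.all(np.isfinite(x)):
            raise ValueError(f"non-finite values in column {c!r}")
        s = float(x.std(ddof=ddof))
        if s == 0.0:
            raise ConstantColumnError(f"column {c!r} is constant (sd = 0) on the fit data")
        mean[c] = float(x.mean())
        sd[c] = s
    return TransformState(kind="zscore", columns=tuple(cols), mean=mean, sd=sd,
                          ddof=ddof, fit_subset=fit_subset)


def zscore_apply(state: TransformState, m: DescriptorMatrix) -> DescriptorMatrix:
    """Apply a fitted z-score state using only its stored µ and σ."""
    if state.kind != "zscore":
        raise ValueError(f"expected a zscore state, got {state.kind!r}")
    missing = [c for c in state.columns if c not in m.frame.columns]
    if missing:
        raise SchemaError(f"matrix lacks columns of the transform state: {missing}")
    frame = m.frame.copy()
    for c in state.columns:
        frame[c] = (frame[c] - state.mean[c]) / state.sd[c]
    return DescriptorMatrix(frame=frame, provenance=dict(m.provenance))


def yeojohnson_fit(
    m: DescriptorMatrix,
    columns: Sequence[str] | None = None,
    fit_subset: str = "train",
) -> TransformState:
    """Fit the Yeo-Johnson λ per column by maximum likelihood.

    λ maximizes the Yeo-Johnson log-likelihood on the fit data (the
    piecewise power transform valid on all of R). Delegates the
    optimization to ``scipy.stats.yeojohnson``.
    """
    cols = _transform_columns(m, columns)
    lmbda: dict[str, float] = {}
    for c in cols:
        x = m.frame[c].to_numpy()
        if not np.all(np.isfinite(x)):
            raise ValueError(f"non-finite values in column {c!r}")
        _, lam = stats.yeojohnson(x)
        lmbda[c] = float(lam)
    return TransformState(kind="yeojohnson", columns=tuple(cols), lmbda=lmbda,
                          fit_subset=fit_subset)


def yeojohnson_apply(state: TransformState, m: DescriptorMatrix) -> DescriptorMatrix:
    """Apply a fitted Yeo-Johnson state using only its stored λ."""
    if state.kind != "yeojohnson":
        raise ValueError(f"expected a yeojohnson state, got {state.kind!r}")
    missing = [c for c in state.columns if c not in m.frame.columns]
    if missing:
        raise SchemaError(f"matrix lacks columns of the transform state: {missing}")
    frame = m.frame.copy()
    for c in state.columns:
        frame[c] = stats.yeojohnson(frame[c].to_numpy(), lmbda=state.lmbda[c])
    return DescriptorMatrix(frame=frame, provenance=dict(m.provenance))


def yeojohnson_transform(x: np.ndarray, lmbda: float) -> np.ndarray:
    """The Yeo-Johnson transform at a fixed λ (thin scipy wrapper)."""
    return stats.yeojohnson(np.asarray(x, dtype=float), lmbda=lmbda)
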