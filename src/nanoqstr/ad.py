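"""Standardization-approach applicability domain (AD).

Each query sample's descriptors are standardized against the training
reference as absolute deviations, ``S_ki = |x_ki - µ_i| / σ_i``; the
sample score is

    ``S_new(k) = S̄_k + 1.28 · σ_Sk``

(the mean plus 1.28 population SDs of the sample's standardized
descriptor values — 1.28 being the one-sided 90th-percentile normal
quantile). A sample with ``S_new <= 3`` lies inside the domain (or, for
training rows, is not an outlier). Absolute deviations are used rather
than signed z-scores because a mean of signed scores can cancel; the
rule presumes a magnitude. A stricter published variant additionally
requires ``max_i S_ki <= 3`` (``strict=True``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix
from .errors import ConstantColumnError, SchemaError

#: One-sided 90th-percentile standard-normal quantile used by the score.
K_FACTOR = 1.28
#: Decision threshold of the standardization approach.
S_THRESHOLD = 3.0


@dataclass(frozen=True)
class ADResult:
    """Per-sample applicability-domain summary."""

    index: int
    s_mean: float
    s_sd: float
    s_max: float
    s_new: float
    inside: bool


@dataclass
class ADReport:
    """AD assessment of a query matrix against a training reference."""

    results: list[ADResult]
    columns: tuple[str, ...]
    train_mean: dict[str, float]
    train_sd: dict[str, float]
    threshold: float = S_THRESHOLD
    strict: bool = False

    @property
    def s_new(self) -> np.ndarray:
        return np.array([r.s_new for r in self.results])

    @property
    def inside(self) -> np.ndarray:
        return np.array([r.inside for r in self.results])

    @property
    def all_inside(self) -> bool:
        return bool(self.inside.all())

    @property
    def fraction_inside(self) -> float:
        return float(self.inside.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [r.index for r in self.results],
                "S_mean": [r.s_mean for r in self.results],
                "S_sd": [r.s_sd for r in self.results],
                "S_max": [r.s_max for r in self.results],
                "S_new": [r.s_new for r in self.results],
                "inside": [r.inside for r in self.results],
            }
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.10g")
        return path

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "threshold": self.threshold,
            "strict": self.strict,
            "columns": list(self.columns),
            "n": len(self.results),
            "n_inside": int(self.inside.sum()),
            "fraction_inside": self.fraction_inside,
            "s_new": [r.s_new for r in self.results],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def ad_assess(
    train: DescriptorMatrix,
    query: DescriptorMatrix,
    threshold: float = S_THRESHOLD,
    strict: bool = False,
    ddof: int = 0,
) -> ADReport:
    """Assess every query row against the training descriptor space.

    ``query`` columns must be a subset of (here: equal to) the training
    columns; constant training columns are an error because σ = 0 leaves
    the standardized deviation undefined. Training rows themselves may
    be passed as the query for outlier screening.
    """
    missing = [c for c in train.columns if c not in query.frame.columns]
    if missing:
        raise SchemaError(f"query lacks training columns: {missing}")
    cols = list(train.columns)
    xt = train.frame[cols].to_numpy()
    mu = xt.mean(axis=0)
    sd = xt.std(axis=0, ddof=ddof)
    constant = [c for c, s in zip(cols, sd) if s == 0]
    if constant:
        raise ConstantColumnError(
            f"constant training column(s) (σ = 0): {constant}"
        )
    xq = query.frame[cols].to_numpy()
    s = np.abs(xq - mu) / sd
    s_mean = s.mean(axis=1)
    s_sd = s.std(axis=1)  # population SD across descriptors of one sample
    s_max = s.max(axis=1)
    s_new = s_mean + K_FACTOR * s_sd
    inside = s_new <= threshold
    if strict:
        inside = inside | (s_max <= threshold)
    results = [
        ADResult(index=i, s_mean=float(s_mean[i]), s_sd=float(s_sd[i]),
                 s_max=float(s_max[i]), s_new=float(s_new[i]), inside=bool(inside[i]))
        for i in range(len(xq))
    ]
    return ADReport(
        results=results,
        columns=tuple(cols),
        train_mean={c: float(m) for c, m in zip(cols, mu)},
        train_sd={c: float(v) for c, v in zip(cols, sd)},
        threshold=threshold,
        strict=strict,
    )
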