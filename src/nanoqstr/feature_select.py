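"""Descriptor selection: variance filter, inter-correlation filter,
permutation importance and top-k selection.

Each filter is a projection (applying it twice equals applying it once)
and emits a :class:`SelectionReport` recording what was dropped and why.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix
from .errors import SchemaError


@dataclass
class SelectionReport:
    """Audit trail of the selection steps."""

    dropped_low_variance: dict[str, float] = field(default_factory=dict)
    #: (dropped, survivor, |r|) triples from the correlation filter.
    dropped_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    #: column -> (mean importance, SD over repeats)
    importance_scores: dict[str, tuple[float, float]] = field(default_factory=dict)
    selected: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dropped_low_variance": self.dropped_low_variance,
            "dropped_correlated": [list(t) for t in self.dropped_correlated],
            "importance_scores": {k: list(v) for k, v in self.importance_scores.items()},
            "selected": list(self.selected),
        }


def variance_filter(
    m: DescriptorMatrix, threshold: float = 0.0
) -> tuple[DescriptorMatrix, SelectionReport]:
    """Drop columns whose (population) variance is <= ``threshold``.

    The default threshold 0 removes constants only.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    report = SelectionReport()
    keep = []
    for c in m.columns:
        var = float(m.frame[c].to_numpy().var())
        if var <= threshold:
            report.dropped_low_variance[c] = var
        else:
            keep.append(c)
    return m.select(keep), report


def correlation_filter(
    m: DescriptorMatrix,
    threshold: float = 0.95,
    target: np.ndarray | None = None,
) -> tuple[DescriptorMatrix, SelectionReport]:
    """Greedily remove one member of every pair with |Pearson r| > threshold.

    Pairs are scanned in column order. From an offending pair the member
    with the lower |correlation to target| is dropped; without a target
    the later column is dropped. The surviving matrix has no pair above
    the threshold.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    cols = m.columns
    x = m.frame.to_numpy()
    # np.corrcoef warns on constant columns; treat their r as 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    if target is not None:
        target = np.asarray(target, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            tcorr = np.array(
                [abs(np.corrcoef(x[:, j], target)[0, 1]) for j in range(len(cols))]
            )
        tcorr = np.nan_to_num(tcorr, nan=0.0)
    report = SelectionReport()
    dropped: set[int] = set()
    for i in range(len(cols)):
        if i in dropped:
            continue
        for j in range(i + 1, len(cols)):
            if j in dropped or i in dropped:
                continue
            r = abs(corr[i, j])
            if r > threshold:
                if target is not None and tcorr[i] < tcorr[j]:
                    loser, winner = i, j
                else:
                    loser, winner = j, i
                dropped.add(loser)
                report.dropped_correlated.append((cols[loser], cols[winner], float(r)))
    keep = [c for k, c in enumerate(cols) if k not in dropped]
    return m.select(keep), report


def permutation_importance(
    model,
    m: DescriptorMatrix,
    y: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Permutation importance of every column under a fitted model.

    Importance of a column is the baseline R² minus the mean R² over
    ``n_repeats`` shufflings of that column only (baseline computed
    once). Deterministic given ``seed``.
    """
    from .modeling import FittedModel
    from sklearn.metrics import r2_score

    if isinstance(model, FittedModel):
        if tuple(model.feature_names) != tuple(m.columns):
            raise SchemaError(
                "model schema does not match matrix columns: "
                f"model={list(model.feature_names)}, matrix={m.columns}"
            )
        predict = model.predict_frame
    else:  # bare sklearn estimator
        predict = model.predict
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    baseline = r2_score(y, predict(m.frame))
    out: dict[str, tuple[float, float]] = {}
    for c in m.columns:
        drops = np.empty(n_repeats)
        work = m.frame.copy()
        original = work[c].to_numpy().copy()
        for r in range(n_repeats):
            work[c] = rng.permutation(original)
            drops[r] = baseline - r2_score(y, predict(work))
        work[c] = original
        out[c] = (float(drops.mean()), float(drops.std()))
    return out


def select_top(
    scores: Mapping[str, tuple[float, float]] | Mapping[str, float],
    k: int | None = None,
    cumulative_fraction: float | None = None,
) -> list[str]:
    """Deterministically pick the highest-scoring columns.

    Either the top ``k`` columns, or the smallest prefix reaching the
    requested fraction of the total positive importance. Ties break by
    column-name lexicographic order.
    """
    if not scores:
        raise ValueError("scores must be non-empty")
    if (k is None) == (cumulative_fraction is None):
        raise ValueError("pass exactly one of k or cumulative_fraction")
    means = {
        c: (v[0] if isinstance(v, (tuple, list)) else float(v))
        for c, v in scores.items()
    }
    ranked = sorted(means, key=lambda c: (-means[c], c))
    if k is not None:
        if k > len(ranked):
            raise ValueError(f"k={k} exceeds the {len(ranked)} available columns")
        return ranked[:k]
    total = sum(v for v in means.values() if v > 0)
    if total <= 0:
        return [ranked[0]]
    acc, out = 0.0, []
    for c in ranked:
        out.append(c)
        acc += max(means[c], 0.0)
        if acc / total >= cumulative_fraction:
            break
    return out
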