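"""Splitting protocol and tree-ensemble regressors.

The split protocol first withholds a fixed-size *unseen* subset (to
simulate prospective data), then divides the remainder into training
and test subsets. The three regressors — decision tree (DT), random
forest (RF) and extra-trees (ET) — are standard CART-family algorithms;
tree induction is delegated to scikit-learn behind a uniform
fit/predict contract with a frozen feature schema.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor

from .descriptors import DescriptorMatrix
from .errors import SchemaError

MODEL_KINDS = ("decision_tree", "random_forest", "extra_trees")

_ESTIMATORS = {
    "decision_tree": DecisionTreeRegressor,
    "random_forest": RandomForestRegressor,
    "extra_trees": ExtraTreesRegressor,
}


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint row-index sets covering the whole dataset."""

    train: tuple[int, ...]
    test: tuple[int, ...]
    unseen: tuple[int, ...]
    seed: int
    n_unseen: int
    test_frac: float

    def __post_init__(self) -> None:
        a, b, c = set(self.train), set(self.test), set(self.unseen)
        if a & b or a & c or b & c:
            raise ValueError("split subsets must be pairwise disjoint")

    @property
    def n_total(self) -> int:
        return len(self.train) + len(self.test) + len(self.unseen)


def split_dataset(ds_or_n, n_unseen: int = 33, test_frac: float = 0.3,
                  seed: int = 0) -> SplitIndices:
    """Withhold ``n_unseen`` rows, then split the rest into train/test.

    Test size is ``round(test_frac * n_remaining)`` (banker's rounding,
    documented because 30 % of 300 is exact but other sizes are not);
    the training subset is the remainder. Reproducible given ``seed``.
    """
    n = ds_or_n if isinstance(ds_or_n, int) else len(ds_or_n)
    if n_unseen >= n:
        raise ValueError(f"n_unseen={n_unseen} must be < dataset size {n}")
    if not (0 < test_frac < 1):
        raise ValueError("test_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    unseen = perm[:n_unseen]
    rest = perm[n_unseen:]
    n_test = round(test_frac * len(rest))
    test, train = rest[:n_test], rest[n_test:]
    return SplitIndices(
        train=tuple(int(i) for i in np.sort(train)),
        test=tuple(int(i) for i in np.sort(test)),
        unseen=tuple(int(i) for i in np.sort(unseen)),
        seed=seed,
        n_unseen=n_unseen,
        test_frac=test_frac,
    )


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one regressor."""

    kind: str
    params: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}, got {self.kind!r}")
        object.__setattr__(self, "params", dict(self.params))

    def build(self):
        return _ESTIMATORS[self.kind](random_state=self.seed, **self.params)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": dict(self.params), "seed": self.seed}


@dataclass
class FittedModel:
    """A fitted regressor frozen to its training feature schema."""

    spec: ModelSpec
    estimator: object
    feature_names: tuple[str, ...]

    def _check_schema(self, columns: Sequence[str]) -> None:
        missing = [c for c in self.feature_names if c not in columns]
        extra = [c for c in columns if c not in self.feature_names]
        if missing or extra:
            raise SchemaError(
                f"feature schema mismatch: missing={missing}, extra={extra}"
            )

    def predict_frame(self, frame: pd.DataFrame) -> np.ndarray:
        self._check_schema(list(frame.columns))
        x = frame.loc[:, list(self.feature_names)].to_numpy()
        return np.asarray(self.estimator.predict(x), dtype=float)

    def predict(self, m: DescriptorMatrix | pd.DataFrame) -> np.ndarray:
        frame = m.frame if isinstance(m, DescriptorMatrix) else m
        return self.predict_frame(frame)


def fit(spec: ModelSpec, X: DescriptorMatrix | pd.DataFrame, y: np.ndarray) -> FittedModel:
    """Fit one regressor; rows of ``X`` and ``y`` must be aligned."""
    frame = X.frame if isinstance(X, DescriptorMatrix) else X
    y = np.asarray(y, dtype=float)
    if len(frame) != len(y):
        raise ValueError(f"X has {len(frame)} rows but y has {len(y)}")
    if frame.isna().any().any() or not np.all(np.isfinite(y)):
        raise ValueError("missing or non-finite values in X or y")
    if np.all(y == y[0]):
        warnings.warn("constant response: model degenerates to a constant predictor",
                      stacklevel=2)
    est = spec.build()
    est.fit(frame.to_numpy(), y)
    return FittedModel(spec=spec, estimator=est, feature_names=tuple(frame.columns))


def predict(model: FittedModel, X: DescriptorMatrix | pd.DataFrame) -> np.ndarray:
    """Functional alias for :meth:`FittedModel.predict`."""
    return model.predict(X)
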