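"""Internal/external validation metric suite.

Definitions follow the standard QSAR conventions:

* ``R² = 1 - Σ(y-ŷ)² / Σ(y-ȳ_obs)²`` on the evaluated subset;
* ``Q²_F1 = 1 - Σ(y-ŷ)² / Σ(y-ȳ_train)²`` (training-set mean in the
  denominator);
* ``Q²_F2 = 1 - Σ(y-ŷ)² / Σ(y-ȳ_test)²`` (external-set mean; identical
  to R² on that subset);
* ``CCC = 2·s_xy / (s_x² + s_y² + (x̄-ȳ)²)`` — Lin's concordance
  correlation coefficient, penalizing both imprecision and
  location/scale shift (population moments);
* ``Q²_LOO = 1 - PRESS / Σ(y-ȳ)²`` with PRESS from leave-one-out
  refits.

``Q²_F1 >= Q²_F2`` holds on every input because the training mean can
only enlarge the denominator sum of squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import KFold

from .descriptors import DescriptorMatrix
from .errors import MetricError
from .modeling import ModelSpec, fit


@dataclass(frozen=True)
class MetricReport:
    """The validation statistics of one model on one subset."""

    subset: str
    n: int
    r2: float
    rmse: float
    mae: float
    mse: float
    ccc: float
    q2_f1: float | None = None
    q2_f2: float | None = None
    q2_loo: float | None = None
    #: which response mean each R²-type denominator used
    mean_basis: str = "observed"

    def to_dict(self) -> dict:
        return asdict(self)


def lin_ccc(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    x = np.asarray(y_obs, dtype=float)
    y = np.asarray(y_pred, dtype=float)
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    denom = x.var() + y.var() + (x.mean() - y.mean()) ** 2
    if denom == 0:
        raise MetricError("CCC undefined: both vectors constant and equal")
    return float(2 * sxy / denom)


def regression_metrics(
    y_obs: np.ndarray,
    y_pred: np.ndarray,
    train_mean: float | None = None,
    subset: str = "test",
) -> MetricReport:
    """Compute the full metric set for one (observed, predicted) pair.

    ``train_mean`` feeds the Q²_F1 denominator; without it Q²_F1 is
    omitted with a warning. Q²_F2 always uses the evaluated subset's own
    mean.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.ndim != 1:
        raise ValueError("y_obs and y_pred must be equal-length 1-D vectors")
    if y_obs.size < 2:
        raise ValueError("need at least 2 observations")
    if np.all(y_obs == y_obs[0]):
        raise MetricError("R²-family metrics undefined for a constant response")
    ss_res = float(np.sum((y_obs - y_pred) ** 2))
    mse = mean_squared_error(y_obs, y_pred)
    q2_f1 = None
    basis = f"observed({subset})"
    if train_mean is not None:
        q2_f1 = 1.0 - ss_res / float(np.sum((y_obs - float(train_mean)) ** 2))
        basis += "+train"
    else:
        warnings.warn("train_mean not given: Q²_F1 omitted", stacklevel=2)
    return MetricReport(
        subset=subset,
        n=int(y_obs.size),
        r2=float(r2_score(y_obs, y_pred)),
        rmse=float(np.sqrt(mse)),
        mae=float(mean_absolute_error(y_obs, y_pred)),
        mse=float(mse),
        ccc=lin_ccc(y_obs, y_pred),
        q2_f1=q2_f1,
        q2_f2=1.0 - ss_res / float(np.sum((y_obs - y_obs.mean()) ** 2)),
        mean_basis=basis,
    )


def q2_loo(spec: ModelSpec, X: DescriptorMatrix, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Leave-one-out cross-validated Q².

    For each row the model is refitted (with the spec's seed) on the
    remaining rows and predicts the held-out row; ``Q²_LOO = 1 -
    PRESS/Σ(y-ȳ)²``. Returns the statistic and the LOO predictions.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("Q²_LOO needs at least 3 observations")
    if np.all(y == y[0]):
        raise MetricError("Q²_LOO undefined for a constant response")
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        model = fit(spec, X.frame.iloc[keep], y[keep])
        preds[i] = model.predict_frame(X.frame.iloc[[i]])[0]
    press = float(np.sum((y - preds) ** 2))
    return 1.0 - press / float(np.sum((y - y.mean()) ** 2)), preds


@dataclass
class CVResult:
    """Per-fold and pooled statistics of a k-fold cross-validation."""

    fold_reports: list[MetricReport]
    pooled: MetricReport
    mean_over_folds: dict[str, float]
    fold_sizes: list[int]
    seed: int


def kfold_cv(spec: ModelSpec, X: DescriptorMatrix, y: np.ndarray,
             k: int = 5, seed: int = 0) -> CVResult:
    """Shuffled k-fold cross-validation with pooled out-of-fold metrics.

    The pooled report (metrics over all out-of-fold predictions at once)
    is the headline number; per-fold reports and their mean are also
    returned. Folds are a disjoint cover and reproducible by seed.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.empty(n)
    fold_reports: list[MetricReport] = []
    fold_sizes: list[int] = []
    for f, (tr, te) in enumerate(kf.split(np.zeros(n))):
        model = fit(spec, X.frame.iloc[tr], y[tr])
        pred = model.predict_frame(X.frame.iloc[te])
        oof[te] = pred
        fold_sizes.append(len(te))
        # singleton or constant-response folds carry no per-fold R²-type
        # metrics (the pooled report still covers them)
        if len(te) >= 2 and not np.all(y[te] == y[te][0]):
            fold_reports.append(
                regression_metrics(y[te], pred, train_mean=float(y[tr].mean()),
                                   subset=f"fold-{f}")
            )
    pooled = regression_metrics(y, oof, train_mean=float(y.mean()), subset="validation")
    keys = ("r2", "rmse", "mae", "ccc", "q2_f1", "q2_f2")
    mean_over_folds = {
        key: float(np.mean([getattr(r, key) for r in fold_reports]))
        for key in keys
    } if fold_reports else {}
    return CVResult(fold_reports=fold_reports, pooled=pooled,
                    mean_over_folds=mean_over_folds, fold_sizes=fold_sizes, seed=seed)
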