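"""End-to-end pipeline orchestration.

Stage order is fixed: load/generate -> diameter filter -> split ->
one-hot + descriptor build -> variance filter -> z-score ->
Yeo-Johnson -> correlation filter -> model fitting and validation ->
permutation-importance selection -> retrain on the selected descriptors
-> applicability domain. Every data-dependent fitted state (one-hot
levels, transform parameters, filters, importances, models) is computed
from the training rows only; the unseen subset enters exactly one
computation, the external evaluation of the retrained model.

All randomness derives from one top-level seed fanned out
deterministically per stage, so identical configs give byte-identical
JSON reports.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .ad import ADReport, ad_assess
from .data import ENMDataset, read_dataset
from .descriptors import DescriptorMatrix, FrozenOneHot, build_feature_matrix
from .errors import ConfigError, LeakError, StageError
from .feature_select import (
    SelectionReport,
    correlation_filter,
    permutation_importance,
    select_top,
    variance_filter,
)
from .modeling import MODEL_KINDS, FittedModel, ModelSpec, SplitIndices, fit, split_dataset
from .preprocess import (
    filter_by_diameter,
    validate_transform_order,
    yeojohnson_apply,
    yeojohnson_fit,
    zscore_apply,
    zscore_fit,
)
from .synth import GeneratorConfig, generate_dataset, study_config
from .validation import CVResult, MetricReport, kfold_cv, q2_loo, regression_metrics

DEFAULT_MODELS: dict[str, dict] = {
    "decision_tree": {},
    "random_forest": {},
    "extra_trees": {},
}


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    source: str = "generator"              # "generator" | "file"
    input_path: str | None = None
    column_map: dict[str, str] | None = None
    generator: GeneratorConfig | None = None
    diameter_threshold: float = 200.0
    transform_order: tuple[str, str] = ("zscore", "yeojohnson")
    sd_ddof: int = 0
    variance_threshold: float = 0.0
    correlation_threshold: float = 0.95
    n_selected: int = 12
    n_permutation_repeats: int = 10
    models: dict[str, dict] = field(default_factory=lambda: dict(DEFAULT_MODELS))
    n_unseen: int = 33
    test_frac: float = 0.3
    seed: int = 0
    compute_loo: bool = True
    cv_folds: int = 5
    retrain_model: str = "extra_trees"
    retrain_on: str = "train+test"         # or "train"
    unseen_levels: str = "error"           # one-hot policy off-train
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.generator is None and self.source == "generator":
            self.generator = study_config(seed=self.seed)

    def validate(self) -> None:
        if self.source not in ("generator", "file"):
            raise ConfigError(f"source must be 'generator' or 'file', got {self.source!r}")
        if self.source == "file" and not self.input_path:
            raise ConfigError("source 'file' requires input_path")
        validate_transform_order(self.transform_order)
        if not (0 < self.test_frac < 1):
            raise ConfigError("test_frac must be in (0, 1)")
        if self.n_unseen < 0:
            raise ConfigError("n_unseen must be >= 0")
        if not (0 < self.correlation_threshold <= 1):
            raise ConfigError("correlation_threshold must be in (0, 1]")
        if self.variance_threshold < 0:
            raise ConfigError("variance_threshold must be >= 0")
        unknown = [k for k in self.models if k not in MODEL_KINDS]
        if unknown:
            raise ConfigError(f"unknown model kinds: {unknown}")
        if self.retrain_model not in self.models:
            raise ConfigError(f"retrain_model {self.retrain_model!r} not among models")
        if self.retrain_on not in ("train+test", "train"):
            raise ConfigError("retrain_on must be 'train+test' or 'train'")
        if self.n_selected < 1:
            raise ConfigError("n_selected must be >= 1")
        if self.source == "generator":
            self.generator.validate()

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        gen = None
        if self.generator is not None:
            gen = {
                "seed": self.generator.seed,
                "n_enms": self.generator.n_enms,
                "noise_sd": self.generator.noise_sd,
                "hormesis": self.generator.hormesis,
                "roster": "study" if self.generator.roster is not None else None,
                "effect_sizes": self.generator.effect_sizes.as_dict(),
            }
        return {
            "source": self.source,
            "input_path": self.input_path,
            "column_map": self.column_map,
            "generator": gen,
            "diameter_threshold": self.diameter_threshold,
            "transform_order": list(self.transform_order),
            "sd_ddof": self.sd_ddof,
            "variance_threshold": self.variance_threshold,
            "correlation_threshold": self.correlation_threshold,
            "n_selected": self.n_selected,
            "n_permutation_repeats": self.n_permutation_repeats,
            "models": self.models,
            "n_unseen": self.n_unseen,
            "test_frac": self.test_frac,
            "seed": self.seed,
            "compute_loo": self.compute_loo,
            "cv_folds": self.cv_folds,
            "retrain_model": self.retrain_model,
            "retrain_on": self.retrain_on,
            "unseen_levels": self.unseen_levels,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        gen = d.pop("generator", None)
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        if isinstance(gen, Mapping):
            kwargs = {k: v for k, v in gen.items()
                      if k in ("seed", "n_enms", "noise_sd", "hormesis")}
            if gen.get("roster") == "study":
                cfg.generator = study_config(**kwargs)
            else:
                cfg.generator = GeneratorConfig(**kwargs)
        if isinstance(cfg.transform_order, list):
            cfg.transform_order = tuple(cfg.transform_order)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _fan_out_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(4)
    names = ("split", "model", "permutation", "cv")
    return {name: int(s % 2**31) for name, s in zip(names, state)}


@dataclass
class PipelineResult:
    """Serializable report plus in-memory artifacts of one run."""

    report: dict
    dataset: ENMDataset
    filtered: ENMDataset
    split: SplitIndices
    matrix: DescriptorMatrix          # final transformed + filtered matrix, all rows
    y: np.ndarray
    models: dict[str, FittedModel]
    selection: SelectionReport
    encoder: FrozenOneHot
    ad: ADReport

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.report, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    # -- tabular mirrors -----------------------------------------------------
    def metrics_table(self) -> pd.DataFrame:
        """Training/validation/test metric table (one row per model × subset)."""
        rows = []
        for kind, per_subset in self.report["metrics"].items():
            for subset in ("training", "validation", "test"):
                r = per_subset[subset]
                rows.append({"Model": kind, "Subset": subset, **{
                    k: r.get(k) for k in
                    ("r2", "q2_loo", "q2_f1", "q2_f2", "rmse", "mae", "ccc", "n")
                }})
        return pd.DataFrame(rows)

    def unseen_table(self) -> pd.DataFrame:
        r = self.report["retrained_unseen"]
        return pd.DataFrame([{"Model": self.report["config"]["retrain_model"],
                              "Subset": "unseen", **{
            k: r.get(k) for k in ("r2", "q2_f1", "q2_f2", "rmse", "mae", "ccc", "n")
        }}])


def _metric_dict(r: MetricReport) -> dict:
    return r.to_dict()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline; see the module docstring for the stages."""
    config.validate()
    seeds = _fan_out_seeds(config.seed)
    stage = "input"
    try:
        if config.source == "generator":
            dataset = generate_dataset(config.generator)
        else:
            dataset = read_dataset(config.input_path, dialect=config.column_map)

        stage = "filter"
        filt = filter_by_diameter(dataset, threshold=config.diameter_threshold)
        filtered = filt.dataset
        if len(filtered) <= config.n_unseen:
            raise ConfigError("filtered dataset too small for the split protocol")

        stage = "split"
        split = split_dataset(filtered, n_unseen=config.n_unseen,
                              test_frac=config.test_frac, seed=seeds["split"])
        train_idx = list(split.train)
        y = filtered.viability
        y_train = y[train_idx]

        stage = "features"
        train_ds = filtered.subset(train_idx, provenance="train")
        encoder = FrozenOneHot(unseen=config.unseen_levels).fit(train_ds)
        matrix, _ = build_feature_matrix(filtered, encoder=encoder)

        stage = "variance_filter"
        train_m = matrix.rows(train_idx)
        _, var_report = variance_filter(train_m, threshold=config.variance_threshold)
        keep = [c for c in matrix.columns if c not in var_report.dropped_low_variance]
        matrix = matrix.select(keep)

        stage = "transforms"
        validate_transform_order(config.transform_order)
        z_state = zscore_fit(matrix.rows(train_idx), ddof=config.sd_ddof)
        matrix = zscore_apply(z_state, matrix)
        yj_state = yeojohnson_fit(matrix.rows(train_idx))
        matrix = yeojohnson_apply(yj_state, matrix)

        stage = "correlation_filter"
        _, corr_report = correlation_filter(
            matrix.rows(train_idx), threshold=config.correlation_threshold,
            target=y_train,
        )
        dropped_corr = {t[0] for t in corr_report.dropped_correlated}
        matrix = matrix.select([c for c in matrix.columns if c not in dropped_corr])

        stage = "models"
        test_idx = list(split.test)
        models: dict[str, FittedModel] = {}
        metrics: dict[str, dict[str, dict]] = {}
        for kind, params in config.models.items():
            spec = ModelSpec(kind=kind, params=params, seed=seeds["model"])
            model = fit(spec, matrix.rows(train_idx), y_train)
            models[kind] = model
            train_pred = model.predict(matrix.rows(train_idx))
            rep_train = regression_metrics(y_train, train_pred,
                                           train_mean=float(y_train.mean()),
                                           subset="training")
            cv = kfold_cv(spec, matrix.rows(train_idx), y_train,
                          k=config.cv_folds, seed=seeds["cv"])
            rep_val = cv.pooled
            loo = None
            if config.compute_loo:
                loo, _ = q2_loo(spec, matrix.rows(train_idx), y_train)
            test_pred = model.predict(matrix.rows(test_idx))
            rep_test = regression_metrics(y[test_idx], test_pred,
                                          train_mean=float(y_train.mean()),
                                          subset="test")
            metrics[kind] = {
                "training": _metric_dict(rep_train),
                "validation": {**_metric_dict(rep_val), "q2_loo": loo,
                               "mean_over_folds": cv.mean_over_folds},
                "test": _metric_dict(rep_test),
            }

        stage = "selection"
        importances = permutation_importance(
            models[config.retrain_model], matrix.rows(train_idx), y_train,
            n_repeats=config.n_permutation_repeats, seed=seeds["permutation"],
        )
        selected = select_top(importances, k=min(config.n_selected, len(matrix.columns)))
        selection = SelectionReport(
            dropped_low_variance=var_report.dropped_low_variance,
            dropped_correlated=corr_report.dropped_correlated,
            importance_scores=importances,
            selected=selected,
        )

        stage = "retrain"
        result = PipelineResult(
            report={}, dataset=dataset, filtered=filtered, split=split,
            matrix=matrix, y=y, models=models, selection=selection,
            encoder=encoder, ad=None,  # type: ignore[arg-type]
        )
        rep_unseen = retrain_on_selected(result, config)

        stage = "ad"
        ad_report = ad_assess(matrix.rows(train_idx), matrix)
        result.ad = ad_report

        stage = "report"
        funnel = {
            "input_observations": len(dataset),
            "input_enms": len(dataset.enm_ids),
            "filtered_observations": len(filtered),
            "filtered_enms": len(filtered.enm_ids),
            "dropped_observations": filt.n_dropped,
            "train": len(split.train),
            "test": len(split.test),
            "unseen": len(split.unseen),
        }
        assert funnel["filtered_observations"] + funnel["dropped_observations"] \
            == funnel["input_observations"]
        assert funnel["train"] + funnel["test"] + funnel["unseen"] \
            == funnel["filtered_observations"]
        import sklearn

        result.report = {
            "config": config.to_dict(),
            "seeds": seeds,
            "funnel": funnel,
            "feature_columns": matrix.columns,
            "selection": selection.to_dict(),
            "metrics": metrics,
            "retrained_unseen": _metric_dict(rep_unseen),
            "ad": {
                "n": len(ad_report.results),
                "n_inside": int(ad_report.inside.sum()),
                "fraction_inside": ad_report.fraction_inside,
                "max_s_new": float(ad_report.s_new.max()),
            },
            "versions": {
                "nanoqstr": _pkg_version,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scikit-learn": sklearn.__version__,
            },
        }
        if config.output_dir:
            out = Path(config.output_dir)
            out.mkdir(parents=True, exist_ok=True)
            result.to_json(out / "pipeline_report.json")
            result.metrics_table().to_csv(out / "metrics_table.csv", index=False,
                                          float_format="%.6g")
            result.unseen_table().to_csv(out / "unseen_table.csv", index=False,
                                         float_format="%.6g")
            ad_report.to_csv(out / "applicability_domain.csv")
        return result
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise StageError(stage, exc) from exc


def retrain_on_selected(
    result: PipelineResult,
    config: PipelineConfig,
    selected: Sequence[str] | None = None,
) -> MetricReport:
    """Refit the chosen model on the selected descriptors and score it
    on the untouched unseen subset (external validation).

    Raises :class:`LeakError` if any unseen row would enter the fit.
    """
    selected = list(selected) if selected is not None else list(result.selection.selected)
    split = result.split
    fit_idx = list(split.train) + (list(split.test) if config.retrain_on == "train+test" else [])
    if set(fit_idx) & set(split.unseen):
        raise LeakError("unseen rows must never enter a fit")
    seeds = _fan_out_seeds(config.seed)
    spec = ModelSpec(kind=config.retrain_model,
                     params=config.models[config.retrain_model], seed=seeds["model"])
    sub = result.matrix.select(selected)
    y_fit = result.y[fit_idx]
    model = fit(spec, sub.rows(fit_idx), y_fit)
    unseen_idx = list(split.unseen)
    pred = model.predict(sub.rows(unseen_idx))
    return regression_metrics(result.y[unseen_idx], pred,
                              train_mean=float(y_fit.mean()), subset="unseen")
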