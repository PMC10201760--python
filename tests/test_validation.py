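"""Validation metric suite against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import nanoqstr as nq
from nanoqstr.descriptors import DescriptorMatrix
from nanoqstr.errors import MetricError


def brute_force_metrics(y, p, train_mean=None):
    """Independent straight-from-the-formula evaluation (plain loops)."""
    y, p = list(map(float, y)), list(map(float, p))
    n = len(y)
    ybar = sum(y) / n
    pbar = sum(p) / n
    ss_res = sum((yi - pi) ** 2 for yi, pi in zip(y, p))
    ss_tot = sum((yi - ybar) ** 2 for yi in y)
    sx = sum((yi - ybar) ** 2 for yi in y) / n
    sy = sum((pi - pbar) ** 2 for pi in p) / n
    sxy = sum((yi - ybar) * (pi - pbar) for yi, pi in zip(y, p)) / n
    out = {
        "r2": 1 - ss_res / ss_tot,
        "rmse": (ss_res / n) ** 0.5,
        "mae": sum(abs(yi - pi) for yi, pi in zip(y, p)) / n,
        "ccc": 2 * sxy / (sx + sy + (ybar - pbar) ** 2),
        "q2_f2": 1 - ss_res / ss_tot,
    }
    if train_mean is not None:
        out["q2_f1"] = 1 - ss_res / sum((yi - train_mean) ** 2 for yi in y)
    return out


def _matrix(frame: pd.DataFrame) -> DescriptorMatrix:
    return DescriptorMatrix(frame=frame.astype(float),
                            provenance={c: "raw" for c in frame.columns})


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        y = np.array([90.0, 100.0, 110.0])
        rep = nq.regression_metrics(y, y, train_mean=95.0)
        assert rep.r2 == rep.q2_f1 == rep.q2_f2 == 1.0
        assert rep.rmse == rep.mae == 0.0
        assert rep.ccc == pytest.approx(1.0)

    def test_mean_predictor_scores_zero(self):
        y = np.array([90.0, 100.0, 110.0])
        p = np.full(3, y.mean())
        rep = nq.regression_metrics(y, p, train_mean=float(y.mean()))
        assert rep.r2 == pytest.approx(0.0)
        assert rep.ccc == pytest.approx(0.0)

    def test_three_point_example_matches_formula_oracle(self):
        y = np.array([90.0, 100.0, 110.0])
        p = np.array([95.0, 100.0, 105.0])
        rep = nq.regression_metrics(y, p, train_mean=98.0)
        oracle = brute_force_metrics(y, p, train_mean=98.0)
        for key, val in oracle.items():
            assert getattr(rep, key) == pytest.approx(val, abs=1e-12), key

    def test_oracle_equivalence_on_100_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(3, 12)
            y = rng.normal(100, 20, size=n)
            p = y + rng.normal(0, 10, size=n)
            tm = float(rng.normal(100, 5))
            rep = nq.regression_metrics(y, p, train_mean=tm)
            oracle = brute_force_metrics(y, p, train_mean=tm)
            for key, val in oracle.items():
                assert getattr(rep, key) == pytest.approx(val, abs=1e-12), key

    def test_constant_observed_response_rejected(self):
        with pytest.raises(MetricError):
            nq.regression_metrics([5.0, 5.0, 5.0], [5.0, 5.1, 4.9])

    def test_missing_train_mean_omits_q2f1_with_warning(self):
        with pytest.warns(UserWarning, match="Q²_F1"):
            rep = nq.regression_metrics([1.0, 2.0, 3.0], [1.1, 2.0, 2.9])
        assert rep.q2_f1 is None

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=20, unique=True),
           st.integers(0, 2**31 - 1), st.floats(-50, 50))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_q2f1_never_below_q2f2(self, y, seed, train_mean):
        y = np.array(y)
        p = y + np.random.default_rng(seed).normal(0, 5, size=y.size)
        rep = nq.regression_metrics(y, p, train_mean=train_mean)
        assert rep.q2_f1 >= rep.q2_f2 - 1e-12

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_ccc_never_exceeds_pearson_magnitude(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(0, 1, size=10)
        p = 0.5 * y + rng.normal(0, 1, size=10) + rng.normal()
        if np.ptp(y) == 0 or np.ptp(p) == 0:
            return
        rep = nq.regression_metrics(y, p, train_mean=0.0)
        r = abs(np.corrcoef(y, p)[0, 1])
        assert rep.ccc <= r + 1e-12

    def test_ccc_equals_pearson_iff_identity_line(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert nq.lin_ccc(y, y) == pytest.approx(np.corrcoef(y, y)[0, 1])
        shifted = y + 1.0
        assert nq.lin_ccc(y, shifted) < abs(np.corrcoef(y, shifted)[0, 1])

    def test_invariant_to_paired_shuffling(self):
        rng = np.random.default_rng(3)
        y = rng.normal(100, 15, size=30)
        p = y + rng.normal(0, 5, size=30)
        rep1 = nq.regression_metrics(y, p, train_mean=100.0)
        perm = rng.permutation(30)
        rep2 = nq.regression_metrics(y[perm], p[perm], train_mean=100.0)
        for key in ("r2", "rmse", "mae", "ccc", "q2_f1", "q2_f2"):
            assert getattr(rep1, key) == pytest.approx(getattr(rep2, key), abs=1e-12)


class TestQ2LOO:
    def test_exactly_learnable_data_reaches_one(self):
        x = np.repeat([0.0, 1.0, 2.0], 4)
        y = np.where(x > 0.5, 10.0, 5.0)
        m = _matrix(pd.DataFrame({"x": x}))
        q2, _ = nq.q2_loo(nq.ModelSpec(kind="decision_tree", seed=0), m, y)
        assert q2 == pytest.approx(1.0, abs=1e-9)

    def test_three_point_refit_oracle(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([1.0, 3.0, 2.0])
        m = _matrix(pd.DataFrame({"x": x}))
        spec = nq.ModelSpec(kind="decision_tree", seed=0)
        q2, preds = nq.q2_loo(spec, m, y)
        expected_preds = np.empty(3)
        for i in range(3):
            keep = [j for j in range(3) if j != i]
            model = nq.fit(spec, m.frame.iloc[keep], y[keep])
            expected_preds[i] = model.predict_frame(m.frame.iloc[[i]])[0]
        press = np.sum((y - expected_preds) ** 2)
        assert np.array_equal(preds, expected_preds)
        assert q2 == pytest.approx(1 - press / np.sum((y - y.mean()) ** 2))

    def test_pure_noise_response_not_spuriously_valid(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            m = _matrix(pd.DataFrame({"x": rng.normal(size=25),
                                      "z": rng.normal(size=25)}))
            y = rng.normal(size=25)
            q2, _ = nq.q2_loo(nq.ModelSpec(kind="decision_tree", seed=seed,
                                           params={"max_depth": 3}), m, y)
            vals.append(q2)
        assert np.mean(vals) <= 0.2

    def test_constant_response_rejected(self):
        m = _matrix(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        with pytest.raises(MetricError):
            nq.q2_loo(nq.ModelSpec(kind="decision_tree", seed=0), m,
                      np.array([4.0, 4.0, 4.0]))


class TestKFold:
    def test_fold_sizes_for_333_by_5(self):
        rng = np.random.default_rng(0)
        m = _matrix(pd.DataFrame({"x": rng.normal(size=333)}))
        y = m.frame["x"].to_numpy() * 2 + rng.normal(size=333)
        cv = nq.kfold_cv(nq.ModelSpec(kind="decision_tree", seed=0), m, y,
                         k=5, seed=0)
        assert sorted(cv.fold_sizes, reverse=True) == [67, 67, 67, 66, 66]

    def test_folds_are_disjoint_cover_and_reproducible(self):
        rng = np.random.default_rng(1)
        m = _matrix(pd.DataFrame({"x": rng.normal(size=40)}))
        y = rng.normal(size=40)
        spec = nq.ModelSpec(kind="decision_tree", seed=0, params={"max_depth": 2})
        a = nq.kfold_cv(spec, m, y, k=4, seed=3)
        b = nq.kfold_cv(spec, m, y, k=4, seed=3)
        assert a.pooled == b.pooled
        assert sum(a.fold_sizes) == 40

    def test_k_equals_n_matches_loo_scheme(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 1.5, 3.0, 2.5, 4.0])
        m = _matrix(pd.DataFrame({"x": x}))
        spec = nq.ModelSpec(kind="decision_tree", seed=0)
        cv = nq.kfold_cv(spec, m, y, k=6, seed=0)
        q2, _ = nq.q2_loo(spec, m, y)
        assert cv.pooled.q2_f1 == pytest.approx(q2)

    def test_k_above_n_rejected(self):
        m = _matrix(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        with pytest.raises(ValueError):
            nq.kfold_cv(nq.ModelSpec(kind="decision_tree", seed=0), m,
                        np.array([1.0, 2.0, 3.0]), k=4)
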