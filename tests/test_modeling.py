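import numpy as np
import pytest

from chromaccess.feature_matrix import FeatureMatrix
from chromaccess.modeling import (
    ModelConfig,
    fit_model,
    kfold_cv,
    make_folds,
    model_comparison,
    prediction_power,
)
from helpers_oracles import linear_matrix


class TestModelConfig:
    def test_defaults(self):
        cfg = ModelConfig()
        assert cfg.algorithm == "svr"
        assert cfg.svr_cost == 1.0
        assert cfg.svr_epsilon == 0.1
        assert cfg.svr_gamma is None  # resolved to 1/n_features at fit time
        assert cfg.standardize

    @pytest.mark.parametrize(
        "kwargs",
        [{"algorithm": "forest"}, {"svr_cost": 0.0}, {"svr_epsilon": -1}, {"svr_gamma": 0}],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            ModelConfig(**kwargs)


class TestFitModel:
    def test_lm_recovers_exact_linear_function(self):
        x = np.linspace(0, 10, 30).reshape(-1, 1)
        y = 2 * x.ravel() + 1
        predict = fit_model(x, y, ModelConfig(algorithm="lm"))
        np.testing.assert_allclose(predict(x), y, atol=1e-8)

    def test_svr_beats_lm_on_quadratic(self):
        x = np.linspace(-2, 2, 41).reshape(-1, 1)
        y = x.ravel() ** 2
        r2 = {}
        for algo in ("svr", "lm"):
            pred = fit_model(x, y, ModelConfig(algorithm=algo))(x)
            if np.std(pred) == 0:
                r2[algo] = 0.0
            else:
                r2[algo] = np.corrcoef(pred, y)[0, 1] ** 2
        assert r2["svr"] > r2["lm"]

    def test_lm_constant_target_predicts_constant(self):
        x = np.linspace(0, 10, 20).reshape(-1, 1)
        y = np.full(20, 3.5)
        predict = fit_model(x, y, ModelConfig(algorithm="lm"))
        np.testing.assert_allclose(predict(x), y, atol=1e-8)

    def test_constant_feature_column_survives(self):
        x = np.column_stack([np.linspace(0, 10, 20), np.full(20, 7.0)])
        y = 2 * x[:, 0]
        predict = fit_model(x, y, ModelConfig(algorithm="lm"))
        np.testing.assert_allclose(predict(x), y, atol=1e-8)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            fit_model(np.array([[1.0]]), np.array([1.0]), ModelConfig())

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fit_model(np.array([[1.0], [np.nan]]), np.array([1.0, 2.0]), ModelConfig())


class TestMakeFolds:
    def test_partition_arithmetic(self):
        folds = make_folds(100, 10, seed=0)
        values, counts = np.unique(folds, return_counts=True)
        assert values.tolist() == list(range(1, 11))
        assert counts.tolist() == [10] * 10

    def test_near_equal_sizes(self):
        folds = make_folds(103, 10, seed=0)
        _, counts = np.unique(folds, return_counts=True)
        assert counts.max() - counts.min() <= 1
        assert counts.sum() == 103

    def test_determinism(self):
        np.testing.assert_array_equal(make_folds(50, 5, seed=3), make_folds(50, 5, seed=3))
        assert not np.array_equal(make_folds(50, 5, seed=3), make_folds(50, 5, seed=4))

    def test_partition_property_randomized(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 300))
            k = int(rng.integers(2, min(n, 12)))
            folds = make_folds(n, k, int(rng.integers(1 << 30)))
            values, counts = np.unique(folds, return_counts=True)
            assert len(values) == k
            assert counts.sum() == n
            assert counts.max() - counts.min() <= 1

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            make_folds(5, 1, 0)
        with pytest.raises(ValueError):
            make_folds(5, 6, 0)


class TestKfoldCV:
    def test_noise_free_linear_recovery(self):
        m = linear_matrix(n=200, betas=(2.0,), noise=0.0, seed=1)
        result = kfold_cv(m, config=ModelConfig(algorithm="lm"), k=10, seed=0)
        assert result.R2 >= 0.99

    def test_same_seed_same_result(self):
        m = linear_matrix(n=100, betas=(1.0, 0.5), noise=0.5, seed=2)
        a = kfold_cv(m, config=ModelConfig(algorithm="lm"), k=10, seed=5)
        b = kfold_cv(m, config=ModelConfig(algorithm="lm"), k=10, seed=5)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)
        assert a.R == b.R

    def test_unknown_feature(self):
        m = linear_matrix()
        with pytest.raises(KeyError):
            kfold_cv(m, ["nope"], ModelConfig(algorithm="lm"))

    def test_empty_subset(self):
        with pytest.raises(ValueError):
            kfold_cv(linear_matrix(), [], ModelConfig(algorithm="lm"))

    def test_r_is_sqrt_of_r2(self):
        m = linear_matrix(n=100, betas=(1.0,), noise=1.0, seed=3)
        result = kfold_cv(m, config=ModelConfig(algorithm="lm"), k=5, seed=0)
        assert result.R == pytest.approx(np.sqrt(result.R2))
        assert 0 <= result.R2 <= 1

    def test_pure_noise_feature_low_power(self):
        m = linear_matrix(n=2000, betas=(1.0, 0.0), noise=0.5, seed=4)
        result = kfold_cv(m, ["f1"], ModelConfig(algorithm="lm"), k=10, seed=0)
        assert result.R < 0.15

    def test_noise_scale_monotonicity(self):
        # pooled-CV R2 rises as the generator's noise scale falls
        r2 = []
        for tau in (2.0, 1.0, 0.5, 0.1):
            m = linear_matrix(n=2000, betas=(1.0,), noise=tau, seed=8)
            r2.append(kfold_cv(m, config=ModelConfig(algorithm="lm"), k=10, seed=0).R2)
        assert all(b >= a for a, b in zip(r2, r2[1:]))


class TestPredictionPower:
    def test_identity(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert prediction_power(v, v) == (1.0, 1.0)

    def test_positive_affine(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        r2, r = prediction_power(3 * obs + 7, obs)
        assert r2 == pytest.approx(1.0)
        assert r == pytest.approx(1.0)

    def test_four_point_pearson_oracle(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([1.1, 1.9, 3.2, 3.8])
        r2, r = prediction_power(pred, obs)
        # frozen from the closed-form Pearson formula: 2209/2250
        assert r2 == pytest.approx(2209 / 2250, abs=1e-12)
        assert r == pytest.approx(np.sqrt(2209 / 2250), abs=1e-12)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        assert prediction_power(a, b) == pytest.approx(prediction_power(b, a))

    def test_affine_invariance_of_either_argument(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        base = prediction_power(a, b)
        assert prediction_power(2 * a + 3, b) == pytest.approx(base)
        assert prediction_power(a, 0.5 * b - 1) == pytest.approx(base)

    def test_constant_observed_raises(self):
        with pytest.raises(ValueError, match="constant"):
            prediction_power(np.array([1.0, 2.0, 3.0]), np.array([5.0, 5.0, 5.0]))

    def test_constant_predictions_zero_power(self):
        r2, r = prediction_power(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))
        assert (r2, r) == (0.0, 0.0)

    def test_length_checks(self):
        with pytest.raises(ValueError):
            prediction_power(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            prediction_power(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0]))


class TestModelComparison:
    def _matrices(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 300
        latent = rng.lognormal(1.0, 0.8, n)
        y = latent * np.exp(rng.normal(0, 0.1, n))
        X = np.column_stack(
            [
                latent ** 2 * np.exp(rng.normal(0, 0.3, n)),
                np.sqrt(latent) * np.exp(rng.normal(0, 0.3, n)),
            ]
        )
        names = ["hm1", "tf1"]
        ids = [f"r{i}" for i in range(n)]
        mmax = FeatureMatrix(ids, names, X, y, "max")
        # avg signal: max diluted by a random width ratio per cell
        mavg = FeatureMatrix(
            ids,
            names,
            X * rng.uniform(0.1, 0.45, (n, 2)),
            y * rng.uniform(0.1, 0.45, n),
            "avg",
        )
        return mmax, mavg, {"hm1": "HM", "tf1": "TF"}

    def test_layout(self):
        mmax, mavg, classes = self._matrices()
        table = model_comparison(mmax, mavg, classes, k=5, seed=0)
        assert list(table.index) == ["HM", "TF", "HM+TF"]
        assert list(table.columns) == ["svr_max", "lm_max", "svr_avg", "lm_avg"]
        assert ((table >= 0) & (table <= 1)).all().all()

    def test_max_beats_avg_when_avg_is_diluted(self):
        mmax, mavg, classes = self._matrices(seed=1)
        table = model_comparison(mmax, mavg, classes, k=5, seed=0)
        row = table.loc["HM+TF"]
        assert row["svr_max"] > row["svr_avg"]
        assert row["lm_max"] > row["lm_avg"]

    def test_mismatched_regions_rejected(self):
        mmax, mavg, classes = self._matrices()
        shorter = FeatureMatrix(
            mavg.region_ids[:-1],
            mavg.feature_names,
            mavg.X[:-1],
            mavg.y[:-1],
            "avg",
        )
        with pytest.raises(ValueError, match="region"):
            model_comparison(mmax, shorter, classes)

    def test_linear_truth_both_algorithms_near_perfect(self):
        # noise-free linear links: svr and lm both reach R >= 0.99
        rng = np.random.default_rng(3)
        n = 400
        x = rng.uniform(1, 10, n)
        X = np.column_stack([x, 2 * x])
        m = FeatureMatrix(
            [f"r{i}" for i in range(n)], ["hm1", "tf1"], X, 3 * x, "max"
        )
        classes = {"hm1": "HM", "tf1": "TF"}
        table = model_comparison(m, m, classes, k=5, seed=0)
        assert (table.loc["HM+TF"] >= 0.99).all()
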