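"""Cross-validated SVR and linear models with the prediction-power metric.

Prediction power R is the positive square root of R^2, where R^2 is the
squared Pearson correlation between pooled out-of-fold predictions and the
observed DNase signal — the coefficient of determination of the least-squares
line through the predicted-vs-observed scatter. This is deliberately not
1 - SSE/SST: out-of-fold predictions are pooled across folds first, then a
single line is fit.

SVR defaults follow the classic libsvm epsilon-regression defaults: RBF
kernel, cost 1.0, epsilon 0.1, gamma = 1/n_features, with features and the
target standardized on the training fold (statistics never taken from the
validation fold).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR

from .feature_matrix import FeatureMatrix

__all__ = [
    "ModelConfig",
    "CVResult",
    "fit_model",
    "make_folds",
    "kfold_cv",
    "prediction_power",
    "model_comparison",
]

ALGORITHMS = ("svr", "lm")


@dataclass(frozen=True)
class ModelConfig:
    algorithm: str = "svr"
    svr_cost: float = 1.0
    svr_epsilon: float = 0.1
    svr_gamma: Optional[float] = None  # None -> 1 / n_features
    standardize: bool = True
    log1p: bool = False

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.svr_cost <= 0 or self.svr_epsilon <= 0:
            raise ValueError("svr_cost and svr_epsilon must be > 0")
        if self.svr_gamma is not None and self.svr_gamma <= 0:
            raise ValueError("svr_gamma must be > 0")


@dataclass
class CVResult:
    """Pooled out-of-fold predictions and the derived prediction power."""

    fold_assignment: np.ndarray  # region -> fold index in 1..k
    predictions: np.ndarray
    observed: np.ndarray
    R2: float
    R: float


def _standardizer(train: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    # constant columns map to zeros rather than dividing by 0
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def fit_model(
    train_X: np.ndarray, train_y: np.ndarray, config: ModelConfig
) -> Callable[[np.ndarray], np.ndarray]:
    """Fit one model and return a prediction function in target units."""
    X = np.atleast_2d(np.asarray(train_X, dtype=float))
    y = np.asarray(train_y, dtype=float).ravel()
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if X.shape[1] < 1:
        raise ValueError("need at least 1 feature")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite training data")
    if config.log1p:
        X = np.log1p(X)
        y = np.log1p(y)

    if config.standardize:
        x_mean, x_sd = _standardizer(X)
    else:
        x_mean = np.zeros(X.shape[1])
        x_sd = np.ones(X.shape[1])
    Xs = (X - x_mean) / x_sd

    if config.algorithm == "lm":
        design = np.column_stack([np.ones(len(Xs)), Xs])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)

        def predict(new_X: np.ndarray) -> np.ndarray:
            Z = np.atleast_2d(np.asarray(new_X, dtype=float))
            if config.log1p:
                Z = np.log1p(Z)
            Zs = (Z - x_mean) / x_sd
            out = coef[0] + Zs @ coef[1:]
            return np.expm1(out) if config.log1p else out

        return predict

    gamma = config.svr_gamma if config.svr_gamma is not None else 1.0 / X.shape[1]
    y_mean = float(y.mean())
    y_sd = float(y.std()) or 1.0
    svr = SVR(
        kernel="rbf",
        C=config.svr_cost,
        epsilon=config.svr_epsilon,
        gamma=gamma,
    )
    svr.fit(Xs, (y - y_mean) / y_sd)

    def predict(new_X: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(new_X, dtype=float))
        if config.log1p:
            Z = np.log1p(Z)
        Zs = (Z - x_mean) / x_sd
        out = svr.predict(Zs) * y_sd + y_mean
        return np.expm1(out) if config.log1p else out

    return predict


def make_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Random partition of n rows into k folds with sizes differing by <= 1.

    Returns fold indices in 1..k, deterministic given the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("k must not exceed the number of rows")
    perm = np.random.default_rng(seed).permutation(n)
    assignment = np.empty(n, dtype=np.int64)
    base, extra = divmod(n, k)
    pos = 0
    for fold in range(1, k + 1):
        size = base + (1 if fold <= extra else 0)
        assignment[perm[pos : pos + size]] = fold
        pos += size
    return assignment


def kfold_cv(
    matrix: FeatureMatrix,
    features: Optional[Sequence[str]] = None,
    config: ModelConfig = ModelConfig(),
    k: int = 10,
    seed: int = 0,
    folds: Optional[np.ndarray] = None,
) -> CVResult:
    """k-fold cross-validation on a feature subset with pooled predictions.

    Each fold is predicted by a model trained on the other k-1 folds; the
    out-of-fold predictions are pooled before computing R^2. Passing a
    precomputed ``folds`` assignment lets many subsets share one partition.
    """
    names = list(features) if features is not None else list(matrix.feature_names)
    if not names:
        raise ValueError("feature subset must be non-empty")
    X = matrix.columns(names)
    y = matrix.y
    n = len(y)
    if folds is None:
        folds = make_folds(n, k, seed)
    else:
        folds = np.asarray(folds, dtype=np.int64)
        if len(folds) != n:
            raise ValueError("fold assignment length mismatch")
    predictions = np.empty(n)
    for fold in np.unique(folds):
        val = folds == fold
        predictor = fit_model(X[~val], y[~val], config)
        predictions[val] = predictor(X[val])
    r2, r = prediction_power(predictions, y)
    return CVResult(folds, predictions, y.copy(), r2, r)


def prediction_power(
    predictions: np.ndarray, observed: np.ndarray
) -> Tuple[float, float]:
    """(R^2, R) of the least-squares line through the prediction scatter.

    R^2 is the squared Pearson correlation; R its positive square root.
    A constant observed vector makes the correlation undefined and raises.
    Constant predictions carry no linear information and give R^2 = 0.
    """
    pred = np.asarray(predictions, dtype=float).ravel()
    obs = np.asarray(observed, dtype=float).ravel()
    if len(pred) != len(obs):
        raise ValueError("vectors must have equal length")
    if len(pred) < 3:
        raise ValueError("need at least 3 points")
    if np.std(obs) == 0:
        raise ValueError("observed vector is constant; correlation undefined")
    if np.std(pred) == 0:
        return 0.0, 0.0
    r = float(stats.pearsonr(pred, obs).statistic)
    r2 = min(r * r, 1.0)
    return r2, float(np.sqrt(r2))


def model_comparison(
    matrix_max: FeatureMatrix,
    matrix_avg: FeatureMatrix,
    feature_classes: Dict[str, str],
    config: ModelConfig = ModelConfig(),
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Prediction power R for {HM, TF, HM+TF} x {svr, lm} x {max, avg}.

    Both matrices must describe the same regions and features; all twelve
    cells share the fold partition derived from ``seed``.
    """
    if matrix_max.region_ids != matrix_avg.region_ids:
        raise ValueError("matrices describe different region sets")
    if matrix_max.feature_names != matrix_avg.feature_names:
        raise ValueError("matrices describe different features")
    unknown = set(feature_classes) - set(matrix_max.feature_names)
    if unknown:
        raise ValueError(f"feature classes for unknown features: {sorted(unknown)}")
    sets = {
        "HM": [f for f in matrix_max.feature_names if feature_classes.get(f) == "HM"],
        "TF": [f for f in matrix_max.feature_names if feature_classes.get(f) == "TF"],
    }
    sets["HM+TF"] = sets["HM"] + sets["TF"]
    folds = make_folds(matrix_max.n_regions, k, seed)
    rows = {}
    for set_name, names in sets.items():
        if not names:
            raise ValueError(f"feature set {set_name!r} is empty")
        row = {}
        for algorithm in ("svr", "lm"):
            cfg = replace(config, algorithm=algorithm)
            for agg, matrix in (("max", matrix_max), ("avg", matrix_avg)):
                result = kfold_cv(matrix, names, cfg, folds=folds)
                row[f"{algorithm}_{agg}"] = result.R
        rows[set_name] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    return table[["svr_max", "lm_max", "svr_avg", "lm_avg"]]
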