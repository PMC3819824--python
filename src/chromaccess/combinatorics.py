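"""Exhaustive feature-subset evaluation, enrichment, and sample-size curve.

All subsets of one evaluation run share a single fold partition so that
subset comparisons are free of fold-assignment noise. The enrichment null
treats the top set as a uniform draw of N models from the M enumerated
k-feature models; the reported p-value is the upper tail P(X >= x).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .feature_matrix import FeatureMatrix, sample_regions
from .modeling import ModelConfig, kfold_cv, make_folds

__all__ = [
    "CombinationResult",
    "EnrichmentResult",
    "enumerate_subsets",
    "evaluate_combinations",
    "top_combinations",
    "feature_enrichment",
    "sample_size_curve",
]


@dataclass(frozen=True)
class CombinationResult:
    features: Tuple[str, ...]  # canonical: sorted names
    R: float
    relative_power: float  # R / R_full, not clamped


@dataclass(frozen=True)
class EnrichmentResult:
    feature: str
    x: int  # top-set models containing the feature
    N: int  # top-set size
    K: int  # k-subsets containing the feature = C(F-1, k-1)
    M: int  # total k-subsets = C(F, k)
    p_value: float  # upper tail P(X >= x)
    p_bh: float  # Benjamini-Hochberg adjusted across features
    significant: bool  # raw p < alpha


def enumerate_subsets(feature_names: Sequence[str], k: int) -> List[Tuple[str, ...]]:
    """All C(F, k) canonical k-subsets in lexicographic order."""
    if not 1 <= k <= len(feature_names):
        raise ValueError(f"k must satisfy 1 <= k <= {len(feature_names)}")
    if len(set(feature_names)) != len(feature_names):
        raise ValueError("feature names must be unique")
    return list(itertools.combinations(sorted(feature_names), k))


def evaluate_combinations(
    matrix: FeatureMatrix,
    k: int,
    config: ModelConfig = ModelConfig(),
    folds: int = 10,
    seed: int = 0,
    fold_assignment: Optional[np.ndarray] = None,
) -> Tuple[List[CombinationResult], float]:
    """Cross-validate every k-feature subset plus the full model.

    Every subset — and the full model — is evaluated on the same fold
    partition. Results are sorted by R descending, ties broken
    lexicographically by subset. Returns (results, R_full).
    """
    if fold_assignment is None:
        fold_assignment = make_folds(matrix.n_regions, folds, seed)
    full = kfold_cv(matrix, config=config, folds=fold_assignment)
    results = []
    for subset in enumerate_subsets(matrix.feature_names, k):
        cv = kfold_cv(matrix, subset, config, folds=fold_assignment)
        results.append(
            CombinationResult(subset, cv.R, cv.R / full.R if full.R > 0 else np.inf)
        )
    results.sort(key=lambda r: (-r.R, r.features))
    return results, full.R


def top_combinations(
    results: Sequence[CombinationResult], R_full: float, threshold: float = 0.90
) -> List[CombinationResult]:
    """Subsets whose R strictly exceeds threshold * R_full."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    return [r for r in results if r.R > threshold * R_full]


def feature_enrichment(
    top: Sequence[CombinationResult],
    feature_names: Sequence[str],
    k: int,
    alpha: float = 0.01,
) -> List[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of each feature in the top set.

    With F features, the population is the M = C(F, k) enumerated models of
    which K = C(F-1, k-1) contain a given feature; x counts top-set models
    containing it and N is the top-set size:
    p = sum_{i=x}^{min(N,K)} C(K,i) C(M-K, N-i) / C(M, N).
    """
    if not top:
        raise ValueError("top set is empty")
    sizes = {len(r.features) for r in top}
    if sizes != {k}:
        raise ValueError(f"top set contains subsets of sizes {sorted(sizes)}, expected {k}")
    F = len(feature_names)
    M = comb(F, k)
    K = comb(F - 1, k - 1)
    N = len(top)
    raw = []
    for feature in feature_names:
        x = sum(1 for r in top if feature in r.features)
        p = float(hypergeom.sf(x - 1, M, K, N))  # P(X >= x)
        raw.append((feature, x, min(max(p, 0.0), 1.0)))
    p_bh = _benjamini_hochberg([p for _, _, p in raw])
    return [
        EnrichmentResult(feature, x, N, K, M, p, q, p < alpha)
        for (feature, x, p), q in zip(raw, p_bh)
    ]


def _benjamini_hochberg(p_values: Sequence[float]) -> List[float]:
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running_min = min(running_min, p[i] * m / (rank_from_top + 1))
        adjusted[i] = running_min
    return adjusted.tolist()


def sample_size_curve(
    matrix: FeatureMatrix,
    sizes: Sequence[int],
    reps: int = 500,
    config: ModelConfig = ModelConfig(),
    folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean and dispersion of R over repeated region subsamples per size.

    For each size, ``reps`` independent subsamples are drawn and cross-
    validated; replicate seeds are derived deterministically from the master
    seed, the size index and the replicate index.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = []
    for size_index, size in enumerate(sizes):
        if size > matrix.n_regions:
            raise ValueError(f"size {size} exceeds {matrix.n_regions} regions")
        if size < folds:
            raise ValueError(f"size {size} smaller than fold count {folds}")
        r_values = np.empty(reps)
        for rep in range(reps):
            ss = np.random.SeedSequence([seed, size_index, rep])
            sample_seed, fold_seed = (int(s) for s in ss.generate_state(2))
            sub = sample_regions(matrix, size, sample_seed)
            r_values[rep] = kfold_cv(sub, config=config, k=folds, seed=fold_seed).R
        rows.append(
            {
                "size": size,
                "reps": reps,
                "mean_R": float(r_values.mean()),
                "sd_R": float(r_values.std(ddof=1)) if reps > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Table writers (tab-separated acceptance surface)
# ---------------------------------------------------------------------------


def write_combination_table(
    results: Sequence[CombinationResult], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        fh.write("features\tR\trelative_power\n")
        for r in results:
            fh.write(f"{'+'.join(r.features)}\t{r.R:.6f}\t{r.relative_power:.6f}\n")


def write_enrichment_table(
    results: Sequence[EnrichmentResult], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        fh.write("feature\tx\tN\tK\tM\tp\tp_BH\tsignificant\n")
        for r in sorted(results, key=lambda r: r.p_value):
            fh.write(
                f"{r.feature}\t{r.x}\t{r.N}\t{r.K}\t{r.M}\t"
                f"{r.p_value:.6g}\t{r.p_bh:.6g}\t{int(r.significant)}\n"
            )
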