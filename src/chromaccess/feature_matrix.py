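"""Regions x features signal matrix with the DNase target vector.

Rows are DHS regions exactly as given (sorted order, no resizing); the same
aggregation method (max or avg) is applied to the feature tracks and to the
DNase target, matching how the two are paired downstream. Features with zero
signal everywhere are retained as constant columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .genomic import PeakSet, SignalTrack, aggregate_signal

__all__ = [
    "FeatureMatrix",
    "build_feature_matrix",
    "sample_regions",
    "write_feature_matrix",
    "read_feature_matrix",
]

AGGREGATIONS = ("max", "avg")


@dataclass
class FeatureMatrix:
    """Aggregated signals for DHS regions: X (features) and y (DNase)."""

    region_ids: List[str]
    feature_names: List[str]
    X: np.ndarray
    y: np.ndarray
    aggregation: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        n, f = self.X.shape
        if n != len(self.region_ids) or n != len(self.y):
            raise ValueError("X rows, y entries and region_ids must align")
        if f != len(self.feature_names):
            raise ValueError("X columns and feature_names must align")
        if len(set(self.feature_names)) != f:
            raise ValueError("duplicate feature names")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite signal values")
        if np.any(self.X < 0) or np.any(self.y < 0):
            raise ValueError("negative signal values")

    @property
    def n_regions(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def columns(self, features: Sequence[str]) -> np.ndarray:
        """X restricted to the named features, in the order given."""
        idx = []
        for name in features:
            try:
                idx.append(self.feature_names.index(name))
            except ValueError:
                raise KeyError(f"unknown feature {name!r}") from None
        return self.X[:, idx]


def build_feature_matrix(
    dhs: PeakSet,
    dnase_track: SignalTrack,
    feature_tracks: Sequence[SignalTrack],
    aggregation: str,
) -> FeatureMatrix:
    """Aggregate every track over every DHS region.

    X[i, j] = aggregate_signal(track_j, dhs_i); y[i] aggregates the DNase
    track with the same method. Region order follows the sorted DHS order.
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
    if len(dhs) == 0:
        raise ValueError("no DHS regions")
    names = [t.name for t in feature_tracks]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature track names")
    n = len(dhs)
    X = np.zeros((n, len(feature_tracks)))
    y = np.zeros(n)
    region_ids = [str(iv) for iv in dhs]
    for i, region in enumerate(dhs):
        y[i] = aggregate_signal(dnase_track, region, aggregation)
        for j, track in enumerate(feature_tracks):
            X[i, j] = aggregate_signal(track, region, aggregation)
    return FeatureMatrix(region_ids, names, X, y, aggregation)


def sample_regions(matrix: FeatureMatrix, n: int, seed: int) -> FeatureMatrix:
    """Uniform sample of min(n, rows) regions without replacement.

    Deterministic given the seed; the selected rows keep their original
    relative order, preserving the (X row, y entry) pairing.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    total = matrix.n_regions
    if n >= total:
        return matrix
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(total, size=n, replace=False))
    return FeatureMatrix(
        [matrix.region_ids[i] for i in idx],
        list(matrix.feature_names),
        matrix.X[idx],
        matrix.y[idx],
        matrix.aggregation,
    )


def write_feature_matrix(matrix: FeatureMatrix, path: Union[str, Path]) -> None:
    """Serialize as TSV: region id, feature columns, DNase target last."""
    df = pd.DataFrame(matrix.X, columns=matrix.feature_names)
    df.insert(0, "region", matrix.region_ids)
    df["DNase"] = matrix.y
    with open(path, "w") as fh:
        fh.write(f"# aggregation={matrix.aggregation}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def read_feature_matrix(path: Union[str, Path]) -> FeatureMatrix:
    aggregation = "max"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# aggregation="):
            aggregation = first.strip().split("=", 1)[1]
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    features = [c for c in df.columns if c not in ("region", "DNase")]
    return FeatureMatrix(
        df["region"].tolist(),
        features,
        df[features].to_numpy(dtype=float),
        df["DNase"].to_numpy(dtype=float),
        aggregation,
    )
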