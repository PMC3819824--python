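"""Independent brute-force oracles and small synthetic builders for tests.

These deliberately avoid the library code paths they are used to check:
aggregation and overlap are computed per base on materialized arrays, and
subset counts come from the factorial formula.
"""

from __future__ import annotations

from math import factorial
from typing import Sequence

import numpy as np

from chromaccess.feature_matrix import FeatureMatrix
from chromaccess.genomic import GenomicInterval, SignalTrack


def brute_aggregate(track: SignalTrack, region: GenomicInterval, method: str) -> float:
    """Per-base brute-force aggregation over a materialized value array."""
    values = np.zeros(region.length)
    for iv, v in track.segments():
        if iv.chrom != region.chrom:
            continue
        lo = max(iv.start, region.start)
        hi = min(iv.end, region.end)
        if lo < hi:
            values[lo - region.start : hi - region.start] = v
    return float(values.max()) if method == "max" else float(values.mean())


def brute_overlaps(query: GenomicInterval, targets) -> bool:
    """Per-base membership oracle."""
    bases = set(range(query.start, query.end))
    for t in targets:
        if t.chrom == query.chrom and bases & set(range(t.start, t.end)):
            return True
    return False


def n_subsets(f: int, k: int) -> int:
    """Binomial coefficient via the factorial formula."""
    return factorial(f) // (factorial(k) * factorial(f - k))


def random_track(rng: np.random.Generator, chrom: str = "chrT", length: int = 10_000,
                 max_segments: int = 30) -> SignalTrack:
    """Random sorted non-overlapping segments with random gaps."""
    n = int(rng.integers(0, max_segments + 1))
    cuts = np.sort(rng.choice(length, size=min(2 * n, length), replace=False))
    segments = []
    for i in range(0, len(cuts) - 1, 2):
        s, e = int(cuts[i]), int(cuts[i + 1])
        if s < e:
            segments.append((GenomicInterval(chrom, s, e), float(rng.uniform(0, 50))))
    return SignalTrack("random", segments)


def linear_matrix(
    n: int = 500,
    betas: Sequence[float] = (1.0, 0.0),
    noise: float = 0.1,
    seed: int = 0,
) -> FeatureMatrix:
    """Matrix whose target is a noisy linear function of the features.

    Feature j with beta 0 is pure standard-normal noise (shifted positive);
    y = sum_j beta_j * x_j + noise. All values are shifted to be >= 0.
    """
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 10, size=(n, len(betas)))
    y = X @ np.asarray(betas, dtype=float) + rng.normal(0, noise, n)
    y -= min(y.min(), 0.0)
    names = [f"f{j}" for j in range(len(betas))]
    return FeatureMatrix([f"r{i}" for i in range(n)], names, X, y, "max")
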