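"""Synthetic DHS regions, peak sets, and signal tracks.

The generator encodes the statistical structure the downstream analysis
assumes: a latent per-region accessibility value drives the DNase signal
and, through monotone power links with multiplicative log-normal noise, a
configurable subset of feature signals. Redundancy between features is
controlled by mixing a shared latent with feature-private latents; peak
placement is controlled by a per-feature in-DHS probability.

Signal bumps are discretized symmetric triangles built so that the
per-region maximum equals the bump height exactly and the bump integral
equals height * width / 2 exactly (so the per-region average is
height * width / (2 * region_length)). Bump width varies randomly between
regions, which makes the maximum a cleaner readout of the latent than the
average — the max-vs-avg contrast exists by construction.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .genomic import GenomicInterval, PeakSet, SignalTrack, write_bed, write_bedgraph

__all__ = [
    "FeatureSpec",
    "SyntheticConfig",
    "SyntheticDataset",
    "simulate_regions",
    "simulate_signal_tracks",
    "simulate_peaks",
    "simulate_dataset",
    "default_paper_like_config",
    "tent_bump_segments",
]


@dataclass(frozen=True)
class FeatureSpec:
    """Generative parameters for one chromatin feature.

    ``beta`` is the link exponent (signal height proportional to the
    effective latent raised to beta; beta = 0 means pure noise), ``tau`` the
    multiplicative log-noise scale, ``latent_share`` the weight of the shared
    accessibility latent versus a feature-private latent, and ``p_in_dhs``
    the probability a peak is placed inside a DHS.
    """

    name: str
    feature_class: str  # "HM" | "TF"
    beta: float = 1.0
    tau: float = 0.3
    latent_share: float = 1.0
    p_in_dhs: float = 0.5
    n_peaks: int = 1000
    saturation: float = 0.0  # half-saturation constant; 0 = pure power link

    def __post_init__(self) -> None:
        if self.feature_class not in ("HM", "TF"):
            raise ValueError(f"feature class must be HM or TF, got {self.feature_class!r}")
        if not 0.0 <= self.p_in_dhs <= 1.0:
            raise ValueError("p_in_dhs must be in [0, 1]")
        if not 0.0 <= self.latent_share <= 1.0:
            raise ValueError("latent_share must be in [0, 1]")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")

    @property
    def informative(self) -> bool:
        return self.beta != 0.0


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    chrom: str = "chrSim"
    chrom_length: int = 3_000_000
    n_dhs: int = 2500
    dhs_length_range: Tuple[int, int] = (200, 600)
    min_gap: int = 40
    latent_mu: float = 1.0
    latent_sigma: float = 0.85
    dnase_noise_sd: float = 0.15
    peak_length_range: Tuple[int, int] = (80, 300)
    bump_steps: int = 8  # steps per triangle side
    bump_frac_range: Tuple[float, float] = (0.25, 0.9)
    background_rate: float = 0.0  # per-gap probability of a low bump
    background_height: float = 0.2
    features: Tuple[FeatureSpec, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.dhs_length_range
        if not 0 < lo <= hi:
            raise ValueError("invalid dhs_length_range")
        if self.bump_steps < 2:
            raise ValueError("bump_steps must be >= 2")
        if lo < 2 * 2 * self.bump_steps:
            raise ValueError("min DHS length must fit at least two bump units")
        if self.latent_sigma < 0 or self.dnase_noise_sd < 0:
            raise ValueError("noise scales must be >= 0")
        needed = self.n_dhs * (hi + self.min_gap) + self.min_gap
        if needed >= self.chrom_length:
            raise ValueError(
                f"n_dhs * max length exceeds chromosome: need < {self.chrom_length}, "
                f"worst case {needed}"
            )
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")
        object.__setattr__(self, "features", tuple(self.features))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dhs_length_range"] = list(self.dhs_length_range)
        d["peak_length_range"] = list(self.peak_length_range)
        d["bump_frac_range"] = list(self.bump_frac_range)
        d["features"] = [asdict(f) for f in self.features]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["dhs_length_range"] = tuple(d["dhs_length_range"])
        d["peak_length_range"] = tuple(d["peak_length_range"])
        d["bump_frac_range"] = tuple(d["bump_frac_range"])
        d["features"] = tuple(FeatureSpec(**f) for f in d["features"])
        return cls(**d)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _substream(seed: int, *tags: str) -> np.random.Generator:
    """Independent named RNG substream derived from (seed, tags)."""
    entropy = [seed] + [zlib.crc32(t.encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# Regions and latents
# ---------------------------------------------------------------------------


def simulate_regions(config: SyntheticConfig) -> Tuple[PeakSet, np.ndarray]:
    """Non-overlapping DHS regions plus i.i.d. log-normal latents.

    Regions are placed by distributing the free space left after reserving
    region lengths and minimum gaps, so placement always succeeds when the
    config invariant (regions fit on the chromosome) holds.
    """
    rng = _substream(config.seed, "regions")
    lo, hi = config.dhs_length_range
    lengths = rng.integers(lo, hi + 1, config.n_dhs)
    g = config.min_gap
    free = config.chrom_length - int(lengths.sum()) - g * (config.n_dhs + 1)
    if free < 0:
        raise ValueError("chromosome too crowded to place all regions")
    offsets = np.sort(rng.integers(0, free + 1, config.n_dhs))
    prefix = np.concatenate([[0], np.cumsum(lengths[:-1] + g)])
    starts = g + offsets + prefix
    intervals = [
        GenomicInterval(config.chrom, int(s), int(s + l))
        for s, l in zip(starts, lengths)
    ]
    latents = _substream(config.seed, "latents").lognormal(
        config.latent_mu, config.latent_sigma, config.n_dhs
    )
    return PeakSet("DHS", intervals), latents


# ---------------------------------------------------------------------------
# Signal tracks
# ---------------------------------------------------------------------------


def tent_bump_segments(
    start: int, width: int, height: float, steps_per_side: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Discretized symmetric triangle over [start, start + width).

    Step values rise linearly 0 .. height over ``steps_per_side`` equal-width
    steps and mirror back down, so max = height exactly and the integral is
    height * width / 2 exactly. ``width`` must be divisible by
    2 * steps_per_side. Zero-valued steps are dropped.
    """
    m = steps_per_side
    if m < 2:
        raise ValueError("steps_per_side must be >= 2")
    if width % (2 * m) != 0:
        raise ValueError(f"width must be a multiple of {2 * m}")
    step = width // (2 * m)
    asc = np.arange(m) / (m - 1)
    pattern = np.concatenate([asc, asc[::-1]])
    starts = start + np.arange(2 * m) * step
    ends = starts + step
    values = height * pattern
    keep = values > 0
    return starts[keep], ends[keep], values[keep]


def _bump_arrays(
    region_starts: np.ndarray,
    region_lengths: np.ndarray,
    heights: np.ndarray,
    rng: np.random.Generator,
    config: SyntheticConfig,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized tent bumps (one per region) with randomized width/offset."""
    m = config.bump_steps
    unit = 2 * m
    f_lo, f_hi = config.bump_frac_range
    frac = rng.uniform(f_lo, f_hi, len(region_starts))
    widths = np.clip(
        (frac * region_lengths).astype(np.int64) // unit, 1, region_lengths // unit
    ) * unit
    offsets = rng.integers(0, region_lengths - widths + 1)
    step = widths // unit
    asc = np.arange(m) / (m - 1)
    pattern = np.concatenate([asc, asc[::-1]])  # length 2m, max exactly 1
    starts = (region_starts + offsets)[:, None] + np.arange(unit)[None, :] * step[:, None]
    ends = starts + step[:, None]
    values = heights[:, None] * pattern[None, :]
    starts, ends, values = starts.ravel(), ends.ravel(), values.ravel()
    keep = values > 0
    return starts[keep], ends[keep], values[keep]


def _background_segments(
    dhs: PeakSet, rng: np.random.Generator, config: SyntheticConfig
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Low constant bumps in inter-DHS gaps, one per selected gap."""
    starts, ends, values = [], [], []
    gap_starts, gap_ends = _gaps(dhs, config.chrom_length)
    for gs, ge in zip(gap_starts, gap_ends):
        gap = ge - gs
        if gap < 4 or rng.random() >= config.background_rate:
            continue
        w = min(gap // 2, 50)
        s = gs + (gap - w) // 2
        starts.append(s)
        ends.append(s + w)
        values.append(config.background_height * rng.uniform(0.5, 1.5))
    return (
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        np.array(values, dtype=np.float64),
    )


def simulate_signal_tracks(
    dhs: PeakSet, latents: np.ndarray, config: SyntheticConfig
) -> Tuple[SignalTrack, List[SignalTrack]]:
    """DNase track plus one track per configured feature.

    Within DHS i each track carries one tent bump whose height is
    h_i = g(e_i^beta) * exp(eps), eps ~ Normal(0, tau^2), where the effective
    latent mixes the shared accessibility latent with a feature-private one
    on the log scale: log e_i = share * log a_i + (1 - share) * log b_i.
    The link g is the identity, or the saturating map u -> u / (1 + u / K)
    when the feature's half-saturation constant K is set (a monotone
    nonlinear link). The DNase height uses the shared latent directly
    (beta = 1, no saturation) with its own noise scale.
    """
    if len(dhs) != len(latents):
        raise ValueError("regions and latents must align")
    region_starts = np.array([iv.start for iv in dhs], dtype=np.int64)
    region_lengths = np.array([iv.length for iv in dhs], dtype=np.int64)
    log_a = np.log(latents)

    def build(name: str, heights: np.ndarray, rng: np.random.Generator) -> SignalTrack:
        s, e, v = _bump_arrays(region_starts, region_lengths, heights, rng, config)
        if config.background_rate > 0:
            bs, be, bv = _background_segments(dhs, rng, config)
            order = np.argsort(np.concatenate([s, bs]), kind="stable")
            s = np.concatenate([s, bs])[order]
            e = np.concatenate([e, be])[order]
            v = np.concatenate([v, bv])[order]
        return SignalTrack.from_arrays(name, {config.chrom: (s, e, v)})

    rng = _substream(config.seed, "signal", "DNase")
    dnase_heights = latents * np.exp(rng.normal(0.0, config.dnase_noise_sd, len(dhs)))
    dnase_track = build("DNase", dnase_heights, rng)

    feature_tracks = []
    for spec in config.features:
        rng = _substream(config.seed, "signal", spec.name)
        private = rng.lognormal(config.latent_mu, config.latent_sigma, len(dhs))
        log_eff = spec.latent_share * log_a + (1 - spec.latent_share) * np.log(private)
        powered = np.exp(spec.beta * log_eff)
        if spec.saturation > 0:
            powered = powered / (1.0 + powered / spec.saturation)
        noise = rng.normal(0.0, spec.tau, len(dhs)) if spec.tau > 0 else 0.0
        heights = powered * np.exp(noise)
        feature_tracks.append(build(spec.name, heights, rng))
    return dnase_track, feature_tracks


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------


def _gaps(dhs: PeakSet, chrom_length: int) -> Tuple[np.ndarray, np.ndarray]:
    starts = np.array([iv.start for iv in dhs], dtype=np.int64)
    ends = np.array([iv.end for iv in dhs], dtype=np.int64)
    gap_starts = np.concatenate([[0], ends])
    gap_ends = np.concatenate([starts, [chrom_length]])
    keep = gap_ends > gap_starts
    return gap_starts[keep], gap_ends[keep]


def simulate_peaks(dhs: PeakSet, config: SyntheticConfig) -> Dict[str, PeakSet]:
    """Per-feature peak sets with the configured in-DHS placement probability.

    Each peak lands inside a uniformly chosen DHS with probability p_in_dhs
    and otherwise entirely inside an inter-DHS gap (chosen with probability
    proportional to gap length, peak length clipped to fit).
    """
    region_starts = np.array([iv.start for iv in dhs], dtype=np.int64)
    region_lengths = np.array([iv.length for iv in dhs], dtype=np.int64)
    gap_starts, gap_ends = _gaps(dhs, config.chrom_length)
    gap_lengths = gap_ends - gap_starts
    if len(gap_lengths) == 0:
        raise ValueError("no gap space available for out-of-DHS peaks")
    gap_p = gap_lengths / gap_lengths.sum()
    lo, hi = config.peak_length_range
    peaksets: Dict[str, PeakSet] = {}
    for spec in config.features:
        rng = _substream(config.seed, "peaks", spec.name)
        n = spec.n_peaks
        plen = rng.integers(lo, hi + 1, n)
        inside = rng.random(n) < spec.p_in_dhs
        # inside placement: start uniform within the chosen region
        ridx = rng.integers(0, len(dhs), n)
        in_start = region_starts[ridx] + (
            rng.random(n) * region_lengths[ridx]
        ).astype(np.int64)
        in_end = np.minimum(in_start + plen, config.chrom_length)
        # outside placement: entirely within a length-weighted random gap
        gidx = rng.choice(len(gap_lengths), n, p=gap_p)
        out_len = np.minimum(plen, gap_lengths[gidx])
        out_start = gap_starts[gidx] + (
            rng.random(n) * (gap_lengths[gidx] - out_len + 1)
        ).astype(np.int64)
        out_end = out_start + out_len
        starts = np.where(inside, in_start, out_start)
        ends = np.where(inside, in_end, out_end)
        intervals = [
            GenomicInterval(config.chrom, int(s), int(e)) for s, e in zip(starts, ends)
        ]
        peaksets[spec.name] = PeakSet(spec.name, intervals)
    return peaksets


# ---------------------------------------------------------------------------
# Dataset bundle and the 33-feature default
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    dhs: PeakSet
    latents: np.ndarray
    dnase_track: SignalTrack
    feature_tracks: List[SignalTrack]
    peaks: Dict[str, PeakSet]

    def truth_table(self) -> pd.DataFrame:
        """Generative parameters per feature, for parameter-recovery tests."""
        rows = []
        for spec in self.config.features:
            rows.append(
                {
                    "feature": spec.name,
                    "class": spec.feature_class,
                    "beta": spec.beta,
                    "tau": spec.tau,
                    "latent_share": spec.latent_share,
                    "informativeness": spec.beta * spec.latent_share,
                    "saturation": spec.saturation,
                    "p_in_dhs": spec.p_in_dhs,
                    "n_peaks": spec.n_peaks,
                }
            )
        return pd.DataFrame(rows)

    def feature_classes(self) -> Dict[str, str]:
        return {spec.name: spec.feature_class for spec in self.config.features}


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Run all generator stages from one config; fully seed-deterministic."""
    dhs, latents = simulate_regions(config)
    dnase_track, feature_tracks = simulate_signal_tracks(dhs, latents, config)
    peaks = simulate_peaks(dhs, config)
    return SyntheticDataset(config, dhs, latents, dnase_track, feature_tracks, peaks)


def write_dataset(dataset: SyntheticDataset, outdir: Union[str, Path]) -> None:
    """Write DHS BED, per-feature peak BEDs, bedGraph tracks, config, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed(dataset.dhs, outdir / "dhs.bed")
    write_bedgraph(dataset.dnase_track, outdir / "DNase.bedGraph")
    peaks_dir = outdir / "peaks"
    tracks_dir = outdir / "tracks"
    peaks_dir.mkdir(exist_ok=True)
    tracks_dir.mkdir(exist_ok=True)
    for track in dataset.feature_tracks:
        write_bedgraph(track, tracks_dir / f"{track.name}.bedGraph")
    for name, peakset in dataset.peaks.items():
        write_bed(peakset, peaks_dir / f"{name}.bed")
    dataset.config.to_yaml(outdir / "config.yaml")
    dataset.truth_table().to_csv(outdir / "truth.tsv", sep="\t", index=False)


# (name, class, beta, latent_share, tau, p_in_dhs); beta = 0 marks pure noise
_DEFAULT_FEATURE_TABLE = [
    ("H3k4me2", "HM", 2.00, 0.95, 0.22, 0.62),
    ("H3k4me3", "HM", 1.60, 0.92, 0.25, 0.82),
    ("H3k9ac", "HM", 2.40, 0.88, 0.28, 0.70),
    ("H3k27ac", "HM", 1.80, 0.72, 0.40, 0.55),
    ("H3k4me1", "HM", 2.20, 0.66, 0.45, 0.48),
    ("H2az", "HM", 1.70, 0.60, 0.50, 0.50),
    ("H4k20me1", "HM", 2.30, 0.52, 0.55, 0.25),
    ("H3k27me3", "HM", 1.50, 0.42, 0.62, 0.15),
    ("H3k36me3", "HM", 1.40, 0.30, 0.72, 0.10),
    ("H3k9me3", "HM", 1.30, 0.24, 0.80, 0.06),
    ("SIN3A", "TF", 1.90, 0.93, 0.22, 0.75),
    ("ZNF143", "TF", 2.10, 0.90, 0.24, 0.72),
    ("TAF1", "TF", 1.80, 0.85, 0.28, 0.80),
    ("POU5F1", "TF", 2.20, 0.80, 0.32, 0.70),
    ("NANOG", "TF", 1.60, 0.76, 0.35, 0.68),
    ("YY1", "TF", 2.40, 0.72, 0.38, 0.66),
    ("SP1", "TF", 1.70, 0.68, 0.42, 0.64),
    ("GABPA", "TF", 2.00, 0.64, 0.45, 0.62),
    ("MYC", "TF", 1.80, 0.60, 0.48, 0.60),
    ("MAX", "TF", 2.20, 0.56, 0.52, 0.58),
    ("EGR1", "TF", 1.60, 0.52, 0.55, 0.56),
    ("JUND", "TF", 2.10, 0.48, 0.58, 0.54),
    ("NRF1", "TF", 1.90, 0.44, 0.62, 0.52),
    ("RAD21", "TF", 1.70, 0.40, 0.65, 0.50),
    ("SRF", "TF", 2.00, 0.36, 0.68, 0.48),
    ("TBP", "TF", 1.80, 0.33, 0.72, 0.65),
    ("USF1", "TF", 1.60, 0.30, 0.75, 0.45),
    ("RFX5", "TF", 2.20, 0.27, 0.78, 0.42),
    ("SIX5", "TF", 1.90, 0.24, 0.82, 0.40),
    ("CTCF", "TF", 1.50, 0.22, 0.85, 0.35),
    ("SUZ12", "TF", 1.40, 0.20, 0.88, 0.30),
    ("ZNF274", "TF", 0.00, 0.00, 0.90, 0.15),
    ("REST", "TF", 0.00, 0.00, 0.90, 0.55),
]


def default_paper_like_config(
    seed: int = 0, n_dhs: int = 2500, n_peaks: int = 2000
) -> SyntheticConfig:
    """A 33-feature configuration (10 HMs + 23 TF binding features).

    A few strongly informative, highly shared features; many moderately
    informative redundant ones; weakly informative and pure-noise features
    at the tail. In-DHS placement probabilities spread over [0.06, 0.82]
    with the TF-class mean above the HM-class mean.
    """
    features = tuple(
        FeatureSpec(
            name=name,
            feature_class=cls,
            beta=beta,
            latent_share=share,
            tau=tau,
            p_in_dhs=p,
            n_peaks=n_peaks,
            # half-saturation at the typical powered latent: the link bends
            # where the data live, so feature-vs-DNase relations are nonlinear
            saturation=float(np.exp(beta * 1.0)) if beta > 0 else 0.0,
        )
        for name, cls, beta, share, tau, p in _DEFAULT_FEATURE_TABLE
    )
    return SyntheticConfig(seed=seed, n_dhs=n_dhs, features=features)
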