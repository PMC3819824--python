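"""End-to-end orchestration: localization, matrices, models, combinations.

All randomness flows from a single master seed through named substreams
(one per stage), so rerunning one stage never perturbs another's stream and
two runs with the same seed produce byte-identical tables.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .combinatorics import (
    evaluate_combinations,
    feature_enrichment,
    sample_size_curve,
    top_combinations,
    write_combination_table,
    write_enrichment_table,
)
from .feature_matrix import build_feature_matrix, sample_regions, write_feature_matrix
from .genomic import read_bed, read_signal_track
from .localization import localization_table, write_localization_table
from .modeling import ModelConfig, make_folds, model_comparison

logger = logging.getLogger("chromaccess")

__all__ = ["FeatureInput", "PipelineConfig", "run_full_analysis", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0])


@dataclass
class FeatureInput:
    name: str
    feature_class: str  # "HM" | "TF"
    track_path: str
    peak_path: Optional[str] = None
    dialect: str = "bedgraph"


@dataclass
class PipelineConfig:
    dhs_path: str
    dnase_path: str
    features: List[FeatureInput]
    dnase_dialect: str = "bedgraph"
    sample_n: int = 5000
    folds: int = 10
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)
    combo_model: Optional[ModelConfig] = None  # defaults to ``model``
    combination_ks: Tuple[int, ...] = (1, 2, 3)
    top_threshold: float = 0.90
    enrichment_alpha: float = 0.01
    curve_sizes: Tuple[int, ...] = (200, 500, 1000, 2000)
    curve_reps: int = 20  # scaled down from the reference 500 for routine runs

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if not self.features:
            raise ValueError("at least one feature is required")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["combination_ks"] = list(self.combination_ks)
        d["curve_sizes"] = list(self.curve_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["features"] = [FeatureInput(**f) for f in d["features"]]
        d["model"] = ModelConfig(**d.get("model", {}))
        if d.get("combo_model") is not None:
            d["combo_model"] = ModelConfig(**d["combo_model"])
        d["combination_ks"] = tuple(d.get("combination_ks", (1, 2, 3)))
        d["curve_sizes"] = tuple(d.get("curve_sizes", (200, 500, 1000, 2000)))
        return cls(**d)

    def to_yaml(self, path: Union[str, Path]) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class StageError(RuntimeError):
    """Wraps a failure with the name of the pipeline stage that raised it."""


def _stage(name: str, manifest: dict):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            elapsed = time.perf_counter() - self.t0
            if exc is not None:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            manifest.setdefault("timings", {})[name] = round(elapsed, 3)
            logger.info("stage %s: done in %.2fs", name, elapsed)

    return _Timer()


def run_full_analysis(
    config: PipelineConfig, outdir: Union[str, Path]
) -> Dict[str, object]:
    """Run localization, matrix building, model comparison, combinations,
    enrichment and the sample-size curve; write all tables under ``outdir``.

    Returns a bundle with the in-memory results and writes a manifest of the
    parameters and stage timings.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "sample_n": config.sample_n,
        "folds": config.folds,
        "combination_ks": list(config.combination_ks),
        "top_threshold": config.top_threshold,
        "enrichment_alpha": config.enrichment_alpha,
    }
    bundle: Dict[str, object] = {}

    with _stage("load", manifest):
        dhs = read_bed(config.dhs_path, name="DHS")
        dnase = read_signal_track(config.dnase_path, config.dnase_dialect, name="DNase")
        tracks = [
            read_signal_track(f.track_path, f.dialect, name=f.name)
            for f in config.features
        ]
        peaksets = [
            (read_bed(f.peak_path, name=f.name), f.feature_class)
            for f in config.features
            if f.peak_path
        ]
        classes = {f.name: f.feature_class for f in config.features}
        manifest["n_dhs"] = len(dhs)
        manifest["n_features"] = len(tracks)

    if peaksets:
        with _stage("localization", manifest):
            records, class_means = localization_table(peaksets, dhs)
            write_localization_table(records, class_means, outdir / "localization.tsv")
            bundle["localization"] = (records, class_means)

    with _stage("feature_matrix", manifest):
        sample_s = stage_seed(config.seed, "sample")
        matrices = {}
        for agg in ("max", "avg"):
            full = build_feature_matrix(dhs, dnase, tracks, agg)
            # identical seed for both aggregations -> identical region subset
            matrices[agg] = sample_regions(full, config.sample_n, sample_s)
            write_feature_matrix(matrices[agg], outdir / f"matrix_{agg}.tsv")
        manifest["n_sampled"] = matrices["max"].n_regions
        bundle["matrices"] = matrices

    with _stage("model_comparison", manifest):
        table = model_comparison(
            matrices["max"],
            matrices["avg"],
            classes,
            config.model,
            k=config.folds,
            seed=stage_seed(config.seed, "folds"),
        )
        table.to_csv(outdir / "model_comparison.tsv", sep="\t", float_format="%.6f")
        bundle["model_comparison"] = table

    combo_cfg = config.combo_model if config.combo_model is not None else config.model
    matrix = matrices["max"]
    folds = make_folds(
        matrix.n_regions, config.folds, stage_seed(config.seed, "folds")
    )
    with _stage("combinations", manifest):
        all_results = {}
        r_full = None
        for k in config.combination_ks:
            results, r_full = evaluate_combinations(
                matrix, k, combo_cfg, fold_assignment=folds
            )
            write_combination_table(results, outdir / f"combinations_k{k}.tsv")
            all_results[k] = results
        manifest["R_full"] = r_full
        bundle["combinations"] = all_results
        bundle["R_full"] = r_full

    with _stage("enrichment", manifest):
        k_top = max(config.combination_ks)
        top = top_combinations(all_results[k_top], r_full, config.top_threshold)
        write_combination_table(top, outdir / "top_combinations.tsv")
        bundle["top"] = top
        if top:
            enrichment = feature_enrichment(
                top, matrix.feature_names, k_top, config.enrichment_alpha
            )
            write_enrichment_table(enrichment, outdir / "enrichment.tsv")
            bundle["enrichment"] = enrichment
        manifest["n_top"] = len(top)

    with _stage("sample_size_curve", manifest):
        sizes = [s for s in config.curve_sizes if s <= matrix.n_regions]
        if sizes:
            curve = sample_size_curve(
                matrix,
                sizes,
                reps=config.curve_reps,
                config=combo_cfg,
                folds=config.folds,
                seed=stage_seed(config.seed, "curve"),
            )
            curve.to_csv(outdir / "sample_size_curve.tsv", sep="\t", index=False)
            bundle["sample_size_curve"] = curve

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    bundle["manifest"] = manifest
    return bundle
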