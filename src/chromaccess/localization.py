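"""Per-feature localization of peaks within open-chromatin regions.

A peak is counted as present in open chromatin if it overlaps any DHS
interval by at least one base; peaks overlapping several DHSs count once.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

from .genomic import PeakSet, overlaps_any

__all__ = [
    "LocalizationRecord",
    "fraction_in_open",
    "localization_table",
    "write_localization_table",
]

FEATURE_CLASSES = ("HM", "TF")


@dataclass(frozen=True)
class LocalizationRecord:
    feature: str
    feature_class: str
    n_peaks: int
    n_in_dhs: int
    percent_in_dhs: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_in_dhs <= self.n_peaks:
            raise ValueError("require 0 <= n_in_dhs <= n_peaks")


def fraction_in_open(
    peaks: PeakSet, dhs: PeakSet, feature_class: str = "NA"
) -> LocalizationRecord:
    """Fraction of a feature's peaks overlapping open chromatin.

    Raises ValueError on an empty peak set (the percentage is undefined).
    """
    if len(peaks) == 0:
        raise ValueError(f"peak set {peaks.name!r} is empty; percentage undefined")
    n_in = sum(1 for peak in peaks if overlaps_any(peak, dhs))
    return LocalizationRecord(
        feature=peaks.name,
        feature_class=feature_class,
        n_peaks=len(peaks),
        n_in_dhs=n_in,
        percent_in_dhs=100.0 * n_in / len(peaks),
    )


def localization_table(
    feature_peaksets: Sequence[Tuple[PeakSet, str]], dhs: PeakSet
) -> Tuple[List[LocalizationRecord], Dict[str, float]]:
    """One localization record per feature plus unweighted per-class means.

    ``feature_peaksets`` is a sequence of (peaks, feature_class) pairs with
    feature_class in {"HM", "TF"}. Class means are unweighted arithmetic
    means of the per-feature percentages.
    """
    records = []
    for peaks, feature_class in feature_peaksets:
        if feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {feature_class!r}")
        records.append(fraction_in_open(peaks, dhs, feature_class))
    class_means: Dict[str, float] = {}
    for cls in FEATURE_CLASSES:
        pcts = [r.percent_in_dhs for r in records if r.feature_class == cls]
        if pcts:
            class_means[cls] = sum(pcts) / len(pcts)
    return records, class_means


def write_localization_table(
    records: Sequence[LocalizationRecord],
    class_means: Dict[str, float],
    path: Union[str, Path],
) -> None:
    """Tab-separated table with a per-class mean footer."""
    with open(path, "w") as fh:
        fh.write("feature\tclass\tn_peaks\tn_in_dhs\tpercent_in_dhs\n")
        for r in sorted(records, key=lambda r: -r.percent_in_dhs):
            fh.write(
                f"{r.feature}\t{r.feature_class}\t{r.n_peaks}\t{r.n_in_dhs}\t"
                f"{r.percent_in_dhs:.4f}\n"
            )
        for cls in sorted(class_means):
            fh.write(f"#mean\t{cls}\t.\t.\t{class_means[cls]:.4f}\n")
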