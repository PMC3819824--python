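"""Genomic interval and signal-track data model.

Coordinates are 0-based half-open throughout (BED/bedGraph native); wiggle
input is converted on read. Any base not covered by a signal segment carries
value exactly 0 (sequencing-coverage semantics), and touching intervals
([a, b) vs [b, c)) do not overlap.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "SignalTrack",
    "ParseError",
    "read_bed",
    "write_bed",
    "read_signal_track",
    "write_bedgraph",
    "aggregate_signal",
    "overlaps_any",
]


class ParseError(ValueError):
    """Raised for malformed interval or signal files; message names the line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class PeakSet:
    """A named collection of intervals, kept sorted by (chrom, start, end).

    Intervals are stored exactly as given apart from sorting: overlapping or
    duplicate peaks are never merged.
    """

    def __init__(self, name: str, intervals: Iterable[GenomicInterval]):
        self.name = name
        self.intervals: Tuple[GenomicInterval, ...] = tuple(
            sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        )
        self._index: Union[Dict[str, Tuple[np.ndarray, np.ndarray]], None] = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.name == other.name and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"PeakSet({self.name!r}, n={len(self)})"

    def chromosomes(self) -> List[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def overlap_index(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, running-max ends) arrays for O(log n) queries."""
        if self._index is None:
            index: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
            by_chrom: Dict[str, List[GenomicInterval]] = {}
            for iv in self.intervals:
                by_chrom.setdefault(iv.chrom, []).append(iv)
            for chrom, ivs in by_chrom.items():
                starts = np.array([iv.start for iv in ivs], dtype=np.int64)
                ends = np.array([iv.end for iv in ivs], dtype=np.int64)
                index[chrom] = (starts, np.maximum.accumulate(ends))
            self._index = index
        return self._index


def overlaps_any(
    query: GenomicInterval,
    targets: Union[PeakSet, Sequence[GenomicInterval]],
) -> bool:
    """True iff >= 1 base of ``query`` is shared with any target interval.

    ``targets`` must be sorted by (chrom, start). Half-open arithmetic:
    touching intervals do not overlap. Uses binary search on the sorted
    starts plus a running maximum of ends, so overlapping targets with
    non-monotone ends are handled without a full scan.
    """
    if isinstance(targets, PeakSet):
        index = targets.overlap_index()
        entry = index.get(query.chrom)
        if entry is None:
            return False
        starts, maxends = entry
        # candidates: targets with start < query.end
        k = int(np.searchsorted(starts, query.end, side="left"))
        return k > 0 and int(maxends[k - 1]) > query.start
    # generic sorted sequence: binary search on (chrom, start) keys
    keys = [(iv.chrom, iv.start) for iv in targets]
    k = bisect.bisect_left(keys, (query.chrom, query.end))
    for iv in reversed(targets[:k]):
        if iv.chrom != query.chrom:
            break
        if iv.end > query.start:
            return True
    return False


class SignalTrack:
    """Piecewise-constant per-base signal with bedGraph semantics.

    Segments on each chromosome are sorted and non-overlapping; values are
    non-negative floats; uncovered bases implicitly carry value 0.
    Internally stored per chromosome as parallel (starts, ends, values)
    numpy arrays.
    """

    def __init__(
        self,
        name: str,
        segments: Iterable[Tuple[GenomicInterval, float]] = (),
    ):
        by_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
        for iv, value in segments:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, float(value)))
        data: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=np.float64)
            data[chrom] = (starts, ends, values)
        self.name = name
        self._data = data
        self._validate()

    @classmethod
    def from_arrays(
        cls,
        name: str,
        data: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]],
    ) -> "SignalTrack":
        """Build directly from per-chromosome (starts, ends, values) arrays.

        Arrays must already be sorted by start; validation is still applied.
        """
        track = cls.__new__(cls)
        track.name = name
        track._data = {
            chrom: (
                np.asarray(s, dtype=np.int64),
                np.asarray(e, dtype=np.int64),
                np.asarray(v, dtype=np.float64),
            )
            for chrom, (s, e, v) in data.items()
        }
        track._validate()
        return track

    def _validate(self) -> None:
        for chrom, (starts, ends, values) in self._data.items():
            if len(starts) == 0:
                continue
            if np.any(starts < 0) or np.any(ends <= starts):
                raise ValueError(f"{self.name}/{chrom}: invalid segment coordinates")
            if np.any(np.diff(starts) < 0):
                raise ValueError(f"{self.name}/{chrom}: segments not sorted")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{self.name}/{chrom}: overlapping segments")
            if np.any(values < 0) or not np.all(np.isfinite(values)):
                raise ValueError(f"{self.name}/{chrom}: negative or non-finite value")

    def chromosomes(self) -> List[str]:
        return sorted(self._data)

    def chrom_arrays(self, chrom: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        empty = (
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.float64),
        )
        return self._data.get(chrom, empty)

    def segments(self) -> Iterator[Tuple[GenomicInterval, float]]:
        for chrom in self.chromosomes():
            starts, ends, values = self._data[chrom]
            for s, e, v in zip(starts, ends, values):
                yield GenomicInterval(chrom, int(s), int(e)), float(v)

    def n_segments(self) -> int:
        return sum(len(s) for s, _, _ in self._data.values())

    def value_at(self, chrom: str, pos: int) -> float:
        starts, ends, values = self.chrom_arrays(chrom)
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and ends[i] > pos:
            return float(values[i])
        return 0.0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if self.name != other.name or set(self._data) != set(other._data):
            return False
        for chrom in self._data:
            a, b = self._data[chrom], other._data[chrom]
            if not all(np.array_equal(x, y) for x, y in zip(a, b)):
                return False
        return True

    def __repr__(self) -> str:
        return f"SignalTrack({self.name!r}, segments={self.n_segments()})"


def aggregate_signal(
    track: SignalTrack, region: GenomicInterval, method: str
) -> float:
    """Aggregate the track over a region.

    ``max``: maximum per-base value over all bases of the region (uncovered
    bases count as 0). ``avg``: base-weighted mean over the region with
    uncovered bases contributing 0. An entirely uncovered region yields 0.
    """
    if method not in ("max", "avg"):
        raise ValueError(f"unknown aggregation method {method!r}")
    starts, ends, values = track.chrom_arrays(region.chrom)
    if len(starts) == 0:
        return 0.0
    # segments intersecting [start, end): end > region.start and start < region.end
    i = int(np.searchsorted(ends, region.start, side="right"))
    j = int(np.searchsorted(starts, region.end, side="left"))
    if i >= j:
        return 0.0
    seg_starts = starts[i:j]
    seg_ends = ends[i:j]
    seg_values = values[i:j]
    overlap = np.minimum(seg_ends, region.end) - np.maximum(seg_starts, region.start)
    if method == "avg":
        return float(np.dot(seg_values, overlap) / region.length)
    # values are >= 0, so partial coverage never lowers the max below 0
    return float(seg_values.max())


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("track", "browser", "#")


def _data_lines(path: Union[str, Path]) -> Iterator[Tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line


def read_bed(path: Union[str, Path], name: Union[str, None] = None) -> PeakSet:
    """Read a BED file (>= 3 columns) into a sorted PeakSet.

    Extra columns are ignored; track/browser/comment lines are skipped.
    """
    intervals: List[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 fields, got {len(fields)}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        try:
            intervals.append(GenomicInterval(chrom, start, end))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(name if name is not None else Path(path).stem, intervals)


def write_bed(peaks: PeakSet, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for iv in peaks:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_signal_track(
    path: Union[str, Path], dialect: str = "bedgraph", name: Union[str, None] = None
) -> SignalTrack:
    """Read a bedGraph or wiggle (fixedStep/variableStep) signal track.

    Wiggle coordinates are 1-based per the standard and are converted to the
    internal 0-based half-open convention. Overlapping segments and negative
    values are errors.
    """
    if dialect not in ("bedgraph", "wiggle"):
        raise ValueError(f"unknown dialect {dialect!r}")
    track_name = name if name is not None else Path(path).stem
    segments: List[Tuple[GenomicInterval, float]] = []
    if dialect == "bedgraph":
        for lineno, line in _data_lines(path):
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed bedGraph line") from exc
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative signal value {value}")
            try:
                segments.append((GenomicInterval(fields[0], start, end), value))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    else:
        segments = _parse_wiggle(path)
    try:
        return SignalTrack(track_name, segments)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _parse_wiggle(path: Union[str, Path]) -> List[Tuple[GenomicInterval, float]]:
    segments: List[Tuple[GenomicInterval, float]] = []
    mode = None  # "fixed" | "variable"
    chrom = ""
    span = 1
    step = 1
    pos0 = 0  # next 0-based start for fixedStep
    for lineno, line in _data_lines(path):
        fields = line.split()
        if fields[0] in ("fixedStep", "variableStep"):
            params = dict(f.split("=", 1) for f in fields[1:])
            if "chrom" not in params:
                raise ParseError(f"{path}:{lineno}: declaration missing chrom=")
            chrom = params["chrom"]
            span = int(params.get("span", 1))
            if fields[0] == "fixedStep":
                mode = "fixed"
                if "start" not in params:
                    raise ParseError(f"{path}:{lineno}: fixedStep missing start=")
                pos0 = int(params["start"]) - 1  # 1-based -> 0-based
                step = int(params.get("step", 1))
            else:
                mode = "variable"
            continue
        if mode is None:
            raise ParseError(f"{path}:{lineno}: data before any step declaration")
        try:
            if mode == "fixed":
                value = float(fields[0])
                start = pos0
                pos0 += step
            else:
                if len(fields) < 2:
                    raise ParseError(
                        f"{path}:{lineno}: variableStep line needs position and value"
                    )
                start = int(fields[0]) - 1
                value = float(fields[1])
        except ParseError:
            raise
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed wiggle value") from exc
        if value < 0:
            raise ParseError(f"{path}:{lineno}: negative signal value {value}")
        segments.append((GenomicInterval(chrom, start, start + span), value))
    return segments


def write_bedgraph(track: SignalTrack, path: Union[str, Path]) -> None:
    """Write a track as bedGraph with 6-significant-digit values."""
    with open(path, "w") as fh:
        for iv, value in track.segments():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{value:.6g}\n")
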