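"""Genomic coordinate conventions, interval algebra and percent reporting.

Every coordinate in this package is 0-based, half-open ``[start, end)`` —
the native convention of BED and UCSC chain files.  Conversion to or from
1-based conventions happens only at I/O boundaries, never here.

The central unit of comparison throughout the analysis is the *center
window*: a fixed ±halfwidth interval (400 bp at the default halfwidth of
200) around a hotspot midpoint.  Two hotspots are "the same site" when
their center windows overlap.
"""

from __future__ import annotations

import bisect
from collections.abc import Iterable
from dataclasses import dataclass, field, replace

from .errors import UndefinedFractionError

__all__ = [
    "GenomeAssembly",
    "Interval",
    "Hotspot",
    "HotspotSet",
    "CenterWindow",
    "PercentReport",
    "RegionIndex",
    "merge_intervals",
    "center_window",
    "interval_center",
    "percent_int",
]


@dataclass(frozen=True)
class GenomeAssembly:
    """A named assembly: label (e.g. ``rn5``, ``mm10``) plus chromosome sizes."""

    name: str
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")

    def chrom_length(self, chrom: str) -> int:
        return self.chrom_sizes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: {self}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        """At least one shared base (touching intervals do not overlap)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def interval_center(start: int, end: int) -> int:
    """Midpoint of ``[start, end)``; even widths round down."""
    return (start + end) // 2


@dataclass(frozen=True)
class Hotspot:
    """A called DSB peak: interval, midpoint and SSDS-coverage strength."""

    interval: Interval
    center: int
    strength: float = 0.0
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.interval.start <= self.center < self.interval.end:
            raise ValueError(
                f"center {self.center} outside interval {self.interval}"
            )
        if self.strength < 0:
            raise ValueError(f"negative strength {self.strength}")

    @classmethod
    def from_interval(
        cls, interval: Interval, strength: float = 0.0, name: str | None = None
    ) -> "Hotspot":
        return cls(interval, interval_center(interval.start, interval.end), strength, name)


@dataclass
class HotspotSet:
    """A named per-assembly hotspot collection, kept sorted by (chrom, start)."""

    assembly: GenomeAssembly
    label: str
    hotspots: list[Hotspot] = field(default_factory=list)

    def __post_init__(self) -> None:
        for h in self.hotspots:
            if h.interval.chrom not in self.assembly:
                raise ValueError(
                    f"hotspot on {h.interval.chrom!r} not in assembly {self.assembly.name!r}"
                )
            if h.interval.end > self.assembly.chrom_length(h.interval.chrom):
                raise ValueError(f"hotspot {h.interval} beyond chromosome end")
        self.hotspots = sorted(
            self.hotspots, key=lambda h: (h.interval.chrom, h.interval.start, h.interval.end)
        )

    def __len__(self) -> int:
        return len(self.hotspots)

    def __iter__(self):
        return iter(self.hotspots)

    def on_chroms(self, chroms: Iterable[str]) -> "HotspotSet":
        keep = set(chroms)
        return HotspotSet(
            self.assembly,
            self.label,
            [h for h in self.hotspots if h.interval.chrom in keep],
        )

    def excluding_chroms(self, chroms: Iterable[str]) -> "HotspotSet":
        drop = set(chroms)
        return HotspotSet(
            self.assembly,
            self.label,
            [h for h in self.hotspots if h.interval.chrom not in drop],
        )


@dataclass(frozen=True)
class CenterWindow:
    """±halfwidth window around a hotspot center, clamped at chromosome bounds."""

    source: Hotspot
    window: Interval
    halfwidth: int


def center_window(
    h: Hotspot, halfwidth: int = 200, chrom_length: int | None = None
) -> CenterWindow:
    """Window ``[center - halfwidth, center + halfwidth)`` clamped to ``[0, chrom_length)``."""
    if halfwidth < 1:
        raise ValueError(f"halfwidth must be >= 1, got {halfwidth}")
    start = max(0, h.center - halfwidth)
    end = h.center + halfwidth
    if chrom_length is not None:
        end = min(end, chrom_length)
    return CenterWindow(h, Interval(h.interval.chrom, start, end), halfwidth)


@dataclass(frozen=True)
class PercentReport:
    """A printed integer percentage with its raw counts."""

    numerator: int
    denominator: int
    percent: int

    def as_dict(self) -> dict[str, int]:
        return {
            "numerator": self.numerator,
            "denominator": self.denominator,
            "percent": self.percent,
        }


def percent_int(numerator: int, denominator: int) -> PercentReport:
    """Nearest-integer percent, rounding half away from zero.

    Pure integer arithmetic, so 93.5 -> 94 without float representation
    surprises.
    """
    if denominator == 0:
        raise UndefinedFractionError("percentage with zero denominator")
    if not 0 <= numerator <= denominator:
        raise ValueError(f"counts out of range: {numerator}/{denominator}")
    pct = (200 * numerator + denominator) // (2 * denominator)
    return PercentReport(numerator, denominator, pct)


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping *and touching* intervals into disjoint sorted runs.

    The union of covered bases is preserved; ``end == start`` neighbours
    collapse into one interval.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[Interval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = replace(merged[-1], end=iv.end)
        else:
            merged.append(iv)
    return merged


class RegionIndex:
    """Point- and overlap-queries against a fixed set of intervals.

    The input is merged once; queries then bisect the disjoint runs.
    Built for correctness over raw speed — the sets here are tens of
    thousands of regions, not billions.
    """

    def __init__(self, intervals: Iterable[Interval]):
        self.regions = merge_intervals(intervals)
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for r in self.regions:
            self._starts.setdefault(r.chrom, []).append(r.start)
            self._ends.setdefault(r.chrom, []).append(r.end)

    def __len__(self) -> int:
        return len(self.regions)

    def contains_point(self, chrom: str, pos: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect.bisect_right(starts, pos) - 1
        return i >= 0 and pos < self._ends[chrom][i]

    def overlaps(self, iv: Interval) -> bool:
        """True iff ``iv`` shares >= 1 base with any indexed region."""
        starts = self._starts.get(iv.chrom)
        if not starts:
            return False
        # candidate: last region starting before iv.end
        i = bisect.bisect_left(starts, iv.end) - 1
        return i >= 0 and self._ends[iv.chrom][i] > iv.start
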