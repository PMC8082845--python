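"""Same-assembly comparison of two DSB hotspot maps.

Two hotspots are "the same site" when their ±halfwidth center windows
overlap by at least one base — equivalently, on unclamped windows, when
their centers lie within ``2*halfwidth`` of each other.  A stricter
center-distance rule (|Δcenter| <= halfwidth) is available for
sensitivity checks.

Strength comparisons follow the conventions of SSDS replicate analysis:
only autosomal hotspots called in both sets are paired (one-to-one,
nearest center wins) and compared by Spearman rank correlation; X-linked
hotspot strengths can be scaled by two to account for the single X in
males.
"""

from __future__ import annotations

import bisect
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    Hotspot,
    HotspotSet,
    PercentReport,
    center_window,
    merge_intervals,
    percent_int,
)
from .errors import IncompatibleSetsError, InsufficientPairsError

__all__ = [
    "OverlapReport",
    "StrengthPairing",
    "StrengthSummary",
    "shared_hotspots",
    "strength_correlation",
    "x_strength_summary",
]


@dataclass(frozen=True)
class OverlapReport:
    n_a: int
    n_b: int
    n_a_shared: int
    n_b_shared: int
    percent_a_shared: PercentReport | None
    percent_b_shared: PercentReport | None
    n_merged_shared_regions: int

    def as_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_a_shared": self.n_a_shared,
            "n_b_shared": self.n_b_shared,
            "percent_a_shared": None
            if self.percent_a_shared is None
            else self.percent_a_shared.percent,
            "percent_b_shared": None
            if self.percent_b_shared is None
            else self.percent_b_shared.percent,
            "n_merged_shared_regions": self.n_merged_shared_regions,
        }


@dataclass
class StrengthPairing:
    pairs: list[tuple[float, float]]
    spearman_rho: float
    spearman_rho_sq: float


@dataclass(frozen=True)
class StrengthSummary:
    n: int
    median: float | None
    q1: float | None
    q3: float | None

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "StrengthSummary":
        if len(values) == 0:
            return cls(0, None, None, None)
        arr = np.asarray(values, dtype=float)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        return cls(len(arr), float(med), float(q1), float(q3))

    def as_dict(self) -> dict:
        return {"n": self.n, "median": self.median, "q1": self.q1, "q3": self.q3}


def _check_same_assembly(a: HotspotSet, b: HotspotSet) -> None:
    if a.assembly.name != b.assembly.name:
        raise IncompatibleSetsError(
            f"assemblies differ: {a.assembly.name!r} vs {b.assembly.name!r}"
        )


def _centers_by_chrom(hs: HotspotSet) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for h in hs:
        out.setdefault(h.interval.chrom, []).append(h.center)
    for lst in out.values():
        lst.sort()
    return out


def _has_partner(
    centers: dict[str, list[int]], chrom: str, center: int, threshold: int, strict: bool
) -> bool:
    """Any partner center with |Δ| < threshold (or <= under strict rule)?"""
    lst = centers.get(chrom)
    if not lst:
        return False
    i = bisect.bisect_left(lst, center)
    for j in (i - 1, i):
        if 0 <= j < len(lst):
            d = abs(lst[j] - center)
            if (d <= threshold) if strict else (d < threshold):
                return True
    return False


def shared_hotspots(
    a: HotspotSet,
    b: HotspotSet,
    halfwidth: int = 200,
    rule: str = "window-overlap",
) -> OverlapReport:
    """Classify hotspots of each set as shared or set-specific.

    rule ``window-overlap`` (default): center windows overlap by >= 1 bp,
    i.e. |Δcenter| < 2*halfwidth on unclamped windows.  rule
    ``center-distance``: |Δcenter| <= halfwidth.
    """
    _check_same_assembly(a, b)
    if rule == "window-overlap":
        threshold, strict = 2 * halfwidth, False
    elif rule == "center-distance":
        threshold, strict = halfwidth, True
    else:
        raise ValueError(f"unknown rule {rule!r}")

    a_centers, b_centers = _centers_by_chrom(a), _centers_by_chrom(b)
    a_shared = [
        h for h in a if _has_partner(b_centers, h.interval.chrom, h.center, threshold, strict)
    ]
    b_shared = [
        h for h in b if _has_partner(a_centers, h.interval.chrom, h.center, threshold, strict)
    ]

    windows = [
        center_window(h, halfwidth, hs.assembly.chrom_length(h.interval.chrom)).window
        for hs, shared in ((a, a_shared), (b, b_shared))
        for h in shared
    ]
    merged = merge_intervals(windows)

    return OverlapReport(
        n_a=len(a),
        n_b=len(b),
        n_a_shared=len(a_shared),
        n_b_shared=len(b_shared),
        percent_a_shared=percent_int(len(a_shared), len(a)) if len(a) else None,
        percent_b_shared=percent_int(len(b_shared), len(b)) if len(b) else None,
        n_merged_shared_regions=len(merged),
    )


def pair_one_to_one(
    a: HotspotSet, b: HotspotSet, halfwidth: int = 200
) -> list[tuple[Hotspot, Hotspot]]:
    """Greedy one-to-one pairing of window-overlapping hotspots.

    Candidate pairs are ranked by center distance (ties broken toward the
    lower coordinate), then taken greedily so each hotspot is used once.
    """
    b_by_chrom: dict[str, list[tuple[int, int]]] = {}
    b_list = list(b)
    for idx, h in enumerate(b_list):
        b_by_chrom.setdefault(h.interval.chrom, []).append((h.center, idx))
    for lst in b_by_chrom.values():
        lst.sort()

    threshold = 2 * halfwidth
    candidates: list[tuple[int, int, int, int, int]] = []
    a_list = list(a)
    for ai, h in enumerate(a_list):
        lst = b_by_chrom.get(h.interval.chrom, [])
        lo = bisect.bisect_left(lst, (h.center - threshold + 1, -1))
        for c, bi in lst[lo:]:
            if c - h.center >= threshold:
                break
            candidates.append((abs(c - h.center), h.center, c, ai, bi))

    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _d, _ac, _bc, ai, bi in candidates:
        if ai in used_a or bi in used_b:
            continue
        used_a.add(ai)
        used_b.add(bi)
        pairs.append((a_list[ai], b_list[bi]))
    return pairs


def strength_correlation(
    a: HotspotSet,
    b: HotspotSet,
    halfwidth: int = 200,
    sex_chroms: Sequence[str] = ("chrX", "chrY"),
) -> StrengthPairing:
    """Spearman rank correlation of strengths over shared autosomal hotspots."""
    _check_same_assembly(a, b)
    a_auto = a.excluding_chroms(sex_chroms)
    b_auto = b.excluding_chroms(sex_chroms)
    pairs = pair_one_to_one(a_auto, b_auto, halfwidth)
    if len(pairs) < 3:
        raise InsufficientPairsError(
            f"need >= 3 shared autosomal hotspots, got {len(pairs)}"
        )
    xs = np.array([p[0].strength for p in pairs])
    ys = np.array([p[1].strength for p in pairs])
    rho = float(stats.spearmanr(xs, ys).statistic)
    return StrengthPairing(
        pairs=[(float(x), float(y)) for x, y in zip(xs, ys)],
        spearman_rho=rho,
        spearman_rho_sq=rho * rho,
    )


def x_strength_summary(
    hs: HotspotSet,
    x_chrom: str = "chrX",
    male_scale: float = 2.0,
    sex_chroms: Sequence[str] = ("chrX", "chrY"),
) -> dict[str, StrengthSummary]:
    """Strength summaries for autosomes vs chromosome X, raw and male-scaled.

    With a single X per male nucleus, X coverage is halved relative to
    autosomes; ``x_scaled`` multiplies X strengths by ``male_scale``
    (default 2) to put them on the per-chromatid scale.
    """
    if x_chrom not in hs.assembly:
        raise IncompatibleSetsError(f"{x_chrom!r} not in assembly {hs.assembly.name!r}")
    x_strengths = [h.strength for h in hs if h.interval.chrom == x_chrom]
    auto = [h.strength for h in hs if h.interval.chrom not in set(sex_chroms)]
    return {
        "autosomes": StrengthSummary.from_values(auto),
        "x_raw": StrengthSummary.from_values(x_strengths),
        "x_scaled": StrengthSummary.from_values([s * male_scale for s in x_strengths]),
    }
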