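"""Cross-species hotspot conservation and promoter co-localization.

After the query species' hotspot center windows have been lifted onto the
reference assembly (see :mod:`dsbatlas.liftover`), windows of the two
species that overlap are pooled and merged into *conserved regions*; a
hotspot is conserved iff its window intersects a conserved region, and
species-specific otherwise.  Promoters are strand-aware TSS windows
(default −2000/+200 bp); the same merge logic applied to promoters of the
two species yields *conserved promoters*, which are then cross-tabulated
against hotspots and conserved regions.

The default hotspot-to-region rule is center-in-region (a hotspot
"localizes to" a promoter when its midpoint falls inside), which is
insensitive to called peak widths; full-interval ``any-overlap`` is
available as an option.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

from .core import (
    GenomeAssembly,
    Hotspot,
    HotspotSet,
    Interval,
    PercentReport,
    RegionIndex,
    center_window,
    merge_intervals,
    percent_int,
)
from .errors import IncompatibleSetsError, UndefinedFractionError
from .io import TssRecord

__all__ = [
    "Promoter",
    "PromoterSet",
    "ConservationReport",
    "ConservedPromoterReport",
    "build_promoters",
    "classify_conservation",
    "hotspot_region_overlap",
    "conserved_promoters",
    "promoter_hotspot_cross",
]


@dataclass(frozen=True)
class Promoter:
    gene_id: str
    strand: str
    window: Interval


@dataclass
class PromoterSet:
    """Strand-aware TSS windows, optionally restricted by biotype."""

    assembly: GenomeAssembly
    promoters: list[Promoter]
    upstream: int = 2000
    downstream: int = 200
    biotype_filter: str | None = None

    def __len__(self) -> int:
        return len(self.promoters)

    def __iter__(self):
        return iter(self.promoters)

    def windows(self) -> list[Interval]:
        return [p.window for p in self.promoters]


def build_promoters(
    tss: Iterable[TssRecord],
    assembly: GenomeAssembly,
    upstream: int = 2000,
    downstream: int = 200,
    biotype_filter: str | None = None,
) -> PromoterSet:
    """Promoter window per TSS: + strand ``[t-up, t+down)``, − strand mirrored.

    Windows are clamped to chromosome bounds; the biotype filter (e.g.
    ``protein_coding``) is applied before window construction.
    """
    if upstream < 0 or downstream < 0 or (upstream == 0 and downstream == 0):
        raise ValueError("upstream/downstream must be >= 0 and not both 0")
    promoters: list[Promoter] = []
    for rec in tss:
        if biotype_filter is not None and rec.biotype != biotype_filter:
            continue
        if rec.chrom not in assembly:
            raise IncompatibleSetsError(
                f"TSS chromosome {rec.chrom!r} not in assembly {assembly.name!r}"
            )
        length = assembly.chrom_length(rec.chrom)
        if rec.strand == "+":
            start, end = rec.tss - upstream, rec.tss + downstream
        else:
            start, end = rec.tss - downstream, rec.tss + upstream
        start, end = max(0, start), min(length, end)
        if start >= end:
            continue  # window entirely off-chromosome
        promoters.append(Promoter(rec.gene_id, rec.strand, Interval(rec.chrom, start, end)))
    promoters.sort(key=lambda p: (p.window.chrom, p.window.start, p.window.end))
    return PromoterSet(assembly, promoters, upstream, downstream, biotype_filter)


@dataclass
class ConservationReport:
    n_a: int
    n_b: int
    n_conserved_regions: int
    n_a_conserved: int
    n_b_conserved: int
    n_a_specific: int
    n_b_specific: int
    percent_a_conserved: PercentReport | None
    percent_b_conserved: PercentReport | None
    promoter_overlap: dict[str, PercentReport] | None = None

    def as_dict(self) -> dict:
        out = {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_conserved_regions": self.n_conserved_regions,
            "n_a_conserved": self.n_a_conserved,
            "n_b_conserved": self.n_b_conserved,
            "n_a_specific": self.n_a_specific,
            "n_b_specific": self.n_b_specific,
            "percent_a_conserved": None
            if self.percent_a_conserved is None
            else self.percent_a_conserved.percent,
            "percent_b_conserved": None
            if self.percent_b_conserved is None
            else self.percent_b_conserved.percent,
        }
        if self.promoter_overlap is not None:
            out["promoter_overlap"] = {
                k: v.as_dict() for k, v in sorted(self.promoter_overlap.items())
            }
        return out


def _windows(hs: HotspotSet, halfwidth: int) -> list[Interval]:
    return [
        center_window(h, halfwidth, hs.assembly.chrom_length(h.interval.chrom)).window
        for h in hs
    ]


def classify_conservation(
    a_lifted: HotspotSet,
    b_native: HotspotSet,
    halfwidth: int = 200,
    promoter_regions: Sequence[Interval] | None = None,
) -> tuple[ConservationReport, list[Interval]]:
    """Split two same-assembly hotspot sets into conserved vs species-specific.

    ``a_lifted`` must already have survived remapping and the converted-
    length filter.  Windows of A overlapping >= 1 window of B (and vice
    versa) are pooled and merged into conserved regions; each hotspot is
    conserved iff its window intersects a conserved region.

    If ``promoter_regions`` is given, center-in-promoter fractions are
    reported per category: conserved (both species pooled), a-specific,
    b-specific.

    Returns the report and the merged conserved regions.
    """
    if a_lifted.assembly.name != b_native.assembly.name:
        raise IncompatibleSetsError(
            f"assemblies differ: {a_lifted.assembly.name!r} vs {b_native.assembly.name!r}"
        )
    a_wins = _windows(a_lifted, halfwidth)
    b_wins = _windows(b_native, halfwidth)
    a_index = RegionIndex(a_wins)
    b_index = RegionIndex(b_wins)

    overlapping = [w for w in a_wins if b_index.overlaps(w)]
    overlapping += [w for w in b_wins if a_index.overlaps(w)]
    conserved_regions = merge_intervals(overlapping)
    conserved_index = RegionIndex(conserved_regions)

    a_flags = [conserved_index.overlaps(w) for w in a_wins]
    b_flags = [conserved_index.overlaps(w) for w in b_wins]
    n_a_cons, n_b_cons = sum(a_flags), sum(b_flags)

    promoter_overlap = None
    if promoter_regions is not None:
        prom_index = RegionIndex(promoter_regions)

        def frac(hotspots: list[Hotspot]) -> PercentReport | None:
            if not hotspots:
                return None
            n_in = sum(
                prom_index.contains_point(h.interval.chrom, h.center) for h in hotspots
            )
            return percent_int(n_in, len(hotspots))

        cons = [h for h, f in zip(a_lifted, a_flags) if f]
        cons += [h for h, f in zip(b_native, b_flags) if f]
        spec_a = [h for h, f in zip(a_lifted, a_flags) if not f]
        spec_b = [h for h, f in zip(b_native, b_flags) if not f]
        promoter_overlap = {
            key: report
            for key, report in (
                ("conserved", frac(cons)),
                ("a_specific", frac(spec_a)),
                ("b_specific", frac(spec_b)),
            )
            if report is not None
        }

    report = ConservationReport(
        n_a=len(a_lifted),
        n_b=len(b_native),
        n_conserved_regions=len(conserved_regions),
        n_a_conserved=n_a_cons,
        n_b_conserved=n_b_cons,
        n_a_specific=len(a_lifted) - n_a_cons,
        n_b_specific=len(b_native) - n_b_cons,
        percent_a_conserved=percent_int(n_a_cons, len(a_lifted)) if len(a_lifted) else None,
        percent_b_conserved=percent_int(n_b_cons, len(b_native)) if len(b_native) else None,
        promoter_overlap=promoter_overlap,
    )
    return report, conserved_regions


def hotspot_region_overlap(
    hs: HotspotSet,
    regions: Sequence[Interval],
    rule: str = "center-in",
) -> PercentReport:
    """Fraction of hotspots co-localizing with a region set.

    ``center-in`` counts hotspots whose midpoint falls inside a region;
    ``any-overlap`` counts hotspots whose full called interval shares
    >= 1 bp with a region.
    """
    if len(hs) == 0:
        raise UndefinedFractionError("empty hotspot set")
    index = RegionIndex(regions)
    if rule == "center-in":
        n = sum(index.contains_point(h.interval.chrom, h.center) for h in hs)
    elif rule == "any-overlap":
        n = sum(index.overlaps(h.interval) for h in hs)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return percent_int(n, len(hs))


@dataclass
class ConservedPromoterReport:
    n_a_promoters: int
    n_b_promoters: int
    n_merged_conserved: int
    percent_a_overlapping: PercentReport | None
    percent_b_overlapping: PercentReport | None
    percent_conserved_with_any_hs: PercentReport | None = None
    percent_conserved_with_conserved_hs: PercentReport | None = None

    def as_dict(self) -> dict:
        def pct(p: PercentReport | None):
            return None if p is None else p.percent

        return {
            "n_a_promoters": self.n_a_promoters,
            "n_b_promoters": self.n_b_promoters,
            "n_merged_conserved": self.n_merged_conserved,
            "percent_a_overlapping": pct(self.percent_a_overlapping),
            "percent_b_overlapping": pct(self.percent_b_overlapping),
            "percent_conserved_with_any_hs": pct(self.percent_conserved_with_any_hs),
            "percent_conserved_with_conserved_hs": pct(
                self.percent_conserved_with_conserved_hs
            ),
        }


def conserved_promoters(
    a_promoters_lifted: PromoterSet,
    b_promoters: PromoterSet,
) -> tuple[ConservedPromoterReport, list[Interval]]:
    """Merge cross-species overlapping promoters into conserved promoter regions."""
    if len(a_promoters_lifted) == 0 or len(b_promoters) == 0:
        raise UndefinedFractionError("empty promoter set")
    a_wins = a_promoters_lifted.windows()
    b_wins = b_promoters.windows()
    a_index = RegionIndex(a_wins)
    b_index = RegionIndex(b_wins)

    a_over = [w for w in a_wins if b_index.overlaps(w)]
    b_over = [w for w in b_wins if a_index.overlaps(w)]
    merged = merge_intervals(a_over + b_over)

    report = ConservedPromoterReport(
        n_a_promoters=len(a_wins),
        n_b_promoters=len(b_wins),
        n_merged_conserved=len(merged),
        percent_a_overlapping=percent_int(len(a_over), len(a_wins)),
        percent_b_overlapping=percent_int(len(b_over), len(b_wins)),
    )
    return report, merged


def promoter_hotspot_cross(
    conserved_proms: Sequence[Interval],
    hs_a: HotspotSet,
    hs_b: HotspotSet,
    conserved_regions: Sequence[Interval],
) -> tuple[PercentReport, PercentReport]:
    """Cross-tabulate conserved promoters against hotspots.

    Returns (percent of conserved promoters containing >= 1 hotspot center
    of either species, percent overlapping >= 1 conserved hotspot region).
    """
    proms = merge_intervals(conserved_proms)
    if not proms:
        raise UndefinedFractionError("no conserved promoters")
    centers: dict[str, list[int]] = {}
    for hs in (hs_a, hs_b):
        for h in hs:
            centers.setdefault(h.interval.chrom, []).append(h.center)
    for lst in centers.values():
        lst.sort()

    import bisect as _bisect

    def contains_center(iv: Interval) -> bool:
        lst = centers.get(iv.chrom)
        if not lst:
            return False
        i = _bisect.bisect_left(lst, iv.start)
        return i < len(lst) and lst[i] < iv.end

    cons_index = RegionIndex(conserved_regions)
    n_any = sum(contains_center(p) for p in proms)
    n_cons = sum(cons_index.overlaps(p) for p in proms)
    return percent_int(n_any, len(proms)), percent_int(n_cons, len(proms))
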