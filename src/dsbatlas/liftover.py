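"""Chain-based interval liftover between genome assemblies.

Implements the coordinate-conversion step of the cross-species hotspot
comparison: each hotspot's 400-bp center window is remapped through a UCSC
chain file, a mapping succeeds when at least ``min_match`` of its bases
align to a single chain (the UCSC ``-minMatch`` semantics, default 0.1),
and successfully mapped windows whose converted span exceeds
``max_converted_length`` (default 800 bp — twice the window) are excluded
as gap-inflated.

Minus-strand chains are handled with UCSC semantics: query coordinates in
the chain count from the 3' end, and every reported image is converted
back to the + strand (``pos' = q_size - 1 - raw``).
"""

from __future__ import annotations

import bisect
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from enum import Enum

from .core import (
    GenomeAssembly,
    Hotspot,
    HotspotSet,
    Interval,
    PercentReport,
    center_window,
    interval_center,
    percent_int,
)
from .errors import AmbiguousMappingError
from .io import Chain

__all__ = [
    "LiftStatus",
    "LiftoverConfig",
    "LiftResult",
    "RemapReport",
    "ChainIndex",
    "map_base",
    "lift_interval",
    "remap_center_windows",
]


class LiftStatus(str, Enum):
    MAPPED = "mapped"
    DELETED = "deleted"
    PARTIAL_BELOW_MIN_MATCH = "partial_below_min_match"
    SPLIT_ACROSS_CHAINS = "split_across_chains"


@dataclass(frozen=True)
class LiftoverConfig:
    """Liftover parameters.

    min_match
        minimum fraction of input bases that must map through one chain.
    max_converted_length
        converted-span ceiling for center windows (bp); longer mappings
        are counted and dropped.
    multi_chain_policy
        ``best-chain`` (pick the chain mapping the most bases, ties by
        score) or ``reject`` (any multi-chain coverage is a failure).
    """

    min_match: float = 0.1
    max_converted_length: int = 800
    multi_chain_policy: str = "best-chain"

    def __post_init__(self) -> None:
        if not 0 < self.min_match <= 1:
            raise ValueError(f"min_match must be in (0, 1], got {self.min_match}")
        if self.max_converted_length < 1:
            raise ValueError("max_converted_length must be >= 1")
        if self.multi_chain_policy not in ("best-chain", "reject"):
            raise ValueError(f"unknown policy {self.multi_chain_policy!r}")


@dataclass(frozen=True)
class LiftResult:
    status: LiftStatus
    input_bases: int
    mapped_bases: int = 0
    mapped_interval: Interval | None = None
    strand: str | None = None
    chain_id: str | None = None

    @property
    def match_fraction(self) -> float:
        return self.mapped_bases / self.input_bases if self.input_bases else 0.0

    @property
    def converted_length(self) -> int | None:
        return len(self.mapped_interval) if self.mapped_interval is not None else None


@dataclass
class RemapReport:
    """Whole-set remap tally: inputs, successes, failures, long-gap exclusions."""

    n_input: int
    n_remapped: int
    n_failed: int
    n_excluded_long: int
    status_counts: dict[str, int] = field(default_factory=dict)

    @property
    def remapped_percent(self) -> PercentReport | None:
        if self.n_input == 0:
            return None
        return percent_int(self.n_remapped, self.n_input)

    def as_dict(self) -> dict:
        out = {
            "n_input": self.n_input,
            "n_remapped": self.n_remapped,
            "n_failed": self.n_failed,
            "n_excluded_long": self.n_excluded_long,
            "status_counts": dict(sorted(self.status_counts.items())),
        }
        pct = self.remapped_percent
        if pct is not None:
            out["remapped_percent"] = pct.percent
        return out


class ChainIndex:
    """Chains grouped by source (target-side) chromosome, block offsets precomputed."""

    def __init__(self, chains: Iterable[Chain]):
        self.by_chrom: dict[str, list[_IndexedChain]] = {}
        for chain in chains:
            self.by_chrom.setdefault(chain.t_name, []).append(_IndexedChain(chain))
        for lst in self.by_chrom.values():
            # higher score first: 'best' tie-breaks prefer the stronger chain
            lst.sort(key=lambda ic: -ic.chain.score)

    def candidates(self, chrom: str) -> "Sequence[_IndexedChain]":
        return self.by_chrom.get(chrom, ())

    def query_assembly(self, name: str = "target") -> GenomeAssembly:
        """Assembly of the conversion target, reconstructed from q_size fields."""
        sizes: dict[str, int] = {}
        for lst in self.by_chrom.values():
            for ic in lst:
                sizes[ic.chain.q_name] = ic.chain.q_size
        return GenomeAssembly(name, sizes)


class _IndexedChain:
    """Per-chain block geometry: target starts/ends and raw query starts."""

    def __init__(self, chain: Chain):
        self.chain = chain
        t_starts, t_ends, q_starts = [], [], []
        t, q = chain.t_start, chain.q_start
        for b in chain.blocks:
            t_starts.append(t)
            t_ends.append(t + b.size)
            q_starts.append(q)
            t += b.size + b.dt
            q += b.size + b.dq
        self.t_starts = t_starts
        self.t_ends = t_ends
        self.q_starts = q_starts

    def map_pos(self, pos: int) -> tuple[str, int, str] | None:
        """Image of one target base on the + strand of the query, or None."""
        c = self.chain
        if not c.t_start <= pos < c.t_end:
            return None
        i = bisect.bisect_right(self.t_starts, pos) - 1
        if i < 0 or pos >= self.t_ends[i]:
            return None  # inside a target gap (dt)
        raw = self.q_starts[i] + (pos - self.t_starts[i])
        if c.q_strand == "-":
            return c.q_name, c.q_size - 1 - raw, "-"
        return c.q_name, raw, "+"

    def map_interval(self, iv: Interval) -> tuple[int, int, int] | None:
        """(mapped_bases, min_plus_image, max_plus_image) of ``iv`` or None.

        Computed by block intersection, equivalent to mapping every base.
        """
        c = self.chain
        if iv.chrom != c.t_name or iv.end <= c.t_start or iv.start >= c.t_end:
            return None
        mapped = 0
        lo = hi = None
        for ts, te, qs in zip(self.t_starts, self.t_ends, self.q_starts):
            a, b = max(iv.start, ts), min(iv.end, te)
            if a >= b:
                continue
            mapped += b - a
            raw_lo, raw_hi = qs + (a - ts), qs + (b - 1 - ts)
            if c.q_strand == "-":
                plus_lo, plus_hi = c.q_size - 1 - raw_hi, c.q_size - 1 - raw_lo
            else:
                plus_lo, plus_hi = raw_lo, raw_hi
            lo = plus_lo if lo is None else min(lo, plus_lo)
            hi = plus_hi if hi is None else max(hi, plus_hi)
        if mapped == 0:
            return None
        return mapped, lo, hi  # type: ignore[return-value]


def _as_index(chains: ChainIndex | Iterable[Chain]) -> ChainIndex:
    return chains if isinstance(chains, ChainIndex) else ChainIndex(chains)


def map_base(
    chains: ChainIndex | Iterable[Chain],
    chrom: str,
    pos: int,
    policy: str = "best-chain",
) -> tuple[str, int, str] | None:
    """Map one base to (query chrom, + strand position, strand), or None.

    Under ``reject`` policy, two chains both covering the base (in aligned
    blocks) raise :class:`AmbiguousMappingError`; under ``best-chain`` the
    highest-scoring chain wins.
    """
    index = _as_index(chains)
    hits = [img for ic in index.candidates(chrom) if (img := ic.map_pos(pos)) is not None]
    if not hits:
        return None
    if len(hits) > 1 and policy == "reject":
        raise AmbiguousMappingError(f"{chrom}:{pos} covered by {len(hits)} chains")
    return hits[0]  # candidates are score-sorted


def lift_interval(
    iv: Interval,
    chains: ChainIndex | Iterable[Chain],
    config: LiftoverConfig = LiftoverConfig(),
) -> LiftResult:
    """Lift one interval, UCSC liftOver style.

    Status ``mapped`` requires that >= ``min_match`` of the bases align
    through a *single* chain (hence one strand); the mapped interval is the
    + strand span from the leftmost to the rightmost image, so query-side
    gaps inflate ``converted_length`` above ``mapped_bases``.
    """
    index = _as_index(chains)
    n = len(iv)
    cands: list[tuple[int, int, int, _IndexedChain]] = []
    for ic in index.candidates(iv.chrom):
        res = ic.map_interval(iv)
        if res is not None:
            cands.append((*res, ic))

    if not cands:
        return LiftResult(LiftStatus.DELETED, input_bases=n)

    if len(cands) > 1:
        if config.multi_chain_policy == "reject":
            return LiftResult(LiftStatus.SPLIT_ACROSS_CHAINS, input_bases=n)
        # two independently valid mappings = "Duplicated in new": a failure
        n_valid = sum(1 for m, _, _, _ in cands if m / n >= config.min_match)
        if n_valid > 1:
            return LiftResult(LiftStatus.SPLIT_ACROSS_CHAINS, input_bases=n)

    mapped, lo, hi, best = max(cands, key=lambda c: (c[0], c[3].chain.score))
    if mapped / n < config.min_match:
        return LiftResult(
            LiftStatus.PARTIAL_BELOW_MIN_MATCH, input_bases=n, mapped_bases=mapped
        )
    return LiftResult(
        LiftStatus.MAPPED,
        input_bases=n,
        mapped_bases=mapped,
        mapped_interval=Interval(best.chain.q_name, lo, hi + 1),
        strand=best.chain.q_strand,
        chain_id=best.chain.chain_id,
    )


def remap_center_windows(
    hs: HotspotSet,
    chains: ChainIndex | Iterable[Chain],
    config: LiftoverConfig = LiftoverConfig(),
    halfwidth: int = 200,
    target_assembly: GenomeAssembly | None = None,
) -> tuple[HotspotSet, RemapReport]:
    """Remap every hotspot's ±halfwidth center window to the target assembly.

    Remapped-then-excluded bookkeeping follows the published convention:
    ``n_remapped`` counts every successful liftover, and windows whose
    converted span exceeds ``max_converted_length`` are then counted in
    ``n_excluded_long`` and dropped from the returned set.
    """
    index = _as_index(chains)
    if target_assembly is None:
        target_assembly = index.query_assembly(f"{hs.assembly.name}-lifted")

    lifted: list[Hotspot] = []
    n_remapped = n_excluded = 0
    status_counts: dict[str, int] = {}
    for h in hs:
        win = center_window(h, halfwidth, hs.assembly.chrom_length(h.interval.chrom))
        res = lift_interval(win.window, index, config)
        status_counts[res.status.value] = status_counts.get(res.status.value, 0) + 1
        if res.status is not LiftStatus.MAPPED:
            continue
        n_remapped += 1
        assert res.mapped_interval is not None
        if len(res.mapped_interval) > config.max_converted_length:
            n_excluded += 1
            continue
        iv = res.mapped_interval
        lifted.append(
            Hotspot(iv, interval_center(iv.start, iv.end), h.strength, h.name)
        )

    report = RemapReport(
        n_input=len(hs),
        n_remapped=n_remapped,
        n_failed=len(hs) - n_remapped,
        n_excluded_long=n_excluded,
        status_counts=status_counts,
    )
    return HotspotSet(target_assembly, f"{hs.label}-lifted", lifted), report


def invert_chain(chain: Chain) -> Chain:
    """Swap target and query so lifts can be run in the reverse direction.

    For + strand chains this is a pure swap with dt/dq exchanged.  Minus
    strand chains additionally reverse block order and re-anchor the spans,
    keeping the new target on the + strand.
    """
    from .io import ChainBlock

    if chain.q_strand == "+":
        blocks = [ChainBlock(b.size, b.dq, b.dt) for b in chain.blocks]
        return Chain(
            chain.score,
            chain.q_name, chain.q_size, "+", chain.q_start, chain.q_end,
            chain.t_name, chain.t_size, "-" if chain.t_strand == "-" else "+",
            chain.t_start, chain.t_end,
            f"{chain.chain_id}-inv", blocks,
        )
    # '-' strand: the new target is the old query on its + strand, so block
    # order reverses; the gap after reversed block i is the gap that
    # preceded it in the original, i.e. the (dq, dt) of original block
    # n-2-i, swapped.
    n = len(chain.blocks)
    sizes = [chain.blocks[n - 1 - i].size for i in range(n)]
    dts = [chain.blocks[n - 2 - i].dq if i < n - 1 else 0 for i in range(n)]
    dqs = [chain.blocks[n - 2 - i].dt if i < n - 1 else 0 for i in range(n)]
    new_blocks = [ChainBlock(s, dt, dq) for s, dt, dq in zip(sizes, dts, dqs)]
    new_t_start = chain.q_size - chain.q_end
    new_t_end = chain.q_size - chain.q_start
    return Chain(
        chain.score,
        chain.q_name, chain.q_size, "+", new_t_start, new_t_end,
        chain.t_name, chain.t_size, "-", chain.t_size - chain.t_end,
        chain.t_size - chain.t_start,
        f"{chain.chain_id}-inv", new_blocks,
    )
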