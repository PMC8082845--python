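"""Ground-truth synthetic data for every pipeline stage.

The generator emulates the shape of the real inputs without sequence
content (coordinates only):

* a *derived* assembly produced from a source assembly by planted
  deletions, insertions and inversions, together with the UCSC chain file
  describing the rearrangement and an exact per-base :class:`TrueMap`
  oracle (inversions emit minus-strand chains, as real over.chain files
  contain);
* paired hotspot sets with a planted shared fraction, per-strain center
  jitter, log-normal strengths with a planted rank correlation on shared
  pairs, and X-linked strengths drawn at a planted multiple of the
  autosomal distribution;
* a TSS landscape in which a planted fraction of hotspot centers fall
  inside promoter windows.

All randomness flows from one ``numpy`` generator seeded by
``SimSpec.seed``: the same spec yields byte-identical outputs.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field

import numpy as np

from .core import GenomeAssembly, Hotspot, HotspotSet, Interval
from .errors import SpecInfeasibleError
from .io import Chain, ChainBlock, TssRecord

__all__ = [
    "SimSpec",
    "TrueMap",
    "simulate_assembly_pair",
    "simulate_hotspot_pair",
    "simulate_promoter_landscape",
    "transfer_hotspots",
]

_MAX_RETRIES = 200


def _default_chrom_sizes() -> dict[str, int]:
    return {"chr1": 2_000_000, "chr2": 2_000_000, "chr3": 1_500_000, "chrX": 1_000_000}


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic scenario.

    Defaults describe a desk-scale stand-in for the real study inputs:
    a few megabases of genome, 2000 hotspots per strain, an 0.88 shared
    fraction (the same-allele strain pair), 50-bp center jitter (well
    inside the 200-bp comparison halfwidth), log-normal strengths with a
    0.8 rank correlation on shared sites, X strengths at twice the
    autosomal level, a handful of 100–1000 bp rearrangements, and 40% of
    hotspots planted inside promoter windows.
    """

    seed: int = 0
    chrom_sizes: dict[str, int] = field(default_factory=_default_chrom_sizes)
    assembly_name: str = "simA"
    derived_name: str = "simB"
    # hotspots
    n_hotspots: int = 2000
    shared_fraction: float = 0.88
    center_jitter_sd: float = 50.0
    strength_mu: float = 1.0
    strength_sigma: float = 1.0
    strength_corr: float = 0.8  # target Spearman on shared pairs
    min_separation: int = 2000
    width_range: tuple[int, int] = (300, 2000)
    sex_chroms: tuple[str, ...] = ("chrX",)
    x_strength_factor: float = 2.0
    # rearrangements
    n_deletions: int = 5
    n_insertions: int = 5
    n_inversions: int = 2
    deletion_size: tuple[int, int] = (100, 1000)
    insertion_size: tuple[int, int] = (100, 1000)
    inversion_size: tuple[int, int] = (500, 5000)
    # promoter landscape
    n_genes: int = 1200
    promoter_hotspot_fraction: float = 0.4
    upstream: int = 2000
    downstream: int = 200

    def __post_init__(self) -> None:
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must be in [0, 1]")
        if not 0 <= self.promoter_hotspot_fraction <= 1:
            raise ValueError("promoter_hotspot_fraction must be in [0, 1]")
        if not -1 <= self.strength_corr <= 1:
            raise ValueError("strength_corr must be in [-1, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# assembly pair + chain + TrueMap


@dataclass(frozen=True)
class _Segment:
    """One colinear run: source [t_start, t_end) -> derived, with strand."""

    t_start: int
    t_end: int
    q_chrom: str
    q_start: int  # + strand start of the image
    strand: str

    def map(self, pos: int) -> tuple[str, int, str]:
        if self.strand == "+":
            return self.q_chrom, self.q_start + (pos - self.t_start), "+"
        return self.q_chrom, self.q_start + (self.t_end - 1 - pos), "-"


class TrueMap:
    """Exact per-base source→derived coordinate oracle.

    Consistent with the emitted chain file by construction; injective on
    mapped bases (each derived base has at most one source preimage).
    """

    def __init__(
        self,
        source_assembly: GenomeAssembly,
        derived_assembly: GenomeAssembly,
        segments: dict[str, list[_Segment]],
    ):
        self.source_assembly = source_assembly
        self.derived_assembly = derived_assembly
        self._segments = segments
        self._starts = {c: [s.t_start for s in segs] for c, segs in segments.items()}

    def map(self, chrom: str, pos: int) -> tuple[str, int, str] | None:
        segs = self._segments.get(chrom)
        if not segs:
            return None
        i = bisect.bisect_right(self._starts[chrom], pos) - 1
        if i < 0 or pos >= segs[i].t_end:
            return None
        return segs[i].map(pos)


@dataclass(frozen=True)
class _Edit:
    kind: str  # deletion | insertion | inversion
    start: int  # insertion: point position
    end: int  # insertion: == start
    insert_len: int = 0

    @property
    def t_span(self) -> int:
        return self.end - self.start


def _place_edits(
    rng: np.random.Generator, sizes: dict[str, int], spec: SimSpec
) -> dict[str, list[_Edit]]:
    """Assign and place non-overlapping edits, >= 1 bp apart and off the ends."""
    requests: list[tuple[str, int]] = []
    for kind, n, rng_sz in (
        ("deletion", spec.n_deletions, spec.deletion_size),
        ("insertion", spec.n_insertions, spec.insertion_size),
        ("inversion", spec.n_inversions, spec.inversion_size),
    ):
        for _ in range(n):
            requests.append((kind, int(rng.integers(rng_sz[0], rng_sz[1] + 1))))

    chroms = sorted(sizes)
    weights = np.array([sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[_Edit]] = {c: [] for c in chroms}
    for kind, size in requests:
        ok = False
        for _ in range(_MAX_RETRIES):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            L = sizes[chrom]
            span = 0 if kind == "insertion" else size
            if L - span - 2 <= 1:
                continue
            start = int(rng.integers(1, L - span - 1))
            end = start + span
            # keep >= 1 unedited base between edits so chain blocks stay >= 1
            if all(e.end + 1 <= start or end + 1 <= e.start for e in placed[chrom]):
                placed[chrom].append(
                    _Edit(kind, start, end, insert_len=size if kind == "insertion" else 0)
                )
                ok = True
                break
        if not ok:
            raise SpecInfeasibleError(f"could not place {kind} of size {size}")
    for lst in placed.values():
        lst.sort(key=lambda e: e.start)
    return placed


def simulate_assembly_pair(
    spec: SimSpec, rng: np.random.Generator | None = None
) -> tuple[GenomeAssembly, GenomeAssembly, list[Chain], TrueMap]:
    """Derive assembly B from A by planted edits; emit chains and TrueMap.

    One plus-strand chain per chromosome carries the colinear blocks
    (deletions become dt gaps, insertions dq gaps, inversions dt+dq gaps),
    and each inversion additionally emits a single-block minus-strand
    chain covering the inverted segment.
    """
    if rng is None:
        rng = spec.rng()
    sizes = dict(spec.chrom_sizes)
    edits = _place_edits(rng, sizes, spec)

    chains: list[Chain] = []
    segments: dict[str, list[_Segment]] = {}
    derived_sizes: dict[str, int] = {}
    chain_counter = 0

    for chrom in sorted(sizes):
        L = sizes[chrom]
        q_len = L
        for e in edits[chrom]:
            if e.kind == "deletion":
                q_len -= e.t_span
            elif e.kind == "insertion":
                q_len += e.insert_len
        derived_sizes[chrom] = q_len

        segs: list[_Segment] = []
        blocks: list[ChainBlock] = []
        inversion_chains: list[tuple[int, int, int]] = []  # (t_start, t_end, q_plus_start)
        t_cursor, q_cursor = 0, 0
        pending: list[tuple[int, int, int]] = []  # (size, dt, dq) accumulating

        def emit_block(size: int, dt: int, dq: int) -> None:
            pending.append((size, dt, dq))

        for e in edits[chrom]:
            size = e.start - t_cursor
            segs.append(_Segment(t_cursor, e.start, chrom, q_cursor, "+"))
            if e.kind == "deletion":
                emit_block(size, e.t_span, 0)
                t_cursor = e.end
                q_cursor += size
            elif e.kind == "insertion":
                emit_block(size, 0, e.insert_len)
                t_cursor = e.start
                q_cursor += size + e.insert_len
            else:  # inversion
                emit_block(size, e.t_span, e.t_span)
                q_seg_start = q_cursor + size
                segs.append(_Segment(e.start, e.end, chrom, q_seg_start, "-"))
                inversion_chains.append((e.start, e.end, q_seg_start))
                t_cursor = e.end
                q_cursor = q_seg_start + e.t_span

        segs.append(_Segment(t_cursor, L, chrom, q_cursor, "+"))
        emit_block(L - t_cursor, 0, 0)
        # strip the final gaps (chain grammar: last block has none)
        blocks = [ChainBlock(s, dt, dq) for s, dt, dq in pending[:-1]]
        blocks.append(ChainBlock(pending[-1][0]))

        chain_counter += 1
        chains.append(
            Chain(
                score=1_000_000,
                t_name=chrom, t_size=L, t_strand="+", t_start=0, t_end=L,
                q_name=chrom, q_size=q_len, q_strand="+", q_start=0, q_end=q_len,
                chain_id=str(chain_counter),
                blocks=blocks,
            )
        )
        for t_start, t_end, q_plus_start in inversion_chains:
            chain_counter += 1
            span = t_end - t_start
            raw_start = q_len - (q_plus_start + span)
            chains.append(
                Chain(
                    score=1_000,
                    t_name=chrom, t_size=L, t_strand="+", t_start=t_start, t_end=t_end,
                    q_name=chrom, q_size=q_len, q_strand="-",
                    q_start=raw_start, q_end=raw_start + span,
                    chain_id=str(chain_counter),
                    blocks=[ChainBlock(span)],
                )
            )
        # drop zero-length leading segments (edit at cursor) defensively
        segments[chrom] = [s for s in segs if s.t_end > s.t_start]

    source = GenomeAssembly(spec.assembly_name, sizes)
    derived = GenomeAssembly(spec.derived_name, derived_sizes)
    return source, derived, chains, TrueMap(source, derived, segments)


# ---------------------------------------------------------------------------
# hotspot pairs


@dataclass
class HotspotPairTruth:
    """Planted identities: hotspot name -> latent site id; shared ids in both."""

    a_site: dict[str, str]
    b_site: dict[str, str]
    shared_ids: set[str]

    @property
    def n_shared(self) -> int:
        return len(self.shared_ids)


def _spaced_positions(
    rng: np.random.Generator, sizes: dict[str, int], n: int, sep: int, margin: int
) -> list[tuple[str, int]]:
    """n positions, pairwise >= sep apart (per chromosome), away from ends."""
    chroms = sorted(sizes)
    weights = np.array([sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(_MAX_RETRIES):
        counts = rng.multinomial(n, weights)
        ok = True
        out: list[tuple[str, int]] = []
        for chrom, k in zip(chroms, counts):
            if k == 0:
                continue
            L = sizes[chrom]
            room = L - 2 * margin - (k - 1) * sep
            if room <= k:
                ok = False
                break
            picks = np.sort(rng.choice(room, size=k, replace=False))
            for i, p in enumerate(picks):
                out.append((chrom, margin + int(p) + i * sep))
        if ok:
            return out
    raise SpecInfeasibleError(
        f"cannot place {n} positions with separation {sep} in genome of "
        f"{sum(sizes.values())} bp"
    )


def _correlated_lognormal(
    rng: np.random.Generator, n: int, mu: float, sigma: float, spearman: float
) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate log-normal pairs with a target Spearman correlation."""
    pearson = 2.0 * math.sin(math.pi * spearman / 6.0)  # Gaussian-copula inverse
    z1 = rng.standard_normal(n)
    z2 = pearson * z1 + math.sqrt(max(0.0, 1 - pearson**2)) * rng.standard_normal(n)
    return np.exp(mu + sigma * z1), np.exp(mu + sigma * z2)


def simulate_hotspot_pair(
    spec: SimSpec,
    assembly: GenomeAssembly | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[HotspotSet, HotspotSet, HotspotPairTruth]:
    """Two hotspot sets with ⌊f·n⌋ shared latent sites.

    Shared sites get independent per-strain center jitter; strain-specific
    sites sit >= min_separation from every other latent site, so at jitter
    well below the comparison halfwidth the planted shared fraction is
    recoverable by :func:`dsbatlas.compare.shared_hotspots`.
    """
    if rng is None:
        rng = spec.rng()
    if assembly is None:
        assembly = GenomeAssembly(spec.assembly_name, dict(spec.chrom_sizes))

    n = spec.n_hotspots
    n_shared = int(math.floor(spec.shared_fraction * n))
    n_unique = n - n_shared
    total = n_shared + 2 * n_unique
    margin = max(3000, spec.width_range[1] + int(6 * spec.center_jitter_sd) + 10)
    latent = _spaced_positions(rng, assembly.chrom_sizes, total, spec.min_separation, margin)
    order = rng.permutation(total)
    shared_sites = [latent[i] for i in order[:n_shared]]
    a_only = [latent[i] for i in order[n_shared : n_shared + n_unique]]
    b_only = [latent[i] for i in order[n_shared + n_unique :]]

    sa, sb = _correlated_lognormal(
        rng, n_shared, spec.strength_mu, spec.strength_sigma, spec.strength_corr
    )
    ua = np.exp(spec.strength_mu + spec.strength_sigma * rng.standard_normal(n_unique))
    ub = np.exp(spec.strength_mu + spec.strength_sigma * rng.standard_normal(n_unique))

    sex = set(spec.sex_chroms)

    def build(
        sites: list[tuple[str, int]],
        strengths: np.ndarray,
        site_ids: list[str],
        jitter: bool,
    ) -> list[Hotspot]:
        out = []
        for (chrom, pos), strength, sid in zip(sites, strengths, site_ids):
            c = pos
            if jitter and spec.center_jitter_sd > 0:
                c = pos + int(round(rng.normal(0.0, spec.center_jitter_sd)))
            w = int(rng.integers(spec.width_range[0], spec.width_range[1] + 1))
            L = assembly.chrom_length(chrom)
            c = min(max(c, w // 2), L - (w - w // 2) - 1)  # keep interval on-chromosome
            start = c - w // 2
            end = start + w
            s = float(strength) * (spec.x_strength_factor if chrom in sex else 1.0)
            out.append(Hotspot(Interval(chrom, start, end), c, s, name=sid))
        return out

    shared_ids = [f"site{j}" for j in range(n_shared)]
    a_ids = [f"a{j}" for j in range(n_unique)]
    b_ids = [f"b{j}" for j in range(n_unique)]

    a_hs = build(shared_sites, sa, shared_ids, jitter=True)
    a_hs += build(a_only, ua, a_ids, jitter=False)
    b_hs = build(shared_sites, sb, shared_ids, jitter=True)
    b_hs += build(b_only, ub, b_ids, jitter=False)

    # HotspotSet sorts; names keep identities traceable, but names must be
    # unique per set — shared sites reuse the latent id in both sets.
    a_set = HotspotSet(assembly, "simStrainA", a_hs)
    b_set = HotspotSet(assembly, "simStrainB", b_hs)
    truth = HotspotPairTruth(
        a_site={h.name: h.name for h in a_set},
        b_site={h.name: h.name for h in b_set},
        shared_ids=set(shared_ids),
    )
    return a_set, b_set, truth


# ---------------------------------------------------------------------------
# promoter landscape


def simulate_promoter_landscape(
    spec: SimSpec,
    hs: HotspotSet,
    rng: np.random.Generator | None = None,
) -> tuple[list[TssRecord], dict[str, bool]]:
    """TSS table in which a planted fraction of hotspot centers sit in promoters.

    A fraction ``promoter_hotspot_fraction`` of hotspots each get a gene
    whose promoter window covers their center (and no other center); the
    remaining genes are placed clear of every hotspot center.  Returns the
    TSS records and per-hotspot truth flags keyed by hotspot name.
    """
    if rng is None:
        rng = spec.rng()
    assembly = hs.assembly
    up, down = spec.upstream, spec.downstream
    centers: dict[str, list[int]] = {}
    for h in hs:
        centers.setdefault(h.interval.chrom, []).append(h.center)
    for lst in centers.values():
        lst.sort()

    def centers_in(chrom: str, start: int, end: int) -> int:
        lst = centers.get(chrom, [])
        return bisect.bisect_left(lst, end) - bisect.bisect_left(lst, start)

    hotspots = list(hs)
    k = int(round(spec.promoter_hotspot_fraction * len(hotspots)))
    if spec.n_genes < k:
        raise SpecInfeasibleError(f"n_genes={spec.n_genes} < planted hotspot count {k}")
    chosen_idx = set(
        int(i) for i in rng.choice(len(hotspots), size=k, replace=False)
    )

    records: list[TssRecord] = []
    flags: dict[str, bool] = {}
    gene_no = 0
    for i, h in enumerate(hotspots):
        name = h.name or f"hs{i}"
        flags[name] = i in chosen_idx
        if i not in chosen_idx:
            continue
        chrom, c = h.interval.chrom, h.center
        L = assembly.chrom_length(chrom)
        placed = False
        for _ in range(_MAX_RETRIES):
            strand = "+" if rng.integers(2) == 0 else "-"
            if strand == "+":
                t = int(rng.integers(c - down + 1, c + up + 1))
                start, end = t - up, t + down
            else:
                t = int(rng.integers(c - up + 1, c + down + 1))
                start, end = t - down, t + up
            if start < 0 or end > L:
                continue
            if centers_in(chrom, start, end) != 1:
                continue  # must cover exactly this center
            records.append(TssRecord(f"g{gene_no}", chrom, strand, t, "protein_coding"))
            gene_no += 1
            placed = True
            break
        if not placed:
            raise SpecInfeasibleError(
                f"cannot place promoter around hotspot at {chrom}:{c}"
            )

    chroms = sorted(assembly.chrom_sizes)
    weights = np.array([assembly.chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(spec.n_genes - k):
        placed = False
        for _ in range(_MAX_RETRIES):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            L = assembly.chrom_length(chrom)
            strand = "+" if rng.integers(2) == 0 else "-"
            t = int(rng.integers(up + down, L - up - down))
            start, end = (t - up, t + down) if strand == "+" else (t - down, t + up)
            if centers_in(chrom, start, end) == 0:
                records.append(TssRecord(f"g{gene_no}", chrom, strand, t, "protein_coding"))
                gene_no += 1
                placed = True
                break
        if not placed:
            raise SpecInfeasibleError("cannot place a hotspot-free promoter")
    return records, flags


# ---------------------------------------------------------------------------
# cross-assembly transfer (for building "native" sets on the derived genome)


def transfer_hotspots(
    hs: HotspotSet, true_map: TrueMap, label: str | None = None
) -> HotspotSet:
    """Move hotspots to the derived assembly via the exact TrueMap.

    Hotspots whose center falls in an unmapped (deleted) region are
    dropped; intervals are re-anchored around the mapped center with the
    original width (clamped at chromosome ends).
    """
    out: list[Hotspot] = []
    derived = true_map.derived_assembly
    for h in hs:
        image = true_map.map(h.interval.chrom, h.center)
        if image is None:
            continue
        q_chrom, q_pos, _strand = image
        w = len(h.interval)
        L = derived.chrom_length(q_chrom)
        start = q_pos - w // 2
        end = start + w
        if start < 0:
            start, end = 0, min(w, L)
        if end > L:
            start, end = max(0, L - w), L
        out.append(Hotspot(Interval(q_chrom, start, end), q_pos, h.strength, h.name))
    return HotspotSet(derived, label or f"{hs.label}-derived", out)
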