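"""Independent brute-force oracles used to check the fast implementations.

These deliberately re-derive chain geometry by walking blocks base by
base; they share no code with the liftover engine.
"""

from __future__ import annotations

from dsbatlas.core import Interval
from dsbatlas.io import Chain


def naive_base_images(chains: list[Chain], chrom: str, pos: int) -> list[tuple[str, int, str, Chain]]:
    """All per-chain images of one target base, by block enumeration."""
    hits = []
    for chain in chains:
        if chain.t_name != chrom:
            continue
        t, q = chain.t_start, chain.q_start
        for block in chain.blocks:
            if t <= pos < t + block.size:
                raw = q + (pos - t)
                if chain.q_strand == "-":
                    hits.append((chain.q_name, chain.q_size - 1 - raw, "-", chain))
                else:
                    hits.append((chain.q_name, raw, "+", chain))
                break
            t += block.size + block.dt
            q += block.size + block.dq
    return hits


def naive_best_image(chains: list[Chain], chrom: str, pos: int) -> tuple[str, int, str] | None:
    hits = naive_base_images(chains, chrom, pos)
    if not hits:
        return None
    hits.sort(key=lambda h: -h[3].score)
    name, p, strand, _ = hits[0]
    return name, p, strand


def naive_lift(iv: Interval, chains: list[Chain], min_match: float):
    """Per-base interval lift: returns (status, mapped_bases, interval_or_None).

    Mirrors the contract: pick the chain mapping the most bases (ties by
    score); two chains independently reaching min_match is a split;
    no mapped base is a deletion; below min_match is partial.
    """
    per_chain: dict[int, list[tuple[int, str]]] = {}
    chain_by_id: dict[int, Chain] = {}
    for pos in range(iv.start, iv.end):
        for name, p, strand, chain in naive_base_images(chains, iv.chrom, pos):
            key = id(chain)
            chain_by_id[key] = chain
            per_chain.setdefault(key, []).append((p, name))
    n = len(iv)
    if not per_chain:
        return "deleted", 0, None
    scored = sorted(
        per_chain.items(),
        key=lambda kv: (len(kv[1]), chain_by_id[kv[0]].score),
        reverse=True,
    )
    if len(scored) > 1:
        n_valid = sum(1 for _k, images in scored if len(images) / n >= min_match)
        if n_valid > 1:
            return "split_across_chains", 0, None
    key, images = scored[0]
    mapped = len(images)
    if mapped / n < min_match:
        return "partial_below_min_match", mapped, None
    positions = [p for p, _ in images]
    qname = images[0][1]
    return "mapped", mapped, Interval(qname, min(positions), max(positions) + 1)


def per_base_union(intervals) -> set[tuple[str, int]]:
    bases = set()
    for iv in intervals:
        for pos in range(iv.start, iv.end):
            bases.add((iv.chrom, pos))
    return bases
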