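import pytest

from dsbatlas.core import GenomeAssembly, Hotspot, HotspotSet, Interval
from dsbatlas.io import Chain, ChainBlock


@pytest.fixture
def toy_assembly() -> GenomeAssembly:
    return GenomeAssembly("toy", {"chr1": 100_000, "chr2": 50_000, "chrX": 30_000})


def make_hotspots(assembly, label, spots):
    """spots: iterable of (chrom, center, strength) -> 400-bp-wide hotspots."""
    hs = []
    for i, (chrom, center, strength) in enumerate(spots):
        hs.append(
            Hotspot(Interval(chrom, center - 200, center + 200), center, strength, f"{label}{i}")
        )
    return HotspotSet(assembly, label, hs)


def identity_chain(chrom: str, size: int, chain_id: str = "1") -> Chain:
    return Chain(
        score=1000,
        t_name=chrom, t_size=size, t_strand="+", t_start=0, t_end=size,
        q_name=chrom, q_size=size, q_strand="+", q_start=0, q_end=size,
        chain_id=chain_id, blocks=[ChainBlock(size)],
    )


@pytest.fixture
def gap_chain() -> Chain:
    """Blocks 100 (dt 50) + 100: target [0,100)+[150,250) maps to query [0,200)."""
    return Chain(
        score=1000,
        t_name="chrA", t_size=1000, t_strand="+", t_start=0, t_end=250,
        q_name="chrB", q_size=1000, q_strand="+", q_start=0, q_end=200,
        chain_id="g1", blocks=[ChainBlock(100, 50, 0), ChainBlock(100)],
    )
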