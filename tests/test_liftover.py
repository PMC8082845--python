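"""Chain liftover: base mapping, interval lifting, window remapping."""

import numpy as np
import pytest

from conftest import identity_chain, make_hotspots
from dsbatlas.core import GenomeAssembly, Hotspot, HotspotSet, Interval
from dsbatlas.errors import AmbiguousMappingError
from dsbatlas.io import Chain, ChainBlock
from dsbatlas.liftover import (
    ChainIndex,
    LiftoverConfig,
    LiftStatus,
    invert_chain,
    lift_interval,
    map_base,
    remap_center_windows,
)
from dsbatlas.simulate import SimSpec, simulate_assembly_pair
from oracles import naive_best_image, naive_lift


@pytest.fixture
def minus_chain():
    """t[0,100) aligned to raw q[0,100) on the minus strand of a 1000-bp query."""
    return Chain(500, "chrA", 1000, "+", 0, 100, "chrB", 1000, "-", 0, 100, "m1",
                 [ChainBlock(100)])


class TestMapBase:
    def test_identity(self):
        idx = ChainIndex([identity_chain("chrA", 1000)])
        assert map_base(idx, "chrA", 123) == ("chrA", 123, "+")

    def test_gap_chain_geometry(self, gap_chain):
        idx = ChainIndex([gap_chain])
        assert map_base(idx, "chrA", 200) == ("chrB", 150, "+")
        assert map_base(idx, "chrA", 120) is None  # inside the dt gap
        assert map_base(idx, "chrA", 99) == ("chrB", 99, "+")
        assert map_base(idx, "chrA", 150) == ("chrB", 100, "+")
        assert map_base(idx, "chrA", 500) is None  # beyond the chain

    def test_minus_strand_flip(self, minus_chain):
        idx = ChainIndex([minus_chain])
        assert map_base(idx, "chrA", 10) == ("chrB", 989, "-")
        # enumeration oracle agrees at every base of the block
        for pos in range(100):
            assert map_base(idx, "chrA", pos) == naive_best_image([minus_chain], "chrA", pos)

    def test_reject_policy_flags_double_coverage(self):
        chains = [identity_chain("chrA", 1000, "1"), identity_chain("chrA", 1000, "2")]
        idx = ChainIndex(chains)
        with pytest.raises(AmbiguousMappingError):
            map_base(idx, "chrA", 5, policy="reject")
        assert map_base(idx, "chrA", 5) == ("chrA", 5, "+")


class TestLiftInterval:
    def test_identity(self):
        res = lift_interval(Interval("chrA", 100, 500), [identity_chain("chrA", 1000)])
        assert res.status is LiftStatus.MAPPED
        assert res.mapped_interval == Interval("chrA", 100, 500)
        assert res.match_fraction == 1.0
        assert res.converted_length == 400

    def test_partial_overlap_with_gap(self, gap_chain):
        res = lift_interval(Interval("chrA", 50, 150), [gap_chain])
        assert res.status is LiftStatus.MAPPED
        assert res.mapped_bases == 50
        assert res.match_fraction == 0.5
        assert res.mapped_interval == Interval("chrB", 50, 100)
        assert res.converted_length == 50

    def test_interval_inside_deletion_gap(self, gap_chain):
        res = lift_interval(Interval("chrA", 110, 140), [gap_chain])
        assert res.status is LiftStatus.DELETED
        assert res.mapped_bases == 0

    def test_below_min_match(self, gap_chain):
        # 200 of 1000 bases map -> fraction 0.2 < a 0.5 minMatch
        cfg = LiftoverConfig(min_match=0.5)
        res = lift_interval(Interval("chrA", 0, 1000), [gap_chain], cfg)
        assert res.status is LiftStatus.PARTIAL_BELOW_MIN_MATCH
        assert res.mapped_bases == 200

    def test_query_gap_inflates_converted_length(self):
        # dq 600 between two 200-bp blocks: a 400-bp window spanning the
        # insertion maps 400 bases onto a 1000-bp span
        chain = Chain(1000, "chrA", 10_000, "+", 0, 400, "chrB", 10_000, "+", 0, 1000,
                      "ins", [ChainBlock(200, 0, 600), ChainBlock(200)])
        res = lift_interval(Interval("chrA", 0, 400), [chain])
        assert res.status is LiftStatus.MAPPED
        assert res.mapped_bases == 400
        assert res.converted_length == 1000
        assert res.converted_length >= res.mapped_bases

    def test_duplicated_mapping_is_a_failure(self):
        chains = [identity_chain("chrA", 1000, "1"), identity_chain("chrA", 1000, "2")]
        res = lift_interval(Interval("chrA", 10, 60), chains)
        assert res.status is LiftStatus.SPLIT_ACROSS_CHAINS

    def test_minus_strand_interval(self, minus_chain):
        res = lift_interval(Interval("chrA", 10, 20), [minus_chain])
        assert res.status is LiftStatus.MAPPED
        # bases 10..19 -> plus strand 980..989
        assert res.mapped_interval == Interval("chrB", 980, 990)
        assert res.strand == "-"

    def test_agrees_with_per_base_oracle_on_random_chains(self):
        rng = np.random.default_rng(7)
        spec = SimSpec(
            seed=11,
            chrom_sizes={"chrA": 50_000, "chrB": 40_000},
            n_deletions=4, n_insertions=4, n_inversions=2,
            deletion_size=(50, 400), insertion_size=(50, 400), inversion_size=(200, 1500),
        )
        _a, _b, chains, _tm = simulate_assembly_pair(spec)
        idx = ChainIndex(chains)
        cfg = LiftoverConfig()
        for _ in range(300):
            chrom = "chrA" if rng.integers(2) == 0 else "chrB"
            start = int(rng.integers(0, spec.chrom_sizes[chrom] - 1200))
            iv = Interval(chrom, start, start + int(rng.integers(1, 1200)))
            got = lift_interval(iv, idx, cfg)
            status, mapped, interval = naive_lift(iv, chains, cfg.min_match)
            assert got.status.value == status, iv
            if status == "mapped":
                assert got.mapped_bases == mapped
                assert got.mapped_interval == interval


class TestRemapCenterWindows:
    def test_identity_chain_full_remap(self, toy_assembly):
        hs = make_hotspots(
            toy_assembly, "s", [("chr1", c, 1.0) for c in range(1000, 11_000, 1000)]
        )
        chains = [identity_chain(c, L) for c, L in toy_assembly.chrom_sizes.items()]
        lifted, report = remap_center_windows(hs, chains)
        assert report.n_remapped == 10
        assert report.remapped_percent.percent == 100
        assert report.n_excluded_long == 0
        assert [h.center for h in lifted] == [h.center for h in hs]

    def test_unaligned_windows_count_as_failed(self):
        # chain covers only [0, 5000); hotspots beyond it fail
        asm = GenomeAssembly("t", {"chr1": 20_000})
        chain = Chain(10, "chr1", 20_000, "+", 0, 5000, "q1", 5000, "+", 0, 5000, "1",
                      [ChainBlock(5000)])
        centers = [500, 1500, 2500, 3500, 4500, 6000, 7000, 9000, 11_000, 13_000]
        hs = make_hotspots(asm, "s", [("chr1", c, 1.0) for c in centers[:7]])
        hs = HotspotSet(asm, "s", list(hs) + [
            Hotspot(Interval("chr1", c - 200, c + 200), c, 1.0) for c in centers[7:]
        ])
        lifted, report = remap_center_windows(hs, [chain])
        assert report.n_input == 10
        assert report.n_remapped == 5  # windows centred at 500..4500 map fully
        assert report.n_failed == 5
        assert report.remapped_percent.percent == 50

    def test_long_converted_window_excluded(self):
        asm = GenomeAssembly("t", {"chrA": 10_000})
        chain = Chain(1000, "chrA", 10_000, "+", 0, 400, "chrB", 10_000, "+", 0, 1000,
                      "ins", [ChainBlock(200, 0, 600), ChainBlock(200)])
        h = Hotspot(Interval("chrA", 0, 400), 200, 2.0, "w")
        hs = HotspotSet(asm, "s", [h])
        lifted, report = remap_center_windows(hs, [chain])
        assert report.n_remapped == 1
        assert report.n_excluded_long == 1
        assert len(lifted) == 0

    def test_empty_input(self, toy_assembly):
        hs = HotspotSet(toy_assembly, "empty", [])
        chains = [identity_chain("chr1", 100_000)]
        lifted, report = remap_center_windows(hs, chains)
        assert len(lifted) == 0
        assert report.n_input == 0
        assert report.remapped_percent is None
        assert "remapped_percent" not in report.as_dict()


class TestInvertChain:
    def test_plus_strand_round_trip(self, gap_chain):
        idx_fwd = ChainIndex([gap_chain])
        idx_rev = ChainIndex([invert_chain(gap_chain)])
        iv = Interval("chrA", 10, 90)  # clear of the gap
        fwd = lift_interval(iv, idx_fwd)
        back = lift_interval(fwd.mapped_interval, idx_rev)
        assert back.mapped_interval == iv

    def test_minus_strand_round_trip(self):
        chain = Chain(500, "chrA", 1000, "+", 100, 400, "chrB", 2000, "-", 50, 350, "m",
                      [ChainBlock(100, 50, 50), ChainBlock(150)])
        inv = invert_chain(chain)
        idx_fwd, idx_rev = ChainIndex([chain]), ChainIndex([inv])
        for iv in (Interval("chrA", 110, 190), Interval("chrA", 260, 390)):
            fwd = lift_interval(iv, idx_fwd)
            assert fwd.status is LiftStatus.MAPPED
            back = lift_interval(fwd.mapped_interval, idx_rev)
            assert back.mapped_interval == iv

    def test_inverted_chain_is_well_formed(self):
        chain = Chain(500, "chrA", 1000, "+", 100, 400, "chrB", 2000, "-", 50, 350, "m",
                      [ChainBlock(100, 50, 50), ChainBlock(150)])
        inv = invert_chain(chain)  # Chain.__post_init__ validates the arithmetic
        assert inv.t_strand == "+"
        assert inv.q_strand == "-"
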