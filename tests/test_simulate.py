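"""Synthetic-data generator: determinism, chain consistency, planted truth."""

import io

import numpy as np
import pytest

from dsbatlas.compare import shared_hotspots
from dsbatlas.conserve import build_promoters, hotspot_region_overlap
from dsbatlas.core import Interval
from dsbatlas.errors import SpecInfeasibleError
from dsbatlas.io import parse_chain_file, write_chain_file, write_hotspots
from dsbatlas.liftover import ChainIndex, LiftStatus, lift_interval, map_base
from dsbatlas.simulate import (
    SimSpec,
    simulate_assembly_pair,
    simulate_hotspot_pair,
    simulate_promoter_landscape,
    transfer_hotspots,
)

SMALL_GENOME = {"chrA": 80_000, "chrB": 60_000}


def small_spec(**overrides) -> SimSpec:
    defaults = dict(
        seed=42,
        chrom_sizes=dict(SMALL_GENOME),
        n_hotspots=40,
        min_separation=1000,
        width_range=(300, 800),
        sex_chroms=(),
        n_deletions=3,
        n_insertions=3,
        n_inversions=2,
        deletion_size=(50, 300),
        insertion_size=(50, 300),
        inversion_size=(200, 1000),
        n_genes=30,
    )
    defaults.update(overrides)
    return SimSpec(**defaults)


class TestAssemblyPair:
    def test_zero_edits_gives_identity(self):
        spec = small_spec(n_deletions=0, n_insertions=0, n_inversions=0)
        a, b, chains, tm = simulate_assembly_pair(spec)
        assert a.chrom_sizes == b.chrom_sizes
        idx = ChainIndex(chains)
        for iv in (Interval("chrA", 0, 500), Interval("chrB", 59_000, 60_000)):
            res = lift_interval(iv, idx)
            assert res.status is LiftStatus.MAPPED
            assert res.mapped_interval == iv

    def test_emitted_chain_reparses_identically(self):
        spec = small_spec()
        _a, _b, chains, _tm = simulate_assembly_pair(spec)
        buf = io.StringIO()
        write_chain_file(chains, buf)
        buf.seek(0)
        assert parse_chain_file(buf) == chains

    def test_chain_agrees_with_truemap_exhaustively(self):
        spec = small_spec()
        a, _b, chains, tm = simulate_assembly_pair(spec)
        idx = ChainIndex(chains)
        for chrom, size in a.chrom_sizes.items():
            for pos in range(size):
                assert map_base(idx, chrom, pos) == tm.map(chrom, pos)

    def test_truemap_is_injective(self):
        spec = small_spec()
        a, _b, _chains, tm = simulate_assembly_pair(spec)
        seen = set()
        for chrom, size in a.chrom_sizes.items():
            for pos in range(size):
                image = tm.map(chrom, pos)
                if image is not None:
                    assert image not in seen
                    seen.add(image)

    def test_deletion_splits_and_removes_windows(self):
        spec = small_spec(n_deletions=1, n_insertions=0, n_inversions=0,
                          deletion_size=(500, 500), chrom_sizes={"chrA": 50_000})
        _a, b, chains, tm = simulate_assembly_pair(spec)
        idx = ChainIndex(chains)
        # find the deleted segment from the main chain's dt gap
        main = next(c for c in chains if c.q_strand == "+")
        gap_start = main.t_start + main.blocks[0].size
        inside = Interval("chrA", gap_start + 50, gap_start + 450)
        assert lift_interval(inside, idx).status is LiftStatus.DELETED
        assert b.chrom_sizes["chrA"] == 49_500

    def test_insertion_inflates_converted_length(self):
        spec = small_spec(n_deletions=0, n_insertions=1, n_inversions=0,
                          insertion_size=(600, 600), chrom_sizes={"chrA": 50_000})
        _a, _b, chains, _tm = simulate_assembly_pair(spec)
        idx = ChainIndex(chains)
        main = next(c for c in chains if c.q_strand == "+")
        p = main.t_start + main.blocks[0].size  # insertion point
        window = Interval("chrA", p - 200, p + 200)
        res = lift_interval(window, idx)
        assert res.status is LiftStatus.MAPPED
        assert res.mapped_bases == 400
        assert res.converted_length == 1000  # 400 + 600-bp insertion

    def test_inversions_emit_minus_strand_chains(self):
        spec = small_spec(n_inversions=2)
        _a, _b, chains, _tm = simulate_assembly_pair(spec)
        assert sum(1 for c in chains if c.q_strand == "-") == 2


class TestHotspotPair:
    def test_full_sharing_no_jitter(self):
        spec = small_spec(shared_fraction=1.0, center_jitter_sd=0.0)
        a, b, truth = simulate_hotspot_pair(spec)
        rep = shared_hotspots(a, b)
        assert rep.percent_a_shared.percent == 100
        assert rep.percent_b_shared.percent == 100
        assert truth.n_shared == len(a)

    def test_zero_sharing_with_wide_separation(self):
        spec = small_spec(shared_fraction=0.0, min_separation=1000)
        a, b, truth = simulate_hotspot_pair(spec)
        rep = shared_hotspots(a, b)
        assert rep.n_a_shared == 0 and rep.n_b_shared == 0
        assert truth.n_shared == 0

    def test_planted_fraction_within_sampling_bounds(self):
        spec = SimSpec(seed=3, n_hotspots=2000, shared_fraction=0.5,
                       center_jitter_sd=50.0, min_separation=2000,
                       chrom_sizes={"chr1": 4_000_000, "chr2": 4_000_000,
                                    "chr3": 3_000_000, "chrX": 2_000_000})
        a, b, _ = simulate_hotspot_pair(spec)
        rep = shared_hotspots(a, b)
        se = 100 * np.sqrt(0.25 / 2000)
        assert abs(100 * rep.n_a_shared / rep.n_a - 50) <= 3 * se

    def test_min_separation_respected_between_latent_sites(self):
        spec = small_spec(shared_fraction=0.0, center_jitter_sd=0.0)
        a, b, _ = simulate_hotspot_pair(spec)
        centers = sorted(
            (h.interval.chrom, h.center) for hs in (a, b) for h in hs
        )
        for (c1, p1), (c2, p2) in zip(centers, centers[1:]):
            if c1 == c2:
                assert p2 - p1 >= spec.min_separation

    def test_infeasible_placement_raises(self):
        with pytest.raises(SpecInfeasibleError):
            simulate_hotspot_pair(small_spec(n_hotspots=5000, min_separation=5000))


class TestPromoterLandscape:
    def test_zero_fraction(self):
        spec = small_spec(promoter_hotspot_fraction=0.0)
        a, _b, _ = simulate_hotspot_pair(spec)
        tss, flags = simulate_promoter_landscape(spec, a)
        prom = build_promoters(tss, a.assembly)
        assert hotspot_region_overlap(a, prom.windows()).percent == 0
        assert not any(flags.values())

    def test_full_fraction(self):
        spec = small_spec(promoter_hotspot_fraction=1.0, n_genes=45)
        a, _b, _ = simulate_hotspot_pair(spec)
        tss, flags = simulate_promoter_landscape(spec, a)
        prom = build_promoters(tss, a.assembly)
        assert hotspot_region_overlap(a, prom.windows()).percent == 100
        assert all(flags.values())

    def test_planted_fraction_recovered_exactly(self):
        spec = small_spec(promoter_hotspot_fraction=0.4)
        a, _b, _ = simulate_hotspot_pair(spec)
        tss, flags = simulate_promoter_landscape(spec, a)
        prom = build_promoters(tss, a.assembly)
        rep = hotspot_region_overlap(a, prom.windows())
        assert rep.numerator == round(0.4 * len(a)) == sum(flags.values())

    def test_gene_count_matches_spec(self):
        spec = small_spec()
        a, _b, _ = simulate_hotspot_pair(spec)
        tss, _ = simulate_promoter_landscape(spec, a)
        assert len(tss) == spec.n_genes


class TestDeterminism:
    def scenario_bytes(self, seed: int) -> bytes:
        spec = small_spec(seed=seed)
        rng = spec.rng()
        _a, _b, chains, _tm = simulate_assembly_pair(spec, rng)
        a, b, _truth = simulate_hotspot_pair(spec, None, rng)
        tss, _flags = simulate_promoter_landscape(spec, a, rng)
        chain_buf, a_buf, b_buf = io.StringIO(), io.StringIO(), io.StringIO()
        write_chain_file(chains, chain_buf)
        write_hotspots(a, a_buf)
        write_hotspots(b, b_buf)
        tss_txt = "".join(f"{r.gene_id}\t{r.chrom}\t{r.strand}\t{r.tss}\n" for r in tss)
        return (chain_buf.getvalue() + a_buf.getvalue() + b_buf.getvalue() + tss_txt).encode()

    def test_same_seed_same_bytes(self):
        assert self.scenario_bytes(7) == self.scenario_bytes(7)

    def test_different_seed_different_bytes(self):
        assert self.scenario_bytes(7) != self.scenario_bytes(8)


class TestTransferHotspots:
    def test_identity_transfer_preserves_centers(self):
        spec = small_spec(n_deletions=0, n_insertions=0, n_inversions=0)
        rng = spec.rng()
        a_asm, _b, _chains, tm = simulate_assembly_pair(spec, rng)
        a, _b2, _ = simulate_hotspot_pair(spec, a_asm, rng)
        moved = transfer_hotspots(a, tm)
        assert [h.center for h in moved] == [h.center for h in a]

    def test_centers_in_deleted_regions_dropped(self):
        spec = small_spec(n_deletions=1, n_insertions=0, n_inversions=0,
                          deletion_size=(500, 500), chrom_sizes={"chrA": 50_000})
        rng = spec.rng()
        a_asm, _b, chains, tm = simulate_assembly_pair(spec, rng)
        main = next(c for c in chains if c.q_strand == "+")
        gap_start = main.t_start + main.blocks[0].size
        from dsbatlas.core import Hotspot, HotspotSet

        inside = Hotspot(Interval("chrA", gap_start, gap_start + 400), gap_start + 200, 1.0)
        outside = Hotspot(Interval("chrA", 1000, 1400), 1200, 1.0)
        hs = HotspotSet(a_asm, "t", [inside, outside])
        moved = transfer_hotspots(hs, tm)
        assert len(moved) == 1
        assert moved.hotspots[0].center == 1200
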