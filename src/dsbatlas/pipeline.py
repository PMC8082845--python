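"""End-to-end orchestration: read → lift → compare → conserve → report.

One config drives the full analysis; outputs are deterministic (identical
inputs and config produce byte-identical JSON) and a run manifest records
parameters, input checksums and the package version so every reported
count is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .compare import shared_hotspots, strength_correlation, x_strength_summary
from .conserve import (
    build_promoters,
    classify_conservation,
    conserved_promoters,
    hotspot_region_overlap,
    promoter_hotspot_cross,
)
from .errors import ConfigurationError, InsufficientPairsError, UndefinedFractionError
from .io import parse_chain_file, read_hotspots, read_tss_table, write_report
from .liftover import ChainIndex, LiftoverConfig, remap_center_windows

logger = logging.getLogger("dsbatlas")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs and parameters of one analysis run.

    Parameter defaults are the study's published ones: 200-bp comparison
    halfwidth, liftover minMatch 0.1 with an 800-bp converted-length
    ceiling, and −2000/+200 bp promoter windows.
    """

    # same-assembly strain comparison
    compare_a: str | None = None
    compare_b: str | None = None
    # cross-assembly conservation: query lifted onto reference
    chain: str | None = None
    query_bed: str | None = None
    reference_bed: str | None = None
    tss: str | None = None
    peaks: str | None = None  # e.g. H3K4me3 default sites on the reference
    # optional assembly labels for consistency checking
    query_assembly: str | None = None
    reference_assembly: str | None = None
    chain_source: str | None = None
    chain_target: str | None = None
    # parameters
    halfwidth: int = 200
    min_match: float = 0.1
    max_converted_length: int = 800
    upstream: int = 2000
    downstream: int = 200
    overlap_rule: str = "center-in"
    sharing_rule: str = "window-overlap"
    sex_chroms: tuple[str, ...] = ("chrX", "chrY")
    biotype_filter: str | None = None
    strength_column: int = 5
    outdir: str = "dsbatlas-out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "sex_chroms" in data:
            data["sex_chroms"] = tuple(data["sex_chroms"])
        return cls(**data)

    def validate(self) -> None:
        if (self.query_bed is None) != (self.chain is None):
            raise ConfigurationError("query_bed and chain must be given together")
        if self.chain_source and self.query_assembly and self.chain_source != self.query_assembly:
            raise ConfigurationError(
                f"chain source {self.chain_source!r} != query assembly {self.query_assembly!r}"
            )
        if (
            self.chain_target
            and self.reference_assembly
            and self.chain_target != self.reference_assembly
        ):
            raise ConfigurationError(
                f"chain target {self.chain_target!r} != reference assembly "
                f"{self.reference_assembly!r}"
            )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str, t0: float, **counts) -> None:
    extra = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s wall=%.2fs %s", name, time.perf_counter() - t0, extra)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage the config enables and write JSON/TSV reports.

    Returns the report bundle as a dict (the same object serialised to
    ``report.json`` in ``cfg.outdir``).
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    inputs: dict[str, str] = {}

    lift_cfg = LiftoverConfig(
        min_match=cfg.min_match, max_converted_length=cfg.max_converted_length
    )

    # ---- same-assembly strain comparison
    if cfg.compare_a and cfg.compare_b:
        t0 = time.perf_counter()
        a = read_hotspots(cfg.compare_a, cfg.strength_column, label="A")
        b = read_hotspots(cfg.compare_b, cfg.strength_column, label="B")
        inputs["compare_a"] = _sha256(cfg.compare_a)
        inputs["compare_b"] = _sha256(cfg.compare_b)
        # merge observed chrom sizes so both sets share one assembly frame
        sizes = dict(a.assembly.chrom_sizes)
        for c, s in b.assembly.chrom_sizes.items():
            sizes[c] = max(sizes.get(c, 0), s)
        from .core import GenomeAssembly, HotspotSet

        frame = GenomeAssembly(cfg.query_assembly or "shared", sizes)
        a = HotspotSet(frame, a.label, list(a))
        b = HotspotSet(frame, b.label, list(b))
        overlap = shared_hotspots(a, b, cfg.halfwidth, cfg.sharing_rule)
        bundle["strain_overlap"] = overlap.as_dict()
        try:
            pairing = strength_correlation(a, b, cfg.halfwidth, cfg.sex_chroms)
            bundle["strength_correlation"] = {
                "n_pairs": len(pairing.pairs),
                "spearman_rho": pairing.spearman_rho,
                "spearman_rho_sq": pairing.spearman_rho_sq,
            }
        except InsufficientPairsError:
            bundle["strength_correlation"] = None
        _stage("compare", t0, n_a=len(a), n_b=len(b))

    # ---- liftover + conservation
    lifted = None
    reference = None
    conserved_regions = None
    if cfg.query_bed and cfg.chain:
        t0 = time.perf_counter()
        chains = ChainIndex(parse_chain_file(cfg.chain))
        query = read_hotspots(
            cfg.query_bed, cfg.strength_column, label=cfg.query_assembly or "query"
        )
        inputs["chain"] = _sha256(cfg.chain)
        inputs["query_bed"] = _sha256(cfg.query_bed)
        lifted, remap = remap_center_windows(query, chains, lift_cfg, cfg.halfwidth)
        bundle["remap"] = remap.as_dict()
        _stage("liftover", t0, n_in=remap.n_input, n_out=len(lifted))

        if cfg.reference_bed:
            t0 = time.perf_counter()
            reference = read_hotspots(
                cfg.reference_bed,
                cfg.strength_column,
                label=cfg.reference_assembly or "reference",
            )
            inputs["reference_bed"] = _sha256(cfg.reference_bed)
            from .core import GenomeAssembly, HotspotSet

            sizes = dict(lifted.assembly.chrom_sizes)
            for c, s in reference.assembly.chrom_sizes.items():
                sizes[c] = max(sizes.get(c, 0), s)
            frame = GenomeAssembly(cfg.reference_assembly or lifted.assembly.name, sizes)
            lifted = HotspotSet(frame, lifted.label, list(lifted))
            reference = HotspotSet(frame, reference.label, list(reference))

            promoter_windows = None
            prom_set = None
            if cfg.tss:
                tss = read_tss_table(cfg.tss)
                inputs["tss"] = _sha256(cfg.tss)
                prom_set = build_promoters(
                    tss, frame, cfg.upstream, cfg.downstream, cfg.biotype_filter
                )
                promoter_windows = prom_set.windows()

            conservation, conserved_regions = classify_conservation(
                lifted, reference, cfg.halfwidth, promoter_windows
            )
            bundle["conservation"] = conservation.as_dict()
            _stage(
                "conserve",
                t0,
                n_lifted=len(lifted),
                n_reference=len(reference),
                n_conserved_regions=conservation.n_conserved_regions,
            )

            if prom_set is not None and len(prom_set) and conserved_regions is not None:
                t0 = time.perf_counter()
                try:
                    promoter_frac = hotspot_region_overlap(
                        reference, prom_set.windows(), cfg.overlap_rule
                    )
                    bundle["reference_hotspots_in_promoters"] = promoter_frac.as_dict()
                except UndefinedFractionError:
                    pass
                _stage("promoters", t0, n_promoters=len(prom_set))

    # ---- peak (e.g. H3K4me3 default-site) co-localization
    if cfg.peaks and (reference is not None or lifted is not None):
        t0 = time.perf_counter()
        peaks = read_hotspots(cfg.peaks, cfg.strength_column, label="peaks")
        inputs["peaks"] = _sha256(cfg.peaks)
        target = reference if reference is not None else lifted
        assert target is not None
        peak_frac = hotspot_region_overlap(
            target, [h.interval for h in peaks], cfg.overlap_rule
        )
        bundle["hotspots_in_peaks"] = peak_frac.as_dict()
        _stage("peaks", t0, n_peaks=len(peaks))

    manifest = {
        "version": __version__,
        "parameters": {
            k: v for k, v in asdict(cfg).items() if not isinstance(v, (type(None),))
        },
        "input_sha256": inputs,
    }
    write_report(bundle, outdir / "report.json", outdir / "report.tsv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=list)
        fh.write("\n")
    return bundle
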