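"""Readers and writers for the pipeline's text formats.

Formats handled:

* hotspot / peak tables — BED3+ with a configurable strength column
  (default: column 5, the BED score slot);
* UCSC chain files, plain or gzip, with full block-arithmetic validation;
* TSS tables — headered TSV with gene_id, chrom, strand, tss, biotype;
* reports — JSON (nested) and TSV (one row per category), with
  deterministic key ordering so identical runs are byte-identical.

Chromosome-name normalisation ("1" vs "chr1") is an explicit opt-in:
silent aliasing hides genuine assembly mismatches.
"""

from __future__ import annotations

import gzip
import io as _io
import json
from collections.abc import Iterable
from dataclasses import dataclass, field
from pathlib import Path
from typing import TextIO

from .core import GenomeAssembly, Hotspot, HotspotSet, Interval, interval_center
from .errors import CorruptChainError, MalformedRecordError

__all__ = [
    "ChainBlock",
    "Chain",
    "TssRecord",
    "read_hotspots",
    "write_hotspots",
    "parse_chain_file",
    "write_chain_file",
    "read_tss_table",
    "write_tss_table",
    "write_report",
]


# ---------------------------------------------------------------------------
# chain types


@dataclass(frozen=True)
class ChainBlock:
    """One gapless aligned block: ``size`` bases, then gaps dt (target) / dq (query)."""

    size: int
    dt: int = 0
    dq: int = 0

    def __post_init__(self) -> None:
        if self.size < 1 or self.dt < 0 or self.dq < 0:
            raise ValueError(f"invalid chain block {self}")


@dataclass
class Chain:
    """A UCSC chain: one gapped pairwise alignment between two assemblies.

    Target coordinates are always on the + strand.  Query coordinates are
    given on ``q_strand``; for '-' chains they count from the 3' end and
    the liftover engine converts images back to + strand positions.
    """

    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: str
    blocks: list[ChainBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.t_strand != "+":
            raise CorruptChainError(f"chain {self.chain_id}: target strand must be +")
        if self.q_strand not in "+-":
            raise CorruptChainError(f"chain {self.chain_id}: bad query strand {self.q_strand!r}")
        if not (0 <= self.t_start < self.t_end <= self.t_size):
            raise CorruptChainError(f"chain {self.chain_id}: bad target span")
        if not (0 <= self.q_start < self.q_end <= self.q_size):
            raise CorruptChainError(f"chain {self.chain_id}: bad query span")
        if not self.blocks:
            raise CorruptChainError(f"chain {self.chain_id}: no blocks")
        if self.blocks[-1].dt != 0 or self.blocks[-1].dq != 0:
            raise CorruptChainError(f"chain {self.chain_id}: final block has gaps")
        t_span = sum(b.size + b.dt for b in self.blocks)
        q_span = sum(b.size + b.dq for b in self.blocks)
        if t_span != self.t_end - self.t_start:
            raise CorruptChainError(
                f"chain {self.chain_id}: target blocks sum to {t_span}, "
                f"header span is {self.t_end - self.t_start}"
            )
        if q_span != self.q_end - self.q_start:
            raise CorruptChainError(
                f"chain {self.chain_id}: query blocks sum to {q_span}, "
                f"header span is {self.q_end - self.q_start}"
            )


@dataclass(frozen=True)
class TssRecord:
    """One transcription start site (0-based position) with strand and biotype."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    biotype: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"negative TSS {self.tss}")


# ---------------------------------------------------------------------------
# helpers


def _open_text(source: str | Path | TextIO) -> tuple[TextIO, bool]:
    """Return a text handle and whether the caller should close it."""
    if hasattr(source, "read"):
        return source, False  # type: ignore[return-value]
    path = Path(source)
    raw = path.open("rb")
    head = raw.read(2)
    raw.seek(0)
    if head == b"\x1f\x8b":
        return _io.TextIOWrapper(gzip.GzipFile(fileobj=raw)), True
    return _io.TextIOWrapper(raw), True


_SKIP_PREFIXES = ("#", "track", "browser")


def _normalize_chrom(name: str) -> str:
    return name if name.startswith("chr") else "chr" + name


# ---------------------------------------------------------------------------
# hotspot BED


def read_hotspots(
    source: str | Path | TextIO,
    strength_column: int = 5,
    assembly: GenomeAssembly | None = None,
    label: str = "",
    normalize_chroms: bool = False,
) -> HotspotSet:
    """Read a BED3+ hotspot table into a sorted :class:`HotspotSet`.

    ``strength_column`` is 1-based (BED convention: column 5 is the score
    slot).  A missing or unparsable strength yields 0 rather than an error,
    matching how score-less peak BEDs are commonly distributed.

    When ``assembly`` is None a single-use assembly is synthesised from the
    observed coordinates, so files can be loaded without a chrom.sizes table.
    """
    handle, close = _open_text(source)
    hotspots: list[tuple[str, int, int, float, str | None]] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MalformedRecordError("fewer than 3 BED columns", lineno)
            chrom = fields[0]
            if normalize_chroms:
                chrom = _normalize_chrom(chrom)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise MalformedRecordError(f"non-integer coordinate: {exc}", lineno)
            if start < 0:
                raise MalformedRecordError(f"negative coordinate {start}", lineno)
            if start >= end:
                raise MalformedRecordError(f"start {start} >= end {end}", lineno)
            if assembly is not None:
                if chrom not in assembly:
                    raise MalformedRecordError(
                        f"unknown chromosome {chrom!r} for assembly {assembly.name!r}",
                        lineno,
                    )
                if end > assembly.chrom_length(chrom):
                    raise MalformedRecordError(
                        f"interval end {end} beyond {chrom} length", lineno
                    )
            strength = 0.0
            if len(fields) >= strength_column:
                try:
                    strength = float(fields[strength_column - 1])
                except ValueError:
                    strength = 0.0
            name = fields[3] if len(fields) >= 4 and fields[3] not in (".", "") else None
            hotspots.append((chrom, start, end, strength, name))
    finally:
        if close:
            handle.close()

    if assembly is None:
        sizes: dict[str, int] = {}
        for chrom, _s, end, _v, _n in hotspots:
            sizes[chrom] = max(sizes.get(chrom, 0), end)
        assembly = GenomeAssembly("unspecified", sizes or {"chr1": 1})
    return HotspotSet(
        assembly,
        label,
        [
            Hotspot(Interval(c, s, e), interval_center(s, e), v, n)
            for c, s, e, v, n in hotspots
        ],
    )


def write_hotspots(hs: HotspotSet, dest: str | Path | TextIO, precision: int = 6) -> None:
    """Write BED5: chrom, start, end, name, strength."""
    own = not hasattr(dest, "write")
    handle = open(dest, "w") if own else dest  # type: ignore[arg-type]
    try:
        for i, h in enumerate(hs):
            name = h.name if h.name is not None else f"{hs.label or 'hs'}_{i}"
            handle.write(
                f"{h.interval.chrom}\t{h.interval.start}\t{h.interval.end}"
                f"\t{name}\t{h.strength:.{precision}g}\n"
            )
    finally:
        if own:
            handle.close()


# ---------------------------------------------------------------------------
# UCSC chain


def parse_chain_file(source: str | Path | TextIO) -> list[Chain]:
    """Parse a UCSC chain file (plain or gzip) with invariant checks.

    Any mismatch between the header spans and the block sums raises
    :class:`CorruptChainError` naming the offending chain.
    """
    handle, close = _open_text(source)
    chains: list[Chain] = []
    header: list[str] | None = None
    blocks: list[ChainBlock] = []

    def flush() -> None:
        nonlocal header, blocks
        if header is None:
            return
        (score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, chain_id) = header
        chains.append(
            Chain(
                float(score), t_name, int(t_size), t_strand, int(t_start), int(t_end),
                q_name, int(q_size), q_strand, int(q_start), int(q_end),
                chain_id, blocks,
            )
        )
        header, blocks = None, []

    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                flush()
                continue
            if line.startswith("chain"):
                flush()
                parts = line.split()
                if len(parts) != 13:
                    raise MalformedRecordError(
                        f"chain header has {len(parts)} fields, expected 13", lineno
                    )
                header = parts[1:]
                blocks = []
            else:
                if header is None:
                    raise MalformedRecordError("block line outside a chain", lineno)
                nums = line.split()
                if len(nums) == 1:
                    blocks.append(ChainBlock(int(nums[0])))
                elif len(nums) == 3:
                    blocks.append(ChainBlock(int(nums[0]), int(nums[1]), int(nums[2])))
                else:
                    raise MalformedRecordError(f"bad block line {line!r}", lineno)
        flush()
    finally:
        if close:
            handle.close()
    return chains


def write_chain_file(chains: Iterable[Chain], dest: str | Path | TextIO) -> None:
    own = not hasattr(dest, "write")
    handle = open(dest, "w") if own else dest  # type: ignore[arg-type]
    try:
        for c in chains:
            score = int(c.score) if float(c.score).is_integer() else c.score
            handle.write(
                f"chain {score} {c.t_name} {c.t_size} {c.t_strand} {c.t_start} {c.t_end} "
                f"{c.q_name} {c.q_size} {c.q_strand} {c.q_start} {c.q_end} {c.chain_id}\n"
            )
            for b in c.blocks[:-1]:
                handle.write(f"{b.size} {b.dt} {b.dq}\n")
            handle.write(f"{c.blocks[-1].size}\n\n")
    finally:
        if own:
            handle.close()


# ---------------------------------------------------------------------------
# TSS tables


_STRAND_TOKENS = {"+": "+", "-": "-", "1": "+", "-1": "-", "−": "-", "−1": "-"}


def read_tss_table(source: str | Path | TextIO) -> list[TssRecord]:
    """Read a headered TSV of gene_id, chrom, strand, tss, biotype.

    Strand tokens ``1``/``-1`` (Ensembl/biomaRt convention) are normalised
    to ``+``/``-``; anything else is a malformed record.
    """
    handle, close = _open_text(source)
    records: list[TssRecord] = []
    try:
        header_seen = False
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True  # first non-comment line is the header
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise MalformedRecordError("fewer than 4 TSS columns", lineno)
            strand = _STRAND_TOKENS.get(fields[2].strip())
            if strand is None:
                raise MalformedRecordError(f"unknown strand token {fields[2]!r}", lineno)
            try:
                tss = int(fields[3])
            except ValueError as exc:
                raise MalformedRecordError(f"non-integer TSS: {exc}", lineno)
            if tss < 0:
                raise MalformedRecordError(f"negative TSS {tss}", lineno)
            biotype = fields[4] if len(fields) > 4 else ""
            records.append(TssRecord(fields[0], fields[1], strand, tss, biotype))
    finally:
        if close:
            handle.close()
    return records


def write_tss_table(records: Iterable[TssRecord], dest: str | Path | TextIO) -> None:
    own = not hasattr(dest, "write")
    handle = open(dest, "w") if own else dest  # type: ignore[arg-type]
    try:
        handle.write("gene_id\tchrom\tstrand\ttss\tbiotype\n")
        for r in records:
            handle.write(f"{r.gene_id}\t{r.chrom}\t{r.strand}\t{r.tss}\t{r.biotype}\n")
    finally:
        if own:
            handle.close()


# ---------------------------------------------------------------------------
# reports


def _flatten(prefix: str, obj, rows: list[tuple[str, object]]) -> None:
    if isinstance(obj, dict):
        for key in sorted(obj):
            _flatten(f"{prefix}.{key}" if prefix else str(key), obj[key], rows)
    else:
        rows.append((prefix, obj))


def write_report(report: dict, json_path: str | Path, tsv_path: str | Path | None = None) -> None:
    """Write a nested report as sorted-key JSON and (optionally) flat TSV."""
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if tsv_path is not None:
        rows: list[tuple[str, object]] = []
        _flatten("", report, rows)
        with open(tsv_path, "w") as fh:
            fh.write("category\tvalue\n")
            for key, value in rows:
                fh.write(f"{key}\t{value}\n")
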