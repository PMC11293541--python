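"""Genomic region sets and the plain-text formats they travel in.

All coordinates inside the package are 0-based half-open; conversion to and
from 1-based conventions (VCF) happens only at the format boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

logger = logging.getLogger(__name__)

REGION_KINDS = ("cgi", "promoter", "exon", "control", "window", "custom")


class BedParseError(ValueError):
    """Raised for a malformed BED line; carries the offending line number."""


@dataclass(frozen=True)
class GenomicRegion:
    """A half-open interval [start, end) on a reference sequence."""

    chrom: str
    start: int
    end: int
    name: str = ""
    kind: str = "custom"
    distance: int | None = None  # signed distance to anchor, for windows

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def __contains__(self, position: int) -> bool:
        return self.start <= position < self.end


def read_regions_bed(path: str | Path, kind: str = "custom") -> list[GenomicRegion]:
    """Read a BED3+ file into regions, taking coordinates verbatim.

    The optional fourth column supplies the region name; records without one
    are auto-named ``region_<i>``.
    """
    regions: list[GenomicRegion] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] else f"region_{len(regions)}"
            try:
                regions.append(GenomicRegion(fields[0], start, end, name, kind))
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
    return regions


def write_regions_bed(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    with open(path, "w") as handle:
        for region in regions:
            handle.write(f"{region.chrom}\t{region.start}\t{region.end}\t{region.name}\n")


def promoters_from_tss(
    tss: Iterable[tuple[str, int, str]],
    up: int = 1000,
    down: int = 100,
) -> list[GenomicRegion]:
    """Promoter windows around transcription start sites, strand-aware.

    A promoter spans `up` bases upstream of and `down` bases downstream from
    the TSS in transcription orientation, clipped at the chromosome origin.
    """
    if up < 0 or down < 0:
        raise ValueError("up and down must be non-negative")
    promoters = []
    for i, (chrom, pos, strand) in enumerate(tss):
        if strand == "+":
            start, end = pos - up, pos + down
        elif strand == "-":
            start, end = pos - down, pos + up
        else:
            raise ValueError(f"unknown strand symbol {strand!r}")
        promoters.append(
            GenomicRegion(chrom, max(0, start), end, f"promoter_{i}", "promoter")
        )
    return promoters


def sliding_window_regions(
    anchors: Iterable[tuple[str, int, str]],
    flank: int = 2000,
    width: int = 100,
) -> list[GenomicRegion]:
    """Tile [anchor-flank, anchor+flank) with non-overlapping windows.

    Each window carries the signed distance of its anchor-proximal edge to
    the anchor, with the sign taken in transcription orientation so profiles
    from opposite strands superimpose.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if flank % width != 0:
        raise ValueError(f"width {width} does not divide flank {flank}")
    windows = []
    for i, (chrom, pos, strand) in enumerate(anchors):
        if strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {strand!r}")
        for start in range(pos - flank, pos + flank, width):
            end = start + width
            if end <= 0:
                continue
            dist = start - pos if strand == "+" else pos - end
            windows.append(
                GenomicRegion(
                    chrom, max(0, start), end,
                    f"window_{i}_{dist}", "window", distance=dist,
                )
            )
    return windows


class SnpMask:
    """Set of (chrom, 0-based position) pairs to exclude from counting."""

    def __init__(self, positions: Iterable[tuple[str, int]] = ()) -> None:
        self._positions: frozenset[tuple[str, int]] = frozenset(positions)

    def __contains__(self, item: tuple[str, int]) -> bool:
        return item in self._positions

    def __len__(self) -> int:
        return len(self._positions)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(sorted(self._positions))

    def __or__(self, other: "SnpMask") -> "SnpMask":
        return SnpMask(self._positions | other._positions)


def read_snp_mask(path: str | Path, min_depth: int = 0) -> SnpMask:
    """Build a SNP mask from a VCF, keeping records that pass FILTER and DP.

    Low-coverage variant calls are unreliable, so records with DP below
    `min_depth` are dropped; records lacking DP entirely are skipped with a
    warning when a depth filter is requested. VCF 1-based POS is converted
    to the package's 0-based convention.
    """
    positions: set[tuple[str, int]] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for record in vcf:
            if list(record.filter.keys()) not in ([], ["PASS"], ["."]):
                continue
            if min_depth > 0:
                depth = record.info.get("DP")
                if depth is None:
                    depths = [
                        sample.get("DP")
                        for sample in record.samples.values()
                        if sample.get("DP") is not None
                    ]
                    depth = sum(depths) if depths else None
                if depth is None:
                    logger.warning(
                        "VCF record %s:%d has no DP field; skipped",
                        record.chrom, record.pos,
                    )
                    continue
                if depth < min_depth:
                    continue
            positions.add((record.chrom, record.pos - 1))
    return SnpMask(positions)
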