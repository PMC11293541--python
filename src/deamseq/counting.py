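"""Context- and strand-aware counting of deamination-induced transitions.

Limited deamination converts a fraction of 5-methylcytosines (and 5hmC) to
thymine, so methylation shows up as an excess of C->T mismatches against
the reference. The protocol's signature is read-asymmetric: Read1 carries
the signal as C->T at reference-C positions, Read2 as G->A at reference-G
positions (the same chemistry seen from the complementary strand). Counting
therefore runs two channels:

* Read1 at reference C: observed T increments ``error``; observed C
  increments ``total`` only. Other bases (sequencing errors to A/G) are not
  cytosine-informative and are excluded from the denominator.
* Read2 at reference G: observed A is an error, observed G a clean call.

The sequence context of a site is the dinucleotide on the cytosine's own
strand: for a reference C read by Read1 the 3' neighbour at position+1; for
a reference G read by Read2 the complement of the base at position-1
(5'-C-G-3' on the bottom strand). CpG is the methylatable context in human;
CpA/CpT/CpC serve as built-in error controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .regions import GenomicRegion, SnpMask

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
CONTEXTS = ("CpG", "CpA", "CpT", "CpC")
_CONTEXT_OF_PARTNER = {"G": "CpG", "A": "CpA", "T": "CpT", "C": "CpC", "N": "CpN"}


@dataclass(frozen=True)
class CountingFilters:
    """Observation-level filters applied before a base is counted.

    Defaults follow the protocol's tuned operating point: mapping quality
    >= 10, base quality >= 30, and exclusion of the first two and last two
    sequencing cycles of each read, where the transition rate is depressed.
    """

    min_mapq: int = 10
    min_baseq: int = 30
    exclude_cycles_start: int = 2
    exclude_cycles_end: int = 2
    snp_mask: SnpMask | None = None

    def __post_init__(self) -> None:
        if min(self.min_mapq, self.min_baseq,
               self.exclude_cycles_start, self.exclude_cycles_end) < 0:
            raise ValueError("filter thresholds must be non-negative")


@dataclass
class SiteTransitionCount:
    """Per-site transition tally for one read channel."""

    chrom: str
    position: int  # 0-based position of the cytosine on its strand
    strand: str  # '+' for reference-C (Read1 channel), '-' for reference-G
    context: str  # CpG / CpA / CpT / CpC / CpN
    upstream_base: str
    read_number: int
    error: int = 0
    total: int = 0

    @property
    def rate(self) -> float:
        return self.error / self.total if self.total else float("nan")


@dataclass
class RegionTransitionCount:
    """Regional Error / Total aggregate over the CpG sites of a region."""

    region: GenomicRegion
    error: int
    total: int
    n_sites: int = 0

    @property
    def covered(self) -> bool:
        return self.total > 0

    @property
    def rate(self) -> float:
        if not self.covered:
            return float("nan")
        return self.error / self.total


class ReferenceLookup:
    """Uppercased per-chromosome sequence cache over a FASTA or a mapping."""

    def __init__(self, reference: str | Path | Mapping[str, str]) -> None:
        if isinstance(reference, (str, Path)):
            import pyfaidx

            self._fasta = pyfaidx.Fasta(str(reference))
            self._mapping = None
        else:
            self._fasta = None
            self._mapping = {k: v.upper() for k, v in reference.items()}
        self._cache: dict[str, str] = {}

    def chrom(self, name: str) -> str:
        if name not in self._cache:
            if self._mapping is not None:
                if name not in self._mapping:
                    raise KeyError(f"reference sequence {name!r} not found")
                self._cache[name] = self._mapping[name]
            else:
                if name not in self._fasta:
                    raise KeyError(f"reference sequence {name!r} not found")
                self._cache[name] = str(self._fasta[name][:]).upper()
        return self._cache[name]


def _indel_adjacent_qpos(read: pysam.AlignedSegment) -> set[int]:
    """Query positions flanking (or inside) insertions and deletions."""
    excluded: set[int] = set()
    qpos = 0
    for op, length in read.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X
            qpos += length
        elif op in (1, 4):  # I, S consume query
            if op == 1:
                excluded.update(range(max(0, qpos - 1), qpos + length + 1))
            qpos += length
        elif op in (2, 3):  # D, N consume reference only
            excluded.update({qpos - 1, qpos})
    excluded.discard(-1)
    return excluded


def _read_cycle(qpos: int, read: pysam.AlignedSegment) -> int:
    """1-based sequencing cycle of a query position.

    SAM stores reverse-strand reads reverse-complemented, so for those the
    stored query position runs opposite to the machine cycle.
    """
    length = read.query_length or len(read.query_sequence or "")
    return length - qpos if read.is_reverse else qpos + 1


def _iter_filtered_observations(read, filters):
    """Yield (rpos, base, cycle) for observations passing all filters."""
    excluded_q = _indel_adjacent_qpos(read)
    length = read.query_length or 0
    seq = read.query_sequence
    quals = read.query_qualities
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if qpos in excluded_q:
            continue
        if quals is not None and quals[qpos] < filters.min_baseq:
            continue
        cycle = _read_cycle(qpos, read)
        if cycle <= filters.exclude_cycles_start or cycle > length - filters.exclude_cycles_end:
            continue
        if filters.snp_mask is not None and (read.reference_name, rpos) in filters.snp_mask:
            continue
        yield rpos, seq[qpos], cycle


def _read_passes(read: pysam.AlignedSegment, filters: CountingFilters) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
        or read.is_qcfail
        or read.mapping_quality < filters.min_mapq
    )


def count_transitions(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
    reference: str | Path | Mapping[str, str] | ReferenceLookup,
    filters: CountingFilters | None = None,
) -> list[SiteTransitionCount]:
    """Count C->T (Read1) and G->A (Read2) transitions per cytosine site.

    `alignments` is a SAM path or an iterable of records that has already
    been through mate-overlap trimming; masked bases fail the base-quality
    filter here and are never double counted.
    """
    filters = filters or CountingFilters()
    ref = reference if isinstance(reference, ReferenceLookup) else ReferenceLookup(reference)

    if isinstance(alignments, (str, Path)):
        handle = pysam.AlignmentFile(str(alignments), "r", check_sq=False)
        reads: Iterable[pysam.AlignedSegment] = handle
    else:
        handle = None
        reads = alignments

    sites: dict[tuple[str, int, int], SiteTransitionCount] = {}
    try:
        for read in reads:
            if not _read_passes(read, filters):
                continue
            read_number = 2 if read.is_read2 else 1
            refseq = ref.chrom(read.reference_name)
            for rpos, base, _cycle in _iter_filtered_observations(read, filters):
                refbase = refseq[rpos]
                if read_number == 1 and refbase == "C":
                    if base not in ("C", "T"):
                        continue
                    strand = "+"
                    partner = refseq[rpos + 1] if rpos + 1 < len(refseq) else "N"
                    upstream = refseq[rpos - 1] if rpos > 0 else "N"
                    is_error = base == "T"
                elif read_number == 2 and refbase == "G":
                    if base not in ("G", "A"):
                        continue
                    strand = "-"
                    partner = _COMPLEMENT[refseq[rpos - 1]] if rpos > 0 else "N"
                    upstream = _COMPLEMENT[refseq[rpos + 1]] if rpos + 1 < len(refseq) else "N"
                    is_error = base == "A"
                else:
                    continue
                key = (read.reference_name, rpos, read_number)
                site = sites.get(key)
                if site is None:
                    site = SiteTransitionCount(
                        chrom=read.reference_name,
                        position=rpos,
                        strand=strand,
                        context=_CONTEXT_OF_PARTNER[partner],
                        upstream_base=upstream,
                        read_number=read_number,
                    )
                    sites[key] = site
                site.total += 1
                site.error += int(is_error)
    finally:
        if handle is not None:
            handle.close()
    return [sites[key] for key in sorted(sites)]


def aggregate_regions(
    sites: Iterable[SiteTransitionCount],
    regions: Sequence[GenomicRegion],
    context: str = "CpG",
    pool_reads: bool = True,
    read_number: int | None = None,
) -> list[RegionTransitionCount]:
    """Sum site-level Error/Total over each region's cytosines.

    By default the Read1 C->T and Read2 G->A channels are pooled into a
    single regional Error/Total; pass ``read_number`` to keep one channel.
    Regions with no informative site are returned uncovered rather than
    dropped, so a partition of the genome conserves counts.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, region in enumerate(regions):
        trees.setdefault(region.chrom, IntervalTree()).addi(region.start, region.end, idx)

    error = np.zeros(len(regions), dtype=np.int64)
    total = np.zeros(len(regions), dtype=np.int64)
    n_sites = np.zeros(len(regions), dtype=np.int64)
    for site in sites:
        if site.context != context:
            continue
        if not pool_reads and read_number is not None and site.read_number != read_number:
            continue
        tree = trees.get(site.chrom)
        if tree is None:
            continue
        for interval in tree[site.position]:
            idx = interval.data
            error[idx] += site.error
            total[idx] += site.total
            n_sites[idx] += 1
    return [
        RegionTransitionCount(region, int(error[i]), int(total[i]), int(n_sites[i]))
        for i, region in enumerate(regions)
    ]


def count_cycle_table(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
    reference: str | Path | Mapping[str, str] | ReferenceLookup,
    filters: CountingFilters | None = None,
) -> pd.DataFrame:
    """Per (read, context, cycle) C->T tally at reference-C positions.

    Both mates are scored on the same reference-C channel here: Read1
    carries deamination signal plus sequencing error, Read2 only the error,
    so their difference isolates the deamination signature. Cycle exclusion
    is deliberately not applied (the table is how edge cycles are examined),
    but base/mapping quality and SNP masking are.
    """
    filters = filters or CountingFilters(exclude_cycles_start=0, exclude_cycles_end=0)
    filters = replace(filters, exclude_cycles_start=0, exclude_cycles_end=0)
    ref = reference if isinstance(reference, ReferenceLookup) else ReferenceLookup(reference)

    if isinstance(alignments, (str, Path)):
        handle = pysam.AlignmentFile(str(alignments), "r", check_sq=False)
        reads: Iterable[pysam.AlignedSegment] = handle
    else:
        handle = None
        reads = alignments

    tally: dict[tuple[int, str, int], list[int]] = {}
    try:
        for read in reads:
            if not _read_passes(read, filters):
                continue
            read_number = 2 if read.is_read2 else 1
            refseq = ref.chrom(read.reference_name)
            for rpos, base, cycle in _iter_filtered_observations(read, filters):
                if refseq[rpos] != "C" or base not in ("C", "T"):
                    continue
                partner = refseq[rpos + 1] if rpos + 1 < len(refseq) else "N"
                context = _CONTEXT_OF_PARTNER[partner]
                if context == "CpN":
                    continue
                cell = tally.setdefault((read_number, context, cycle), [0, 0])
                cell[1] += 1
                cell[0] += int(base == "T")
    finally:
        if handle is not None:
            handle.close()

    rows = [
        {"read": rn, "context": ctx, "cycle": cyc, "error": err, "total": tot}
        for (rn, ctx, cyc), (err, tot) in sorted(tally.items())
    ]
    return pd.DataFrame(rows, columns=["read", "context", "cycle", "error", "total"])


def compute_imbalance(cycle_table: pd.DataFrame) -> pd.DataFrame:
    """Excess of Read1 over Read2 C->T rate per (context, cycle).

    Deamination signal sits on Read1's channel only, while sequencing error
    contributes to both reads alike, so the difference cancels the shared
    error. Cells missing either channel are reported as NaN.
    """
    if cycle_table.empty:
        raise ValueError("empty cycle table")
    rates = cycle_table.assign(rate=lambda d: d["error"] / d["total"]).pivot_table(
        index=["context", "cycle"], columns="read", values="rate"
    )
    out = rates.reindex(columns=[1, 2])
    out["imbalance"] = out[1] - out[2]
    out = out.rename(columns={1: "rate_read1", 2: "rate_read2"}).reset_index()
    out.columns.name = None
    return out
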