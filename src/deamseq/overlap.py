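"""Mate-overlap removal so each sequenced molecule position is counted once.

Paired-end mates from short inserts read the same stretch of the molecule
twice. Counting a deamination-induced transition in both mates would double
its weight, so the portion of Read2 whose reference footprint lies inside
Read1's is silenced. Silencing is done by zeroing base qualities rather
than rewriting CIGARs: the records stay valid SAM and the decision to skip
the bases is left to the counting filters (base quality >= 30), where it is
applied anyway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pysam

logger = logging.getLogger(__name__)

PG_ID = "deamseq-trim-overlap"


@dataclass
class TrimStats:
    pairs_trimmed: int = 0
    pairs_untouched: int = 0
    pairs_rejected: int = 0
    unpaired_passed: int = 0


def _overlap_query_positions(read2: pysam.AlignedSegment, r1_start: int, r1_end: int) -> list[int]:
    """Query positions of read2 whose reference placement falls in [r1_start, r1_end).

    Inserted bases carry no reference coordinate of their own; they are
    assigned the coordinate of the preceding aligned base, so insertions
    inside the overlap are masked together with their anchor.
    """
    positions = []
    last_ref = read2.reference_start
    for qpos, rpos in read2.get_aligned_pairs(matches_only=False):
        if qpos is None:
            if rpos is not None:
                last_ref = rpos
            continue
        anchor = rpos if rpos is not None else last_ref
        if rpos is not None:
            last_ref = rpos
        if anchor is not None and r1_start <= anchor < r1_end:
            positions.append(qpos)
    return positions


def trim_overlap(
    read1: pysam.AlignedSegment, read2: pysam.AlignedSegment
) -> tuple[pysam.AlignedSegment, pysam.AlignedSegment]:
    """Mask Read2 base qualities wherever its footprint overlaps Read1's.

    Read1 is returned unchanged; trimming is always taken from Read2, which
    carries the complementary-strand signal channel. Idempotent.
    """
    if (
        read1.is_unmapped
        or read2.is_unmapped
        or read1.reference_name != read2.reference_name
        or not (read1.is_proper_pair and read2.is_proper_pair)
    ):
        raise ValueError("pair violates AlignedPair invariants")
    qpos = _overlap_query_positions(read2, read1.reference_start, read1.reference_end)
    if qpos:
        quals = list(read2.query_qualities)
        for q in qpos:
            quals[q] = 0
        read2.query_qualities = quals
    return read1, read2


def trim_overlap_sam(
    in_path: str | Path, out_path: str | Path
) -> TrimStats:
    """Stream a SAM file, masking mate overlaps pair by pair.

    Input need not be name-grouped; mates are paired internally by query
    name. Improperly mapped pairs (different chromosome, missing proper-pair
    flag, unmapped mate) are discarded with a logged count. Reads whose mate
    never appears pass through untouched. Output order matches input.
    """
    stats = TrimStats()
    with pysam.AlignmentFile(str(in_path), "r", check_sq=False) as infile:
        header = infile.header.to_dict()
        header.setdefault("PG", []).append(
            {"ID": PG_ID, "PN": "deamseq", "CL": "trim-overlap"}
        )
        order: list[str] = []
        buckets: dict[str, list[pysam.AlignedSegment]] = {}
        for read in infile:
            if read.is_secondary or read.is_supplementary:
                continue
            if read.query_name not in buckets:
                order.append(read.query_name)
                buckets[read.query_name] = []
            buckets[read.query_name].append(read)

    with pysam.AlignmentFile(str(out_path), "w", header=pysam.AlignmentHeader.from_dict(header)) as outfile:
        for name in order:
            reads = buckets[name]
            r1 = next((r for r in reads if r.is_read1), None)
            r2 = next((r for r in reads if r.is_read2), None)
            if r1 is None or r2 is None:
                for read in reads:
                    outfile.write(read)
                stats.unpaired_passed += len(reads)
                continue
            try:
                overlapped = bool(
                    _overlap_query_positions(r2, r1.reference_start, r1.reference_end)
                )
                trim_overlap(r1, r2)
            except ValueError:
                stats.pairs_rejected += 1
                continue
            if overlapped:
                stats.pairs_trimmed += 1
            else:
                stats.pairs_untouched += 1
            for read in reads:
                outfile.write(read)
    if stats.pairs_rejected:
        logger.info("discarded %d improperly mapped pairs", stats.pairs_rejected)
    return stats
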