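"""Synthetic limited-deamination data with known ground truth.

The generator emulates the signal model of a limited-deamination library:
every read-level observation of a methylated CpG cytosine is converted
C->T with probability d (default 0.01, the protocol's tuned deamination
rate), and every cytosine observation additionally errs with the
background rate e (default 1e-5, a typical post-filter Illumina
substitution rate) — a 1000-fold signal-to-noise ratio. The deamination
signature is read-asymmetric, as in the protocol: Read1 carries it as
C->T at top-strand CpG cytosines, Read2 as G->A at bottom-strand CpG
cytosines, while background error affects both mates symmetrically.
5-hydroxymethylated sites deaminate at the same rate and are deliberately
indistinguishable from 5mC.

Two fidelity levels are offered: full SAM read pairs (exercising overlap
trimming and pileup counting end to end) and direct per-site binomial
pileup counts, which are orders of magnitude faster and share the same
truth bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .counting import RegionTransitionCount
from .regions import GenomicRegion

#: Repeating sequence unit: one symmetric CpG (top-strand C at offset 2,
#: bottom-strand C at offset 3) and one non-CpG cytosine (CpA at offset 6)
#: per 8 bases.
_UNIT = "TACGTTCA"
_UNIT_CPG_OFFSET = 2
_UNIT_NONCPG_OFFSET = 6
_SPACER_UNIT = "ATTA"  # cytosine-free spacer between regions


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator; the seed is mandatory.

    `coverage` is the number of informative observations per cytosine site
    in the counting channel; `methylation` fixes per-region levels, or is
    drawn uniformly on [0, 1] when omitted.
    """

    seed: int
    deamination_rate: float = 0.01
    background_rate: float = 1e-5
    coverage: int = 30
    read_length: int = 100
    n_regions: int = 10
    cpg_per_region: int = 100
    methylation: Sequence[float] | None = None
    n_control_regions: int = 4
    snp_rate: float = 0.0
    hydroxymethyl_fraction: float = 0.0
    fragment_length: int = 160
    mate_overlap_fraction: float = 1.0
    degrade_read_ends: bool = False
    spacer_length: int = 200

    def __post_init__(self) -> None:
        if not (0 <= self.background_rate <= self.deamination_rate <= 1):
            raise ValueError("require 0 <= background_rate <= deamination_rate <= 1")
        if self.coverage < 1 or self.cpg_per_region < 1 or self.n_regions < 1:
            raise ValueError("coverage, cpg_per_region and n_regions must be >= 1")
        if self.read_length < 10 or not (0 < self.fragment_length):
            raise ValueError("invalid read geometry")
        if self.methylation is not None and len(self.methylation) != self.n_regions:
            raise ValueError("methylation list must have one value per region")
        if self.spacer_length < self.read_length:
            raise ValueError("spacer must be at least one read length")


@dataclass
class SimTruth:
    """Everything the generator decided, for use as a test oracle."""

    config: SimConfig
    chrom: str
    sequence: str
    regions: list[GenomicRegion]
    control_regions: list[GenomicRegion]
    methylation: np.ndarray
    control_wm: np.ndarray
    cpg_positions: dict[str, np.ndarray]
    noncpg_positions: dict[str, np.ndarray]
    site_methylated: dict[str, np.ndarray]
    site_hydroxy: dict[str, np.ndarray]
    snps: dict[int, tuple[str, str]]
    clipped_regions: list[str] = field(default_factory=list)

    @property
    def all_regions(self) -> list[GenomicRegion]:
        return self.regions + self.control_regions

    def assigned_level(self, name: str) -> float:
        for i, region in enumerate(self.regions):
            if region.name == name:
                return float(self.methylation[i])
        for i, region in enumerate(self.control_regions):
            if region.name == name:
                return float(self.control_wm[i])
        raise KeyError(name)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_reference(config: SimConfig) -> SimTruth:
    """Build the reference, region sets and per-site methylation truth.

    Each region is a run of `cpg_per_region` copies of an 8-bp unit holding
    one symmetric CpG and one non-CpG cytosine, separated from its
    neighbours by a cytosine-free spacer. Control regions are appended
    fully methylated with WM = 1, mirroring stably hypermethylated
    internal controls.
    """
    rng = _rng(config, 0)
    if config.methylation is None:
        methylation = rng.uniform(0.0, 1.0, size=config.n_regions)
    else:
        methylation = np.asarray(config.methylation, dtype=float)
        if ((methylation < 0) | (methylation > 1)).any():
            raise ValueError("assigned methylation must lie in [0, 1]")
    control_wm = np.ones(config.n_control_regions)

    spacer = (_SPACER_UNIT * math.ceil(config.spacer_length / len(_SPACER_UNIT)))[
        : config.spacer_length
    ]
    region_len = len(_UNIT) * config.cpg_per_region

    chunks = [spacer]
    pos = len(spacer)
    regions: list[GenomicRegion] = []
    control_regions: list[GenomicRegion] = []
    cpg_positions: dict[str, np.ndarray] = {}
    noncpg_positions: dict[str, np.ndarray] = {}
    site_methylated: dict[str, np.ndarray] = {}
    site_hydroxy: dict[str, np.ndarray] = {}

    levels = list(methylation) + list(control_wm)
    for i, level in enumerate(levels):
        is_control = i >= config.n_regions
        name = (
            f"control_{i - config.n_regions}" if is_control else f"region_{i}"
        )
        region = GenomicRegion(
            "sim", pos, pos + region_len, name,
            "control" if is_control else "cgi",
        )
        chunks.append(_UNIT * config.cpg_per_region)
        offsets = pos + len(_UNIT) * np.arange(config.cpg_per_region)
        cpg_positions[name] = offsets + _UNIT_CPG_OFFSET
        noncpg_positions[name] = offsets + _UNIT_NONCPG_OFFSET
        status = rng.random(config.cpg_per_region) < level
        site_methylated[name] = status
        site_hydroxy[name] = status & (
            rng.random(config.cpg_per_region) < config.hydroxymethyl_fraction
        )
        (control_regions if is_control else regions).append(region)
        pos += region_len
        chunks.append(spacer)
        pos += len(spacer)

    sequence = "".join(chunks)

    snps: dict[int, tuple[str, str]] = {}
    if config.snp_rate > 0:
        bases = "ACGT"
        for region in regions + control_regions:
            hits = np.nonzero(rng.random(len(region)) < config.snp_rate)[0]
            for offset in hits:
                p = region.start + int(offset)
                ref_base = sequence[p]
                alt = bases[(bases.index(ref_base) + rng.integers(1, 4)) % 4]
                snps[p] = (ref_base, alt)

    return SimTruth(
        config=config, chrom="sim", sequence=sequence,
        regions=regions, control_regions=control_regions,
        methylation=methylation, control_wm=control_wm,
        cpg_positions=cpg_positions, noncpg_positions=noncpg_positions,
        site_methylated=site_methylated, site_hydroxy=site_hydroxy,
        snps=snps,
    )


def simulate_pileup_counts(
    truth: SimTruth,
    rng: np.random.Generator | None = None,
    coverage: int | None = None,
) -> tuple[list[RegionTransitionCount], list[RegionTransitionCount]]:
    """Draw per-region (Error, Total) counts directly at the pileup level.

    Each cytosine site contributes `coverage` observations; errors are
    binomial with probability e (background) plus d at methylated CpG
    sites. Returns (CpG counts, non-CpG counts) over all regions, analysis
    regions first, controls after.
    """
    config = truth.config
    rng = rng if rng is not None else _rng(config, 1)
    cov = coverage if coverage is not None else config.coverage
    d, e = config.deamination_rate, config.background_rate

    cpg_counts: list[RegionTransitionCount] = []
    noncpg_counts: list[RegionTransitionCount] = []
    for region in truth.all_regions:
        status = truth.site_methylated[region.name]
        p = np.where(status, min(1.0, d + e), e)
        errors = rng.binomial(cov, p)
        n_sites = status.size
        cpg_counts.append(
            RegionTransitionCount(region, int(errors.sum()), cov * n_sites, n_sites)
        )
        bg_errors = rng.binomial(cov, e, size=n_sites)
        noncpg_counts.append(
            RegionTransitionCount(region, int(bg_errors.sum()), cov * n_sites, n_sites)
        )
    return cpg_counts, noncpg_counts


def _apply_events(
    seq: list[str],
    start: int,
    truth: SimTruth,
    read_number: int,
    rng: np.random.Generator,
) -> None:
    """Mutate a read window in place: SNPs, deamination, background error."""
    config = truth.config
    d, e = config.deamination_rate, config.background_rate
    end = start + len(seq)
    ref = truth.sequence

    for p, (_ref_base, alt) in truth.snps.items():
        if start <= p < end:
            seq[p - start] = alt

    # deamination: Read1 at top-strand CpG C, Read2 at bottom-strand CpG C
    for name in truth.site_methylated:
        positions = (
            truth.cpg_positions[name]
            if read_number == 1
            else truth.cpg_positions[name] + 1
        )
        lo, hi = np.searchsorted(positions, (start, end))
        for k in range(lo, hi):
            if truth.site_methylated[name][k] and rng.random() < d:
                q = int(positions[k]) - start
                if seq[q] == ("C" if read_number == 1 else "G"):
                    seq[q] = "T" if read_number == 1 else "A"

    if e > 0:
        for q in range(len(seq)):
            base = ref[start + q]
            if base == "C" and rng.random() < e:
                seq[q] = "T"
            elif base == "G" and rng.random() < e:
                seq[q] = "A"


def simulate_observations(
    truth: SimTruth,
    sam_path: str | Path,
    rng: np.random.Generator | None = None,
) -> int:
    """Write paired-end SAM reads carrying the deamination signature.

    Pairs are emitted in FR orientation (Read1 forward); mates overlap
    whenever the fragment is shorter than two read lengths. Returns the
    number of pairs written. Same truth and generator state give
    byte-identical output.
    """
    config = truth.config
    rng = rng if rng is not None else _rng(config, 2)
    read_len = config.read_length
    frag_len = max(config.fragment_length, read_len)

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": truth.chrom, "LN": len(truth.sequence)}],
            "PG": [{"ID": "deamseq-simulate", "PN": "deamseq"}],
        }
    )
    base_qual = [37] * read_len
    if config.degrade_read_ends:
        for i in (0, 1, read_len - 2, read_len - 1):
            base_qual[i] = 20

    n_pairs_total = 0
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for region in truth.all_regions:
            span = len(region) + frag_len
            n_pairs = math.ceil(config.coverage * span / read_len)
            starts = rng.integers(
                region.start - frag_len + 1, region.end, size=n_pairs
            )
            starts = np.clip(starts, 0, len(truth.sequence) - frag_len)
            for i, f in enumerate(sorted(int(s) for s in starts)):
                r2_start = f + frag_len - read_len
                seq1 = list(truth.sequence[f : f + read_len])
                seq2 = list(truth.sequence[r2_start : r2_start + read_len])
                _apply_events(seq1, f, truth, 1, rng)
                _apply_events(seq2, r2_start, truth, 2, rng)

                name = f"{region.name}_pair{n_pairs_total + i}"
                r1 = pysam.AlignedSegment(header)
                r1.query_name = name
                r1.query_sequence = "".join(seq1)
                r1.flag = 0x1 | 0x2 | 0x20 | 0x40  # paired, proper, mate rev, first
                r1.reference_id = 0
                r1.reference_start = f
                r1.mapping_quality = 60
                r1.cigarstring = f"{read_len}M"
                r1.next_reference_id = 0
                r1.next_reference_start = r2_start
                r1.template_length = frag_len
                r1.query_qualities = base_qual

                r2 = pysam.AlignedSegment(header)
                r2.query_name = name
                r2.query_sequence = "".join(seq2)
                r2.flag = 0x1 | 0x2 | 0x10 | 0x80  # paired, proper, reverse, second
                r2.reference_id = 0
                r2.reference_start = r2_start
                r2.mapping_quality = 60
                r2.cigarstring = f"{read_len}M"
                r2.next_reference_id = 0
                r2.next_reference_start = f
                r2.template_length = -frag_len
                r2.query_qualities = base_qual

                out.write(r1)
                out.write(r2)
            n_pairs_total += n_pairs
    return n_pairs_total


def simulate_paired_conditions(
    config: SimConfig,
    dmr_fraction: float,
    effect: float,
    n_replicates: int = 3,
) -> dict:
    """Two-condition replicated pileup datasets with true DMR labels.

    A `dmr_fraction` of regions shift their methylation by `effect` in
    condition A (alternating direction, clipped to [0, 1] with the clip
    recorded in the truth); replicates differ only by their generator
    stream. Returns a dict with per-condition truths, per-replicate
    (CpG, non-CpG) counts, and the boolean label series.
    """
    if not (0 < effect <= 1):
        raise ValueError("effect must lie in (0, 1]")
    if not (0 <= dmr_fraction <= 1):
        raise ValueError("dmr_fraction must lie in [0, 1]")
    truth_b = simulate_reference(config)
    base = truth_b.methylation.copy()

    n_shift = int(round(dmr_fraction * config.n_regions))
    shifted = base.copy()
    labels = np.zeros(config.n_regions, dtype=bool)
    clipped = []
    for idx in range(n_shift):
        delta = effect if idx % 2 == 0 else -effect
        value = base[idx] + delta
        if not (0 <= value <= 1):
            value = base[idx] - delta  # try the other direction first
            if not (0 <= value <= 1):
                value = min(1.0, max(0.0, base[idx] + delta))
                clipped.append(f"region_{idx}")
        if value != base[idx]:
            labels[idx] = True
        shifted[idx] = value

    config_a = replace(config, methylation=tuple(shifted))
    truth_a = simulate_reference(config_a)
    truth_a.clipped_regions = clipped

    reps_a = [
        simulate_pileup_counts(truth_a, rng=_rng(config, 100 + r))
        for r in range(n_replicates)
    ]
    reps_b = [
        simulate_pileup_counts(truth_b, rng=_rng(config, 200 + r))
        for r in range(n_replicates)
    ]
    region_names = [r.name for r in truth_b.regions]
    import pandas as pd

    return {
        "truth_a": truth_a,
        "truth_b": truth_b,
        "replicates_a": reps_a,
        "replicates_b": reps_b,
        "labels": pd.Series(labels, index=region_names),
    }


def write_fasta(truth: SimTruth, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as handle:
        handle.write(f">{truth.chrom}\n")
        for i in range(0, len(truth.sequence), width):
            handle.write(truth.sequence[i : i + width] + "\n")


def write_controls_tsv(truth: SimTruth, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("chrom\tstart\tend\tname\twm\n")
        for region, wm in zip(truth.control_regions, truth.control_wm):
            handle.write(
                f"{region.chrom}\t{region.start}\t{region.end}\t{region.name}\t{wm:.4f}\n"
            )


def write_truth_tsv(truth: SimTruth, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("name\tassigned_methylation\tn_cpg\tn_methylated\n")
        for i, region in enumerate(truth.regions):
            status = truth.site_methylated[region.name]
            handle.write(
                f"{region.name}\t{truth.methylation[i]:.6f}\t{status.size}\t{int(status.sum())}\n"
            )


def write_snp_vcf(truth: SimTruth, path: str | Path, depth: int = 30) -> None:
    """Plain-text VCF of the simulated homozygous SNPs (1-based POS)."""
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write(f"##contig=<ID={truth.chrom},length={len(truth.sequence)}>\n")
        handle.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pos in sorted(truth.snps):
            ref_base, alt = truth.snps[pos]
            handle.write(
                f"{truth.chrom}\t{pos + 1}\t.\t{ref_base}\t{alt}\t60\tPASS\tDP={depth}\n"
            )
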