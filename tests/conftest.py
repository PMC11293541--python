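import numpy as np
import pysam
import pytest

import deamseq as ds


@pytest.fixture
def header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100000}]}
    )


@pytest.fixture
def make_read(header):
    """Factory for minimal aligned SAM records."""

    def _make(
        name="r1",
        start=0,
        seq="ACGT",
        read_number=1,
        reverse=False,
        mapq=60,
        qual=37,
        cigar=None,
        proper_pair=True,
        chrom_id=0,
    ):
        read = pysam.AlignedSegment(header)
        read.query_name = name
        read.query_sequence = seq
        flag = 0x1 if proper_pair else 0
        flag |= 0x2 if proper_pair else 0
        flag |= 0x40 if read_number == 1 else 0x80
        flag |= 0x10 if reverse else 0
        read.flag = flag
        read.reference_id = chrom_id
        read.reference_start = start
        read.mapping_quality = mapq
        read.cigarstring = cigar or f"{len(seq)}M"
        if isinstance(qual, int):
            read.query_qualities = [qual] * len(seq)
        else:
            read.query_qualities = list(qual)
        return read

    return _make


@pytest.fixture
def no_cycle_filters():
    """Counting filters without the read-end cycle exclusion, for short reads."""
    return ds.CountingFilters(exclude_cycles_start=0, exclude_cycles_end=0)


@pytest.fixture(scope="session")
def small_truth():
    """A small mixed-methylation simulated genome shared across tests."""
    config = ds.SimConfig(
        seed=11,
        n_regions=4,
        cpg_per_region=60,
        coverage=40,
        methylation=(0.0, 0.3, 0.7, 1.0),
        n_control_regions=2,
    )
    return ds.simulate_reference(config)


@pytest.fixture(scope="session")
def small_sam(small_truth, tmp_path_factory):
    """Simulated, overlap-trimmed SAM for the small genome."""
    tmp = tmp_path_factory.mktemp("sam")
    raw = tmp / "reads.sam"
    trimmed = tmp / "trimmed.sam"
    ds.simulate_observations(small_truth, raw)
    ds.trim_overlap_sam(raw, trimmed)
    return trimmed
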