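"""Transition counting: filters, contexts, aggregation, imbalance."""

import numpy as np
import pandas as pd
import pytest

import deamseq as ds
from deamseq.counting import count_cycle_table

# 12-bp reference: CpG cytosine at 3 (G at 4), CpA cytosine at 8
REF = {"chr1": "AAACGTTACATT"}


def _single(sites):
    assert len(sites) == 1
    return sites[0]


class TestCountTransitions:
    def test_read1_transition_counted_with_cpg_context(self, make_read, no_cycle_filters):
        read = make_read(seq="AAATGTTACATT")  # T over the reference C at pos 3
        sites = {s.position: s for s in ds.count_transitions([read], REF, no_cycle_filters)}
        site = sites[3]
        assert (site.context, site.error, site.total) == ("CpG", 1, 1)
        assert site.upstream_base == "A" and site.read_number == 1

    def test_read1_clean_cytosine_counts_total_only(self, make_read, no_cycle_filters):
        read = make_read(seq="AAACGTTACATT")
        sites = ds.count_transitions([read], REF, no_cycle_filters)
        cpg = [s for s in sites if s.context == "CpG"][0]
        assert (cpg.error, cpg.total) == (0, 1)

    def test_low_base_quality_not_counted(self, make_read, no_cycle_filters):
        read = make_read(seq="AAATGTTACATT", qual=20)
        assert ds.count_transitions([read], REF, no_cycle_filters) == []

    def test_low_mapping_quality_not_counted(self, make_read, no_cycle_filters):
        read = make_read(seq="AAATGTTACATT", mapq=5)
        assert ds.count_transitions([read], REF, no_cycle_filters) == []

    def test_read2_g_to_a_is_bottom_strand_cpg(self, make_read, no_cycle_filters):
        # reference G at 4 preceded by C: a CpG seen from the bottom strand
        read = make_read(seq="AAACATTACATT", read_number=2, reverse=True)
        site = _single(ds.count_transitions([read], REF, no_cycle_filters))
        assert (site.position, site.strand, site.context) == (4, "-", "CpG")
        assert (site.error, site.total) == (1, 1)

    def test_read2_ignores_reference_c(self, make_read, no_cycle_filters):
        # Read2 C->T at the reference C must not enter the signal channel
        read = make_read(seq="AAATGTTACATT", read_number=2, reverse=True)
        sites = ds.count_transitions([read], REF, no_cycle_filters)
        assert all(s.position != 3 for s in sites)

    def test_non_ct_base_excluded_from_denominator(self, make_read, no_cycle_filters):
        read = make_read(seq="AAAGGTTACATT")  # G over the reference C
        sites = ds.count_transitions([read], REF, no_cycle_filters)
        assert all(s.position != 3 for s in sites)

    def test_cpa_context_assigned(self, make_read, no_cycle_filters):
        read = make_read(seq="AAACGTTATATT")  # T over the CpA cytosine at 8
        sites = {s.position: s for s in ds.count_transitions([read], REF, no_cycle_filters)}
        assert sites[8].context == "CpA" and sites[8].error == 1

    def test_snp_mask_removes_exactly_masked_sites(self, make_read, no_cycle_filters):
        from dataclasses import replace

        read = make_read(seq="AAACGTTACATT")
        masked = replace(no_cycle_filters, snp_mask=ds.SnpMask([("chr1", 3)]))
        positions = {s.position for s in ds.count_transitions([read], REF, masked)}
        unmasked = {s.position for s in ds.count_transitions([read], REF, no_cycle_filters)}
        assert unmasked - positions == {3}

    def test_cycle_exclusion_drops_read_edges(self, make_read):
        # default filters exclude the first two and last two cycles
        read = make_read(seq="CGACGTTACACG", start=0)
        ref = {"chr1": "CGACGTTACACG"}
        sites = {s.position for s in ds.count_transitions([read], ref, ds.CountingFilters())}
        assert 0 not in sites and 10 not in sites and 3 in sites

    def test_cycle_exclusion_respects_reverse_orientation(self, make_read):
        # for a reverse read the machine cycles run from the stored 3' end
        ref = {"chr1": "GGAAAAAAAAGG"}
        read = make_read(seq="AGAAAAAAAAGG", read_number=2, reverse=True)
        filters = ds.CountingFilters(exclude_cycles_start=2, exclude_cycles_end=0)
        sites = {s.position for s in ds.count_transitions([read], ref, filters)}
        # stored positions 10, 11 are machine cycles 2, 1 -> excluded
        assert sites == {0, 1}

    def test_missing_reference_is_hard_error(self, make_read, no_cycle_filters):
        read = make_read(seq="AAATGTTACATT")
        with pytest.raises(KeyError):
            ds.count_transitions([read], {"chrX": "A" * 12}, no_cycle_filters)

    def test_raising_baseq_never_increases_totals(self, small_sam, small_truth):
        ref = {"sim": small_truth.sequence}
        lo = ds.count_transitions(small_sam, ref, ds.CountingFilters(min_baseq=20))
        hi = ds.count_transitions(small_sam, ref, ds.CountingFilters(min_baseq=35))
        lo_totals = {(s.chrom, s.position, s.read_number): s.total for s in lo}
        for site in hi:
            assert site.total <= lo_totals[(site.chrom, site.position, site.read_number)]


class TestAggregateRegions:
    def _sites(self):
        return [
            ds.SiteTransitionCount("chr1", 10, "+", "CpG", "A", 1, error=1, total=100),
            ds.SiteTransitionCount("chr1", 20, "+", "CpG", "A", 1, error=2, total=100),
            ds.SiteTransitionCount("chr1", 30, "+", "CpA", "A", 1, error=5, total=100),
        ]

    def test_region_sums_counts_of_requested_context(self):
        region = ds.GenomicRegion("chr1", 0, 50, "r")
        (count,) = ds.aggregate_regions(self._sites(), [region], context="CpG")
        assert (count.error, count.total, count.n_sites) == (3, 200, 2)
        assert count.rate == pytest.approx(0.015)

    def test_uncovered_region_flagged_not_errored(self):
        region = ds.GenomicRegion("chr2", 0, 50, "r")
        (count,) = ds.aggregate_regions(self._sites(), [region])
        assert not count.covered and np.isnan(count.rate)

    def test_whole_chromosome_region_conserves_counts(self, small_sam, small_truth):
        sites = ds.count_transitions(small_sam, {"sim": small_truth.sequence})
        whole = ds.GenomicRegion("sim", 0, len(small_truth.sequence), "all")
        (count,) = ds.aggregate_regions(sites, [whole], context="CpG")
        cpg = [s for s in sites if s.context == "CpG"]
        assert count.error == sum(s.error for s in cpg)
        assert count.total == sum(s.total for s in cpg)

    def test_partition_conserves_counts(self, small_sam, small_truth):
        sites = ds.count_transitions(small_sam, {"sim": small_truth.sequence})
        length = len(small_truth.sequence)
        mid = length // 2
        parts = [
            ds.GenomicRegion("sim", 0, mid, "left"),
            ds.GenomicRegion("sim", mid, length, "right"),
        ]
        whole = ds.GenomicRegion("sim", 0, length, "all")
        split = ds.aggregate_regions(sites, parts, context="CpG")
        (total,) = ds.aggregate_regions(sites, [whole], context="CpG")
        assert sum(c.error for c in split) == total.error
        assert sum(c.total for c in split) == total.total

    def test_half_open_region_boundaries(self):
        sites = [
            ds.SiteTransitionCount("chr1", 9, "+", "CpG", "A", 1, error=0, total=1),
            ds.SiteTransitionCount("chr1", 10, "+", "CpG", "A", 1, error=0, total=1),
            ds.SiteTransitionCount("chr1", 19, "+", "CpG", "A", 1, error=0, total=1),
            ds.SiteTransitionCount("chr1", 20, "+", "CpG", "A", 1, error=0, total=1),
        ]
        region = ds.GenomicRegion("chr1", 10, 20, "r")
        (count,) = ds.aggregate_regions(sites, [region])
        assert count.n_sites == 2  # positions 10 and 19 only


class TestImbalance:
    def test_identical_channels_give_zero(self):
        table = pd.DataFrame(
            {
                "read": [1, 2, 1, 2],
                "context": ["CpG", "CpG", "CpA", "CpA"],
                "cycle": [5, 5, 5, 5],
                "error": [10, 10, 2, 2],
                "total": [1000, 1000, 1000, 1000],
            }
        )
        imbalance = ds.compute_imbalance(table)
        assert (imbalance["imbalance"] == 0).all()

    def test_shared_error_cancels(self):
        base = pd.DataFrame(
            {
                "read": [1, 2], "context": ["CpG", "CpG"], "cycle": [5, 5],
                "error": [30, 10], "total": [1000, 1000],
            }
        )
        raised = base.assign(error=base["error"] + 5)
        delta_base = ds.compute_imbalance(base)["imbalance"].iloc[0]
        delta_raised = ds.compute_imbalance(raised)["imbalance"].iloc[0]
        assert delta_base == pytest.approx(delta_raised)

    def test_missing_channel_reported_missing(self):
        table = pd.DataFrame(
            {"read": [1], "context": ["CpG"], "cycle": [5], "error": [1], "total": [10]}
        )
        imbalance = ds.compute_imbalance(table)
        assert np.isnan(imbalance["imbalance"].iloc[0])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ds.compute_imbalance(pd.DataFrame(columns=["read", "context", "cycle", "error", "total"]))

    def test_simulated_deamination_shows_up_as_cpg_imbalance(self, small_sam, small_truth):
        """With deamination on the Read1 signal strand, the CpG imbalance
        approaches the deamination rate while non-CpG contexts stay flat."""
        table = count_cycle_table(small_sam, {"sim": small_truth.sequence})
        imbalance = ds.compute_imbalance(table)
        pooled = (
            table.groupby(["context", "read"])[["error", "total"]]
            .sum()
            .assign(rate=lambda d: d["error"] / d["total"])
        )
        # fully + partially methylated regions average to ~0.5 methylation
        cpg_gap = pooled.loc[("CpG", 1), "rate"] - pooled.loc[("CpG", 2), "rate"]
        truth_mean = float(
            np.mean([m.mean() for m in small_truth.site_methylated.values()])
        )
        expected = small_truth.config.deamination_rate * truth_mean
        assert cpg_gap == pytest.approx(expected, rel=0.35)
        cpa_gap = pooled.loc[("CpA", 1), "rate"] - pooled.loc[("CpA", 2), "rate"]
        assert abs(cpa_gap) < 1e-3
        assert not imbalance.empty
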