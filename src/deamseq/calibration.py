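"""Two-point calibration and regional aggregated methylation levels (RAML).

The transition rate of a region interpolates linearly between two internal
anchors measured in the same sequencing run: R0, the background C->T rate
at unmethylated cytosines (non-CpG sites of stably hypermethylated control
regions), and R100, the rate at fully methylated CpG sites in those same
controls, adjusted by each control's true mean methylation WM so that
imperfectly methylated controls do not bias the anchor downward. A region
with pooled counts (Error, Total) is then estimated as

    Meth = clamp_[0,1]( (Error - Total*R0) / ((R100 - R0) * Total) ).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .counting import RegionTransitionCount
from .regions import GenomicRegion

logger = logging.getLogger(__name__)

#: Regions with fewer combined CpG sites than this are flagged
#: low-confidence: with a ~1% deamination rate, fewer sites leave too few
#: expected events to pin the regional level down.
MIN_RELIABLE_SITES = 100


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationConstants:
    """Background (r0) and fully-methylated (r100) transition-rate anchors."""

    r0: float
    r100: float

    def __post_init__(self) -> None:
        if not (0 <= self.r0 < self.r100 <= 1):
            raise CalibrationError(
                f"require 0 <= R0 < R100 <= 1, got R0={self.r0}, R100={self.r100}"
            )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump({"r0": self.r0, "r100": self.r100}, handle, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationConstants":
        with open(path) as handle:
            data = json.load(handle)
        return cls(data["r0"], data["r100"])


@dataclass
class RamlEstimate:
    """Clamped methylation estimate for one region, with a binomial SE."""

    region: GenomicRegion
    meth: float
    error: int
    total: int
    se: float
    clamped: bool = False
    low_confidence: bool = False


def estimate_r0(counts: Iterable[RegionTransitionCount]) -> float:
    """Pooled background rate over non-CpG cytosine observations."""
    error = total = 0
    for count in counts:
        error += count.error
        total += count.total
    if total == 0:
        raise CalibrationError("no non-CpG observations to estimate R0 from")
    return error / total


def estimate_r100(
    counts: Sequence[RegionTransitionCount], wm: Sequence[float]
) -> float:
    """WM-adjusted fully-methylated rate from control-region CpG counts.

    R100 = (sum_n Error_n / WM_n) / (sum_n Total_n). Dividing each control's
    transition count by its true methylation scales the observed events up
    to what a perfectly methylated region would have produced.
    """
    if len(counts) != len(wm):
        raise CalibrationError("one WM value per control region required")
    adj_error = 0.0
    total = 0
    for count, w in zip(counts, wm):
        if not (0 < w <= 1):
            logger.warning(
                "control region %s has WM=%s outside (0,1]; excluded",
                count.region.name, w,
            )
            continue
        adj_error += count.error / w
        total += count.total
    if total == 0:
        raise CalibrationError("no usable control regions for R100")
    return adj_error / total


def fold_increase(cal: CalibrationConstants) -> float:
    """Signal-to-noise ratio R100/R0; infinite when the background is zero."""
    if cal.r0 == 0:
        return math.inf
    return cal.r100 / cal.r0


def estimate_raml(
    count: RegionTransitionCount,
    cal: CalibrationConstants,
    min_sites: int = MIN_RELIABLE_SITES,
) -> RamlEstimate:
    """Convert a region's pooled counts into a methylation level in [0, 1].

    The raw linear inversion can leave [0, 1] through sampling noise; it is
    clamped and flagged. The standard error propagates the binomial noise
    of the observed rate through the calibration:
    se = sqrt(R(1-R)/Total) / (R100 - R0).
    """
    if count.total == 0:
        raise ValueError(f"region {count.region.name} has no coverage")
    rate = count.error / count.total
    raw = (rate - cal.r0) / (cal.r100 - cal.r0)
    meth = min(1.0, max(0.0, raw))
    se = math.sqrt(rate * (1 - rate) / count.total) / (cal.r100 - cal.r0)
    return RamlEstimate(
        region=count.region,
        meth=meth,
        error=count.error,
        total=count.total,
        se=se,
        clamped=raw != meth,
        low_confidence=0 < count.n_sites < min_sites,
    )


def calibrate(
    control_cpg: Sequence[RegionTransitionCount],
    control_noncpg: Iterable[RegionTransitionCount],
    wm: Sequence[float],
) -> CalibrationConstants:
    """Run both anchor estimates and package them as calibration constants."""
    return CalibrationConstants(
        r0=estimate_r0(control_noncpg),
        r100=estimate_r100(control_cpg, wm),
    )
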