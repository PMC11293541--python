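"""Consensus methylation across technologies and the rate-vs-methylation fit.

Per-region methylation calls from three independent technologies (typically
WGBS, EM-seq and Nanopore) are integrated into a benchmarked level BM_n:
the two measurements that agree best are averaged, weighted by each
method's relative coverage of the region. Regions are then binned by BM,
transition counts pooled per bin, and the pooled rate regressed on the bin
mean methylation — the linear fit whose two endpoints (background rate and
fully-methylated rate) later calibrate methylation estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .counting import RegionTransitionCount

logger = logging.getLogger(__name__)

#: Default per-method minimum CpG coverage for a region to enter the
#: benchmark (WGBS, EM-seq, Nanopore).
DEFAULT_MIN_COVERAGE = (50, 50, 20)


def filter_by_coverage(
    coverage: pd.DataFrame, min_coverage: Sequence[int] = DEFAULT_MIN_COVERAGE
) -> pd.Index:
    """Regions whose coverage meets each method's minimum."""
    if coverage.shape[1] != len(min_coverage):
        raise ValueError("one minimum per method required")
    keep = (coverage >= np.asarray(min_coverage)).all(axis=1)
    return coverage.index[keep]


def method_weights(coverage: pd.DataFrame) -> pd.DataFrame:
    """Per-region method weights W from CpG coverages C.

    Coverage is first normalised within each method across regions
    (P_{n,i} = C_{n,i} / sum_m C_{m,i}), removing between-method depth
    differences, then each region's proportions are renormalised to sum to
    one. Scale-invariant in C.
    """
    column_sums = coverage.sum(axis=0)
    if (column_sums <= 0).any():
        raise ValueError("every method needs at least one region with positive coverage")
    proportions = coverage / column_sums
    row_sums = proportions.sum(axis=1)
    zero_rows = row_sums == 0
    if zero_rows.any():
        logger.warning("excluding %d regions with all-zero coverage", int(zero_rows.sum()))
        proportions = proportions.loc[~zero_rows]
        row_sums = row_sums.loc[~zero_rows]
    return proportions.div(row_sums, axis=0)


@dataclass(frozen=True)
class RegionBenchmark:
    region: object
    pair: tuple[int, int]  # column indices of the two closest measurements
    bm: float


def benchmark_methylation(
    methylation: pd.DataFrame, weights: pd.DataFrame
) -> pd.DataFrame:
    """Benchmarked methylation BM per region from three method calls.

    The closest pair (i, j) = argmin |M_i - M_j| is chosen per region and
    averaged with the region's method weights:
    BM = (W_i M_i + W_j M_j) / (W_i + W_j). Ties in the argmin go to the
    pair with the larger combined weight, which is deterministic.

    Returns a frame indexed like `methylation` (restricted to rows present
    in `weights`) with columns pair_i, pair_j, bm.
    """
    if methylation.shape[1] != 3:
        raise ValueError("exactly three methods expected")
    common = methylation.index.intersection(weights.index)
    meth = methylation.loc[common].to_numpy(dtype=float)
    wts = weights.loc[common].to_numpy(dtype=float)
    if ((meth < 0) | (meth > 1)).any():
        raise ValueError("methylation values must lie in [0, 1]")

    pairs = list(combinations(range(3), 2))
    records = []
    for n in range(meth.shape[0]):
        best, best_gap, best_weight = None, np.inf, -np.inf
        for i, j in pairs:
            gap = abs(meth[n, i] - meth[n, j])
            weight = wts[n, i] + wts[n, j]
            if gap < best_gap or (gap == best_gap and weight > best_weight):
                best, best_gap, best_weight = (i, j), gap, weight
        i, j = best
        denom = wts[n, i] + wts[n, j]
        bm = (wts[n, i] * meth[n, i] + wts[n, j] * meth[n, j]) / denom
        records.append({"pair_i": i, "pair_j": j, "bm": bm})
    return pd.DataFrame(records, index=common)


def bin_and_pool(
    bm: pd.Series,
    counts: Iterable[RegionTransitionCount] | pd.DataFrame,
    n_bin: int = 10,
) -> pd.DataFrame:
    """Equal-width methylation bins with count-pooled transition rates.

    Region n falls in bin k when BM_n is in [(k-1)/n_bin, k/n_bin), the last
    bin closed at 1.0 so fully methylated regions are kept. The bin rate
    R_k pools raw counts, sum(Error)/sum(Total) — not the mean of
    per-region rates, so deeply covered regions weigh more. ABM_k is the
    mean BM of the bin's members. Empty bins are reported with zero counts
    and NaN rate.
    """
    if isinstance(counts, pd.DataFrame):
        count_df = counts[["error", "total"]]
    else:
        count_df = pd.DataFrame(
            {"error": [c.error for c in counts], "total": [c.total for c in counts]},
            index=[c.region.name for c in counts],
        )
    common = bm.index.intersection(count_df.index)
    bm = bm.loc[common]
    count_df = count_df.loc[common]

    k = np.minimum(np.floor(bm.to_numpy() * n_bin).astype(int) + 1, n_bin)
    rows = []
    for b in range(1, n_bin + 1):
        members = k == b
        error = int(count_df["error"].to_numpy()[members].sum())
        total = int(count_df["total"].to_numpy()[members].sum())
        rows.append(
            {
                "bin": b,
                "lb": (b - 1) / n_bin,
                "ub": b / n_bin,
                "n_regions": int(members.sum()),
                "abm": float(bm.to_numpy()[members].mean()) if members.any() else np.nan,
                "error": error,
                "total": total,
                "rate": error / total if total > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("bin")


@dataclass
class RegressionFit:
    """OLS fit of pooled bin transition rate on bin mean methylation."""

    intercept: float
    slope: float
    r_squared: float
    pvalue_slope: float
    pvalue_intercept: float
    residuals: np.ndarray

    def summary(self) -> str:
        return (
            f"rate = {self.intercept:.3e} + {self.slope:.3e} * methylation"
            f"  (R^2 = {self.r_squared:.4f}, slope p = {self.pvalue_slope:.2e})"
        )


def fit_linear_model(bins: pd.DataFrame, min_bins: int = 3) -> RegressionFit:
    """Ordinary least squares of R_k on ABM_k over non-empty bins."""
    usable = bins.dropna(subset=["abm", "rate"])
    if len(usable) < min_bins:
        raise ValueError(f"need at least {min_bins} non-empty bins, have {len(usable)}")
    y = usable["rate"].to_numpy()
    x = sm.add_constant(usable["abm"].to_numpy())
    model = sm.OLS(y, x).fit()
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    # a flat response has no variance to explain; define R^2 = 0 there
    r_squared = float(model.rsquared) if ss_tot > 1e-30 else 0.0
    if not np.isfinite(r_squared):
        r_squared = 0.0
    return RegressionFit(
        intercept=float(model.params[0]),
        slope=float(model.params[1]),
        r_squared=r_squared,
        pvalue_slope=float(model.pvalues[1]),
        pvalue_intercept=float(model.pvalues[0]),
        residuals=np.asarray(model.resid),
    )


def quadrant_consistency(
    x: Sequence[float], y: Sequence[float], cuts: tuple[float, float] = (0.3, 0.7)
) -> float:
    """Fraction of regions placed in the same methylation stratum by x and y.

    Both axes are split into low / intermediate / high at `cuts` (nine cells
    in total); a region is consistent when it lands in the diagonal cell.
    The default cuts follow the common <30% hypomethylation convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("x and y must be equal-length, non-empty")
    if not (0 < cuts[0] < cuts[1] < 1):
        raise ValueError("cuts must be strictly increasing inside (0, 1)")
    edges = np.asarray(cuts)
    return float(np.mean(np.digitize(x, edges) == np.digitize(y, edges)))


def compare_methods(
    x: Sequence[float], y: Sequence[float], cuts: tuple[float, float] = (0.3, 0.7)
) -> dict[str, float]:
    """Quadrant consistency plus Pearson correlation between two call sets."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return {
        "quadrant_consistency": quadrant_consistency(x, y, cuts),
        "pearson_r": float(np.corrcoef(x, y)[0, 1]),
    }
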