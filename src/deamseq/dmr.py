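"""Differential methylation between two conditions with a +/-10% margin.

Replicate methylation estimates are pooled per region by the same
closest-pair weighted average used for cross-technology benchmarking; the
two conditions are then compared with a one-sided two-proportion z-test
against a practical-difference margin delta (default 0.1): a region is
called differential only when the difference exceeds delta with
statistical confidence, not merely when it is nonzero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .benchmark import method_weights

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupSummary:
    """Pooled methylation and coverage for one condition at one region."""

    label: str
    bm: float
    total: int

    def __post_init__(self) -> None:
        if not (0 <= self.bm <= 1):
            raise ValueError("BM must lie in [0, 1]")
        if self.total < 0:
            raise ValueError("Total must be non-negative")


@dataclass
class DmrTestResult:
    region: object
    mean_bm: float
    z_greater: float
    z_less: float
    p_greater: float
    p_less: float
    p: float
    delta: float
    called: bool
    undefined: bool = False


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    not_evaluated: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn + self.not_evaluated


def pool_replicates(
    meth: pd.DataFrame, totals: pd.DataFrame
) -> pd.DataFrame:
    """Pool per-region replicate estimates into (BM, Total) per region.

    For each region the two closest of the three replicate estimates are
    kept and averaged with the coverage-derived replicate weights; Total is
    the sum of the chosen pair's totals. Ties in the closest-pair argmin go
    to the pair containing the replicate with the largest Total. With two
    replicates both are used; with one it is passed through with a warning.
    """
    n_reps = meth.shape[1]
    if n_reps == 1:
        logger.warning("single replicate: pooling is a pass-through")
        return pd.DataFrame(
            {"bm": meth.iloc[:, 0], "total": totals.iloc[:, 0]}, index=meth.index
        )
    weights = method_weights(totals)
    meth = meth.loc[weights.index]
    totals = totals.loc[weights.index]
    m = meth.to_numpy(dtype=float)
    t = totals.to_numpy()
    w = weights.to_numpy()

    from itertools import combinations

    pairs = list(combinations(range(n_reps), 2))
    bm_out = np.empty(len(meth))
    total_out = np.empty(len(meth), dtype=np.int64)
    for n in range(len(meth)):
        best, best_gap, best_max_total = None, np.inf, -1
        for i, j in pairs:
            gap = abs(m[n, i] - m[n, j])
            max_total = max(t[n, i], t[n, j])
            if gap < best_gap or (gap == best_gap and max_total > best_max_total):
                best, best_gap, best_max_total = (i, j), gap, max_total
        i, j = best
        bm_out[n] = (w[n, i] * m[n, i] + w[n, j] * m[n, j]) / (w[n, i] + w[n, j])
        total_out[n] = t[n, i] + t[n, j]
    return pd.DataFrame({"bm": bm_out, "total": total_out}, index=meth.index)


def mean_bm(a: GroupSummary, b: GroupSummary) -> float:
    """Coverage-weighted mean methylation of the two conditions."""
    denom = a.total + b.total
    if denom == 0:
        raise ValueError("both conditions have zero coverage")
    return (a.bm * a.total + b.bm * b.total) / denom


def dmr_z_test(
    a: GroupSummary,
    b: GroupSummary,
    delta: float = 0.1,
    alpha: float = 0.05,
    region: object = None,
) -> DmrTestResult:
    """One-sided two-proportion z-test for |methylation difference| > delta.

    z> tests whether condition a exceeds b by more than delta, z< the
    reverse; the reported one-sided p is min(P>, P<) with
    P> = 1 - Phi(z>) and P< = Phi(z<). The pooled variance uses the
    coverage-weighted mean methylation, se = sqrt(MeanBM(1-MeanBM)
    (1/Total_a + 1/Total_b)). Regions with MeanBM of exactly 0 or 1 have
    zero variance and are returned flagged undefined instead of tested.
    """
    if a.total == 0 or b.total == 0:
        raise ValueError("both conditions need positive coverage")
    mbm = mean_bm(a, b)
    if mbm in (0.0, 1.0):
        return DmrTestResult(
            region=region, mean_bm=mbm, z_greater=math.nan, z_less=math.nan,
            p_greater=math.nan, p_less=math.nan, p=math.nan, delta=delta,
            called=False, undefined=True,
        )
    se = math.sqrt(mbm * (1 - mbm) * (1 / a.total + 1 / b.total))
    z_greater = (a.bm - (b.bm + delta)) / se
    z_less = (a.bm - (b.bm - delta)) / se
    p_greater = float(1 - norm.cdf(z_greater))
    p_less = float(norm.cdf(z_less))
    p = min(p_greater, p_less)
    return DmrTestResult(
        region=region, mean_bm=mbm, z_greater=z_greater, z_less=z_less,
        p_greater=p_greater, p_less=p_less, p=p, delta=delta, called=p < alpha,
    )


def dmr_table(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    delta: float = 0.1,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Region-wise z-tests for two pooled condition tables (bm, total).

    An optional Benjamini-Hochberg correction can replace the raw p-value
    threshold; it is off by default.
    """
    common = group_a.index.intersection(group_b.index)
    results = []
    for name in common:
        a = GroupSummary("a", group_a.loc[name, "bm"], int(group_a.loc[name, "total"]))
        b = GroupSummary("b", group_b.loc[name, "bm"], int(group_b.loc[name, "total"]))
        r = dmr_z_test(a, b, delta=delta, alpha=alpha, region=name)
        results.append(
            {
                "region": name, "mean_bm": r.mean_bm,
                "z_greater": r.z_greater, "z_less": r.z_less,
                "p": r.p, "called": r.called, "undefined": r.undefined,
            }
        )
    table = pd.DataFrame(results).set_index("region")
    if fdr and len(table):
        ok = ~table["undefined"]
        rejected = np.zeros(len(table), dtype=bool)
        if ok.any():
            rejected[ok.to_numpy()] = multipletests(
                table.loc[ok, "p"], alpha=alpha, method="fdr_bh"
            )[0]
        table["called"] = rejected
    return table


def classify_confusion(
    calls: Mapping[object, bool] | pd.Series,
    reference: Mapping[object, bool] | pd.Series,
    evaluable: Mapping[object, bool] | pd.Series | None = None,
) -> ConfusionCounts:
    """Score calls against a reference label set over evaluable regions.

    Regions failing the evaluable filter (for instance, reference
    differences below the margin) are tallied separately rather than
    forced into the 2x2 table. Region identifiers must match exactly.
    """
    calls = pd.Series(calls)
    reference = pd.Series(reference)
    missing = calls.index.symmetric_difference(reference.index)
    if len(missing):
        raise ValueError(f"unmatched region identifiers: {sorted(missing)[:10]}")
    counts = ConfusionCounts()
    for name in calls.index:
        if evaluable is not None and not bool(pd.Series(evaluable).get(name, True)):
            counts.not_evaluated += 1
            continue
        call, ref = bool(calls[name]), bool(reference[name])
        if call and ref:
            counts.tp += 1
        elif call and not ref:
            counts.fp += 1
        elif not call and ref:
            counts.fn += 1
        else:
            counts.tn += 1
    return counts
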