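"""Tab-separated tables exchanged between pipeline stages."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .calibration import RamlEstimate
from .counting import RegionTransitionCount
from .regions import GenomicRegion

COUNTS_COLUMNS = ["chrom", "start", "end", "name", "error", "total", "n_sites", "rate"]


def write_counts_tsv(counts: Iterable[RegionTransitionCount], path: str | Path) -> None:
    rows = [
        {
            "chrom": c.region.chrom, "start": c.region.start, "end": c.region.end,
            "name": c.region.name, "error": c.error, "total": c.total,
            "n_sites": c.n_sites, "rate": c.rate,
        }
        for c in counts
    ]
    pd.DataFrame(rows, columns=COUNTS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path, kind: str = "custom") -> list[RegionTransitionCount]:
    frame = pd.read_csv(path, sep="\t")
    return [
        RegionTransitionCount(
            GenomicRegion(row["chrom"], int(row["start"]), int(row["end"]),
                          str(row["name"]), kind),
            int(row["error"]), int(row["total"]), int(row.get("n_sites", 0)),
        )
        for _, row in frame.iterrows()
    ]


def read_methylation_tsv(path: str | Path) -> pd.DataFrame:
    """Per-region comparator table: name, methylation, CpG coverage."""
    frame = pd.read_csv(path, sep="\t")
    required = {"name", "methylation", "coverage"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return frame.set_index("name")


def read_controls_tsv(path: str | Path) -> pd.DataFrame:
    """Control-region table: chrom, start, end, name, wm."""
    frame = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "name", "wm"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return frame.set_index("name")


def write_raml_tsv(estimates: Iterable[RamlEstimate], path: str | Path) -> None:
    rows = [
        {
            "chrom": e.region.chrom, "start": e.region.start, "end": e.region.end,
            "name": e.region.name, "error": e.error, "total": e.total,
            "meth": e.meth, "se": e.se, "clamped": e.clamped,
            "low_confidence": e.low_confidence,
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_raml_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("name")


def read_reference_dmr_tsv(path: str | Path) -> pd.Series:
    """Reference DMR label set: name, is_dmr (boolean)."""
    frame = pd.read_csv(path, sep="\t")
    if not {"name", "is_dmr"}.issubset(frame.columns):
        raise ValueError(f"{path}: expected columns ['name', 'is_dmr']")
    return frame.set_index("name")["is_dmr"].astype(bool)
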