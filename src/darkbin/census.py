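"""Single-copy-marker completeness/contamination census and quality gate.

A single-copy marker gene is expected exactly once per genome. For a bin,
completeness is estimated as the percentage of a fixed marker set (105
bacterial markers by default) found at least once among the bin's contigs,
and contamination as the percentage of the same set found in more than one
copy. Both use the full marker-set size as denominator and are reported to
one decimal (half away from zero). Bins pass the quality gate when
completeness exceeds 60% and contamination is below 10% (strict
inequalities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

DEFAULT_MARKER_SET_SIZE = 105
DEFAULT_MIN_COMPLETENESS = 60.0
DEFAULT_MAX_CONTAMINATION = 10.0

__all__ = [
    "DEFAULT_MARKER_SET_SIZE",
    "MarkerCensus",
    "default_marker_set",
    "census",
    "quality_gate",
    "census_table",
    "read_hits",
    "read_marker_set",
    "write_marker_set",
    "write_census",
    "read_census",
]


def round1(x: float) -> float:
    """Round to one decimal, half away from zero (presentation convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def default_marker_set(n: int = DEFAULT_MARKER_SET_SIZE) -> list[str]:
    """Placeholder ids standing in for the 105 bacterial single-copy markers."""
    return [f"M{i:03d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class MarkerCensus:
    bin_id: str
    marker_set_size: int
    present: int
    multi_copy: int
    completeness_pct: float
    contamination_pct: float

    def __post_init__(self):
        if not 0 <= self.multi_copy <= self.present <= self.marker_set_size:
            raise ValueError(
                f"bin {self.bin_id!r}: need 0 <= multi_copy <= present <= set size, "
                f"got {self.multi_copy}/{self.present}/{self.marker_set_size}"
            )


def census(
    bin_contigs: Iterable[str],
    hits: pd.DataFrame,
    marker_set: Iterable[str],
    bin_id: str = "bin",
) -> MarkerCensus:
    """Count distinct and multi-copy markers among a bin's contigs.

    ``hits`` has one row per marker hit with columns ``contig_id`` and
    ``marker_id``; two hits of the same marker within the bin (on the same
    contig or different contigs) make it multi-copy. Hits naming markers
    outside the marker set are ignored with a warning.
    """
    marker_set = list(marker_set)
    if not marker_set:
        raise ValueError("marker set must be non-empty")
    known = set(marker_set)
    contigs = set(bin_contigs)
    sub = hits[hits["contig_id"].isin(contigs)]
    unknown = set(sub["marker_id"]) - known
    if unknown:
        warnings.warn(
            f"ignoring hits for {len(unknown)} marker(s) outside the marker set: "
            f"{sorted(unknown)[:5]}..."
        )
        sub = sub[sub["marker_id"].isin(known)]
    counts = sub["marker_id"].value_counts()
    present = int((counts >= 1).sum())
    multi = int((counts >= 2).sum())
    size = len(marker_set)
    return MarkerCensus(
        bin_id=bin_id,
        marker_set_size=size,
        present=present,
        multi_copy=multi,
        completeness_pct=round1(100.0 * present / size),
        contamination_pct=round1(100.0 * multi / size),
    )


def quality_gate(
    c: MarkerCensus,
    min_completeness: float = DEFAULT_MIN_COMPLETENESS,
    max_contamination: float = DEFAULT_MAX_CONTAMINATION,
) -> bool:
    """Pass iff completeness > min AND contamination < max (both strict)."""
    return (
        c.completeness_pct > min_completeness
        and c.contamination_pct < max_contamination
    )


def census_table(
    bins: Mapping[str, Iterable[str]],
    hits: pd.DataFrame,
    marker_set: Iterable[str],
    min_completeness: float = DEFAULT_MIN_COMPLETENESS,
    max_contamination: float = DEFAULT_MAX_CONTAMINATION,
) -> pd.DataFrame:
    """One census row per bin, sorted by bin id, with the gate verdict.

    ``bins`` maps bin_id -> contig ids. Duplicate bin ids are an error.
    """
    bin_ids = list(bins)
    if len(set(bin_ids)) != len(bin_ids):
        raise ValueError("duplicate bin ids")
    marker_set = list(marker_set)
    rows = []
    for bin_id in sorted(bin_ids):
        c = census(bins[bin_id], hits, marker_set, bin_id=bin_id)
        rows.append(
            {
                "bin_id": c.bin_id,
                "present": c.present,
                "multi_copy": c.multi_copy,
                "completeness_pct": c.completeness_pct,
                "contamination_pct": c.contamination_pct,
                "gate": quality_gate(c, min_completeness, max_contamination),
            }
        )
    cols = ["bin_id", "present", "multi_copy", "completeness_pct", "contamination_pct", "gate"]
    return pd.DataFrame(rows, columns=cols)


def read_hits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"contig_id": str, "marker_id": str})


def read_marker_set(path: str | Path) -> list[str]:
    lines = Path(path).read_text().split()
    return [ln for ln in lines if ln]


def write_marker_set(marker_set: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(marker_set) + "\n")


def write_census(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_census(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"bin_id": str})
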