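"""Differential-coverage genome binning.

Contigs deriving from the same population genome rise and fall together in
read coverage across related samples of a community, while contigs from
different populations do not. This module groups contigs by that
covariation: per-contig coverage profiles are log-transformed and scaled to
unit norm (so only the *shape* of the profile matters, not sequencing
depth), projected onto the top three principal axes, and clustered by
single-linkage agglomeration at a fixed distance threshold. Clusters below
a minimum size are reported as unbinned, as are contigs with no coverage at
all. The whole chain is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

UNBINNED = "unbinned"

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_LINKAGE_DIST = 0.05
DEFAULT_MIN_BIN_SIZE = 5

__all__ = [
    "UNBINNED",
    "CoverageMatrix",
    "BinAssignment",
    "transform_coverage",
    "project_3d",
    "cluster_contigs",
    "bin_contigs",
    "binning_purity",
]


@dataclass(frozen=True)
class CoverageMatrix:
    """Contig x sample mean per-base coverage with contig lengths."""

    contig_ids: list[str]
    lengths: np.ndarray
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "lengths", np.asarray(self.lengths))
        if values.ndim != 2 or values.shape != (len(self.contig_ids), len(self.sample_ids)):
            raise ValueError("coverage shape does not match contig/sample ids")
        if len(self.sample_ids) < 1:
            raise ValueError("need at least 1 sample column")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("coverage values must be finite and non-negative")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CoverageMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"contig_id": str})
        samples = [c for c in df.columns if c not in ("contig_id", "length")]
        return cls(
            contig_ids=df["contig_id"].tolist(),
            lengths=df["length"].to_numpy(),
            sample_ids=samples,
            values=df[samples].to_numpy(dtype=float),
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.sample_ids)
        df.insert(0, "length", self.lengths)
        df.insert(0, "contig_id", self.contig_ids)
        df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class BinAssignment:
    """contig -> bin id (or 'unbinned') plus the 3-D embedding used."""

    contig_ids: list[str]
    bins: dict[str, str]
    embedding: np.ndarray

    def members(self) -> dict[str, list[str]]:
        """bin_id -> contig ids, excluding unbinned contigs."""
        out: dict[str, list[str]] = {}
        for cid in self.contig_ids:
            b = self.bins[cid]
            if b != UNBINNED:
                out.setdefault(b, []).append(cid)
        return out

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"contig_id": self.contig_ids, "bin_id": [self.bins[c] for c in self.contig_ids]}
        ).to_csv(path, sep="\t", index=False)


def transform_coverage(cov: CoverageMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """log10(coverage + pseudocount) per row, scaled to unit Euclidean norm.

    Rows of all-zero coverage map to the zero vector (they carry no
    differential signal and are flagged unbinned downstream).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logged = np.log10(cov.values + pseudocount)
    norms = np.linalg.norm(logged, axis=1)
    zero_rows = ~cov.values.any(axis=1)
    out = np.zeros_like(logged)
    ok = (~zero_rows) & (norms > 0)
    out[ok] = logged[ok] / norms[ok, None]
    return out


def project_3d(transformed: np.ndarray) -> np.ndarray:
    """Orthogonal projection onto the top-3 principal axes.

    The matrix is column-centered and decomposed by SVD; axes are ordered by
    decreasing variance, with the sign convention that the first nonzero
    loading of each axis is positive. Inputs with fewer than 3 columns are
    zero-padded, so the trailing coordinates are identically 0.
    """
    x = np.asarray(transformed, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if x.shape[1] < 3:
        x = np.hstack([x, np.zeros((x.shape[0], 3 - x.shape[1]))])
    centered = x - x.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    axes = vt[:3]
    # fix signs so the projection does not depend on SVD sign ambiguity
    for i, axis in enumerate(axes):
        nz = np.nonzero(np.abs(axis) > 1e-12)[0]
        if nz.size and axis[nz[0]] < 0:
            axes[i] = -axis
    scores = centered @ axes.T
    if scores.shape[1] < 3:
        scores = np.hstack([scores, np.zeros((scores.shape[0], 3 - scores.shape[1]))])
    return scores


def cluster_contigs(
    embedding: np.ndarray,
    contig_ids: list[str],
    min_bin_size: int = DEFAULT_MIN_BIN_SIZE,
    linkage_dist: float = DEFAULT_LINKAGE_DIST,
    unbinnable: Iterable[str] = (),
) -> BinAssignment:
    """Single-linkage agglomeration at a fixed distance threshold.

    Contigs named in ``unbinnable`` (e.g. zero-coverage rows) are excluded
    up front. Clusters smaller than ``min_bin_size`` are reported unbinned.
    Deterministic given input ordering; bin ids are assigned in order of
    first member appearance.
    """
    if min_bin_size < 1:
        raise ValueError("min_bin_size must be >= 1")
    if linkage_dist <= 0:
        raise ValueError("linkage_dist must be positive")
    embedding = np.asarray(embedding, dtype=float)
    if not np.all(np.isfinite(embedding)):
        raise ValueError("embedding must be finite")
    unbinnable = set(unbinnable)
    bins = {cid: UNBINNED for cid in contig_ids}
    idx = [i for i, cid in enumerate(contig_ids) if cid not in unbinnable]
    if len(idx) == 1:
        labels = np.array([1])
    elif idx:
        z = linkage(pdist(embedding[idx]), method="single")
        labels = fcluster(z, t=linkage_dist, criterion="distance")
    else:
        labels = np.array([], dtype=int)
    sizes: dict[int, int] = {}
    for lab in labels:
        sizes[lab] = sizes.get(lab, 0) + 1
    next_bin, bin_names = 1, {}
    for pos, i in enumerate(idx):
        lab = labels[pos]
        if sizes[lab] < min_bin_size:
            continue
        if lab not in bin_names:
            bin_names[lab] = f"bin_{next_bin:03d}"
            next_bin += 1
        bins[contig_ids[i]] = bin_names[lab]
    return BinAssignment(contig_ids=list(contig_ids), bins=bins, embedding=embedding)


def bin_contigs(
    cov: CoverageMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_bin_size: int = DEFAULT_MIN_BIN_SIZE,
    linkage_dist: float = DEFAULT_LINKAGE_DIST,
) -> BinAssignment:
    """Full chain: transform -> project to 3-D -> single-linkage cluster."""
    transformed = transform_coverage(cov, pseudocount)
    embedding = project_3d(transformed)
    zero = [cid for cid, row in zip(cov.contig_ids, cov.values) if not row.any()]
    return cluster_contigs(
        embedding, cov.contig_ids, min_bin_size=min_bin_size,
        linkage_dist=linkage_dist, unbinnable=zero,
    )


def binning_purity(assign: BinAssignment, truth: Mapping[str, str]) -> pd.DataFrame:
    """Per-bin purity and recall against planted genome labels.

    Purity is the largest fraction of a bin deriving from a single genome;
    recall is the fraction of that genome's contigs captured by the bin.
    """
    missing = [c for c in assign.contig_ids if c not in truth]
    if missing:
        raise ValueError(f"truth labels missing for contigs: {missing[:5]}...")
    genome_sizes: dict[str, int] = {}
    for cid in assign.contig_ids:
        genome_sizes[truth[cid]] = genome_sizes.get(truth[cid], 0) + 1
    rows = []
    for bin_id, members in sorted(assign.members().items()):
        counts: dict[str, int] = {}
        for cid in members:
            counts[truth[cid]] = counts.get(truth[cid], 0) + 1
        dominant = max(sorted(counts), key=lambda g: counts[g])
        rows.append(
            {
                "bin_id": bin_id,
                "size": len(members),
                "dominant_genome": dominant,
                "purity": counts[dominant] / len(members),
                "recall": counts[dominant] / genome_sizes[dominant],
            }
        )
    cols = ["bin_id", "size", "dominant_genome", "purity", "recall"]
    return pd.DataFrame(rows, columns=cols)
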