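"""Distance-based phylogenetics over masked, concatenated marker alignments.

The pipeline's tree-building arm: per-marker alignments are masked by a gap
rule (a column may not be gapped in more than half of the sequences),
concatenated into a supermatrix with gap padding for genomes missing a
marker, converted to pairwise LogDet (paralinear) distances, and resolved
with neighbor joining. Branch robustness is assessed by bootstrap
resampling of supermatrix columns, and named groups are tested for
monophyly on the resulting tree.

LogDet is used because it remains consistent under base-composition drift
between lineages: with ``F`` the 4x4 joint relative-frequency matrix of the
two sequences over shared unambiguous columns and ``f_x``, ``f_y`` their
marginal base frequencies,

    d = -(1/4) * [ ln det F - (1/2) * sum_k ln(f_x[k] * f_y[k]) ].

Amino-acid supermatrices fall back to a gap-excluded normalized mismatch
distance (flagged in the distance matrix); the LogDet form here is the
4-state nucleotide one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .trees import bipartitions, canonical_split, is_monophyletic

GAP_CHARS = "-."
NT_CANON = "ACGT"
AA_CANON = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_MAX_GAP_FRACTION = 0.5
DEFAULT_BOOTSTRAP_REPLICATES = 100

_NT_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(NT_CANON):
    _NT_CODE[ord(_c)] = _i
    _NT_CODE[ord(_c.lower())] = _i
_NT_CODE[ord("U")] = _NT_CODE[ord("u")] = _NT_CODE[ord("T")]

__all__ = [
    "AlignmentBlock",
    "Supermatrix",
    "DistanceMatrix",
    "SaturatedDistanceError",
    "mask_alignment",
    "concatenate",
    "logdet_distance",
    "mismatch_distance",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "BootstrapResult",
    "is_monophyletic",
    "read_fasta_alignment",
    "write_fasta_alignment",
]


class SaturatedDistanceError(ValueError):
    """Raised when a distance matrix contains saturated (undefined) pairs."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        super().__init__(
            f"saturated LogDet distance for {len(self.pairs)} pair(s): "
            f"{self.pairs[:5]}"
        )


@dataclass(frozen=True)
class AlignmentBlock:
    """One marker's alignment: genome_id -> equal-length row."""

    marker_id: str
    sequences: dict[str, str]

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"block {self.marker_id!r}: unequal row lengths {lengths}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def genome_ids(self) -> list[str]:
        return list(self.sequences)


@dataclass(frozen=True)
class Supermatrix:
    """Column-wise concatenation of masked blocks, gap-padded per genome.

    ``block_map`` records each block's half-open 0-based column span.
    """

    sequences: dict[str, str]
    block_map: dict[str, tuple[int, int]]

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def genome_ids(self) -> list[str]:
        return list(self.sequences)


@dataclass(frozen=True)
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    method: str = "logdet"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", index_label="label"
        )


def _is_nucleotide(block: AlignmentBlock) -> bool:
    chars = [c for s in block.sequences.values() for c in s.upper() if c not in GAP_CHARS]
    if not chars:
        return True
    frac = sum(c in "ACGTUN" for c in chars) / len(chars)
    return frac >= 0.95


def mask_alignment(
    block: AlignmentBlock,
    max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
    molecule: str = "auto",
) -> AlignmentBlock:
    """Drop over-gapped and all-ambiguous columns, preserving column order.

    A column is removed when its gap fraction strictly exceeds
    ``max_gap_fraction`` (so a column gapped in exactly half of the
    sequences is retained) or when every non-gap character in it is an
    ambiguity code.
    """
    if molecule == "auto":
        molecule = "nt" if _is_nucleotide(block) else "aa"
    canon = NT_CANON if molecule == "nt" else AA_CANON
    ids = list(block.sequences)
    rows = [block.sequences[g].upper() for g in ids]
    n = len(rows)
    keep = []
    for j in range(block.length):
        col = [r[j] for r in rows]
        gaps = sum(c in GAP_CHARS for c in col)
        if n and gaps / n > max_gap_fraction:
            continue
        nongap = [c for c in col if c not in GAP_CHARS]
        if not nongap or all(c not in canon for c in nongap):
            continue
        keep.append(j)
    if not keep:
        warnings.warn(f"block {block.marker_id!r}: masking removed every column")
    masked = {g: "".join(row[j] for j in keep) for g, row in zip(ids, rows)}
    return AlignmentBlock(marker_id=block.marker_id, sequences=masked)


def concatenate(blocks: Sequence[AlignmentBlock], genome_universe: Sequence[str]) -> Supermatrix:
    """Concatenate masked blocks over a genome universe with gap padding."""
    if not blocks:
        raise ValueError("cannot concatenate an empty block list")
    ids = [b.marker_id for b in blocks]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate marker ids in blocks")
    genome_universe = list(genome_universe)
    parts: dict[str, list[str]] = {g: [] for g in genome_universe}
    block_map: dict[str, tuple[int, int]] = {}
    offset = 0
    for block in blocks:
        span = block.length
        block_map[block.marker_id] = (offset, offset + span)
        for g in genome_universe:
            parts[g].append(block.sequences.get(g, "-" * span))
        offset += span
    return Supermatrix(
        sequences={g: "".join(parts[g]) for g in genome_universe},
        block_map=block_map,
    )


def encode_nt(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3 (case-insensitive, U as T); gaps and ambiguity -> -1."""
    return _NT_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _logdet_from_codes(x: np.ndarray, y: np.ndarray) -> float:
    ok = (x >= 0) & (y >= 0)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no shared unambiguous, ungapped columns")
    joint = np.bincount(x[ok] * 4 + y[ok], minlength=16).reshape(4, 4).astype(float)
    f = joint / n
    fx = f.sum(axis=1)
    fy = f.sum(axis=0)
    if np.any(fx <= 0) or np.any(fy <= 0):
        return float("nan")
    det = np.linalg.det(f)
    if det <= 0:
        return float("nan")
    d = -0.25 * (np.log(det) - 0.5 * (np.sum(np.log(fx)) + np.sum(np.log(fy))))
    return float(d) if d > 0 else 0.0


def logdet_distance(x: str, y: str) -> float:
    """Paralinear distance between two aligned nucleotide sequences.

    Only columns unambiguous and ungapped in both sequences are used.
    Returns NaN for a saturated pair (non-positive joint determinant or a
    missing base in either marginal); raises if no usable columns remain.
    """
    if len(x) != len(y):
        raise ValueError("sequences must have equal length")
    return _logdet_from_codes(encode_nt(x), encode_nt(y))


def mismatch_distance(x: str, y: str, canon: str = AA_CANON) -> float:
    """Normalized mismatch over columns canonical in both rows (aa fallback)."""
    if len(x) != len(y):
        raise ValueError("sequences must have equal length")
    canon_set = set(canon)
    used = mis = 0
    for a, b in zip(x.upper(), y.upper()):
        if a in canon_set and b in canon_set:
            used += 1
            mis += a != b
    if used == 0:
        raise ValueError("no shared unambiguous, ungapped columns")
    return mis / used


def distance_matrix(
    sequences: Mapping[str, str] | Supermatrix,
    method: str = "logdet",
) -> DistanceMatrix:
    """Pairwise distances for a set of aligned sequences.

    With the LogDet method, a saturated pair anywhere fails the build with
    an error listing the offending pairs (a NaN entry would poison NJ).
    """
    if isinstance(sequences, Supermatrix):
        sequences = sequences.sequences
    labels = sorted(sequences)
    n = len(labels)
    d = np.zeros((n, n))
    saturated = []
    if method == "logdet":
        codes = {g: encode_nt(sequences[g]) for g in labels}
        for i in range(n):
            for j in range(i + 1, n):
                v = _logdet_from_codes(codes[labels[i]], codes[labels[j]])
                if np.isnan(v):
                    saturated.append((labels[i], labels[j]))
                d[i, j] = d[j, i] = v
    elif method == "mismatch":
        for i in range(n):
            for j in range(i + 1, n):
                v = mismatch_distance(sequences[labels[i]], sequences[labels[j]])
                d[i, j] = d[j, i] = v
    else:
        raise ValueError(f"unknown distance method {method!r}")
    if saturated:
        raise SaturatedDistanceError(saturated)
    return DistanceMatrix(labels=labels, values=d, method=method)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor joining with deterministic tie-breaking.

    The pair minimizing the Q criterion is joined at each step; ties are
    broken by the lexicographically smallest pair of cluster keys (a
    cluster's key is its smallest leaf label). Negative branch lengths are
    clamped to 0. The result is an unrooted tree with a trifurcating seed
    node.
    """
    labels = list(dm.labels)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    if np.any(np.isnan(dm.values)):
        raise ValueError("distance matrix contains NaN")
    tns = dendropy.TaxonNamespace()
    nodes = [dendropy.Node(taxon=tns.require_taxon(label=lab)) for lab in labels]
    keys = list(labels)
    d = dm.values.astype(float).copy()

    while len(keys) > 3:
        m = len(keys)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    key = tuple(sorted((keys[i], keys[j])))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = max(li, 0.0)
        nodes[j].edge.length = max(lj, 0.0)
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    root = dendropy.Node()
    (a, b, c) = (0, 1, 2)
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for k, lk in zip((a, b, c), (la, lb, lc)):
        root.add_child(nodes[k])
        nodes[k].edge.length = max(lk, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


@dataclass(frozen=True)
class BootstrapResult:
    tree: dendropy.Tree
    supports: dict[frozenset, int]  # internal split -> integer percent
    n_replicates: int
    n_skipped: int  # replicates dropped for a saturated distance


def bootstrap_support(
    sm: Supermatrix,
    n_replicates: int = DEFAULT_BOOTSTRAP_REPLICATES,
    seed: int = 0,
    method: str = "logdet",
) -> BootstrapResult:
    """Column-resampling bootstrap of the distance + NJ tree.

    Support for each internal bipartition of the original tree is the
    percentage of successful replicate trees containing it. Replicates in
    which a pair's distance saturates are skipped and counted in
    ``n_skipped``. Deterministic for a fixed seed.
    """
    labels = sorted(sm.sequences)
    if len(labels) < 4:
        raise ValueError("bootstrap needs at least 4 genomes")
    arr = np.stack([encode_nt(sm.sequences[g]) for g in labels])
    dm0 = distance_matrix(sm, method=method)
    tree0 = neighbor_joining(dm0)
    all_leaves = frozenset(labels)
    internal = [s for s in bipartitions(tree0) if 2 <= len(s) <= len(labels) - 2]
    counts = {s: 0 for s in internal}
    rng = np.random.default_rng(seed)
    n_ok = n_skipped = 0
    ncols = arr.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, ncols, size=ncols)
        rep = arr[:, cols]
        n = len(labels)
        d = np.zeros((n, n))
        try:
            if method == "logdet":
                for i in range(n):
                    for j in range(i + 1, n):
                        v = _logdet_from_codes(rep[i], rep[j])
                        if np.isnan(v):
                            raise SaturatedDistanceError([(labels[i], labels[j])])
                        d[i, j] = d[j, i] = v
            else:
                for i in range(n):
                    for j in range(i + 1, n):
                        ok = (rep[i] >= 0) & (rep[j] >= 0)
                        if not ok.any():
                            raise SaturatedDistanceError([(labels[i], labels[j])])
                        d[i, j] = d[j, i] = np.mean(rep[i][ok] != rep[j][ok])
        except SaturatedDistanceError:
            n_skipped += 1
            continue
        rep_tree = neighbor_joining(DistanceMatrix(labels=labels, values=d, method=method))
        rep_splits = set(bipartitions(rep_tree))
        n_ok += 1
        for s in internal:
            if s in rep_splits:
                counts[s] += 1
    supports = {
        s: int(round(100.0 * counts[s] / n_ok)) if n_ok else 0 for s in internal
    }
    return BootstrapResult(
        tree=tree0, supports=supports, n_replicates=n_replicates, n_skipped=n_skipped
    )


def annotate_support(tree: dendropy.Tree, supports: Mapping[frozenset, int]) -> dendropy.Tree:
    """Write integer support percentages onto matching internal-node labels."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = canonical_split(below, all_leaves)
        if key in supports:
            node.label = str(supports[key])
    return tree


def read_fasta_alignment(path: str | Path, marker_id: str | None = None) -> AlignmentBlock:
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return AlignmentBlock(marker_id=marker_id or Path(path).stem, sequences=seqs)


def write_fasta_alignment(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n{sequences[name]}\n")
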