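"""16S rRNA read-pair recruitment, concordance filtering, and greedy clustering.

rRNA genes co-assemble across populations and thereby acquire distorted
coverage, so they are recovered outside the binning stage: shotgun read
pairs matching a 16S model are mapped to a reference database, filtered by
alignment quality, and grouped by the phylogenetic proximity of their
reference assignments for independent per-cluster assembly.

Filters (defaults follow the recruitment protocol this module implements):

* a read is reliably mapped when at least 85% of it aligned to the
  reference and its edit distance is strictly less than 10% of the read
  length (e.g. less than 10 for a 100 bp read);
* a pair is concordant when its two mates' references lie within a
  patristic branch length of 0.03 of each other on the reference phylogeny.

Surviving pairs are clustered greedily: the unprocessed reference with the
most assigned pairs seeds a cluster absorbing every unprocessed reference
within the patristic radius, until all pairs are clustered. Clusters are
emitted as interleaved read sets for external assembly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .trees import patristic_distance, patristic_matrix

DEFAULT_MIN_ALIGNED_FRAC = 0.85
DEFAULT_MAX_EDIT_RATIO = 0.10
DEFAULT_RADIUS = 0.03

__all__ = [
    "DEFAULT_MIN_ALIGNED_FRAC",
    "DEFAULT_MAX_EDIT_RATIO",
    "DEFAULT_RADIUS",
    "ReadMapping",
    "ReadPairMapping",
    "RecruitCluster",
    "read_filter",
    "pair_concordance",
    "filter_pairs",
    "pairs_by_reference",
    "greedy_cluster",
    "emit_clusters",
    "lineage_abundance",
    "read_mappings",
    "write_mappings",
]


@dataclass(frozen=True)
class ReadMapping:
    """One read's best mapping to a reference sequence."""

    ref_id: str
    read_len: int
    aligned_frac: float
    edit_distance: int

    def __post_init__(self):
        if not 0.0 <= self.aligned_frac <= 1.0:
            raise ValueError(f"aligned_frac {self.aligned_frac} outside [0, 1]")
        if self.edit_distance < 0 or self.edit_distance > self.read_len:
            raise ValueError("edit_distance must be in [0, read_len]")


@dataclass(frozen=True)
class ReadPairMapping:
    pair_id: str
    read1: ReadMapping
    read2: ReadMapping


@dataclass(frozen=True)
class RecruitCluster:
    seed_ref: str
    member_refs: frozenset
    pair_ids: tuple
    n_pairs: int


def read_filter(
    m: ReadMapping,
    min_aligned_frac: float = DEFAULT_MIN_ALIGNED_FRAC,
    max_edit_ratio: float = DEFAULT_MAX_EDIT_RATIO,
) -> bool:
    """Pass iff aligned_frac >= min AND edit_distance < max_edit_ratio * len.

    The edit-distance bound is strict: a 100 bp read must have fewer than
    10 edits at the default ratio.
    """
    return (
        m.aligned_frac >= min_aligned_frac
        and m.edit_distance < max_edit_ratio * m.read_len
    )


def pair_concordance(
    p: ReadPairMapping,
    tree: dendropy.Tree,
    radius: float = DEFAULT_RADIUS,
    _pdm: tuple[dict, np.ndarray] | None = None,
) -> bool:
    """Pass iff the two mates' references are within the patristic radius.

    A reference absent from the tree removes the pair with a warning.
    """
    if _pdm is not None:
        index, d = _pdm
        a, b = p.read1.ref_id, p.read2.ref_id
        if a not in index or b not in index:
            warnings.warn(f"pair {p.pair_id}: reference absent from tree; pair removed")
            return False
        return d[index[a], index[b]] <= radius
    try:
        dist = patristic_distance(tree, p.read1.ref_id, p.read2.ref_id)
    except KeyError:
        warnings.warn(f"pair {p.pair_id}: reference absent from tree; pair removed")
        return False
    return dist <= radius


def filter_pairs(
    pairs: Sequence[ReadPairMapping],
    tree: dendropy.Tree,
    min_aligned_frac: float = DEFAULT_MIN_ALIGNED_FRAC,
    max_edit_ratio: float = DEFAULT_MAX_EDIT_RATIO,
    radius: float = DEFAULT_RADIUS,
) -> tuple[list[ReadPairMapping], dict[str, int]]:
    """Apply the read-quality and pair-concordance filters.

    Returns surviving pairs and a tally of removals by cause.
    """
    labels, d = patristic_matrix(tree)
    pdm = ({lab: i for i, lab in enumerate(labels)}, d)
    surviving = []
    stats = {"input": len(pairs), "failed_read_filter": 0, "failed_concordance": 0}
    for p in pairs:
        if not (
            read_filter(p.read1, min_aligned_frac, max_edit_ratio)
            and read_filter(p.read2, min_aligned_frac, max_edit_ratio)
        ):
            stats["failed_read_filter"] += 1
            continue
        if not pair_concordance(p, tree, radius, _pdm=pdm):
            stats["failed_concordance"] += 1
            continue
        surviving.append(p)
    stats["surviving"] = len(surviving)
    return surviving, stats


def pairs_by_reference(pairs: Iterable[ReadPairMapping]) -> dict[str, list[str]]:
    """Assign each pair to its first mate's reference for clustering."""
    out: dict[str, list[str]] = {}
    for p in pairs:
        out.setdefault(p.read1.ref_id, []).append(p.pair_id)
    return out


def greedy_cluster(
    assignments: Mapping[str, Sequence[str]] | Mapping[str, int],
    tree: dendropy.Tree,
    radius: float = DEFAULT_RADIUS,
) -> list[RecruitCluster]:
    """Greedy reference clustering by patristic proximity.

    Repeatedly seed on the unprocessed reference with the most assigned
    pairs (ties -> lexicographically smallest id), absorb every unprocessed
    reference within the patristic radius of the seed, and emit the
    cluster. The emitted clusters partition the assigned pairs.

    ``assignments`` maps reference id to either a list of pair ids or a
    bare pair count.
    """
    norm: dict[str, tuple] = {}
    for ref, v in assignments.items():
        if isinstance(v, int):
            norm[ref] = tuple(f"{ref}:pair{k}" for k in range(v))
        else:
            norm[ref] = tuple(v)
    labels, d = patristic_matrix(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    missing = sorted(set(norm) - set(index))
    if missing:
        warnings.warn(f"dropping references absent from tree: {missing}")
        for ref in missing:
            del norm[ref]
    remaining = set(norm)
    clusters: list[RecruitCluster] = []
    while remaining:
        seed = min(remaining, key=lambda r: (-len(norm[r]), r))
        members = {
            r for r in remaining if d[index[seed], index[r]] <= radius
        }
        pair_ids = tuple(sorted(pid for r in members for pid in norm[r]))
        clusters.append(
            RecruitCluster(
                seed_ref=seed,
                member_refs=frozenset(members),
                pair_ids=pair_ids,
                n_pairs=len(pair_ids),
            )
        )
        remaining -= members
    return clusters


def emit_clusters(
    clusters: Sequence[RecruitCluster],
    reads: Mapping[str, tuple[str, str]],
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write one interleaved FASTA per cluster plus a manifest TSV.

    ``reads`` maps pair_id -> (read1 sequence, read2 sequence). Cluster
    assembly itself is external; this prepares its inputs.
    """
    seen: set[str] = set()
    for cl in clusters:
        dup = seen & set(cl.pair_ids)
        if dup:
            raise ValueError(f"pair ids present in more than one cluster: {sorted(dup)[:5]}")
        seen.update(cl.pair_ids)
    missing = sorted(pid for pid in seen if pid not in reads)
    if missing:
        raise KeyError(f"reads missing for pair ids: {missing[:10]}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, cl in enumerate(clusters, start=1):
        name = f"cluster_{k:03d}"
        path = out_dir / f"{name}.fasta"
        with open(path, "w") as fh:
            for pid in cl.pair_ids:
                r1, r2 = reads[pid]
                fh.write(f">{pid}/1\n{r1}\n>{pid}/2\n{r2}\n")
        rows.append(
            {
                "cluster_id": name,
                "seed_ref": cl.seed_ref,
                "n_refs": len(cl.member_refs),
                "n_pairs": cl.n_pairs,
                "n_reads": 2 * cl.n_pairs,
                "fasta": path.name,
            }
        )
    cols = ["cluster_id", "seed_ref", "n_refs", "n_pairs", "n_reads", "fasta"]
    manifest = pd.DataFrame(rows, columns=cols)
    manifest.to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
    return manifest


def lineage_abundance(
    clusters: Sequence[RecruitCluster],
    ref_lineage: Mapping[str, str],
) -> dict[str, float]:
    """Fraction of surviving pairs per lineage, via each cluster's seed ref."""
    total = sum(cl.n_pairs for cl in clusters)
    if total == 0:
        warnings.warn("no surviving pairs; abundance undefined")
        return {}
    counts: dict[str, float] = {}
    for cl in clusters:
        lin = ref_lineage[cl.seed_ref]
        counts[lin] = counts.get(lin, 0) + cl.n_pairs
    return {lin: c / total for lin, c in sorted(counts.items())}


def read_mappings(path: str | Path) -> list[ReadPairMapping]:
    """Read the long-format mapping TSV (one row per read, two per pair)."""
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "ref_id": str})
    pairs = []
    for pid, grp in df.groupby("pair_id", sort=True):
        grp = grp.sort_values("read_index")
        if list(grp["read_index"]) != [1, 2]:
            raise ValueError(f"pair {pid}: expected read indices 1 and 2")
        reads = [
            ReadMapping(
                ref_id=row["ref_id"],
                read_len=int(row["read_len"]),
                aligned_frac=float(row["aligned_frac"]),
                edit_distance=int(row["edit_distance"]),
            )
            for _, row in grp.iterrows()
        ]
        pairs.append(ReadPairMapping(pair_id=pid, read1=reads[0], read2=reads[1]))
    return pairs


def write_mappings(pairs: Sequence[ReadPairMapping], path: str | Path) -> None:
    rows = []
    for p in pairs:
        for idx, m in ((1, p.read1), (2, p.read2)):
            rows.append(
                {
                    "pair_id": p.pair_id,
                    "read_index": idx,
                    "ref_id": m.ref_id,
                    "read_len": m.read_len,
                    "aligned_frac": m.aligned_frac,
                    "edit_distance": m.edit_distance,
                }
            )
    cols = ["pair_id", "read_index", "ref_id", "read_len", "aligned_frac", "edit_distance"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
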