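"""Gene-tree vs. taxonomy congruence scoring and marker selection.

A single-copy marker gene is only useful for concatenated phylogenomics if
its gene tree carries a taxonomic signal consistent with an accepted
reference taxonomy. Each node (edge) of the unrooted gene tree splits the
genomes into a "right" and "left" subset; for a taxonomy clade ``c`` with
``T(c)`` genomes in the tree, a side ``x`` contains ``N_x(c)`` members of
the clade and ``I_x(c)`` intruders. The consistency of the node for clade
``c`` is

    C = max_{x in {R, L}} (N_x(c) - I_x(c)) / T(c),  floored at 0,

which is 1 exactly when some edge isolates the clade (perfect monophyly)
and is penalised both by absent members and by intruding genomes. A clade's
consistency is the maximum over all nodes; tree-level consistency is the
mean over domain, phylum and class rank averages, each rank averaging
clades with at least ``min_genomes`` genomes present in the tree. Trees
scoring below a retention threshold (default 0.86) are discarded from the
concatenation set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from .trees import bipartitions

RANKS = ("domain", "phylum", "class")

DEFAULT_CONSISTENCY_THRESHOLD = 0.86
DEFAULT_MIN_GENOMES = 5

__all__ = [
    "RANKS",
    "DEFAULT_CONSISTENCY_THRESHOLD",
    "DEFAULT_MIN_GENOMES",
    "TaxonomyMap",
    "ConsistencyReport",
    "node_consistency",
    "clade_consistency",
    "tree_score",
    "filter_markers",
    "report_table",
]


@dataclass(frozen=True)
class TaxonomyMap:
    """genome_id -> (domain, phylum, class) ranked labels.

    A genome with an empty label at some rank is excluded from that rank's
    clades (it still counts as an intruder for every clade it is not in).
    """

    labels: dict[str, tuple[str, str, str]]

    def __post_init__(self):
        for g, ranks in self.labels.items():
            if len(ranks) != 3:
                raise ValueError(f"genome {g!r}: expected 3 rank labels, got {ranks!r}")

    @property
    def genomes(self) -> list[str]:
        return sorted(self.labels)

    def clades(self, rank: str) -> dict[str, frozenset]:
        """Clade label -> genome set at the given rank."""
        idx = RANKS.index(rank)
        out: dict[str, set] = {}
        for g, ranks in self.labels.items():
            label = ranks[idx]
            if label:
                out.setdefault(label, set()).add(g)
        return {k: frozenset(v) for k, v in out.items()}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyMap":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        return cls(
            {
                row["genome_id"]: (row["domain"], row["phylum"], row["class"])
                for _, row in df.iterrows()
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"genome_id": g, "domain": d, "phylum": p, "class": c}
            for g, (d, p, c) in sorted(self.labels.items())
        ]
        pd.DataFrame(rows, columns=["genome_id", "domain", "phylum", "class"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class ConsistencyReport:
    """Per-clade and per-rank consistency of one gene tree."""

    marker_id: str
    clade_scores: dict[tuple[str, str], float]  # (rank, clade label) -> score
    rank_means: dict[str, float]  # only ranks with >= 1 eligible clade
    tree_score: float


def node_consistency(split, clade_members, all_leaves) -> float:
    """Consistency of one bipartition with one taxonomy clade.

    ``split`` is the leaf set of one side; the other side is its complement
    within ``all_leaves``. Returns max over the two sides of
    (members - intruders) / clade size in tree, floored at 0.
    """
    split = frozenset(split)
    clade_members = frozenset(clade_members)
    all_leaves = frozenset(all_leaves)
    t_c = len(clade_members & all_leaves)
    if t_c == 0:
        raise ValueError("clade has no members among the tree leaves")
    best = 0.0
    for side in (split, all_leaves - split):
        n_x = len(side & clade_members)
        i_x = len(side) - n_x
        best = max(best, (n_x - i_x) / t_c)
    return best


def clade_consistency(tree: dendropy.Tree, clade_members) -> float:
    """Highest node consistency for the clade over all edges of the tree."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    return max(
        node_consistency(split, clade_members, all_leaves)
        for split in bipartitions(tree)
    )


def tree_score(
    tree: dendropy.Tree,
    taxonomy: TaxonomyMap,
    min_genomes: int = DEFAULT_MIN_GENOMES,
    marker_id: str = "",
) -> ConsistencyReport:
    """Score a gene tree against the taxonomy.

    Per rank, clade consistencies are averaged over clades with at least
    ``min_genomes`` genomes present in the tree; the tree score is the
    unweighted mean of the rank averages over ranks having at least one
    eligible clade. Leaves absent from the taxonomy are intruders for every
    clade.
    """
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    splits = bipartitions(tree)
    clade_scores: dict[tuple[str, str], float] = {}
    rank_means: dict[str, float] = {}
    for rank in RANKS:
        scores = []
        for label, members in sorted(taxonomy.clades(rank).items()):
            in_tree = members & all_leaves
            if len(in_tree) < min_genomes:
                continue
            score = max(
                node_consistency(split, in_tree, all_leaves) for split in splits
            )
            clade_scores[(rank, label)] = score
            scores.append(score)
        if scores:
            rank_means[rank] = sum(scores) / len(scores)
    if not rank_means:
        raise ValueError(
            f"no clade with >= {min_genomes} genomes at any rank; cannot score tree"
        )
    score = sum(rank_means.values()) / len(rank_means)
    return ConsistencyReport(
        marker_id=marker_id,
        clade_scores=clade_scores,
        rank_means=rank_means,
        tree_score=score,
    )


def filter_markers(
    reports: dict[str, ConsistencyReport] | list[ConsistencyReport],
    threshold: float = DEFAULT_CONSISTENCY_THRESHOLD,
) -> set[str]:
    """Marker ids whose tree score meets the retention threshold.

    Trees scoring strictly below the threshold are discarded; a score equal
    to the threshold is retained.
    """
    if isinstance(reports, dict):
        reports = list(reports.values())
    return {r.marker_id for r in reports if r.tree_score >= threshold}


def report_table(
    reports: list[ConsistencyReport],
    threshold: float = DEFAULT_CONSISTENCY_THRESHOLD,
) -> pd.DataFrame:
    """One row per marker: rank averages, tree score, retention verdict."""
    ids = [r.marker_id for r in reports]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate marker ids in reports")
    rows = []
    for r in sorted(reports, key=lambda r: r.marker_id):
        row = {"marker_id": r.marker_id}
        for rank in RANKS:
            row[f"{rank}_mean"] = r.rank_means.get(rank, float("nan"))
        row["tree_score"] = r.tree_score
        row["retained"] = r.tree_score >= threshold
        rows.append(row)
    cols = ["marker_id", *(f"{r}_mean" for r in RANKS), "tree_score", "retained"]
    if not rows:
        warnings.warn("no consistency reports; emitting empty table")
    return pd.DataFrame(rows, columns=cols)
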