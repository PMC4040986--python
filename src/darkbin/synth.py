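"""Synthetic multi-sample metagenome data with known ground truth.

Every input the pipeline consumes can be generated here so that all
downstream stages are testable without any external download: multi-sample
communities with lognormal genome abundances and per-contig multiplicative
coverage noise, planted single-copy-marker hit tables, gene trees with
controlled taxonomic congruence, sequence alignments evolved along a known
tree under the one-parameter symmetric (Jukes-Cantor) substitution model,
and 16S read-pair mapping tables with controlled aligned fractions, edit
distances and reference placements.

All randomness flows from one integer seed; each operation derives a child
generator deterministically, so identical seeds and arguments give
byte-identical outputs.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .binning import CoverageMatrix
from .consistency import RANKS, TaxonomyMap
from .ribo import ReadMapping, ReadPairMapping
from .trees import patristic_matrix

DEFAULT_DEPTH = 10.0
DEFAULT_SDLOG = 1.0
DEFAULT_CONTIG_LENGTH_RANGE = (5_000, 50_000)

__all__ = [
    "GenomeRecord",
    "SyntheticCommunity",
    "SimulatedAlignment",
    "make_taxonomy",
    "simulate_community",
    "plant_markers",
    "simulate_gene_tree",
    "evolve_alignment",
    "simulate_read_pairs",
    "write_contigs_fasta",
]


def child_rng(seed: int, tag: str) -> np.random.Generator:
    """Deterministic per-operation child generator from one global seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(tag.encode())])


@dataclass(frozen=True)
class GenomeRecord:
    genome_id: str
    taxonomy: tuple[str, str, str]
    contig_ids: tuple
    contig_lengths: tuple


@dataclass(frozen=True)
class SyntheticCommunity:
    """Planted community: genome abundances and derived contig coverage."""

    genomes: tuple
    sample_ids: tuple
    abundances: np.ndarray  # genome x sample, positive
    coverage: np.ndarray  # contig x sample, non-negative
    depth: float
    seed: int

    def __post_init__(self):
        if np.any(self.abundances <= 0):
            raise ValueError("abundances must be positive")
        if np.any(self.coverage < 0):
            raise ValueError("coverage must be non-negative")
        n_contigs = sum(len(g.contig_ids) for g in self.genomes)
        if self.coverage.shape != (n_contigs, len(self.sample_ids)):
            raise ValueError("coverage shape mismatch")

    @property
    def contig_ids(self) -> list[str]:
        return [c for g in self.genomes for c in g.contig_ids]

    @property
    def contig_lengths(self) -> np.ndarray:
        return np.array([ln for g in self.genomes for ln in g.contig_lengths])

    def truth(self) -> dict[str, str]:
        """contig_id -> genome_id ground truth."""
        return {c: g.genome_id for g in self.genomes for c in g.contig_ids}

    def taxonomy(self) -> TaxonomyMap:
        return TaxonomyMap({g.genome_id: g.taxonomy for g in self.genomes})

    def coverage_matrix(self) -> CoverageMatrix:
        return CoverageMatrix(
            contig_ids=self.contig_ids,
            lengths=self.contig_lengths,
            sample_ids=list(self.sample_ids),
            values=self.coverage,
        )


@dataclass(frozen=True)
class SimulatedAlignment:
    """Sequences evolved along a known tree; ids equal the tree's leaves."""

    sequences: dict[str, str]
    tree: dendropy.Tree
    length: int

    def __post_init__(self):
        if any(len(s) != self.length for s in self.sequences.values()):
            raise ValueError("all sequences must have the stated length")
        leaves = {lf.taxon.label for lf in self.tree.leaf_node_iter()}
        if set(self.sequences) != leaves:
            raise ValueError("sequence ids must equal tree leaf labels")


def make_taxonomy(
    n_genomes: int,
    n_domains: int = 1,
    n_phyla: int = 2,
    n_classes: int = 4,
    prefix: str = "G",
) -> TaxonomyMap:
    """Nested ranked taxonomy over ``n_genomes`` ids, split into contiguous
    blocks: classes nest inside phyla, phyla inside domains."""
    if not 1 <= n_domains <= n_phyla <= n_classes <= n_genomes:
        raise ValueError("need 1 <= domains <= phyla <= classes <= genomes")
    ids = [f"{prefix}{i:03d}" for i in range(1, n_genomes + 1)]
    class_of = np.array_split(np.arange(n_genomes), n_classes)
    labels = {}
    for ci, members in enumerate(class_of):
        pi = ci * n_phyla // n_classes
        di = pi * n_domains // n_phyla
        for g in members:
            labels[ids[g]] = (f"d{di + 1}", f"p{pi + 1}", f"c{ci + 1}")
    return TaxonomyMap(labels)


def simulate_community(
    n_genomes: int,
    n_samples: int,
    contigs_per_genome: int = 20,
    noise_sd: float = 0.05,
    seed: int = 0,
    depth: float = DEFAULT_DEPTH,
    sdlog: float = DEFAULT_SDLOG,
    contig_length_range: tuple[int, int] = DEFAULT_CONTIG_LENGTH_RANGE,
    taxonomy: TaxonomyMap | None = None,
) -> SyntheticCommunity:
    """Multi-sample community with lognormal abundances and noisy coverage.

    Per sample, each genome's relative abundance is lognormal(0, sdlog);
    each contig's coverage is abundance x depth x multiplicative lognormal
    noise with log-sd ``noise_sd`` (exactly abundance x depth when
    noise_sd = 0).
    """
    if n_genomes < 1 or n_samples < 1 or contigs_per_genome < 1:
        raise ValueError("counts must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if taxonomy is None:
        taxonomy = make_taxonomy(
            n_genomes,
            n_domains=1,
            n_phyla=min(2, n_genomes),
            n_classes=min(2, n_genomes),
        )
    ids = taxonomy.genomes
    if len(ids) != n_genomes:
        raise ValueError("taxonomy must cover exactly n_genomes genomes")
    rng_ab = child_rng(seed, "abundance")
    rng_len = child_rng(seed, "contig-lengths")
    rng_noise = child_rng(seed, "coverage-noise")
    abundances = rng_ab.lognormal(mean=0.0, sigma=sdlog, size=(n_genomes, n_samples))
    lo, hi = contig_length_range
    genomes = []
    for gi, gid in enumerate(ids):
        contig_ids = tuple(f"{gid}_ctg{k:04d}" for k in range(1, contigs_per_genome + 1))
        lengths = tuple(int(x) for x in rng_len.integers(lo, hi + 1, contigs_per_genome))
        genomes.append(
            GenomeRecord(
                genome_id=gid,
                taxonomy=taxonomy.labels[gid],
                contig_ids=contig_ids,
                contig_lengths=lengths,
            )
        )
    n_contigs = n_genomes * contigs_per_genome
    base = np.repeat(abundances, contigs_per_genome, axis=0) * depth
    if noise_sd == 0:
        coverage = base
    else:
        noise = rng_noise.lognormal(0.0, noise_sd, size=(n_contigs, n_samples))
        coverage = base * noise
    return SyntheticCommunity(
        genomes=tuple(genomes),
        sample_ids=tuple(f"sample_{s + 1}" for s in range(n_samples)),
        abundances=abundances,
        coverage=coverage,
        depth=depth,
        seed=seed,
    )


def plant_markers(
    community: SyntheticCommunity,
    marker_ids: Sequence[str],
    present: int | Mapping[str, int],
    duplicated: int | Mapping[str, int] = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Plant single-copy-marker hits on randomly chosen contigs per genome.

    ``present`` markers (distinct, chosen at random from the marker set)
    are placed once each; ``duplicated`` of them receive a second hit on
    another contig. Returns a hit table with columns contig_id, marker_id.
    """
    marker_ids = list(marker_ids)
    rng = child_rng(seed, "plant-markers")
    rows = []
    for g in community.genomes:
        n_present = present if isinstance(present, int) else present.get(g.genome_id, 0)
        n_dup = duplicated if isinstance(duplicated, int) else duplicated.get(g.genome_id, 0)
        if n_present < 0 or n_present > len(marker_ids):
            raise ValueError(f"{g.genome_id}: present must be in [0, {len(marker_ids)}]")
        if n_dup < 0 or n_dup > n_present:
            raise ValueError(f"{g.genome_id}: duplicated must be in [0, present]")
        chosen = rng.choice(marker_ids, size=n_present, replace=False)
        dups = set(rng.choice(chosen, size=n_dup, replace=False)) if n_dup else set()
        contigs = list(g.contig_ids)
        for marker in chosen:
            first = contigs[rng.integers(len(contigs))]
            rows.append({"contig_id": first, "marker_id": str(marker)})
            if marker in dups:
                others = [c for c in contigs if c != first] or contigs
                second = others[rng.integers(len(others))]
                rows.append({"contig_id": second, "marker_id": str(marker)})
    return pd.DataFrame(rows, columns=["contig_id", "marker_id"])


def _join_ladder(nodes: list[dendropy.Node], branch_length: float) -> dendropy.Node:
    acc = nodes[0]
    for nd in nodes[1:]:
        parent = dendropy.Node()
        parent.add_child(acc)
        parent.add_child(nd)
        acc.edge.length = branch_length
        nd.edge.length = branch_length
        acc = parent
    return acc


def simulate_gene_tree(
    taxonomy: TaxonomyMap,
    congruence: float = 1.0,
    seed: int = 0,
    branch_length: float = 0.1,
) -> dendropy.Tree:
    """Gene tree with controlled agreement with the taxonomy.

    At congruence 1 the tree nests classes within phyla within domains, so
    every taxonomy clade is monophyletic. Lower congruence applies
    round((1 - congruence) * n_leaves) random leaf relocations, each
    implemented as a label swap between two leaves of different classes.
    Deterministic for a fixed seed.
    """
    if not 0.0 <= congruence <= 1.0:
        raise ValueError("congruence must be in [0, 1]")
    genomes = taxonomy.genomes
    if len(genomes) < 4:
        raise ValueError("need at least 4 genomes")
    tns = dendropy.TaxonNamespace()

    def leaf(gid):
        return dendropy.Node(taxon=tns.require_taxon(label=gid))

    domains: dict[str, dict[str, dict[str, list]]] = {}
    for gid in genomes:
        d, p, c = taxonomy.labels[gid]
        domains.setdefault(d, {}).setdefault(p, {}).setdefault(c, []).append(gid)
    domain_nodes = []
    for d in sorted(domains):
        phylum_nodes = []
        for p in sorted(domains[d]):
            class_nodes = []
            for c in sorted(domains[d][p]):
                class_nodes.append(
                    _join_ladder([leaf(g) for g in sorted(domains[d][p][c])], branch_length)
                )
            phylum_nodes.append(_join_ladder(class_nodes, branch_length))
        domain_nodes.append(_join_ladder(phylum_nodes, branch_length))
    root = _join_ladder(domain_nodes, branch_length)
    if root.edge is not None:
        root.edge.length = None
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False

    n_swaps = round((1.0 - congruence) * len(genomes))
    if n_swaps:
        rng = child_rng(seed, "gene-tree-swaps")
        leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
        class_of = {g: taxonomy.labels[g][2] for g in genomes}
        for _ in range(n_swaps):
            for _attempt in range(100):
                i, j = rng.integers(len(leaves), size=2)
                a, b = leaves[i], leaves[j]
                if class_of[a.taxon.label] != class_of[b.taxon.label]:
                    a.taxon, b.taxon = b.taxon, a.taxon
                    break
    return tree


def evolve_alignment(tree: dendropy.Tree, length: int, seed: int = 0) -> SimulatedAlignment:
    """Evolve an alignment along the tree under the symmetric 4-state model.

    Sites are independent; root states are uniform over {A, C, G, T}; along
    a branch of length ``d`` (expected substitutions/site) a site changes
    with probability (3/4)(1 - exp(-4d/3)), uniformly to one of the other
    three states.
    """
    if length < 1:
        raise ValueError("length must be positive")
    rng = child_rng(seed, "evolve-alignment")
    nucs = np.array(list("ACGT"))
    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.integers(0, 4, size=length)
    seqs: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is not root:
            d = node.edge.length
            if d is None:
                raise ValueError("tree has edges with missing branch lengths")
            parent_states = states[id(node.parent_node)]
            p_change = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
            u = rng.random(length)
            child = parent_states.copy()
            mut = u < p_change
            n_mut = int(mut.sum())
            if n_mut:
                child[mut] = (child[mut] + rng.integers(1, 4, size=n_mut)) % 4
            states[id(node)] = child
        if node.is_leaf():
            seqs[node.taxon.label] = "".join(nucs[states[id(node)]])
    return SimulatedAlignment(sequences=seqs, tree=tree, length=length)


def simulate_read_pairs(
    ref_tree: dendropy.Tree,
    source_leaf: str,
    n_pairs: int,
    aligned_frac_range: tuple[float, float] = (0.85, 1.0),
    edit_ratio_range: tuple[float, float] = (0.0, 0.10),
    placement_sd: float = 0.0,
    seed: int = 0,
    read_len: int = 100,
) -> list[ReadPairMapping]:
    """Simulated 16S read-pair mappings originating from one reference leaf.

    Each read maps to the reference leaf whose patristic distance from the
    source best matches a half-normal displacement with sd
    ``placement_sd`` (the source itself when sd = 0); aligned fractions and
    edit-distance ratios are uniform over the given ranges.
    """
    labels, d = patristic_matrix(ref_tree)
    if source_leaf not in labels:
        raise KeyError(f"source leaf {source_leaf!r} not in reference tree")
    src = labels.index(source_leaf)
    dist = d[src]
    rng = child_rng(seed, f"read-pairs-{source_leaf}")
    pairs = []
    for k in range(1, n_pairs + 1):
        reads = []
        for _ in range(2):
            disp = abs(rng.normal(0.0, placement_sd)) if placement_sd > 0 else 0.0
            ref = labels[int(np.argmin(np.abs(dist - disp)))]
            frac = float(rng.uniform(*aligned_frac_range))
            ratio = float(rng.uniform(*edit_ratio_range))
            reads.append(
                ReadMapping(
                    ref_id=ref,
                    read_len=read_len,
                    aligned_frac=frac,
                    edit_distance=int(math.floor(ratio * read_len)),
                )
            )
        pairs.append(
            ReadPairMapping(
                pair_id=f"{source_leaf}_pair{k:05d}", read1=reads[0], read2=reads[1]
            )
        )
    return pairs


def write_contigs_fasta(community: SyntheticCommunity, path: str | Path, seed: int = 0) -> None:
    """Random nucleotide sequences of the planted contig lengths."""
    rng = child_rng(seed, "contig-seqs")
    nucs = np.array(list("ACGT"))
    with open(path, "w") as fh:
        for g in community.genomes:
            for cid, ln in zip(g.contig_ids, g.contig_lengths):
                seq = "".join(nucs[rng.integers(0, 4, size=int(ln))])
                fh.write(f">{cid}\n{seq}\n")
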