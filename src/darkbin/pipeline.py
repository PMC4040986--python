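"""End-to-end orchestration: synthetic or user data in; bins, census,
retained markers, supported tree, monophyly verdicts and 16S clusters out.

The demo configuration plants a community whose ground truth is known, runs
every stage in order (synth -> bin -> census/gate -> congruence ->
mask/concat/dist/NJ/bootstrap -> monophyly -> 16S recruitment), writes each
stage's outputs to a run directory, and emits a JSON report whose canonical
checksum is reproducible byte-for-byte for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from . import binning, census, consistency, phylo, ribo, synth, trees

log = logging.getLogger("darkbin")

STAGES = ("synth", "bin", "census", "congruence", "phylo", "ribo")

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "classify_bins", "report_checksum"]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the analysis defaults.

    Threshold defaults: quality gate >60% completeness / <10% contamination,
    marker retention at average consistency 0.86 over clades with >= 5
    genomes, masking at gap fraction 0.5, 16S recruitment at >= 85% aligned
    with edit distance < 10% of read length and a 0.03 patristic radius,
    100 bootstrap replicates.
    """

    out_dir: str = "run"
    seed: int = 0
    stages: tuple = STAGES
    # quality gate
    min_completeness: float = census.DEFAULT_MIN_COMPLETENESS
    max_contamination: float = census.DEFAULT_MAX_CONTAMINATION
    # congruence
    consistency_threshold: float = consistency.DEFAULT_CONSISTENCY_THRESHOLD
    min_genomes: int = consistency.DEFAULT_MIN_GENOMES
    # phylo
    max_gap_fraction: float = phylo.DEFAULT_MAX_GAP_FRACTION
    bootstrap_replicates: int = phylo.DEFAULT_BOOTSTRAP_REPLICATES
    # 16S recruitment
    radius: float = ribo.DEFAULT_RADIUS
    min_aligned_frac: float = ribo.DEFAULT_MIN_ALIGNED_FRAC
    max_edit_ratio: float = ribo.DEFAULT_MAX_EDIT_RATIO
    # binning
    pseudocount: float = binning.DEFAULT_PSEUDOCOUNT
    linkage_dist: float = binning.DEFAULT_LINKAGE_DIST
    min_bin_size: int = binning.DEFAULT_MIN_BIN_SIZE
    # synthetic fixture
    n_genomes: int = 12
    n_samples: int = 4
    contigs_per_genome: int = 20
    noise_sd: float = 0.02
    n_marker_trees: int = 6
    n_incongruent_trees: int = 1
    alignment_length: int = 10_000
    gene_branch_length: float = 0.12
    marker_set_size: int = census.DEFAULT_MARKER_SET_SIZE
    n_ref_leaves: int = 20
    pairs_per_source: int = 30

    def validate(self) -> None:
        if not self.stages:
            raise ValueError("no stages enabled")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        checks = [
            (0 <= self.min_completeness <= 100, "min_completeness in [0, 100]"),
            (0 <= self.max_contamination <= 100, "max_contamination in [0, 100]"),
            (0 <= self.consistency_threshold <= 1, "consistency_threshold in [0, 1]"),
            (self.min_genomes >= 1, "min_genomes >= 1"),
            (0 <= self.max_gap_fraction <= 1, "max_gap_fraction in [0, 1]"),
            (self.radius >= 0, "radius >= 0"),
            (0 <= self.min_aligned_frac <= 1, "min_aligned_frac in [0, 1]"),
            (0 <= self.max_edit_ratio <= 1, "max_edit_ratio in [0, 1]"),
            (self.bootstrap_replicates >= 1, "bootstrap_replicates >= 1"),
            (self.min_bin_size >= 1, "min_bin_size >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"config out of range: {msg}")

    def to_json(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(self.stages)
        Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        data["stages"] = tuple(data.get("stages", STAGES))
        return cls(**data)


@dataclass
class PipelineReport:
    """Per-stage summaries; serialized as the run's report.json."""

    seed: int
    version: str
    stages: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"seed": self.seed, "version": self.version, "stages": self.stages}


def report_checksum(report: PipelineReport) -> str:
    payload = json.dumps(report.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()


def classify_bins(tree, supports, ingroup_definitions: dict) -> list[dict]:
    """Monophyly verdicts with minimum subtending-edge support per group.

    Groups with no leaves in the tree are skipped with a warning; single-
    leaf groups are trivially monophyletic with support reported as None.
    """
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    rows = []
    for name in sorted(ingroup_definitions):
        group = frozenset(ingroup_definitions[name]) & leaves
        if not group:
            warnings.warn(f"group {name!r} has no leaves in the tree; skipped")
            rows.append({"group": name, "n_leaves": 0, "monophyletic": None, "support": None})
            continue
        mono = trees.is_monophyletic(tree, group)
        support = None
        if mono and 2 <= len(group) <= len(leaves) - 2:
            support = supports.get(trees.canonical_split(group, leaves))
        rows.append(
            {
                "group": name,
                "n_leaves": len(group),
                "monophyletic": bool(mono),
                "support": support,
            }
        )
    return rows


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the enabled stages in order on a planted synthetic community.

    Each stage writes its outputs to a subfolder of the run directory; a
    manifest and log accompany the report.
    """
    config.validate()
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report = PipelineReport(seed=config.seed, version=__version__)
    try:
        state: dict = {}
        for stage in STAGES:
            if stage not in config.stages:
                continue
            log.info("stage %s: start", stage)
            stage_dir = run_dir / stage
            stage_dir.mkdir(exist_ok=True)
            _STAGE_FNS[stage](config, state, stage_dir, report)
            log.info("stage %s: done", stage)
        config.to_json(run_dir / "config.json")
        report_path = run_dir / "report.json"
        report_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
        manifest = {
            "config": "config.json",
            "report": "report.json",
            "checksum": report_checksum(report),
            "stages": {s: s for s in config.stages},
        }
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return report


def _stage_synth(cfg: PipelineConfig, state: dict, out: Path, report: PipelineReport) -> None:
    taxonomy = synth.make_taxonomy(cfg.n_genomes, n_domains=2, n_phyla=2, n_classes=2)
    community = synth.simulate_community(
        cfg.n_genomes,
        cfg.n_samples,
        contigs_per_genome=cfg.contigs_per_genome,
        noise_sd=cfg.noise_sd,
        seed=cfg.seed,
        taxonomy=taxonomy,
    )
    marker_set = census.default_marker_set(cfg.marker_set_size)
    # every genome complete; the first genome carries one duplicated marker
    duplicated = {g.genome_id: (1 if i == 0 else 0) for i, g in enumerate(community.genomes)}
    hits = synth.plant_markers(
        community, marker_set, present=len(marker_set), duplicated=duplicated, seed=cfg.seed
    )
    species_tree = synth.simulate_gene_tree(
        taxonomy, congruence=1.0, seed=cfg.seed, branch_length=cfg.gene_branch_length
    )
    gene_trees = {}
    for k in range(cfg.n_marker_trees):
        marker = marker_set[k]
        congruent = k >= cfg.n_incongruent_trees
        gene_trees[marker] = synth.simulate_gene_tree(
            taxonomy,
            congruence=1.0 if congruent else 0.3,
            seed=cfg.seed + k + 1,
            branch_length=cfg.gene_branch_length,
        )
    n_blocks = max(1, cfg.n_marker_trees - cfg.n_incongruent_trees)
    block_len = max(1, cfg.alignment_length // n_blocks)
    alignments = {
        marker: synth.evolve_alignment(species_tree, block_len, seed=cfg.seed + 101 + k)
        for k, marker in enumerate(marker_set[: cfg.n_marker_trees])
    }
    ref_tax = synth.make_taxonomy(cfg.n_ref_leaves, 1, 2, 4, prefix="R")
    ref_tree = synth.simulate_gene_tree(ref_tax, congruence=1.0, seed=cfg.seed + 500, branch_length=0.1)
    ref_labels = trees.leaf_labels(ref_tree)
    sources = [ref_labels[0], ref_labels[-1]]
    pairs = []
    for src in sources:
        pairs.extend(
            synth.simulate_read_pairs(
                ref_tree,
                src,
                cfg.pairs_per_source,
                aligned_frac_range=(0.90, 0.95),
                edit_ratio_range=(0.0, 0.05),
                placement_sd=0.0,
                seed=cfg.seed,
            )
        )
    community.coverage_matrix().to_tsv(out / "coverage.tsv")
    taxonomy.to_tsv(out / "taxonomy.tsv")
    hits.to_csv(out / "marker_hits.tsv", sep="\t", index=False)
    census.write_marker_set(marker_set, out / "markers.txt")
    trees.write_newick(species_tree, out / "species_tree.nwk")
    trees.write_newick(ref_tree, out / "ref_16s.nwk")
    ribo.write_mappings(pairs, out / "read_pairs.tsv")
    for marker, aln in alignments.items():
        phylo.write_fasta_alignment(aln.sequences, out / f"{marker}.aln.fasta")
    state.update(
        community=community,
        taxonomy=taxonomy,
        marker_set=marker_set,
        hits=hits,
        gene_trees=gene_trees,
        alignments=alignments,
        ref_tree=ref_tree,
        ref_tax=ref_tax,
        pairs=pairs,
        sources=sources,
    )
    report.stages["synth"] = {
        "n_genomes": cfg.n_genomes,
        "n_samples": cfg.n_samples,
        "n_contigs": len(community.contig_ids),
        "n_marker_trees": cfg.n_marker_trees,
        "n_read_pairs": len(pairs),
    }


def _stage_bin(cfg: PipelineConfig, state: dict, out: Path, report: PipelineReport) -> None:
    community = state["community"]
    assign = binning.bin_contigs(
        community.coverage_matrix(),
        pseudocount=cfg.pseudocount,
        min_bin_size=cfg.min_bin_size,
        linkage_dist=cfg.linkage_dist,
    )
    assign.to_tsv(out / "bins.tsv")
    purity = binning.binning_purity(assign, community.truth())
    purity.to_csv(out / "purity.tsv", sep="\t", index=False)
    state["assignment"] = assign
    state["purity"] = purity
    report.stages["bin"] = {
        "n_bins": len(assign.members()),
        "n_unbinned": sum(1 for b in assign.bins.values() if b == binning.UNBINNED),
        "min_purity": float(purity["purity"].min()) if len(purity) else None,
        "min_recall": float(purity["recall"].min()) if len(purity) else None,
    }


def _stage_census(cfg: PipelineConfig, state: dict, out: Path, report: PipelineReport) -> None:
    assign = state["assignment"]
    table = census.census_table(
        assign.members(),
        state["hits"],
        state["marker_set"],
        min_completeness=cfg.min_completeness,
        max_contamination=cfg.max_contamination,
    )
    census.write_census(table, out / "census.tsv")
    # label each bin by its dominant planted genome for downstream reporting
    purity = state["purity"]
    state["bin_genome"] = dict(zip(purity["bin_id"], purity["dominant_genome"]))
    state["census"] = table
    report.stages["census"] = {
        "n_bins": int(len(table)),
        "n_pass_gate": int(table["gate"].sum()),
        "rows": table.to_dict(orient="records"),
    }


def _stage_congruence(cfg: PipelineConfig, state: dict, out: Path, report: PipelineReport) -> None:
    reports = [
        consistency.tree_score(tree, state["taxonomy"], cfg.min_genomes, marker_id=marker)
        for marker, tree in sorted(state["gene_trees"].items())
    ]
    table = consistency.report_table(reports, threshold=cfg.consistency_threshold)
    table.to_csv(out / "consistency.tsv", sep="\t", index=False)
    retained = sorted(consistency.filter_markers(reports, cfg.consistency_threshold))
    (out / "retained_markers.txt").write_text("\n".join(retained) + "\n")
    state["retained_markers"] = retained
    report.stages["congruence"] = {
        "n_markers": len(reports),
        "n_retained": len(retained),
        "retained": retained,
        "tree_scores": {r.marker_id: round(r.tree_score, 6) for r in reports},
    }


def _stage_phylo(cfg: PipelineConfig, state: dict, out: Path, report: PipelineReport) -> None:
    retained = state["retained_markers"]
    if not retained:
        raise RuntimeError("no retained markers; cannot build supermatrix")
    blocks = [
        phylo.mask_alignment(
            phylo.AlignmentBlock(marker_id=m, sequences=state["alignments"][m].sequences),
            max_gap_fraction=cfg.max_gap_fraction,
        )
        for m in retained
    ]
    universe = state["taxonomy"].genomes
    sm = phylo.concatenate(blocks, universe)
    phylo.write_fasta_alignment(sm.sequences, out / "supermatrix.fasta")
    (out / "supermatrix_map.json").write_text(
        json.dumps({m: list(span) for m, span in sm.block_map.items()}, indent=2, sort_keys=True) + "\n"
    )
    boot = phylo.bootstrap_support(sm, n_replicates=cfg.bootstrap_replicates, seed=cfg.seed)
    dm = phylo.distance_matrix(sm)
    dm.to_tsv(out / "distances.tsv")
    phylo.annotate_support(boot.tree, boot.supports)
    trees.write_newick(boot.tree, out / "nj_tree.nwk")
    ingroups = {
        f"phylum_{label}": members
        for label, members in state["taxonomy"].clades("phylum").items()
    }
    verdicts = classify_bins(boot.tree, boot.supports, ingroups)
    state["boot"] = boot
    state["verdicts"] = verdicts
    report.stages["phylo"] = {
        "supermatrix_length": sm.length,
        "n_blocks": len(blocks),
        "n_replicates": boot.n_replicates,
        "n_skipped_replicates": boot.n_skipped,
        "supports": sorted(boot.supports.values()),
        "verdicts": verdicts,
    }


def _stage_ribo(cfg: PipelineConfig, state: dict, out: Path, report: PipelineReport) -> None:
    surviving, stats = ribo.filter_pairs(
        state["pairs"],
        state["ref_tree"],
        min_aligned_frac=cfg.min_aligned_frac,
        max_edit_ratio=cfg.max_edit_ratio,
        radius=cfg.radius,
    )
    clusters = ribo.greedy_cluster(
        ribo.pairs_by_reference(surviving), state["ref_tree"], radius=cfg.radius
    )
    rng = synth.child_rng(cfg.seed, "ribo-reads")
    nucs = np.array(list("ACGT"))
    reads = {
        p.pair_id: (
            "".join(nucs[rng.integers(0, 4, p.read1.read_len)]),
            "".join(nucs[rng.integers(0, 4, p.read2.read_len)]),
        )
        for p in surviving
    }
    manifest = ribo.emit_clusters(clusters, reads, out)
    ref_lineage = {r: state["ref_tax"].labels[r][2] for r in state["ref_tax"].genomes}
    abundance = ribo.lineage_abundance(clusters, ref_lineage)
    with open(out / "abundance.tsv", "w") as fh:
        fh.write("lineage\tfraction\n")
        for lin, frac in abundance.items():
            fh.write(f"{lin}\t{frac}\n")
    report.stages["ribo"] = {
        "filter_stats": stats,
        "n_clusters": len(clusters),
        "clusters": manifest.to_dict(orient="records"),
        "abundance": abundance,
    }


_STAGE_FNS = {
    "synth": _stage_synth,
    "bin": _stage_bin,
    "census": _stage_census,
    "congruence": _stage_congruence,
    "phylo": _stage_phylo,
    "ribo": _stage_ribo,
}
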