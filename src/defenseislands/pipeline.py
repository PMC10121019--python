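"""End-to-end orchestration: QC -> core -> islands -> hotspots -> reports.

``run_pipeline`` executes the whole analysis on an in-memory cohort (or gene
tables read from disk) and returns a :class:`PipelineResult` holding every
intermediate product; when given an output directory it also writes the full
report tree (TSV tables plus JSON summaries and a manifest). Identical inputs
and configuration produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .core_islands import Island, call_core, filter_islands, find_islands, islands_to_frame
from .defense_merge import (
    DefenseSystemCall,
    assign_calls_to_islands,
    calls_from_frame,
    colocalization_stats,
    genome_defense_summary,
    hotspot_defense_matrix,
    hotspot_diversity,
    merge_defense_calls,
    merged_to_frame,
)
from .hotspot_mapper import (
    Hotspot,
    OccupancyRecord,
    anchor_islands,
    hotspots_to_frame,
    merge_to_hotspots,
    occupancy_matrix,
)
from .island_dedup import IslandCluster, cluster_islands, clusters_to_frame, select_representatives
from .mge_classifier import MGECall, MGERuleConfig, calls_to_frame, classify_mge, mge_summary
from .pangenome_io import Genome, build_cluster_catalog, qc_genomes, read_gene_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline thresholds with their defaults.

    Defaults encode the published constants: core prevalence strictly above
    0.80; islands of at least 10 interior genes with flanks adjacent (<= 3
    intervening genes) somewhere in the cohort; 5-gene synteny blocks; the
    10-gene window with >= 5 in-order matches; contigs of more than 20 genes;
    islands capped at 200 genes; empty means <= 3 intervening genes; genomes
    of more than 200 contigs discarded; island dedup at identity 0.6 /
    bidirectional coverage 0.8.
    """

    reference: str | None = None  # genome_id; None = first genome in the cohort
    core_prevalence: float = 0.80
    min_island_genes: int = 10
    adjacency_max: int = 3
    synteny_block: int = 5
    window: int = 10
    window_min_match: int = 5
    min_contig_genes: int = 20
    max_island_genes: int = 200
    empty_max: int = 3
    max_contigs: int = 200
    dedup_identity: float = 0.6
    dedup_coverage: float = 0.8
    mge_rules: MGERuleConfig = field(default_factory=MGERuleConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.core_prevalence < 1.0):
            raise ValueError("core_prevalence must lie strictly between 0 and 1")
        if self.window_min_match > self.window:
            raise ValueError("window_min_match cannot exceed window")
        if not (self.empty_max < self.min_island_genes <= self.max_island_genes):
            raise ValueError("require empty_max < min_island_genes <= max_island_genes")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "mge_rules" in raw:
            rules = raw.pop("mge_rules")
            raw["mge_rules"] = MGERuleConfig(
                ice_required=frozenset(rules.get("ice_required", MGERuleConfig().ice_required)),
                short_gene_max_bp=rules.get("short_gene_max_bp", MGERuleConfig().short_gene_max_bp),
            )
        return cls(**raw)

    def manifest(self) -> dict:
        return {
            "reference": self.reference,
            "core_prevalence": self.core_prevalence,
            "min_island_genes": self.min_island_genes,
            "adjacency_max": self.adjacency_max,
            "synteny_block": self.synteny_block,
            "window": self.window,
            "window_min_match": self.window_min_match,
            "min_contig_genes": self.min_contig_genes,
            "max_island_genes": self.max_island_genes,
            "empty_max": self.empty_max,
            "max_contigs": self.max_contigs,
            "dedup_identity": self.dedup_identity,
            "dedup_coverage": self.dedup_coverage,
            "ice_required": sorted(self.mge_rules.ice_required),
            "short_gene_max_bp": self.mge_rules.short_gene_max_bp,
            "seed": self.seed,
        }


@dataclass
class PipelineResult:
    config: PipelineConfig
    genomes: list[Genome]
    dropped_genomes: list[str]
    core: set[str]
    islands: list[Island]
    n_unbounded: int
    unmapped: list[tuple[Island, str]]
    hotspots: list[Hotspot]
    occupancy: pd.DataFrame
    occupancy_records: dict[tuple[str, int], OccupancyRecord]
    clusters: list[IslandCluster]
    representatives: list[Island]
    rep_hotspot: dict[str, int]
    mge_calls: list[MGECall]
    merged_defense: list[DefenseSystemCall]
    calls_by_island: dict[str, list[DefenseSystemCall]]
    colocalization_fraction: float
    defense_matrix: pd.DataFrame
    genome_summary: pd.DataFrame
    stage_counters: dict[str, int]


def report_occupancy_summary(occupancy: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-hotspot occupancy fractions and the cohort median fraction.

    The fraction is occupied / (occupied + empty + not_found) per hotspot.
    """
    if occupancy.empty:
        return pd.DataFrame(columns=["hotspot_id", "occupied", "empty", "not_found",
                                     "occupancy_fraction"]), 0.0
    counts = (
        occupancy.pivot_table(
            index="hotspot_id", columns="status", aggfunc="size", fill_value=0
        )
        .reindex(columns=["occupied", "empty", "not_found"], fill_value=0)
        .reset_index()
    )
    counts.columns.name = None
    total = counts[["occupied", "empty", "not_found"]].sum(axis=1)
    counts["occupancy_fraction"] = counts["occupied"] / total
    median = float(counts["occupancy_fraction"].median())
    return counts, median


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(
    genomes: list[Genome] | str | Path,
    calls_a: pd.DataFrame | None = None,
    calls_b: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis.

    Parameters
    ----------
    genomes
        Either a cohort of :class:`Genome` objects or a path to a gene-table
        TSV. The reference genome is ``config.reference`` or, when unset, the
        first genome of the cohort.
    calls_a, calls_b
        Defense-system call tables from the two annotation sources
        (columns: context_id, system_type, gene_indices). Either may be None.
    out_dir
        When given, the report tree is written there.
    """
    config = config or PipelineConfig()
    if not isinstance(genomes, list):
        genomes = read_gene_table(genomes, format="tsv")
    if not genomes:
        raise ValueError("empty cohort")

    kept, dropped = qc_genomes(genomes, max_contigs=config.max_contigs)
    if not kept:
        raise ValueError("no genome passed contig-count QC")
    ref_id = config.reference or kept[0].genome_id
    by_id = {g.genome_id: g for g in kept}
    if ref_id not in by_id:
        raise ValueError(f"reference genome {ref_id!r} absent from the QC-passing cohort")
    reference = by_id[ref_id]

    catalog = build_cluster_catalog(kept)
    core = call_core(catalog, threshold=config.core_prevalence)

    all_islands: list[Island] = []
    n_unbounded = 0
    for genome in kept:
        islands, unbounded = find_islands(genome, core)
        all_islands.extend(islands)
        n_unbounded += unbounded
    retained = filter_islands(
        all_islands, kept, min_genes=config.min_island_genes, adjacency_max=config.adjacency_max
    )

    anchors, unmapped = anchor_islands(retained, by_id, reference, block=config.synteny_block)
    hotspots = merge_to_hotspots(
        anchors, reference, core, empty_max=config.empty_max, window=config.window
    )

    occupancy, records = occupancy_matrix(
        hotspots,
        kept,
        window=config.window,
        window_min_match=config.window_min_match,
        min_contig_genes=config.min_contig_genes,
        max_island_genes=config.max_island_genes,
        empty_max=config.empty_max,
    )

    clusters: list[IslandCluster] = []
    rep_hotspot: dict[str, int] = {}
    island_hotspot: dict[str, int] = {}
    for hotspot in hotspots:
        occupied_islands = [
            rec.island
            for (g, h), rec in records.items()
            if h == hotspot.hotspot_id and rec.status == "occupied" and rec.island is not None
        ]
        for isl in occupied_islands:
            island_hotspot[isl.island_id] = hotspot.hotspot_id
        if occupied_islands:
            hclusters = cluster_islands(
                occupied_islands,
                hotspot.hotspot_id,
                min_identity=config.dedup_identity,
                min_coverage=config.dedup_coverage,
            )
            clusters.extend(hclusters)
    representatives = select_representatives(clusters, genomes_by_id=by_id)
    for cluster, rep in zip(clusters, representatives):
        rep_hotspot[rep.island_id] = cluster.hotspot_id

    mge_calls = [classify_mge(rep, config.mge_rules) for rep in representatives]

    source_calls_a = calls_from_frame(calls_a, "A") if calls_a is not None else []
    source_calls_b = calls_from_frame(calls_b, "B") if calls_b is not None else []
    merged = merge_defense_calls(source_calls_a, source_calls_b)
    calls_by_island = assign_calls_to_islands(merged, records)
    coloc_fraction, coloc_table = colocalization_stats(calls_by_island)
    defense_matrix = hotspot_defense_matrix(calls_by_island, island_hotspot)
    genome_summary = genome_defense_summary(kept, records, merged, finished_only=True)

    counters = {
        "genomes_in": len(genomes),
        "genomes_dropped": len(dropped),
        "core_clusters": len(core),
        "islands_delineated": len(all_islands),
        "islands_unbounded": n_unbounded,
        "islands_retained": len(retained),
        "islands_unmapped": len(unmapped),
        "hotspots": len(hotspots),
        "island_clusters": len(clusters),
        "merged_defense_calls": len(merged),
    }
    for stage, count in counters.items():
        logger.info("pipeline %s = %d", stage, count)

    result = PipelineResult(
        config=config,
        genomes=kept,
        dropped_genomes=dropped,
        core=core,
        islands=retained,
        n_unbounded=n_unbounded,
        unmapped=unmapped,
        hotspots=hotspots,
        occupancy=occupancy,
        occupancy_records=records,
        clusters=clusters,
        representatives=representatives,
        rep_hotspot=rep_hotspot,
        mge_calls=mge_calls,
        merged_defense=merged,
        calls_by_island=calls_by_island,
        colocalization_fraction=coloc_fraction,
        defense_matrix=defense_matrix,
        genome_summary=genome_summary,
        stage_counters=counters,
    )

    if out_dir is not None:
        write_reports(result, Path(out_dir), catalog_frame=catalog.to_frame(),
                      coloc_table=coloc_table)
    return result


def write_reports(result: PipelineResult, out_dir: Path,
                  catalog_frame: pd.DataFrame | None = None,
                  coloc_table: pd.DataFrame | None = None) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if catalog_frame is not None:
        _write_tsv(catalog_frame, out_dir / "cluster_catalog.tsv")
    _write_tsv(islands_to_frame(result.islands), out_dir / "islands.tsv")
    _write_tsv(hotspots_to_frame(result.hotspots), out_dir / "hotspots.tsv")
    _write_tsv(result.occupancy, out_dir / "occupancy.tsv")
    _write_tsv(clusters_to_frame(result.clusters), out_dir / "island_clusters.tsv")
    _write_tsv(islands_to_frame(result.representatives), out_dir / "representative_islands.tsv")
    _write_tsv(calls_to_frame(result.mge_calls, result.rep_hotspot), out_dir / "mge_calls.tsv")
    _write_tsv(
        mge_summary(result.mge_calls, result.rep_hotspot), out_dir / "mge_summary.tsv"
    )
    _write_tsv(merged_to_frame(result.merged_defense), out_dir / "defense_merged.tsv")
    _write_tsv(result.defense_matrix, out_dir / "defense_matrix.tsv")
    _write_tsv(hotspot_diversity(result.defense_matrix), out_dir / "hotspot_diversity.tsv")
    _write_tsv(result.genome_summary, out_dir / "genome_defense_summary.tsv")
    if coloc_table is not None:
        _write_tsv(coloc_table, out_dir / "island_system_counts.tsv")

    summary_table, median = report_occupancy_summary(result.occupancy)
    _write_tsv(summary_table, out_dir / "occupancy_summary.tsv")

    summary = {
        "stage_counters": result.stage_counters,
        "median_occupancy_fraction": round(median, 6),
        "colocalization_fraction": round(result.colocalization_fraction, 6),
    }
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest = result.config.manifest()
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    manifest["package_version"] = _pkg_version
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
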