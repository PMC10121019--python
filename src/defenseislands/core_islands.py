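"""Core-genome calling and defense-seeded mobile-island delineation.

An island is delineated by walking outward from a defense-system gene until
the first *core* gene (cluster present in more than 80% of the cohort) is
reached on each side; the core genes become the island's flanks and everything
strictly between them its interior. Candidate islands are then filtered for
mobility: at least ten interior genes, and the flank pair adjacent (a handful
of intervening genes at most) in at least one cohort genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .pangenome_io import ClusterCatalog, GeneRecord, Genome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Island:
    """A defense-containing segment bounded by core flanking genes."""

    genome_id: str
    contig_id: str
    left_flank: GeneRecord
    right_flank: GeneRecord
    interior: tuple[GeneRecord, ...]
    seed_systems: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.left_flank.index >= self.right_flank.index:
            raise ValueError("left flank must precede right flank")
        if len(self.interior) != self.right_flank.index - self.left_flank.index - 1:
            raise ValueError("interior must contain every gene strictly between the flanks")

    @property
    def n_genes(self) -> int:
        return len(self.interior)

    @property
    def island_id(self) -> str:
        return f"{self.genome_id}:{self.contig_id}:{self.left_flank.index}-{self.right_flank.index}"

    @property
    def flank_clusters(self) -> tuple[str, str]:
        return (self.left_flank.cluster_id, self.right_flank.cluster_id)

    def interior_clusters(self) -> tuple[str, ...]:
        return tuple(g.cluster_id for g in self.interior)

    def defense_systems(self) -> frozenset[str]:
        """Defense-system names labeled anywhere in the interior."""
        systems: set[str] = set()
        for g in self.interior:
            systems |= g.labels_in_namespace("defense")
        return frozenset(systems)


def call_core(catalog: ClusterCatalog, threshold: float = 0.80) -> set[str]:
    """Clusters present in strictly more than ``threshold`` of cohort genomes."""
    return {
        cid
        for cid, n in catalog.n_genomes_present.items()
        if n / catalog.n_genomes > threshold
    }


def delineate_island(genome: Genome, seed: GeneRecord, core: set[str]) -> Island | None:
    """Walk outward from a defense seed gene to the nearest core gene each side.

    Returns ``None`` (the unbounded marker) when a contig boundary is reached
    before a core gene on either side; such segments cannot be used for
    hotspot discovery.
    """
    if not core:
        raise ValueError("core set must be nonempty")
    genes = genome.contigs.get(seed.contig_id)
    if genes is None or seed.index >= len(genes) or genes[seed.index].cluster_id != seed.cluster_id:
        raise ValueError(f"seed gene {seed.cluster_id} not found in genome {genome.genome_id}")
    left = None
    for i in range(seed.index - 1, -1, -1):
        if genes[i].cluster_id in core:
            left = i
            break
    right = None
    for i in range(seed.index + 1, len(genes)):
        if genes[i].cluster_id in core:
            right = i
            break
    if left is None or right is None:
        return None
    return Island(
        genome_id=genome.genome_id,
        contig_id=seed.contig_id,
        left_flank=genes[left],
        right_flank=genes[right],
        interior=tuple(genes[left + 1 : right]),
        seed_systems=frozenset(seed.labels_in_namespace("defense")),
    )


def find_islands(genome: Genome, core: set[str]) -> tuple[list[Island], int]:
    """Delineate islands around every defense-system block of one genome.

    Multi-gene systems seed once per contiguous same-system block, not per
    gene, and islands sharing the same flank pair are merged with the union of
    their seed systems. Returns the islands plus the number of unbounded
    (contig-truncated) seeds that were discarded.
    """
    by_extent: dict[tuple[str, int, int], Island] = {}
    n_unbounded = 0
    for contig_id, genes in genome.contigs.items():
        prev_systems: frozenset[str] = frozenset()
        for g in genes:
            systems = frozenset(g.labels_in_namespace("defense"))
            new_systems = systems - prev_systems
            prev_systems = systems
            if not new_systems:
                continue
            island = delineate_island(genome, g, core)
            if island is None:
                n_unbounded += 1
                continue
            key = (contig_id, island.left_flank.index, island.right_flank.index)
            if key in by_extent:
                merged = by_extent[key]
                by_extent[key] = Island(
                    genome_id=merged.genome_id,
                    contig_id=merged.contig_id,
                    left_flank=merged.left_flank,
                    right_flank=merged.right_flank,
                    interior=merged.interior,
                    seed_systems=merged.seed_systems | new_systems,
                )
            else:
                by_extent[key] = Island(
                    genome_id=island.genome_id,
                    contig_id=island.contig_id,
                    left_flank=island.left_flank,
                    right_flank=island.right_flank,
                    interior=island.interior,
                    seed_systems=new_systems,
                )
    islands = [by_extent[k] for k in sorted(by_extent)]
    return islands, n_unbounded


def _flank_pair_adjacent(
    left_cluster: str, right_cluster: str, genomes: list[Genome], adjacency_max: int
) -> bool:
    """True iff the two clusters occur on one contig with <= adjacency_max genes between."""
    for genome in genomes:
        for genes in genome.contigs.values():
            left_pos = [g.index for g in genes if g.cluster_id == left_cluster]
            if not left_pos:
                continue
            right_pos = [g.index for g in genes if g.cluster_id == right_cluster]
            for a in left_pos:
                for b in right_pos:
                    if a != b and abs(a - b) - 1 <= adjacency_max:
                        return True
    return False


def filter_islands(
    islands: list[Island],
    genomes: list[Genome],
    min_genes: int = 10,
    adjacency_max: int = 3,
) -> list[Island]:
    """Keep islands that are big enough and demonstrably mobile.

    An island passes iff its interior has at least ``min_genes`` genes (the
    flanks are not counted) and its flank clusters are found adjacent — at
    most ``adjacency_max`` intervening genes, matching the empty-hotspot rule —
    on a single contig in at least one cohort genome.
    """
    adjacency_cache: dict[tuple[str, str], bool] = {}
    kept = []
    for island in islands:
        if island.n_genes < min_genes:
            continue
        pair = island.flank_clusters
        if pair not in adjacency_cache:
            adjacency_cache[pair] = _flank_pair_adjacent(pair[0], pair[1], genomes, adjacency_max)
        if adjacency_cache[pair]:
            kept.append(island)
    return kept


def islands_to_frame(islands: list[Island]) -> pd.DataFrame:
    rows = [
        {
            "island_id": isl.island_id,
            "genome_id": isl.genome_id,
            "contig_id": isl.contig_id,
            "left_flank_cluster": isl.left_flank.cluster_id,
            "right_flank_cluster": isl.right_flank.cluster_id,
            "left_index": isl.left_flank.index,
            "right_index": isl.right_flank.index,
            "n_genes": isl.n_genes,
            "seed_systems": ";".join(sorted(isl.seed_systems)),
        }
        for isl in islands
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "island_id", "genome_id", "contig_id", "left_flank_cluster",
            "right_flank_cluster", "left_index", "right_index", "n_genes", "seed_systems",
        ],
    )
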