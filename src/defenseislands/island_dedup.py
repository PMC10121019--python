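"""Redundancy removal among islands at one hotspot.

Islands at a hotspot are near-copies of the same element across genomes.
They are clustered by gene-content similarity — the in-order longest common
subsequence (LCS) of their interior cluster-ID sequences — using a greedy
set-cover rule: the largest unassigned island seeds a cluster and absorbs
every unassigned island with identity >= 0.6 and bidirectional coverage >=
0.8 against it. This is the gene-cluster-level analog of clustering island
nucleotide sequences (identity 0.6, coverage 0.8, bidirectional, set-cover
cluster mode); it is an analog, not a base-pair reproduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core_islands import Island
from .pangenome_io import Genome


@dataclass
class IslandCluster:
    hotspot_id: int
    representative: Island
    members: list[Island] = field(default_factory=list)

    @property
    def member_ids(self) -> list[str]:
        return [isl.island_id for isl in self.members]


def _lcs_length(a: tuple[str, ...], b: tuple[str, ...]) -> int:
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 0
    prev = [0] * (m + 1)
    for i in range(n):
        cur = [0] * (m + 1)
        ai = a[i]
        for j in range(m):
            cur[j + 1] = prev[j] + 1 if ai == b[j] else max(prev[j + 1], cur[j])
        prev = cur
    return prev[m]


def island_similarity(a: Island, b: Island) -> tuple[float, float, float]:
    """Gene-level identity and coverages of two islands.

    Returns ``(identity, coverage_a, coverage_b)`` where L is the LCS length
    of the interior cluster sequences, identity = L / max(n_a, n_b) and
    coverage_x = L / n_x.
    """
    if a.n_genes == 0 or b.n_genes == 0:
        raise ValueError("island similarity is undefined for empty interiors")
    L = _lcs_length(a.interior_clusters(), b.interior_clusters())
    return (L / max(a.n_genes, b.n_genes), L / a.n_genes, L / b.n_genes)


def cluster_islands(
    islands: list[Island],
    hotspot_id: int,
    min_identity: float = 0.6,
    min_coverage: float = 0.8,
) -> list[IslandCluster]:
    """Greedy set-cover clustering of one hotspot's islands.

    Islands sorted by descending interior size (ties broken by island id) are
    consumed largest-first: each seed absorbs every unassigned island meeting
    both the identity and the bidirectional coverage thresholds against it.
    The sort makes the outcome invariant to input order.
    """
    pending = sorted(islands, key=lambda isl: (-isl.n_genes, isl.island_id))
    clusters: list[IslandCluster] = []
    assigned: set[str] = set()
    for seed in pending:
        if seed.island_id in assigned:
            continue
        cluster = IslandCluster(hotspot_id=hotspot_id, representative=seed, members=[seed])
        assigned.add(seed.island_id)
        for other in pending:
            if other.island_id in assigned:
                continue
            identity, cov_a, cov_b = island_similarity(seed, other)
            if identity >= min_identity and cov_a >= min_coverage and cov_b >= min_coverage:
                cluster.members.append(other)
                assigned.add(other.island_id)
        clusters.append(cluster)
    return clusters


def apply_flank_override(
    island: Island, genome: Genome, left_cluster: str, right_cluster: str
) -> Island:
    """Re-delineate an island against curated flank clusters.

    Replaces manual flank adjustment for pseudogenized or repeated flank
    genes: the island extends outward to the nearest occurrence of each forced
    cluster on its contig.
    """
    genes = genome.contigs[island.contig_id]
    li = island.left_flank.index
    ri = island.right_flank.index
    new_left = next((i for i in range(li, -1, -1) if genes[i].cluster_id == left_cluster), None)
    new_right = next(
        (i for i in range(ri, len(genes)) if genes[i].cluster_id == right_cluster), None
    )
    if new_left is None or new_right is None:
        raise ValueError(
            f"override flanks ({left_cluster}, {right_cluster}) not found around {island.island_id}"
        )
    return Island(
        genome_id=island.genome_id,
        contig_id=island.contig_id,
        left_flank=genes[new_left],
        right_flank=genes[new_right],
        interior=tuple(genes[new_left + 1 : new_right]),
        seed_systems=island.seed_systems,
    )


def select_representatives(
    clusters: list[IslandCluster],
    genomes_by_id: dict[str, Genome] | None = None,
    overrides: dict[str, tuple[str, str]] | None = None,
) -> list[Island]:
    """One representative per cluster: the seeding (largest) member.

    ``overrides`` maps an island id to forced (left, right) flank clusters,
    the deterministic stand-in for manual flank curation; applying one
    requires ``genomes_by_id`` to re-delineate.
    """
    reps = []
    for cluster in clusters:
        rep = cluster.representative
        if overrides and rep.island_id in overrides:
            if genomes_by_id is None:
                raise ValueError("flank overrides require genomes_by_id")
            left, right = overrides[rep.island_id]
            rep = apply_flank_override(rep, genomes_by_id[rep.genome_id], left, right)
        reps.append(rep)
    return reps


def clusters_to_frame(clusters: list[IslandCluster]) -> pd.DataFrame:
    rows = [
        {
            "hotspot_id": c.hotspot_id,
            "representative": c.representative.island_id,
            "n_members": len(c.members),
            "members": ";".join(sorted(c.member_ids)),
        }
        for c in clusters
    ]
    return pd.DataFrame(rows, columns=["hotspot_id", "representative", "n_members", "members"])
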