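"""Shared fixtures: hand-built micro-genomes and a small synthetic cohort."""

from __future__ import annotations

import pytest

from defenseislands.pangenome_io import GeneRecord, Genome
from defenseislands.synthetic_data import SimConfig, generate_pangenome


def make_contig(genome_id: str, contig_id: str, genes, start_index: int = 0):
    """Build GeneRecords from (cluster_id, labels) pairs or bare cluster ids."""
    records = []
    for i, spec in enumerate(genes):
        if isinstance(spec, str):
            cluster, labels = spec, frozenset()
        else:
            cluster, labels = spec[0], frozenset(spec[1])
        records.append(
            GeneRecord(
                genome_id=genome_id,
                contig_id=contig_id,
                index=start_index + i,
                strand="+",
                cluster_id=cluster,
                annotations=labels,
            )
        )
    return records


def make_genome(genome_id: str, contigs: dict, is_finished: bool = True) -> Genome:
    """Genome from {contig_id: [cluster or (cluster, labels), ...]}."""
    genome = Genome(genome_id=genome_id, is_finished=is_finished)
    for contig_id, genes in contigs.items():
        genome.contigs[contig_id] = make_contig(genome_id, contig_id, genes)
    genome.validate()
    return genome


def linear_genome(genome_id: str, clusters, contig_id: str = "c0") -> Genome:
    return make_genome(genome_id, {contig_id: list(clusters)})


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A scaled-down cohort: 40 genomes, 800-gene backbone, 5 hotspots."""
    return SimConfig(
        n_genomes=40,
        n_core=800,
        n_hotspots=5,
        occupancy_prob=(0.2, 0.4, 0.1, 0.3, 0.9),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_pangenome(small_config)
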