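"""Synteny-block mapping, hotspot merging and occupancy classification."""

from __future__ import annotations

import numpy as np
import pytest

from defenseislands.core_islands import Island, call_core, find_islands
from defenseislands.hotspot_mapper import (
    Hotspot,
    anchor_islands,
    classify_occupancy,
    map_island_to_reference,
    merge_to_hotspots,
    occupancy_matrix,
)
from defenseislands.pangenome_io import build_cluster_catalog
from defenseislands.pipeline import run_pipeline
from defenseislands.synthetic_data import SimConfig, generate_pangenome

from conftest import linear_genome, make_genome


def R(i: int) -> str:
    return f"R{i:02d}"


REF_CLUSTERS = [R(i) for i in range(30)]


@pytest.fixture()
def reference():
    return linear_genome("REF", REF_CLUSTERS, contig_id="ref0")


def island_from(genome, contig_id, li, ri, systems=()):
    genes = genome.contigs[contig_id]
    return Island(
        genome_id=genome.genome_id,
        contig_id=contig_id,
        left_flank=genes[li],
        right_flank=genes[ri],
        interior=tuple(genes[li + 1 : ri]),
        seed_systems=frozenset(systems),
    )


def test_exact_synteny_block_anchors(reference):
    # flank context equals a verbatim 5-gene reference run on both sides
    clusters = REF_CLUSTERS[:10] + ["iA", "iB", "iC"] + REF_CLUSTERS[10:]
    genome = linear_genome("gA", clusters)
    island = island_from(genome, "c0", 9, 13)
    anchor = map_island_to_reference(island, genome, reference)
    assert anchor is not None
    assert anchor.ref_contig == "ref0"
    assert (anchor.left_inner, anchor.right_inner) == (9, 10)
    assert anchor.orientation == "forward"


def test_reversed_contig_anchors_with_flip(reference):
    clusters = REF_CLUSTERS[:10] + ["iA", "iB", "iC"] + REF_CLUSTERS[10:]
    genome = linear_genome("gA", list(reversed(clusters)))
    # in the reversed contig the island's left flank is R10
    li = clusters[::-1].index(R(10)) - 0  # gene before interior
    island = island_from(genome, "c0", 19, 23)
    assert island.flank_clusters == (R(10), R(9))
    anchor = map_island_to_reference(island, genome, reference)
    assert anchor is not None
    assert anchor.orientation == "flipped"
    assert (anchor.left_inner, anchor.right_inner) == (9, 10)


def test_four_gene_match_is_not_enough(reference):
    # only 4 consecutive reference genes flank the island; block of five required
    junk_l = [f"jl{i}" for i in range(6)]
    junk_r = [f"jr{i}" for i in range(6)]
    clusters = junk_l + REF_CLUSTERS[6:10] + ["iA", "iB"] + REF_CLUSTERS[10:14] + junk_r
    genome = linear_genome("gA", clusters)
    island = island_from(genome, "c0", 9, 12)
    assert island.flank_clusters == (R(9), R(10))
    assert map_island_to_reference(island, genome, reference) is None


def test_merge_same_interval_and_distinct_intervals(reference):
    def genome_with_island(gid, slot, interior):
        clusters = REF_CLUSTERS[: slot + 1] + interior + REF_CLUSTERS[slot + 1 :]
        return linear_genome(gid, clusters)

    gA = genome_with_island("gA", 9, ["iA", "iB", "iC", "iD"])
    gB = genome_with_island("gB", 9, ["iX", "iY", "iZ", "iW"])
    gC = genome_with_island("gC", 20, ["iQ", "iR", "iS", "iT"])
    islands = [
        island_from(gA, "c0", 9, 14),
        island_from(gB, "c0", 9, 14),
        island_from(gC, "c0", 20, 25),
    ]
    by_id = {g.genome_id: g for g in (gA, gB, gC)}
    anchors, unmapped = anchor_islands(islands, by_id, reference)
    assert not unmapped
    hotspots = merge_to_hotspots(anchors, reference, core=set(REF_CLUSTERS))
    assert len(hotspots) == 2
    first, second = hotspots
    assert first.hotspot_id == 1 and second.hotspot_id == 2
    assert (first.ref_left_cluster, first.ref_right_cluster) == (R(9), R(10))
    assert len(first.member_islands) == 2
    assert (second.ref_left_cluster, second.ref_right_cluster) == (R(20), R(21))


def test_hotspot_occupied_in_reference():
    # the reference itself carries a 12-gene island between R9 and R10
    ref_clusters = REF_CLUSTERS[:10] + [f"refisl{i}" for i in range(12)] + REF_CLUSTERS[10:]
    reference = linear_genome("REF", ref_clusters, contig_id="ref0")
    clusters = REF_CLUSTERS[:10] + ["iA", "iB", "iC", "iD"] + REF_CLUSTERS[10:]
    genome = linear_genome("gA", clusters)
    island = island_from(genome, "c0", 9, 14)
    anchors, _ = anchor_islands([island], {"gA": genome}, reference)
    hotspots = merge_to_hotspots(anchors, reference, core=set(REF_CLUSTERS))
    assert len(hotspots) == 1
    assert hotspots[0].occupied_in_reference is True
    assert (hotspots[0].ref_left_cluster, hotspots[0].ref_right_cluster) == (R(9), R(10))


def _hotspot(reference, left_idx=9, right_idx=10, window=10):
    genes = reference.contigs["ref0"]
    return Hotspot(
        hotspot_id=1,
        ref_contig="ref0",
        ref_left_index=left_idx,
        ref_right_index=right_idx,
        ref_left_cluster=genes[left_idx].cluster_id,
        ref_right_cluster=genes[right_idx].cluster_id,
        left_window=tuple(g.cluster_id for g in genes[max(0, left_idx - window + 1) : left_idx + 1]),
        right_window=tuple(g.cluster_id for g in genes[right_idx : right_idx + window]),
    )


PAD = [f"pad{i}" for i in range(15)]  # unique junk to satisfy the contig-size rule


@pytest.mark.parametrize(
    "n_between,status,reason",
    [
        (0, "empty", None),
        (3, "empty", None),          # "three or fewer genes" is empty
        (4, "occupied", None),       # strictly more than three
        (25, "occupied", None),
        (200, "occupied", None),     # at the cap
        (201, "not_found", "oversize_island"),
    ],
)
def test_interval_size_rules(reference, n_between, status, reason):
    filler = [f"f{i}" for i in range(n_between)]
    if n_between == 25:
        filler[10] = ("D", {"defense:Gabija"})
    clusters = PAD + [R(9)] + filler + [R(10)] + PAD
    genome = make_genome("gX", {"c0": clusters})
    rec = classify_occupancy(_hotspot(reference), genome)
    assert rec.status == status
    assert rec.exclusion_reason == reason
    if status == "occupied":
        assert rec.island is not None and rec.island.n_genes == n_between
        if n_between == 25:
            assert rec.island.seed_systems == frozenset({"Gabija"})


def test_flanks_on_different_contigs(reference):
    genome = make_genome(
        "gX",
        {
            "c1": PAD + [R(9)] + [f"q{i}" for i in range(10)],
            "c2": [f"w{i}" for i in range(10)] + [R(10)] + PAD,
        },
    )
    rec = classify_occupancy(_hotspot(reference), genome)
    assert rec.status == "not_found"
    assert rec.exclusion_reason == "different_contigs"


def test_short_contigs_are_ignored(reference):
    # both flanks present but on a 20-gene contig: "more than 20 genes" required
    core_bit = [R(9), R(10)]
    short = [f"s{i}" for i in range(18)] + core_bit  # exactly 20 genes
    genome = make_genome("gX", {"c0": short})
    rec = classify_occupancy(_hotspot(reference), genome)
    assert rec.status == "not_found"
    assert rec.exclusion_reason == "short_contig"
    # one more gene makes the contig eligible
    genome2 = make_genome("gX", {"c0": [f"s{i}" for i in range(19)] + core_bit})
    rec2 = classify_occupancy(_hotspot(reference), genome2)
    assert rec2.status == "empty"


def test_window_fallback_resolves_deleted_flank(reference):
    # right flank R10 deleted; 6 of the 10 right-window genes remain in order
    right_context = [R(11), R(12), R(13), R(14), R(15), R(16)]
    clusters = PAD + [R(9), "iA", "iB"] + right_context + PAD
    genome = make_genome("gX", {"c0": clusters})
    rec = classify_occupancy(_hotspot(reference), genome)
    assert rec.status == "empty"  # resolved flank sits right of the 2 interveners
    assert rec.resolved_flank_indices is not None


def test_window_fallback_insufficient_matches(reference):
    # only 4 right-window genes present: below the >=5 match requirement
    right_context = [R(11), R(12), R(13), R(14)]
    clusters = PAD + [R(9), "iA", "iB"] + right_context + PAD
    genome = make_genome("gX", {"c0": clusters})
    rec = classify_occupancy(_hotspot(reference), genome)
    assert rec.status == "not_found"
    assert rec.exclusion_reason == "flank_missing"


def test_closest_pair_wins_on_duplicated_flanks(reference):
    # the flank pair occurs twice; the placement with fewer intervening genes
    # defines the hotspot
    far = [R(9)] + [f"f{i}" for i in range(10)] + [R(10)]
    near = [R(9), "x1", R(10)]
    clusters = PAD + far + [f"m{i}" for i in range(5)] + near + PAD
    genome = make_genome("gX", {"c0": clusters})
    rec = classify_occupancy(_hotspot(reference), genome)
    assert rec.status == "empty"
    contig, lo, hi = rec.resolved_flank_indices
    assert hi - lo - 1 == 1


def test_closest_pair_matches_exhaustive_search():
    # random junk genomes with scattered flank copies: the chosen pair must
    # minimize the intervening count over all same-contig placements
    rng = np.random.default_rng(42)
    reference = linear_genome("REF", REF_CLUSTERS, contig_id="ref0")
    hotspot = _hotspot(reference)
    for trial in range(30):
        n = int(rng.integers(50, 300))
        clusters = [f"junk{trial}_{i}" for i in range(n)]
        n_left, n_right = rng.integers(1, 4, size=2)
        pos = sorted(rng.choice(n, size=n_left + n_right, replace=False))
        rng.shuffle(pos)
        for p in pos[:n_left]:
            clusters[p] = R(9)
        for p in pos[n_left:]:
            clusters[p] = R(10)
        genome = make_genome("gX", {"c0": clusters})
        rec = classify_occupancy(hotspot, genome)
        left_pos = [i for i, c in enumerate(clusters) if c == R(9)]
        right_pos = [i for i, c in enumerate(clusters) if c == R(10)]
        gaps = [abs(a - b) - 1 for a in left_pos for b in right_pos if a != b]
        assert gaps, "fixture must place both flanks"
        best = min(gaps)
        assert rec.resolved_flank_indices is not None
        _, lo, hi = rec.resolved_flank_indices
        assert hi - lo - 1 == best


def test_raising_empty_max_only_converts_occupied_to_empty(reference):
    hotspot = _hotspot(reference)
    for n_between in range(0, 12):
        clusters = PAD + [R(9)] + [f"f{i}" for i in range(n_between)] + [R(10)] + PAD
        genome = make_genome("gX", {"c0": clusters})
        before = classify_occupancy(hotspot, genome, empty_max=3).status
        after = classify_occupancy(hotspot, genome, empty_max=6).status
        if before == "empty":
            assert after == "empty"
        elif before == "occupied":
            assert after in ("occupied", "empty")


def test_occupancy_partition_and_truth_agreement(small_cohort, small_config):
    genomes, truth = small_cohort
    result = run_pipeline(genomes)
    # partition: every hotspot's statuses sum to the cohort size
    counts = result.occupancy.groupby("hotspot_id")["status"].count()
    assert (counts == len(genomes)).all()
    # noise-free: recovered hotspots carry the planted flanks and statuses
    flank_map = {f: i for i, f in enumerate(truth.hotspot_flanks)}
    assert len(result.hotspots) == small_config.n_hotspots
    for hotspot in result.hotspots:
        planted = flank_map[(hotspot.ref_left_cluster, hotspot.ref_right_cluster)]
        for genome in genomes:
            rec = result.occupancy_records[(genome.genome_id, hotspot.hotspot_id)]
            assert rec.status == truth.statuses[(genome.genome_id, planted)]


def test_occupancy_islands_match_planted_extents(small_cohort):
    genomes, truth = small_cohort
    result = run_pipeline(genomes)
    planted = {
        (isl.genome_id, isl.contig_id, isl.interior_start - 1, isl.interior_end + 1)
        for isl in truth.islands
    }
    recovered = set()
    for rec in result.occupancy_records.values():
        if rec.status == "occupied":
            recovered.add(
                (rec.island.genome_id, rec.island.contig_id,
                 rec.island.left_flank.index, rec.island.right_flank.index)
            )
    assert recovered == planted
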