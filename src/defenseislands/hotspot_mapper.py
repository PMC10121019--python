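"""Mapping islands to a reference genome and classifying hotspot occupancy.

Islands found across the cohort are anchored onto the reference genome by
5-gene syntenic blocks (five consecutive genes outside the island matching
five consecutive reference genes in the same order, or exactly reversed).
Anchored islands whose reference intervals overlap are merged into discrete
integration hotspots, identified by the reference core genes immediately
flanking the innermost anchors and numbered in ascending reference coordinate.

Per-genome occupancy of each hotspot is then classified with the reference
flanking genes: contigs of 20 genes or fewer are ignored; a flank that is
missing or multi-copy is resolved through a 10-gene reference window requiring
at least 5 in-order cluster matches; among candidate flank pairs the closest
pair on one contig wins; up to 3 intervening genes means "empty", up to 200
means "occupied", more means the hotspot was not found.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .core_islands import Island
from .pangenome_io import Genome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Anchor:
    """A mapped island: inner reference gene indices bounding its insertion."""

    island: Island
    ref_contig: str
    left_inner: int   # reference gene index immediately left of the insertion span
    right_inner: int  # reference gene index immediately right of it
    orientation: str  # "forward" or "flipped"


@dataclass
class Hotspot:
    """A reference insertion locus aggregating islands from many genomes."""

    hotspot_id: int
    ref_contig: str
    ref_left_index: int
    ref_right_index: int
    ref_left_cluster: str
    ref_right_cluster: str
    member_islands: list[Island] = field(default_factory=list)
    occupied_in_reference: bool = False
    left_window: tuple[str, ...] = ()   # reference clusters [left-9 .. left], inner last
    right_window: tuple[str, ...] = ()  # reference clusters [right .. right+9], inner first


@dataclass(frozen=True)
class OccupancyRecord:
    genome_id: str
    hotspot_id: int
    status: str  # occupied / empty / not_found
    resolved_flank_indices: tuple[str, int, int] | None = None  # (contig, left, right)
    island: Island | None = None
    exclusion_reason: str | None = None


def _window_index(reference: Genome, block: int):
    """Index every block-length cluster tuple of the reference, both orientations."""
    index: dict[tuple[str, ...], list[tuple[str, int, str]]] = {}
    for contig_id, genes in reference.contigs.items():
        clusters = [g.cluster_id for g in genes]
        for s in range(len(clusters) - block + 1):
            window = tuple(clusters[s : s + block])
            index.setdefault(window, []).append((contig_id, s, "forward"))
            rev = tuple(reversed(window))
            if rev != window:
                index.setdefault(rev, []).append((contig_id, s, "flipped"))
    return index


def map_island_to_reference(
    island: Island, genome: Genome, reference: Genome, block: int = 5, _index=None
) -> Anchor | None:
    """Anchor an island on the reference via 5-gene syntenic flank blocks.

    Starting at each flank and moving outward in the island's own genome, the
    first window of ``block`` consecutive genes whose cluster sequence matches
    ``block`` consecutive reference genes (in order, or exactly reversed)
    anchors that side. Both sides must land on the same reference contig with
    a consistent orientation and left anchor < right anchor; otherwise the
    island is unmapped. Among multiple consistent pairs the smallest reference
    span wins, ties broken by orientation (forward first) then coordinate.
    """
    index = _index if _index is not None else _window_index(reference, block)
    contig_clusters = [g.cluster_id for g in genome.contigs[island.contig_id]]
    anchor, _reason = _anchor_one(island, contig_clusters, index, block)
    return anchor


def _anchor_one(
    island: Island,
    contig_clusters: list[str],
    index,
    block: int,
) -> tuple[Anchor | None, str]:
    li, ri = island.left_flank.index, island.right_flank.index
    left_context = [contig_clusters[i] for i in range(li, -1, -1)]      # inward->outward
    right_context = [contig_clusters[i] for i in range(ri, len(contig_clusters))]

    def side_hits(context, side):
        for offset in range(len(context) - block + 1):
            outward = context[offset : offset + block]
            # ascending genome order: left side context is reversed
            window = tuple(reversed(outward)) if side == "left" else tuple(outward)
            hits = []
            for contig, s, orient in index.get(window, ()):
                if side == "left":
                    inner = s + block - 1 if orient == "forward" else s
                else:
                    inner = s if orient == "forward" else s + block - 1
                hits.append((contig, inner, orient))
            if hits:
                return hits
        return []

    left_hits = side_hits(left_context, "left")
    right_hits = side_hits(right_context, "right")
    if not left_hits or not right_hits:
        return None, "no_block_match"

    pairs = []
    for lc, lin, lo in left_hits:
        for rc, rin, ro in right_hits:
            if lc != rc or lo != ro:
                continue
            if lo == "forward":
                j, k = lin, rin
            else:
                j, k = rin, lin
            if j < k:
                pairs.append((k - j, 0 if lo == "forward" else 1, lc, j, k, lo))
    if not pairs:
        return None, "conflicting_anchors"
    _, _, contig, j, k, orient = min(pairs)
    return (
        Anchor(island=island, ref_contig=contig, left_inner=j, right_inner=k, orientation=orient),
        "ok",
    )


def anchor_islands(
    islands: list[Island],
    genomes_by_id: dict[str, Genome],
    reference: Genome,
    block: int = 5,
) -> tuple[list[Anchor], list[tuple[Island, str]]]:
    """Map each island to the reference; return anchors and unmapped islands."""
    index = _window_index(reference, block)
    anchors: list[Anchor] = []
    unmapped: list[tuple[Island, str]] = []
    for island in islands:
        genome = genomes_by_id[island.genome_id]
        contig_clusters = [g.cluster_id for g in genome.contigs[island.contig_id]]
        anchor, reason = _anchor_one(island, contig_clusters, index, block)
        if anchor is None:
            unmapped.append((island, reason))
        else:
            anchors.append(anchor)
    return anchors, unmapped


def merge_to_hotspots(
    anchors: list[Anchor],
    reference: Genome,
    core: set[str],
    empty_max: int = 3,
    window: int = 10,
) -> list[Hotspot]:
    """Merge anchored islands into hotspots by overlapping reference intervals.

    Anchors whose open reference intervals overlap belong to one hotspot. The
    hotspot's flanks are the core genes immediately outside the *innermost*
    anchors of the group, which absorbs anchors shifted outward by local gene
    content differences. Hotspots are numbered 1..N in ascending reference
    coordinate; an interval holding more than ``empty_max`` reference genes is
    flagged as occupied in the reference itself.
    """
    if not anchors:
        return []
    ref_core_positions: dict[str, list[int]] = {}
    for contig_id, genes in reference.contigs.items():
        ref_core_positions[contig_id] = [g.index for g in genes if g.cluster_id in core]

    groups: list[list[Anchor]] = []
    for anchor in sorted(anchors, key=lambda a: (a.ref_contig, a.left_inner, a.right_inner)):
        placed = None
        for grp in groups:
            g0 = grp[0]
            if g0.ref_contig != anchor.ref_contig:
                continue
            lo = max(a.left_inner for a in grp)
            hi = min(a.right_inner for a in grp)
            if anchor.left_inner < hi and lo < anchor.right_inner:
                placed = grp
                break
        if placed is not None:
            placed.append(anchor)
        else:
            groups.append([anchor])

    # Resolve each group to its flanking core interval, then merge groups that
    # resolve to the same interval. Anchor blocks skip over genes the
    # reference lacks, so the member islands' own flank clusters — located in
    # the reference — refine the interval inward before the core fallback.
    ref_positions: dict[str, dict[str, list[int]]] = {}
    for contig_id, genes in reference.contigs.items():
        pos = ref_positions.setdefault(contig_id, {})
        for g in genes:
            pos.setdefault(g.cluster_id, []).append(g.index)

    by_interval: dict[tuple[str, int, int], list[Anchor]] = {}
    for grp in groups:
        contig = grp[0].ref_contig
        jmax = max(a.left_inner for a in grp)
        kmin = min(a.right_inner for a in grp)
        cores = ref_core_positions.get(contig, [])
        pos = ref_positions[contig]

        left_flanks = []
        right_flanks = []
        for a in grp:
            lp = pos.get(a.island.left_flank.cluster_id)
            if lp:
                left_flanks.append(min(lp, key=lambda p: abs(p - jmax)))
            rp = pos.get(a.island.right_flank.cluster_id)
            if rp:
                right_flanks.append(min(rp, key=lambda p: abs(p - kmin)))
        left_core = max(left_flanks) if left_flanks else None
        right_core = min(right_flanks) if right_flanks else None
        if left_core is None or right_core is None or left_core >= right_core:
            left_core = max((p for p in cores if p <= jmax), default=None)
            right_core = min((p for p in cores if p >= kmin), default=None)
        if left_core is None or right_core is None or left_core >= right_core:
            logger.warning(
                "anchor group at %s:%d-%d has no bounding core interval; dropped", contig, jmax, kmin
            )
            continue
        by_interval.setdefault((contig, left_core, right_core), []).extend(grp)

    hotspots: list[Hotspot] = []
    for n, ((contig, lc, rc), grp) in enumerate(sorted(by_interval.items()), start=1):
        genes = reference.contigs[contig]
        left_window = tuple(
            g.cluster_id for g in genes[max(0, lc - window + 1) : lc + 1]
        )
        right_window = tuple(g.cluster_id for g in genes[rc : rc + window])
        hotspots.append(
            Hotspot(
                hotspot_id=n,
                ref_contig=contig,
                ref_left_index=lc,
                ref_right_index=rc,
                ref_left_cluster=genes[lc].cluster_id,
                ref_right_cluster=genes[rc].cluster_id,
                member_islands=[a.island for a in grp],
                occupied_in_reference=(rc - lc - 1) > empty_max,
                left_window=left_window,
                right_window=right_window,
            )
        )
    return hotspots


def _lcs_matches(a: tuple[str, ...], b: tuple[str, ...]):
    """Longest common subsequence of two cluster tuples, with matched pairs."""
    n, m = len(a), len(b)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if a[i] == b[j]:
                dp[i][j] = dp[i + 1][j + 1] + 1
            else:
                dp[i][j] = max(dp[i + 1][j], dp[i][j + 1])
    pairs = []
    i = j = 0
    while i < n and j < m:
        if a[i] == b[j]:
            pairs.append((i, j))
            i += 1
            j += 1
        elif dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return dp[0][0], pairs


def _window_fallback(
    ref_window: tuple[str, ...],
    side: str,
    contigs: list[tuple[str, list[str]]],
    window: int,
    window_min_match: int,
) -> list[tuple[str, int]]:
    """Resolve a flank through the 10-gene reference window rule.

    Slides a ``window``-gene frame over each eligible contig and scores it by
    in-order cluster LCS against the reference window (both orientations);
    frames with at least ``window_min_match`` matches yield a resolved flank
    position: the genome gene matched to the innermost reference-window gene,
    or its extrapolated position when the innermost gene itself is absent.
    """
    inner_pos = len(ref_window) - 1 if side == "left" else 0
    window_set = set(ref_window)
    candidates: dict[tuple[str, int], None] = {}
    for contig_id, clusters in contigs:
        n = len(clusters)
        span = min(window, n)
        # only frames overlapping an occurrence of a window cluster can score
        starts: set[int] = set()
        for q, c in enumerate(clusters):
            if c in window_set:
                starts.update(range(max(0, q - span + 1), min(q, n - span) + 1))
        for s in sorted(starts):
            frame = tuple(clusters[s : s + span])
            for orient in ("forward", "flipped"):
                ref = ref_window if orient == "forward" else tuple(reversed(ref_window))
                count, pairs = _lcs_matches(ref, frame)
                if count < window_min_match:
                    continue
                target = inner_pos if orient == "forward" else len(ref_window) - 1 - inner_pos
                matched = {wi: s + fj for wi, fj in pairs}
                if target in matched:
                    est = matched[target]
                else:
                    # innermost window gene deleted: extrapolate from the
                    # nearest matched one, assuming locally colinear order
                    wi, fj = min(pairs, key=lambda p: abs(p[0] - target))
                    est = s + fj + (target - wi)
                est = max(0, min(n - 1, est))
                candidates[(contig_id, est)] = None
    return sorted(candidates)


def classify_occupancy(
    hotspot: Hotspot,
    genome: Genome,
    window: int = 10,
    window_min_match: int = 5,
    min_contig_genes: int = 20,
    max_island_genes: int = 200,
    empty_max: int = 3,
) -> OccupancyRecord:
    """Classify one (hotspot, genome) pair as occupied / empty / not found.

    Implements, in order: the >20-gene contig filter; direct lookup of the two
    reference flanking clusters; the 10-gene window fallback (>=5 in-order
    matches) when a flank is absent or multi-copy; closest-pair selection among
    candidate flank pairs; the same-contig requirement; and the interval-size
    rules (<=3 genes empty, <=200 occupied, larger not found).
    """
    contigs = [
        (cid, [g.cluster_id for g in genes])
        for cid, genes in genome.contigs.items()
        if len(genes) > min_contig_genes
    ]
    if not contigs:
        return OccupancyRecord(genome.genome_id, hotspot.hotspot_id, "not_found",
                               exclusion_reason="short_contig")

    def resolve(cluster: str, ref_window: tuple[str, ...], side: str):
        direct = [
            (cid, i) for cid, clusters in contigs for i, c in enumerate(clusters) if c == cluster
        ]
        if len(direct) == 1:
            return direct
        fallback = _window_fallback(ref_window, side, contigs, window, window_min_match)
        if fallback:
            return fallback
        return direct  # multiple direct copies, window inconclusive: keep them

    left_cands = resolve(hotspot.ref_left_cluster, hotspot.left_window, "left")
    right_cands = resolve(hotspot.ref_right_cluster, hotspot.right_window, "right")
    if not left_cands or not right_cands:
        return OccupancyRecord(genome.genome_id, hotspot.hotspot_id, "not_found",
                               exclusion_reason="flank_missing")

    pairs = []
    for lc, li in left_cands:
        for rc, ri in right_cands:
            if lc != rc:
                continue
            lo, hi = (li, ri) if li < ri else (ri, li)
            if lo == hi:
                continue
            pairs.append((hi - lo - 1, lc, lo, hi))
    if not pairs:
        return OccupancyRecord(genome.genome_id, hotspot.hotspot_id, "not_found",
                               exclusion_reason="different_contigs")
    n_between, contig_id, lo, hi = min(pairs)
    resolved = (contig_id, lo, hi)

    if n_between <= empty_max:
        return OccupancyRecord(genome.genome_id, hotspot.hotspot_id, "empty",
                               resolved_flank_indices=resolved)
    if n_between > max_island_genes:
        return OccupancyRecord(genome.genome_id, hotspot.hotspot_id, "not_found",
                               resolved_flank_indices=resolved,
                               exclusion_reason="oversize_island")
    genes = genome.contigs[contig_id]
    interior = tuple(genes[lo + 1 : hi])
    systems: set[str] = set()
    for g in interior:
        systems |= g.labels_in_namespace("defense")
    island = Island(
        genome_id=genome.genome_id,
        contig_id=contig_id,
        left_flank=genes[lo],
        right_flank=genes[hi],
        interior=interior,
        seed_systems=frozenset(systems),
    )
    return OccupancyRecord(genome.genome_id, hotspot.hotspot_id, "occupied",
                           resolved_flank_indices=resolved, island=island)


def occupancy_matrix(
    hotspots: list[Hotspot],
    genomes: list[Genome],
    **params,
) -> tuple[pd.DataFrame, dict[tuple[str, int], OccupancyRecord]]:
    """Classify every (hotspot, genome) pair; long-format status table + records."""
    records: dict[tuple[str, int], OccupancyRecord] = {}
    rows = []
    for hotspot in hotspots:
        for genome in genomes:
            rec = classify_occupancy(hotspot, genome, **params)
            records[(genome.genome_id, hotspot.hotspot_id)] = rec
            rows.append(
                {
                    "genome_id": genome.genome_id,
                    "hotspot_id": hotspot.hotspot_id,
                    "status": rec.status,
                    "exclusion_reason": rec.exclusion_reason or "",
                    "island_id": rec.island.island_id if rec.island else "",
                }
            )
    frame = pd.DataFrame(
        rows, columns=["genome_id", "hotspot_id", "status", "exclusion_reason", "island_id"]
    )
    return frame, records


def hotspots_to_frame(hotspots: list[Hotspot]) -> pd.DataFrame:
    rows = [
        {
            "hotspot_id": h.hotspot_id,
            "ref_contig": h.ref_contig,
            "ref_left_index": h.ref_left_index,
            "ref_right_index": h.ref_right_index,
            "ref_left_cluster": h.ref_left_cluster,
            "ref_right_cluster": h.ref_right_cluster,
            "n_member_islands": len(h.member_islands),
            "occupied_in_reference": h.occupied_in_reference,
        }
        for h in hotspots
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "hotspot_id", "ref_contig", "ref_left_index", "ref_right_index",
            "ref_left_cluster", "ref_right_cluster", "n_member_islands", "occupied_in_reference",
        ],
    )
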