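"""Merging defense-system calls from two annotation sources.

Two annotation tools (sources A and B) each emit per-context calls: a system
type plus the gene indices it spans. Merging (1) discards source-B calls whose
type ends in ``_other`` (partial or split systems), (2) unions overlapping
same-type calls into one merged system, (3) keeps-and-flags overlapping calls
of *different* types for review instead of auto-resolving them, and (4) passes
non-overlapping calls through. Overlap means sharing at least one gene index.

Downstream summaries: the co-localization fraction (systems sharing an island
with at least one other system), the system x hotspot count matrix, and the
per-genome defense repertoire of finished genomes (occupied hotspots,
defensively occupied hotspots, and the fraction of all systems that fall
inside occupied hotspot intervals).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

import pandas as pd

from .hotspot_mapper import OccupancyRecord
from .pangenome_io import Genome


@dataclass(frozen=True)
class DefenseSystemCall:
    context_id: str  # "<genome_id>:<contig_id>"
    system_type: str
    gene_indices: frozenset[int]
    source: str = "merged"  # A, B or merged
    flag_review: bool = False

    def __post_init__(self) -> None:
        if not self.gene_indices:
            raise ValueError("a defense-system call must cover at least one gene")

    @property
    def genome_id(self) -> str:
        return self.context_id.split(":", 1)[0]

    @property
    def contig_id(self) -> str:
        return self.context_id.split(":", 1)[1]


def calls_from_frame(df: pd.DataFrame, source: str) -> list[DefenseSystemCall]:
    """Parse a call table (context_id, system_type, gene_indices CSV)."""
    calls = []
    for _, row in df.iterrows():
        indices = frozenset(int(x) for x in str(row["gene_indices"]).split(",") if x != "")
        calls.append(
            DefenseSystemCall(
                context_id=str(row["context_id"]),
                system_type=str(row["system_type"]),
                gene_indices=indices,
                source=source,
            )
        )
    return calls


def merge_defense_calls(
    calls_a: list[DefenseSystemCall], calls_b: list[DefenseSystemCall]
) -> list[DefenseSystemCall]:
    """Consolidate two call sets into one merged list (order-independent)."""
    survivors = list(calls_a) + [
        c for c in calls_b if not c.system_type.endswith("_other")
    ]

    # Union-find over same-(context, type) calls sharing a gene index.
    by_key: dict[tuple[str, str], list[DefenseSystemCall]] = {}
    for c in survivors:
        by_key.setdefault((c.context_id, c.system_type), []).append(c)

    merged: list[DefenseSystemCall] = []
    for (context, stype), group in by_key.items():
        group = sorted(group, key=lambda c: (min(c.gene_indices), c.source))
        components: list[tuple[set[int], set[str]]] = []  # (indices, sources)
        for c in group:
            touching = [comp for comp in components if comp[0] & c.gene_indices]
            fresh: tuple[set[int], set[str]] = (set(c.gene_indices), {c.source})
            for comp in touching:
                fresh = (fresh[0] | comp[0], fresh[1] | comp[1])
                components.remove(comp)
            components.append(fresh)
        for indices, sources in components:
            merged.append(
                DefenseSystemCall(
                    context_id=context,
                    system_type=stype,
                    gene_indices=frozenset(indices),
                    source="merged" if len(sources) > 1 else next(iter(sources)),
                )
            )

    # Cross-type overlaps are kept but flagged for review.
    flagged: set[int] = set()
    by_context: dict[str, list[int]] = {}
    for i, c in enumerate(merged):
        by_context.setdefault(c.context_id, []).append(i)
    for indices in by_context.values():
        for ai in range(len(indices)):
            for bi in range(ai + 1, len(indices)):
                ca, cb = merged[indices[ai]], merged[indices[bi]]
                if ca.system_type != cb.system_type and ca.gene_indices & cb.gene_indices:
                    flagged.add(indices[ai])
                    flagged.add(indices[bi])
    out = [
        replace(c, flag_review=True) if i in flagged else c for i, c in enumerate(merged)
    ]
    return sorted(out, key=lambda c: (c.context_id, c.system_type, min(c.gene_indices)))


def assign_calls_to_islands(
    calls: list[DefenseSystemCall],
    occupancy: dict[tuple[str, int], OccupancyRecord],
) -> dict[str, list[DefenseSystemCall]]:
    """Map merged calls into the occupied hotspot islands that contain them.

    A call belongs to an island iff its context matches the island's genome
    and contig and every gene index lies strictly between the island's
    resolved flanks.
    """
    intervals: list[tuple[str, str, int, int, str]] = []
    for (genome_id, _h), rec in occupancy.items():
        if rec.status == "occupied" and rec.island is not None:
            contig, lo, hi = rec.resolved_flank_indices
            intervals.append((genome_id, contig, lo, hi, rec.island.island_id))
    by_island: dict[str, list[DefenseSystemCall]] = {}
    for c in calls:
        for genome_id, contig, lo, hi, island_id in intervals:
            if c.genome_id == genome_id and c.contig_id == contig:
                if all(lo < i < hi for i in c.gene_indices):
                    by_island.setdefault(island_id, []).append(c)
                    break
    return by_island


def colocalization_stats(
    calls_by_island: dict[str, list[DefenseSystemCall]]
) -> tuple[float, pd.DataFrame]:
    """Fraction of systems sharing an island with >=1 other system.

    Returns the overall fraction plus a per-island table of system counts.
    """
    n_total = 0
    n_coloc = 0
    rows = []
    for island_id, calls in sorted(calls_by_island.items()):
        k = len(calls)
        n_total += k
        if k >= 2:
            n_coloc += k
        rows.append({"island_id": island_id, "n_systems": k})
    fraction = n_coloc / n_total if n_total else 0.0
    return fraction, pd.DataFrame(rows, columns=["island_id", "n_systems"])


def hotspot_defense_matrix(
    calls_by_island: dict[str, list[DefenseSystemCall]],
    island_hotspot: dict[str, int],
) -> pd.DataFrame:
    """System-type x hotspot count matrix (long format, with per-hotspot diversity)."""
    counts: Counter[tuple[str, int]] = Counter()
    for island_id, calls in calls_by_island.items():
        h = island_hotspot[island_id]
        for c in calls:
            counts[(c.system_type, h)] += 1
    rows = [
        {"system_type": s, "hotspot_id": h, "n_occurrences": n}
        for (s, h), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["system_type", "hotspot_id", "n_occurrences"])


def hotspot_diversity(matrix: pd.DataFrame) -> pd.DataFrame:
    """Distinct defense-system types per hotspot."""
    if matrix.empty:
        return pd.DataFrame(columns=["hotspot_id", "n_system_types"])
    div = (
        matrix.groupby("hotspot_id")["system_type"].nunique().reset_index()
        .rename(columns={"system_type": "n_system_types"})
    )
    return div


def genome_defense_summary(
    genomes: list[Genome],
    occupancy: dict[tuple[str, int], OccupancyRecord],
    calls: list[DefenseSystemCall],
    finished_only: bool = True,
) -> pd.DataFrame:
    """Per-genome defense repertoire relative to the hotspot map.

    For each (finished) genome: the number of hotspots occupied, the number
    of those whose island carries at least one system ("defensively
    occupied"), the total number of systems called on the genome, and the
    fraction of those systems lying inside occupied hotspot intervals.
    """
    calls_by_genome: dict[str, list[DefenseSystemCall]] = {}
    for c in calls:
        calls_by_genome.setdefault(c.genome_id, []).append(c)

    rows = []
    for genome in genomes:
        if finished_only and not genome.is_finished:
            continue
        gid = genome.genome_id
        occupied = [
            rec
            for (g, _h), rec in occupancy.items()
            if g == gid and rec.status == "occupied"
        ]
        my_calls = calls_by_genome.get(gid, [])

        def in_interval(call, rec):
            contig, lo, hi = rec.resolved_flank_indices
            return call.contig_id == contig and all(lo < i < hi for i in call.gene_indices)

        defensively = sum(
            1 for rec in occupied if any(in_interval(c, rec) for c in my_calls)
        )
        at_hotspot = sum(
            1 for c in my_calls if any(in_interval(c, rec) for rec in occupied)
        )
        rows.append(
            {
                "genome_id": gid,
                "n_occupied_hotspots": len(occupied),
                "n_defensively_occupied": defensively,
                "n_systems": len(my_calls),
                "systems_at_hotspots_fraction": at_hotspot / len(my_calls) if my_calls else 0.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id", "n_occupied_hotspots", "n_defensively_occupied",
            "n_systems", "systems_at_hotspots_fraction",
        ],
    )


def merged_to_frame(calls: list[DefenseSystemCall]) -> pd.DataFrame:
    rows = [
        {
            "context_id": c.context_id,
            "system_type": c.system_type,
            "gene_indices": ",".join(str(i) for i in sorted(c.gene_indices)),
            "source": c.source,
            "flag_review": c.flag_review,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["context_id", "system_type", "gene_indices", "source", "flag_review"]
    )
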