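"""Synthetic pan-genomes with planted integration hotspots and ground truth.

The generator emulates the structure the pipeline assumes in real data: a
conserved-order core backbone shared by the whole cohort, discrete intergenic
integration hotspots, mobile-genetic-element (MGE) templates carrying defense
systems at dedicated cargo slots, per-hotspot occupancy probabilities, core
gene loss, accessory noise genes, contig fragmentation and annotation false
negatives. Every planted island is recorded in a ground-truth ledger so that
hotspot discovery, occupancy classification, island deduplication, MGE typing
and defense-repertoire summaries can all be scored against known answers.

It does not model nucleotide sequences, recombination or phylogeny: genomes
are ordered gene-cluster sequences, which is the only substrate the pipeline
operates on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .pangenome_io import GeneRecord, Genome

# Gene length in bp used for ordinary genes; "short hypothetical" genes in
# GInt-like elements get SHORT_GENE_BP (below the 300 bp shortness cutoff).
GENE_BP = 900
SHORT_GENE_BP = 200
INTERGENIC_BP = 100

#: Default defense repertoire: system name -> (number of genes, sampling weight).
DEFAULT_DEFENSE_REPERTOIRE: dict[str, tuple[int, float]] = {
    "RM_typeI": (3, 3.0),
    "RM_typeII": (2, 3.0),
    "Gabija": (2, 2.0),
    "CBASS": (4, 2.0),
    "Zorya": (4, 1.5),
    "Septu": (2, 1.5),
    "Thoeris": (3, 1.5),
    "Hachiman": (2, 1.5),
    "Lamassu": (2, 1.0),
    "Druantia": (5, 1.0),
    "Wadjet": (4, 1.0),
    "Kiwa": (2, 1.0),
    "Shedu": (1, 1.0),
    "retron": (2, 1.5),
    "BREX": (6, 1.0),
    "AbiEii": (1, 1.0),
    "Dodola": (2, 0.5),
    "Menshen": (3, 0.5),
    "Olokun": (2, 0.5),
    "DISARM": (5, 0.5),
}


class SimConfigError(ValueError):
    """The simulation configuration is internally inconsistent or infeasible."""


@dataclass(frozen=True)
class MGETemplate:
    """A mobile-element blueprint: a fixed gene backbone plus cargo slots.

    ``backbone`` is an ordered list of ``(cluster_id, labels)`` pairs;
    ``cargo_slots`` are backbone positions after which sampled defense systems
    are inserted (slots are used round-robin). ``allowed_hotspots`` restricts
    which hotspots the template integrates at ("any" = no restriction),
    mirroring the observed per-MGE-type integration-site preferences.
    """

    name: str
    mge_type: str
    backbone: tuple[tuple[str, frozenset[str]], ...]
    cargo_slots: tuple[int, ...]
    cargo_range: tuple[int, int] = (1, 3)
    allowed_hotspots: tuple[int, ...] | str = "any"
    short_gene_clusters: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.backbone:
            raise SimConfigError(f"template {self.name}: empty backbone")
        if not all(0 <= s <= len(self.backbone) for s in self.cargo_slots):
            raise SimConfigError(f"template {self.name}: cargo slot out of range")
        lo, hi = self.cargo_range
        if lo < 0 or hi < lo:
            raise SimConfigError(f"template {self.name}: bad cargo_range {self.cargo_range}")
        n_int = sum(
            1 for _, labels in self.backbone if "integrase" in labels or "recombinase" in labels
        )
        if self.mge_type == "GInt":
            n_short = sum(1 for _, labels in self.backbone if "short_hypothetical" in labels)
            if n_int != 3 or n_short != 1:
                raise SimConfigError(
                    f"GInt template {self.name} must contain exactly three integrase genes "
                    f"and one short hypothetical gene (got {n_int} integrases, {n_short} short)"
                )
        if self.mge_type == "prophage":
            names: dict[str, int] = {}
            for _, labels in self.backbone:
                for lab in labels:
                    if lab.startswith("phage:"):
                        names[lab] = names.get(lab, 0) + 1
            if not names or max(names.values()) < 2:
                raise SimConfigError(
                    f"prophage template {self.name} needs >=2 genes sharing a phage:<name> label"
                )
        if self.mge_type == "IME":
            conj = {
                lab.split(":", 1)[1]
                for _, labels in self.backbone
                for lab in labels
                if lab.startswith("conjugation:")
            }
            if "relaxase" in conj or not {"virb5", "virb6"} <= conj:
                raise SimConfigError(
                    f"IME template {self.name} must carry virB5+virB6 without a relaxase"
                )

    def allows(self, hotspot: int) -> bool:
        return self.allowed_hotspots == "any" or hotspot in self.allowed_hotspots


def _tpl(name, mge_type, genes, cargo_slots, cargo_range, allowed="any"):
    backbone = tuple((f"MGE_{name}_{i:02d}", frozenset(labels)) for i, labels in enumerate(genes))
    short = frozenset(
        f"MGE_{name}_{i:02d}" for i, labels in enumerate(genes) if "short_hypothetical" in labels
    )
    return MGETemplate(
        name=name,
        mge_type=mge_type,
        backbone=backbone,
        cargo_slots=tuple(cargo_slots),
        cargo_range=tuple(cargo_range),
        allowed_hotspots=allowed if allowed == "any" else tuple(allowed),
        short_gene_clusters=short,
    )


def default_templates() -> list[MGETemplate]:
    """The default MGE template set: one blueprint per element category.

    Backbones are >=10 genes so every planted island clears the 10-gene
    discovery filter even with a single one-gene cargo system.
    """
    P = "phage:FelsduoSim"
    Q = "phage:LambdoSim"
    return [
        _tpl(
            "FelsduoSim",
            "prophage",
            [{ "integrase", P }, {P}, {P}, {P}, {P}, {P}, {P}, {P}, {P}, {P}, {"hypothetical"}, {P}, {P}, {P}],
            cargo_slots=[5, 9],
            cargo_range=(1, 3),
            allowed=[8],
        ),
        _tpl(
            "LambdoSim",
            "prophage",
            [{ "integrase", Q }, {Q}, {Q}, {Q}, {Q}, {"hypothetical"}, {Q}, {Q}, {Q}, {Q}, {Q}, {Q}, {Q}, {Q}, {Q}, {Q}, {Q}, {Q}],
            cargo_slots=[6, 12],
            cargo_range=(1, 4),
        ),
        _tpl(
            "P4Sim",
            "satellite",
            [
                {"integrase"},
                {"satellite:P4_typeA"},
                {"satellite:P4_typeA"},
                {"hypothetical"},
                set(),
                set(),
                {"hypothetical"},
                set(),
                set(),
                set(),
            ],
            cargo_slots=[4, 7],
            cargo_range=(1, 2),
        ),
        _tpl(
            "ICESim",
            "ICE",
            [
                {"integrase"},
                {"conjugation:relaxase"},
                {"conjugation:t4cp"},
                {"conjugation:virb4"},
                {"conjugation:virb5"},
                {"conjugation:virb6"},
                set(),
                set(),
                {"hypothetical"},
                set(),
                set(),
                set(),
                {"hypothetical"},
                set(),
                set(),
                set(),
                set(),
                set(),
                set(),
                set(),
            ],
            cargo_slots=[8, 14],
            cargo_range=(1, 5),
        ),
        _tpl(
            "IMESim",
            "IME",
            [
                {"integrase"},
                {"conjugation:virb5"},
                {"conjugation:virb6"},
                {"hypothetical"},
                set(),
                set(),
                set(),
                {"hypothetical"},
                set(),
                set(),
                set(),
            ],
            cargo_slots=[5, 8],
            cargo_range=(1, 3),
        ),
        _tpl(
            "Tn7Sim",
            "Tn7",
            [
                {"transposon:tnsA"},
                {"transposon:tnsB"},
                {"transposon:tnsC"},
                {"transposon:tnsD"},
                {"transposon:tniQ"},
                set(),
                {"hypothetical"},
                set(),
                set(),
                set(),
                set(),
                set(),
            ],
            cargo_slots=[6, 9],
            cargo_range=(1, 4),
            allowed=[2],
        ),
        _tpl(
            "GIntSim",
            "GInt",
            [
                {"integrase", "gint_integrase_homolog"},
                {"integrase"},
                {"integrase"},
                {"short_hypothetical"},
                {"hypothetical"},
                set(),
                set(),
                set(),
                {"hypothetical"},
                set(),
                set(),
            ],
            cargo_slots=[6, 9],
            cargo_range=(1, 3),
        ),
        _tpl(
            "IntOnlySim",
            "integrase_only",
            [
                {"integrase"},
                {"hypothetical"},
                set(),
                set(),
                {"hypothetical"},
                set(),
                set(),
                set(),
                set(),
                set(),
            ],
            cargo_slots=[4, 7],
            cargo_range=(1, 3),
        ),
        _tpl(
            "PutTnSim",
            "putative_transposon",
            [
                {"integrase"},
                {"recombinase"},
                {"hypothetical"},
                set(),
                set(),
                set(),
                {"hypothetical"},
                set(),
                set(),
                set(),
            ],
            cargo_slots=[4, 7],
            cargo_range=(1, 3),
        ),
    ]


_DEFAULT_OCCUPANCY = (0.10, 0.15, 0.08, 0.20, 0.12, 0.25, 0.18, 0.10, 0.30, 0.15, 0.22, 0.97)


@dataclass
class SimConfig:
    """Study conditions for a synthetic cohort.

    Defaults describe a noise-free cohort of 150 genomes with 12 hotspots, the
    last of which is a high-occupancy (0.97) "mega-hotspot" open to every MGE
    template and the full defense repertoire. ``hotspot_positions`` are core
    backbone slots: position ``p`` means islands insert between core genes
    ``p`` and ``p+1``.
    """

    n_genomes: int = 150
    n_core: int = 4000
    n_hotspots: int = 12
    hotspot_positions: tuple[int, ...] | None = None
    occupancy_prob: tuple[float, ...] = _DEFAULT_OCCUPANCY
    mge_templates: list[MGETemplate] = field(default_factory=default_templates)
    core_loss_rate: float = 0.0
    accessory_noise_rate: float = 0.0
    fragmentation: float = 1.0
    annotation_fn_rate: float = 0.0
    defense_repertoire: dict[str, tuple[int, float]] = field(
        default_factory=lambda: dict(DEFAULT_DEFENSE_REPERTOIRE)
    )
    reference_occupied_hotspots: tuple[int, ...] = ()
    allow_cut_in_island: bool = False
    seed: int = 17

    def __post_init__(self) -> None:
        if self.hotspot_positions is None:
            # keep a margin from the chromosome ends so every hotspot has a
            # full flanking-window context on both sides
            margin = min(50, max(1, self.n_core // 10))
            step = (self.n_core - 2 * margin) // max(self.n_hotspots, 1)
            if step < 2:
                raise SimConfigError("more hotspots than available intergenic slots")
            self.hotspot_positions = tuple(margin + i * step for i in range(self.n_hotspots))
        self.hotspot_positions = tuple(self.hotspot_positions)
        if len(self.hotspot_positions) != self.n_hotspots:
            raise SimConfigError("hotspot_positions length must equal n_hotspots")
        if len(set(self.hotspot_positions)) != self.n_hotspots:
            raise SimConfigError("hotspot positions must be distinct")
        if any(not (0 <= p < self.n_core - 1) for p in self.hotspot_positions):
            raise SimConfigError("hotspot position outside the core backbone")
        if len(self.occupancy_prob) != self.n_hotspots:
            raise SimConfigError("occupancy_prob length must equal n_hotspots")
        if any(not (0.0 <= p <= 1.0) for p in self.occupancy_prob):
            raise SimConfigError("occupancy probabilities must lie in [0, 1]")
        if not self.mge_templates:
            raise SimConfigError("at least one MGE template is required")
        if not (0.0 <= self.core_loss_rate < 1.0):
            raise SimConfigError("core_loss_rate must lie in [0, 1)")
        if not (0.0 <= self.annotation_fn_rate < 1.0):
            raise SimConfigError("annotation_fn_rate must lie in [0, 1)")
        if self.accessory_noise_rate < 0:
            raise SimConfigError("accessory_noise_rate must be >= 0")
        if self.fragmentation < 1:
            raise SimConfigError("fragmentation (mean contigs per genome) must be >= 1")
        for h in self.hotspot_positions:
            if not any(t.allows(self.hotspot_positions.index(h)) for t in self.mge_templates):
                raise SimConfigError(f"no template allows hotspot at position {h}")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "mge_templates" in raw:
            raise SimConfigError("custom templates are constructed in code, not YAML")
        if "defense_repertoire" in raw:
            raw["defense_repertoire"] = {
                k: tuple(v) for k, v in raw["defense_repertoire"].items()
            }
        for key in ("hotspot_positions", "occupancy_prob", "reference_occupied_hotspots"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def manifest(self) -> dict:
        return {
            "n_genomes": self.n_genomes,
            "n_core": self.n_core,
            "n_hotspots": self.n_hotspots,
            "hotspot_positions": list(self.hotspot_positions),
            "occupancy_prob": list(self.occupancy_prob),
            "templates": [t.name for t in self.mge_templates],
            "core_loss_rate": self.core_loss_rate,
            "accessory_noise_rate": self.accessory_noise_rate,
            "fragmentation": self.fragmentation,
            "annotation_fn_rate": self.annotation_fn_rate,
            "reference_occupied_hotspots": list(self.reference_occupied_hotspots),
            "seed": self.seed,
        }


@dataclass(frozen=True)
class PlantedIsland:
    genome_id: str
    hotspot: int
    contig_id: str
    interior_start: int  # final per-contig gene index of first interior gene
    interior_end: int    # final index of last interior gene (inclusive)
    template_name: str
    mge_type: str
    systems: tuple[tuple[str, tuple[int, ...]], ...]  # (system, final gene indices)


@dataclass
class GroundTruth:
    """Planted truth for one synthetic cohort: the oracle for every stage."""

    config: SimConfig
    statuses: dict[tuple[str, int], str]          # (genome_id, hotspot) -> occupied/empty
    islands: list[PlantedIsland]
    hotspot_flanks: list[tuple[str, str]]         # per hotspot: (left core, right core)

    def status_frame(self) -> pd.DataFrame:
        rows = [
            {"genome_id": g, "hotspot": h, "status": s,
             }
            for (g, h), s in sorted(self.statuses.items())
        ]
        return pd.DataFrame(rows, columns=["genome_id", "hotspot", "status"])

    def island_frame(self) -> pd.DataFrame:
        rows = [
            {
                "genome_id": isl.genome_id,
                "hotspot": isl.hotspot,
                "contig_id": isl.contig_id,
                "interior_start": isl.interior_start,
                "interior_end": isl.interior_end,
                "template": isl.template_name,
                "mge_type": isl.mge_type,
                "systems": ";".join(name for name, _ in isl.systems),
            }
            for isl in self.islands
        ]
        return pd.DataFrame(
            rows,
            columns=["genome_id", "hotspot", "contig_id", "interior_start",
                     "interior_end", "template", "mge_type", "systems"],
        )

    def write(self, path) -> None:
        self.island_frame().to_csv(path, sep="\t", index=False)


def core_cluster(i: int) -> str:
    return f"CORE_{i:04d}"


def _sample_cargo(rng: np.random.Generator, template: MGETemplate, repertoire) -> list[str]:
    names = sorted(repertoire)
    weights = np.array([repertoire[n][1] for n in names], dtype=float)
    weights /= weights.sum()
    lo, hi = template.cargo_range
    n = int(rng.integers(lo, hi + 1))
    n = min(n, len(names))
    if n == 0:
        return []
    picked = rng.choice(len(names), size=n, replace=False, p=weights)
    return [names[i] for i in sorted(picked)]


def _island_genes(rng, template: MGETemplate, repertoire, hotspot: int):
    """Materialize one island instance: backbone plus sampled defense cargo."""
    systems = _sample_cargo(rng, template, repertoire)
    slots = list(template.cargo_slots) or [len(template.backbone)]
    inserts: dict[int, list] = {s: [] for s in slots}
    for i, name in enumerate(systems):
        slot = slots[i % len(slots)]
        n_genes = repertoire[name][0]
        for k in range(n_genes):
            inserts[slot].append(
                {
                    "cluster": f"DEF_{name}_{k}",
                    "labels": {f"defense:{name}"},
                    "system": name,
                    "bp": GENE_BP,
                }
            )
    genes = []
    for pos, (cluster, labels) in enumerate(template.backbone):
        genes.append(
            {
                "cluster": cluster,
                "labels": set(labels),
                "system": None,
                "bp": SHORT_GENE_BP if cluster in template.short_gene_clusters else GENE_BP,
            }
        )
        if pos + 1 in inserts:
            genes.extend(inserts[pos + 1])
    if 0 in inserts:
        genes = inserts[0] + genes
    return genes, systems


def generate_pangenome(config: SimConfig) -> tuple[list[Genome], GroundTruth]:
    """Generate a synthetic cohort and its ground-truth ledger.

    Genome ``G000`` is the designated reference; it is occupied only at the
    hotspots listed in ``config.reference_occupied_hotspots``. Every hotspot
    is guaranteed to be unoccupied in at least one genome, so the flanking
    genes of every planted island are adjacent somewhere in the cohort (the
    mobility criterion holds by construction). Fully deterministic given the
    config, including its seed.
    """
    rng = np.random.default_rng(config.seed)
    # separate stream for annotation dropout so the false-negative rate never
    # perturbs genome composition
    label_rng = np.random.default_rng((config.seed, 1))
    n, H = config.n_genomes, config.n_hotspots

    # Hotspot-major occupancy sampling, reference forced, then the guarantee:
    # flip the lowest-index occupied non-reference genome to empty if needed.
    occupied = np.zeros((n, H), dtype=bool)
    for h in range(H):
        occupied[:, h] = rng.random(n) < config.occupancy_prob[h]
        occupied[0, h] = h in config.reference_occupied_hotspots
        if occupied[:, h].all():
            occupied[int(np.argmax(occupied[1:, h])) + 1, h] = False

    slot_to_hotspot = {p: h for h, p in enumerate(config.hotspot_positions)}
    hotspot_flanks = [
        (core_cluster(p), core_cluster(p + 1)) for p in config.hotspot_positions
    ]

    genomes: list[Genome] = []
    statuses: dict[tuple[str, int], str] = {}
    planted: list[PlantedIsland] = []

    for g in range(n):
        genome_id = f"G{g:03d}"
        seq = []  # dicts: cluster, labels, system, bp, island (hotspot idx or None), sys_uid
        island_meta: dict[int, dict] = {}  # hotspot -> template/systems for this genome

        # Accessory noise positions: core slots >=2 away from any hotspot slot.
        n_noise = int(rng.poisson(config.accessory_noise_rate)) if config.accessory_noise_rate else 0
        eligible = [
            p
            for p in range(config.n_core - 1)
            if all(abs(p - q) >= 2 for q in config.hotspot_positions)
        ]
        noise_at: dict[int, int] = {}
        if n_noise:
            for j, p in enumerate(rng.choice(eligible, size=min(n_noise, len(eligible)), replace=False)):
                noise_at[int(p)] = j

        for p in range(config.n_core):
            if config.core_loss_rate == 0 or rng.random() >= config.core_loss_rate:
                seq.append(
                    {"cluster": core_cluster(p), "labels": set(), "system": None,
                     "bp": GENE_BP, "island": None, "sysid": None}
                )
            if p in noise_at:
                seq.append(
                    {"cluster": f"NOISE_{genome_id}_{noise_at[p]}", "labels": {"hypothetical"},
                     "system": None, "bp": GENE_BP, "island": None, "sysid": None}
                )
            h = slot_to_hotspot.get(p)
            if h is not None:
                if occupied[g, h]:
                    allowed = [t for t in config.mge_templates if t.allows(h)]
                    template = allowed[int(rng.integers(len(allowed)))]
                    genes, systems = _island_genes(rng, template, config.defense_repertoire, h)
                    for gene in genes:
                        seq.append({**gene, "island": h,
                                    "sysid": (h, gene["system"]) if gene["system"] else None})
                    island_meta[h] = {"template": template, "systems": systems}
                    statuses[(genome_id, h)] = "occupied"
                else:
                    statuses[(genome_id, h)] = "empty"

        # Fragmentation: cuts at gaps, never inside a planted island by default.
        # The reference (genome 0) stays unfragmented: it emulates a finished
        # reference assembly.
        n_contigs = 1
        if config.fragmentation > 1 and g > 0:
            n_contigs = max(1, int(rng.poisson(config.fragmentation - 1)) + 1)
        cut_points: list[int] = []
        if n_contigs > 1:
            gaps = [
                i + 1
                for i in range(len(seq) - 1)
                if config.allow_cut_in_island
                or (seq[i]["island"] is None and seq[i + 1]["island"] is None)
            ]
            k = min(n_contigs - 1, len(gaps))
            if k:
                cut_points = sorted(int(x) for x in rng.choice(gaps, size=k, replace=False))

        bounds = [0, *cut_points, len(seq)]
        genome = Genome(genome_id=genome_id)
        sys_positions: dict[tuple[int, str], list[tuple[str, int]]] = {}
        island_extent: dict[int, tuple[str, int, int]] = {}
        for c, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
            contig_id = f"{genome_id}_c{c:02d}"
            genes: list[GeneRecord] = []
            bp_cursor = 1
            for i, entry in enumerate(seq[lo:hi]):
                labels = set(entry["labels"])
                if config.annotation_fn_rate and labels:
                    labels = {
                        lab for lab in sorted(labels)
                        if label_rng.random() >= config.annotation_fn_rate
                    }
                genes.append(
                    GeneRecord(
                        genome_id=genome_id,
                        contig_id=contig_id,
                        index=i,
                        strand="+",
                        cluster_id=entry["cluster"],
                        annotations=frozenset(labels),
                        start_bp=bp_cursor,
                        end_bp=bp_cursor + entry["bp"] - 1,
                    )
                )
                bp_cursor += entry["bp"] + INTERGENIC_BP
                h = entry["island"]
                if h is not None:
                    cur = island_extent.get(h)
                    island_extent[h] = (
                        contig_id,
                        i if cur is None or cur[0] != contig_id else cur[1],
                        i,
                    ) if cur is None or cur[0] == contig_id else cur
                    if entry["sysid"] is not None:
                        sys_positions.setdefault(entry["sysid"], []).append((contig_id, i))
            genome.contigs[contig_id] = genes
        genome.is_finished = genome.n_contigs == 1
        genome.validate()
        genomes.append(genome)

        for h, meta in island_meta.items():
            contig_id, start, end = island_extent[h]
            systems = tuple(
                (
                    name,
                    tuple(i for cid, i in sys_positions.get((h, name), ()) if cid == contig_id),
                )
                for name in meta["systems"]
            )
            planted.append(
                PlantedIsland(
                    genome_id=genome_id,
                    hotspot=h,
                    contig_id=contig_id,
                    interior_start=start,
                    interior_end=end,
                    template_name=meta["template"].name,
                    mge_type=meta["template"].mge_type,
                    systems=systems,
                )
            )

    truth = GroundTruth(
        config=config, statuses=statuses, islands=planted, hotspot_flanks=hotspot_flanks
    )
    return genomes, truth


def truth_summary(truth: GroundTruth) -> pd.DataFrame:
    """Per-hotspot planted occupancy fractions and defense-system counts."""
    n = truth.config.n_genomes
    rows = []
    for h in range(truth.config.n_hotspots):
        occ = sum(
            1 for (_, hh), s in truth.statuses.items() if hh == h and s == "occupied"
        )
        systems = sum(len(isl.systems) for isl in truth.islands if isl.hotspot == h)
        rows.append(
            {
                "hotspot": h,
                "n_occupied": occ,
                "occupancy_fraction": occ / n,
                "n_planted_systems": systems,
            }
        )
    return pd.DataFrame(rows, columns=["hotspot", "n_occupied", "occupancy_fraction", "n_planted_systems"])


def simulate_defense_calls(
    truth: GroundTruth,
    fn_rate_a: float = 0.0,
    fn_rate_b: float = 0.0,
    other_rate_b: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive two defense-call tables (sources A and B) from the planted truth.

    Emulates two annotation tools run independently: each misses a planted
    system at its own false-negative rate, and source B additionally emits
    partial "<type>_other" calls at ``other_rate_b`` (which downstream merging
    must discard).
    """
    rng = np.random.default_rng(seed)
    rows_a, rows_b = [], []
    for isl in truth.islands:
        for name, indices in isl.systems:
            if not indices:
                continue
            ctx = f"{isl.genome_id}:{isl.contig_id}"
            row = {
                "context_id": ctx,
                "system_type": name,
                "gene_indices": ",".join(str(i) for i in indices),
            }
            if rng.random() >= fn_rate_a:
                rows_a.append(dict(row))
            if rng.random() >= fn_rate_b:
                rows_b.append(dict(row))
            if other_rate_b and rng.random() < other_rate_b:
                rows_b.append(
                    {
                        "context_id": ctx,
                        "system_type": f"{name}_other",
                        "gene_indices": str(indices[0]),
                    }
                )
    cols = ["context_id", "system_type", "gene_indices"]
    return pd.DataFrame(rows_a, columns=cols), pd.DataFrame(rows_b, columns=cols)


def write_manifest(config: SimConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(config.manifest(), fh, indent=2, sort_keys=True)
        fh.write("\n")
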