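"""Deterministic MGE typing of islands from annotation labels.

Each island is assigned a mobile-genetic-element type by rules over the
namespaced annotation labels of its interior genes, encoding the decisions an
annotator would make from prophage, satellite, conjugation, transposon and
integrase evidence:

* prophage — more than one gene matching the same phage (``phage:<name>`` on
  >= 2 genes);
* P4-like / PICI satellites — ``satellite:P4_type{A,B,C}`` or
  ``satellite:PICI_type{A,B}`` labels; a satellite call overrides a prophage
  call that shares genes with it;
* ICE — a full conjugation module (relaxase + coupling protein + mating-pair
  ATPase by default); IME — a relaxase without the full module, or virB5+virB6
  without any relaxase (non-canonical relaxase-less IMEs);
* Tn7-like — a ``transposon:tniQ`` gene;
* GInt — a GInt-integrase homolog in a cassette of exactly three integrase
  genes plus a short hypothetical gene;
* putative transposon — multi-integrase cassettes that are neither Tn7 nor
  GInt; integrase-only — a single integrase/recombinase and nothing else.

Two or more distinct surviving base types make the island ``multiple``; no
evidence at all makes it ``none``. Classification is a pure function of one
island's labels and gene order.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .core_islands import Island

logger = logging.getLogger(__name__)

P4_TYPES = {"P4_typeA", "P4_typeB", "P4_typeC"}
PICI_TYPES = {"PICI_typeA", "PICI_typeB"}


@dataclass(frozen=True)
class MGERuleConfig:
    """Tunable label sets for the classification rules.

    ``ice_required`` is the conjugation-label set that counts as a full
    conjugative module (the exact requirement is annotation-tool internal, so
    it is configuration, not a fixed fact). ``short_gene_max_bp`` bounds the
    "short hypothetical gene" of the GInt organization when bp coordinates
    exist; without coordinates a ``short_hypothetical`` label is accepted.
    """

    ice_required: frozenset[str] = frozenset({"relaxase", "t4cp", "virb4"})
    short_gene_max_bp: int = 300


@dataclass(frozen=True)
class MGECall:
    island_id: str
    mge_type: str
    evidence: tuple[tuple[str, tuple[int, ...]], ...] = ()
    phage_name: str | None = None


def _is_short_hypothetical(gene, config: MGERuleConfig) -> bool:
    if "short_hypothetical" in gene.annotations:
        return True
    if gene.length_bp is not None and gene.length_bp <= config.short_gene_max_bp:
        return "hypothetical" in gene.annotations
    return False


def classify_mge(island: Island, config: MGERuleConfig = MGERuleConfig()) -> MGECall:
    """Type one island's MGE from its interior annotation labels."""
    genes = island.interior
    if not any(g.annotations for g in genes):
        logger.warning("island %s carries no annotation labels at all", island.island_id)
        return MGECall(island_id=island.island_id, mge_type="none")

    fired: dict[str, tuple[int, ...]] = {}

    # prophage: >1 gene matching the same phage name
    phage_counts: Counter[str] = Counter()
    phage_genes: dict[str, list[int]] = {}
    for g in genes:
        for name in g.labels_in_namespace("phage"):
            phage_counts[name] += 1
            phage_genes.setdefault(name, []).append(g.index)
    phage_name = None
    prophage_gene_set: set[int] = set()
    qualifying = sorted(
        (n for n, c in phage_counts.items() if c >= 2),
        key=lambda n: (-phage_counts[n], n),
    )
    if qualifying:
        phage_name = qualifying[0]
        for n in qualifying:
            prophage_gene_set.update(phage_genes[n])
        fired["prophage"] = tuple(sorted(prophage_gene_set))

    # satellites
    sat_p4 = [
        g.index for g in genes if g.labels_in_namespace("satellite") & P4_TYPES
    ]
    sat_pici = [
        g.index for g in genes if g.labels_in_namespace("satellite") & PICI_TYPES
    ]
    if sat_p4:
        fired["satellite_P4"] = tuple(sat_p4)
    if sat_pici:
        fired["satellite_PICI"] = tuple(sat_pici)
    # a satellite call sharing >=1 gene with the prophage evidence overrides it
    if "prophage" in fired and (set(sat_p4) | set(sat_pici)) & prophage_gene_set:
        del fired["prophage"]
        phage_name = None

    # conjugation machinery
    conj_genes: dict[str, list[int]] = {}
    for g in genes:
        for lab in g.labels_in_namespace("conjugation"):
            conj_genes.setdefault(lab.lower(), []).append(g.index)
    conj = set(conj_genes)
    if config.ice_required <= conj:
        fired["ICE"] = tuple(sorted(i for lab in sorted(conj) for i in conj_genes[lab]))
    elif "relaxase" in conj:
        fired["IME"] = tuple(sorted(i for lab in sorted(conj) for i in conj_genes[lab]))
    elif {"virb5", "virb6"} <= conj:
        fired["IME"] = tuple(sorted(conj_genes["virb5"] + conj_genes["virb6"]))

    # transposons
    tniq = [
        g.index for g in genes if {t.lower() for t in g.labels_in_namespace("transposon")} & {"tniq"}
    ]
    if tniq:
        fired["Tn7"] = tuple(tniq)

    integrases = [
        g.index for g in genes if "integrase" in g.annotations or "recombinase" in g.annotations
    ]
    gint_homologs = [g.index for g in genes if "gint_integrase_homolog" in g.annotations]
    short_hypos = [g.index for g in genes if _is_short_hypothetical(g, config)]
    if gint_homologs and len(integrases) == 3 and short_hypos:
        fired["GInt"] = tuple(sorted(set(integrases) | set(gint_homologs) | {short_hypos[0]}))
    elif len(integrases) >= 2 and "Tn7" not in fired:
        fired["putative_transposon"] = tuple(integrases)

    evidence = tuple(sorted(fired.items()))
    if len(fired) >= 2:
        return MGECall(island.island_id, "multiple", evidence, phage_name)
    if len(fired) == 1:
        mge_type = next(iter(fired))
        return MGECall(island.island_id, mge_type, evidence, phage_name)
    if len(integrases) == 1:
        return MGECall(
            island.island_id, "integrase_only", (("integrase_only", tuple(integrases)),)
        )
    return MGECall(island_id=island.island_id, mge_type="none")


def mge_summary(calls: list[MGECall], island_hotspot: dict[str, int]) -> pd.DataFrame:
    """Counts per (hotspot, MGE type) over representative-island calls."""
    counts: Counter[tuple[int, str]] = Counter()
    for call in calls:
        counts[(island_hotspot[call.island_id], call.mge_type)] += 1
    rows = [
        {"hotspot_id": h, "mge_type": t, "n_islands": n}
        for (h, t), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["hotspot_id", "mge_type", "n_islands"])


def calls_to_frame(calls: list[MGECall], island_hotspot: dict[str, int]) -> pd.DataFrame:
    rows = [
        {
            "island_id": c.island_id,
            "hotspot_id": island_hotspot.get(c.island_id, -1),
            "mge_type": c.mge_type,
            "phage_name": c.phage_name or "",
            "evidence": ";".join(
                f"{rule}:{','.join(str(i) for i in idx)}" for rule, idx in c.evidence
            ),
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["island_id", "hotspot_id", "mge_type", "phage_name", "evidence"]
    )
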