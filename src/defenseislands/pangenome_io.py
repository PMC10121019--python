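"""Gene-table IO, genome QC and the homolog-cluster catalog.

The universal substrate of the pipeline is a *gene table*: one row per gene
with genome, contig, gene-order index, optional bp coordinates, strand,
homolog-cluster ID and a set of namespaced annotation labels. Gene order
(0-based, per contig) is the primary coordinate; bp coordinates are optional
and informational, since every downstream rule is stated in gene counts.

Annotation labels use a small namespace vocabulary (``defense:<system>``,
``phage:<name>``, ``satellite:<type>``, ``conjugation:<gene>``,
``transposon:<gene>``, ``integrase``, ``recombinase``,
``gint_integrase_homolog``, ``short_hypothetical``, ``hypothetical``);
unknown namespaces are carried through opaquely so real annotation-tool
outputs can be mapped in without code changes.
"""

from __future__ import annotations

import logging
import urllib.parse
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

GENE_TABLE_COLUMNS = [
    "genome_id",
    "contig_id",
    "index",
    "start_bp",
    "end_bp",
    "strand",
    "cluster_id",
    "annotations",
]

_REQUIRED_COLUMNS = ["genome_id", "contig_id", "index", "strand", "cluster_id", "annotations"]


class GeneTableFormatError(ValueError):
    """A gene table violates the documented schema."""


class GeneTableIntegrityError(ValueError):
    """A gene table is schema-valid but internally inconsistent."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene: position in a genome plus cluster membership and labels.

    ``index`` is the 0-based gene order within the contig. ``start_bp`` /
    ``end_bp`` are 1-based inclusive coordinates when known, else ``None``.
    """

    genome_id: str
    contig_id: str
    index: int
    strand: str
    cluster_id: str
    annotations: frozenset[str] = frozenset()
    start_bp: int | None = None
    end_bp: int | None = None

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"negative gene index {self.index}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start_bp is not None and self.end_bp is not None and self.start_bp > self.end_bp:
            raise ValueError(f"start_bp {self.start_bp} > end_bp {self.end_bp}")

    @property
    def length_bp(self) -> int | None:
        if self.start_bp is None or self.end_bp is None:
            return None
        return self.end_bp - self.start_bp + 1

    def has_label(self, label: str) -> bool:
        return label in self.annotations

    def labels_in_namespace(self, namespace: str) -> set[str]:
        """Values of labels of the form ``namespace:value``."""
        prefix = namespace + ":"
        return {a[len(prefix):] for a in self.annotations if a.startswith(prefix)}


@dataclass
class Genome:
    """A genome as an ordered map contig_id -> ordered list of GeneRecord."""

    genome_id: str
    contigs: dict[str, list[GeneRecord]] = field(default_factory=dict)
    is_finished: bool = False

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def n_genes(self) -> int:
        return sum(len(g) for g in self.contigs.values())

    def genes(self):
        """Iterate over all genes in contig order."""
        for contig_genes in self.contigs.values():
            yield from contig_genes

    def cluster_set(self) -> set[str]:
        return {g.cluster_id for g in self.genes()}

    def validate(self) -> None:
        for contig_id, genes in self.contigs.items():
            for i, g in enumerate(genes):
                if g.genome_id != self.genome_id:
                    raise GeneTableIntegrityError(
                        f"gene in genome {self.genome_id} carries genome_id {g.genome_id}"
                    )
                if g.contig_id != contig_id:
                    raise GeneTableIntegrityError(
                        f"gene at {contig_id}[{i}] carries contig_id {g.contig_id}"
                    )
                if g.index != i:
                    raise GeneTableIntegrityError(
                        f"genome {self.genome_id} contig {contig_id}: index {g.index} at list "
                        f"position {i}; indices must be consecutive 0..n-1"
                    )


@dataclass
class ClusterCatalog:
    """Per-cluster genome prevalence and consensus annotation over a cohort.

    Presence is binary per genome: paralogs do not inflate prevalence, so
    ``prevalence`` is the fraction of genomes carrying at least one gene of
    the cluster.
    """

    n_genomes: int
    n_genomes_present: dict[str, int]
    consensus_annotations: dict[str, frozenset[str]]

    def prevalence(self, cluster_id: str) -> float:
        return self.n_genomes_present.get(cluster_id, 0) / self.n_genomes

    @property
    def cluster_ids(self) -> set[str]:
        return set(self.n_genomes_present)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cluster_id": cid,
                "n_genomes_present": n,
                "prevalence": n / self.n_genomes,
                "consensus_annotations": ";".join(sorted(self.consensus_annotations.get(cid, ()))),
            }
            for cid, n in sorted(self.n_genomes_present.items())
        ]
        return pd.DataFrame(rows, columns=["cluster_id", "n_genomes_present", "prevalence", "consensus_annotations"])


def _parse_annotations(raw) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return frozenset()
    raw = str(raw).strip()
    if not raw:
        return frozenset()
    return frozenset(part.strip() for part in raw.split(";") if part.strip())


def _genomes_from_rows(rows: pd.DataFrame) -> list[Genome]:
    genomes: list[Genome] = []
    for genome_id, gdf in rows.groupby("genome_id", sort=True):
        genome = Genome(genome_id=str(genome_id))
        for contig_id, cdf in gdf.groupby("contig_id", sort=True):
            # Rebuild indices from bp coordinates when present, else file order.
            if cdf["start_bp"].notna().all():
                cdf = cdf.sort_values("start_bp", kind="stable")
            else:
                cdf = cdf.sort_values("index", kind="stable")
            seen = set()
            for idx_orig in cdf["index"]:
                key = int(idx_orig)
                if key in seen:
                    raise GeneTableIntegrityError(
                        f"duplicate (genome, contig, index) = ({genome_id}, {contig_id}, {key})"
                    )
                seen.add(key)
            genes = []
            for i, (_, row) in enumerate(cdf.iterrows()):
                genes.append(
                    GeneRecord(
                        genome_id=str(genome_id),
                        contig_id=str(contig_id),
                        index=i,
                        strand=str(row["strand"]),
                        cluster_id=str(row["cluster_id"]),
                        annotations=_parse_annotations(row["annotations"]),
                        start_bp=None if pd.isna(row["start_bp"]) else int(row["start_bp"]),
                        end_bp=None if pd.isna(row["end_bp"]) else int(row["end_bp"]),
                    )
                )
            genome.contigs[str(contig_id)] = genes
        genome.validate()
        genomes.append(genome)
    return genomes


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "contig_id": str, "cluster_id": str})
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise GeneTableFormatError(f"gene table {path} is missing required column '{col}'")
    for col in ("start_bp", "end_bp"):
        if col not in df.columns:
            df[col] = pd.NA
    return df


def _read_gff3(path) -> pd.DataFrame:
    """Read CDS features from a GFF3 file carrying cluster_id= / annotations= attributes."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GeneTableFormatError(f"GFF3 line with {len(fields)} columns (expected 9): {line[:80]}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k.strip()] = urllib.parse.unquote(v.strip())
            if "cluster_id" not in attr_map:
                raise GeneTableFormatError(f"GFF3 CDS without cluster_id attribute: {line[:80]}")
            genome_id = attr_map.get("genome_id", seqid.split("__")[0])
            labels = frozenset(x.strip() for x in attr_map.get("annotations", "").split(",") if x.strip())
            rows.append(
                {
                    "genome_id": genome_id,
                    "contig_id": seqid,
                    "index": len(rows),
                    "start_bp": int(start),
                    "end_bp": int(end),
                    "strand": strand,
                    "cluster_id": attr_map["cluster_id"],
                    "annotations": ";".join(sorted(labels)),
                }
            )
    if not rows:
        return pd.DataFrame(columns=GENE_TABLE_COLUMNS)
    return pd.DataFrame(rows)


def read_gene_table(path, format: str = "tsv") -> list[Genome]:
    """Read a gene table into Genome objects.

    Per-contig gene indices are rebuilt from ascending start_bp when bp
    coordinates are present, otherwise from the stated index / file order.

    Parameters
    ----------
    path : str or Path
        Input file.
    format : {"tsv", "gff3"}
        Tab-delimited gene table (see module docstring) or GFF3 whose CDS
        features carry ``cluster_id=`` and ``annotations=`` attributes.
    """
    if format == "tsv":
        df = _read_tsv(path)
    elif format == "gff3":
        df = _read_gff3(path)
    else:
        raise ValueError(f"unknown gene-table format {format!r}")
    return _genomes_from_rows(df)


def genomes_to_frame(genomes: list[Genome]) -> pd.DataFrame:
    rows = []
    for genome in genomes:
        for g in genome.genes():
            rows.append(
                {
                    "genome_id": g.genome_id,
                    "contig_id": g.contig_id,
                    "index": g.index,
                    "start_bp": g.start_bp if g.start_bp is not None else pd.NA,
                    "end_bp": g.end_bp if g.end_bp is not None else pd.NA,
                    "strand": g.strand,
                    "cluster_id": g.cluster_id,
                    "annotations": ";".join(sorted(g.annotations)),
                }
            )
    return pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)


def write_gene_table(genomes: list[Genome], path) -> None:
    """Write genomes back to the TSV gene-table schema (round-trip identity)."""
    genomes_to_frame(genomes).to_csv(path, sep="\t", index=False)


def qc_genomes(genomes: list[Genome], max_contigs: int = 200) -> tuple[list[Genome], list[str]]:
    """Drop highly fragmented assemblies.

    A genome is kept iff its contig count is <= ``max_contigs`` (assemblies of
    *more than* 200 contigs are discarded under the default).
    """
    if max_contigs < 1:
        raise ValueError("max_contigs must be >= 1")
    if not genomes:
        logger.warning("qc_genomes called with an empty cohort")
        return [], []
    kept, dropped = [], []
    for genome in genomes:
        if genome.n_contigs <= max_contigs:
            kept.append(genome)
        else:
            dropped.append(genome.genome_id)
    if dropped:
        logger.info("qc_genomes dropped %d of %d genomes (> %d contigs)", len(dropped), len(genomes), max_contigs)
    return kept, dropped


def build_cluster_catalog(genomes: list[Genome]) -> ClusterCatalog:
    """Count per-cluster genome presence and pool annotation labels.

    Presence is binary per genome: a cluster seen five times in one genome
    contributes one to ``n_genomes_present``. Consensus annotations are the
    union of labels observed on any gene of the cluster across the cohort.
    """
    if not genomes:
        raise ValueError("cannot build a cluster catalog from zero genomes")
    n_present: dict[str, int] = {}
    labels: dict[str, set[str]] = {}
    for genome in genomes:
        seen: set[str] = set()
        for g in genome.genes():
            if g.cluster_id not in seen:
                seen.add(g.cluster_id)
                n_present[g.cluster_id] = n_present.get(g.cluster_id, 0) + 1
            if g.annotations:
                labels.setdefault(g.cluster_id, set()).update(g.annotations)
    return ClusterCatalog(
        n_genomes=len(genomes),
        n_genomes_present=n_present,
        consensus_annotations={c: frozenset(s) for c, s in labels.items()},
    )
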