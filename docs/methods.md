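# Methods

## Scope and data model

The pipeline discovers integration hotspots of defense-system-carrying mobile
genetic elements (MGEs) in a bacterial pan-genome and classifies per-genome
hotspot occupancy. It deliberately operates on **gene order and homolog
cluster identity only**: a genome is an ordered list of cluster IDs per
contig, each gene optionally carrying bp coordinates and namespaced
annotation labels. Clustering proteins into homolog families, and calling
defense systems, prophage genes, conjugation machinery etc., are *inputs* —
the table-level contracts let real annotation-tool outputs be mapped in
without code changes. Every rule in the analysis is stated in gene counts,
which is why bp coordinates are informational (they matter only for the
"short gene" criterion of the GInt rule).

## The analysis, stage by stage

**Genome QC.** Assemblies of more than `max_contigs` (default 200) contigs
are discarded as too fragmented for flank-based reasoning.

**Core genome.** A cluster is core iff present in strictly more than
`core_prevalence` (default 0.80) of QC-passing genomes. Presence is binary
per genome so paralog expansions cannot promote a cluster into the core.
The strict inequality matters at the boundary: a cluster in exactly 80% of
genomes is *not* core.

**Island delineation.** Every gene with a `defense:<system>` label seeds a
bidirectional walk that stops at the first core cluster on each side
(annotation labels are ignored during the walk; only cluster membership
counts). Contiguous genes of one system seed once, and islands sharing a
flank pair within a genome merge, so multi-gene systems and co-resident
systems yield one island. A walk that hits a contig end before a core gene
marks the island *unbounded*; unbounded islands are excluded from discovery
(they carry no usable flank) but counted in the stage log.

**Island filters.** Retained islands need (a) at least `min_island_genes`
(default 10) interior genes — flanks not counted — and (b) *mobility*: the
flank pair occurs on one contig with at most `adjacency_max` (default 3)
intervening genes in at least one cohort genome. The adjacency tolerance
reuses the empty-hotspot constant deliberately, keeping the discovery and
occupancy stages consistent about what "the element is absent here" means.

**Reference anchoring.** For each island, starting at each flank and moving
outward, the first window of `synteny_block` (default 5) consecutive genes
whose cluster sequence equals 5 consecutive reference genes — in order or
exactly reversed — anchors that side. Reversed matches are accepted because
contig orientation in draft assemblies is arbitrary; the orientation is
recorded, and mixed-orientation or cross-contig anchor pairs unmap the island
rather than guess. Among multiple consistent anchor pairs the smallest
reference span wins, ties broken forward-first then by coordinate.

**Hotspot merging.** Anchored islands whose reference intervals overlap form
one hotspot. Because a 5-gene block cannot match across a gene the reference
genome itself lacks, anchors can sit a few genes outside the true insertion
point; the group interval is therefore refined inward using the member
islands' own flank clusters located in the reference (innermost position
wins), falling back to the nearest core genes around the anchors. This is the
deterministic replacement for what would otherwise be per-hotspot manual
curation of flanking genes; a curation-override table (island id → forced
flank clusters) remains available for cases that genuinely need a human
decision. Hotspots are numbered 1..N along the reference, and an interval
whose interior exceeds `empty_max` genes is flagged occupied-in-reference.

**Occupancy classification.** Per (hotspot, genome), in order: only contigs
with strictly more than `min_contig_genes` (default 20) genes are considered;
the two reference flanking clusters are located directly; a flank that is
absent or multi-copy is resolved through the `window` (default 10) reference
genes on that side, scored by in-order longest-common-subsequence matches
against sliding genome frames, requiring at least `window_min_match` (default
5) matches — the resolved position is the genome gene matched to the
innermost window gene, extrapolated if that gene is deleted. Among candidate
flank pairs the one with the fewest intervening genes wins (ties: smallest
coordinate); both flanks must share a contig. With *n* intervening genes:
*n* ≤ `empty_max` (3) → empty; *n* ≤ `max_island_genes` (200) → occupied,
and the island is materialized; larger → not found (oversize). Islands found
at this stage are *not* subject to the 10-gene minimum — that filter belongs
to discovery, where it separates islands from annotation debris; at
occupancy time the hotspot is already established.

**Island dedup.** Within a hotspot, islands are clustered greedily: sort by
descending interior size (ties by island id), take the largest unassigned
island as representative, absorb every unassigned island with identity ≥
`dedup_identity` (0.6) and both coverages ≥ `dedup_coverage` (0.8), where
identity = LCS / max(n_a, n_b) and coverage_x = LCS / n_x over interior
cluster sequences. This mirrors set-cover-style greedy sequence clustering
with bidirectional coverage at the stated thresholds, transplanted from
nucleotide space to gene-cluster space — an analog, not a reproduction: it
cannot see sequence divergence within one cluster, and it treats any
cluster substitution as equally different. The representative is the seeding
(largest) member; the choice is deterministic under input permutation.

**MGE typing.** A pure function of one island's labels and gene order; the
rule set and its reasoning are in the README. Two open parameters are
explicit config: the conjugation-label set counting as a "full" module
(default `{relaxase, t4cp, virb4}` — the exact requirement is
annotation-tool-internal, so it is configuration, not a fixed fact), and the
"short gene" bound for the GInt cassette (default ≤ 300 bp, or a
`short_hypothetical` label when coordinates are absent; no published length
exists for the helix-loop-helix gene, so 300 bp was chosen to separate it
clearly from ordinary ~900 bp genes).

**Defense-call merging.** Source-B calls whose type ends in `_other` are
dropped (partial/split systems). Same-type calls sharing ≥ 1 gene index merge
with the union of their genes (transitively). Different-type calls sharing a
gene are both kept and flagged for review — cross-type conflicts are a
curation decision, not something to auto-resolve. Merging is idempotent and
order-independent, and no gene index is lost except via the `_other` rule.
"Overlap" means shared gene indices; bp-interval overlap is the fallback
granularity when indices are unavailable.

## The synthetic cohort

`SimConfig` defaults define the study conditions: 150 genomes; a 4,000-gene
conserved-order core backbone (the scale of an enteric bacterial chromosome,
so that fragmentation into ~30 contigs still leaves most contigs above the
20-gene filter); 12 hotspots at evenly spaced intergenic slots, with
occupancy probabilities 0.08–0.30 except one 0.97-occupancy "mega-hotspot"
open to every MGE template and the full 20-system defense repertoire —
emulating the empirically observed near-universally-occupied, high-diversity
defense hotspot. Each occupied slot receives one instance of an MGE template
(prophage, P4-like satellite, ICE, IME, Tn7-like, GInt, putative transposon,
integrase-only; every backbone ≥ 10 genes) carrying 1–5 defense systems
sampled by weight at dedicated cargo slots — cargo is drawn independently per
island instance, so identical elements carry different defensive payloads and
the dedup/matrix stages are genuinely exercised. Island sizes land in the
~11–40 gene range; no distribution for real island sizes or cargo counts is
published, so these are declared defaults, not facts.

Noise knobs, all off by default: per-gene core loss rate; accessory noise
genes with fresh singleton cluster IDs (never core by construction), inserted
≥ 2 slots from any hotspot; contig fragmentation (Poisson mean contigs per
genome; cuts never fall inside or immediately at the boundary of a planted
island unless the stress mode is enabled, so ground-truth recovery stays
well-defined); and per-label annotation false negatives, driven by an RNG
stream separate from genome composition so the dropout rate never perturbs
the genomes themselves.

Three generator guarantees worth knowing: genome 0 is the designated
reference and is never fragmented (it plays the role of a finished reference
assembly); every hotspot is left unoccupied in at least one genome (flipping
the lowest-index occupied genome if sampling leaves none), so the mobility
criterion of discovery holds by construction rather than with probability
1 − (occupancy)^n; and every planted defense system lives in exactly one
planted island. The ground-truth ledger records per-(genome, hotspot) status,
island extents, template/MGE type, and the final gene indices of each planted
system, from which the two defense-call tables (sources A and B, independent
false-negative rates, optional `_other` emissions from B) are derived.

**What the simulator does not model** — and hence what passing tests do not
show about real data: nucleotide sequences and within-cluster divergence;
phylogenetic structure and recombination (genomes are i.i.d. given the
backbone); homolog-clustering errors (cluster IDs are exact); tandem
duplications and repeat-driven mis-assembly; plasmids; tRNA-gene biology of
integration sites; and partially degraded elements. Real-data performance
depends on upstream clustering and annotation quality in ways these tests
cannot measure.

## Numerical and tie-break choices

All thresholds are strict or non-strict exactly as stated above (core
prevalence strict >, contig filter strict >, empty/cap non-strict ≤). Anchor
selection prefers forward orientation, then the smallest reference span, then
the smallest coordinate. The occupancy window search evaluates only genome
frames overlapping at least one occurrence of a window cluster (an exact
pruning, not an approximation), scans both orientations, and deduplicates
candidates by position; candidate pair choice is (fewest intervening genes,
contig id, coordinate). Dedup ties on island size break lexicographically by
island id. Degenerate inputs: an empty cohort and an unparseable table raise;
a cohort with zero defense labels runs through and produces schema-valid
empty reports; empty interiors make island similarity undefined (error, not
zero). All randomness flows from the config seed through NumPy PCG64
generators; reports are written with fixed float formatting and sorted keys,
making rerun outputs byte-identical.

Problem sizes used by the test suite and the acceptance script: unit fixtures
of tens of genes; a 40-genome / 800-gene / 5-hotspot cohort for integration
tests; the full 150-genome / 4,000-gene / 12-hotspot cohort (noise-free and
under 2% core loss + 5% annotation dropout + mean-30-contig fragmentation)
for the end-to-end checks.

## Known limitations

* Hotspot identity is a reference core-gene interval; elements integrating at
  distinct attachment sites between the same two core genes are one hotspot
  here, and bp-resolution attB/attP detection is out of scope.
* The occupancy window fallback extrapolates a deleted flank's position
  assuming local colinearity; large rearrangements inside the window can
  misplace it by a few genes (bounded by the window size).
* Under heavy fragmentation the same-contig rule necessarily reports
  *not found* for hotspots whose flanking regions were split by an assembly
  cut; this is a property of the method, not recoverable by tuning.
* The gene-level dedup analog under-merges islands whose shared elements
  diverged enough to split homolog clusters upstream.
* Satellite/PICI typing, phage naming and GInt homology arrive as labels;
  the classifier encodes how the evidence combines, not how it is produced.
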