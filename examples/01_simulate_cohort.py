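"""Generate a synthetic pan-genome cohort with planted defense islands.

Builds a small cohort (40 genomes, 800-gene core backbone, 5 integration
hotspots), writes nothing to disk, and prints the planted ground truth: how
often each hotspot is occupied and how many defense systems its islands carry.
"""

from defenseislands import SimConfig, generate_pangenome, truth_summary

config = SimConfig(
    n_genomes=40,
    n_core=800,
    n_hotspots=5,
    occupancy_prob=(0.2, 0.4, 0.1, 0.3, 0.9),  # last one is a busy hotspot
    seed=11,
)
genomes, truth = generate_pangenome(config)

print(f"cohort: {len(genomes)} genomes, {genomes[0].n_genes} genes in the reference")
print(f"planted islands: {len(truth.islands)}")
print()
print(truth_summary(truth).to_string(index=False))
print()
print("Each row is one planted hotspot: the fraction of genomes carrying an")
print("island there, and the total defense systems planted in those islands.")
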