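"""Deduplicate islands per hotspot and type their mobile genetic elements.

Islands at a hotspot are near-copies across genomes; greedy gene-content
clustering (identity >= 0.6, bidirectional coverage >= 0.8) picks one
representative per cluster, which is then MGE-typed from its annotation
labels (prophage / satellite / ICE / IME / Tn7 / GInt / putative transposon /
integrase-only).
"""

from defenseislands import SimConfig, generate_pangenome, run_pipeline
from defenseislands.mge_classifier import calls_to_frame, mge_summary

config = SimConfig(
    n_genomes=40,
    n_core=800,
    n_hotspots=5,
    occupancy_prob=(0.2, 0.4, 0.1, 0.3, 0.9),
    seed=11,
)
genomes, _ = generate_pangenome(config)
result = run_pipeline(genomes)

n_occupied = (result.occupancy["status"] == "occupied").sum()
print(f"occupied (hotspot, genome) pairs: {n_occupied}")
print(f"island clusters after dedup: {len(result.clusters)}")
print(f"representative islands: {len(result.representatives)}")
print()
print(mge_summary(result.mge_calls, result.rep_hotspot).to_string(index=False))
print()
print("Counts are per representative island, so each distinct element variant")
print("at a hotspot is counted once however many genomes carry it.")
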