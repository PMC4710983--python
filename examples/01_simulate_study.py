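"""Simulate a two-strain inhibitor-stress RNA-seq study.

Generates NB counts for an inhibitor-resistant strain and its wild-type
control under four culture conditions (blank, acetic acid, furfural, mixture)
in biological triplicate, with 100 planted strain-responsive "consensus"
genes, and prints what was planted.
"""

import stresstf as st

cfg = st.SimulationConfig(n_genes=2000, de_fraction_strain=0.05, seed=0)
matrix, truth = st.simulate_counts(cfg)

print(f"count matrix: {matrix.counts.shape[0]} genes x {matrix.counts.shape[1]} samples")
print(f"conditions: {', '.join(cfg.conditions)}; replicates: {cfg.n_replicates}")
n_up = (truth.consensus_direction == "up").sum()
n_down = (truth.consensus_direction == "down").sum()
n_bif = (truth.consensus_direction == "bifurcated").sum()
print(f"planted consensus genes: {len(truth.consensus_genes)} "
      f"({n_up} up, {n_down} down, {n_bif} bifurcated)")
print("\nfirst corner of the matrix:")
print(matrix.counts.iloc[:4, :3])
# Each entry is an NB-distributed read count; planted genes carry a
# consistent-sign log2 fold change between the strains in every condition.
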