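"""Consensus genes across all four strain-vs-strain contrasts, then a GO
pool-percentage profile of a printed gene-list table.

The consensus set contains genes called DE with a recorded direction in every
contrast; genes whose sign flips between conditions are classified bifurcated.
"""

import stresstf as st
from stresstf import datasets

cfg = st.SimulationConfig(n_genes=2000, de_fraction_strain=0.05, seed=0)
matrix, truth = st.simulate_counts(cfg)
size_factors = st.estimate_size_factors(matrix)

gene_sets = []
for cond in cfg.conditions:
    spec = st.ContrastSpec(
        f"{cond}:resistant_vs_control",
        matrix.samples_where(strain="resistant", condition=cond),
        matrix.samples_where(strain="control", condition=cond),
    )
    sub = matrix.subset_samples(list(spec.samples))
    disp = st.estimate_dispersion(
        sub, size_factors.reindex(sub.sample_ids), groups=[spec.group_a, spec.group_b]
    )
    gene_sets.append(st.call_de(st.wald_test(matrix, size_factors, disp, spec)))

consensus = st.consensus_genes(gene_sets)
print(f"consensus genes: {len(consensus.consensus)} "
      f"({len(consensus.universal_up)} universally up, "
      f"{len(consensus.universal_down)} universally down, "
      f"{len(consensus.bifurcated)} bifurcated)")
for gene in consensus.bifurcated:
    print(f"  bifurcated {gene}: {consensus.sign_vectors[gene]}")

# GO pool percentages on the bundled wild-type printed table
table = datasets.load_wildtype_stress_go()
pools = datasets.pools_from_table(table)
ann = datasets.annotation_from_table(table)
prof = st.profile(pools["FF"], ann)
print("\nGO profile of the furfural DE pool (percent of pool per term):")
print(prof.table[["term", "name", "n_genes", "percentage"]].round(2).to_string(index=False))
# Percentages are 100 * |term genes in pool| / |pool|; genes annotated to
# several terms count toward each, so columns need not sum to 100.
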