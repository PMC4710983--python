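"""Two-group NB Wald differential expression with the abundance filter.

Tests resistant vs control under acetic-acid stress and applies the calling
rule baseMean >= 1000 and BH-adjusted p <= 0.001.
"""

import stresstf as st

matrix, truth = st.simulate_counts(
    st.SimulationConfig(n_genes=2000, de_fraction_strain=0.05, seed=0)
)
size_factors = st.estimate_size_factors(matrix)
spec = st.ContrastSpec(
    "AA:resistant_vs_control",
    matrix.samples_where(strain="resistant", condition="AA"),
    matrix.samples_where(strain="control", condition="AA"),
)
sub = matrix.subset_samples(list(spec.samples))
dispersions = st.estimate_dispersion(
    sub, size_factors.reindex(sub.sample_ids), groups=[spec.group_a, spec.group_b]
)
result = st.wald_test(matrix, size_factors, dispersions, spec)
called = st.call_de(result)  # default DECallConfig(1000, 0.001)

print(result.table.dropna().sort_values("padj").head(5).round(4))
print(f"\ncalled DE: {len(called.called)} genes "
      f"({len(called.up)} up, {len(called.down)} down)")
planted = truth.consensus_genes
print(f"planted genes recovered in this contrast: "
      f"{len(called.called & planted)}/{len(planted)}")
# log2FoldChange is resistant over control; padj is the BH-adjusted Wald p.
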