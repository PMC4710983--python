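"""Cross-validation metrics: ddCt qPCR fold changes and fermentation rates.

A noiseless simulated Ct table returns exactly the planted fold changes
(fold = efficiency^(-ddCt)); a logistic-growth fermentation series returns
its specific growth rate and product yield by windowed regression.
"""

import numpy as np

import stresstf as st

_, truth = st.simulate_counts(
    st.SimulationConfig(n_genes=500, de_fraction_strain=0.1, seed=0)
)
targets = sorted(truth.consensus_genes)[:3]
ct = st.simulate_qpcr(truth, targets, control_gene="ALG9", noise_sd=0.0, seed=0)

contrast = "AA:resistant_vs_control"
print("gene      qPCR fold   true fold")
for gene in targets:
    fold = st.delta_delta_ct(ct, gene)[contrast]
    true = 2.0 ** truth.true_lfc.loc[gene, contrast]
    print(f"{gene}  {fold:10.4f}  {true:10.4f}")

series = st.simulate_fermentation(
    growth_rate=0.35, lag=2.0, od0=0.05, inhibition_factor=1.0,
    timepoints=np.arange(0.0, 30.1, 0.5),
)
rates = st.specific_rates(series, window=(2.5, 6.5))
print(f"\nspecific growth rate: {rates.growth_rate:.3f} 1/h (true 0.35)")
print(f"specific glucose consumption: {rates.glucose_consumption_rate:.3f} g/OD/h")
print(f"specific ethanol production: {rates.ethanol_production_rate:.3f} g/OD/h")
print(f"implied ethanol yield: "
      f"{rates.ethanol_production_rate / rates.glucose_consumption_rate:.3f} g/g (true 0.45)")
# Metabolite rates are per OD600 unit; consumption is sign-normalized positive.
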