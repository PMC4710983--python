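"""End-to-end configuration-driven run.

Simulate -> 10 contrasts of NB Wald DE -> per-strain Venn overlaps ->
consensus -> GO profiles -> TF coverage profile -> report files under outdir.
"""

import stresstf as st

cfg = st.PipelineConfig(
    seed=0,
    outdir="scratch/example_run",
    simulate={"n_genes": 1000, "de_fraction_strain": 0.05},
    tf={"planted_coverage": 0.9, "background_coverage": 0.1, "k": 10},
)
report = st.run(cfg)

print(f"stresstf {report.version}, config {report.config_hash}")
print("\nper-contrast DE calls (total / up / down):")
for label, rec in report.contrasts.items():
    print(f"  {label}: {rec['total']} / {rec['up']} / {rec['down']}")
cons = report.consensus
print(f"\nconsensus: {cons['n_consensus']} genes "
      f"({cons['n_universal_up']} up, {cons['n_universal_down']} down, "
      f"{cons['n_bifurcated']} bifurcated)")
print("\ntop TFs by consensus coverage:")
for rec in report.tf_profile[:5]:
    print(f"  {rec['rank']}. {rec['tf']}: {rec['coverage_pct']:.1f}%")
print(f"\nall stage outputs and report.json written under {cfg.outdir}/")
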