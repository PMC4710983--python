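# Methods

`stresstf` implements a transcriptome-guided workflow for discovering
transcription-factor (TF) targets behind a complex microbial phenotype —
here, yeast tolerance to the fermentation inhibitors acetic acid and
furfural. The workflow compares an inhibitor-resistant strain against its
wild-type control under several culture conditions, finds the genes that are
differentially expressed between the strains in *every* condition (the
consensus genes), characterises them by GO category percentages, and ranks
TFs by how much of the consensus pool their documented regulon covers. This
note records the models, the parameters that matter, and the choices made
where the design was genuinely open.

## Differential expression model

Counts for gene *g* in sample *j* are modelled as negative binomial,

    K_gj ~ NB(mu_gj, alpha_g),        Var = mu + alpha mu^2,
    log mu_gj = beta0_g + beta1_g x_j + log s_j,

with `x_j` the group indicator of a two-group contrast and `s_j` the sample
size factor. The test on `beta1` is a Wald test against the standard normal;
`log2FoldChange = beta1 / ln 2`, with standard error from the observed Fisher
information. p-values are Benjamini–Hochberg adjusted per contrast over the
tested genes (all-zero and non-converging genes are excluded from the BH
universe and reported as NaN).

*Normalization.* Median-of-ratios: each sample's size factor is the median,
over genes with no zero count, of the ratio of its count to the gene's
geometric mean across samples. When no zero-free gene exists the
`pseudo_reference=True` flag computes geometric means over positive entries
only. Size factors are defined up to a common scale; all downstream
statistics depend only on their ratios.

*Dispersion.* Per-gene method of moments on normalized counts, computed
within replicate groups (so genuine between-group signal is not booked as
dispersion) and pooled across groups weighted by degrees of freedom:
`alpha_raw = max(floor, (s^2 - m) / m^2)`, floor `1e-8`. Three refinements
keep the Wald test calibrated at triplicate sample sizes:

1. **Log-bias correction.** A variance estimate with df residual degrees of
   freedom behaves like `sigma^2 * chi2_df / df`, whose logarithm is biased
   by `psi(df/2) - log(df/2)` (≈ −0.27 at df = 4). The gene-wise log estimate
   is debiased by this amount before averaging.
2. **Trend shrinkage.** A mean–dispersion trend `alpha(mu) = a0/mu + a1`
   (non-negative least squares) is fitted across genes, and the final
   log-dispersion is the weighted average of gene-wise and trend values with
   gene weight 0.25 — at df = 4 the per-gene information is weak, so most of
   the weight sits on the trend.
3. **Trend floor.** The result is floored at 0.7 × trend, a conservative
   sharing rule in the spirit of DESeq's classic "maximum" mode: a gene may
   exceed the trend when its data demand it, but can fall only modestly
   below, which prevents chance underdispersion from inflating Wald
   statistics.

With this estimator, null simulations (2,000 NB genes, 3 vs 3, dispersions
uniform on 0.005–0.05) give an empirical type-I error of 0.050 (mean over 30
independent seeds, SD 0.006) at nominal p < 0.05. Without the correction and
floor the same test rejects at 0.07–0.08. The constants (weight 0.25, floor
0.7) were fixed by this calibration study and are exposed as arguments.

*Fitting.* The GLM is fit by IRLS, vectorised across genes (the two-group
design decouples into per-group weighted means), tolerance 1e-8, at most 100
iterations. Genes that fail to converge — in practice genes with one group
entirely zero, whose MLE is at infinity — are flagged, reported NaN, and
counted in the log.

*Calling rule.* A gene is differentially expressed iff
`baseMean >= 1000` **and** `padj <= 0.001`, both inclusive; `baseMean` is the
mean of size-factor-normalized counts over the samples of that contrast
only. The partition into up/down follows the sign of the fold change; an
exact zero (impossible in continuous arithmetic) would deterministically go
to "up" with a warning. The abundance cut is deliberately aggressive — it is
the published rule this pipeline reproduces — and it implies the analysis
only ever sees abundant transcripts.

Known limitation: the Wald test and the likelihood-ratio test diverge in the
extreme tail (|z| ≳ 5), as they do for any log-link GLM; at such effect
sizes the Wald p-value is the more conservative of the two. Agreement with
an independent GLM implementation (statsmodels) is exact; agreement with the
LRT is close only up to moderate effect sizes.

## Consensus genes and set algebra

`consensus_genes` intersects the *called* DE sets of the four
strain-vs-strain contrasts (one per condition, the no-inhibitor blank
included — a flag allows dropping it) and classifies each consensus gene as
universally up, universally down, or bifurcated (sign differs between
contrasts; the per-contrast sign vector is recorded). The three classes are
asserted to partition the consensus set on every run. Consensus membership
requires passing the full calling rule in every contrast, not merely sign
consistency. `venn_overlap` produces the exclusive-region decomposition of
labeled gene sets (regions pairwise disjoint, union equal to the input
union), and `condition_specific_genes` the per-condition exclusive sets and
the all-condition common set.

## GO profiling

The annotation contract is a flat gene → slim-term table; no ontology
traversal is performed because the inputs are taken to be already slimmed by
a GO term mapper. A profile reports, per term, the DE-pool genes annotated
to it and the percentage `100 * |term ∩ pool| / |pool|`. A gene annotated to
several terms counts toward each, so percentages need not sum to 100; the
package counts genes per term independently, not gene–term pairs.
`term_condition_table` lays per-condition pools out per term and marks genes
present for that term in every condition as common; the marking is always
recomputed, never read from a file. Three bundled TSV fixtures carry the
printed per-term gene lists of the study's GO tables (wild-type strain,
resistant strain, and consensus pool) for worked-example tests.

## TF regulon coverage

The regulon contract is a three-column TSV (tf, target, evidence) in the
style of a YEASTRACT export; live database queries are deliberately out of
scope for reproducibility. Edges are first restricted to documented
regulations (`documented-direct`, `documented-indirect`; `potential` is
dropped). Each TF's score is its coverage fraction
`|targets ∩ consensus pool| / |pool|`; TFs are ranked by coverage descending
with ties broken by TF id ascending, and the top-20 profile is the primary
deliverable. Duplicate edges never double-count. A one-sided hypergeometric
tail probability per TF (universe = all genes in the count matrix, BH across
TFs) is provided as a companion statistic clearly beyond the original
ranking; it never reorders the profile.

## Validation metrics

*qPCR.* The ddCt method with a designated endogenous control gene and
reference sample: `fold = efficiency^(-ddCt)`, efficiency 2.0 (perfect
doubling) by default and configurable. Technical replicates are averaged
first. The statistic is invariant to per-sample machine offsets because dCt
removes them. `concordance` reports the Pearson r (symmetric) and the
y-on-x regression slope of paired log2 fold changes.

*Fermentation kinetics.* Specific rates over a user-chosen time window:
growth rate is the least-squares slope of ln(OD600) versus time; metabolite
rates are concentration slopes divided by the window-mean OD600,
sign-normalized so consumption is positive. Rates are per OD600 unit — no
dry-weight conversion is applied, so absolute values are comparable only
within a study. Window selection is explicit user input; no automatic
exponential-phase detection is attempted, because a wrong automatic window
is worse than a visible parameter.

## Synthetic data generator

The generator emulates the study design the analysis assumes: 2 strains × 4
conditions × 3 biological replicates, ~6,000 genes by default. Baseline
means are log-normal (natural-log location 6.0, scale 1.3, i.e. median
≈ 400 counts — a plausible depth for a lane-multiplexed yeast library);
dispersions are uniform on 0.005–0.05, the range typical for abundant
transcripts in laboratory yeast; library sizes are log-uniform on 0.5–2 to
exercise size-factor estimation without extreme outliers. Planted effects:

- *Condition-responsive genes* (3% per inhibitor condition) get a signed
  log2 effect, uniform magnitude 1–2.5, applied in both strains.
- *Consensus genes* (fraction `de_fraction_strain`, default 5%) get a
  consistent-sign strain effect in every condition, with per-condition
  magnitude redrawn from the same range. They are drawn from an abundant
  baseline stratum (log-uniform mean 2,500–25,000): the calling rule's
  abundance filter (`baseMean >= 1000`) can by construction only recover
  abundant transcripts, so planting consensus genes below it would make the
  ground truth unrecoverable by *any* method honouring that rule — the
  planted truth is meant to test the pipeline, not the filter. For the same
  reason consensus genes are disjoint from condition-responsive genes.
- One *bifurcated gene* (configurable count) flips sign between
  acid-containing and acid-free conditions, giving the consensus classifier
  a guaranteed positive control.

Evidence labels on simulated regulon edges mix 60% direct / 30% indirect /
10% potential — arbitrary but fixed, so the evidence filter is exercised.
The qPCR generator writes Ct values whose ddCt transform returns the true
fold changes exactly at zero noise; the fermentation generator produces a
logistic biomass curve with glucose drawn down stoichiometrically
(0.4 OD units per g/L) and products formed at stated g/g yields (ethanol
0.45, glycerol 0.05); the dosed acetate stays constant.

What the generator does **not** emulate: GC/length biases, batch effects,
outlier samples, correlated gene modules, mean-dependent dispersion, or a
real yeast annotation. Passing recovery tests therefore demonstrates the
pipeline's statistical machinery under its own model assumptions, not
robustness to the full messiness of real RNA-seq.

## Problem sizes in the test and acceptance runs

The recovery and calibration studies run at 2,000 genes (100 planted
consensus genes at 5%), 3 vs 3 replicates, and 100 seeded regulon draws —
large enough for stable rates (binomial SE ≈ 0.005 on the type-I error) and
small enough to iterate quickly. The vectorised IRLS fits a 2,000-gene
contrast in well under a second, so the defaults scale to the full 6,000-gene
design unchanged.

## Pipeline

The orchestrator runs simulate-or-ingest → size factors → per-contrast
dispersions and Wald tests (three condition-vs-blank contrasts per strain
plus one strain-vs-strain contrast per condition: ten in total) → per-strain
Venn overlaps → consensus → GO profiles → TF profile → JSON + text report.
Configuration is a strictly validated flat document — unknown keys are
errors, not warnings, because silent misconfiguration is the main
reproducibility hazard. Every reported count is re-checked against the
emitted file before the run returns, and a rerun with the same configuration
and seed is bit-identical.
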