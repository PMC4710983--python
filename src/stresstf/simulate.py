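"""Synthetic inputs with the statistical structure the pipeline assumes.

The count generator emulates a two-strain stress-response study: an
inhibitor-resistant strain and its wild-type control grown under four culture
conditions (no inhibitor, acetic acid, furfural, and the acetic acid +
furfural mixture) in biological triplicate.  Counts are negative-binomial
with Var = mu + alpha mu^2, per-sample library-size scaling, planted
condition-responsive genes, and a planted set of "consensus" genes that are
differentially expressed between the strains in every condition with a
consistent sign.  An optional planted bifurcated gene flips sign between
acetic-acid-containing and acid-free conditions, mirroring genes whose
regulation reverses with the stressor.

Companion generators produce a TF->target regulon table in which designated
TFs are enriched among the planted consensus genes, a flat gene -> GO-term
annotation, qPCR Ct tables consistent with the simulated fold changes, and
logistic-growth fermentation time series.  Every generator is deterministic
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .de import CountMatrix
from .tf import EVIDENCE_LEVELS, RegulonNetwork
from .go import GOAnnotation
from .validation import CtTable, FermentationSeries


class ConfigurationError(ValueError):
    """A simulation parameter is outside its valid range."""


def _require(ok: bool, fieldname: str, message: str) -> None:
    if not ok:
        raise ConfigurationError(f"{fieldname}: {message}")


@dataclass
class SimulationConfig:
    """Study-design and distributional parameters of the count simulator.

    ``mean_log_expression`` is the (location, scale) of the natural-log
    baseline mean; ``dispersion_range`` bounds the per-gene NB dispersion
    alpha; ``lfc_magnitude`` bounds the absolute log2 effect size of planted
    genes; ``library_size_range`` bounds the log-uniform per-sample scaling.
    Planted consensus genes are drawn from an abundant baseline stratum
    (``planted_mean_range``) so that an abundance-filtered calling rule can in
    principle recover them, and are disjoint from condition-responsive genes.
    """

    n_genes: int = 6000
    n_replicates: int = 3
    strains: tuple[str, str] = ("resistant", "control")
    conditions: tuple[str, ...] = ("blank", "AA", "FF", "AAFF")
    mean_log_expression: tuple[float, float] = (6.0, 1.3)
    dispersion_range: tuple[float, float] = (0.005, 0.05)
    de_fraction_condition: float = 0.03
    de_fraction_strain: float = 0.05
    lfc_magnitude: tuple[float, float] = (1.0, 2.5)
    library_size_range: tuple[float, float] = (0.5, 2.0)
    n_bifurcated: int = 1
    planted_mean_range: tuple[float, float] = (2500.0, 25000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_genes >= 1, "n_genes", "must be >= 1")
        _require(self.n_replicates >= 2, "n_replicates", "must be >= 2")
        _require(len(self.strains) == 2, "strains", "exactly two strains required")
        _require(len(self.conditions) >= 1, "conditions", "at least one condition")
        _require(
            len(set(self.strains)) == 2 and len(set(self.conditions)) == len(self.conditions),
            "strains",
            "labels must be unique",
        )
        _require(
            0 <= self.de_fraction_condition <= 1,
            "de_fraction_condition",
            "must be in [0, 1]",
        )
        _require(
            0 <= self.de_fraction_strain <= 1,
            "de_fraction_strain",
            "must be in [0, 1]",
        )
        _require(
            0 < self.dispersion_range[0] <= self.dispersion_range[1],
            "dispersion_range",
            "must be strictly positive and ordered",
        )
        _require(
            0 < self.library_size_range[0] <= self.library_size_range[1],
            "library_size_range",
            "must be strictly positive and ordered",
        )
        _require(
            0 <= self.lfc_magnitude[0] <= self.lfc_magnitude[1],
            "lfc_magnitude",
            "must be non-negative and ordered",
        )
        _require(self.n_bifurcated >= 0, "n_bifurcated", "must be >= 0")
        _require(
            0 < self.planted_mean_range[0] <= self.planted_mean_range[1],
            "planted_mean_range",
            "must be strictly positive and ordered",
        )

    @property
    def reference_condition(self) -> str:
        return self.conditions[0]


def strain_contrast_label(condition: str, strains: Sequence[str]) -> str:
    return f"{condition}:{strains[0]}_vs_{strains[1]}"


def condition_contrast_label(strain: str, condition: str, reference: str) -> str:
    return f"{strain}:{condition}_vs_{reference}"


@dataclass
class GroundTruth:
    """Truth ledger of a simulation run.

    ``true_lfc`` holds the per-gene true log2 fold change for every contrast
    the pipeline will test (strain-vs-strain per condition, and
    condition-vs-reference per strain).  ``consensus_direction`` maps each
    planted consensus gene to 'up', 'down' or 'bifurcated';
    ``bifurcated_signs`` records the per-contrast sign vector of bifurcated
    genes.  ``planted_tfs`` is filled in by :func:`simulate_regulon`.
    """

    true_lfc: pd.DataFrame
    consensus_direction: pd.Series
    bifurcated_signs: dict = field(default_factory=dict)
    planted_tfs: list = field(default_factory=list)
    baseline_mean: pd.Series | None = None
    dispersion: pd.Series | None = None

    @property
    def consensus_genes(self) -> frozenset:
        return frozenset(self.consensus_direction.index)

    def validate(self, gene_universe) -> None:
        universe = set(gene_universe)
        if not self.consensus_genes <= universe:
            raise ValueError("planted consensus set must be within the gene universe")
        bad = set(self.consensus_direction) - {"up", "down", "bifurcated"}
        if bad:
            raise ValueError(f"invalid consensus directions: {bad}")

    def to_tsv(self, path) -> None:
        ledger = self.true_lfc.copy()
        ledger["consensus_direction"] = self.consensus_direction.reindex(ledger.index)
        ledger.rename_axis("gene").to_csv(path, sep="\t")


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw a gene x sample NB count matrix plus its ground-truth ledger."""
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    conditions = list(config.conditions)
    ref = config.reference_condition
    strains = list(config.strains)

    loc, scale = config.mean_log_expression
    baseline = np.exp(rng.normal(loc, scale, size=config.n_genes))
    lo_a, hi_a = config.dispersion_range
    alpha = rng.uniform(lo_a, hi_a, size=config.n_genes)

    n_consensus = int(round(config.n_genes * config.de_fraction_strain))
    n_special = n_consensus + config.n_bifurcated
    _require(
        n_special <= config.n_genes,
        "de_fraction_strain",
        "planted consensus + bifurcated genes exceed n_genes",
    )
    special_idx = rng.choice(config.n_genes, size=n_special, replace=False)
    consensus_idx = special_idx[:n_consensus]
    bifurcated_idx = special_idx[n_consensus:]
    # abundant stratum so the baseMean filter cannot hide planted genes
    lo_m, hi_m = np.log(config.planted_mean_range)
    baseline[special_idx] = np.exp(rng.uniform(lo_m, hi_m, size=n_special))

    lo_l, hi_l = config.lfc_magnitude

    # condition effects (both strains), disjoint from planted strain genes
    cond_lfc = {c: np.zeros(config.n_genes) for c in conditions}
    eligible = np.setdiff1d(np.arange(config.n_genes), special_idx)
    n_cond = int(round(config.n_genes * config.de_fraction_condition))
    for cond in conditions:
        if cond == ref or n_cond == 0 or len(eligible) == 0:
            continue
        chosen = rng.choice(eligible, size=min(n_cond, len(eligible)), replace=False)
        signs = rng.choice([-1.0, 1.0], size=len(chosen))
        mags = rng.uniform(lo_l, hi_l, size=len(chosen))
        cond_lfc[cond][chosen] = signs * mags

    # strain effects: consistent sign across all conditions for consensus
    # genes; sign flip between acid-containing and acid-free conditions for
    # bifurcated genes
    strain_lfc = {c: np.zeros(config.n_genes) for c in conditions}
    cons_sign = rng.choice([-1.0, 1.0], size=n_consensus)
    for cond in conditions:
        mags = rng.uniform(lo_l, hi_l, size=n_consensus)
        strain_lfc[cond][consensus_idx] = cons_sign * mags
    bif_signs: dict[str, dict[str, float]] = {}
    for j, gi in enumerate(bifurcated_idx):
        per_cond = {}
        for cond in conditions:
            sign = -1.0 if "AA" in cond else 1.0
            mag = rng.uniform(lo_l, hi_l)
            strain_lfc[cond][gi] = sign * mag
            per_cond[strain_contrast_label(cond, strains)] = sign
        bif_signs[genes[gi]] = per_cond

    sample_rows = []
    mus = []
    lib_lo, lib_hi = np.log(config.library_size_range)
    for strain in strains:
        for cond in conditions:
            for rep in range(1, config.n_replicates + 1):
                sample_rows.append(
                    {
                        "sample": f"{strain}_{cond}_r{rep}",
                        "strain": strain,
                        "condition": cond,
                        "replicate": rep,
                    }
                )
                mu = baseline * 2.0 ** cond_lfc[cond]
                if strain == strains[0]:
                    mu = mu * 2.0 ** strain_lfc[cond]
                mus.append(mu)
    lib = np.exp(rng.uniform(lib_lo, lib_hi, size=len(sample_rows)))
    mu_mat = np.column_stack(mus) * lib[None, :]

    r = 1.0 / alpha
    p = r[:, None] / (r[:, None] + mu_mat)
    counts = rng.negative_binomial(r[:, None], p)

    samples = pd.DataFrame(sample_rows).set_index("sample")
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples.index)
    matrix = CountMatrix(counts_df, samples)

    lfc_cols = {}
    for cond in conditions:
        lfc_cols[strain_contrast_label(cond, strains)] = strain_lfc[cond]
    for strain in strains:
        for cond in conditions:
            if cond == ref:
                continue
            lfc_cols[condition_contrast_label(strain, cond, ref)] = cond_lfc[cond]
    true_lfc = pd.DataFrame(lfc_cols, index=counts_df.index)

    direction = pd.Series(
        np.where(cons_sign > 0, "up", "down"),
        index=[genes[i] for i in consensus_idx],
        dtype=object,
    )
    for gi in bifurcated_idx:
        direction[genes[gi]] = "bifurcated"
    truth = GroundTruth(
        true_lfc=true_lfc,
        consensus_direction=direction,
        bifurcated_signs=bif_signs,
        baseline_mean=pd.Series(baseline, index=counts_df.index),
        dispersion=pd.Series(alpha, index=counts_df.index),
    )
    truth.validate(counts_df.index)
    return matrix, truth


# ---------------------------------------------------------------------------
# regulon network
# ---------------------------------------------------------------------------

#: documented-direct / documented-indirect / potential mixing fractions
EVIDENCE_MIX = (0.6, 0.3, 0.1)


def simulate_regulon(
    gene_universe: Sequence[str],
    truth: GroundTruth,
    n_tfs: int = 50,
    planted_tfs: int = 2,
    background_coverage: float = 0.1,
    planted_coverage: float = 0.9,
    seed: int = 0,
    evidence_mix: tuple[float, float, float] = EVIDENCE_MIX,
) -> RegulonNetwork:
    """Random regulon table with designated TFs enriched on the consensus set.

    Every TF regulates a uniform random ``background_coverage`` fraction of
    all genes; each of the ``planted_tfs`` additionally regulates a
    ``planted_coverage`` fraction of the planted consensus genes.  Edge
    evidence labels are drawn from ``evidence_mix``.  The planted TF ids are
    recorded in ``truth.planted_tfs``.
    """
    if planted_tfs > n_tfs:
        raise ConfigurationError("planted_tfs: must not exceed n_tfs")
    if not (0 <= background_coverage <= 1 and 0 <= planted_coverage <= 1):
        raise ConfigurationError("coverage fractions must be in [0, 1]")
    if planted_tfs > 0 and planted_coverage <= background_coverage:
        raise ConfigurationError(
            "planted_coverage: must exceed background_coverage"
        )
    universe = list(gene_universe)
    rng = np.random.default_rng(seed)
    tf_ids = [f"TF{i:03d}" for i in range(1, n_tfs + 1)]
    planted_ids = list(rng.choice(tf_ids, size=planted_tfs, replace=False))
    consensus = sorted(truth.consensus_genes & set(universe))

    n_bg = int(round(background_coverage * len(universe)))
    n_pl = int(round(planted_coverage * len(consensus)))
    tf_col: list[str] = []
    target_col: list[str] = []
    for tf in tf_ids:
        targets = set(rng.choice(universe, size=n_bg, replace=False)) if n_bg else set()
        if tf in planted_ids and n_pl:
            targets |= set(rng.choice(consensus, size=n_pl, replace=False))
        ordered = sorted(targets)
        tf_col.extend([tf] * len(ordered))
        target_col.extend(ordered)
    evidence_col = rng.choice(EVIDENCE_LEVELS, size=len(tf_col), p=evidence_mix)
    edges = pd.DataFrame(
        {"tf": tf_col, "target": target_col, "evidence": evidence_col}
    )
    truth.planted_tfs = sorted(planted_ids)
    return RegulonNetwork(edges)


# ---------------------------------------------------------------------------
# GO annotation
# ---------------------------------------------------------------------------

def simulate_go_annotation(
    gene_universe: Sequence[str],
    n_terms: int = 20,
    terms_per_gene: float = 1.5,
    seed: int = 0,
) -> GOAnnotation:
    """Flat gene -> GO-term annotation; Poisson(terms_per_gene) terms per gene."""
    universe = list(gene_universe)
    if not universe:
        raise ValueError("gene universe must be non-empty")
    if n_terms < 1:
        raise ConfigurationError("n_terms: must be >= 1")
    if terms_per_gene < 0:
        raise ConfigurationError("terms_per_gene: must be >= 0")
    rng = np.random.default_rng(seed)
    terms = [f"GO:SIM{i:04d}" for i in range(1, n_terms + 1)]
    names = {t: f"simulated process {i}" for i, t in enumerate(terms, start=1)}
    gene_terms: dict[str, frozenset[str]] = {}
    for gene in universe:
        k = min(int(rng.poisson(terms_per_gene)), n_terms)
        if k:
            gene_terms[gene] = frozenset(rng.choice(terms, size=k, replace=False))
    return GOAnnotation(gene_terms=gene_terms, term_names=names)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_qpcr(
    truth: GroundTruth,
    target_genes: Sequence[str],
    control_gene: str = "ALG9",
    efficiency: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    contrasts: Sequence[str] | None = None,
) -> CtTable:
    """Ct table whose efficiency^(-ddCt) fold changes match the simulated truth.

    One qPCR "sample" is emitted per requested contrast plus a reference
    sample; the endogenous control gene has constant expression.  With
    ``noise_sd=0`` the ddCt-derived log2 fold change equals the true LFC
    exactly.
    """
    if efficiency <= 1.0:
        raise ConfigurationError("efficiency: must be > 1")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd: must be >= 0")
    rng = np.random.default_rng(seed)
    if contrasts is None:
        contrasts = list(truth.true_lfc.columns)
    missing = set(target_genes) - set(truth.true_lfc.index)
    if missing:
        raise ValueError(f"target genes absent from truth ledger: {sorted(missing)}")
    ct_control, ct_target_ref = 20.0, 25.0
    scale = np.log(2.0) / np.log(efficiency)  # Ct shift per log2 unit
    reference = "reference"
    rows = [
        {"sample": reference, "gene": control_gene, "ct": ct_control + rng.normal(0, noise_sd)}
    ]
    for gene in target_genes:
        rows.append(
            {"sample": reference, "gene": gene, "ct": ct_target_ref + rng.normal(0, noise_sd)}
        )
    for contrast in contrasts:
        rows.append(
            {"sample": contrast, "gene": control_gene, "ct": ct_control + rng.normal(0, noise_sd)}
        )
        for gene in target_genes:
            lfc = float(truth.true_lfc.loc[gene, contrast])
            rows.append(
                {
                    "sample": contrast,
                    "gene": gene,
                    "ct": ct_target_ref - lfc * scale + rng.normal(0, noise_sd),
                }
            )
    table = pd.DataFrame(rows)
    return CtTable(ct=table, control_gene=control_gene, reference_sample=reference)


# ---------------------------------------------------------------------------
# fermentation
# ---------------------------------------------------------------------------

DEFAULT_YIELDS: Mapping[str, float] = {"ethanol": 0.45, "glycerol": 0.05}


def simulate_fermentation(
    growth_rate: float = 0.3,
    lag: float = 2.0,
    yields: Mapping[str, float] | None = None,
    inhibition_factor: float = 1.0,
    timepoints: Sequence[float] | None = None,
    seed: int = 0,
    od0: float = 0.2,
    glucose0: float = 20.0,
    acetate0: float = 2.0,
    biomass_yield_od: float = 0.4,
    noise_sd: float = 0.0,
) -> FermentationSeries:
    """Logistic-growth batch fermentation time series.

    Biomass (OD600) follows a logistic curve with effective specific growth
    rate ``growth_rate * inhibition_factor`` after a lag phase; glucose is
    drawn down proportionally to biomass formed (``biomass_yield_od`` OD units
    per g/L glucose) and products are formed from consumed glucose with the
    stated g/g ``yields``.  Acetate (a dosed inhibitor, not a product here)
    stays at its initial level.  Concentrations are non-negative.
    """
    if growth_rate < 0 or inhibition_factor < 0:
        raise ConfigurationError("growth_rate/inhibition_factor: must be >= 0")
    if timepoints is None:
        timepoints = np.arange(0.0, 48.1, 2.0)
    t = np.asarray(timepoints, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ConfigurationError("timepoints: must be strictly increasing, length >= 2")
    yields = dict(DEFAULT_YIELDS if yields is None else yields)
    rng = np.random.default_rng(seed)

    mu = growth_rate * inhibition_factor
    carrying = od0 + glucose0 * biomass_yield_od
    te = np.maximum(t - lag, 0.0)
    if mu > 0:
        growth = np.exp(mu * te)
        od = carrying * od0 * growth / (carrying + od0 * (growth - 1.0))
    else:
        od = np.full_like(t, od0)
    glucose = np.maximum(glucose0 - (od - od0) / biomass_yield_od, 0.0)
    consumed = glucose0 - glucose
    data = {
        "time": t,
        "od600": od,
        "glucose": glucose,
        "ethanol": yields.get("ethanol", 0.0) * consumed,
        "acetate": np.full_like(t, acetate0),
        "glycerol": yields.get("glycerol", 0.0) * consumed,
    }
    frame = pd.DataFrame(data)
    if noise_sd > 0:
        for col in ("od600", "glucose", "ethanol", "acetate", "glycerol"):
            frame[col] = np.maximum(
                frame[col] * (1.0 + rng.normal(0, noise_sd, size=len(frame))), 0.0
            )
    return FermentationSeries(frame)


# ---------------------------------------------------------------------------
# disk output
# ---------------------------------------------------------------------------

def write_simulation(
    outdir,
    matrix: CountMatrix,
    truth: GroundTruth,
    regulon: RegulonNetwork | None = None,
    annotation: GOAnnotation | None = None,
) -> dict[str, Path]:
    """Write all simulated inputs as TSV files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
    }
    matrix.to_tsv(paths["counts"], paths["samples"])
    truth.to_tsv(paths["truth"])
    if regulon is not None:
        paths["regulon"] = outdir / "regulon.tsv"
        regulon.to_tsv(paths["regulon"])
    if annotation is not None:
        paths["annotation"] = outdir / "go_annotation.tsv"
        paths["term_names"] = outdir / "go_term_names.tsv"
        annotation.to_tsv(paths["annotation"], paths["term_names"])
    return paths
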