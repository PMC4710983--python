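"""Negative-binomial Wald differential expression for two-group contrasts.

Implements the count-based testing stack the pipeline is built on:
median-of-ratios library-size normalization, method-of-moments dispersion
estimation with trend shrinkage, a per-gene NB generalized linear model with
log link fit by IRLS, a Wald test on the group coefficient, Benjamini-Hochberg
adjustment, and the abundance/significance calling rule
(baseMean >= 1000 and padj <= 0.001 by default).

The model for gene g in sample j is

    K_gj ~ NB(mu_gj, alpha_g),   Var = mu + alpha * mu^2
    log mu_gj = beta0_g + beta1_g * x_j + log s_j

where x_j indicates membership in group A of the contrast and s_j is the
sample size factor.  log2FoldChange = beta1 / ln 2 and its standard error
comes from the observed Fisher information.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import psi
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))

#: Default evidence-agnostic dispersion floor; guards against under-dispersion.
DISPERSION_FLOOR = 1e-8

RESULT_COLUMNS = [
    "baseMean",
    "log2FoldChange",
    "lfcSE",
    "stat",
    "pvalue",
    "padj",
]


class SizeFactorError(ValueError):
    """No zero-free reference gene available for median-of-ratios."""


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with sample metadata.

    Parameters
    ----------
    counts:
        DataFrame indexed by gene id with one column per sample id.
    samples:
        DataFrame indexed by sample id with columns ``strain``, ``condition``
        and ``replicate`` (extra columns are allowed and ignored).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        if self.counts.columns.has_duplicates:
            raise ValueError("sample ids must be unique")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if np.any(vals != np.floor(vals)):
            raise ValueError("counts must be integers")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        ids = list(sample_ids)
        return CountMatrix(self.counts[ids], self.samples.loc[ids])

    def samples_where(self, **criteria: str) -> list[str]:
        """Sample ids whose metadata match all ``column=value`` criteria."""
        mask = pd.Series(True, index=self.samples.index)
        for col, value in criteria.items():
            mask &= self.samples[col] == value
        return [s for s in self.counts.columns if mask.get(s, False)]

    def to_tsv(self, counts_path, samples_path) -> None:
        self.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
        self.samples.rename_axis("sample").to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(counts, samples)


@dataclass(frozen=True)
class ContrastSpec:
    """Two disjoint sample groups to compare (A over B)."""

    label: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __init__(self, label: str, group_a: Iterable[str], group_b: Iterable[str]):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "group_a", tuple(group_a))
        object.__setattr__(self, "group_b", tuple(group_b))
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError("each contrast group needs at least 2 samples")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("contrast groups must be disjoint")

    @property
    def samples(self) -> tuple[str, ...]:
        return self.group_a + self.group_b


@dataclass
class ContrastResult:
    """Per-gene Wald statistics for one contrast.

    ``table`` has columns baseMean, log2FoldChange, lfcSE, stat, pvalue, padj
    indexed by gene; untested genes (all-zero or non-converged) carry NaN in
    the inferential columns.
    """

    label: str
    table: pd.DataFrame
    size_factors: pd.Series
    n_nonconverged: int = 0

    def to_tsv(self, path) -> None:
        self.table.rename_axis("gene").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, label: str = "", size_factors: pd.Series | None = None):
        table = pd.read_csv(path, sep="\t", index_col=0)
        if size_factors is None:
            size_factors = pd.Series(dtype=float)
        return cls(label=label, table=table, size_factors=size_factors)


@dataclass(frozen=True)
class DECallConfig:
    """Calling rule: gene is DE iff baseMean >= base_mean_min and padj <= padj_max."""

    base_mean_min: float = 1000.0
    padj_max: float = 0.001

    def __post_init__(self) -> None:
        if self.base_mean_min < 0:
            raise ValueError("base_mean_min must be >= 0")
        if not (0 < self.padj_max <= 1):
            raise ValueError("padj_max must be in (0, 1]")


@dataclass(frozen=True)
class DEGeneSet:
    """Called genes of one contrast, partitioned by fold-change sign."""

    label: str
    up: frozenset
    down: frozenset

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets must be disjoint")

    @property
    def called(self) -> frozenset:
        return self.up | self.down

    def direction_of(self, gene) -> int:
        """+1 for up, -1 for down; KeyError if the gene was not called."""
        if gene in self.up:
            return 1
        if gene in self.down:
            return -1
        raise KeyError(gene)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# contrast: {self.label}\n")
            for gene in sorted(self.up):
                fh.write(f"{gene}\tup\n")
            for gene in sorted(self.down):
                fh.write(f"{gene}\tdown\n")

    @classmethod
    def from_file(cls, path) -> "DEGeneSet":
        label = ""
        up, down = set(), set()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "contrast:" in line:
                        label = line.split("contrast:", 1)[1].strip()
                    continue
                gene, direction = line.split("\t")
                (up if direction == "up" else down).add(gene)
        return cls(label=label, up=frozenset(up), down=frozenset(down))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def estimate_size_factors(
    counts: CountMatrix | pd.DataFrame, pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample, the factor is the median over reference genes of
    count / geometric-mean-across-samples.  Reference genes are those with no
    zero count; if none exists, pass ``pseudo_reference=True`` to compute
    geometric means over positive entries only.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    vals = mat.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(vals)
    zero_free = np.all(vals > 0, axis=1)
    if not zero_free.any():
        if not pseudo_reference:
            raise SizeFactorError(
                "no gene has all-positive counts; rerun with "
                "pseudo_reference=True to use a positive-entry pseudo-reference"
            )
        pos = vals > 0
        ngenes_pos = pos.sum(axis=1)
        usable = ngenes_pos > 0
        log_geo = np.full(vals.shape[0], np.nan)
        log_geo[usable] = (
            np.where(pos, logc, 0.0).sum(axis=1)[usable] / ngenes_pos[usable]
        )
        log_ratio = logc - log_geo[:, None]
        factors = np.exp(np.nanmedian(np.where(pos, log_ratio, np.nan), axis=0))
    else:
        log_geo = logc[zero_free].mean(axis=1)
        log_ratio = logc[zero_free] - log_geo[:, None]
        factors = np.exp(np.median(log_ratio, axis=0))
    return pd.Series(factors, index=mat.columns, name="size_factor")


def normalized_counts(
    counts: CountMatrix | pd.DataFrame, size_factors: pd.Series
) -> pd.DataFrame:
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    return mat / size_factors.reindex(mat.columns)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def _fit_dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0/mu + a1 (both non-negative) and return fitted values.

    Falls back to the median dispersion when too few informative genes exist.
    """
    mask = (mu > 0) & (alpha > DISPERSION_FLOOR) & np.isfinite(alpha)
    out_mu = np.where(mu > 0, mu, np.nan)
    if mask.sum() < 10:
        level = float(np.median(alpha[mask])) if mask.any() else DISPERSION_FLOOR
        return np.full_like(alpha, max(level, DISPERSION_FLOOR))
    design = np.column_stack([1.0 / mu[mask], np.ones(mask.sum())])
    coef, _ = _nnls(design, alpha[mask])
    fitted = coef[0] / out_mu + coef[1]
    fitted = np.where(np.isfinite(fitted), fitted, DISPERSION_FLOOR)
    return np.maximum(fitted, DISPERSION_FLOOR)


def _nnls(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    from scipy.optimize import nnls

    return nnls(design, y)


def estimate_dispersion(
    counts: CountMatrix | pd.DataFrame,
    size_factors: pd.Series,
    groups: Sequence[Sequence[str]] | None = None,
    floor: float = DISPERSION_FLOOR,
    gene_weight: float = 0.25,
    trend_floor: float = 0.7,
    shrink: bool = True,
) -> pd.Series:
    """Per-gene NB dispersion alpha with Var = mu + alpha mu^2.

    A method-of-moments estimate ``max(floor, (s^2 - m)/m^2)`` is computed on
    normalized counts within each replicate group (so real between-group
    signal does not masquerade as dispersion), pooled across groups weighted
    by degrees of freedom.  The gene-wise estimate is then corrected for the
    downward log-scale bias of a chi-square-distributed variance estimate
    (``psi(df/2) - log(df/2)`` with df the pooled residual degrees of
    freedom) and shrunk toward a fitted a0/mu + a1 mean-dispersion trend by a
    log-space weighted average with weight ``gene_weight`` on the gene-wise
    estimate.  To keep the downstream Wald test calibrated at few replicates,
    the result is floored at ``trend_floor`` times the trend (a conservative
    sharing rule in the spirit of DESeq's "maximum" mode).  ``shrink=False``
    returns the raw floored method-of-moments values.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    if mat.shape[1] < 2:
        raise ValueError("dispersion estimation needs at least 2 samples")
    if groups is None:
        groups = [list(mat.columns)]
    norm = normalized_counts(mat, size_factors)

    num = np.zeros(mat.shape[0])
    den = np.zeros(mat.shape[0])
    df_total = 0
    for group in groups:
        sub = norm[list(group)].to_numpy()
        n = sub.shape[1]
        if n < 2:
            continue
        df_total += n - 1
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / (m * m)
        ok = m > 0
        num[ok] += (n - 1) * a[ok]
        den[ok] += n - 1
    with np.errstate(invalid="ignore"):
        raw = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    raw = np.where(np.isfinite(raw), raw, floor)
    raw = np.maximum(raw, floor)

    if not shrink:
        return pd.Series(raw, index=mat.index, name="dispersion")

    overall_mu = norm.to_numpy().mean(axis=1)
    trend = _fit_dispersion_trend(overall_mu, raw)
    # E[log(chi2_df / df)] correction for the log-scale averaging
    log_bias = psi(df_total / 2.0) - np.log(df_total / 2.0) if df_total >= 1 else 0.0
    log_gene = np.log(raw) - log_bias
    log_final = gene_weight * log_gene + (1.0 - gene_weight) * np.log(trend)
    final = np.maximum(np.exp(log_final), trend_floor * trend)
    final = np.maximum(final, floor)
    return pd.Series(final, index=mat.index, name="dispersion")


# ---------------------------------------------------------------------------
# Wald test
# ---------------------------------------------------------------------------

_BETA_CLAMP = 50.0  # natural-log scale; |lfc| <= 50/ln2


def wald_test(
    counts: CountMatrix,
    size_factors: pd.Series,
    dispersions: pd.Series,
    contrast: ContrastSpec,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ContrastResult:
    """Per-gene NB GLM Wald test of group A versus group B.

    Genes with all-zero counts across the contrast samples are excluded from
    testing (NaN statistics).  Genes whose IRLS fit fails to converge within
    ``max_iter`` iterations are flagged, set NaN, and excluded from the BH
    universe; their count is logged.
    """
    ids = list(contrast.samples)
    missing = set(ids) - set(counts.sample_ids)
    if missing:
        raise ValueError(f"contrast references unknown samples: {sorted(missing)}")
    y = counts.counts[ids].to_numpy(dtype=float)
    s = size_factors.reindex(ids).to_numpy(dtype=float)
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("size factors must be positive and finite")
    alpha = dispersions.reindex(counts.genes).to_numpy(dtype=float)
    x = np.array([1.0 if sid in set(contrast.group_a) else 0.0 for sid in ids])
    log_s = np.log(s)

    n_genes = y.shape[0]
    tested = y.sum(axis=1) > 0

    q = y / s  # normalized counts
    base_mean = q.mean(axis=1)

    in_a = x == 1.0
    eps = 1e-8
    mu_a0 = np.maximum(q[:, in_a].mean(axis=1), eps)
    mu_b0 = np.maximum(q[:, ~in_a].mean(axis=1), eps)
    beta0 = np.log(mu_b0)
    beta1 = np.log(mu_a0) - beta0

    converged = np.zeros(n_genes, dtype=bool)
    active = tested.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        eta = beta0[:, None] + beta1[:, None] * x[None, :] + log_s[None, :]
        mu = np.exp(np.clip(eta, -500, 500))
        mu = np.clip(mu, 1e-10, 1e12)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - log_s[None, :]) + (y - mu) / mu
        wa = (w * in_a[None, :]).sum(axis=1)
        wb = (w * (~in_a)[None, :]).sum(axis=1)
        swz_a = (w * z * in_a[None, :]).sum(axis=1)
        swz_b = (w * z * (~in_a)[None, :]).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            new_b0 = swz_b / wb
            new_b1 = swz_a / wa - new_b0
        new_b0 = np.clip(np.where(np.isfinite(new_b0), new_b0, beta0), -_BETA_CLAMP, _BETA_CLAMP)
        new_b1 = np.clip(np.where(np.isfinite(new_b1), new_b1, beta1), -_BETA_CLAMP, _BETA_CLAMP)
        delta = np.maximum(np.abs(new_b0 - beta0), np.abs(new_b1 - beta1))
        beta0 = np.where(active, new_b0, beta0)
        beta1 = np.where(active, new_b1, beta1)
        newly = active & (delta < tol)
        converged |= newly
        active &= ~newly
    n_nonconverged = int((tested & ~converged).sum())
    if n_nonconverged:
        logger.warning(
            "%s: %d gene(s) did not converge in %d IRLS iterations; excluded",
            contrast.label,
            n_nonconverged,
            max_iter,
        )
    usable = tested & converged

    eta = beta0[:, None] + beta1[:, None] * x[None, :] + log_s[None, :]
    mu = np.clip(np.exp(np.clip(eta, -500, 500)), 1e-10, 1e12)
    w = mu / (1.0 + alpha[:, None] * mu)
    wa = (w * in_a[None, :]).sum(axis=1)
    wb = (w * (~in_a)[None, :]).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_nat = np.sqrt(1.0 / wa + 1.0 / wb)

    lfc = np.where(usable, beta1 / LN2, np.nan)
    lfc_se = np.where(usable, se_nat / LN2, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = lfc / lfc_se
    pvalue = np.where(np.isfinite(stat), 2.0 * stats.norm.sf(np.abs(stat)), np.nan)

    table = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": lfc,
            "lfcSE": lfc_se,
            "stat": stat,
            "pvalue": pvalue,
        },
        index=counts.genes,
    )
    table["padj"] = adjust_bh(table["pvalue"])
    return ContrastResult(
        label=contrast.label,
        table=table[RESULT_COLUMNS],
        size_factors=pd.Series(s, index=ids, name="size_factor"),
        n_nonconverged=n_nonconverged,
    )


def adjust_bh(p_values: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjustment with NaN propagation.

    NaN entries (untested genes) are ignored for the adjustment and stay NaN
    in the output; the BH universe is the set of finite p-values.
    """
    is_series = isinstance(p_values, pd.Series)
    arr = np.asarray(p_values, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = np.isfinite(arr)
    if mask.any():
        out[mask] = multipletests(arr[mask], method="fdr_bh")[1]
    if is_series:
        return pd.Series(out, index=p_values.index, name="padj")
    return out


def call_de(result: ContrastResult, cfg: DECallConfig | None = None) -> DEGeneSet:
    """Apply the abundance/significance rule and partition by fold-change sign.

    A gene is called iff baseMean >= base_mean_min AND padj <= padj_max (both
    inclusive).  A called gene with log2FoldChange exactly 0 is assigned "up"
    and a warning is emitted (deterministic tie rule; cannot occur in
    continuous arithmetic).
    """
    cfg = cfg or DECallConfig()
    t = result.table
    called = t[
        (t["baseMean"] >= cfg.base_mean_min) & (t["padj"] <= cfg.padj_max)
    ]
    zero_lfc = called.index[called["log2FoldChange"] == 0.0]
    if len(zero_lfc):
        warnings.warn(
            f"{len(zero_lfc)} called gene(s) with log2FoldChange exactly 0 "
            "assigned 'up'",
            stacklevel=2,
        )
    up = frozenset(called.index[called["log2FoldChange"] >= 0.0])
    down = frozenset(called.index[called["log2FoldChange"] < 0.0])
    return DEGeneSet(label=result.label, up=up, down=down)
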