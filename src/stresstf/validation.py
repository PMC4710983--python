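"""Cross-validation computations: ddCt qPCR fold changes, RNA-seq
concordance, and fermentation specific rates.

The ddCt method quantifies a target transcript relative to an endogenous
control gene and a reference sample:

    dCt  = Ct_target - Ct_control            (per sample)
    ddCt = dCt_sample - dCt_reference
    fold change = efficiency ** (-ddCt)

with perfect-doubling efficiency 2.0 by default.  Specific fermentation rates
are least-squares slopes over a user-chosen time window, normalized per OD600
unit for the metabolite rates (no dry-weight conversion is applied).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CtTable:
    """Cycle-threshold measurements per (sample, gene).

    ``ct`` is long format with columns sample, gene, ct; technical replicates
    (duplicate sample/gene rows) are resolved to their mean.  The control gene
    must be measured in every sample.
    """

    ct: pd.DataFrame
    control_gene: str
    reference_sample: str

    def __post_init__(self) -> None:
        required = {"sample", "gene", "ct"}
        if not required <= set(self.ct.columns):
            raise ValueError(f"Ct table needs columns {sorted(required)}")
        vals = self.ct["ct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError("Ct values must be finite and positive")
        if self.reference_sample not in set(self.ct["sample"]):
            raise ValueError(f"reference sample {self.reference_sample!r} not measured")
        resolved = self.resolved()
        for sample in resolved.index:
            if self.control_gene not in resolved.columns or np.isnan(
                resolved.loc[sample, self.control_gene]
            ):
                raise ValueError(
                    f"control gene {self.control_gene!r} missing in sample {sample!r}"
                )

    def resolved(self) -> pd.DataFrame:
        """Sample x gene mean Ct with technical replicates averaged."""
        return self.ct.groupby(["sample", "gene"])["ct"].mean().unstack("gene")

    def to_tsv(self, path) -> None:
        self.ct.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, control_gene: str, reference_sample: str) -> "CtTable":
        return cls(
            ct=pd.read_csv(path, sep="\t"),
            control_gene=control_gene,
            reference_sample=reference_sample,
        )


def delta_delta_ct(
    table: CtTable, target: str, efficiency: float = 2.0
) -> pd.Series:
    """Per-sample fold change of ``target`` by the ddCt method.

    The reference sample's fold change is exactly 1 by construction.  Adding a
    constant to all Ct values of one sample (a machine offset) leaves the
    result unchanged because dCt removes it.
    """
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must be > 1")
    resolved = table.resolved()
    if target not in resolved.columns:
        raise ValueError(f"target gene {target!r} not measured")
    missing = resolved.index[resolved[target].isna()]
    if len(missing):
        raise ValueError(f"target {target!r} missing in sample {missing[0]!r}")
    dct = resolved[target] - resolved[table.control_gene]
    ddct = dct - dct.loc[table.reference_sample]
    fold = np.power(efficiency, -ddct)
    fold.name = f"fold_change_{target}"
    return fold


@dataclass
class Concordance:
    r: float
    slope: float
    n: int


def concordance(
    qpcr_lfc: Sequence[float] | pd.Series, rnaseq_lfc: Sequence[float] | pd.Series
) -> Concordance:
    """Pearson correlation (symmetric) and y-on-x slope of paired log2 FCs.

    Pairs with a non-finite value in either vector are dropped; n reports the
    pairs used.
    """
    x = np.asarray(qpcr_lfc, dtype=float)
    y = np.asarray(rnaseq_lfc, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 2:
        raise ValueError("need at least 2 finite pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    slope = float(np.polyfit(x, y, 1)[0])
    return Concordance(r=r, slope=slope, n=int(len(x)))


@dataclass
class FermentationSeries:
    """Batch fermentation time series: OD600 and metabolite concentrations."""

    data: pd.DataFrame  # columns: time, od600, glucose, ethanol, acetate, glycerol

    def __post_init__(self) -> None:
        required = {"time", "od600", "glucose", "ethanol", "acetate", "glycerol"}
        if not required <= set(self.data.columns):
            raise ValueError(f"series needs columns {sorted(required)}")
        t = self.data["time"].to_numpy(dtype=float)
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        conc = self.data[["od600", "glucose", "ethanol", "acetate", "glycerol"]]
        if (conc.to_numpy(dtype=float) < 0).any():
            raise ValueError("concentrations must be non-negative")

    def window(self, t0: float, t1: float) -> pd.DataFrame:
        mask = (self.data["time"] >= t0) & (self.data["time"] <= t1)
        return self.data[mask]

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FermentationSeries":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class SpecificRates:
    """Window-based specific rates.

    ``growth_rate`` (1/h) is the slope of ln(OD600) versus time; metabolite
    rates (g per OD unit per h) are concentration slopes divided by the mean
    OD600 in the window, sign-normalized so that consumption is positive.
    """

    growth_rate: float
    glucose_consumption_rate: float
    ethanol_production_rate: float
    n_points: int
    window: tuple[float, float]


def specific_rates(
    series: FermentationSeries, window: tuple[float, float]
) -> SpecificRates:
    """Least-squares specific rates over a time window.

    Requires >= 3 points in the window with positive OD.  Invariant under a
    constant time shift applied to both the series and the window.
    """
    t0, t1 = window
    sub = series.window(t0, t1)
    if len(sub) < 3:
        raise ValueError(
            f"window [{t0}, {t1}] contains {len(sub)} point(s); need >= 3"
        )
    od = sub["od600"].to_numpy(dtype=float)
    if np.any(od <= 0):
        raise ValueError("OD600 must be positive inside the window")
    t = sub["time"].to_numpy(dtype=float)
    mu = float(np.polyfit(t, np.log(od), 1)[0])
    mean_od = float(od.mean())
    glucose_slope = float(np.polyfit(t, sub["glucose"].to_numpy(dtype=float), 1)[0])
    ethanol_slope = float(np.polyfit(t, sub["ethanol"].to_numpy(dtype=float), 1)[0])
    return SpecificRates(
        growth_rate=mu,
        glucose_consumption_rate=-glucose_slope / mean_od,
        ethanol_production_rate=ethanol_slope / mean_od,
        n_points=int(len(sub)),
        window=(float(t0), float(t1)),
    )
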