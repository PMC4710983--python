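"""Transcription-factor regulon coverage profiling.

Given a TF -> target regulon table (YEASTRACT-export style, with evidence
labels) and a pool of consensus differentially expressed genes, rank TFs by
coverage fraction

    coverage(TF) = |targets(TF) ∩ pool| / |pool|

after restricting the table to documented (direct or indirect) regulations.
The top-k profile of that ranking is the analysis's primary deliverable.  A
hypergeometric enrichment companion statistic is provided as an extension
beyond the coverage ranking; it never alters the ranking itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de import adjust_bh

EVIDENCE_LEVELS = ("documented-direct", "documented-indirect", "potential")

#: The evidence filter used throughout the analysis: documented only.
DOCUMENTED = frozenset({"documented-direct", "documented-indirect"})


@dataclass
class RegulonNetwork:
    """TF -> target edges with evidence labels.

    ``edges`` has columns tf, target, evidence.  Duplicate (tf, target,
    evidence) triples are rejected; duplicate (tf, target) pairs with distinct
    evidence are allowed and never double-count coverage.
    """

    edges: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"tf", "target", "evidence"}
        if not required <= set(self.edges.columns):
            raise ValueError(f"edge table needs columns {sorted(required)}")
        if self.edges.duplicated(["tf", "target", "evidence"]).any():
            raise ValueError("duplicate (tf, target, evidence) edges")
        for col in ("tf", "target"):
            vals = self.edges[col]
            if len(vals) and (vals.astype(str).str.len() == 0).any():
                raise ValueError(f"empty {col} identifier")

    @property
    def tfs(self) -> list[str]:
        return sorted(self.edges["tf"].unique())

    def targets_of(self, tf: str) -> frozenset:
        return frozenset(self.edges.loc[self.edges["tf"] == tf, "target"])

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RegulonNetwork":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class TFProfile:
    """Ranked per-TF coverage of a gene pool.

    ``table`` columns: tf, n_covered, coverage, genes — sorted by coverage
    descending, tf id ascending.  ``boundary_tie`` is set by :func:`top_k`
    when the cut falls inside a tie group.
    """

    pool_size: int
    table: pd.DataFrame
    boundary_tie: bool = False

    def coverage_of(self, tf: str) -> float:
        row = self.table[self.table["tf"] == tf]
        if row.empty:
            raise KeyError(tf)
        return float(row["coverage"].iloc[0])

    def rank_of(self, tf: str) -> int:
        """1-based rank in the deterministic ordering."""
        idx = self.table.index[self.table["tf"] == tf]
        if len(idx) == 0:
            raise KeyError(tf)
        return int(self.table.index.get_loc(idx[0])) + 1

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "rank", np.arange(1, len(out) + 1))
        out["coverage_pct"] = 100.0 * out.pop("coverage")
        out["genes"] = out["genes"].map(lambda gs: ";".join(sorted(gs)))
        out.to_csv(path, sep="\t", index=False)


def filter_evidence(
    net: RegulonNetwork, allowed: frozenset | set = DOCUMENTED
) -> RegulonNetwork:
    """Restrict the regulon table to edges whose evidence is in ``allowed``."""
    allowed = frozenset(allowed)
    kept = net.edges[net.edges["evidence"].isin(allowed)].reset_index(drop=True)
    return RegulonNetwork(kept)


def coverage_profile(net: RegulonNetwork, pool: set) -> TFProfile:
    """Per-TF coverage of the pool; zero-coverage TFs are retained.

    Ordering is coverage descending with ties broken by tf id ascending;
    duplicate edges and edge order cannot affect the result.
    """
    pool = set(pool)
    if not pool:
        raise ValueError("empty gene pool: coverage is undefined")
    rows = []
    unique = net.edges.drop_duplicates(["tf", "target"])
    grouped = unique.groupby("tf")["target"]
    for tf, targets in grouped:
        covered = frozenset(targets) & pool
        rows.append(
            {
                "tf": tf,
                "n_covered": len(covered),
                "coverage": len(covered) / len(pool),
                "genes": frozenset(covered),
            }
        )
    table = pd.DataFrame(rows, columns=["tf", "n_covered", "coverage", "genes"])
    table = table.sort_values(
        ["coverage", "tf"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return TFProfile(pool_size=len(pool), table=table)


def top_k(profile: TFProfile, k: int = 20) -> TFProfile:
    """First k records of the deterministic ordering.

    Ties at the k-boundary are broken by tf id ascending (the ordering already
    encodes that); ``boundary_tie`` notes when the cut splits a tie group.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    table = profile.table
    if k >= len(table):
        return TFProfile(pool_size=profile.pool_size, table=table.copy())
    tie = (
        len(table) > k
        and k > 0
        and table["coverage"].iloc[k - 1] == table["coverage"].iloc[k]
    )
    return TFProfile(
        pool_size=profile.pool_size,
        table=table.iloc[:k].reset_index(drop=True),
        boundary_tie=bool(tie),
    )


def hypergeometric_enrichment(
    net: RegulonNetwork,
    pool: set,
    gene_universe: Sequence[str],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of each regulon in the pool.

    Extension beyond the coverage ranking: for each TF, the tail probability
    P(X >= observed overlap) of drawing the overlap when |pool| genes are
    sampled from the universe, with the regulon restricted to universe genes.
    BH-adjusted q-values are computed across TFs.  Never used for ranking.
    """
    pool = set(pool)
    universe = set(gene_universe)
    if not pool:
        raise ValueError("empty gene pool")
    if not pool <= universe:
        raise ValueError("pool must be a subset of the gene universe")
    rows = []
    unique = net.edges.drop_duplicates(["tf", "target"])
    for tf, targets in unique.groupby("tf")["target"]:
        regulon = frozenset(targets) & universe
        overlap = len(regulon & pool)
        p = float(hypergeom.sf(overlap - 1, len(universe), len(regulon), len(pool)))
        rows.append(
            {"tf": tf, "regulon_size": len(regulon), "overlap": overlap, "pvalue": p}
        )
    out = pd.DataFrame(rows, columns=["tf", "regulon_size", "overlap", "pvalue"])
    out["qvalue"] = adjust_bh(out["pvalue"].to_numpy())
    return out.sort_values("tf", kind="mergesort").reset_index(drop=True)
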