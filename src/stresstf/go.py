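"""GO pool-percentage profiling of differentially expressed gene sets.

The annotation is a flat gene -> slim-term table (no ontology traversal: the
input is taken to be already slimmed by a GO term mapper).  A profile reports,
for each term, the genes of a DE pool annotated to it and the percentage
100 * |term genes ∩ pool| / |pool|; multi-annotated genes count toward every
term they carry, so percentages need not sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .consensus import condition_specific_genes


@dataclass
class GOAnnotation:
    """Flat gene -> set-of-term annotation plus term id -> name mapping."""

    gene_terms: dict[str, frozenset]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene in self.gene_terms:
            if not isinstance(gene, str) or not gene:
                raise ValueError(f"malformed gene id: {gene!r}")

    @property
    def terms(self) -> frozenset:
        out: set = set()
        for t in self.gene_terms.values():
            out |= t
        return frozenset(out)

    def genes_of(self, term: str) -> frozenset:
        return frozenset(g for g, ts in self.gene_terms.items() if term in ts)

    def name_of(self, term: str) -> str:
        return self.term_names.get(term, term)

    def to_tsv(self, annotation_path, names_path=None) -> None:
        rows = [
            {"gene": g, "term": t}
            for g, ts in sorted(self.gene_terms.items())
            for t in sorted(ts)
        ]
        pd.DataFrame(rows, columns=["gene", "term"]).to_csv(
            annotation_path, sep="\t", index=False
        )
        if names_path is not None:
            pd.DataFrame(
                sorted(self.term_names.items()), columns=["term", "name"]
            ).to_csv(names_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, annotation_path, names_path=None) -> "GOAnnotation":
        ann = pd.read_csv(annotation_path, sep="\t")
        gene_terms: dict[str, set] = {}
        for gene, term in zip(ann["gene"], ann["term"]):
            gene_terms.setdefault(str(gene), set()).add(str(term))
        names = {}
        if names_path is not None:
            nm = pd.read_csv(names_path, sep="\t")
            names = dict(zip(nm["term"].astype(str), nm["name"].astype(str)))
        return cls(
            gene_terms={g: frozenset(ts) for g, ts in gene_terms.items()},
            term_names=names,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, term_name_col: str | None = None):
        """Build from a long DataFrame with ``gene`` and ``term`` columns."""
        gene_terms: dict[str, set] = {}
        for gene, term in zip(frame["gene"], frame["term"]):
            gene_terms.setdefault(str(gene), set()).add(str(term))
        names = {}
        if term_name_col is not None and term_name_col in frame:
            names = (
                frame.drop_duplicates("term")
                .set_index("term")[term_name_col]
                .astype(str)
                .to_dict()
            )
        return cls(
            gene_terms={g: frozenset(ts) for g, ts in gene_terms.items()},
            term_names=names,
        )


@dataclass
class GOProfile:
    """Per-term membership and pool percentages for one DE gene pool."""

    pool_size: int
    table: pd.DataFrame  # columns: term, name, n_genes, percentage, genes
    unannotated: frozenset

    def percentage_of(self, term: str) -> float:
        row = self.table[self.table["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["percentage"].iloc[0])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["genes"] = out["genes"].map(lambda gs: ";".join(sorted(gs)))
        out.to_csv(path, sep="\t", index=False)


def profile(
    pool: set,
    annotation: GOAnnotation,
    terms: Sequence[str] | None = None,
) -> GOProfile:
    """Percentage of the DE pool annotated to each term.

    ``terms`` restricts the reported terms (the full annotated term universe
    otherwise).  Pool genes with no annotation are reported separately.
    """
    pool = set(pool)
    if not pool:
        raise ValueError("empty gene pool: percentages are undefined")
    term_list = list(terms) if terms is not None else sorted(annotation.terms)
    rows = []
    for term in term_list:
        members = annotation.genes_of(term) & pool
        rows.append(
            {
                "term": term,
                "name": annotation.name_of(term),
                "n_genes": len(members),
                "percentage": 100.0 * len(members) / len(pool),
                "genes": frozenset(members),
            }
        )
    table = pd.DataFrame(rows, columns=["term", "name", "n_genes", "percentage", "genes"])
    unannotated = frozenset(
        g for g in pool if not (annotation.gene_terms.get(g, frozenset()))
    )
    return GOProfile(pool_size=len(pool), table=table, unannotated=unannotated)


@dataclass
class TermConditionTable:
    """Per term x condition gene listings with cross-condition common marking.

    ``table`` is long format (term, name, condition, gene, common) where
    ``common`` marks membership in the all-condition intersection within that
    term.  ``common_genes`` gives the intersection per term.
    """

    conditions: tuple[str, ...]
    table: pd.DataFrame
    common_genes: dict[str, frozenset]

    @property
    def total_common(self) -> int:
        return sum(len(v) for v in self.common_genes.values())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def term_condition_table(
    pools: Mapping[str, set],
    annotation: GOAnnotation,
    terms: Sequence[str] | None = None,
) -> TermConditionTable:
    """Cross-condition per-term gene table with common genes marked.

    For each term, the genes of each condition's pool annotated to it are
    listed; a gene is marked common iff it appears for that term in every
    condition.
    """
    if not pools:
        raise ValueError("term_condition_table needs at least one condition pool")
    conditions = tuple(pools)
    term_list = list(terms) if terms is not None else sorted(annotation.terms)
    rows = []
    common_map: dict[str, frozenset] = {}
    for term in term_list:
        term_genes = annotation.genes_of(term)
        per_cond = {c: term_genes & set(pools[c]) for c in conditions}
        _, common = condition_specific_genes(per_cond)
        common_map[term] = common
        for cond in conditions:
            for gene in sorted(per_cond[cond]):
                rows.append(
                    {
                        "term": term,
                        "name": annotation.name_of(term),
                        "condition": cond,
                        "gene": gene,
                        "common": gene in common,
                    }
                )
    table = pd.DataFrame(rows, columns=["term", "name", "condition", "gene", "common"])
    return TermConditionTable(conditions=conditions, table=table, common_genes=common_map)
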