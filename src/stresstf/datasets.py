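"""Bundled gene-list fixtures transcribed from the study's printed GO tables.

Three small TSVs ship with the package:

``wildtype_stress_go.tsv``
    Per GO term and inhibitor condition (AA = acetic acid, FF = furfural,
    AAFF = mixture), the genes of the wild-type control strain's DE pool
    annotated to that term.
``resistant_stress_go.tsv``
    The same layout for the inhibitor-resistant strain.
``consensus_go.tsv``
    Per GO term, the consensus genes (resistant vs wild-type, all conditions)
    annotated to that term.

Gene lists are stored verbatim; cross-condition common-gene marking is always
recomputed by :func:`stresstf.go.term_condition_table`, never read from disk.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .go import GOAnnotation

CONDITIONS = ("AA", "FF", "AAFF")


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("stresstf").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_wildtype_stress_go() -> pd.DataFrame:
    """Long table (term, name, condition, gene) for the wild-type strain."""
    return _read("wildtype_stress_go.tsv")


def load_resistant_stress_go() -> pd.DataFrame:
    """Long table (term, name, condition, gene) for the resistant strain."""
    return _read("resistant_stress_go.tsv")


def load_consensus_go() -> pd.DataFrame:
    """Long table (term, name, gene) of consensus genes per GO term."""
    return _read("consensus_go.tsv")


def pools_from_table(table: pd.DataFrame) -> dict[str, set]:
    """Per-condition DE gene pools: the union of all term rows per condition."""
    return {
        cond: set(sub["gene"])
        for cond, sub in table.groupby("condition", sort=False)
    }


def annotation_from_table(table: pd.DataFrame) -> GOAnnotation:
    """Flat GO annotation built from a fixture's (gene, term) rows."""
    return GOAnnotation.from_frame(table, term_name_col="name")


def term_gene_lists(table: pd.DataFrame) -> dict[str, dict[str, frozenset]]:
    """Nested term -> condition -> genes view of a per-condition fixture."""
    out: dict[str, dict[str, frozenset]] = {}
    for (term, cond), sub in table.groupby(["term", "condition"], sort=False):
        out.setdefault(term, {})[cond] = frozenset(sub["gene"])
    return out
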