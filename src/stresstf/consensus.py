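"""Set algebra over differential-expression gene sets.

Three operations mirror the comparative stage of the analysis: exclusive-region
Venn decomposition of per-condition DE sets, identification of consensus genes
called in every strain-vs-strain contrast with direction classification
(universally up, universally down, or bifurcated), and per-condition
exclusive/common gene partitioning within one strain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

from .de import DEGeneSet


@dataclass
class VennOverlap:
    """Exclusive-region decomposition of labeled gene sets.

    ``regions`` maps every non-empty label combination (as a frozenset of
    labels) to the genes belonging to exactly those input sets.  Regions are
    pairwise disjoint and their union equals the union of the inputs.
    """

    labels: tuple[str, ...]
    regions: dict[frozenset, frozenset]

    @property
    def counts(self) -> dict[frozenset, int]:
        return {combo: len(genes) for combo, genes in self.regions.items()}

    def region(self, *labels: str) -> frozenset:
        return self.regions[frozenset(labels)]


def venn_overlap(sets: Mapping[str, set] | Sequence[tuple[str, set]]) -> VennOverlap:
    """Decompose >= 2 labeled gene sets into exclusive Venn regions."""
    if isinstance(sets, Mapping):
        items = list(sets.items())
    else:
        items = [(label, set(genes)) for label, genes in sets]
        labels_seen = [label for label, _ in items]
        if len(labels_seen) != len(set(labels_seen)):
            raise ValueError("duplicate set labels")
    if len(items) < 2:
        raise ValueError("venn_overlap needs at least 2 sets")
    labels = tuple(label for label, _ in items)
    by_label = {label: set(genes) for label, genes in items}
    universe = set().union(*by_label.values())
    membership: dict[frozenset, set] = {}
    for gene in universe:
        combo = frozenset(l for l in labels if gene in by_label[l])
        membership.setdefault(combo, set()).add(gene)
    regions = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            key = frozenset(combo)
            regions[key] = frozenset(membership.get(key, set()))
    return VennOverlap(labels=labels, regions=regions)


@dataclass
class ConsensusResult:
    """Genes called in every contrast, partitioned by direction behaviour.

    ``sign_vectors`` records, for each bifurcated gene, the per-contrast call
    direction (+1 up / -1 down).  The three classes partition ``consensus``.
    """

    contrast_labels: tuple[str, ...]
    consensus: frozenset
    universal_up: frozenset
    universal_down: frozenset
    bifurcated: frozenset
    sign_vectors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        parts = [self.universal_up, self.universal_down, self.bifurcated]
        union = frozenset().union(*parts)
        if union != self.consensus or sum(map(len, parts)) != len(union):
            raise ValueError("direction classes must partition the consensus set")

    def classification(self, gene) -> str:
        if gene in self.universal_up:
            return "up"
        if gene in self.universal_down:
            return "down"
        if gene in self.bifurcated:
            return "bifurcated"
        raise KeyError(gene)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tclass\t" + "\t".join(self.contrast_labels) + "\n")
            for gene in sorted(self.consensus):
                cls = self.classification(gene)
                default = 1 if cls == "up" else -1
                signs = self.sign_vectors.get(gene, {})
                row = "\t".join(
                    str(signs.get(label, default)) for label in self.contrast_labels
                )
                fh.write(f"{gene}\t{cls}\t{row}\n")


def consensus_genes(contrast_sets: Sequence[DEGeneSet]) -> ConsensusResult:
    """Intersect called sets across contrasts and classify directions.

    A gene is consensus iff it passed the full DE call in every contrast.  It
    is universal-up (down) iff its fold-change sign is positive (negative) in
    every contrast, and bifurcated otherwise; bifurcated genes carry their
    per-contrast sign vector.
    """
    if len(contrast_sets) < 2:
        raise ValueError("consensus requires at least 2 contrasts")
    labels = tuple(cs.label for cs in contrast_sets)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate contrast labels")
    consensus = set(contrast_sets[0].called)
    for cs in contrast_sets[1:]:
        consensus &= cs.called
    up, down, bifurcated = set(), set(), set()
    sign_vectors: dict = {}
    for gene in consensus:
        signs = {cs.label: cs.direction_of(gene) for cs in contrast_sets}
        values = set(signs.values())
        if values == {1}:
            up.add(gene)
        elif values == {-1}:
            down.add(gene)
        else:
            bifurcated.add(gene)
            sign_vectors[gene] = signs
    return ConsensusResult(
        contrast_labels=labels,
        consensus=frozenset(consensus),
        universal_up=frozenset(up),
        universal_down=frozenset(down),
        bifurcated=frozenset(bifurcated),
        sign_vectors=sign_vectors,
    )


def condition_specific_genes(
    per_condition: Mapping[str, set],
) -> tuple[dict[str, frozenset], frozenset]:
    """Per-condition exclusive gene sets and the all-condition common set.

    A gene is exclusive to a condition iff it occurs in that condition's set
    only; the common set is the intersection of all condition sets.
    """
    if not per_condition:
        raise ValueError("at least one condition set required")
    sets = {cond: set(genes) for cond, genes in per_condition.items()}
    common = frozenset(set.intersection(*sets.values()))
    exclusive = {}
    for cond, genes in sets.items():
        others = set().union(*(g for c, g in sets.items() if c != cond)) if len(sets) > 1 else set()
        exclusive[cond] = frozenset(genes - others)
    return exclusive, common
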