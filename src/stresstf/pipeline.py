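"""Configuration-driven end-to-end pipeline.

Stages: simulate (or ingest) counts -> per-contrast NB Wald differential
expression (three condition-vs-reference contrasts per strain plus one
strain-vs-strain contrast per condition) -> per-strain Venn overlaps ->
cross-contrast consensus genes -> GO pool profiles -> evidence-filtered TF
coverage profile -> serialized run report.  A rerun with the same
configuration and seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .consensus import consensus_genes, venn_overlap
from .de import (
    CountMatrix,
    ContrastSpec,
    DECallConfig,
    call_de,
    estimate_dispersion,
    estimate_size_factors,
    wald_test,
)
from .go import GOAnnotation, profile
from .simulate import (
    SimulationConfig,
    condition_contrast_label,
    simulate_counts,
    simulate_go_annotation,
    simulate_regulon,
    strain_contrast_label,
)
from .tf import RegulonNetwork, coverage_profile, filter_evidence, top_k

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def _check_keys(section: str, given: Mapping[str, Any], allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in [{section}]: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Flat, strictly validated run configuration.

    Either ``simulate`` (keyword arguments of :class:`SimulationConfig`) or
    ``input`` (paths: counts, samples, regulon, annotation, term_names) must
    be given.  Unknown keys anywhere are errors, not warnings.
    """

    seed: int = 0
    outdir: str = "stresstf_run"
    simulate: dict = field(default_factory=dict)
    input: dict = field(default_factory=dict)
    de: dict = field(default_factory=dict)
    go: dict = field(default_factory=dict)
    tf: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.input and self.simulate:
            raise ValueError("give either [simulate] or [input], not both")
        _check_keys(
            "simulate",
            self.simulate,
            {f.name for f in fields(SimulationConfig)} - {"seed"},
        )
        _check_keys(
            "input", self.input, {"counts", "samples", "regulon", "annotation", "term_names"}
        )
        _check_keys("de", self.de, {"base_mean_min", "padj_max"})
        _check_keys("go", self.go, {"terms", "n_terms", "terms_per_gene"})
        _check_keys("tf", self.tf, {"evidence", "k", "n_tfs", "planted_tfs",
                                    "background_coverage", "planted_coverage"})
        if self.input:
            for key in ("counts", "samples"):
                if key not in self.input:
                    raise ValueError(f"[input] requires '{key}'")
            for key, path in self.input.items():
                if not Path(path).exists():
                    raise ValueError(f"[input] {key}: file not found: {path}")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        _check_keys("pipeline", data, {f.name for f in fields(cls)})
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @property
    def de_call(self) -> DECallConfig:
        return DECallConfig(**self.de)


@dataclass
class RunReport:
    """Serializable record of one pipeline run."""

    version: str
    seed: int
    config_hash: str
    contrasts: dict  # label -> {total, up, down, n_nonconverged}
    venn: dict  # strain -> {region label -> count}
    consensus: dict  # sizes + gene lists
    go_profiles: dict  # contrast label -> {term -> percentage}
    tf_profile: list  # ranked records
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def write_report(report: RunReport, path) -> None:
    """Serialize the report as JSON plus a human-readable text summary."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    lines = [
        f"stresstf {report.version}  seed={report.seed}  config={report.config_hash}",
        "",
        "Differential expression (total / up / down):",
    ]
    for label, c in report.contrasts.items():
        lines.append(f"  {label}: {c['total']} / {c['up']} / {c['down']}")
    cons = report.consensus
    lines += [
        "",
        f"Consensus genes: {cons['n_consensus']} "
        f"(up {cons['n_universal_up']}, down {cons['n_universal_down']}, "
        f"bifurcated {cons['n_bifurcated']})",
        "",
        "Top TF coverage of the consensus pool:",
    ]
    for rec in report.tf_profile[:5]:
        lines.append(
            f"  {rec['rank']:>2}. {rec['tf']}  {rec['n_covered']} genes "
            f"({rec['coverage_pct']:.1f}%)"
        )
    for note in report.notes:
        lines.append(f"note: {note}")
    with open(path.with_suffix(".txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage failures must name the stage
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


def run(config: PipelineConfig) -> RunReport:
    """Execute all stages, write outputs under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    notes: list[str] = []

    matrix, truth, regulon, annotation = _acquire_inputs(config)
    logger.info("inputs: %d genes x %d samples", *matrix.counts.shape)

    size_factors = estimate_size_factors(matrix)
    strains = list(dict.fromkeys(matrix.samples["strain"]))
    conditions = list(dict.fromkeys(matrix.samples["condition"]))
    if len(strains) != 2:
        raise PipelineError("stage 'contrasts' failed: exactly two strains required")
    reference = conditions[0]

    contrasts: list[ContrastSpec] = []
    for strain in strains:
        for cond in conditions[1:]:
            contrasts.append(
                ContrastSpec(
                    condition_contrast_label(strain, cond, reference),
                    matrix.samples_where(strain=strain, condition=cond),
                    matrix.samples_where(strain=strain, condition=reference),
                )
            )
    strain_contrasts: list[ContrastSpec] = []
    for cond in conditions:
        strain_contrasts.append(
            ContrastSpec(
                strain_contrast_label(cond, strains),
                matrix.samples_where(strain=strains[0], condition=cond),
                matrix.samples_where(strain=strains[1], condition=cond),
            )
        )

    de_cfg = config.de_call
    contrast_report: dict = {}
    gene_sets = {}
    for spec in contrasts + strain_contrasts:
        result, called = _run_contrast(matrix, size_factors, spec, de_cfg)
        result.to_tsv(outdir / f"de_{_safe(spec.label)}.tsv")
        called.to_file(outdir / f"genes_{_safe(spec.label)}.txt")
        gene_sets[spec.label] = called
        contrast_report[spec.label] = {
            "total": len(called.called),
            "up": len(called.up),
            "down": len(called.down),
            "n_nonconverged": result.n_nonconverged,
        }
        logger.info(
            "contrast %s: %d called (%d up / %d down)",
            spec.label,
            len(called.called),
            len(called.up),
            len(called.down),
        )

    venn_report = _venn_stage(gene_sets, strains, conditions, reference)

    consensus_sets = [gene_sets[spec.label] for spec in strain_contrasts]
    cons = consensus_genes(consensus_sets)
    cons.to_tsv(outdir / "consensus.tsv")
    consensus_report = {
        "n_consensus": len(cons.consensus),
        "n_universal_up": len(cons.universal_up),
        "n_universal_down": len(cons.universal_down),
        "n_bifurcated": len(cons.bifurcated),
        "genes": sorted(cons.consensus),
    }

    go_report = _go_stage(config, gene_sets, annotation, outdir, notes)
    tf_report = _tf_stage(config, regulon, cons.consensus, outdir, notes)

    report = RunReport(
        version=__version__,
        seed=config.seed,
        config_hash=_config_hash(config),
        contrasts=contrast_report,
        venn=venn_report,
        consensus=consensus_report,
        go_profiles=go_report,
        tf_profile=tf_report,
        notes=notes,
    )
    write_report(report, outdir / "report.json")
    _verify_counts(report, outdir)
    return report


@_stage("inputs")
def _acquire_inputs(config: PipelineConfig):
    if config.input:
        matrix = CountMatrix.from_tsv(config.input["counts"], config.input["samples"])
        truth = None
        regulon = (
            RegulonNetwork.from_tsv(config.input["regulon"])
            if "regulon" in config.input
            else None
        )
        annotation = (
            GOAnnotation.from_tsv(
                config.input["annotation"], config.input.get("term_names")
            )
            if "annotation" in config.input
            else None
        )
        return matrix, truth, regulon, annotation
    sim_cfg = SimulationConfig(**config.simulate, seed=config.seed)
    matrix, truth = simulate_counts(sim_cfg)
    tf_cfg = {
        k: v
        for k, v in config.tf.items()
        if k in {"n_tfs", "planted_tfs", "background_coverage", "planted_coverage"}
    }
    regulon = simulate_regulon(
        list(matrix.genes), truth, seed=config.seed + 1, **tf_cfg
    )
    go_cfg = {k: v for k, v in config.go.items() if k in {"n_terms", "terms_per_gene"}}
    annotation = simulate_go_annotation(
        list(matrix.genes), seed=config.seed + 2, **go_cfg
    )
    return matrix, truth, regulon, annotation


@_stage("differential_expression")
def _run_contrast(matrix, size_factors, spec, de_cfg):
    sub = matrix.subset_samples(list(spec.samples))
    dispersions = estimate_dispersion(
        sub, size_factors.reindex(sub.sample_ids), groups=[spec.group_a, spec.group_b]
    )
    result = wald_test(matrix, size_factors, dispersions, spec)
    return result, call_de(result, de_cfg)


@_stage("venn")
def _venn_stage(gene_sets, strains, conditions, reference):
    venn_report: dict = {}
    for strain in strains:
        labeled = {
            cond: set(gene_sets[condition_contrast_label(strain, cond, reference)].called)
            for cond in conditions[1:]
        }
        if len(labeled) < 2:
            continue
        overlap = venn_overlap(labeled)
        venn_report[strain] = {
            "+".join(sorted(combo)): count for combo, count in overlap.counts.items()
        }
    return venn_report


@_stage("go_profile")
def _go_stage(config, gene_sets, annotation, outdir, notes):
    if annotation is None:
        notes.append("no GO annotation provided; GO stage skipped")
        return {}
    terms = config.go.get("terms")
    go_report = {}
    for label, called in gene_sets.items():
        pool = set(called.called)
        if not pool:
            notes.append(f"GO profile skipped for {label}: empty DE pool")
            continue
        prof = profile(pool, annotation, terms=terms)
        prof.to_tsv(outdir / f"go_{_safe(label)}.tsv")
        go_report[label] = dict(
            zip(prof.table["term"], prof.table["percentage"].round(6))
        )
    return go_report


@_stage("tf_profile")
def _tf_stage(config, regulon, pool, outdir, notes):
    if regulon is None:
        notes.append("no regulon table provided; TF stage skipped")
        return []
    if not pool:
        notes.append("TF stage skipped: empty consensus pool")
        return []
    allowed = config.tf.get("evidence")
    filtered = filter_evidence(regulon) if allowed is None else filter_evidence(
        regulon, frozenset(allowed)
    )
    prof = top_k(coverage_profile(filtered, set(pool)), k=int(config.tf.get("k", 20)))
    prof.to_tsv(outdir / "tf_profile.tsv")
    return [
        {
            "rank": i + 1,
            "tf": row.tf,
            "n_covered": int(row.n_covered),
            "coverage_pct": 100.0 * row.coverage,
        }
        for i, row in enumerate(prof.table.itertuples())
    ]


def _verify_counts(report: RunReport, outdir: Path) -> None:
    """Report-vs-file consistency: every count equals the emitted file's length."""
    for label, rec in report.contrasts.items():
        genes_file = outdir / f"genes_{_safe(label)}.txt"
        n_lines = sum(
            1 for line in genes_file.read_text().splitlines() if line and not line.startswith("#")
        )
        if n_lines != rec["total"]:
            raise PipelineError(
                f"stage 'report' failed: {genes_file.name} has {n_lines} genes, "
                f"report says {rec['total']}"
            )
    cons_file = outdir / "consensus.tsv"
    n_rows = max(len(cons_file.read_text().splitlines()) - 1, 0)
    if n_rows != report.consensus["n_consensus"]:
        raise PipelineError(
            "stage 'report' failed: consensus.tsv row count mismatch"
        )


def _safe(label: str) -> str:
    return label.replace(":", "_").replace("/", "_")
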