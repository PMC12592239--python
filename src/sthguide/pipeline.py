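"""End-to-end guide-design pipeline: scan -> motif filter -> uniqueness ->
annotate -> report -> select, driven by a single YAML config.

Every stage's attrition is conserved and recorded in an audit table
(|input| = |kept| + |rejected| at each filter), and all outputs are
deterministic for identical inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

from . import tables
from .annotate import (
    DEFAULT_CONVENTION,
    DEFAULT_UPSTREAM_WINDOW,
    annotate_guides,
    select_guides_per_gene,
    targetability_report,
    uncovered_genes,
)
from .genome_io import GeneFeature, GenomeSequence, read_fasta, read_gff3
from .guide_filter import RestrictionMotifSet, motif_filter, spacer_multiplicity
from .pam_scan import (
    DEFAULT_SPACER_LEN,
    GuideCandidate,
    PamSpec,
    ScanStats,
    scan_genomes,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "load_pam_spec",
    "load_motif_set",
    "run_pipeline",
]

log = logging.getLogger("sthguide")


def _builtin(name: str) -> dict:
    with resources.files("sthguide").joinpath(f"data/{name}").open() as fh:
        return yaml.safe_load(fh)


def load_pam_spec(name_or_patterns) -> PamSpec:
    """A PamSpec from a built-in set name, an inline pattern list, or a
    YAML file path containing named sets."""
    if isinstance(name_or_patterns, (list, tuple)):
        return PamSpec("inline", list(name_or_patterns))
    name = str(name_or_patterns)
    builtins = _builtin("pam_sets.yaml")
    if name in builtins:
        return PamSpec(name, builtins[name]["patterns"])
    p = Path(name)
    if p.exists():
        data = yaml.safe_load(p.read_text())
        if len(data) == 1:
            key = next(iter(data))
            return PamSpec(key, data[key]["patterns"])
        raise ValueError(f"{p}: file defines multiple PAM sets; name one")
    raise ValueError(f"unknown PAM set {name!r} (builtins: {sorted(builtins)})")


def load_motif_set(name_or_motifs) -> RestrictionMotifSet:
    if isinstance(name_or_motifs, (list, tuple)):
        return RestrictionMotifSet("inline", list(name_or_motifs))
    name = str(name_or_motifs)
    builtins = _builtin("motif_sets.yaml")
    if name in builtins:
        e = builtins[name]
        return RestrictionMotifSet(name, e["motifs"], e.get("source", ""))
    p = Path(name)
    if p.exists():
        data = yaml.safe_load(p.read_text())
        if len(data) == 1:
            key = next(iter(data))
            return RestrictionMotifSet(key, data[key]["motifs"],
                                       data[key].get("source", ""))
        raise ValueError(f"{p}: file defines multiple motif sets; name one")
    raise ValueError(f"unknown motif set {name!r} (builtins: {sorted(builtins)})")


@dataclass
class PipelineConfig:
    genome: str
    annotation: str | None = None
    pam_set: object = "sth1_consensus"      # name, path, or pattern list
    motif_set: object = "bbreve_ucc2003"    # name, path, or motif list
    spacer_len: int = DEFAULT_SPACER_LEN
    circular: bool = False
    uniqueness_mode: str = "sequence"       # or pam_adjacent
    motif_window: str = "spacer_only"       # or spacer_plus_pam
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW
    strand_convention: str = DEFAULT_CONVENTION
    report_rule: str = "any_strand"         # or non_template
    n_per_gene: int = 3
    feature_types: tuple = ("gene", "CDS")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict) or "genome" not in data:
            raise ValueError(f"{path}: config must be a mapping with a 'genome' key")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "feature_types" in data:
            data["feature_types"] = tuple(data["feature_types"])
        return cls(**data)


@dataclass
class PipelineResult:
    retained: list[GuideCandidate]
    rejected: list[GuideCandidate]
    selected: list[GuideCandidate]
    uncovered: list[str]
    report: dict
    audit: dict
    genomes: list[GenomeSequence] = field(default_factory=list)
    features: list[GeneFeature] = field(default_factory=list)


def run_pipeline(config: PipelineConfig | str | Path,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full design pipeline; optionally write all artifacts."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)

    log.info("stage=read genome=%s annotation=%s", config.genome, config.annotation)
    genomes = read_fasta(config.genome, circular=config.circular)
    features: list[GeneFeature] = []
    if config.annotation:
        features = read_gff3(config.annotation, config.feature_types, genomes)

    pam_spec = load_pam_spec(config.pam_set)
    motif_set = load_motif_set(config.motif_set)
    log.info("stage=scan pam_set=%s patterns=%s spacer_len=%d",
             pam_spec.name, pam_spec.patterns, config.spacer_len)

    stats = ScanStats()
    guides = scan_genomes(genomes, pam_spec, config.spacer_len, stats)

    kept, motif_rejected = motif_filter(guides, motif_set, config.motif_window)
    log.info("stage=motif_filter kept=%d rejected=%d", len(kept), len(motif_rejected))

    spacer_multiplicity(kept, genomes, config.uniqueness_mode,
                        pam_spec if config.uniqueness_mode == "pam_adjacent" else None)
    retained = [g for g in kept if g.multiplicity == 1]
    nonunique = [g for g in kept if g.multiplicity > 1]
    log.info("stage=uniqueness kept=%d rejected=%d", len(retained), len(nonunique))

    if features:
        annotate_guides(retained, features, config.upstream_window,
                        config.strand_convention)
    report = targetability_report(
        retained, features, genomes, config.report_rule,
        config.strand_convention, config.feature_types,
    )
    selected = (select_guides_per_gene(retained, features, config.n_per_gene)
                if features else [])
    uncovered = uncovered_genes(selected, features)

    rejected = motif_rejected + nonunique
    audit = {
        "pam_sites": stats.n_pam_sites,
        "insufficient_flank": stats.n_insufficient_flank,
        "scanned_guides": len(guides),
        "motif_rejected": len(motif_rejected),
        "after_motif_filter": len(kept),
        "nonunique_rejected": len(nonunique),
        "retained": len(retained),
        "selected": len(selected),
        "uncovered_genes_strict": len(uncovered),
        "parameters": {
            "pam_set": pam_spec.name,
            "pam_patterns": list(pam_spec.patterns),
            "motif_set": motif_set.name,
            "motifs": list(motif_set.motifs),
            "spacer_len": config.spacer_len,
            "circular": config.circular,
            "uniqueness_mode": config.uniqueness_mode,
            "motif_window": config.motif_window,
            "upstream_window": config.upstream_window,
            "strand_convention": config.strand_convention,
            "report_rule": config.report_rule,
            "n_per_gene": config.n_per_gene,
            "feature_types": list(config.feature_types),
        },
    }
    assert audit["scanned_guides"] == len(kept) + len(motif_rejected)
    assert audit["after_motif_filter"] == len(retained) + len(nonunique)

    result = PipelineResult(retained=retained, rejected=rejected,
                            selected=selected, uncovered=uncovered,
                            report=report.to_dict(), audit=audit,
                            genomes=genomes, features=features)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables.write_guide_tsv(retained, out / "guides.tsv")
        tables.write_guide_tsv(rejected, out / "rejected.tsv")
        tables.write_bed6(retained, out / "guides.bed")
        tables.write_spacer_fasta(retained, out / "spacers.fasta")
        tables.write_guide_tsv(selected, out / "selected.tsv")
        (out / "uncovered.tsv").write_text(
            "".join(f"{tag}\n" for tag in uncovered))
        tables.write_json(result.report, out / "report.json")
        tables.write_json(result.audit, out / "audit.json")
    return result
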