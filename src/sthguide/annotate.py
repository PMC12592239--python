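"""Gene-level annotation of guides and genome-wide targetability reporting.

CRISPRi blocks transcription elongation most effectively when the guide
anneals to the non-template (coding/sense) strand of a gene, with the
PAM on the displaced strand.  Under the default convention a guide is
``non_template`` iff its protospacer (PAM-bearing) strand is the
opposite of the gene's coding strand; because the literature uses
"targeting strand X" in both senses, a single switch inverts the
convention genome-wide and every report records which convention
produced it.

Guide-to-gene assignment uses the protospacer midpoint against each
gene's strand-aware interval extended by an upstream window (default
100 bp) so 5' UTR-targeting guides are assigned to the downstream gene.
``offset_from_start`` is the signed distance from the gene's
translational start to the PAM-proximal end of the protospacer
(negative = upstream), the position where the dCas9 roadblock sits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from intervaltree import IntervalTree

from .genome_io import GeneFeature, GenomeSequence
from .pam_scan import GuideCandidate

__all__ = [
    "TargetabilityReport",
    "classify_strand",
    "assign_to_gene",
    "annotate_guides",
    "targetability_report",
    "select_guides_per_gene",
    "uncovered_genes",
]

StrandClass = Literal["non_template", "template"]
Convention = Literal["pam_opposite_coding", "pam_on_coding"]
Rule = Literal["any_strand", "non_template"]

DEFAULT_UPSTREAM_WINDOW = 100
DEFAULT_CONVENTION: Convention = "pam_opposite_coding"


def classify_strand(guide: GuideCandidate, gene: GeneFeature,
                    convention: Convention = DEFAULT_CONVENTION) -> StrandClass:
    """Template / non-template classification of a guide against a gene.

    The guide's target strand (the strand its spacer base-pairs with) is
    the complement of the protospacer strand.  Default convention: the
    guide is non_template iff the target strand is the gene's coding
    strand, i.e. iff protospacer strand != gene strand.
    """
    opposite = guide.protospacer_strand != gene.strand
    if convention == "pam_opposite_coding":
        return "non_template" if opposite else "template"
    if convention == "pam_on_coding":
        return "template" if opposite else "non_template"
    raise ValueError(f"unknown strand convention {convention!r}")


def _gene_window(gene: GeneFeature, upstream_window: int) -> tuple[int, int]:
    """0-based half-open interval of gene body + strand-aware upstream window."""
    s0, e0 = gene.start - 1, gene.end  # GFF3 1-based inclusive -> 0-based half-open
    if gene.strand == "+":
        return max(0, s0 - upstream_window), e0
    return s0, e0 + upstream_window


def _offset_from_start(guide: GuideCandidate, gene: GeneFeature) -> int:
    """Signed bases from the translational start to the PAM-proximal end
    of the protospacer; negative = upstream of the start codon."""
    if guide.protospacer_strand == "+":
        pam_prox = guide.spacer_end - 1  # 0-based last (3'-most) spacer base
    else:
        pam_prox = guide.spacer_start
    if gene.strand == "+":
        return pam_prox - (gene.start - 1)
    return (gene.end - 1) - pam_prox


def assign_to_gene(guide: GuideCandidate, features: Sequence[GeneFeature],
                   upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
                   convention: Convention = DEFAULT_CONVENTION) -> GuideCandidate:
    """Assign a guide to (at most) one gene and fill its annotation fields.

    The guide goes to the gene whose extended interval contains the
    protospacer midpoint; ties (operonic overlap) break by smallest
    |offset_from_start|, then lexicographic locus_tag.  No overlap gives
    strand_class "intergenic".
    """
    if upstream_window < 0:
        raise ValueError("upstream_window must be >= 0")
    mid = guide.midpoint
    candidates = []
    for gene in features:
        if gene.seqid != guide.seqid:
            continue
        lo, hi = _gene_window(gene, upstream_window)
        if lo <= mid < hi:
            off = _offset_from_start(guide, gene)
            candidates.append((abs(off), gene.locus_tag, off, gene))
    if not candidates:
        guide.gene = None
        guide.strand_class = "intergenic"
        guide.offset_from_start = None
        return guide
    candidates.sort(key=lambda t: (t[0], t[1]))
    _, _, off, gene = candidates[0]
    guide.gene = gene.locus_tag
    guide.offset_from_start = off
    guide.strand_class = classify_strand(guide, gene, convention)
    return guide


def annotate_guides(guides: Sequence[GuideCandidate],
                    features: Sequence[GeneFeature],
                    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
                    convention: Convention = DEFAULT_CONVENTION
                    ) -> list[GuideCandidate]:
    """assign_to_gene over a guide list, with an interval index per contig."""
    trees: dict[str, IntervalTree] = {}
    for gene in features:
        lo, hi = _gene_window(gene, upstream_window)
        trees.setdefault(gene.seqid, IntervalTree()).addi(lo, hi, gene)
    for g in guides:
        tree = trees.get(g.seqid)
        overlapping = [iv.data for iv in tree[g.midpoint]] if tree else []
        assign_to_gene(g, overlapping, upstream_window, convention)
    return list(guides)


@dataclass
class TargetabilityReport:
    """Genome-wide guide density and per-gene coverage summary."""

    n_guides: int
    genome_length: int
    bp_per_guide: float | None
    n_genes: int
    n_targetable: int
    per_gene: dict[str, dict]
    rule: str
    convention: str
    feature_types: tuple[str, ...] = ("gene", "CDS")

    def to_dict(self) -> dict:
        return {
            "n_guides": self.n_guides,
            "genome_length": self.genome_length,
            "bp_per_guide": (round(self.bp_per_guide, 2)
                             if self.bp_per_guide is not None else None),
            "n_genes": self.n_genes,
            "n_targetable": self.n_targetable,
            "rule": self.rule,
            "strand_convention": self.convention,
            "feature_types": list(self.feature_types),
            "per_gene": self.per_gene,
        }


def targetability_report(guides: Sequence[GuideCandidate],
                         features: Sequence[GeneFeature],
                         genome: Sequence[GenomeSequence],
                         rule: Rule = "any_strand",
                         convention: Convention = DEFAULT_CONVENTION,
                         feature_types: Sequence[str] = ("gene", "CDS"),
                         ) -> TargetabilityReport:
    """Density and per-gene coverage of an already-filtered guide list.

    rule="any_strand" counts every retained guide assigned to a gene
    (possible target sites); rule="non_template" counts only guides in
    the CRISPRi-effective orientation.
    """
    genome_length = sum(g.length for g in genome)
    n_guides = len(guides)
    per_gene: dict[str, dict] = {}
    for g in guides:
        if g.gene is None:
            continue
        if rule == "non_template" and g.strand_class != "non_template":
            continue
        entry = per_gene.setdefault(g.gene, {"n_guides": 0, "best_offset": None})
        entry["n_guides"] += 1
        off = g.offset_from_start
        if entry["best_offset"] is None or abs(off) < abs(entry["best_offset"]):
            entry["best_offset"] = off
    return TargetabilityReport(
        n_guides=n_guides,
        genome_length=genome_length,
        bp_per_guide=(genome_length / n_guides) if n_guides else None,
        n_genes=len(features),
        n_targetable=len(per_gene),
        per_gene=per_gene,
        rule=rule,
        convention=convention,
        feature_types=tuple(feature_types),
    )


def _selection_key(guide: GuideCandidate) -> tuple:
    off = guide.offset_from_start
    # upstream-window (negative-offset) guides first, nearest the start
    # codon first; then genic guides by ascending offset; guide_id breaks ties
    return (off >= 0, abs(off), guide.guide_id)


def select_guides_per_gene(guides: Sequence[GuideCandidate],
                           features: Sequence[GeneFeature],
                           n_per_gene: int) -> list[GuideCandidate]:
    """Pick up to n_per_gene non-template guides per gene, 5'-proximal first.

    Deterministic: guides rank by upstream-first proximity to the start
    codon, then guide_id.  Genes with no non-template guide contribute
    nothing (see uncovered_genes).
    """
    if n_per_gene < 1:
        raise ValueError("n_per_gene must be >= 1")
    by_gene: dict[str, list[GuideCandidate]] = {}
    for g in guides:
        if g.gene is not None and g.strand_class == "non_template":
            by_gene.setdefault(g.gene, []).append(g)
    order = {f.locus_tag: i for i, f in enumerate(features)}
    selected: list[GuideCandidate] = []
    for tag in sorted(by_gene, key=lambda t: order.get(t, len(order))):
        ranked = sorted(by_gene[tag], key=_selection_key)
        selected.extend(ranked[:n_per_gene])
    return selected


def uncovered_genes(selected: Sequence[GuideCandidate],
                    features: Sequence[GeneFeature]) -> list[str]:
    """Locus tags with zero selected guides under the strict rule."""
    covered = {g.gene for g in selected if g.gene is not None}
    return [f.locus_tag for f in features if f.locus_tag not in covered]
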