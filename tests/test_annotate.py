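"""annotate: strand classification, gene assignment, report, selection."""

import pytest

from sthguide.annotate import (
    annotate_guides,
    assign_to_gene,
    classify_strand,
    select_guides_per_gene,
    targetability_report,
    uncovered_genes,
)
from sthguide.genome_io import GeneFeature, GenomeSequence
from sthguide.guide_filter import RestrictionMotifSet, motif_filter, spacer_multiplicity
from sthguide.pam_scan import GuideCandidate, PamSite, PamSpec, enumerate_guides

CONSENSUS = PamSpec.sth1_consensus()


def _guide(start, strand, seqid="c"):
    k = 22
    pam_start = start + k if strand == "+" else start - 7
    pam = PamSite(seqid=seqid, strand=strand, start=pam_start, end=pam_start + 7,
                  matched_patterns=("NNAGAAW",), pam_seq="AAAGAAA")
    return GuideCandidate(guide_id=f"{seqid}:{start}:{strand}", seqid=seqid,
                          protospacer_strand=strand, spacer_seq="A" * k,
                          spacer_start=start, spacer_end=start + k, pam=pam)


GENE_PLUS = GeneFeature("c", 1000, 2000, "+", "gplus")
GENE_MINUS = GeneFeature("c", 3000, 4000, "-", "gminus")


class TestClassifyStrand:
    def test_pam_opposite_gene_is_non_template(self):
        assert classify_strand(_guide(1100, "-"), GENE_PLUS) == "non_template"

    def test_pam_same_strand_is_template(self):
        assert classify_strand(_guide(1100, "+"), GENE_PLUS) == "template"

    def test_convention_switch_swaps_labels(self):
        for strand in "+-":
            g = _guide(1100, strand)
            default = classify_strand(g, GENE_PLUS, "pam_opposite_coding")
            flipped = classify_strand(g, GENE_PLUS, "pam_on_coding")
            assert {default, flipped} == {"non_template", "template"}


class TestAssignToGene:
    def test_genic_assignment_and_offset(self):
        # '+' gene at 1000..2000 (1-based); protospacer midpoint ~1100
        g = _guide(1089 - 1, "+")  # interval [1088, 1110), midpoint 1099
        assign_to_gene(g, [GENE_PLUS])
        assert g.gene == "gplus"
        # PAM-proximal end = last spacer base (0-based 1109) -> offset 110
        assert g.offset_from_start == 1109 - 999

    def test_upstream_window_gives_negative_offset(self):
        g = _guide(938, "-")  # midpoint 949, within 100 bp upstream of 1000
        assign_to_gene(g, [GENE_PLUS], upstream_window=100)
        assert g.gene == "gplus"
        assert g.offset_from_start < 0
        assert g.strand_class == "non_template"

    def test_intergenic(self):
        g = _guide(489, "+")  # midpoint 500: far from both genes
        assign_to_gene(g, [GENE_PLUS, GENE_MINUS])
        assert g.gene is None
        assert g.strand_class == "intergenic"
        assert g.offset_from_start is None

    def test_minus_strand_gene_offset(self):
        # '-' gene start codon is at its high coordinate (end=4000)
        g = _guide(3959, "-")  # protospacer [3959, 3981), PAM-proximal = 3959
        assign_to_gene(g, [GENE_MINUS])
        assert g.gene == "gminus"
        assert g.offset_from_start == (4000 - 1) - 3959

    def test_overlap_tie_broken_by_offset_then_tag(self):
        overlapping = GeneFeature("c", 1900, 2600, "+", "aaa_second")
        g = _guide(1949, "+")  # midpoint 1960, inside both genes
        assign_to_gene(g, [GENE_PLUS, overlapping])
        # offsets: |1970-999|=971 for gplus, |1970-1899|=71 for aaa_second
        assert g.gene == "aaa_second"


class TestTargetabilityReport:
    def _fixture_retained(self, fixture_genome):
        genome, genes, _ = fixture_genome
        guides = enumerate_guides(genome, CONSENSUS)
        kept, _ = motif_filter(guides, RestrictionMotifSet.bbreve_ucc2003())
        spacer_multiplicity(kept, [genome])
        retained = [g for g in kept if g.multiplicity == 1]
        annotate_guides(retained, genes)
        return genome, genes, retained

    def test_fixture_coverage_counts(self, fixture_genome):
        genome, genes, retained = self._fixture_retained(fixture_genome)
        rep = targetability_report(retained, genes, [genome])
        assert rep.n_genes == len(genes)
        assert 0 <= rep.n_targetable <= rep.n_genes
        assert rep.n_guides == len(retained)
        # every per_gene key is a real locus tag
        assert set(rep.per_gene) <= {f.locus_tag for f in genes}
        assert sum(e["n_guides"] for e in rep.per_gene.values()) <= rep.n_guides

    def test_bp_per_guide_identity(self, fixture_genome):
        genome, genes, retained = self._fixture_retained(fixture_genome)
        rep = targetability_report(retained, genes, [genome])
        assert rep.bp_per_guide * rep.n_guides == rep.genome_length

    def test_empty_guides_degenerate(self, fixture_genome):
        genome, genes, _ = fixture_genome
        rep = targetability_report([], genes, [genome])
        assert rep.n_guides == 0
        assert rep.bp_per_guide is None
        assert rep.n_targetable == 0

    def test_strict_rule_monotone(self, fixture_genome):
        genome, genes, retained = self._fixture_retained(fixture_genome)
        any_rule = targetability_report(retained, genes, [genome], "any_strand")
        strict = targetability_report(retained, genes, [genome], "non_template")
        assert strict.n_targetable <= any_rule.n_targetable

    def test_convention_involution_exchanges_class_counts(self, fixture_genome):
        genome, genes, retained = self._fixture_retained(fixture_genome)

        def counts(convention):
            annotate_guides(retained, genes, convention=convention)
            nt = sum(g.strand_class == "non_template" for g in retained)
            t = sum(g.strand_class == "template" for g in retained)
            return nt, t

        nt1, t1 = counts("pam_opposite_coding")
        nt2, t2 = counts("pam_on_coding")
        assert (nt1, t1) == (t2, nt2)
        assert nt1 + t1 == nt2 + t2


class TestSelection:
    def _annotated(self, offsets, strand_class="non_template"):
        gene = GeneFeature("c", 1000, 3000, "+", "g1")
        guides = []
        for i, off in enumerate(offsets):
            g = _guide(500 + 30 * i, "-")
            g.gene = "g1"
            g.offset_from_start = off
            g.strand_class = strand_class
            guides.append(g)
        return gene, guides

    def test_ranking_prefers_upstream_then_5prime(self):
        gene, guides = self._annotated([-20, 5, 40, 300, 900])
        sel = select_guides_per_gene(guides, [gene], 3)
        assert [g.offset_from_start for g in sel] == [-20, 5, 40]

    def test_template_only_gene_uncovered(self):
        gene, guides = self._annotated([10, 50], strand_class="template")
        sel = select_guides_per_gene(guides, [gene], 3)
        assert sel == []
        assert uncovered_genes(sel, [gene]) == ["g1"]

    def test_selection_subset_and_cap(self, fixture_genome):
        genome, genes, truth = fixture_genome
        guides = enumerate_guides(genome, CONSENSUS)
        annotate_guides(guides, genes)
        for n in (1, 2, 5):
            sel = select_guides_per_gene(guides, genes, n)
            ids = {g.guide_id for g in sel}
            assert ids <= {g.guide_id for g in guides}
            per_gene = {}
            for g in sel:
                per_gene[g.gene] = per_gene.get(g.gene, 0) + 1
                assert g.strand_class == "non_template"
            assert all(v <= n for v in per_gene.values())

    def test_bad_n_per_gene(self):
        with pytest.raises(ValueError):
            select_guides_per_gene([], [], 0)
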