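"""guide_filter: motif exclusion, uniqueness, off-target enumeration."""

import numpy as np
import pytest

from sthguide.genome_io import GenomeSequence, reverse_complement
from sthguide.guide_filter import (
    RestrictionMotifSet,
    find_offtargets,
    motif_filter,
    spacer_multiplicity,
)
from sthguide.pam_scan import PamSpec, enumerate_guides

from .conftest import brute_hamming, random_dna

CONSENSUS = PamSpec.sth1_consensus()
MOTIFS = RestrictionMotifSet.bbreve_ucc2003()


def _mk_guide(spacer, genome_seq=None, start=0, strand="+"):
    """A minimal GuideCandidate for filter-level tests."""
    from sthguide.pam_scan import GuideCandidate, PamSite

    pam = PamSite(seqid="c", strand=strand, start=start + len(spacer),
                  end=start + len(spacer) + 7, matched_patterns=("NNAGAAW",),
                  pam_seq="AAAGAAA")
    return GuideCandidate(
        guide_id=f"c:{start}:{strand}", seqid="c", protospacer_strand=strand,
        spacer_seq=spacer, spacer_start=start, spacer_end=start + len(spacer),
        pam=pam,
    )


class TestMotifFilter:
    def test_ctgcag_rejected(self):
        g = _mk_guide("AAAAAAAA" + "CTGCAG" + "AAAAAAAA")
        kept, rejected = motif_filter([g], MOTIFS)
        assert kept == [] and rejected == [g]
        assert "motif_hit:CTGCAG" in g.flags

    def test_rtcgay_expansion_rejected(self):
        g = _mk_guide("AAAAAAAA" + "GTCGAT" + "AAAAAAAA")
        _, rejected = motif_filter([g], MOTIFS)
        assert rejected == [g]
        assert "motif_hit:RTCGAY" in g.flags

    def test_poly_a_kept(self):
        g = _mk_guide("A" * 22)
        kept, rejected = motif_filter([g], MOTIFS)
        assert kept == [g] and rejected == []

    def test_motif_on_opposite_strand_rejected(self):
        # non-RC-closed user motif present only as the window's revcomp
        ms = RestrictionMotifSet("custom", ["GAATTT"])
        g = _mk_guide("CCCCCCCC" + reverse_complement("GAATTT") + "CCCCCCCC")
        _, rejected = motif_filter([g], ms)
        assert rejected == [g]

    def test_spacer_plus_pam_window(self):
        # motif spans the spacer/PAM junction: only caught with the wide window
        from sthguide.pam_scan import GuideCandidate, PamSite
        pam = PamSite(seqid="c", strand="+", start=22, end=29,
                      matched_patterns=("NNAGAAW",), pam_seq="AGAGAAA")
        g = GuideCandidate(guide_id="c:0:+", seqid="c", protospacer_strand="+",
                           spacer_seq="G" * 18 + "CTGC", spacer_start=0,
                           spacer_end=22, pam=pam)
        kept, _ = motif_filter([g], MOTIFS, window="spacer_only")
        assert kept == [g]
        g.flags.clear()
        _, rejected = motif_filter([g], MOTIFS, window="spacer_plus_pam")
        assert rejected == [g]  # CTGC + AG from the PAM forms CTGCAG

    def test_empty_motif_set_is_error(self):
        with pytest.raises(ValueError):
            RestrictionMotifSet("empty", [])

    def test_idempotent_and_order_independent(self, fixture_genome):
        genome, _, _ = fixture_genome
        guides = enumerate_guides(genome, CONSENSUS)
        kept1, rej1 = motif_filter(guides, MOTIFS)
        kept2, rej2 = motif_filter(list(reversed(guides)), MOTIFS)
        assert {g.guide_id for g in kept1} == {g.guide_id for g in kept2}
        kept3, rej3 = motif_filter(kept1, MOTIFS)
        assert kept3 == kept1 and rej3 == []

    def test_attrition_conserved(self, fixture_genome):
        genome, _, _ = fixture_genome
        guides = enumerate_guides(genome, CONSENSUS)
        kept, rejected = motif_filter(guides, MOTIFS)
        assert len(kept) + len(rejected) == len(guides)
        assert {g.guide_id for g in kept} | {g.guide_id for g in rejected} == \
               {g.guide_id for g in guides}

    def test_default_set_rc_closed_single_strand_equivalent(self):
        # the default motif set equals its own reverse-complement closure,
        # so single-strand scanning with the closure = double-strand scanning
        assert MOTIFS.is_rc_closed()
        assert set(MOTIFS.rc_closure()) == set(MOTIFS.expanded())


class TestSpacerMultiplicity:
    def test_duplicated_block_flagged(self, fixture_genome):
        genome, _, truth = fixture_genome
        guides = enumerate_guides(genome, CONSENSUS)
        spacer_multiplicity(guides, [genome])
        expected_nonunique = {p.guide_id for p in truth.nonunique_rejected()}
        got = {g.guide_id for g in guides if g.multiplicity > 1}
        assert got == expected_nonunique
        for g in guides:
            if g.guide_id in expected_nonunique:
                assert g.multiplicity == 2
                assert "non_unique" in g.flags
            else:
                assert g.multiplicity == 1

    def test_palindromic_spacer_counts_once(self):
        spacer = "ACGT" * 3  # revcomp == itself
        assert reverse_complement(spacer) == spacer
        genome = GenomeSequence("c", "GG" + spacer + "GG")
        g = _mk_guide(spacer, start=2)
        spacer_multiplicity([g], [genome])
        assert g.multiplicity == 1

    def test_own_site_missing_is_error(self):
        genome = GenomeSequence("c", "G" * 50)
        g = _mk_guide("A" * 22)
        with pytest.raises(ValueError, match="not found"):
            spacer_multiplicity([g], [genome])

    def test_pam_adjacent_mode_is_less_strict(self, fixture_genome):
        genome, _, _ = fixture_genome
        guides = enumerate_guides(genome, CONSENSUS)
        seq_counts = [g.multiplicity for g in
                      spacer_multiplicity(guides, [genome], "sequence")]
        for g in guides:
            g.multiplicity = None
        pam_counts = [g.multiplicity for g in
                      spacer_multiplicity(guides, [genome], "pam_adjacent",
                                          pam_spec=CONSENSUS)]
        assert all(p <= s for p, s in zip(pam_counts, seq_counts))
        assert all(p >= 1 for p in pam_counts)


class TestFindOfftargets:
    def test_own_site_only_at_zero_mismatches(self, fixture_genome):
        genome, _, truth = fixture_genome
        guides = enumerate_guides(genome, CONSENSUS)
        unique = next(g for g in guides
                      if g.guide_id in {p.guide_id for p in truth.retained()})
        hits = find_offtargets(unique, [genome], 0)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.mismatches) == (unique.spacer_start, 0)
        assert h.mismatch_positions == ()

    def test_planted_decoys_found_with_correct_positions(self, fixture_genome):
        genome, _, truth = fixture_genome
        guides = {g.guide_id: g for g in enumerate_guides(genome, CONSENSUS)}
        for d in truth.decoy_offtargets:
            src = guides[d.source_guide_id]
            hits2 = [h for h in find_offtargets(src, [genome], 2)
                     if h.start == d.position]
            assert len(hits2) == 1
            assert hits2[0].strand == d.strand
            assert hits2[0].mismatches == 2
            assert hits2[0].mismatch_positions == d.mismatch_positions
            hits1 = [h for h in find_offtargets(src, [genome], 1)
                     if h.start == d.position]
            assert hits1 == []

    def test_agrees_with_naive_hamming_oracle(self):
        rng = np.random.default_rng(11)
        seq = random_dna(rng, 3000)
        genome = GenomeSequence("c", seq)
        for mm in (0, 2, 4):
            spacer = seq[100:122]
            g = _mk_guide(spacer, start=100)
            got = {(h.start, h.strand): h.mismatches
                   for h in find_offtargets(g, [genome], mm)}
            assert got == brute_hamming(seq, spacer, mm)

    def test_zero_mismatch_count_equals_sequence_multiplicity(self, fixture_genome):
        genome, _, _ = fixture_genome
        guides = enumerate_guides(genome, CONSENSUS)
        spacer_multiplicity(guides, [genome])
        for g in guides[::3]:
            hits = find_offtargets(g, [genome], 0)
            assert len(hits) == g.multiplicity

    def test_require_pam_restricts_to_flanked_sites(self, fixture_genome):
        genome, _, _ = fixture_genome
        g = enumerate_guides(genome, CONSENSUS)[0]
        hits = find_offtargets(g, [genome], 2, require_pam=True,
                               pam_spec=CONSENSUS)
        assert all(h.pam_adjacent for h in hits)
        assert any(h.mismatches == 0 for h in hits)  # its own site qualifies

    def test_negative_mismatches_rejected(self, fixture_genome):
        genome, _, _ = fixture_genome
        g = enumerate_guides(genome, CONSENSUS)[0]
        with pytest.raises(ValueError):
            find_offtargets(g, [genome], -1)
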