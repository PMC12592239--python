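# Methods

## The design problem

Sth1 dCas9 (from the *S. thermophilus* CRISPR1 locus) represses
transcription in GC-rich bacteria where *S. pyogenes* dCas9 often fails.
Designing a genome-wide CRISPRi guide library for it involves four coupled
steps: find every protospacer adjacent to a permissible 3′ PAM; discard
guides that cannot be cloned into a restriction-modification (R-M)
protected host or that target repeated sequence; classify each guide's
orientation relative to its gene (only guides annealing to the
non-template strand block elongation efficiently); and summarize density
and per-gene coverage. A companion recoder prepares the synthetic genes of
the delivery construct so that they are codon-optimized for the host and
free of its R-M motifs.

## Coordinates, alphabet, conventions

Internal coordinates are 0-based half-open; TSV reports are 1-based
inclusive; BED output is 0-based half-open. Genome sequences are
uppercase over `{A,C,G,T,N}`. A genomic `N` matches **no** IUPAC pattern
position: a window containing an unresolved base cannot be confirmed as a
target site, so it is conservatively excluded (the same rule makes `N`s
count as mismatches in the off-target scan). Guide identifiers are
`seqid:<0-based spacer start>:<strand>`; they are stable across runs.

Contigs default to linear. With `circular: true` scans wrap the origin by
virtually appending the first `pattern length − 1` bases; wrapped
coordinates are reported modulo the contig length.

## PAM scanning and spacer extraction

A PAM set is a list of equal-length degenerate IUPAC patterns (default
set `sth1_consensus` = `{NNAGAAW}`). Matching is implemented as compiled
character-class regexes with an overlap-permitting lookahead; every
(position, strand) window matching any pattern is reported once, and
patterns hitting the same physical window collapse into one site that
records all matched patterns. Correctness is pinned to an independent
brute-force oracle (per-position set membership over every window, both
strands) in the tests.

The spacer is the `spacer_len` bases (default 22, configurable 18–30)
immediately 5′ of the PAM on the protospacer strand; on the minus strand
this is the reverse complement of the genomic window 3′ of the PAM
interval. Guides whose flank runs off a linear contig are dropped and
counted (`insufficient_flank` in the audit), never silently.

The relaxed PAM list for Sth1 dCas9 is experimentally defined and not
derivable from first principles, so it ships as an *editable data file*
(`data/pam_sets.yaml`); the bundled `sth1_relaxed` entry is an
illustrative example and must be replaced with the validated list before
comparing genome-wide site counts against published numbers. Reports
print the pattern list and feature-type filter used so that any
discrepancy is attributable to inputs.

## Filtering

**Motif exclusion.** A guide is rejected iff any concrete expansion of any
motif occurs in the filter window or its reverse complement. The default
window is the spacer only (the sequence actually cloned into the cassette);
`spacer_plus_pam` is available since the genomic protospacer+PAM locus is
what a plasmid-borne target would carry. Both orientations are always
scanned so non-RC-closed user motif sets behave correctly; the default
*B. breve* UCC2003 triple (`CTGCAG`, `RTCGAY`, `GGCGCC`) happens to be
RC-closed, which a regression test asserts. Motifs spanning the junction
between spacer and vector scaffold are out of scope (no scaffold is
modeled). An empty motif set is an error, not a no-op.

**Uniqueness.** Multiplicity is the number of exact occurrences of the
spacer sequence across all contigs and both strands (`sequence` mode,
default and stricter), or only occurrences flanked 3′ by a permissible PAM
(`pam_adjacent` mode, the biologically minimal criterion, kept for
sensitivity analysis). All copies of a repeated spacer are dropped
(flag `non_unique` on each), not one representative kept. A palindromic
spacer at one locus occupies a single genomic footprint and counts once.

**Off-targets.** Exhaustive Hamming-distance scanning (vectorized window
comparison; no index, no bulges) over both strands, optionally restricted
to PAM-flanked windows. Mismatch positions are reported 1-based,
PAM-proximal (position 1 = the spacer base adjacent to the PAM), because
seed-proximal mismatches dominate specificity. The guide's own site
appears at distance 0, which ties the off-target scan to multiplicity:
at `max_mismatches=0` without a PAM requirement the hit count equals the
sequence-mode multiplicity (tested). Exhaustive scanning is a deliberate
choice: genomes in scope are ≤ ~10 Mb and the transparent implementation
is itself a testable reference.

## Annotation and selection

The guide's target strand is the strand its spacer base-pairs with — the
complement of the protospacer (PAM-bearing) strand. Default convention:
**non_template ⇔ protospacer strand ≠ gene strand** (the mechanistic
reading: the spacer anneals to the non-template strand, the PAM sits on
the displaced strand). Because the literature uses "targets strand X" in
both senses, a single config switch (`pam_on_coding`) inverts the
convention genome-wide; flipping it exactly exchanges the class counts
(an asserted involution), and every report records the convention used.

A guide is assigned to the gene whose strand-aware interval, extended by
an upstream window (default 100 bp, capturing 5′-UTR-targeting guides),
contains the protospacer midpoint; operonic overlaps resolve to one gene
by smallest |offset| then lexicographic locus tag, keeping per-gene sums
interpretable. `offset_from_start` is measured from the translational
start to the PAM-proximal end of the protospacer — the dCas9 roadblock
position — with negative values upstream.

The targetability report counts, under `any_strand` (default; "possible
target sites" need not restrict orientation) or strict `non_template`
rules, the genes with ≥ 1 retained guide, plus genome length / guide
count (`bp_per_guide`, rounded only at presentation). Per-gene selection
returns up to `n_per_gene` non-template guides ranked upstream-first by
|offset|, then genic by ascending offset, then guide id — deterministic
by construction; genes with no non-template guide land in an "uncovered"
list.

## Construct recoding

Codon optimization is the deterministic argmax rule: each residue gets
its most frequent synonymous codon under the host usage table
(lexicographic tie-break), with a terminal stop appended (default `TAA`).
Motif removal then iterates: locate the leftmost motif occurrence on
either strand; among the codons overlapping it, apply the synonymous
substitution of highest usage frequency that eliminates that occurrence
and introduces no new occurrence within the affected window (the changed
codon ± motif length − 1); repeat to a fixpoint, with an iteration cap of
10 × the initial occurrence count to prevent oscillation between
overlapping motifs. Occurrences no synonymous change can break (e.g. a
motif spanning only Met/Trp codons) are reported as residuals and the
result is marked unsuccessful rather than silently incomplete. The
translation is re-checked after recoding. Stop codons are treated as a
synonym class of their own (uniform frequency) so a terminal stop can
also be recoded away from a motif. GC content, codon harmonization and
mRNA structure are deliberately not optimized.

No organism-specific codon-usage data is bundled, to avoid shipping
unverifiable numbers: built-ins are `uniform` and `gc_biased` (frequency
∝ weight^(G+C of codon), a parameter-defined emulation of a GC-rich
host), and real tables load from TSV (`codon  amino_acid  frequency`) or
are counted from coding sequences (`from_cds_sequences`, +1 pseudocount).

## The synthetic-genome generator

Fixtures emulate a small GC-rich bacterial chromosome in which ground
truth is exact by construction. Defaults — chosen once as the standard
validation condition — are: 10 genes of 900 bp on alternating strands,
200-bp intergenic gaps, GC 0.60 (bifidobacteria are ~59–60% GC),
20 clean planted guides cycling through four positional categories
(genic non-template, genic template, 5′-UTR window, intergenic),
5 motif-bearing guides, one duplicated 500-bp block carrying 2 guides
(hence 4 non-unique scan hits after copying), and 3 two-mismatch decoy
windows (no PAM) for the off-target search; total ~12.6 kb.

The key trick is background sanitization: any `NNAGAAW` match on either
strand implies one of the four 5-mers `AGAAA/AGAAT/TTTCT/ATTCT`, so the
background is resampled until none occur, each planted 29-mer is checked
to contribute exactly one PAM core, and plant/copy junctions are locally
re-verified (a 5-mer spans ≤ 5 bases, so locality suffices). A final
verification pass — plain substring search, independent of the scanner
under test — asserts that the genome's PAM-implying 5-mers are exactly
the planted ones and that each planted spacer occurs exactly as many
times as intended. All randomness flows from one seeded NumPy generator;
regeneration is byte-identical.

What the fixtures do **not** emulate: real intergenic structure, operons,
transposons and other repeat families, skewed oligonucleotide
composition, or sequencing ambiguity. Passing the fixture suite therefore
demonstrates the correctness of the algorithms (exact recovery,
conservation of attrition, coordinate arithmetic on both strands), not
the biological quality of guides in any particular genome.

## Problem sizes and determinism

Validation workloads are desk-scale by design: 100 × 2-kb random
sequences for scanner/oracle agreement, ten ~12.6-kb fixture genomes for
end-to-end recovery, 50 × 300-codon proteins for the recoder. All
outputs (tables, BED, FASTA, JSON) are fully sorted with no timestamps,
so identical inputs give byte-identical artifacts; the CLI subcommands
(`scan` → `report`) compose through intermediate TSVs with the same
results as the monolithic `design` run.

## Known limitations

- No PAM scoring or weighting: patterns are binary permissible/not, as in
  the underlying design procedure; 5′-PAM systems (Cas12a) are out of scope.
- Off-target search is Hamming-only (no bulges) and unscored; it reports
  candidates, not activity predictions.
- Guide-to-gene assignment uses the annotation's gene/CDS intervals only;
  no operon or TSS inference, so polar effects within operons are not
  flagged.
- The bundled `sth1_relaxed` PAM list is illustrative; genome-wide site
  counts depend on supplying the experimentally validated list and on the
  annotation version, both of which the reports print.
- Methylation state is not modeled: motif filtering treats every
  occurrence of an R-M recognition sequence as forbidden.
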