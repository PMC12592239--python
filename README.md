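# sthguide

CRISPRi guide design for **Sth1 dCas9** in GC-rich bacteria such as
bifidobacteria, plus host-aware recoding of synthetic constructs.

CRISPR interference (CRISPRi) represses a gene by parking a catalytically
dead Cas9 on its DNA as a roadblock for RNA polymerase. The widely used
*S. pyogenes* dCas9 performs poorly in some GC-rich genomes, while the
*S. thermophilus* CRISPR1 variant (Sth1 dCas9) works well — but it needs a
longer, AT-rich PAM (consensus `NNAGAAW`, with experimentally relaxed
variants), a 22-bp spacer, and, for delivery into strains with active
restriction–modification (R-M) systems, guide cassettes and synthetic genes
free of the host's restriction motifs. `sthguide` implements that whole
design procedure:

- **PAM scanning** — all sites matching a configurable set of degenerate
  IUPAC PAM patterns, both strands, linear or circular contigs, with
  22-bp (configurable) spacer extraction.
- **Filtering** — rejection of spacers containing R-M motifs (default set
  for *B. breve* UCC2003: `CTGCAG`, `RTCGAY`, `GGCGCC`) and of spacers whose
  sequence occurs more than once in the genome; Hamming-distance off-target
  enumeration with PAM-proximal mismatch positions (mismatched guides can
  retain activity, so near-matches are worth knowing about).
- **Annotation** — assignment of guides to genes (including a 5′-UTR
  window), template / non-template strand classification (CRISPRi blocks
  elongation only when the guide anneals to the non-template strand),
  genome-wide density and per-gene targetability reports, and deterministic
  per-gene selection of 5′-proximal non-template guides.
- **Construct recoding** — codon optimization of proteins for a host usage
  table with iterative synonymous substitutions that eliminate every R-M
  motif occurrence on both strands while preserving the translation.
- **Synthetic fixtures** — a generator of PAM-sanitized genomes with planted
  guides, motif-bearing spacers, duplicated blocks and off-target decoys,
  so the entire pipeline is verifiable against exact ground truth.

## Worked example

Generate a synthetic 12.6-kb genome with known ground truth, then run the
full design pipeline on it:

```sh
sthguide simulate --seed 1 --out-dir demo
# wrote demo/genome.fasta (12590 bp), annotation.gff3 (10 genes),
# truth.json (29 planted guides)

cat > demo/config.yaml <<EOF
genome: demo/genome.fasta
annotation: demo/annotation.gff3
pam_set: sth1_consensus
motif_set: bbreve_ucc2003
EOF

sthguide design --config demo/config.yaml --out-dir demo/out
# scanned 29 guides; motif-rejected 5; non-unique 4; retained 20;
# selected 10 -> demo/out
```

The numbers mean: the scanner found all 29 planted PAM-adjacent spacers
(and nothing else — the background is PAM-free by construction); 5 spacers
carrying restriction motifs were rejected; the 4 scan hits inside the
duplicated block (2 originals + 2 copies) were rejected as non-unique;
20 guides survive, and per-gene selection picked up to 3 non-template,
5′-proximal guides per gene. `demo/out/` contains the retained-guide TSV
(1-based coordinates), a rejected-guide TSV with reason flags, BED6 and
spacer FASTA, the targetability report
(`n_guides`, `bp_per_guide`, `n_targetable`, per-gene counts) and a
per-stage audit JSON in which attrition is conserved
(`scanned = motif_rejected + nonunique_rejected + retained`).

The same `design` command runs on any real genome: point `genome:` at a
FASTA, `annotation:` at a GFF3, and choose a PAM set (`sth1_consensus`, the
editable `sth1_relaxed` entry in `src/sthguide/data/pam_sets.yaml`, or
inline `patterns: [...]`) and a motif set for the target strain.

Recode a protein for a GC-rich host while excluding the R-M motifs:

```sh
sthguide recode --input protein.fasta --codon-table gc_biased \
    --motif-set bbreve_ucc2003 --out-dir recoded/
```

As a library:

```python
from sthguide import (PamSpec, RestrictionMotifSet, enumerate_guides,
                      motif_filter, spacer_multiplicity, read_fasta)

genome = read_fasta("genome.fasta")[0]
guides = enumerate_guides(genome, PamSpec.sth1_consensus(), spacer_len=22)
kept, rejected = motif_filter(guides, RestrictionMotifSet.bbreve_ucc2003())
spacer_multiplicity(kept, [genome])
unique = [g for g in kept if g.multiplicity == 1]
```

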