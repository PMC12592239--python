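# Built-in restriction-modification (R-M) recognition-motif sets.
#
# bbreve_ucc2003 holds the three B. breve UCC2003 motifs used to filter
# guide cassettes before cloning.  Add entries for other host strains as
# needed; degenerate IUPAC codes are allowed and both strands are always
# scanned.
bbreve_ucc2003:
  motifs: [CTGCAG, RTCGAY, GGCGCC]
  source: B. breve UCC2003 restriction-modification recognition motifs
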