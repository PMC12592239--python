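# Built-in PAM pattern sets (3' PAMs, IUPAC codes).
#
# sth1_consensus is the published Sth1 dCas9 consensus.  sth1_relaxed is
# an ILLUSTRATIVE example of a relaxed set: functional Sth1 PAMs beyond
# the consensus have been characterized experimentally, and reproducing a
# published genome-wide site count requires supplying that exact
# validated list here (or via an inline `patterns:` config entry).  Edit
# freely — this file is data, not code.
sth1_consensus:
  patterns: [NNAGAAW]
sth1_relaxed:
  patterns: [NNAGAAW, NNAGGAW, NNAGAAG, NNAGGAG]
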