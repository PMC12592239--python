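"""Genome-wide PAM scanning and spacer extraction for 3'-PAM Cas9 systems.

A :class:`PamSpec` is a set of equal-length degenerate IUPAC patterns
(e.g. the Sth1 dCas9 consensus ``NNAGAAW``).  Scanning reports every
window on either strand whose strand-oriented reading matches any
pattern; overlapping matches by different patterns at the same
(position, strand) collapse into one :class:`PamSite` that records all
matched patterns, since they describe one physical target site.

Spacers (default 22 bp, the guide's targeting sequence) are the bases
immediately 5' of the PAM on the protospacer strand.  On linear contigs
a PAM too close to the contig end yields no guide; the attrition is
counted, not silent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genome_io import (
    GenomeSequence,
    iupac_expand,
    pattern_to_regex,
    reverse_complement,
)

__all__ = [
    "PamSpec",
    "PamSite",
    "GuideCandidate",
    "ScanStats",
    "find_pam_sites",
    "extract_spacer",
    "enumerate_guides",
    "scan_genomes",
]

DEFAULT_SPACER_LEN = 22

# Filter-outcome flag names used on GuideCandidate.flags
FLAG_NON_UNIQUE = "non_unique"
FLAG_INSUFFICIENT_FLANK = "insufficient_flank"


def motif_hit_flag(motif: str) -> str:
    return f"motif_hit:{motif}"


@dataclass(frozen=True)
class PamSpec:
    """A named collection of equal-length 3' PAM patterns."""

    name: str
    patterns: tuple[str, ...]

    def __init__(self, name: str, patterns: Sequence[str]):
        if not patterns:
            raise ValueError("PamSpec requires at least one pattern")
        pats = tuple(p.upper() for p in patterns)
        lengths = {len(p) for p in pats}
        if len(lengths) != 1:
            raise ValueError(f"PAM patterns must share one length, got {sorted(lengths)}")
        for p in pats:
            iupac_expand(p)  # validates codes
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "patterns", pats)

    @property
    def length(self) -> int:
        return len(self.patterns[0])

    @property
    def side(self) -> str:
        return "3prime"

    def matches(self, window: str) -> bool:
        from .genome_io import iupac_matches
        return any(iupac_matches(p, window) for p in self.patterns)

    @classmethod
    def sth1_consensus(cls) -> "PamSpec":
        return cls("sth1_consensus", ("NNAGAAW",))


@dataclass(frozen=True)
class PamSite:
    """One physical PAM occurrence.

    ``start``/``end`` are 0-based half-open genome coordinates of the PAM
    on the forward sequence; for sites wrapping a circular origin,
    ``start`` is reduced modulo the contig length and ``end`` may exceed
    it.  ``strand`` is the strand whose 5'->3' reading matches the
    pattern (the protospacer strand).
    """

    seqid: str
    strand: str
    start: int
    end: int
    matched_patterns: tuple[str, ...]
    pam_seq: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GuideCandidate:
    """A spacer + PAM site, annotated progressively by the pipeline stages."""

    guide_id: str
    seqid: str
    protospacer_strand: str
    spacer_seq: str
    spacer_start: int
    spacer_end: int
    pam: PamSite
    flags: set[str] = field(default_factory=set)
    multiplicity: int | None = None
    gene: str | None = None
    strand_class: str | None = None
    offset_from_start: int | None = None

    @property
    def pam_seq(self) -> str:
        return self.pam.pam_seq

    @property
    def midpoint(self) -> int:
        """0-based genomic midpoint of the protospacer interval."""
        return (self.spacer_start + self.spacer_end) // 2


@dataclass
class ScanStats:
    """Per-contig attrition accounting for a PAM scan."""

    n_pam_sites: int = 0
    n_guides: int = 0
    n_insufficient_flank: int = 0


def _finditer_overlapping(regex: re.Pattern, text: str):
    """Yield start offsets of (possibly overlapping) matches."""
    pos = 0
    while True:
        m = regex.search(text, pos)
        if m is None:
            return
        yield m.start()
        pos = m.start() + 1


def find_pam_sites(genome: GenomeSequence, spec: PamSpec) -> list[PamSite]:
    """All PAM matches on both strands, one PamSite per (position, strand).

    On circular contigs the scan wraps the origin by virtually appending
    the first (pattern length - 1) bases; wrapped start coordinates are
    reported modulo the contig length.
    """
    plen = spec.length
    L = genome.length
    if L == 0:
        return []
    text = genome.seq + (genome.seq[: plen - 1] if genome.circular and L >= 1 else "")

    # (start, strand) -> set of matched pattern strings
    hits: dict[tuple[int, str], set[str]] = {}
    for pattern in spec.patterns:
        for strand, pat in (("+", pattern), ("-", reverse_complement(pattern))):
            rx = re.compile(pattern_to_regex(pat))
            for s in _finditer_overlapping(rx, text):
                if s >= L:  # wrapped duplicate of an already-scanned origin window
                    continue
                hits.setdefault((s % L, strand), set()).add(pattern)

    sites = []
    for (start, strand), pats in hits.items():
        window = genome.subseq(start, start + plen)
        pam_seq = window if strand == "+" else reverse_complement(window)
        sites.append(PamSite(
            seqid=genome.id, strand=strand, start=start, end=start + plen,
            matched_patterns=tuple(sorted(pats)), pam_seq=pam_seq,
        ))
    sites.sort(key=lambda s: (s.seqid, s.start, s.strand))
    return sites


def extract_spacer(genome: GenomeSequence, site: PamSite,
                   spacer_len: int = DEFAULT_SPACER_LEN) -> GuideCandidate | None:
    """Extract the spacer immediately 5' of a PAM on the protospacer strand.

    Returns None when the flank runs off a linear contig (the caller
    counts the attrition).  On the '-' strand the spacer is the reverse
    complement of the genomic window immediately 3' (in genome
    coordinates) of the PAM interval.
    """
    if spacer_len <= 0:
        raise ValueError("spacer_len must be >= 1")
    L = genome.length
    if site.strand == "+":
        s0, e0 = site.start - spacer_len, site.start
        if s0 < 0 and not genome.circular:
            return None
        spacer = genome.subseq(s0, e0)
        s0 %= L
        e0 = s0 + spacer_len
    else:
        s0, e0 = site.end, site.end + spacer_len
        if e0 > L and not genome.circular:
            return None
        spacer = reverse_complement(genome.subseq(s0, e0))
        s0 %= L
        e0 = s0 + spacer_len
    return GuideCandidate(
        guide_id=f"{genome.id}:{s0}:{site.strand}",
        seqid=genome.id,
        protospacer_strand=site.strand,
        spacer_seq=spacer,
        spacer_start=s0,
        spacer_end=e0,
        pam=site,
    )


def enumerate_guides(genome: GenomeSequence, spec: PamSpec,
                     spacer_len: int = DEFAULT_SPACER_LEN,
                     stats: ScanStats | None = None) -> list[GuideCandidate]:
    """find_pam_sites composed with extract_spacer, in deterministic order."""
    sites = find_pam_sites(genome, spec)
    if stats is not None:
        stats.n_pam_sites += len(sites)
    guides: list[GuideCandidate] = []
    for site in sites:
        g = extract_spacer(genome, site, spacer_len)
        if g is None:
            if stats is not None:
                stats.n_insufficient_flank += 1
            continue
        guides.append(g)
    if stats is not None:
        stats.n_guides += len(guides)
    guides.sort(key=lambda g: (g.seqid, g.spacer_start, g.protospacer_strand))
    return guides


def scan_genomes(genomes: Iterable[GenomeSequence], spec: PamSpec,
                 spacer_len: int = DEFAULT_SPACER_LEN,
                 stats: ScanStats | None = None) -> list[GuideCandidate]:
    out: list[GuideCandidate] = []
    for g in genomes:
        out.extend(enumerate_guides(g, spec, spacer_len, stats))
    return out
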