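"""Guide filtering: restriction-motif exclusion, uniqueness, off-targets.

Hosts with active restriction-modification (R-M) systems cleave
unmethylated DNA at their recognition motifs, so guide cassettes to be
cloned must avoid those motifs; the default set is the B. breve UCC2003
triple CTGCAG, RTCGAY, GGCGCC.  Uniqueness removes guides whose spacer
occurs more than once in the genome (repeat/redundant sequences), and
the off-target search enumerates near-matches by Hamming distance since
mismatched guides can retain activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .genome_io import (
    GenomeSequence,
    iupac_expand,
    iupac_matches,
    reverse_complement,
)
from .pam_scan import (
    FLAG_NON_UNIQUE,
    GuideCandidate,
    PamSpec,
    motif_hit_flag,
)

__all__ = [
    "RestrictionMotifSet",
    "OffTargetHit",
    "motif_filter",
    "spacer_multiplicity",
    "find_offtargets",
]


@dataclass(frozen=True)
class RestrictionMotifSet:
    """A named set of degenerate restriction/R-M recognition motifs.

    The expanded concrete set is recorded together with its
    reverse-complement closure, so single-strand scanning of the closure
    is equivalent to double-strand scanning of the original motifs.
    """

    name: str
    motifs: tuple[str, ...]
    source: str = ""

    def __init__(self, name: str, motifs: Sequence[str], source: str = ""):
        if not motifs:
            raise ValueError("motif set must be nonempty")
        pats = tuple(m.upper() for m in motifs)
        for m in pats:
            iupac_expand(m)  # validates
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "motifs", pats)
        object.__setattr__(self, "source", source)

    def expanded(self) -> dict[str, str]:
        """Concrete sequence -> originating motif pattern (no RC closure)."""
        out: dict[str, str] = {}
        for m in self.motifs:
            for c in sorted(iupac_expand(m)):
                out.setdefault(c, m)
        return out

    def rc_closure(self) -> dict[str, str]:
        """Concrete sequence -> motif, closed under reverse complementation."""
        out = self.expanded()
        for c, m in list(out.items()):
            out.setdefault(reverse_complement(c), m)
        return out

    def is_rc_closed(self) -> bool:
        exp = set(self.expanded())
        return exp == {reverse_complement(c) for c in exp}

    @classmethod
    def bbreve_ucc2003(cls) -> "RestrictionMotifSet":
        return cls(
            "bbreve_ucc2003",
            ("CTGCAG", "RTCGAY", "GGCGCC"),
            source="B. breve UCC2003 restriction-modification recognition motifs",
        )


@dataclass(frozen=True)
class OffTargetHit:
    """A genomic window within Hamming distance of a spacer.

    ``mismatch_positions`` are 1-based and PAM-proximal: position 1 is
    the spacer base adjacent to the PAM, where mismatches matter most
    for (d)Cas9 activity.
    """

    guide_id: str
    seqid: str
    strand: str
    start: int
    end: int
    mismatches: int
    mismatch_positions: tuple[int, ...]
    pam_adjacent: bool


MotifWindow = Literal["spacer_only", "spacer_plus_pam"]
MultiplicityMode = Literal["sequence", "pam_adjacent"]


def motif_filter(guides: Iterable[GuideCandidate], motifs: RestrictionMotifSet,
                 window: MotifWindow = "spacer_only",
                 ) -> tuple[list[GuideCandidate], list[GuideCandidate]]:
    """Partition guides into (kept, rejected) by restriction-motif content.

    A guide is rejected iff any expanded motif occurs as a substring of
    the window sequence (spacer, or spacer+PAM) or of its reverse
    complement; both orientations are always checked so non-RC-closed
    user motif sets behave correctly.  Rejected guides get flags
    ``motif_hit:<motif>`` for every motif that hit.
    """
    concrete = motifs.rc_closure()
    kept: list[GuideCandidate] = []
    rejected: list[GuideCandidate] = []
    for g in guides:
        w = g.spacer_seq if window == "spacer_only" else g.spacer_seq + g.pam_seq
        both = (w, reverse_complement(w))
        hit_motifs = {m for c, m in concrete.items() if any(c in s for s in both)}
        if hit_motifs:
            g.flags.update(motif_hit_flag(m) for m in sorted(hit_motifs))
            rejected.append(g)
        else:
            kept.append(g)
    return kept, rejected


def _occurrences(contig: GenomeSequence, query: str) -> list[int]:
    """Start offsets of exact (overlapping) occurrences, origin-wrapping if circular."""
    text = contig.seq
    if contig.circular and contig.length > len(query):
        text = text + contig.seq[: len(query) - 1]
    out, pos = [], 0
    while True:
        i = text.find(query, pos)
        if i == -1:
            return out
        out.append(i % contig.length)
        pos = i + 1


def _pam_flanked(contig: GenomeSequence, start: int, end: int, strand: str,
                 pam_spec: PamSpec) -> bool:
    """Is the window [start,end) on `strand` followed 3' by a permissible PAM?"""
    plen = pam_spec.length
    try:
        if strand == "+":
            window = contig.subseq(end, end + plen)
        else:
            window = reverse_complement(contig.subseq(start - plen, start))
    except IndexError:
        return False
    return pam_spec.matches(window)


def spacer_multiplicity(guides: Sequence[GuideCandidate],
                        genome: Sequence[GenomeSequence],
                        mode: MultiplicityMode = "sequence",
                        pam_spec: PamSpec | None = None) -> list[GuideCandidate]:
    """Fill each guide's multiplicity; flag guides found at >1 site.

    multiplicity counts exact occurrences of the spacer across all
    contigs on both strands (mode="sequence"), or only occurrences
    flanked 3' by a permissible PAM (mode="pam_adjacent", requires
    pam_spec).  A spacer equal to its own reverse complement occupies
    one genomic footprint per locus and is counted once there.
    """
    if mode == "pam_adjacent" and pam_spec is None:
        raise ValueError("mode='pam_adjacent' requires pam_spec")
    contigs = list(genome)
    cache: dict[str, int] = {}
    for g in guides:
        if g.spacer_seq not in cache:
            sp = g.spacer_seq
            rc = reverse_complement(sp)
            occ: set[tuple[str, int, str]] = set()
            for contig in contigs:
                for pos in _occurrences(contig, sp):
                    occ.add((contig.id, pos, "+"))
                for pos in _occurrences(contig, rc):
                    occ.add((contig.id, pos, "-"))
            if sp == rc:  # palindromic: one footprint, not two strand records
                occ = {(c, p, "+") for c, p, _ in occ}
            if mode == "pam_adjacent":
                by_id = {c.id: c for c in contigs}
                occ = {
                    (cid, pos, strand) for cid, pos, strand in occ
                    if _pam_flanked(by_id[cid], pos, pos + len(sp), strand, pam_spec)
                }
            cache[sp] = len(occ)
        m = cache[g.spacer_seq]
        if m == 0:
            raise ValueError(
                f"guide {g.guide_id}: its own spacer was not found in the genome "
                "(corrupt input?)"
            )
        g.multiplicity = m
        if m > 1:
            g.flags.add(FLAG_NON_UNIQUE)
    return list(guides)


def _hamming_scan(contig: GenomeSequence, query: str, max_mismatches: int
                  ) -> list[tuple[int, tuple[int, ...]]]:
    """(start, 0-based genomic mismatch offsets) of windows within distance."""
    k = len(query)
    L = contig.length
    text = contig.seq
    if contig.circular and L >= k:
        text = text + contig.seq[: k - 1]
    n = len(text) - k + 1
    if n <= 0:
        return []
    arr = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    mism = np.zeros(n, dtype=np.int32)
    for j in range(k):
        mism += arr[j:j + n] != q[j]
    out = []
    for start in np.nonzero(mism <= max_mismatches)[0]:
        start = int(start)
        if start >= L:  # wrapped duplicate
            continue
        w = arr[start:start + k]
        offs = tuple(int(j) for j in np.nonzero(w != q)[0])
        out.append((start % L, offs))
    return out


def find_offtargets(guide: GuideCandidate, genome: Sequence[GenomeSequence],
                    max_mismatches: int, require_pam: bool = False,
                    pam_spec: PamSpec | None = None) -> list[OffTargetHit]:
    """All genomic windows within `max_mismatches` of the spacer (Hamming).

    Both strands are searched; no insertions/deletions.  The guide's own
    site appears with mismatches = 0.  With require_pam, only windows
    flanked 3' by a permissible PAM are reported; pam_spec is also used
    to fill the pam_adjacent field when given.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    if max_mismatches > len(guide.spacer_seq):
        raise ValueError("max_mismatches exceeds spacer length")
    if require_pam and pam_spec is None:
        raise ValueError("require_pam=True needs pam_spec")
    sp = guide.spacer_seq
    k = len(sp)
    strands = [("+", sp)]
    if reverse_complement(sp) != sp:  # palindromic spacer: one footprint per locus
        strands.append(("-", reverse_complement(sp)))
    hits: list[OffTargetHit] = []
    for contig in genome:
        for strand, query in strands:
            for start, offs in _hamming_scan(contig, query, max_mismatches):
                # PAM-proximal 1-based positions: 1 = spacer base next to PAM.
                if strand == "+":
                    positions = tuple(sorted(k - j for j in offs))
                else:
                    positions = tuple(sorted(j + 1 for j in offs))
                pam_adj = (
                    _pam_flanked(contig, start, start + k, strand, pam_spec)
                    if pam_spec is not None else False
                )
                if require_pam and not pam_adj:
                    continue
                hits.append(OffTargetHit(
                    guide_id=guide.guide_id, seqid=contig.id, strand=strand,
                    start=start, end=start + k, mismatches=len(offs),
                    mismatch_positions=positions, pam_adjacent=pam_adj,
                ))
    hits.sort(key=lambda h: (h.seqid, h.start, h.strand))
    return hits
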