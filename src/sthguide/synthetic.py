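"""Synthetic genomes with known ground truth for end-to-end testing.

The generator emits a bacterial-genome-like FASTA + GFF3 pair in which
every PAM site is planted on purpose: the background is rejection-
sampled to contain no window matching the Sth1 consensus PAM ``NNAGAAW``
on either strand (equivalently, none of the four 5-mers AGAAA / AGAAT /
TTTCT / ATTCT occur), so a scan recovers exactly the planted guides.
Plantings cover genic positions on both strand classes, 5'-UTR-window
positions, intergenic positions, restriction-motif-bearing spacers, a
duplicated block (non-unique spacers) and near-match decoys for the
off-target search.  The truth table exactly describes all of them.

All randomness comes from one ``numpy`` generator keyed by ``seed``;
regeneration from the same seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .genome_io import GeneFeature, GenomeSequence, reverse_complement
from .guide_filter import RestrictionMotifSet

__all__ = [
    "PlantedGuide",
    "DecoyOffTarget",
    "SyntheticGenomeTruth",
    "generate_synthetic_genome",
]

SPACER_LEN = 22
PAM_LEN = 7
PLANT_LEN = SPACER_LEN + PAM_LEN
UPSTREAM_WINDOW = 100

# Any NNAGAAW match on either strand implies one of these 5-mers, so a
# genome free of them is PAM-free for the Sth1 consensus.
_FORBIDDEN = ("AGAAA", "AGAAT", "TTTCT", "ATTCT")
_CONTIG_ID = "synchr1"
_BLOCK_LEN = 500
_DECOY_SLOT = 80


@dataclass(frozen=True)
class PlantedGuide:
    """One deliberately planted protospacer + PAM."""

    position: int          # 0-based genomic start of the protospacer
    strand: str            # protospacer strand
    spacer: str            # strand-oriented spacer sequence (22 nt)
    pam: str               # strand-oriented PAM (concrete NNAGAAW match)
    pattern: str           # the degenerate pattern the PAM satisfies
    category: str          # genic_nt | genic_t | utr | intergenic | duplicate
    gene: str | None = None       # intended locus_tag for genic/utr plantings
    motif: str | None = None      # restriction motif embedded in the spacer
    in_duplicated_block: bool = False

    @property
    def guide_id(self) -> str:
        return f"{_CONTIG_ID}:{self.position}:{self.strand}"


@dataclass(frozen=True)
class DecoyOffTarget:
    """A planted near-match (Hamming) window for one source guide."""

    source_guide_id: str
    position: int                       # 0-based window start
    strand: str
    mismatch_positions: tuple[int, ...]  # PAM-proximal, 1-based, sorted


@dataclass
class SyntheticGenomeTruth:
    seed: int
    planted_guides: list[PlantedGuide]
    planted_motif_guides: list[int]          # positions of motif-bearing plants
    duplicated_block: tuple[int, int, int] | None  # (start, end, copy_start)
    decoy_offtargets: list[DecoyOffTarget]
    genes: list[GeneFeature]

    # -- convenience views used by tests and the pipeline audit ----------
    def expected_guide_ids(self) -> set[str]:
        return {p.guide_id for p in self.planted_guides}

    def retained(self) -> list[PlantedGuide]:
        """Plantings that survive motif + uniqueness filtering."""
        return [p for p in self.planted_guides
                if p.motif is None and not p.in_duplicated_block]

    def motif_rejected(self) -> list[PlantedGuide]:
        return [p for p in self.planted_guides if p.motif is not None]

    def nonunique_rejected(self) -> list[PlantedGuide]:
        return [p for p in self.planted_guides if p.in_duplicated_block]

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "planted_guides": [asdict(p) for p in self.planted_guides],
            "planted_motif_guides": self.planted_motif_guides,
            "duplicated_block": self.duplicated_block,
            "decoy_offtargets": [asdict(d) for d in self.decoy_offtargets],
            "genes": [asdict(g) for g in self.genes],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _forbidden_hits(s: str) -> list[int]:
    out = []
    for f in _FORBIDDEN:
        pos = 0
        while True:
            i = s.find(f, pos)
            if i == -1:
                break
            out.append(i)
            pos = i + 1
    return sorted(out)


class _Builder:
    def __init__(self, length: int, gc: float, rng: np.random.Generator):
        self.rng = rng
        self.gc = gc
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        self.seq = list(rng.choice(list("ACGT"), size=length, p=p))
        self.L = length
        self.occupied: list[tuple[int, int]] = []
        self._p = p

    def rand_base(self) -> str:
        return str(self.rng.choice(list("ACGT"), p=self._p))

    def rand_kmer(self, k: int) -> str:
        return "".join(self.rng.choice(list("ACGT"), size=k, p=self._p))

    def sanitize(self) -> None:
        """Resample bases until no PAM-implying 5-mer remains anywhere."""
        for _ in range(500):
            s = "".join(self.seq)
            hits = _forbidden_hits(s)
            if not hits:
                return
            for h in hits:
                self.seq[h + 2] = self.rand_base()
        raise RuntimeError("background sanitization did not converge")

    def is_free(self, lo: int, hi: int, margin: int = 5) -> bool:
        return all(hi + margin <= a or b + margin <= lo for a, b in self.occupied)

    def reserve(self, lo: int, hi: int) -> None:
        self.occupied.append((lo, hi))

    def text(self, lo: int, hi: int) -> str:
        return "".join(self.seq[max(0, lo):min(self.L, hi)])

    def write_plant(self, pos: int, strand: str, full: str) -> bool:
        """Write a spacer+PAM 29-mer; verify the local neighbourhood carries
        exactly the one intended PAM core; roll back on failure."""
        ins = full if strand == "+" else reverse_complement(full)
        old = self.seq[pos:pos + PLANT_LEN]
        self.seq[pos:pos + PLANT_LEN] = list(ins)
        lo = max(0, pos - 4)
        region = self.text(lo, pos + PLANT_LEN + 4)
        expected = (pos + SPACER_LEN + 2 - lo) if strand == "+" else (pos - lo)
        if _forbidden_hits(region) != [expected]:
            self.seq[pos:pos + PLANT_LEN] = old
            return False
        return True

    def write_bare(self, pos: int, kmer: str) -> bool:
        """Write a PAM-less window (decoy); neighbourhood must stay PAM-free."""
        old = self.seq[pos:pos + len(kmer)]
        self.seq[pos:pos + len(kmer)] = list(kmer)
        lo = max(0, pos - 4)
        if _forbidden_hits(self.text(lo, pos + len(kmer) + 4)):
            self.seq[pos:pos + len(kmer)] = old
            return False
        return True


def _sample_spacer(b: _Builder, used: set[str], concrete_motifs: Sequence[str],
                   motif: str | None = None) -> str:
    """A 22-mer free of PAM-implying 5-mers and (unless requested) of
    restriction motifs, distinct from previously used spacers."""
    for _ in range(500):
        s = b.rand_kmer(SPACER_LEN)
        if motif is not None:
            s = s[:8] + motif + s[8 + len(motif):]
        if _forbidden_hits(s):
            continue
        if motif is None and any(m in s or m in reverse_complement(s)
                                 for m in concrete_motifs):
            continue
        if s in used or reverse_complement(s) in used:
            continue
        return s
    raise RuntimeError("could not sample a clean spacer")


def _sample_plant(b: _Builder, spacer: str) -> tuple[str, str]:
    """(full 29-mer, pam) whose only PAM core sits at the intended offset."""
    for _ in range(200):
        pam = (b.rand_kmer(2) + "AGAA"
               + ("A" if b.rng.integers(2) == 0 else "T"))
        full = spacer + pam
        if _forbidden_hits(full) == [SPACER_LEN + 2]:
            return full, pam
    raise RuntimeError("could not sample a clean PAM context")


def generate_synthetic_genome(
    n_genes: int = 10,
    gene_len: int = 900,
    intergenic_len: int = 200,
    gc: float = 0.60,
    n_planted_guides: int = 20,
    n_motif_guides: int = 5,
    duplicate_block: bool = True,
    n_decoys: int = 3,
    seed: int = 0,
) -> tuple[GenomeSequence, list[GeneFeature], SyntheticGenomeTruth]:
    """Build a PAM-sanitized genome with planted, fully-known features.

    Defaults describe the standard validation condition: a 10-gene,
    ~13 kb GC-rich chromosome with 20 clean guides split across genic
    (both strand classes), 5'-UTR-window and intergenic positions, 5
    motif-bearing guides, one duplicated 500-bp block carrying 2 guides
    (4 non-unique scan hits after copying) and 3 two-mismatch decoys.
    """
    if not (0 < gc < 1):
        raise ValueError("gc must be in (0, 1)")
    if min(n_genes, gene_len, intergenic_len, n_planted_guides,
           n_motif_guides, n_decoys) < 0 or n_genes == 0:
        raise ValueError("counts must be >= 0 and n_genes >= 1")
    if intergenic_len < 2 * UPSTREAM_WINDOW or gene_len < PLANT_LEN + 60:
        raise ValueError("gene/intergenic lengths too small for planting")

    rng = np.random.default_rng(seed)

    unit = gene_len + intergenic_len
    gene_lo = [intergenic_len + i * unit for i in range(n_genes)]
    after_genes = gene_lo[-1] + gene_len + intergenic_len
    if duplicate_block:
        block_lo, block_hi = after_genes, after_genes + _BLOCK_LEN
        copy_lo, copy_hi = block_hi + 50, block_hi + 50 + _BLOCK_LEN
        tail0 = copy_hi + 50
    else:
        block_lo = block_hi = copy_lo = copy_hi = 0
        tail0 = after_genes
    decoy_lo = tail0
    L = decoy_lo + n_decoys * _DECOY_SLOT + 50

    b = _Builder(L, gc, rng)
    b.sanitize()

    genes = [
        GeneFeature(seqid=_CONTIG_ID, start=gene_lo[i] + 1,
                    end=gene_lo[i] + gene_len,
                    strand="+" if i % 2 == 0 else "-",
                    locus_tag=f"SYN_{i:04d}", product="synthetic gene")
        for i in range(n_genes)
    ]

    motif_set = RestrictionMotifSet.bbreve_ucc2003()
    concrete_motifs = sorted(motif_set.rc_closure())
    used_spacers: set[str] = set()
    planted: list[PlantedGuide] = []

    def place(lo: int, hi: int, strand: str, spacer: str,
              category: str, gene: str | None, motif: str | None,
              mid_lo: int | None = None, mid_hi: int | None = None) -> PlantedGuide:
        """Plant spacer+PAM with the 29-mer inside [lo, hi); optionally
        constrain the protospacer midpoint to [mid_lo, mid_hi]."""
        mid_off = 11 if strand == "+" else 18   # protospacer midpoint - plant pos
        for _ in range(300):
            p_lo, p_hi = lo, hi - PLANT_LEN
            if mid_lo is not None:
                p_lo = max(p_lo, mid_lo - mid_off)
                p_hi = min(p_hi, mid_hi - mid_off)
            if p_hi < p_lo:
                break
            pos = int(rng.integers(p_lo, p_hi + 1))
            if not b.is_free(pos, pos + PLANT_LEN):
                continue
            full, pam = _sample_plant(b, spacer)
            if not b.write_plant(pos, strand, full):
                continue
            b.reserve(pos, pos + PLANT_LEN)
            used_spacers.add(spacer)
            ps = pos if strand == "+" else pos + PAM_LEN
            return PlantedGuide(position=ps, strand=strand, spacer=spacer,
                                pam=pam, pattern="NNAGAAW", category=category,
                                gene=gene, motif=motif)
        raise RuntimeError(
            f"could not place a {category} guide in [{lo}, {hi}); "
            "requested plantings exceed genome capacity"
        )

    # --- clean guides across the four positional categories -------------
    categories = ["genic_nt", "genic_t", "utr", "intergenic"]
    # intergenic gaps lie between a '+' gene and the following '-' gene
    inter_gaps = [(gene_lo[i] + gene_len, gene_lo[i + 1])
                  for i in range(n_genes - 1) if i % 2 == 0]
    # UTR slots: (midpoint lo, midpoint hi, gene index); unambiguous halves
    utr_slots: list[tuple[int, int, int]] = []
    if genes[0].strand == "+":
        utr_slots.append((gene_lo[0] - 85, gene_lo[0] - 15, 0))
    for i in range(n_genes - 1):
        if genes[i].strand == "-" and genes[i + 1].strand == "+":
            gap_lo, gap_hi = gene_lo[i] + gene_len, gene_lo[i + 1]
            utr_slots.append((gap_lo + 15, gap_lo + 80, i))        # gene i 3' side
            utr_slots.append((gap_hi - 80, gap_hi - 15, i + 1))    # gene i+1 5' side

    gi = ii = ui = 0
    for k in range(n_planted_guides):
        cat = categories[k % len(categories)]
        spacer = _sample_spacer(b, used_spacers, concrete_motifs)
        if cat in ("genic_nt", "genic_t"):
            gene = genes[gi % n_genes]
            gi += 1
            want_nt = cat == "genic_nt"
            strand = ("-" if gene.strand == "+" else "+") if want_nt else gene.strand
            lo, hi = gene.start - 1 + 30, gene.end - 30
            planted.append(place(lo, hi, strand, spacer, cat, gene.locus_tag, None))
        elif cat == "utr":
            if not utr_slots:
                raise RuntimeError("no unambiguous UTR slots in this layout")
            m_lo, m_hi, gidx = utr_slots[ui % len(utr_slots)]
            ui += 1
            gene = genes[gidx]
            strand = "-" if gene.strand == "+" else "+"
            planted.append(place(m_lo - PLANT_LEN, m_hi + PLANT_LEN, strand, spacer,
                                 cat, gene.locus_tag, None, m_lo, m_hi))
        else:  # intergenic
            if not inter_gaps:
                raise RuntimeError("no window-free intergenic gaps in this layout")
            gap_lo, gap_hi = inter_gaps[ii % len(inter_gaps)]
            ii += 1
            strand = "+" if ii % 2 else "-"
            planted.append(place(gap_lo + 2, gap_hi - 2, strand, spacer, cat,
                                 None, None, gap_lo + 8, gap_hi - 8))

    # --- motif-bearing guides (rejected by the restriction filter) ------
    motif_cycle = ["CTGCAG", "GGCGCC", "GTCGAT", "ATCGAC"]  # incl. RTCGAY forms
    for k in range(n_motif_guides):
        motif = motif_cycle[k % len(motif_cycle)]
        spacer = _sample_spacer(b, used_spacers, concrete_motifs, motif=motif)
        gene = genes[(gi + k) % n_genes]
        lo, hi = gene.start - 1 + 30, gene.end - 30
        strand = "-" if gene.strand == "+" else "+"
        planted.append(place(lo, hi, strand, spacer, "motif",
                             gene.locus_tag, motif))

    # --- duplicated block: plant two guides, then copy the block ---------
    dup_block = None
    if duplicate_block:
        originals = []
        for strand in ("+", "-"):
            spacer = _sample_spacer(b, used_spacers, concrete_motifs)
            originals.append(place(block_lo + 20, block_hi - 20, strand, spacer,
                                   "duplicate", None, None))
        shift = copy_lo - block_lo
        dup_block = (block_lo, block_hi, copy_lo)
        b.seq[copy_lo:copy_hi] = b.seq[block_lo:block_hi]
        # the block interior is clean near its edges (plants sit >= 20 in),
        # so any forbidden 5-mer at a copy junction spans it and contains a
        # background base we may resample
        for junction in (copy_lo, copy_hi):
            for _ in range(100):
                lo = junction - 8
                region = b.text(lo, junction + 8)
                bad = [h + lo for h in _forbidden_hits(region)
                       if not (copy_lo <= h + lo and h + lo + 5 <= copy_hi)]
                if not bad:
                    break
                outside = [i for i in range(bad[0], bad[0] + 5)
                           if not (copy_lo <= i < copy_hi)]
                b.seq[outside[0]] = b.rand_base()
            else:
                raise RuntimeError("could not sanitize duplicated-block junction")
        for g in originals:
            for pos_shift in (0, shift):
                planted.append(PlantedGuide(
                    position=g.position + pos_shift, strand=g.strand,
                    spacer=g.spacer, pam=g.pam, pattern=g.pattern,
                    category="duplicate", gene=None, motif=None,
                    in_duplicated_block=True,
                ))

    # --- near-match decoys for the off-target search ---------------------
    decoys: list[DecoyOffTarget] = []
    clean = [p for p in planted
             if p.motif is None and not p.in_duplicated_block]
    for d in range(n_decoys):
        src = clean[d % len(clean)]
        for _ in range(300):
            q1, q2 = sorted(int(q) for q in rng.choice(SPACER_LEN, size=2, replace=False))
            variant = list(src.spacer)
            for q in (q1, q2):
                alt = [c for c in "ACGT" if c != variant[q]]
                variant[q] = alt[int(rng.integers(3))]
            variant = "".join(variant)
            if _forbidden_hits(variant):
                continue
            pos = decoy_lo + d * _DECOY_SLOT + 20
            if not b.is_free(pos, pos + SPACER_LEN):
                raise RuntimeError("decoy slot unexpectedly occupied")
            if b.write_bare(pos, variant):
                b.reserve(pos, pos + SPACER_LEN)
                positions = tuple(sorted(SPACER_LEN - q for q in (q1, q2)))
                # the variant is written in the spacer's own orientation, so
                # the off-target search reports it on the '+' strand
                decoys.append(DecoyOffTarget(
                    source_guide_id=src.guide_id, position=pos,
                    strand="+", mismatch_positions=positions,
                ))
                break
        else:
            raise RuntimeError("could not plant a decoy window")

    planted.sort(key=lambda p: (p.position, p.strand))
    genome = GenomeSequence(id=_CONTIG_ID, seq="".join(b.seq), circular=False)
    truth = SyntheticGenomeTruth(
        seed=seed,
        planted_guides=planted,
        planted_motif_guides=[p.position for p in planted if p.motif],
        duplicated_block=dup_block,
        decoy_offtargets=decoys,
        genes=genes,
    )
    _verify(genome, truth)
    return genome, genes, truth


def _verify(genome: GenomeSequence, truth: SyntheticGenomeTruth) -> None:
    """Construction invariants, checked with plain substring search so the
    guarantee is independent of the scanner under test."""
    expected = set()
    for p in truth.planted_guides:
        expected.add(p.position + SPACER_LEN + 2 if p.strand == "+"
                     else p.position - PAM_LEN)
    actual = set(_forbidden_hits(genome.seq))
    if actual != expected:
        raise RuntimeError(
            f"planted-PAM invariant violated: unexpected {sorted(actual - expected)}, "
            f"missing {sorted(expected - actual)}"
        )
    counts: dict[str, int] = {}
    for p in truth.planted_guides:
        counts[p.spacer] = counts.get(p.spacer, 0) + 1
    for p in truth.planted_guides:
        n = 0
        for q in (p.spacer, reverse_complement(p.spacer)):
            pos = 0
            while True:
                i = genome.seq.find(q, pos)
                if i == -1:
                    break
                n += 1
                pos = i + 1
        if n != counts[p.spacer]:
            raise RuntimeError(
                f"spacer multiplicity invariant violated for {p.guide_id}: "
                f"found {n}, expected {counts[p.spacer]}"
            )
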