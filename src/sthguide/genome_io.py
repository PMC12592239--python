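"""Genome and annotation I/O plus the alphabet conventions used package-wide.

Coordinate conventions: internal coordinates are 0-based half-open
throughout the package; user-facing tables are 1-based inclusive; BED
output is 0-based half-open.  GFF3 input coordinates (1-based inclusive)
are kept as-is on :class:`GeneFeature` and converted at the point of use.

The ambiguity code ``N`` in a genome never matches any IUPAC pattern
position: an unresolved base cannot be confirmed as part of a target
site, so scans treat it conservatively as a non-match.
"""

from __future__ import annotations

import itertools
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeSequence",
    "GeneFeature",
    "IUPAC_CODES",
    "reverse_complement",
    "iupac_expand",
    "iupac_matches",
    "pattern_to_regex",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
]

# 15 IUPAC nucleotide codes -> concrete bases each code stands for.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_GENOME_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# Expanding very degenerate patterns (e.g. a 22-mer of N) would explode;
# anything a PAM or restriction motif needs stays far below this.
_MAX_EXPANSION = 4 ** 12


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA contig over {A,C,G,T,N} with linear/circular topology."""

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be nonempty")
        bad = set(self.seq) - _GENOME_ALPHABET
        if bad:
            offset = next(i for i, c in enumerate(self.seq) if c in bad)
            raise ValueError(
                f"record {self.id!r}: illegal character {self.seq[offset]!r} "
                f"at offset {offset} (alphabet is A/C/G/T/N)"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def subseq(self, start: int, end: int) -> str:
        """0-based half-open slice; wraps past the origin on circular contigs."""
        if start < 0 or end > self.length:
            if not self.circular:
                raise IndexError(
                    f"interval [{start}, {end}) outside linear contig "
                    f"{self.id!r} of length {self.length}"
                )
            L = self.length
            return "".join(self.seq[i % L] for i in range(start, end))
        return self.seq[start:end]


@dataclass(frozen=True)
class GeneFeature:
    """A gene locus: 1-based inclusive coordinates, as in GFF3."""

    seqid: str
    start: int
    end: int
    strand: str
    locus_tag: str
    product: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.locus_tag}: invalid interval {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: strand must be + or -")
        if not self.locus_tag:
            raise ValueError("locus_tag must be nonempty")


def _validate_iupac(seq: str, what: str = "sequence") -> None:
    for i, c in enumerate(seq):
        if c not in IUPAC_CODES:
            raise ValueError(f"{what} contains non-IUPAC character {c!r} at position {i}")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/IUPAC string (involution)."""
    _validate_iupac(seq, "sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_expand(pattern: str) -> set[str]:
    """All concrete A/C/G/T sequences matching a degenerate IUPAC pattern."""
    _validate_iupac(pattern, "pattern")
    size = 1
    for c in pattern:
        size *= len(IUPAC_CODES[c])
    if size > _MAX_EXPANSION:
        raise ValueError(f"pattern {pattern!r} expands to {size} sequences; refusing")
    return {"".join(p) for p in itertools.product(*(IUPAC_CODES[c] for c in pattern))}


def iupac_matches(pattern: str, window: str) -> bool:
    """Position-wise IUPAC match of a concrete genome window against a pattern.

    A genome ``N`` matches nothing (conservative handling of ambiguity).
    """
    if len(pattern) != len(window):
        return False
    return all(w in IUPAC_CODES[p] for p, w in zip(pattern, window))


def pattern_to_regex(pattern: str) -> str:
    """Regex character-class form of an IUPAC pattern (genome N never matches)."""
    _validate_iupac(pattern, "pattern")
    return "".join(c if len(IUPAC_CODES[c]) == 1 else f"[{IUPAC_CODES[c]}]" for c in pattern)


def read_fasta(path: str | os.PathLike, circular: bool = False) -> list[GenomeSequence]:
    """Read a (multi-record) FASTA file into GenomeSequence records.

    Sequences are uppercased; characters outside A/C/G/T/N are rejected
    with the record name and offset.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(f"{path}: not FASTA — first non-blank line lacks '>'")
                break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    records: list[GenomeSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        records.append(GenomeSequence(id=rec.id, seq=seq, circular=circular))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeSequence] | dict[str, str],
                path: str | os.PathLike, width: int = 70) -> None:
    """Write sequences as FASTA, 70 columns per line."""
    if isinstance(records, dict):
        items = list(records.items())
    else:
        items = [(r.id, r.seq) for r in records]
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _feature_name(attrs: dict[str, list[str]]) -> str | None:
    # precedence: locus_tag > ID > Name
    for key in ("locus_tag", "ID", "Name"):
        if key in attrs and attrs[key]:
            return attrs[key][0]
    return None


def read_gff3(path: str | os.PathLike,
              feature_types: Sequence[str] = ("gene", "CDS"),
              contigs: Sequence[GenomeSequence] | None = None) -> list[GeneFeature]:
    """Read gene features from GFF3.

    When both a gene and its CDS describe the same locus (same name), the
    gene record wins.  Coordinates are validated against contig lengths
    when contigs are supplied.  Duplicate locus tags (after deduplication)
    are an error listing the offenders.
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GFF3 file not found: {path}")
    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True,
        merge_strategy="create_unique", sort_attribute_values=True,
    )
    lengths = {c.id: c.length for c in contigs} if contigs is not None else None

    # gene preferred over CDS for the same locus name
    rank = {t: i for i, t in enumerate(feature_types)}
    chosen: dict[str, tuple[int, GeneFeature]] = {}
    anonymous: list[GeneFeature] = []
    seen_names: dict[str, int] = {}
    for feat in db.all_features():
        if feat.featuretype not in rank:
            continue
        if lengths is not None:
            if feat.seqid not in lengths:
                raise ValueError(f"feature on unknown seqid {feat.seqid!r}")
            if feat.end > lengths[feat.seqid]:
                raise ValueError(
                    f"feature {feat.id!r} ends at {feat.end}, beyond contig "
                    f"{feat.seqid!r} of length {lengths[feat.seqid]}"
                )
        name = _feature_name(dict(feat.attributes))
        product = feat.attributes.get("product", [None])[0]
        if name is None:
            raise ValueError(
                f"{feat.featuretype} feature at {feat.seqid}:{feat.start}-{feat.end} "
                "has no locus_tag/ID/Name attribute"
            )
        gf = GeneFeature(seqid=feat.seqid, start=feat.start, end=feat.end,
                         strand=feat.strand, locus_tag=name, product=product)
        r = rank[feat.featuretype]
        if name in chosen:
            prev_rank, prev = chosen[name]
            if r < prev_rank:
                chosen[name] = (r, gf)
            elif r == prev_rank:
                seen_names[name] = seen_names.get(name, 1) + 1
        else:
            chosen[name] = (r, gf)
    dupes = sorted(n for n, k in seen_names.items() if k > 1)
    if dupes:
        raise ValueError(f"duplicate locus_tag(s) in annotation: {', '.join(dupes)}")
    feats = [gf for _, gf in chosen.values()]
    feats.sort(key=lambda f: (f.seqid, f.start, f.end, f.locus_tag))
    return feats


def write_gff3(features: Iterable[GeneFeature], path: str | os.PathLike,
               source: str = "sthguide", feature_type: str = "gene") -> None:
    """Write gene features as a minimal GFF3 file."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.locus_tag};locus_tag={f.locus_tag}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(
                f"{f.seqid}\t{source}\t{feature_type}\t{f.start}\t{f.end}"
                f"\t.\t{f.strand}\t.\t{attrs}\n"
            )
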