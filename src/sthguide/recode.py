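"""Host-aware construct recoding: codon optimization with motif exclusion.

Synthetic genes destined for a host with active restriction-modification
systems must avoid the host's recognition motifs or they are cleaved on
entry.  The recoder first encodes each residue with its most frequent
synonymous codon under a host codon-usage table, then repairs motif
occurrences by the smallest-cost synonymous downgrades: for the leftmost
occurrence (either strand), the highest-frequency synonymous codon swap
among the codons overlapping it that (a) eliminates that occurrence and
(b) introduces no new occurrence in the affected window is applied, and
the scan repeats to a fixpoint.  Translation is invariant throughout.

GC content and mRNA structure are deliberately not optimized.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio.Data import CodonTable as _BioCodonTable

from .genome_io import pattern_to_regex, reverse_complement
from .guide_filter import RestrictionMotifSet

__all__ = [
    "CodonUsageTable",
    "RecodeResult",
    "Substitution",
    "MotifOccurrence",
    "translate",
    "codon_optimize",
    "remove_motifs",
]

DEFAULT_GENETIC_CODE = 11  # bacterial/archaeal
DEFAULT_STOP = "TAA"

_BASES = "ACGT"


def _code_tables(code: int) -> tuple[dict[str, str], frozenset[str]]:
    tbl = _BioCodonTable.unambiguous_dna_by_id[code]
    return dict(tbl.forward_table), frozenset(tbl.stop_codons)


def translate(cds: str, code: int = DEFAULT_GENETIC_CODE) -> str:
    """Translate a CDS; a terminal stop codon is consumed, an internal one
    is an error naming the codon index."""
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    fwd, stops = _code_tables(code)
    n_codons = len(cds) // 3
    protein = []
    for i in range(n_codons):
        codon = cds[3 * i: 3 * i + 3]
        if codon in stops:
            if i == n_codons - 1:
                break
            raise ValueError(f"internal stop codon {codon} at codon index {i}")
        if codon not in fwd:
            raise ValueError(f"untranslatable codon {codon!r} at codon index {i}")
        protein.append(fwd[codon])
    return "".join(protein)


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-amino-acid relative synonymous codon frequencies for a host.

    All 61 sense codons must be present and each amino acid's
    frequencies must sum to 1.  Stop codons are handled separately
    (uniform across the code's stop set) so terminal stops can also be
    recoded away from motifs.
    """

    organism: str
    freq: dict[str, float]
    genetic_code: int = DEFAULT_GENETIC_CODE

    def __post_init__(self) -> None:
        fwd, _ = _code_tables(self.genetic_code)
        missing = set(fwd) - set(self.freq)
        if missing:
            raise ValueError(f"codon table missing sense codons: {sorted(missing)[:5]} ...")
        by_aa: dict[str, float] = {}
        for codon, aa in fwd.items():
            f = self.freq[codon]
            if f < 0:
                raise ValueError(f"negative frequency for codon {codon}")
            by_aa[aa] = by_aa.get(aa, 0.0) + f
        bad = {aa: s for aa, s in by_aa.items() if abs(s - 1.0) > 1e-9}
        if bad:
            raise ValueError(f"per-amino-acid frequencies do not sum to 1: {bad}")

    # -- lookups ---------------------------------------------------------
    def synonyms(self, aa: str) -> list[str]:
        """Synonymous codons for a residue ('*' = stop), by descending
        frequency then lexicographic order."""
        fwd, stops = _code_tables(self.genetic_code)
        if aa == "*":
            codons = sorted(stops)
            return codons  # uniform: lexicographic
        codons = [c for c, a in fwd.items() if a == aa]
        if not codons:
            raise ValueError(f"unknown residue {aa!r}")
        return sorted(codons, key=lambda c: (-self.freq[c], c))

    def best_codon(self, aa: str) -> str:
        if aa == "*":
            return DEFAULT_STOP
        return self.synonyms(aa)[0]

    def frequency(self, codon: str) -> float:
        _, stops = _code_tables(self.genetic_code)
        if codon in stops:
            return 1.0 / len(stops)
        return self.freq[codon]

    # -- constructors ----------------------------------------------------
    @classmethod
    def uniform(cls, code: int = DEFAULT_GENETIC_CODE) -> "CodonUsageTable":
        """Equal frequency for every synonymous codon."""
        fwd, _ = _code_tables(code)
        counts: dict[str, int] = {}
        for aa in fwd.values():
            counts[aa] = counts.get(aa, 0) + 1
        return cls("uniform", {c: 1.0 / counts[aa] for c, aa in fwd.items()}, code)

    @classmethod
    def gc_biased(cls, weight: float = 2.0, code: int = DEFAULT_GENETIC_CODE
                  ) -> "CodonUsageTable":
        """Frequencies proportional to weight^(G+C count), emulating usage
        in a GC-rich host without asserting any real organism's data."""
        fwd, _ = _code_tables(code)
        raw = {c: weight ** sum(b in "GC" for b in c) for c in fwd}
        totals: dict[str, float] = {}
        for c, aa in fwd.items():
            totals[aa] = totals.get(aa, 0.0) + raw[c]
        return cls(f"gc_biased(w={weight})",
                   {c: raw[c] / totals[aa] for c, aa in fwd.items()}, code)

    @classmethod
    def from_cds_sequences(cls, seqs: Sequence[str], organism: str = "empirical",
                           code: int = DEFAULT_GENETIC_CODE) -> "CodonUsageTable":
        """Relative frequencies counted from coding sequences (+1 pseudocount
        so every sense codon stays represented)."""
        fwd, stops = _code_tables(code)
        counts = {c: 1 for c in fwd}
        for s in seqs:
            s = s.upper()
            for i in range(0, len(s) - len(s) % 3, 3):
                codon = s[i:i + 3]
                if codon in counts:
                    counts[codon] += 1
        totals: dict[str, int] = {}
        for c, aa in fwd.items():
            totals[aa] = totals.get(aa, 0) + counts[c]
        return cls(organism, {c: counts[c] / totals[aa] for c, aa in fwd.items()}, code)

    @classmethod
    def from_tsv(cls, path: str | Path, organism: str | None = None,
                 code: int = DEFAULT_GENETIC_CODE) -> "CodonUsageTable":
        """Read a 3-column table: codon, amino acid, relative frequency.

        Lines starting with '#' and a header line are tolerated.
        Frequencies are renormalized within each amino-acid class.
        """
        fwd, _ = _code_tables(code)
        raw: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.replace(",", "\t").split()
                if parts[0].lower() in ("codon",):
                    continue
                codon, aa, f = parts[0].upper(), parts[1].upper(), float(parts[2])
                if codon in fwd and fwd[codon] != aa:
                    raise ValueError(f"codon {codon} listed as {aa}, expected {fwd[codon]}")
                if codon in fwd:
                    raw[codon] = f
        totals: dict[str, float] = {}
        for c in raw:
            totals[fwd[c]] = totals.get(fwd[c], 0.0) + raw[c]
        freq = {c: raw[c] / totals[fwd[c]] for c in raw}
        return cls(organism or str(path), freq, code)

    def to_tsv(self, path: str | Path) -> None:
        fwd, _ = _code_tables(self.genetic_code)
        with open(path, "w") as fh:
            fh.write("codon\tamino_acid\tfrequency\n")
            for codon in sorted(fwd):
                fh.write(f"{codon}\t{fwd[codon]}\t{self.freq[codon]:.6f}\n")


def codon_optimize(protein: str, table: CodonUsageTable,
                   stop_codon: str | None = DEFAULT_STOP) -> str:
    """Encode each residue with its maximum-frequency codon (ties broken
    lexicographically); a terminal stop codon is appended unless
    stop_codon is None or the protein already carries a '*' marker."""
    protein = protein.upper()
    body = protein[:-1] if protein.endswith("*") else protein
    cds = []
    for i, aa in enumerate(body):
        if aa == "*":
            raise ValueError(f"internal stop marker at residue {i}")
        cds.append(table.best_codon(aa))  # raises on unknown residue
    out = "".join(cds)
    if protein.endswith("*") or stop_codon is not None:
        out += stop_codon if stop_codon is not None else DEFAULT_STOP
    return out


@dataclass(frozen=True)
class MotifOccurrence:
    start: int        # 0-based offset in the CDS (forward coordinates)
    end: int
    motif: str        # originating degenerate pattern
    strand: str       # '+' motif on the CDS, '-' on its reverse complement


@dataclass(frozen=True)
class Substitution:
    codon_index: int
    old_codon: str
    new_codon: str
    motif_broken: str


@dataclass
class RecodeResult:
    cds: str
    substitutions: list[Substitution]
    residual_motifs: list[MotifOccurrence]
    iterations: int = 0

    @property
    def success(self) -> bool:
        return not self.residual_motifs


def _motif_regexes(motifs: RestrictionMotifSet) -> list[tuple[re.Pattern, str, str]]:
    """(compiled lookahead regex, motif pattern, strand) for both strands."""
    out = []
    seen: set[str] = set()
    for m in motifs.motifs:
        rx = pattern_to_regex(m)
        out.append((re.compile(f"(?=({rx}))"), m, "+"))
        seen.add(rx)
        rc = pattern_to_regex(reverse_complement(m))
        if rc not in seen:  # palindromic / RC-duplicate patterns scan once
            out.append((re.compile(f"(?=({rc}))"), m, "-"))
            seen.add(rc)
    return out


def _find_occurrences(cds: str, regexes, lo: int = 0, hi: int | None = None
                      ) -> list[MotifOccurrence]:
    """Motif occurrences (both strands, forward coordinates) overlapping
    [lo, hi); deduplicated, sorted by start."""
    hi = len(cds) if hi is None else hi
    occ: set[MotifOccurrence] = set()
    for rx, motif, strand in regexes:
        for m in rx.finditer(cds):
            s, e = m.start(), m.start() + len(m.group(1))
            if e > lo and s < hi:
                occ.add(MotifOccurrence(s, e, motif, strand))
    return sorted(occ, key=lambda o: (o.start, o.end, o.motif, o.strand))


def remove_motifs(cds: str, motifs: RestrictionMotifSet, table: CodonUsageTable,
                  max_iter_factor: int = 10) -> RecodeResult:
    """Eliminate restriction-motif occurrences from a CDS by synonymous
    codon substitutions, preserving translation.

    Works leftmost-first; an occurrence no synonymous swap can break is
    recorded as residual and skipped, so the result's ``success`` is
    False iff any occurrence survives on either strand.
    """
    cds = cds.upper()
    protein_before = translate(cds, table.genetic_code)  # validates the CDS
    _, stops = _code_tables(table.genetic_code)
    regexes = _motif_regexes(motifs)
    max_len = max(len(m) for m in motifs.motifs)

    occurrences = _find_occurrences(cds, regexes)
    cap = max(1, max_iter_factor * len(occurrences))
    subs: list[Substitution] = []
    stuck: set[tuple[int, int]] = set()  # footprints proven unbreakable
    iterations = 0

    def codon_at(seq: str, ci: int) -> str:
        return seq[3 * ci: 3 * ci + 3]

    def residue(seq: str, ci: int) -> str:
        codon = codon_at(seq, ci)
        return "*" if codon in stops else translate(codon + "TAA", table.genetic_code)

    while iterations < cap:
        occurrences = _find_occurrences(cds, regexes)
        pending = [o for o in occurrences if (o.start, o.end) not in stuck]
        if not pending:
            break
        occ = pending[0]
        iterations += 1
        first_ci = occ.start // 3
        last_ci = (occ.end - 1) // 3
        # window where a codon change could create or destroy occurrences
        candidates: list[tuple[float, int, str, int, str]] = []
        for ci in range(first_ci, last_ci + 1):
            old = codon_at(cds, ci)
            aa = residue(cds, ci)
            for rank, alt in enumerate(table.synonyms(aa)):
                if alt == old:
                    continue
                candidates.append((-table.frequency(alt), rank, alt, ci, old))
        candidates.sort(key=lambda t: (t[0], t[1], t[3], t[2]))
        applied = False
        for _, _, alt, ci, old in candidates:
            trial = cds[: 3 * ci] + alt + cds[3 * ci + 3:]
            lo = 3 * ci - (max_len - 1)
            hi = 3 * ci + 3 + (max_len - 1)
            before = set(_find_occurrences(cds, regexes, lo, hi))
            after = set(_find_occurrences(trial, regexes, lo, hi))
            if occ in after:
                continue  # did not break the target occurrence
            if not after <= (before - {occ}):
                continue  # introduced a new occurrence nearby
            cds = trial
            subs.append(Substitution(ci, old, alt, occ.motif))
            applied = True
            break
        if not applied:
            stuck.add((occ.start, occ.end))

    residual = _find_occurrences(cds, regexes)
    if translate(cds, table.genetic_code) != protein_before:
        raise AssertionError("recoding changed the translation (internal error)")
    return RecodeResult(cds=cds, substitutions=subs,
                        residual_motifs=residual, iterations=iterations)
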