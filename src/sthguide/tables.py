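"""Tabular output: guide TSV (1-based), BED6 (0-based half-open), FASTA.

All tables are sorted by (seqid, start, strand, guide_id) with no
locale-dependent collation and no timestamps, so reruns on identical
inputs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .pam_scan import GuideCandidate

__all__ = [
    "guides_to_frame",
    "write_guide_tsv",
    "read_guide_tsv",
    "write_bed6",
    "write_spacer_fasta",
    "write_json",
]

_COLUMNS = [
    "guide_id", "seqid", "strand", "spacer_start_1based", "spacer_end_1based",
    "spacer_seq", "pam_seq", "matched_pattern", "multiplicity", "gene",
    "strand_class", "offset_from_start", "flags",
]


def _sort_key(g: GuideCandidate):
    return (g.seqid, g.spacer_start, g.protospacer_strand, g.guide_id)


def guides_to_frame(guides: Sequence[GuideCandidate]) -> pd.DataFrame:
    rows = []
    for g in sorted(guides, key=_sort_key):
        rows.append({
            "guide_id": g.guide_id,
            "seqid": g.seqid,
            "strand": g.protospacer_strand,
            "spacer_start_1based": g.spacer_start + 1,
            "spacer_end_1based": g.spacer_end,
            "spacer_seq": g.spacer_seq,
            "pam_seq": g.pam_seq,
            "matched_pattern": ",".join(g.pam.matched_patterns),
            "multiplicity": g.multiplicity,
            "gene": g.gene,
            "strand_class": g.strand_class,
            "offset_from_start": g.offset_from_start,
            "flags": ",".join(sorted(g.flags)),
        })
    df = pd.DataFrame(rows, columns=_COLUMNS)
    for col in ("multiplicity", "offset_from_start"):
        df[col] = df[col].astype("Int64")
    return df


def write_guide_tsv(guides: Sequence[GuideCandidate], path: str | Path) -> None:
    guides_to_frame(guides).to_csv(path, sep="\t", index=False, na_rep="")


def read_guide_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"flags": "string", "gene": "string",
                                              "strand_class": "string"})


def write_bed6(guides: Sequence[GuideCandidate], path: str | Path) -> None:
    """Protospacer intervals as BED6; score column carries multiplicity."""
    with open(path, "w") as fh:
        for g in sorted(guides, key=_sort_key):
            score = g.multiplicity if g.multiplicity is not None else 0
            fh.write(f"{g.seqid}\t{g.spacer_start}\t{g.spacer_end}\t"
                     f"{g.guide_id}\t{score}\t{g.protospacer_strand}\n")


def write_spacer_fasta(guides: Sequence[GuideCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(guides, key=_sort_key):
            fh.write(f">{g.guide_id}\n{g.spacer_seq}\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
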