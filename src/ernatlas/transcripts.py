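"""Post-assembly lncRNA transcript filtering and expression rules.

Assembled transcript predictions are reduced to candidate lncRNAs by a
conjunctive cascade: minimum exonic length 200 bp, non-zero FPKM,
multi-exonic, no coding potential by either external predictor, longest
open reading frame at most 300 nt, and a novelty class code in
{x, i, j, u, o}.  Coding-potential verdicts arrive as input flags
(the predictors themselves are external tools).  The removal log names
the first failing rule for every dropped transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "TranscriptRecord",
    "longest_orf_length",
    "filter_lncrna_transcripts",
    "expressed_gene_set",
    "LNCRNA_CLASS_CODES",
]

LNCRNA_CLASS_CODES = frozenset("xijuo")

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class TranscriptRecord:
    id: str
    gene_id: str
    exons: list = field(default_factory=list)   # sorted, non-overlapping intervals
    fpkm: list = field(default_factory=list)    # per-sample values
    class_code: str = "u"
    coding_flag_a: bool = False                 # external predictor verdicts
    coding_flag_b: bool = False
    sequence: str | None = None

    def __post_init__(self):
        ex = sorted(self.exons, key=lambda e: (e.chrom, e.start))
        for a, b in zip(ex[:-1], ex[1:]):
            if a.overlaps(b):
                raise ValueError(f"overlapping exons in {self.id}")
        self.exons = ex

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)


def longest_orf_length(seq: str) -> int:
    """Longest ATG-to-stop open reading frame (nt, stop codon included).

    Scans the three forward frames of the sense strand only — assembled
    transcripts are already oriented.  An ATG without a downstream
    in-frame stop does not count as an ORF.
    """
    s = seq.upper().replace("U", "T")
    best = 0
    for frame in range(3):
        open_start = None
        for i in range(frame, len(s) - 2, 3):
            codon = s[i:i + 3]
            if codon == "ATG" and open_start is None:
                open_start = i
            elif codon in _STOPS and open_start is not None:
                best = max(best, i + 3 - open_start)
                open_start = None
    return best


_RULES = ("exonic_length", "zero_fpkm", "monoexonic", "coding_potential",
          "orf_length", "class_code")


def filter_lncrna_transcripts(records, min_exonic_len: int = 200,
                              max_orf: int = 300,
                              allowed_codes=LNCRNA_CLASS_CODES):
    """Apply the lncRNA candidate cascade; log the first failing rule.

    Returns ``(kept, log)`` where ``log`` is a DataFrame with one row
    per input transcript and columns ``transcript_id, kept, first_fail``.
    Kept and dropped records partition the input.
    """
    kept, rows = [], []
    for rec in records:
        fail = None
        if rec.exonic_length < min_exonic_len:
            fail = "exonic_length"
        elif len(rec.fpkm) == 0 or max(rec.fpkm) == 0:
            fail = "zero_fpkm"
        elif len(rec.exons) < 2:
            fail = "monoexonic"
        elif rec.coding_flag_a or rec.coding_flag_b:
            fail = "coding_potential"
        elif rec.sequence is not None and longest_orf_length(rec.sequence) > max_orf:
            fail = "orf_length"
        elif rec.class_code not in allowed_codes:
            fail = "class_code"
        if fail is None:
            kept.append(rec)
        rows.append({"transcript_id": rec.id, "kept": fail is None,
                     "first_fail": fail})
    return kept, pd.DataFrame(rows)


def expressed_gene_set(gene_fpkm: pd.DataFrame, threshold: float = 1.0) -> set:
    """Genes expressed above ``threshold`` FPKM in at least one sample (strict >)."""
    if gene_fpkm.size == 0:
        raise ValueError("empty FPKM matrix")
    mx = gene_fpkm.max(axis=1)
    return set(gene_fpkm.index[mx > threshold])
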