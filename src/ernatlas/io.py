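"""Readers and writers for the plain-text formats the pipeline consumes.

BED and TSV go through pandas; FASTA through Biopython.  The GTF reader
is restricted to ``gene``/``transcript``/``exon`` features and converts
the 1-based closed GTF coordinates to the package's 0-based half-open
convention on read.  All readers tolerate ``#`` comment lines.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval

__all__ = [
    "read_bed",
    "write_bed",
    "read_gtf",
    "read_fasta",
    "write_fasta",
    "write_tsv",
    "read_tsv",
]

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3- or 6-column BED file into intervals."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=_BED_COLS, usecols=range(6), engine="python",
    )
    out = []
    for row in df.itertuples(index=False):
        strand = row.strand if row.strand in ("+", "-") else "."
        out.append(GenomicInterval(str(row.chrom), int(row.start), int(row.end), strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Iterable[str] | None = None) -> None:
    ivs = list(intervals)
    if names is None:
        names = [f"region_{i}" for i in range(len(ivs))]
    df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in ivs],
            "start": [iv.start for iv in ivs],
            "end": [iv.end for iv in ivs],
            "name": list(names),
            "score": 0,
            "strand": [iv.strand for iv in ivs],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr))


def read_gtf(path: str | Path) -> pd.DataFrame:
    """Read gene/transcript/exon features from a GTF file.

    Returns a DataFrame with columns ``chrom, source, feature, start, end,
    strand, gene_id, transcript_id, class_code`` — coordinates converted to
    0-based half-open.  Other feature types are skipped.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] not in ("gene", "transcript", "exon"):
                continue
            attrs = _parse_attributes(f[8]) if len(f) > 8 else {}
            rows.append(
                {
                    "chrom": f[0],
                    "source": f[1],
                    "feature": f[2],
                    "start": int(f[3]) - 1,  # GTF is 1-based closed
                    "end": int(f[4]),
                    "strand": f[6],
                    "gene_id": attrs.get("gene_id", ""),
                    "transcript_id": attrs.get("transcript_id", ""),
                    "class_code": attrs.get("class_code", ""),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "source", "feature", "start", "end", "strand",
                 "gene_id", "transcript_id", "class_code"],
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{id: sequence}`` with T mapped to U (RNA alphabet)."""
    return {
        rec.id: str(rec.seq).upper().replace("T", "U")
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
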