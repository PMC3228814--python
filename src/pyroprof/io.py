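"""FASTA and TSV input/output.

Thin wrappers over Biopython's SeqIO and pandas, fixing the conventions
used throughout the package: records are ``(id, sequence)`` pairs, IDs are
the FASTA header up to the first whitespace, and write-then-read is an
identity.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, sequence)`` pairs.

    Raises ``ValueError`` (with the line number) on a record without a
    header or with an empty sequence; an empty file yields an empty list
    with a warning.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        logger.warning("empty FASTA file: %s", path)
        return []
    first = next(ln for ln in text.splitlines() if ln.strip())
    if not first.startswith(">"):
        lineno = 1 + text.splitlines().index(first)
        raise ValueError(f"{path}:{lineno}: expected FASTA header, got {first!r}")
    records = [(rec.id, str(rec.seq).upper())
               for rec in SeqIO.parse(str(path), "fasta")]
    for k, (rid, seq) in enumerate(records):
        if not seq:
            raise ValueError(f"{path}: record {rid!r} (#{k + 1}) has an empty sequence")
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    """Write ``(id, sequence)`` pairs as wrapped FASTA."""
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)
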