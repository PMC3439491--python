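"""Sequence and table IO, plus small sequence utilities.

FASTA reading/writing goes through Bio.SeqIO; tables through pandas. Records
are normalised on ingest: sequence identifiers must be non-empty and bases
are upper-cased.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import CargBendError, InvalidAlphabetError, SchemaError

logger = logging.getLogger("cargbend")

_DNA_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (upper-case ACGTN)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise CargBendError("sequence record id must be non-empty")
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - _DNA_ALPHABET
        if bad:
            raise InvalidAlphabetError(
                f"record {self.id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly line-wrapped, mixed-case) multi-record FASTA file."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def read_table(path: str | Path, schema: Mapping[str, type]) -> pd.DataFrame:
    """Read a TSV with header and validate it against ``schema``.

    ``schema`` maps required column names to the dtype they must coerce to
    (``float``, ``int`` or ``str``). Extra columns are kept untouched.
    Raises :class:`SchemaError` naming the missing column or the 1-based
    file line of the first malformed row.
    """
    df = pd.read_csv(path, sep="\t")
    for col, typ in schema.items():
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
        if typ in (float, int):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any() or df[col].isna().any():
                idx = int((coerced.isna()).idxmax())
                # +2: one for the header line, one for 1-based numbering
                raise SchemaError(
                    f"{path}: malformed value in column {col!r} at line {idx + 2}"
                )
            df[col] = coerced.astype(typ)
        else:
            df[col] = df[col].astype(str)
    return df


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse-complement of an ACGTN string (an involution)."""
    seq = seq.upper()
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise InvalidAlphabetError(f"invalid characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def orf_protein_length(orf_nt: int) -> int:
    """Amino-acid count encoded by an ORF of ``orf_nt`` nucleotides.

    The ORF length includes the stop codon, so a 732 bp ORF encodes a
    243-residue protein (732/3 - 1).
    """
    if orf_nt % 3 != 0:
        raise CargBendError(f"ORF length {orf_nt} is not a multiple of 3")
    if orf_nt < 6:
        raise CargBendError(f"ORF length {orf_nt} too short (< start + stop)")
    return orf_nt // 3 - 1


def file_checksum(path: str | Path) -> str:
    """SHA-256 hex digest of a file, for provenance logging."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def log_run(command: str, seed: int | None = None, inputs: Iterable[str | Path] = ()) -> None:
    """Record version, seed and input checksums for a pipeline run."""
    from . import __version__

    parts = [f"cargbend {__version__}", f"command={command}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    for p in inputs:
        parts.append(f"{Path(p).name}:sha256={file_checksum(p)[:12]}")
    logger.info(" ".join(parts))
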