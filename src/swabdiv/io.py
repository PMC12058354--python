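"""Reading, writing and quality/length filtering of amplicon reads.

Reads arrive as demultiplexed, per-sample FASTQ (Phred+33).  The filters
implemented here mirror the standard nanopore amplicon intake: a minimum
mean Q-score (computed in error-probability space, the nanopore convention)
and an inclusive length window bracketing the expected amplicon size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Read",
    "FilterSpec",
    "FastqParseError",
    "read_fastq",
    "write_fastq",
    "write_fasta",
    "mean_qscore",
    "filter_reads",
    "write_rejection_report",
    "read_manifest",
]


class FastqParseError(ValueError):
    """Raised for malformed FASTQ records; the message names the record."""


@dataclass(frozen=True)
class Read:
    """A single sequencing read with per-base Phred qualities.

    ``qualities`` must have the same length as ``sequence``; both are
    validated at construction time.
    """

    id: str
    sequence: str
    qualities: tuple[int, ...]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise FastqParseError(
                f"read {self.id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        if len(self.sequence) == 0:
            raise FastqParseError(f"read {self.id!r}: empty sequence")
        if any(q < 0 for q in self.qualities):
            raise FastqParseError(f"read {self.id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FilterSpec:
    """Read-level filter thresholds.

    Defaults: mean Q >= 12 and length in [115, 315] bases, the window
    bracketing a ~215 bp mitochondrial 16S amplicon.  Both length bounds
    are inclusive on the kept side.
    """

    min_mean_q: float = 12.0
    min_len: int = 115
    max_len: int = 315
    #: if True, average Phred scores arithmetically instead of averaging
    #: error probabilities (not the default convention).
    arithmetic_mean: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError(
                f"require 0 < min_len <= max_len, got [{self.min_len}, {self.max_len}]"
            )
        if self.min_mean_q < 0:
            raise ValueError("min_mean_q must be >= 0")


def read_fastq(path: str | Path, sample_id: str = "") -> list[Read]:
    """Parse a Phred+33 FASTQ file into a list of :class:`Read`.

    Record order is preserved.  Malformed records (quality/sequence length
    mismatch, missing separator) raise :class:`FastqParseError` naming the
    offending record.
    """
    path = Path(path)
    if not sample_id:
        sample_id = path.stem
    reads: list[Read] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = tuple(rec.letter_annotations["phred_quality"])
            reads.append(Read(rec.id, str(rec.seq).upper(), quals, sample_id))
    except ValueError as exc:  # biopython reports the record in its message
        raise FastqParseError(f"{path}: {exc}") from exc
    return reads


def _to_seqrecord(read: Read) -> SeqRecord:
    rec = SeqRecord(Seq(read.sequence), id=read.id, description="")
    rec.letter_annotations["phred_quality"] = list(read.qualities)
    return rec


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads as Phred+33 FASTQ; returns the number written."""
    return SeqIO.write((_to_seqrecord(r) for r in reads), str(path), "fastq")


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> int:
    """Write ``(header, sequence)`` pairs as FASTA; returns the count."""
    n = 0
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")
            n += 1
    return n


def mean_qscore(read: Read, arithmetic: bool = False) -> float:
    """Mean Q-score of a read.

    By default the per-base Phred scores are converted to error
    probabilities, averaged, and converted back:
    ``-10 * log10(mean(10**(-q/10)))``.  This error-domain average is what
    nanopore basecallers report as the "mean Q-score" of a read and is
    always <= the arithmetic mean of the Q values (Jensen's inequality).
    """
    if len(read) == 0:
        raise ValueError(f"read {read.id!r} is empty")
    q = np.asarray(read.qualities, dtype=float)
    if arithmetic:
        return float(q.mean())
    return float(-10.0 * math.log10(np.mean(10.0 ** (-q / 10.0))))


def filter_reads(
    reads: Iterable[Read], spec: FilterSpec | None = None
) -> tuple[list[Read], list[tuple[Read, str]]]:
    """Partition reads into (kept, rejected-with-reason).

    A read is kept when ``min_len <= len <= max_len`` (both inclusive) and
    its mean Q-score is >= ``min_mean_q``.  Rejection reasons are
    ``"too_short"``, ``"too_long"`` or ``"quality"``; length is checked
    before quality.  Every input read lands in exactly one of the two
    outputs.
    """
    spec = spec or FilterSpec()
    kept: list[Read] = []
    rejected: list[tuple[Read, str]] = []
    for read in reads:
        if len(read) < spec.min_len:
            rejected.append((read, "too_short"))
        elif len(read) > spec.max_len:
            rejected.append((read, "too_long"))
        elif mean_qscore(read, arithmetic=spec.arithmetic_mean) < spec.min_mean_q:
            rejected.append((read, "quality"))
        else:
            kept.append(read)
    return kept, rejected


def write_rejection_report(
    rejected: Iterable[tuple[Read, str]], path: str | Path
) -> None:
    """TSV report of rejected reads: read_id, sample_id, reason."""
    rows = [(r.id, r.sample_id, reason) for r, reason in rejected]
    pd.DataFrame(rows, columns=["read_id", "sample_id", "reason"]).to_csv(
        path, sep="\t", index=False
    )


_MANIFEST_COLS = ["file", "sample_id", "habitat", "replicate", "time_of_day"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest TSV mapping FASTQ files to sample metadata.

    Required columns: file, sample_id, habitat, replicate, time_of_day.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _MANIFEST_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"manifest {path} has duplicate sample_ids")
    return df[_MANIFEST_COLS]
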