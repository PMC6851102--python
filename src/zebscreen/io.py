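"""Shared format readers and writers.

All genomic intervals are 0-based half-open. FASTA headers are tokenized on
the first whitespace. Malformed records raise :class:`FormatError` carrying
the file name and line number.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator


class FormatError(ValueError):
    """A record violated its file format."""


@dataclass(frozen=True)
class BedInterval:
    """One BED record; ``start``/``end`` are 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )


@dataclass(frozen=True)
class FastqRecord:
    name: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise FormatError(f"sequence/quality length mismatch for {self.name!r}")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    The record id is the header up to the first whitespace. An empty file
    yields an empty mapping.
    """
    records: dict[str, str] = {}
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            name = header.split()[0] if header.split() else header
            if name in records:
                raise FormatError(f"{path}: duplicate FASTA id {name!r}")
            records[name] = seq.upper()
    return records


def write_fasta(path: str | os.PathLike, records: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as handle:
        for name, seq in records.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_fastq(path: str | os.PathLike) -> list[FastqRecord]:
    """Read 4-line FASTQ records."""
    out = []
    with open(path) as handle:
        for name, seq, qual in FastqGeneralIterator(handle):
            out.append(FastqRecord(name, seq, qual))
    return out


def write_fastq(path: str | os.PathLike, records: Iterable[FastqRecord]) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f"@{rec.name}\n{rec.sequence}\n+\n{rec.quality}\n")


def iter_fastq_sequences(path: str | os.PathLike) -> Iterator[str]:
    """Yield only the sequence lines of a FASTQ file (fast path for demux)."""
    with open(path) as handle:
        for i, line in enumerate(handle):
            if i % 4 == 1:
                yield line.rstrip("\n")


def read_bed(path: str | os.PathLike) -> list[BedInterval]:
    """Parse BED3..BED6 into sorted intervals.

    Records are sorted by (chrom, start, end) after loading. Parse failures
    are fatal and name the offending line.
    """
    intervals = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED fields")
            try:
                interval = BedInterval(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=fields[3] if len(fields) > 3 else ".",
                    score=float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0,
                    strand=fields[5] if len(fields) > 5 else ".",
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            intervals.append(interval)
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_bed(path: str | os.PathLike, intervals: Iterable[BedInterval]) -> None:
    with open(path, "w") as handle:
        for iv in intervals:
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    """Read a TSV with a header row; lines starting with '#' are metadata."""
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_tsv(path: str | os.PathLike, frame: pd.DataFrame, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)
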