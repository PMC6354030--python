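"""Sequence input, sample registration, and size-based sample grouping.

Samples are one FASTA or FASTQ file each (optionally gzip-compressed).
Qualities are parsed but never used downstream; there is no quality filtering.
Grouping by byte size only stages index construction — it never changes results.
"""
from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ConfigError, ParseError

#: extensions stripped (after .gz) when deriving a sample id from a file name
SEQUENCE_EXTENSIONS = (".fasta", ".fa", ".fna", ".ffn", ".fastq", ".fq")

_GZIP_MAGIC = b"\x1f\x8b"

#: default staging-group byte cap (4 GiB)
DEFAULT_GROUP_CAP = 4 * 1024**3


@dataclass
class SequenceRecord:
    """One read: identifier, uppercase nucleotide string, optional quality."""

    id: str
    sequence: str
    quality: str | None = None


@dataclass
class SampleRecord:
    """One registered input sample (a single sequence file)."""

    sample_id: str
    path: Path
    format: str  # "fasta" | "fastq"
    compressed: bool
    byte_size: int
    read_count: int | None = None  # filled lazily by count_reads


@dataclass
class SampleGroup:
    """Samples staged together during index construction."""

    members: list[SampleRecord] = field(default_factory=list)
    total_bytes: int = 0


def _is_gzip(path: Path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == _GZIP_MAGIC


def open_text(path: str | os.PathLike) -> IO[str]:
    """Open a possibly gzip-compressed file as text."""
    path = Path(path)
    if _is_gzip(path):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "rt", encoding="ascii")


def detect_format(path: str | os.PathLike) -> str | None:
    """Return "fasta", "fastq", or None for an empty file.

    The first non-blank character decides: '>' FASTA, '@' FASTQ.
    """
    with open_text(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped[0] == ">":
                return "fasta"
            if stripped[0] == "@":
                return "fastq"
            raise ParseError(
                f"{path}: cannot detect format, first record starts with "
                f"{stripped[0]!r} (expected '>' or '@')"
            )
    return None


def read_sequences(path: str | os.PathLike) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA/FASTQ file (plain or gzip), in file order.

    Multi-line FASTA sequences are concatenated and all sequences uppercased.
    An empty file yields an empty stream.
    """
    path = Path(path)
    fmt = detect_format(path)
    if fmt is None:
        return
    with open_text(path) as fh:
        if fmt == "fasta":
            for ordinal, (title, seq) in enumerate(SimpleFastaParser(fh)):
                rid = title.split(None, 1)[0] if title.strip() else ""
                if not rid:
                    raise ParseError(f"{path}: empty FASTA header (record {ordinal + 1})")
                yield SequenceRecord(rid, seq.upper())
        else:
            ordinal = 0
            try:
                for title, seq, qual in FastqGeneralIterator(fh):
                    rid = title.split(None, 1)[0] if title.strip() else ""
                    if not rid:
                        raise ParseError(
                            f"{path}: empty FASTQ header near line {4 * ordinal + 1}"
                        )
                    if len(qual) != len(seq):
                        raise ParseError(
                            f"{path}: quality length != sequence length "
                            f"near line {4 * ordinal + 1}"
                        )
                    yield SequenceRecord(rid, seq.upper(), qual)
                    ordinal += 1
            except ValueError as exc:  # malformed record inside Biopython
                raise ParseError(
                    f"{path}: malformed FASTQ near line {4 * ordinal + 1}: {exc}"
                ) from exc


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="ascii") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def write_fastq(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="ascii") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else "I" * len(rec.sequence)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


def sample_id_from_path(path: str | os.PathLike) -> str:
    """Derive a sample id from a file basename.

    Strips a trailing .gz/.gzip, then one known sequence extension.
    """
    name = Path(path).name
    for ext in (".gz", ".gzip"):
        if name.lower().endswith(ext):
            name = name[: -len(ext)]
            break
    for ext in SEQUENCE_EXTENSIONS:
        if name.lower().endswith(ext):
            name = name[: -len(ext)]
            break
    return name


def register_samples(
    paths: Sequence[str | os.PathLike],
    sample_ids: Sequence[str | None] | None = None,
) -> list[SampleRecord]:
    """Register input files as samples, preserving input order.

    Explicit ``sample_ids`` entries (from a manifest) override basename-derived
    ids. Duplicate ids are a configuration error: the distance matrix labels
    would be ambiguous.
    """
    if not paths:
        raise ConfigError("no input samples given")
    samples: list[SampleRecord] = []
    seen: set[str] = set()
    for i, p in enumerate(paths):
        p = Path(p)
        sid = None
        if sample_ids is not None:
            sid = sample_ids[i]
        if sid is None:
            sid = sample_id_from_path(p)
        if sid in seen:
            raise ConfigError(f"duplicate sample id {sid}")
        seen.add(sid)
        fmt = detect_format(p) or "fasta"
        samples.append(
            SampleRecord(
                sample_id=sid,
                path=p,
                format=fmt,
                compressed=_is_gzip(p),
                byte_size=os.stat(p).st_size,
            )
        )
    return samples


def read_manifest(path: str | os.PathLike) -> tuple[list[str], list[str | None]]:
    """Read a manifest: one file path per line, optional tab-separated sample id."""
    paths: list[str] = []
    ids: list[str | None] = []
    base = Path(path).parent
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            p = Path(parts[0])
            if not p.is_absolute():
                p = base / p
            paths.append(str(p))
            ids.append(parts[1] if len(parts) > 1 and parts[1] else None)
    return paths, ids


def count_reads(sample: SampleRecord) -> int:
    """Count reads in a sample (cached on the record)."""
    if sample.read_count is None:
        sample.read_count = sum(1 for _ in read_sequences(sample.path))
    return sample.read_count


def group_samples(
    samples: Sequence[SampleRecord], cap: int = DEFAULT_GROUP_CAP
) -> list[SampleGroup]:
    """Greedy first-fit grouping of samples by byte size, in input order.

    Every sample lands in exactly one group; a group exceeds ``cap`` only when
    it holds a single oversized sample. Grouping affects staging only.
    """
    if cap <= 0:
        raise ConfigError(f"group cap must be positive, got {cap}")
    groups: list[SampleGroup] = []
    for s in samples:
        placed = False
        for g in groups:
            if g.total_bytes + s.byte_size <= cap:
                g.members.append(s)
                g.total_bytes += s.byte_size
                placed = True
                break
        if not placed:
            groups.append(SampleGroup(members=[s], total_bytes=s.byte_size))
    return groups
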