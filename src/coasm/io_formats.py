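"""Sequence I/O: FASTA/FASTQ ingestion, color manifests, and the annotated
contig FASTA dialect.

Readers are streaming and transparently handle gzip-compressed input
(detected by magic bytes, not file extension).  Sequences are uppercased on
ingest; FASTQ quality strings are carried along but never used downstream.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, List, Optional, Sequence, Tuple

__all__ = [
    "FormatError",
    "ReadRecord",
    "ManifestEntry",
    "ColorManifest",
    "parse_fasta",
    "parse_fastq",
    "parse_reads",
    "read_manifest",
    "write_manifest",
    "write_contigs",
    "read_contigs",
    "write_bed",
]


class FormatError(ValueError):
    """An input file violates its declared format."""

    def __init__(self, message: str, path=None, line: Optional[int] = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read (or any named sequence).

    ``sequence`` is uppercase over {A,C,G,T,N,...}; arbitrary letters are
    tolerated here and filtered downstream by :func:`~coasm.kmer_core.split_on_ambiguous`.
    """

    id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path) -> IO[str]:
    """Open a possibly gzip-compressed text file (magic-byte detection)."""
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="latin-1")
    return io.TextIOWrapper(raw, encoding="latin-1")


def parse_fasta(path) -> Iterator[ReadRecord]:
    """Stream records from a FASTA file (plain or gzipped).

    Raises :class:`FormatError` naming the line number for a malformed
    header, a record with an empty sequence, or sequence data appearing
    before the first header.
    """
    with _open_text(path) as fh:
        header: Optional[str] = None
        header_line = 0
        chunks: List[str] = []
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    if not chunks:
                        raise FormatError(
                            f"record {header!r} has an empty sequence",
                            path, header_line,
                        )
                    yield ReadRecord(header, "".join(chunks))
                name = line[1:].strip()
                if not name:
                    raise FormatError("empty FASTA header", path, lineno)
                header = name.split()[0]
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(
                        "sequence data before first '>' header", path, lineno
                    )
                chunks.append(line.upper())
        if header is not None:
            if not chunks:
                raise FormatError(
                    f"record {header!r} has an empty sequence", path, header_line
                )
            yield ReadRecord(header, "".join(chunks))


def parse_fastq(path) -> Iterator[ReadRecord]:
    """Stream records from a 4-line-per-record FASTQ file (plain or gzipped)."""
    with _open_text(path) as fh:
        lineno = 0
        while True:
            block = [fh.readline() for _ in range(4)]
            if block[0] == "":
                return
            if any(l == "" for l in block[1:]):
                raise FormatError(
                    "truncated FASTQ record (expected 4 lines)", path, lineno + 1
                )
            head, seq, plus, qual = (l.rstrip("\r\n") for l in block)
            if not head.startswith("@") or len(head) < 2:
                raise FormatError("malformed FASTQ header", path, lineno + 1)
            if not plus.startswith("+"):
                raise FormatError("missing '+' separator line", path, lineno + 3)
            if len(seq) != len(qual):
                raise FormatError(
                    f"sequence/quality length mismatch ({len(seq)} vs {len(qual)})",
                    path, lineno + 4,
                )
            if not seq:
                raise FormatError("empty sequence", path, lineno + 2)
            yield ReadRecord(head[1:].split()[0], seq.upper(), qual)
            lineno += 4


def parse_reads(path) -> Iterator[ReadRecord]:
    """Auto-detect FASTA vs FASTQ by the first non-blank character."""
    with _open_text(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line.strip()[0]
                break
    if first == "@":
        return parse_fastq(path)
    return parse_fasta(path)


# ---------------------------------------------------------------------------
# Color manifest: one line per color, "<label>\t<comma-separated paths>";
# the color index is the (0-based) line order.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestEntry:
    color: int
    label: str
    paths: Tuple[str, ...]


@dataclass(frozen=True)
class ColorManifest:
    entries: Tuple[ManifestEntry, ...]

    def __post_init__(self):
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("manifest labels must be unique")
        for i, e in enumerate(self.entries):
            if e.color != i:
                raise ValueError("manifest color indices must be 0..m-1 in order")
            if not e.paths:
                raise ValueError(f"color {e.label!r} lists no input files")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def labels(self) -> List[str]:
        return [e.label for e in self.entries]

    @classmethod
    def from_paths(cls, groups: Sequence[Tuple[str, Sequence[str]]]) -> "ColorManifest":
        return cls(tuple(
            ManifestEntry(i, label, tuple(str(p) for p in paths))
            for i, (label, paths) in enumerate(groups)
        ))


def read_manifest(path) -> ColorManifest:
    """Parse a manifest TSV; relative paths resolve against the manifest's dir."""
    base = Path(path).parent
    groups: List[Tuple[str, List[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    "expected '<label>\\t<comma-separated paths>'", path, lineno
                )
            label, paths = parts
            resolved = []
            for p in paths.split(","):
                p = p.strip()
                if not p:
                    raise FormatError("empty path entry", path, lineno)
                resolved.append(p if os.path.isabs(p) else str(base / p))
            groups.append((label.strip(), resolved))
    if not groups:
        raise FormatError("manifest lists no colors", path)
    return ColorManifest.from_paths(groups)


def write_manifest(manifest: ColorManifest, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in manifest:
            fh.write(f"{e.label}\t{','.join(e.paths)}\n")


# ---------------------------------------------------------------------------
# Contig FASTA dialect: ">contig_<n> len=<L> cov=<c0,c1,...>", 2-decimal
# coverages, contigs ordered by (length desc, sequence asc).
# ---------------------------------------------------------------------------

_WRAP = 80


def write_contigs(contigs, path) -> None:
    ordered = sorted(contigs, key=lambda c: (-len(c.sequence), c.sequence))
    with open(path, "w", encoding="ascii") as fh:
        for n, c in enumerate(ordered):
            cov = ",".join(f"{float(v):.2f}" for v in c.avg_coverage)
            fh.write(f">contig_{n} len={len(c.sequence)} cov={cov}\n")
            for i in range(0, len(c.sequence), _WRAP):
                fh.write(c.sequence[i:i + _WRAP] + "\n")


def read_contigs(path):
    """Read a contig FASTA written by :func:`write_contigs` back into
    :class:`~coasm.graph.Contig` objects.

    The ``cov=`` header annotation is optional so that plain FASTA
    assemblies can still be fed to the length-statistics tools.
    """
    import numpy as np

    from .graph import Contig

    contigs = []
    header_tokens: Optional[List[str]] = None
    chunks: List[str] = []

    def flush():
        if header_tokens is None:
            return
        cov = None
        for token in header_tokens[1:]:
            if token.startswith("cov="):
                cov = np.array([float(v) for v in token[4:].split(",")])
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"contig {header_tokens[0]!r} has an empty sequence", path)
        contigs.append(Contig(sequence=seq, kmer_count=None, avg_coverage=cov))

    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header_tokens = line[1:].split()
                chunks = []
            else:
                chunks.append(line.upper())
        flush()
    return contigs


def write_bed(intervals: Iterable[Tuple[int, int]], path, name: str = "region") -> None:
    """Write 0-based half-open intervals as BED3(+name)."""
    with open(path, "w", encoding="ascii") as fh:
        for i, (start, end) in enumerate(intervals):
            fh.write(f"{name}\t{start}\t{end}\tinterval_{i}\n")
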