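"""Canonical k-mer extraction and colored multiplicity counting.

A colored de Bruijn graph superimposes several read sets ("colors") on one
graph.  Its vertex set is the set of canonical k-mers observed in *any*
color; each vertex carries a per-color multiplicity vector, so the inputs
are virtually combined while remaining fully separable after assembly.

Conventions
-----------
* A k-mer and its reverse complement are identified: the *canonical* form
  is the lexicographic minimum of the two.  k is forced odd so no k-mer is
  its own reverse complement, which makes vertex identity across strands
  unambiguous.
* Edges of the graph are recorded only as *witnessed* canonical
  (k+1)-mers: an edge exists between two k-mers only if some read contains
  them consecutively overlapping.  Adjacency is never inferred from bare
  (k-1)-overlap.
* Per-color multiplicities saturate at 2**32 - 1 (bounded-memory contract).

k-mers are packed 2 bits/base into unsigned 64-bit integers (A=0, C=1,
G=2, T=3, first base most significant — so integer order equals
lexicographic order), which caps k at 31; the default assembly k is 25.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, List, Optional, Tuple, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_formats import ReadRecord

__all__ = [
    "BASES",
    "SATURATION",
    "AssemblyConfig",
    "KmerTable",
    "revcomp",
    "canonicalize",
    "split_on_ambiguous",
    "count_kmers",
    "encode_kmer",
    "decode_kmer",
]

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Per-color multiplicities clamp here instead of overflowing.
SATURATION = 2**32 - 1

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i

_ACGT_RUN = re.compile(r"[ACGT]+")


def revcomp(s: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return s.translate(_COMPLEMENT)[::-1]


def canonicalize(s: str) -> Tuple[str, bool]:
    """Return ``(canonical form, is_forward)`` for an odd-length DNA string.

    The canonical form is ``min(s, revcomp(s))``; the flag is True when the
    input itself was returned.  Odd length guarantees ``s != revcomp(s)``.
    """
    if len(s) % 2 == 0:
        raise ValueError(f"canonical form requires odd length, got {len(s)}")
    if _ACGT_RUN.fullmatch(s) is None:
        raise ValueError(f"ambiguous base in k-mer {s!r}")
    rc = revcomp(s)
    if s <= rc:
        return s, True
    return rc, False


def split_on_ambiguous(read: Union[ReadRecord, str]) -> List[str]:
    """Maximal runs of unambiguous {A,C,G,T} in a read's sequence.

    Runs shorter than k are returned as-is; they simply contribute no
    k-mers downstream.
    """
    seq = read.sequence if isinstance(read, ReadRecord) else str(read)
    return _ACGT_RUN.findall(seq.upper())


# ---------------------------------------------------------------------------
# 2-bit integer packing
# ---------------------------------------------------------------------------

def encode_kmer(s: str) -> int:
    """Pack a DNA string into a 2-bit-per-base integer."""
    code = 0
    for ch in s:
        v = int(_CODE[ord(ch)])
        if v > 3:
            raise ValueError(f"ambiguous base {ch!r} in k-mer")
        code = (code << 2) | v
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer` for a length-k string."""
    return "".join(BASES[(code >> (2 * i)) & 3] for i in range(k - 1, -1, -1))


def rc_code(code: int, k: int) -> int:
    """Reverse complement in packed form."""
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 - (code & 3))
        code >>= 2
    return out


def _rc_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized :func:`rc_code` over a uint64 array."""
    res = np.zeros_like(codes)
    tmp = codes.copy()
    two, three = np.uint64(2), np.uint64(3)
    for _ in range(k):
        res = (res << two) | (three - (tmp & three))
        tmp = tmp >> two
    return res


def _window_codes(base_codes: np.ndarray, w: int) -> np.ndarray:
    """Canonical packed codes for every ACGT-only window of width ``w``.

    ``base_codes`` is a uint8 array with values 0..3 for bases and >3 for
    separators/ambiguous characters; windows touching the latter are
    dropped.
    """
    if base_codes.size < w:
        return np.empty(0, dtype=np.uint64)
    W = sliding_window_view(base_codes, w)
    valid = (W <= 3).all(axis=1)
    if not valid.any():
        return np.empty(0, dtype=np.uint64)
    Wv = W[valid].astype(np.uint64)
    fwd_weights = np.uint64(4) ** np.arange(w - 1, -1, -1, dtype=np.uint64)
    rc_weights = np.uint64(4) ** np.arange(w, dtype=np.uint64)
    fwd = Wv @ fwd_weights
    rc = (np.uint64(3) - Wv) @ rc_weights
    return np.minimum(fwd, rc)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssemblyConfig:
    """Parameters of a coassembly run.

    Defaults follow the published single-cell runs of the method this
    package implements: k = 25, coverage cutoff 100, and a >= 100 bp
    contig filter.

    Parameters
    ----------
    k:
        de Bruijn graph k-mer length; odd, 3..31.
    coverage_cutoff:
        Final threshold of the progressive low-coverage trimming schedule
        (in average k-mer multiplicity units).  A unitig survives if its
        *maximum* per-color average coverage reaches the threshold — this
        is the multi-color rescue mechanism.
    min_contig_len:
        Minimum output contig length in bp.
    presence_epsilon:
        A contig is "present" in a color when its average coverage there
        strictly exceeds this value.
    num_colors:
        Number of colors m; usually derived from the manifest.
    tip_len_factor:
        Dead-end branches shorter than ``tip_len_factor * k`` bp are
        candidates for tip clipping.
    trim_steps:
        Number of linearly rising thresholds in the trimming schedule.
    seed:
        Recorded for provenance; the assembler itself is deterministic.
    """

    k: int = 25
    coverage_cutoff: float = 100.0
    min_contig_len: int = 100
    presence_epsilon: float = 0.0
    num_colors: Optional[int] = None
    tip_len_factor: float = 2.0
    trim_steps: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError(f"k must be an odd integer >= 3, got {self.k}")
        if self.k > 31:
            raise ValueError(f"k must be <= 31 (2-bit packing), got {self.k}")
        if self.coverage_cutoff < 0:
            raise ValueError("coverage_cutoff must be >= 0")
        if self.min_contig_len < 1:
            raise ValueError("min_contig_len must be >= 1")
        if self.presence_epsilon < 0:
            raise ValueError("presence_epsilon must be >= 0")
        if self.trim_steps < 1:
            raise ValueError("trim_steps must be >= 1")
        if self.num_colors is not None and self.num_colors < 1:
            raise ValueError("num_colors must be >= 1")


# ---------------------------------------------------------------------------
# The table itself
# ---------------------------------------------------------------------------

class KmerTable:
    """Canonical k-mer -> per-color multiplicity vector, plus the set of
    observed canonical (k+1)-mers that witness graph edges.

    Acts as a read-only mapping keyed by canonical k-mer string; counting
    happens through :meth:`count_reads` (or the module-level
    :func:`count_kmers`), which is vectorized over batches of reads.
    """

    def __init__(self, k: int, num_colors: int):
        if k < 3 or k % 2 == 0 or k > 31:
            raise ValueError(f"k must be odd and in 3..31, got {k}")
        if num_colors < 1:
            raise ValueError("num_colors must be >= 1")
        self.k = k
        self.num_colors = num_colors
        self._index: dict = {}
        self._counts = np.zeros((1024, num_colors), dtype=np.uint64)
        #: canonical (k+1)-mer codes observed in some read
        self.witnesses: set = set()
        #: shortest read seen so far (None before any counting)
        self.min_read_len: Optional[int] = None

    # -- mapping interface ---------------------------------------------------

    def __len__(self) -> int:
        return len(self._index)

    def _canon_code(self, kmer: str) -> int:
        code = encode_kmer(kmer)
        return min(code, rc_code(code, self.k))

    def __contains__(self, kmer: str) -> bool:
        if len(kmer) != self.k:
            return False
        try:
            return self._canon_code(kmer) in self._index
        except ValueError:
            return False

    def __getitem__(self, kmer: str) -> np.ndarray:
        if len(kmer) != self.k:
            raise KeyError(kmer)
        row = self._index.get(self._canon_code(kmer))
        if row is None:
            raise KeyError(kmer)
        return self._counts[row].copy()

    def items(self) -> Iterator[Tuple[str, np.ndarray]]:
        for code, row in self._index.items():
            yield decode_kmer(code, self.k), self._counts[row].copy()

    def keys(self) -> Iterator[str]:
        for code in self._index:
            yield decode_kmer(code, self.k)

    @property
    def counts(self) -> np.ndarray:
        """(n_kmers, m) view of the multiplicity matrix (do not mutate)."""
        return self._counts[: len(self._index)]

    def total_count(self, color: Optional[int] = None):
        """Sum of multiplicities — equals the number of counted k-windows
        while below saturation."""
        if color is None:
            return int(self.counts.sum())
        return int(self.counts[:, color].sum())

    # -- counting ------------------------------------------------------------

    def count_reads(self, reads: Iterable[Union[ReadRecord, str]], color: int,
                    _batch_chars: int = 2_000_000) -> "KmerTable":
        """Count every k-window and record every (k+1)-window of ``reads``
        under ``color``.  Reads shorter than k contribute nothing."""
        if not 0 <= color < self.num_colors:
            raise ValueError(f"color {color} out of range 0..{self.num_colors - 1}")
        buf: List[str] = []
        size = 0
        for r in reads:
            seq = r.sequence if isinstance(r, ReadRecord) else str(r)
            if self.min_read_len is None or len(seq) < self.min_read_len:
                self.min_read_len = len(seq)
            buf.append(seq.upper())
            size += len(seq) + 1
            if size >= _batch_chars:
                self._ingest("N".join(buf), color)
                buf, size = [], 0
        if buf:
            self._ingest("N".join(buf), color)
        return self

    def _ingest(self, text: str, color: int) -> None:
        base_codes = _CODE[np.frombuffer(text.encode("latin-1"), dtype=np.uint8)]
        kw = _window_codes(base_codes, self.k)
        if kw.size:
            uniq, cnt = np.unique(kw, return_counts=True)
            self._bump(uniq, cnt.astype(np.uint64), color)
        ew = _window_codes(base_codes, self.k + 1)
        if ew.size:
            self.witnesses.update(np.unique(ew).tolist())

    def _bump(self, codes: np.ndarray, cnt: np.ndarray, color: int) -> None:
        idx = self._index
        n = len(idx)
        rows = np.empty(codes.size, dtype=np.intp)
        for i, code in enumerate(codes.tolist()):
            row = idx.get(code)
            if row is None:
                row = n
                idx[code] = n
                n += 1
            rows[i] = row
        if n > self._counts.shape[0]:
            grown = np.zeros((max(2 * self._counts.shape[0], n), self.num_colors),
                             dtype=np.uint64)
            grown[: self._counts.shape[0]] = self._counts
            self._counts = grown
        col = self._counts[rows, color] + cnt
        self._counts[rows, color] = np.minimum(col, np.uint64(SATURATION))


def count_kmers(reads: Iterable[Union[ReadRecord, str]], color: int, k: int,
                table: KmerTable) -> KmerTable:
    """Accumulate ``reads`` into ``table`` under ``color`` (see
    :meth:`KmerTable.count_reads`)."""
    if table.k != k:
        raise ValueError(f"table was built for k={table.k}, not k={k}")
    return table.count_reads(reads, color)
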