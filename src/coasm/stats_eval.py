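"""Assembly statistics and a lightweight reference-based evaluator.

``length_stats`` gives the usual N50/NG50/total summaries over a minimum
contig length.  ``reference_kmer_eval`` approximates "missing reference
bases" by shared-k-mer coverage of reference positions: a position counts
as covered when at least one k-window containing it has its canonical
k-mer present in the assembly.  This is a desk-scale, alignment-free
surrogate for alignment-pipeline evaluators — monotone in true
completeness, but not claiming their exact error classes.

``blackout_regions`` quantifies zero-coverage gaps of a per-position depth
track; intervals are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .graph import Contig
from .kmer_core import _CODE, _window_codes

__all__ = [
    "AssemblyStats",
    "ReferenceEval",
    "length_stats",
    "reference_kmer_eval",
    "blackout_regions",
    "format_stats",
]


@dataclass(frozen=True)
class AssemblyStats:
    """Length statistics over contigs >= ``min_len``.

    ``ng50`` is None when either no genome size was given or the filtered
    assembly never accumulates half the genome size.
    """

    num_contigs: int
    total_bp: int
    max_len: int
    n50: int
    ng50: Optional[int]
    empty: bool


@dataclass(frozen=True)
class ReferenceEval:
    reference_len: int
    total_kmers: int          # distinct canonical k-mers of the reference
    missing_kmers: int
    missing_fraction: float
    covered_positions: int
    missing_bases: int


def _lengths(contigs: Sequence[Union[Contig, int]]) -> List[int]:
    return [c if isinstance(c, int) else len(c.sequence) for c in contigs]


def length_stats(contigs: Sequence[Union[Contig, int]], min_len: int = 1,
                 genome_size: Optional[int] = None) -> AssemblyStats:
    """N50 = largest L such that contigs of length >= L sum to at least
    half the (filtered) assembly total; NG50 replaces the assembly total
    with ``genome_size``.  The length filter is applied first."""
    lengths = sorted((l for l in _lengths(contigs) if l >= min_len), reverse=True)
    if not lengths:
        return AssemblyStats(0, 0, 0, 0, None, True)
    total = int(sum(lengths))
    cumulative = np.cumsum(lengths)
    n50 = lengths[int(np.searchsorted(cumulative, total / 2))]
    ng50 = None
    if genome_size is not None:
        half = genome_size / 2
        if cumulative[-1] >= half:
            ng50 = lengths[int(np.searchsorted(cumulative, half))]
    return AssemblyStats(len(lengths), total, lengths[0], int(n50), ng50, False)


def reference_kmer_eval(contigs: Sequence[Union[Contig, str]], reference: str,
                        k: int) -> ReferenceEval:
    """Shared-k-mer completeness of an assembly against a reference.

    Ambiguous reference bases are masked: windows containing them are
    skipped and those positions can only be covered through neighbouring
    clean windows (an all-N position is never covered).
    """
    reference = reference.upper()
    n = len(reference)
    if k > n:
        raise ValueError(f"k={k} exceeds reference length {n}")

    def codes_of(seq: str) -> np.ndarray:
        base = _CODE[np.frombuffer(seq.encode("latin-1"), dtype=np.uint8)]
        return _window_codes(base, k)

    asm_parts = []
    for c in contigs:
        seq = c if isinstance(c, str) else c.sequence
        w = codes_of(seq)
        if w.size:
            asm_parts.append(w)
    asm_kmers = (np.unique(np.concatenate(asm_parts))
                 if asm_parts else np.empty(0, dtype=np.uint64))

    ref_base = _CODE[np.frombuffer(reference.encode("latin-1"), dtype=np.uint8)]
    # per-window canonical codes including invalid (masked) windows, so
    # window index maps back to reference position
    from numpy.lib.stride_tricks import sliding_window_view
    W = sliding_window_view(ref_base, k)
    valid = (W <= 3).all(axis=1)
    ref_codes = np.zeros(W.shape[0], dtype=np.uint64)
    if valid.any():
        Wv = W[valid].astype(np.uint64)
        fwd_w = np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64)
        rc_w = np.uint64(4) ** np.arange(k, dtype=np.uint64)
        ref_codes[valid] = np.minimum(Wv @ fwd_w, (np.uint64(3) - Wv) @ rc_w)

    distinct_ref = np.unique(ref_codes[valid]) if valid.any() else np.empty(0, np.uint64)
    if asm_kmers.size and distinct_ref.size:
        hit = np.isin(distinct_ref, asm_kmers, assume_unique=True)
        missing_kmers = int(distinct_ref.size - hit.sum())
    else:
        missing_kmers = int(distinct_ref.size)
    missing_fraction = missing_kmers / distinct_ref.size if distinct_ref.size else 0.0

    window_hit = np.zeros(W.shape[0], dtype=bool)
    if asm_kmers.size and valid.any():
        window_hit[valid] = np.isin(ref_codes[valid], asm_kmers)
    delta = np.zeros(n + 1, dtype=np.int64)
    starts = np.nonzero(window_hit)[0]
    np.add.at(delta, starts, 1)
    np.add.at(delta, starts + k, -1)
    covered = int((np.cumsum(delta[:-1]) > 0).sum())

    return ReferenceEval(
        reference_len=n,
        total_kmers=int(distinct_ref.size),
        missing_kmers=missing_kmers,
        missing_fraction=missing_fraction,
        covered_positions=covered,
        missing_bases=n - covered,
    )


def blackout_regions(track: Sequence[float], threshold: float = 0.0
                     ) -> Tuple[List[Tuple[int, int]], float]:
    """Maximal runs of depth <= ``threshold`` as sorted, disjoint 0-based
    half-open intervals, plus the fraction of positions they cover."""
    t = np.asarray(track)
    if t.size == 0:
        return [], 0.0
    mask = t <= threshold
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = edges[0::2], edges[1::2]
    intervals = [(int(s), int(e)) for s, e in zip(starts, ends)]
    return intervals, float(mask.sum() / t.size)


def format_stats(stats: AssemblyStats, min_len: int) -> str:
    lines = [
        f"contigs (>= {min_len} bp)\t{stats.num_contigs}",
        f"total bp\t{stats.total_bp}",
        f"longest contig\t{stats.max_len}",
        f"N50\t{stats.n50}",
        f"NG50\t{stats.ng50 if stats.ng50 is not None else 'NA'}",
    ]
    if stats.empty:
        lines.append("# no contigs pass the length filter")
    return "\n".join(lines) + "\n"
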