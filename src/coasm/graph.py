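"""Colored de Bruijn graph: construction, cleaning, and contig extraction.

The graph is bidirected: every vertex is a canonical k-mer standing for
both strands.  Traversal works on *oriented* vertices — a vertex paired
with the strand being read — encoded as ``code * 2 + orient`` where
``orient`` is 0 when the traversal sequence equals the stored canonical
string and 1 when it is the reverse complement.  An arc exists only if its
(k+1)-mer witness was observed in some read; for every witness both the
forward arc and its mirror (reverse-complement) arc are installed, so
predecessor queries reduce to successor queries on the flipped vertex.

Contigs are *color-oblivious*: unitigs (maximal non-branching paths) are
extracted from the union graph ignoring colors entirely, and only then
annotated with per-color average coverage.  That single property yields
both behaviors this assembler exists for:

* rescue — a region poorly amplified in one cell survives cleaning
  because another color covers it well (trimming condemns on the MAX over
  colors);
* comparison — shared and exclusive sequence between colors falls out of
  which contigs have non-zero coverage in which colors, with no alignment.

All tie-breaking (node iteration, contig ordering) is lexicographic on
canonical sequence, so the whole pipeline is deterministic without a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import io_formats
from .io_formats import ColorManifest, ReadRecord
from .kmer_core import (
    BASES,
    AssemblyConfig,
    KmerTable,
    _rc_codes,
    decode_kmer,
    revcomp,
)

__all__ = [
    "Contig",
    "ColoredGraph",
    "build_graph",
    "condense",
    "clip_tips",
    "trim_low_coverage",
    "assemble",
    "assemble_reads",
    "assemble_with_report",
    "iterative_assemble",
    "iterative_assemble_reads",
]


@dataclass(frozen=True, eq=False)
class Contig:
    """An output contig: sequence in canonical orientation (min of the
    sequence and its reverse complement) plus the per-color average
    coverage over its constituent k-mers."""

    sequence: str
    kmer_count: Optional[int]
    avg_coverage: Optional[np.ndarray]

    def __len__(self) -> int:
        return len(self.sequence)


class ColoredGraph:
    """Vertices (canonical k-mer codes with multiplicity vectors) plus the
    witness-derived oriented adjacency.

    Node removal is cheap: drop the code from :attr:`nodes`; adjacency is
    filtered against the live node set at query time.
    """

    def __init__(self, k: int, num_colors: int, nodes: set,
                 adj: Dict[int, Tuple[int, ...]], table: KmerTable):
        self.k = k
        self.num_colors = num_colors
        self.nodes = nodes              # live canonical k-mer codes
        self._adj = adj                 # oriented key -> tuple of oriented keys
        self._table = table

    def __len__(self) -> int:
        return len(self.nodes)

    def succ(self, key: int) -> List[int]:
        """Oriented successors of an oriented vertex key."""
        return [t for t in self._adj.get(key, ()) if (t >> 1) in self.nodes]

    def pred(self, key: int) -> List[int]:
        """Oriented predecessors; the mirror arcs make this a successor
        query on the flipped key."""
        return [t ^ 1 for t in self._adj.get(key ^ 1, ()) if (t >> 1) in self.nodes]

    def coverage_rows(self, codes: Sequence[int]) -> np.ndarray:
        idx = self._table._index
        rows = [idx[c] for c in codes]
        return self._table._counts[rows]

    def remove_nodes(self, codes: Iterable[int]) -> None:
        self.nodes.difference_update(codes)


def build_graph(table: KmerTable) -> ColoredGraph:
    """Materialize the graph from a counted table.

    A connection is installed iff its (k+1)-mer witness was observed and
    both endpoint k-mers are present in the table.
    """
    k = table.k
    nodes = set(table._index.keys())
    adj: Dict[int, List[int]] = {}
    if table.witnesses:
        w = np.fromiter(table.witnesses, dtype=np.uint64, count=len(table.witnesses))
        mask = np.uint64((1 << (2 * k)) - 1)
        u = w >> np.uint64(2)
        v = w & mask
        cu = np.minimum(u, _rc_codes(u, k))
        cv = np.minimum(v, _rc_codes(v, k))
        ou = (u != cu).view(np.uint8)
        ov = (v != cv).view(np.uint8)
        idx = table._index
        for cu_i, ou_i, cv_i, ov_i in zip(
            cu.tolist(), ou.tolist(), cv.tolist(), ov.tolist()
        ):
            if cu_i not in idx or cv_i not in idx:
                continue
            a = cu_i * 2 + ou_i
            b = cv_i * 2 + ov_i
            adj.setdefault(a, []).append(b)
            adj.setdefault(b ^ 1, []).append(a ^ 1)
    frozen = {key: tuple(sorted(set(targets))) for key, targets in adj.items()}
    return ColoredGraph(k, table.num_colors, nodes, frozen, table)


# ---------------------------------------------------------------------------
# Unitigs
# ---------------------------------------------------------------------------

@dataclass
class _Unitig:
    keys: List[int]          # oriented vertex keys along the walk
    codes: List[int]         # canonical codes (same order)
    codes_set: set
    seq: str                 # sequence in walk orientation
    cov: np.ndarray          # per-color mean multiplicity (float)

    @property
    def max_cov(self) -> float:
        return float(self.cov.max())

    @property
    def first_key(self) -> int:
        return self.keys[0]

    @property
    def last_key(self) -> int:
        return self.keys[-1]


def _oriented_seq(key: int, k: int) -> str:
    s = decode_kmer(key >> 1, k)
    return revcomp(s) if key & 1 else s


def _walk(g: ColoredGraph, start_code: int) -> List[int]:
    """Maximal non-branching path through ``start_code`` (both directions).

    Extension stops at a junction (vertex whose in- or out-degree in the
    union graph differs from 1) or when the next vertex — as a canonical
    k-mer, i.e. either strand — is already on the path, which bounds
    cycles and palindromic (k+1)-mer turnarounds.
    """
    key = start_code * 2
    path = [key]
    used = {start_code}
    cur = key
    while True:
        nxt = g.succ(cur)
        if len(nxt) != 1:
            break
        nk = nxt[0]
        if len(g.pred(nk)) != 1 or (nk >> 1) in used:
            break
        path.append(nk)
        used.add(nk >> 1)
        cur = nk
    front: List[int] = []
    cur = path[0]
    while True:
        prv = g.pred(cur)
        if len(prv) != 1:
            break
        pk = prv[0]
        if len(g.succ(pk)) != 1 or (pk >> 1) in used:
            break
        front.append(pk)
        used.add(pk >> 1)
        cur = pk
    front.reverse()
    return front + path


def _unitigs(g: ColoredGraph) -> List[_Unitig]:
    """Partition the live node set into maximal non-branching paths."""
    k = g.k
    visited: set = set()
    out: List[_Unitig] = []
    for code in sorted(g.nodes):
        if code in visited:
            continue
        path = _walk(g, code)
        codes = [key >> 1 for key in path]
        visited.update(codes)
        parts = [_oriented_seq(path[0], k)]
        for key in path[1:]:
            c = key >> 1
            if key & 1:
                parts.append(BASES[3 - ((c >> (2 * (k - 1))) & 3)])
            else:
                parts.append(BASES[c & 3])
        cov = g.coverage_rows(codes).astype(float).mean(axis=0)
        out.append(_Unitig(path, codes, set(codes), "".join(parts), cov))
    return out


def condense(g: ColoredGraph) -> List[Contig]:
    """Color-oblivious contigs: one per maximal non-branching path, with
    per-color average coverage, ordered (length desc, sequence asc)."""
    contigs = []
    for u in _unitigs(g):
        rc = revcomp(u.seq)
        seq = u.seq if u.seq <= rc else rc
        contigs.append(Contig(seq, len(u.codes), u.cov))
    contigs.sort(key=lambda c: (-len(c.sequence), c.sequence))
    return contigs


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

def clip_tips(g: ColoredGraph, cfg: AssemblyConfig) -> ColoredGraph:
    """Remove dominated short dead-end branches, to a fixpoint.

    A unitig is a *tip* when exactly one of its ends has no continuation.
    It is clipped when it is shorter than ``tip_len_factor * k`` bp and
    its maximum per-color average coverage is strictly below that of the
    best alternative branch at its junction.  Isolated linear components
    (both ends dead) are never tips.
    """
    while True:
        unis = _unitigs(g)
        owner: Dict[int, _Unitig] = {}
        for u in unis:
            for c in u.codes:
                owner[c] = u
        removed_any = False
        dropped: set = set()
        for u in unis:
            if u.codes_set & dropped:
                continue
            fwd = g.succ(u.last_key)
            bwd = g.pred(u.first_key)
            dead_f, dead_b = not fwd, not bwd
            if dead_f == dead_b:
                continue
            if len(u.seq) >= cfg.tip_len_factor * cfg.k:
                continue
            if dead_f:
                # attached through the first vertex; competitors are the
                # other branches leaving the junction vertices behind us
                sibs = [s for p in bwd for s in g.succ(p)
                        if (s >> 1) not in u.codes_set]
            else:
                sibs = [s for nxt in fwd for s in g.pred(nxt)
                        if (s >> 1) not in u.codes_set]
            alt = [owner[s >> 1].max_cov for s in sibs
                   if (s >> 1) in owner and (s >> 1) not in dropped]
            if not alt:
                continue
            if u.max_cov < max(alt):
                g.remove_nodes(u.codes_set)
                dropped |= u.codes_set
                removed_any = True
        if not removed_any:
            return g


def trim_low_coverage(g: ColoredGraph, cfg: AssemblyConfig) -> ColoredGraph:
    """Progressive low-coverage trimming with multi-color rescue.

    ``trim_steps`` thresholds rise linearly from ``cutoff/trim_steps`` to
    ``cutoff``; at each step the graph is recondensed into unitigs and
    every unitig whose **maximum** per-color average coverage falls
    strictly below the current threshold is deleted.  Judging on the max
    over colors is what lets one well-covered color rescue a region that
    another color barely sampled, while many weak colors cannot pool their
    coverage to fake strength.
    """
    cutoff = cfg.coverage_cutoff
    if cutoff <= 0:
        return g
    for step in range(1, cfg.trim_steps + 1):
        threshold = cutoff * step / cfg.trim_steps
        for u in _unitigs(g):
            if u.max_cov < threshold:
                g.remove_nodes(u.codes_set)
    return g


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _count_manifest(manifest: ColorManifest, cfg: AssemblyConfig,
                    stats: Optional[list] = None) -> KmerTable:
    m = cfg.num_colors if cfg.num_colors is not None else len(manifest)
    if m < len(manifest):
        raise ValueError("num_colors smaller than the number of manifest entries")
    table = KmerTable(cfg.k, m)
    for entry in manifest:
        n_reads = 0
        n_bases = 0

        def counted():
            nonlocal n_reads, n_bases
            for path in entry.paths:
                for rec in io_formats.parse_reads(path):
                    n_reads += 1
                    n_bases += len(rec)
                    yield rec

        table.count_reads(counted(), entry.color)
        if stats is not None:
            stats.append({"label": entry.label, "reads": n_reads, "bases": n_bases})
    return table


def _assemble_table(table: KmerTable, cfg: AssemblyConfig) -> List[Contig]:
    g = build_graph(table)
    clip_tips(g, cfg)
    trim_low_coverage(g, cfg)
    contigs = [c for c in condense(g) if len(c.sequence) >= cfg.min_contig_len]
    contigs.sort(key=lambda c: (-len(c.sequence), c.sequence))
    return contigs


def assemble(manifest: ColorManifest, cfg: AssemblyConfig) -> List[Contig]:
    """Full coassembly: count -> build -> clip tips -> progressive trim ->
    condense -> length filter.  Deterministic given inputs and config."""
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    table = _count_manifest(manifest, cfg)
    return _assemble_table(table, cfg)


def assemble_reads(read_sets: Sequence[Iterable[Union[ReadRecord, str]]],
                   cfg: AssemblyConfig) -> List[Contig]:
    """Like :func:`assemble` but over in-memory read sets (one per color)."""
    if not read_sets:
        raise ValueError("no read sets given")
    m = cfg.num_colors if cfg.num_colors is not None else len(read_sets)
    table = KmerTable(cfg.k, m)
    for color, reads in enumerate(read_sets):
        table.count_reads(reads, color)
    return _assemble_table(table, cfg)


def assemble_with_report(manifest: ColorManifest, cfg: AssemblyConfig):
    """:func:`assemble` plus a run-report dictionary (per-color read and
    k-mer input tallies)."""
    per_color: list = []
    table = _count_manifest(manifest, cfg, stats=per_color)
    contigs = _assemble_table(table, cfg)
    report = {
        "num_colors": table.num_colors,
        "k": cfg.k,
        "colors": per_color,
        "distinct_kmers": len(table),
        "num_contigs": len(contigs),
        "total_bp": sum(len(c) for c in contigs),
    }
    return contigs, report


def _iterative(make_table, k_list: Sequence[int], cfg: AssemblyConfig,
               m: int) -> List[Contig]:
    ks = list(k_list)
    if not ks:
        raise ValueError("k_list is empty")
    if any(k % 2 == 0 for k in ks) or sorted(set(ks)) != ks:
        raise ValueError("k_list must be strictly ascending odd integers")
    contigs: Optional[List[Contig]] = None
    for k in ks:
        cfg_k = replace(cfg, k=k, num_colors=m)
        table = make_table(cfg_k)
        if table.min_read_len is not None and k > table.min_read_len - 1:
            warnings.warn(
                f"k={k} exceeds shortest read length minus one "
                f"({table.min_read_len - 1}); only injected contigs can "
                f"contribute k-mers at this k",
                stacklevel=3,
            )
        if contigs is not None:
            # contigs from the previous round re-enter as pseudo-reads, once
            # per color in which they were present
            for c in contigs:
                for color in range(m):
                    if c.avg_coverage[color] > cfg.presence_epsilon:
                        table.count_reads([c.sequence], color)
        contigs = _assemble_table(table, cfg_k)
    return contigs


def iterative_assemble(manifest: ColorManifest, k_list: Sequence[int],
                       cfg: AssemblyConfig) -> List[Contig]:
    """Iterative multi-k coassembly (off by default in the CLI).

    Round one assembles at ``k_list[0]``; each later round re-counts the
    reads at the next k and additionally injects the previous round's
    contigs as pseudo-reads (multiplicity 1) into every color whose
    average coverage on that contig exceeds ``presence_epsilon``.  Longer
    k then resolves repeats whose length lies between consecutive k's.
    """
    m = cfg.num_colors if cfg.num_colors is not None else len(manifest)
    return _iterative(lambda c: _count_manifest(manifest, c), k_list, cfg, m)


def iterative_assemble_reads(read_sets: Sequence[Sequence[Union[ReadRecord, str]]],
                             k_list: Sequence[int],
                             cfg: AssemblyConfig) -> List[Contig]:
    """In-memory variant of :func:`iterative_assemble`; read sets must be
    re-iterable (lists, not generators)."""
    m = cfg.num_colors if cfg.num_colors is not None else len(read_sets)

    def make_table(cfg_k: AssemblyConfig) -> KmerTable:
        table = KmerTable(cfg_k.k, m)
        for color, reads in enumerate(read_sets):
            table.count_reads(reads, color)
        return table

    return _iterative(make_table, k_list, cfg, m)
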