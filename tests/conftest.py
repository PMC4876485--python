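"""Shared fixtures and independent oracles for the test suite.

The unitig oracle here deliberately uses a different representation from
the package (an explicit doubled-strand networkx digraph instead of
canonical vertices with oriented keys) so that agreement between the two
is meaningful.
"""

import re

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from coasm.kmer_core import revcomp

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

_ACGT = re.compile(r"[ACGT]+")


def brute_force_kmer_counts(reads, k):
    """Dict-of-strings recount: canonical k-mer -> multiplicity."""
    counts = {}
    for seq in reads:
        for frag in _ACGT.findall(seq.upper()):
            for i in range(len(frag) - k + 1):
                km = frag[i:i + k]
                canon = min(km, revcomp(km))
                counts[canon] = counts.get(canon, 0) + 1
    return counts


def oracle_unitigs(reads, k):
    """Maximal non-branching paths via an explicit doubled-strand digraph.

    Every observed k-mer and its reverse complement become separate
    digraph nodes; every observed (k+1)-mer adds one arc per strand.
    Unitigs partition the node set: a walk crosses an arc u -> w only
    when u has out-degree 1 and w has in-degree 1, and stops when the
    next node (or its reverse complement) is already on the path — the
    turnaround rule at palindromic (k+1)-mers and cycles.  Returns the
    set of canonical path sequences.
    """
    import networkx as nx

    G = nx.DiGraph()
    for seq in reads:
        for frag in _ACGT.findall(seq.upper()):
            for i in range(len(frag) - k + 1):
                km = frag[i:i + k]
                G.add_node(km)
                G.add_node(revcomp(km))
            for i in range(len(frag) - k):
                e = frag[i:i + k + 1]
                G.add_edge(e[:k], e[1:])
                re_ = revcomp(e)
                G.add_edge(re_[:k], re_[1:])

    sequences = set()
    claimed = set()
    for v in sorted(G):
        if v in claimed:
            continue
        path = [v]
        used = {v, revcomp(v)}
        cur = v
        while G.out_degree(cur) == 1:
            nxt = next(iter(G.successors(cur)))
            if G.in_degree(nxt) != 1 or nxt in used:
                break
            path.append(nxt)
            used.add(nxt)
            used.add(revcomp(nxt))
            cur = nxt
        cur = v
        front = []
        while G.in_degree(cur) == 1:
            prv = next(iter(G.predecessors(cur)))
            if G.out_degree(prv) != 1 or prv in used:
                break
            front.append(prv)
            used.add(prv)
            used.add(revcomp(prv))
            cur = prv
        path = front[::-1] + path
        seq = path[0] + "".join(p[-1] for p in path[1:])
        sequences.add(min(seq, revcomp(seq)))
        claimed.update(path)
        claimed.update(revcomp(p) for p in path)
    return sequences


def tiling_reads(genome, read_len=60, step=20):
    """Error-free single-end reads tiling a linear genome end to end."""
    if len(genome) <= read_len:
        return [genome]
    reads = [genome[i:i + read_len]
             for i in range(0, len(genome) - read_len + 1, step)]
    if (len(genome) - read_len) % step:
        reads.append(genome[-read_len:])
    return reads


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def write_fasta(tmp_path):
    def _write(name, records):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path
    return _write
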