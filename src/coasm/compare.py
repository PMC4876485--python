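"""Pairwise shared/exclusive sequence decomposition and the exclusivity
matrix over colors.

Because contigs come from a single union graph, any stretch of sequence at
least k long that two colors share already lies in common contigs; so the
comparison works at whole-contig granularity through coverage-presence
vectors and needs no alignment.  The *exclusivity ratio* of color i with
respect to color j is the summed length of contigs present in i but not j,
divided by the total assembly size of color i — near 0 for cells of the
same genome, near 1 for unrelated genomes.

Ratios are kept at full precision here; the TSV report layer rounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Set

import numpy as np

from .graph import Contig

__all__ = [
    "PairwiseComparison",
    "ExclusivityMatrix",
    "color_presence",
    "compare_pair",
    "exclusivity_matrix",
    "write_pairwise_tsv",
    "write_matrix_tsv",
]


@dataclass(frozen=True)
class PairwiseComparison:
    """Shared/exclusive base-pair totals for an ordered color pair.

    Invariants: ``total_i == shared + exclusive_i`` (likewise for j) and
    ``ratio_i_wrt_j == exclusive_i / total_i`` (0 when the total is 0).
    """

    i: int
    j: int
    total_i: int
    total_j: int
    shared: int
    exclusive_i: int
    exclusive_j: int
    ratio_i_wrt_j: float
    ratio_j_wrt_i: float


@dataclass(frozen=True)
class ExclusivityMatrix:
    """m x m matrix of exclusivity ratios, entry (i, j) = ratio of row
    color i with respect to column color j; diagonal exactly 0."""

    values: np.ndarray
    labels: List[str]
    #: colors whose length-filtered assembly is empty (ratios 0 by convention)
    empty_colors: List[int]


def color_presence(contig: Contig, eps: float = 0.0) -> Set[int]:
    """Colors in which a contig is present: average coverage strictly
    greater than ``eps``."""
    return {i for i, v in enumerate(contig.avg_coverage) if v > eps}


def _ratio(exclusive: int, total: int) -> float:
    return exclusive / total if total > 0 else 0.0


def compare_pair(contigs: Sequence[Contig], i: int, j: int,
                 eps: float = 0.0, min_len: int = 0) -> PairwiseComparison:
    """Decompose an assembly into shared/exclusive bp for colors i and j.

    Contigs shorter than ``min_len`` are ignored; a contig present in
    neither color contributes to no total.  ``i == j`` is defined and
    yields ratio 0 with ``shared == total_i``.
    """
    shared = excl_i = excl_j = 0
    for c in contigs:
        if len(c.sequence) < min_len:
            continue
        pres = color_presence(c, eps)
        has_i, has_j = i in pres, j in pres
        if has_i and has_j:
            shared += len(c.sequence)
        elif has_i:
            excl_i += len(c.sequence)
        elif has_j:
            excl_j += len(c.sequence)
    if i == j:
        total = shared + excl_i
        return PairwiseComparison(i, j, total, total, total, 0, 0, 0.0, 0.0)
    total_i = shared + excl_i
    total_j = shared + excl_j
    return PairwiseComparison(
        i, j, total_i, total_j, shared, excl_i, excl_j,
        _ratio(excl_i, total_i), _ratio(excl_j, total_j),
    )


def exclusivity_matrix(contigs: Sequence[Contig], m: int,
                       eps: float = 0.0, min_len: int = 0) -> ExclusivityMatrix:
    """All ordered pairwise exclusivity ratios over ``m`` colors."""
    if m < 1:
        raise ValueError("m must be >= 1")
    values = np.zeros((m, m))
    totals = np.zeros(m, dtype=np.int64)
    for a in range(m):
        for b in range(a + 1, m):
            pc = compare_pair(contigs, a, b, eps=eps, min_len=min_len)
            values[a, b] = pc.ratio_i_wrt_j
            values[b, a] = pc.ratio_j_wrt_i
            totals[a] = pc.total_i
            totals[b] = pc.total_j
    if m == 1:
        pc = compare_pair(contigs, 0, 0, eps=eps, min_len=min_len)
        totals[0] = pc.total_i
    labels = [f"color{a}" for a in range(m)]
    empty = [a for a in range(m) if totals[a] == 0]
    return ExclusivityMatrix(values, labels, empty)


def write_pairwise_tsv(contigs: Sequence[Contig], m: int, path,
                       eps: float = 0.0, min_len: int = 0,
                       labels: Sequence[str] = None) -> None:
    labels = list(labels) if labels else [f"color{a}" for a in range(m)]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("i\tj\ttotal_i\ttotal_j\tshared\texclusive_i\texclusive_j"
                 "\tratio_ij\tratio_ji\n")
        for a in range(m):
            for b in range(a + 1, m):
                pc = compare_pair(contigs, a, b, eps=eps, min_len=min_len)
                fh.write(
                    f"{labels[a]}\t{labels[b]}\t{pc.total_i}\t{pc.total_j}\t"
                    f"{pc.shared}\t{pc.exclusive_i}\t{pc.exclusive_j}\t"
                    f"{pc.ratio_i_wrt_j:.4f}\t{pc.ratio_j_wrt_i:.4f}\n"
                )


def format_matrix_tsv(matrix: ExclusivityMatrix, percent: bool = False,
                      labels: Sequence[str] = None) -> str:
    labels = list(labels) if labels else matrix.labels
    lines = ["\t" + "\t".join(labels)]
    for a, row in enumerate(matrix.values):
        if percent:
            cells = [f"{100 * v:.1f}" for v in row]
        else:
            cells = [f"{v:.4f}" for v in row]
        lines.append(labels[a] + "\t" + "\t".join(cells))
    if matrix.empty_colors:
        flagged = ", ".join(labels[a] for a in matrix.empty_colors)
        lines.append(f"# empty assembly (ratios 0 by convention): {flagged}")
    return "\n".join(lines) + "\n"


def write_matrix_tsv(matrix: ExclusivityMatrix, path, percent: bool = False,
                     labels: Sequence[str] = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(format_matrix_tsv(matrix, percent=percent, labels=labels))
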