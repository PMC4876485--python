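"""Synthetic genomes and MDA-biased single-cell read sets.

Multiple displacement amplification (MDA) of a single cell produces
strongly non-uniform coverage with *blackout regions* — stretches of the
genome that receive no reads at all — at loci that vary between cells.
This module emulates exactly those phenomena so that rescue and
exclusivity behaviour are testable end to end:

* per-cell blackout intervals of zero amplification, placed uniformly at
  random and together covering a chosen fraction of the genome;
* window-wise multiplicative amplification gain, lognormal with standard
  deviation ``gain_sigma`` on the log scale (a stand-in with stated
  parameters, not a claim about MDA chemistry);
* single-end reads with optional uniform substitution errors.

Read start positions are drawn proportionally to the amplification weight
at the start position, so no read *starts* inside a blackout, but a read
starting just before one may overhang into it — gaps suppress priming,
not read integrity.  Everything is deterministic under the profile seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Tuple

import numpy as np

from .io_formats import ColorManifest, ReadRecord, write_bed, write_manifest
from .kmer_core import BASES, revcomp

__all__ = [
    "MdaProfile",
    "SimulatedCell",
    "random_genome",
    "simulate_cell",
    "make_replicate_cells",
    "write_cells",
]


@dataclass(frozen=True)
class MdaProfile:
    """Parameters of the synthetic amplification-bias model.

    Defaults describe a plausible bacterial single-cell experiment at
    desk scale: 2% of the genome lost to amplification blackouts spread
    over 4 intervals, e-fold (sigma = 1) window gain dispersion over
    500 bp windows, 50x mean depth of 50 bp error-free single-end reads.
    """

    blackout_fraction: float = 0.02
    num_blackout_intervals: int = 4
    gain_sigma: float = 1.0
    window_bp: int = 500
    mean_depth: float = 50.0
    read_len: int = 50
    error_rate: float = 0.0
    circular: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.blackout_fraction < 1:
            raise ValueError("blackout_fraction must be in [0, 1)")
        if self.num_blackout_intervals < 0:
            raise ValueError("num_blackout_intervals must be >= 0")
        if self.gain_sigma < 0:
            raise ValueError("gain_sigma must be >= 0")
        if self.window_bp < 1:
            raise ValueError("window_bp must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass
class SimulatedCell:
    """One synthetic single-cell read set with its ground truth."""

    genome_id: str
    profile: MdaProfile
    #: per-position amplification weight; exactly 0 inside blackouts
    weight_track: np.ndarray
    reads: List[ReadRecord]
    #: true blackout intervals, 0-based half-open, sorted
    truth: List[Tuple[int, int]]
    #: sampled read start positions (genome coordinates)
    read_starts: np.ndarray

    def coverage_track(self) -> np.ndarray:
        """Realized per-position read depth implied by the sampled starts."""
        L = self.weight_track.size
        rl = self.profile.read_len
        delta = np.zeros(L + 1, dtype=np.int64)
        starts = self.read_starts
        np.add.at(delta, starts, 1)
        if self.profile.circular:
            ends = starts + rl
            wrap = ends > L
            np.add.at(delta, np.minimum(ends, L), -1)
            if wrap.any():
                delta[0] += int(wrap.sum())
                np.add.at(delta, ends[wrap] - L, -1)
        else:
            np.add.at(delta, np.minimum(starts + rl, L), -1)
        return np.cumsum(delta[:-1])


def random_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """I.i.d. random genome with P(G) + P(C) = ``gc``."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    draws = rng.choice(4, size=length, p=p)
    lut = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)
    return lut[draws].tobytes().decode("ascii")


def _place_blackouts(rng: np.random.Generator, L: int, total: int,
                     n_intervals: int) -> List[Tuple[int, int]]:
    """``n_intervals`` non-overlapping intervals of combined length
    ``total``, placed uniformly at random."""
    if n_intervals == 0 or total == 0:
        return []
    if total < n_intervals:
        raise ValueError(
            f"cannot split {total} blackout bp into {n_intervals} intervals"
        )
    if n_intervals == 1:
        lens = np.array([total])
    else:
        cuts = np.sort(rng.choice(np.arange(1, total), size=n_intervals - 1,
                                  replace=False))
        lens = np.diff(np.concatenate(([0], cuts, [total])))
    free = L - total
    if free < 0:
        raise ValueError("blackout total exceeds genome length")
    offsets = np.sort(rng.integers(0, free + 1, size=n_intervals))
    starts = offsets + np.concatenate(([0], np.cumsum(lens[:-1])))
    return [(int(s), int(s + l)) for s, l in zip(starts, lens)]


def simulate_cell(genome: str, profile: MdaProfile,
                  genome_id: str = "cell") -> SimulatedCell:
    """Sample one MDA-amplified single-cell read set from ``genome``."""
    L = len(genome)
    rl = profile.read_len
    if L < rl:
        raise ValueError("genome shorter than read length")
    rng = np.random.default_rng(profile.seed)

    total_blackout = int(profile.blackout_fraction * L)
    truth = _place_blackouts(rng, L, total_blackout,
                             profile.num_blackout_intervals)

    n_windows = -(-L // profile.window_bp)
    gains = np.exp(rng.normal(0.0, profile.gain_sigma, size=n_windows))
    weights = np.repeat(gains, profile.window_bp)[:L]
    for s, e in truth:
        weights[s:e] = 0.0

    n_reads = int(rng.poisson(profile.mean_depth * L / rl))
    p = weights / weights.sum()
    starts = rng.choice(L, size=n_reads, replace=True, p=p)
    neg_strand = rng.random(n_reads) < 0.5

    template = genome + genome[:rl] if profile.circular else genome
    err = profile.error_rate
    reads: List[ReadRecord] = []
    for i, (s, neg) in enumerate(zip(starts.tolist(), neg_strand.tolist())):
        seq = template[s:s + rl]
        if err > 0:
            hits = np.flatnonzero(rng.random(len(seq)) < err)
            if hits.size:
                shift = rng.integers(1, 4, size=hits.size)
                chars = list(seq)
                for pos, sh in zip(hits.tolist(), shift.tolist()):
                    chars[pos] = BASES[(BASES.index(chars[pos]) + sh) % 4]
                seq = "".join(chars)
        if neg:
            seq = revcomp(seq)
        reads.append(ReadRecord(f"{genome_id}_r{i}", seq))

    return SimulatedCell(genome_id, profile, weights, reads, truth, starts)


def make_replicate_cells(genome: str, n_cells: int,
                         profile: MdaProfile) -> List[SimulatedCell]:
    """Biological replicates of one genome: blackout placement and window
    gains drawn independently per cell (seed = profile.seed + index)."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    return [
        simulate_cell(genome, replace(profile, seed=profile.seed + i),
                      genome_id=f"cell{i}")
        for i in range(n_cells)
    ]


def write_cells(cells: List[SimulatedCell], genome: str, outdir,
                fmt: str = "fastq") -> ColorManifest:
    """Write per-cell reads, truth blackout BEDs, the genome, and an
    auto-generated color manifest into ``outdir``."""
    if fmt not in ("fastq", "fasta"):
        raise ValueError("fmt must be 'fastq' or 'fasta'")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.fa", "w") as fh:
        fh.write(">genome\n")
        for i in range(0, len(genome), 80):
            fh.write(genome[i:i + 80] + "\n")
    ext = "fq" if fmt == "fastq" else "fa"
    groups = []
    for cell in cells:
        fname = f"{cell.genome_id}.{ext}"
        with open(outdir / fname, "w") as fh:
            for r in cell.reads:
                if fmt == "fastq":
                    fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r)}\n")
                else:
                    fh.write(f">{r.id}\n{r.sequence}\n")
        write_bed(cell.truth, outdir / f"{cell.genome_id}.blackout.bed",
                  name="genome")
        groups.append((cell.genome_id, [fname]))
    manifest = ColorManifest.from_paths(groups)
    write_manifest(manifest, outdir / "manifest.tsv")
    # re-read so relative paths resolve against the manifest location
    from .io_formats import read_manifest
    return read_manifest(outdir / "manifest.tsv")
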