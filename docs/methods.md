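# Methods

## The colored de Bruijn graph

Each input read set is a *color*. Reads are split on ambiguous bases and
decomposed into overlapping k-mers; a k-mer and its reverse complement are
identified by their *canonical* form (the lexicographically smaller of the
two), and k is forced odd so no k-mer is its own reverse complement. Each
canonical k-mer is one vertex of the graph and carries an integer
multiplicity per color (saturating at 2^32 − 1). An edge between two
vertices exists only if some read *witnesses* it — i.e. contains the two
k-mers consecutively overlapping, recorded as the canonical (k+1)-mer.
Adjacency is never inferred from bare (k−1)-overlap, so two reads that
merely share flanking sequence do not join unless the junction itself was
sequenced. Edge multiplicities are not tracked; multiplicity lives on
vertices only.

Whether the original method uses canonical k-mers or an explicitly
bidirected graph is not documented; the canonical-k-mer convention here is
an implementation choice, standard for de Bruijn assemblers, that makes
"one vertex per k-mer" well defined across strands.

Traversal operates on *oriented* vertices (vertex + strand). For every
witness both the forward arc and its strand-mirrored arc are installed, so
predecessor queries are successor queries on the flipped orientation.
Unitigs — maximal non-branching paths in the color-blind union graph —
partition the vertex set; a walk crosses an arc u → w only when u has
exactly one successor and w exactly one predecessor, and stops when the
next vertex (either strand) is already on the path, which bounds perfect
cycles and palindromic (k+1)-mer turnarounds. Contig sequence is emitted
in canonical orientation (min of sequence and its reverse complement), and
per-color average coverage is the unweighted mean of the constituent
vertex multiplicities — deliberately k-mer-based, not per-base, to match
the vertex bookkeeping. All iteration and output orders are lexicographic
on canonical sequence, so the assembler is bit-reproducible without a seed.

## Cleaning: tips, then progressive trimming

Two cleaning passes run between graph construction and final contig
extraction, in this order:

1. **Tip clipping.** A unitig with exactly one dead end, shorter than
   `tip_len_factor * k` bp (default factor 2), is removed when its maximum
   per-color average coverage is strictly below that of the best competing
   branch at its junction; repeated to a fixpoint. Isolated linear
   components are never tips. Whether the original tool clips tips, and
   its exact cleaning order, is unstated; clip-then-trim is this package's
   choice, ordered so that error spurs do not fragment unitigs before
   coverage is judged.
2. **Progressive coverage trimming.** `trim_steps` thresholds (default 10)
   rise linearly from `cutoff/trim_steps` to `cutoff`; at each step the
   graph is recondensed and every unitig whose **maximum** per-color
   average coverage falls strictly below the threshold is deleted. The
   gradual schedule follows the single-cell assembler lineage this method
   descends from, which the source describes only as a coverage cutoff
   (published value: 100 at lane depth ~600x); the linear 10-step ramp is
   this package's concretization. Judging on the max over colors — rather
   than the sum — is also a design choice: it is the mechanism that
   realizes rescue (one well-covered color saves the region) while
   preventing many weak colors from pooling into fake strength.

A contig is *present* in a color when its average coverage there strictly
exceeds `presence_epsilon` (default 0, i.e. any non-zero coverage). The
per-color assembly is the set of contigs present in that color.

## Comparison without alignment

Because all colors share one union graph, any sequence of length ≥ k that
two colors share is already embedded in common unitigs. Shared/exclusive
decomposition therefore works at whole-contig granularity on the presence
sets; no alignment is needed. The exclusivity ratio r(i|j) =
exclusive_bp(i,j) / total_bp(i) is computed at full floating precision and
only rounded in reports (TSV output uses 4 decimals); the source tables
mix 3- and 4-decimal rounding whose convention is ambiguous, so the
artifact never truncates internally. A color whose filtered assembly is
empty gets ratio 0 by convention and is flagged in the matrix report.

## Iterative multi-k mode (off by default)

`iterative_assemble` runs the pipeline at an ascending odd k-list; after
each round the contigs are injected as multiplicity-1 pseudo-reads into
every color in which they were present before recounting at the next k,
letting the larger k resolve repeats between the two k's. The headline
coassembly results use a single k, matching the published runs (which
state that variable k-mer sizes are *not* used although the algorithm
supports the adaptation); the mode exists for completeness and is
exercised by the tests.

## The MDA-bias simulator

`simulate_cell` emulates the two coverage pathologies of MDA-amplified
single cells, with a parametric form chosen for testability rather than as
a chemical model:

* **Blackouts:** `num_blackout_intervals` non-overlapping intervals
  (default 4) whose lengths are a uniform random composition of
  ⌊`blackout_fraction` · L⌋ bp (default 2%), placed uniformly. Read
  *starts* never fall inside a blackout, but a read starting just before
  one may overhang into it — amplification gaps suppress priming, not
  read integrity — so the realized zero-coverage span of an interval
  shrinks by up to `read_len` bp at its upstream edge.
* **Gain dispersion:** each `window_bp` window (default 500 bp) gets an
  amplification weight exp(N(0, σ²)) with σ = `gain_sigma` (default 1,
  i.e. e-fold typical swings); read starts are sampled proportionally.
  Coverage burstiness (coefficient of variation) increases monotonically
  with σ, mirroring the single-cell vs multicell contrast qualitatively.

Read count is Poisson with mean `mean_depth · L / read_len` (defaults 50x,
50 bp single-end), strand uniform, substitutions uniform at `error_rate`
(default 0 — the published headline runs involve no error correction, so
the reference conditions are error-free). Everything derives from one
generator seeded by the profile; replicate cells use seed + cell index.

What the simulator does **not** model: chimeric reads, paired ends, insert
sizes, quality values, GC-dependent bias, or any deterministic preference
of MDA for particular loci. Passing tests therefore demonstrate the graph
machinery and the rescue/separation logic under idealized dropout and
gain noise, not performance on real amplification artifacts.

## Evaluation metrics

N50 is the largest L such that contigs of length ≥ L sum to at least half
the assembly total (NG50: half the genome size; reported as absent, never
0, when unreachable). Reference completeness is measured alignment-free:
a reference position is *covered* when at least one k-window containing it
has its canonical k-mer present in the assembly; "missing bases" is the
complement. This surrogate is monotone in true completeness and exact for
perfect assemblies, but it widens each true gap by up to k−1 bp per edge
and ignores alignment-level error classes (SNPs, indels, relocations), so
it is not exchangeable with alignment-based evaluation pipelines.
Blackout quantification reports maximal runs of depth ≤ threshold as
0-based half-open intervals.

## Scale and determinism of the shipped experiments

The end-to-end experiments in the test suite run at desk scale, chosen as
the smallest sizes at which the phenomena are unambiguous: rescue uses a
100 kb genome, two cells, 2% blackouts, 50x depth, k = 25, cutoff 5 (the
published cutoff of 100 presumes ~600x lanes; 5 keeps the same
cutoff-to-depth ratio at 50x); exclusivity separation uses two 50 kb
genomes and three cells; oracle equivalence uses fifty ≤ 2 kb genomes at
k ∈ {7, 15}. The rescue experiment sets σ = 0 so that the measured
missing-base contrast isolates blackout dropout, the mechanism under
test; gain dispersion has its own calibration checks. Seeds are fixed
constants (0, or small enumerations) throughout; every stochastic claim is
a property of the seeded run, and the pipeline itself is deterministic, so
all test outputs are byte-stable.

## Known limitations

* No error correction, bubble popping, scaffolding, or paired-end use —
  deliberately, matching the scope of the method's headline results.
* Whole-contig comparison granularity means a long contig spanning a
  region absent from one color still counts as shared there if any of its
  k-mers are covered; sub-contig decomposition would need coverage-aware
  contig splitting.
* k ≤ 31 (64-bit 2-bit packing); counting is in-memory, suitable for
  microbial genomes, not metagenome-scale inputs.
* The coverage-track tooling evaluates simulated (intended) coverage; no
  read mapper is embedded, so real-data coverage tracks must come from an
  external aligner.
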