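"""Graph construction, cleaning, contig extraction and orchestration."""

import pytest

from conftest import oracle_unitigs, tiling_reads
from coasm.graph import (
    assemble_reads,
    build_graph,
    clip_tips,
    condense,
    iterative_assemble_reads,
    trim_low_coverage,
)
from coasm.kmer_core import AssemblyConfig, KmerTable, revcomp
from coasm.simulate import random_genome


def table_from(reads, k, m=1, color=0):
    t = KmerTable(k, m)
    if isinstance(reads, dict):
        for c, rs in reads.items():
            t.count_reads(rs, c)
    else:
        t.count_reads(reads, color)
    return t


def cfg(**kw):
    kw.setdefault("k", 3)
    kw.setdefault("coverage_cutoff", 0.0)
    kw.setdefault("min_contig_len", 1)
    return AssemblyConfig(**kw)


class TestBuildGraph:
    def test_palindromic_witness_collapses_to_self_adjacency(self):
        # ACG and CGT are one canonical vertex; the ACGT witness becomes a
        # strand-flip self-connection and the unitig stops at one k-mer
        g = build_graph(table_from(["ACGT"], 3))
        assert len(g) == 1
        contigs = condense(g)
        assert [c.sequence for c in contigs] == ["ACG"]

    def test_empty_table_gives_empty_graph(self):
        g = build_graph(KmerTable(3, 1))
        assert len(g) == 0
        assert condense(g) == []

    def test_no_edge_without_witness(self):
        # two reads sharing a 2-mer overlap but never seen consecutively
        t = table_from(["AAC", "ACA"], 3)
        g = build_graph(t)
        assert len(g) == 2
        assert len(condense(g)) == 2  # no join without a 4-mer witness


class TestCondense:
    def test_linear_chain_is_one_unitig(self):
        # all five canonical 3-mers of AACCGCT are distinct
        (c,) = condense(build_graph(table_from(["AACCGCT"], 3)))
        assert c.sequence == "AACCGCT"
        assert c.kmer_count == 5
        assert c.avg_coverage.tolist() == [1.0]

    def test_branching_node_terminates_unitigs(self):
        # junction at CCG: continuations CGC (chain) and CGA (spur)
        contigs = condense(build_graph(table_from(["AACCGCT", "CCGA"], 3)))
        assert len(contigs) > 1
        all_kmers = sum(c.kmer_count for c in contigs)
        assert all_kmers == 6  # partition of the vertex set

    def test_repeat_free_genome_reconstructs_exactly(self):
        k = 15
        for seed in range(10):
            genome = random_genome(300, seed=seed)
            kmers = [genome[i:i + k - 1] for i in range(len(genome) - k + 2)]
            both = kmers + [revcomp(x) for x in kmers]
            if len(set(both)) == len(both):  # verified repeat-free
                break
        else:
            pytest.fail("no repeat-free genome found")
        (c,) = condense(build_graph(table_from([genome], k)))
        assert c.sequence in (genome, revcomp(genome))

    @pytest.mark.parametrize("k", [7, 15])
    def test_matches_brute_force_oracle_on_random_genomes(self, k):
        for i in range(10):
            genome = random_genome(500 + 137 * i, seed=50 + i)
            reads = tiling_reads(genome)
            got = {c.sequence for c in condense(build_graph(table_from(reads, k)))}
            assert got == oracle_unitigs(reads, k)


class TestClipTips:
    def make_spur_graph(self, main_mult=(200, 150), spur_mult=(1, 0)):
        # main chain long enough (> tip_len_factor * k on both sides of the
        # junction) that only the 1-node spur CGA is a clippable tip
        t = KmerTable(3, 2)
        for color, n in enumerate(main_mult):
            t.count_reads(["AACCGCTTG"] * n, color)
        for color, n in enumerate(spur_mult):
            t.count_reads(["CCGA"] * n, color)
        return build_graph(t)

    def test_dominated_short_spur_removed(self):
        g = self.make_spur_graph()
        clip_tips(g, cfg())
        (c,) = condense(g)
        assert c.sequence == "AACCGCTTG"

    def test_spur_stronger_than_through_path_retained(self):
        g = self.make_spur_graph(main_mult=(5, 0), spur_mult=(300, 0))
        before = len(g)
        clip_tips(g, cfg())
        assert len(g) == before

    def test_isolated_linear_component_never_clipped(self):
        t = KmerTable(3, 2)
        t.count_reads(["AACCGCT"] * 200, 0)
        t.count_reads(["TGGA"], 0)  # isolated, weak, short: both ends dead
        g = build_graph(t)
        clip_tips(g, cfg())
        seqs = {c.sequence for c in condense(g)}
        assert any(s in ("TGGA", revcomp("TGGA")) for s in seqs)


class TestTrimLowCoverage:
    def two_component_graph(self):
        # component A: coverage (150, 0); component B: coverage (50, 40)
        t = KmerTable(3, 2)
        t.count_reads(["AACCGCT"] * 150, 0)
        t.count_reads(["TGGAG"] * 50, 0)
        t.count_reads(["TGGAG"] * 40, 1)
        return build_graph(t)

    def test_strong_in_one_color_survives_weak_in_all_removed(self):
        g = self.two_component_graph()
        trim_low_coverage(g, cfg(coverage_cutoff=100.0))
        (c,) = condense(g)
        assert c.sequence == "AACCGCT"
        assert c.avg_coverage.tolist() == [150.0, 0.0]

    def test_cutoff_zero_leaves_graph_unchanged(self):
        g = self.two_component_graph()
        before = len(g)
        trim_low_coverage(g, cfg(coverage_cutoff=0.0))
        assert len(g) == before


class TestAssemble:
    def test_single_color_tiling_reads_reconstruct_genome(self):
        genome = random_genome(400, seed=3)
        contigs = assemble_reads([tiling_reads(genome)],
                                 cfg(k=15, min_contig_len=100))
        assert len(contigs) == 1
        assert contigs[0].sequence in (genome, revcomp(genome))

    def test_empty_second_color_changes_no_sequences(self):
        genome = random_genome(400, seed=4)
        reads = tiling_reads(genome)
        solo = assemble_reads([reads], cfg(k=15))
        duo = assemble_reads([reads, []], cfg(k=15))
        assert [c.sequence for c in solo] == [c.sequence for c in duo]
        for c in duo:
            assert c.avg_coverage[1] == 0.0

    def test_color_permutation_equivariance(self):
        genome = random_genome(600, seed=5)
        r0 = tiling_reads(genome, read_len=60, step=20)
        r1 = tiling_reads(genome, read_len=60, step=30)
        a = assemble_reads([r0, r1], cfg(k=15))
        b = assemble_reads([r1, r0], cfg(k=15))
        assert [c.sequence for c in a] == [c.sequence for c in b]
        for ca, cb in zip(a, b):
            assert ca.avg_coverage.tolist() == cb.avg_coverage[::-1].tolist()

    def test_determinism_across_runs(self, tmp_path):
        from coasm.io_formats import write_contigs

        genome = random_genome(800, seed=6)
        reads = tiling_reads(genome)
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_contigs(assemble_reads([reads], cfg(k=15)), p1)
        write_contigs(assemble_reads([reads], cfg(k=15)), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_kmer_content_monotone_when_adding_a_color(self):
        """Adding a color never loses surviving sequence (its max-over-colors
        coverage can only rise); assembled k-mer content only grows."""
        from coasm.stats_eval import reference_kmer_eval

        genome = random_genome(2000, seed=7)
        half1 = tiling_reads(genome[:1200]) * 6
        half2 = tiling_reads(genome[800:]) * 6
        c1 = assemble_reads([half1], cfg(k=15, coverage_cutoff=3))
        c2 = assemble_reads([half1, half2], cfg(k=15, coverage_cutoff=3))
        ev = reference_kmer_eval([c.sequence for c in c2],
                                 "N".join(c.sequence for c in c1), 15)
        assert ev.missing_kmers == 0


class TestIterativeAssemble:
    def repeat_genome(self):
        """A + R + B + R + C with an exact 18 bp repeat R: unresolvable at
        k=15, resolvable at k=25."""
        for seed in range(40):
            g = random_genome(220, seed=800 + seed)
            repeat = random_genome(18, seed=900 + seed)
            genome = g[:60] + repeat + g[60:120] + repeat + g[120:180]
            k = 25
            kmers = [genome[i:i + k - 1] for i in range(len(genome) - k + 2)]
            both = kmers + [revcomp(x) for x in kmers]
            if len(set(both)) == len(both):
                return genome
        pytest.fail("could not construct a clean repeat genome")

    def test_single_round_identity(self):
        genome = random_genome(400, seed=9)
        reads = tiling_reads(genome)
        direct = assemble_reads([reads], cfg(k=15))
        single = iterative_assemble_reads([reads], [15], cfg(k=15))
        assert [c.sequence for c in direct] == [c.sequence for c in single]

    def test_repeat_resolved_by_second_k(self):
        genome = self.repeat_genome()
        reads = tiling_reads(genome, read_len=30, step=3)
        small_k = assemble_reads([reads], cfg(k=15))
        assert len(small_k) >= 3  # repeat shatters the assembly
        final = iterative_assemble_reads([reads], [15, 25], cfg(k=15))
        assert len(final) == 1
        assert final[0].sequence in (genome, revcomp(genome))

    def test_injection_respects_color_presence(self):
        genome = random_genome(400, seed=11)
        reads = tiling_reads(genome, read_len=30, step=5)
        contigs = iterative_assemble_reads([reads, []], [15, 25], cfg(k=15))
        for c in contigs:
            assert c.avg_coverage[1] == 0.0

    def test_oversized_k_warns(self):
        genome = random_genome(400, seed=12)
        reads = tiling_reads(genome, read_len=30, step=5)
        with pytest.warns(UserWarning, match="shortest read"):
            iterative_assemble_reads([reads], [15, 31], cfg(k=15))

    def test_nonascending_k_list_rejected(self):
        with pytest.raises(ValueError):
            iterative_assemble_reads([["ACGT"]], [15, 15], cfg(k=15))
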