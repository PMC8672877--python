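import numpy as np
import pandas as pd
import pytest

from _oracles import oracle_decompose
from gat import synteny
from gat.atrich import AtRichBlock
from gat.genome_io import Chromosome, GeneModel, Genome, Interval
from gat.synteny import (
    Breakpoint,
    OrthologPair,
    breakpoint_atblock_association,
    build_synteny_blocks,
    find_breakpoints,
    ortholog_conservation_summary,
)


def _gene_row(chrom, n, prefix):
    return [
        GeneModel(f"{prefix}{i}", chrom, i * 1_000, i * 1_000 + 500)
        for i in range(n)
    ]


def _pair_fixture(perm, chrom_a="a1", chrom_b="b1"):
    """Genome A genes in order 0..n-1; genome B gene of pair i at rank perm[i]."""
    n = len(perm)
    genes_a = _gene_row(chrom_a, n, "A")
    genes_b = [
        GeneModel(f"B{i}", chrom_b, perm[i] * 1_000, perm[i] * 1_000 + 500)
        for i in range(n)
    ]
    pairs = [OrthologPair(f"A{i}", f"B{i}") for i in range(n)]
    return pairs, genes_a, genes_b


class TestBuildSyntenyBlocks:
    def test_identity_map_single_same_block(self):
        pairs, ga, gb = _pair_fixture(list(range(10)))
        blocks = build_synteny_blocks(pairs, ga, gb)
        assert len(blocks) == 1
        assert blocks[0].n_pairs == 10
        assert blocks[0].orientation == "same"

    def test_internal_inversion_three_blocks(self):
        # ranks 4-7 (1-based) reversed in genome B; adjacent-rank chaining
        perm = [0, 1, 2, 6, 5, 4, 3, 7, 8, 9]
        pairs, ga, gb = _pair_fixture(perm)
        blocks = build_synteny_blocks(pairs, ga, gb, max_gene_gap=1)
        assert [(b.n_pairs, b.orientation) for b in blocks] == [
            (4, "inverted"),
            (3, "same"),
            (3, "same"),
        ] or [(b.n_pairs, b.orientation) for b in sorted(blocks, key=lambda b: b.span_a.start)] == [
            (3, "same"),
            (4, "inverted"),
            (3, "same"),
        ]
        bps = find_breakpoints(blocks, ga, gb)
        assert sum(1 for b in bps if b.genome == "A") == 2
        assert sum(1 for b in bps if b.genome == "B") == 2

    def test_empty_pairs(self):
        _, ga, gb = _pair_fixture([0, 1, 2])
        assert build_synteny_blocks([], ga, gb) == []

    def test_duplicated_gene_rejected(self):
        pairs, ga, gb = _pair_fixture([0, 1, 2])
        with pytest.raises(ValueError, match="duplicated"):
            build_synteny_blocks(pairs + [OrthologPair("A0", "B2x")], ga, gb)

    def test_blocks_rank_monotone_and_pairwise_disjoint(self):
        rng = np.random.default_rng(5)
        perm = rng.permutation(20).tolist()
        pairs, ga, gb = _pair_fixture(perm)
        blocks = build_synteny_blocks(pairs, ga, gb, min_block_genes=2)
        seen = set()
        for blk in blocks:
            ids = [p.gene_a for p in blk.pairs]
            assert not (set(ids) & seen)
            seen |= set(ids)
            ra = [int(p.gene_a[1:]) for p in blk.pairs]
            rb = [perm[i] for i in ra]
            assert ra == sorted(ra)
            assert rb == sorted(rb) or rb == sorted(rb, reverse=True)

    def test_agrees_with_exhaustive_oracle(self):
        """Longest-chain-first decomposition equals brute-force enumeration
        on random permutations (scaled-down acceptance property)."""
        rng = np.random.default_rng(11)
        for trial in range(40):
            n = int(rng.integers(4, 13))
            perm = rng.permutation(n).tolist()
            max_gap = int(rng.integers(1, 5))
            min_block = int(rng.integers(1, 4))
            pairs, ga, gb = _pair_fixture(perm)
            blocks = build_synteny_blocks(
                pairs, ga, gb, min_block_genes=min_block, max_gene_gap=max_gap
            )
            got = [
                tuple((int(p.gene_a[1:]), perm[int(p.gene_a[1:])]) for p in b.pairs)
                for b in blocks
            ]
            ranks = [(i, perm[i]) for i in range(n)]
            expected = oracle_decompose(ranks, max_gap, min_block)
            assert sorted(got) == sorted(expected), f"trial {trial}: perm={perm}"


class TestFindBreakpoints:
    def test_single_block_no_breakpoints(self):
        pairs, ga, gb = _pair_fixture(list(range(5)))
        blocks = build_synteny_blocks(pairs, ga, gb)
        assert find_breakpoints(blocks, ga, gb) == []

    def test_breakpoint_interval_spans_flanking_genes(self):
        perm = [0, 1, 2, 6, 5, 4, 3, 7, 8, 9]
        pairs, ga, gb = _pair_fixture(perm)
        blocks = build_synteny_blocks(pairs, ga, gb, max_gene_gap=1)
        bps = [b for b in find_breakpoints(blocks, ga, gb) if b.genome == "A"]
        spans = sorted((b.start, b.end) for b in bps)
        # gene i occupies [i*1000, i*1000+500): boundaries at ranks 2|3 and 6|7
        assert spans == [(2_500, 3_000), (6_500, 7_000)]

    def test_abutting_blocks_give_zero_length_breakpoint(self):
        # two inversions meeting head-to-head: B ranks [2,1,0,5,4,3]
        perm = [2, 1, 0, 5, 4, 3]
        pairs, ga, gb = _pair_fixture(perm)
        blocks = build_synteny_blocks(pairs, ga, gb, max_gene_gap=1)
        assert len(blocks) == 2
        bps = find_breakpoints(blocks, ga, gb)
        a_side = [b for b in bps if b.genome == "A"]
        assert len(a_side) == 1 and a_side[0].length == 500  # gap between g2,g3
        b_side = [b for b in bps if b.genome == "B"]
        assert len(b_side) == 1


class TestAssociation:
    def _genome(self, length=1_000_000):
        return Genome([Chromosome("c1", "A" * length)])

    def _blocks(self, spans):
        return [AtRichBlock(Interval("c1", s, e), 30.0) for s, e in spans]

    def test_saturating_blocks_give_p_one(self):
        genome = self._genome(10_000)
        blocks = self._blocks([(0, 10_000)])
        bps = [Breakpoint("A", "c1", 2_000, 2_100), Breakpoint("A", "c1", 7_000, 7_050)]
        res = breakpoint_atblock_association(bps, blocks, genome, n_perm=200, seed=1)
        assert res.observed_fraction == 1.0
        assert res.empirical_p == 1.0

    def test_reproducible_and_order_invariant(self):
        genome = self._genome(100_000)
        blocks = self._blocks([(10_000, 12_000), (50_000, 53_000)])
        bps = [
            Breakpoint("A", "c1", 10_500, 10_600),
            Breakpoint("A", "c1", 90_000, 90_200),
            Breakpoint("A", "c1", 51_000, 51_100),
        ]
        r1 = breakpoint_atblock_association(bps, blocks, genome, n_perm=300, seed=9)
        r2 = breakpoint_atblock_association(bps, blocks, genome, n_perm=300, seed=9)
        r3 = breakpoint_atblock_association(
            list(reversed(bps)), blocks, genome, n_perm=300, seed=9
        )
        assert r1 == r2 == r3

    def test_zero_breakpoints_rejected(self):
        with pytest.raises(ValueError, match="no breakpoints"):
            breakpoint_atblock_association([], [], self._genome(), n_perm=200)

    def test_zero_length_breakpoints_widened(self):
        genome = self._genome(100_000)
        blocks = self._blocks([(10_000, 12_000)])
        bp = [Breakpoint("A", "c1", 12_500, 12_500)]  # 500 bp from the block
        res = breakpoint_atblock_association(
            bp, blocks, genome, n_perm=200, seed=2, widen_zero_length=1_000
        )
        assert res.observed_fraction == 1.0
        res = breakpoint_atblock_association(
            bp, blocks, genome, n_perm=200, seed=2, widen_zero_length=100
        )
        assert res.observed_fraction == 0.0


class TestConservation:
    def test_published_fractions(self):
        presence = pd.DataFrame(
            {"other": [True] * 190 + [False] * 175},
            index=[f"g{i}" for i in range(365)],
        )
        assert ortholog_conservation_summary(
            [f"g{i}" for i in range(365)], presence
        ) == (190, 52)

    def test_multi_genome_all_required(self):
        presence = pd.DataFrame(
            {
                "g1": [True, True, False],
                "g2": [True, False, True],
            },
            index=["a", "b", "c"],
        )
        assert ortholog_conservation_summary(["a", "b", "c"], presence) == (1, 33)

    def test_zero_conserved(self):
        presence = pd.DataFrame(
            {"other": [False] * 10}, index=[f"g{i}" for i in range(10)]
        )
        assert ortholog_conservation_summary(
            [f"g{i}" for i in range(10)], presence
        ) == (0, 0)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            ortholog_conservation_summary([], pd.DataFrame({"x": []}))
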