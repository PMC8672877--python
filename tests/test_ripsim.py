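import numpy as np
import pytest

from gat import atrich, ripsim, synteny
from gat.ripsim import (
    ClusterSpec,
    SimConfig,
    rip_eligible_sites,
    rip_mutate,
    simulate_genome,
    simulate_rearranged_pair,
)


class TestRipMutate:
    def test_rate_zero_is_identity(self, rng):
        seq = ripsim.random_sequence(rng, 5_000, 50.0)
        assert rip_mutate(seq, 0.0, rng) == seq

    def test_rate_one_saturates_cpa_sites(self, rng):
        assert rip_mutate("CACACA", 1.0, rng) == "TATATA"

    def test_complementary_strand_tpg_converts_g_to_a(self, rng):
        # TG on the forward strand is CA on the complement
        assert rip_mutate("TGTGTG", 1.0, rng) == "TATATA"

    def test_non_context_bases_untouched(self, rng):
        seq = ripsim.random_sequence(rng, 5_000, 50.0)
        out = rip_mutate(seq, 1.0, rng)
        assert len(out) == len(seq)
        for i, (a, b) in enumerate(zip(seq, out)):
            if a == b:
                continue
            if a == "C":
                assert b == "T" and seq[i + 1] == "A"
            else:
                assert a == "G" and b == "A" and seq[i - 1] == "T"

    def test_context_free_mode_hits_every_c_and_g(self, rng):
        out = rip_mutate("CCGG", 1.0, rng, context_free=True)
        assert out == "TTAA"

    def test_conversion_fraction_matches_binomial_mean(self):
        """Scaled-down version of the acceptance-scale calibration: mean
        converted fraction over replicates sits within 3 SE of the rate."""
        rng = np.random.default_rng(42)
        seq = ripsim.random_sequence(rng, 5_000, 50.0)
        n_sites = rip_eligible_sites(seq)
        reps = 200
        converted = 0
        for _ in range(reps):
            out = rip_mutate(seq, 0.5, rng)
            converted += sum(1 for a, b in zip(seq, out) if a != b)
        frac = converted / (reps * n_sites)
        se = (0.25 / (reps * n_sites)) ** 0.5
        assert abs(frac - 0.5) <= 3 * se

    def test_gc_monotone_in_rate_with_common_seed(self, rng):
        seq = ripsim.random_sequence(rng, 10_000, 45.0)
        gcs = []
        for rate in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            out = rip_mutate(seq, rate, np.random.default_rng(99))
            gcs.append(atrich.gc_percent(out))
        assert gcs == sorted(gcs, reverse=True)

    def test_rate_validation(self, rng):
        with pytest.raises(ValueError):
            rip_mutate("ACGT", 1.5, rng)


class TestSimulateGenome:
    def test_deterministic_under_seed(self):
        a = simulate_genome(SimConfig(seed=7))
        b = simulate_genome(SimConfig(seed=7))
        assert [c.sequence for c in a.genome] == [c.sequence for c in b.genome]
        assert a.genes == b.genes
        assert a.features.equals(b.features)
        assert a.mitogenome.sequence == b.mitogenome.sequence
        assert a.truth.at_blocks == b.truth.at_blocks

    def test_bookkeeping_three_chromosomes(self, sim_default):
        res = sim_default
        assert res.genome.total_length == 3 * 200_000
        assert len(res.truth.centromeres) == 3
        assert len(res.genes) == 150
        assert set(res.features["gene_id"]) == {g.gene_id for g in res.genes}

    def test_relic_gc_below_ceiling(self, sim_default):
        res = sim_default
        ctx = atrich.compute_gc_context(res.genome, genes=res.genes)
        ceiling = atrich.gc_ceiling(ctx)
        assert all(gc < ceiling for gc in res.truth.relic_gc.values())

    def test_planted_features_inside_bounds(self, sim_default):
        res = sim_default
        for iv in res.truth.at_blocks:
            assert 0 <= iv.start < iv.end <= res.genome[iv.chromosome].length
        for n in res.truth.numts:
            relics = [
                iv for iv in res.truth.at_blocks if iv.contains(n["nuclear"])
            ]
            assert relics, "NUMT must sit inside a planted relic"
            frag = res.genome[n["chromosome"]].sequence[
                n["nuclear"].start : n["nuclear"].end
            ]
            assert frag == res.mitogenome.sequence[n["mito_start"] : n["mito_end"]]

    def test_infeasible_packing_rejected_before_output(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_genome(SimConfig(chromosome_length=30_000, seed=0))

    def test_cluster_spec_validation(self):
        with pytest.raises(ValueError):
            ClusterSpec(1, 2, (0, 0))
        with pytest.raises(ValueError):
            ClusterSpec(3, 0, (1,))


class TestSimulatedPair:
    def test_empty_script_identity(self):
        pair = simulate_rearranged_pair(SimConfig(seed=2), script=[])
        assert [c.sequence for c in pair.genome_b] == [
            c.sequence for c in pair.a.genome
        ]
        blocks = synteny.build_synteny_blocks(
            pair.ortholog_pairs, pair.a.genes, pair.genes_b
        )
        assert len(blocks) == 3  # one block per chromosome
        assert synteny.find_breakpoints(blocks, pair.a.genes, pair.genes_b) == []

    def test_single_inversion_two_breakpoints_recovered(self):
        cfg = SimConfig(seed=4)
        base = simulate_genome(cfg)
        relics = [
            iv
            for iv in base.truth.at_blocks
            if iv.chromosome == "chr1"
            and iv != base.truth.centromeres["chr1"]["block"]
        ]
        cut1 = (relics[1].start + relics[1].end) // 2
        cut2 = (relics[-2].start + relics[-2].end) // 2
        pair = simulate_rearranged_pair(
            cfg, script=[("inversion", "chr1", cut1, cut2)]
        )
        truth = [
            (t["chromosome"], t["position"])
            for t in pair.breakpoints
            if t["genome"] == "A"
        ]
        assert len(truth) == 2
        blocks = synteny.build_synteny_blocks(
            pair.ortholog_pairs, pair.a.genes, pair.genes_b
        )
        bps = [
            b
            for b in synteny.find_breakpoints(blocks, pair.a.genes, pair.genes_b)
            if b.genome == "A"
        ]
        gene_spacing = 4_000  # ~ one gene plus its spacer at default density
        for chrom, pos in truth:
            assert any(
                b.chromosome == chrom
                and b.start - gene_spacing <= pos <= b.end + gene_spacing
                for b in bps
            )

    def test_translocation_swaps_tails_and_remaps_genes(self):
        cfg = SimConfig(seed=6)
        base = simulate_genome(cfg)
        # cut both chromosomes in their centromeric deserts (gene-free)
        p1 = base.truth.centromeres["chr1"]["desert"].start + 1_000
        p2 = base.truth.centromeres["chr2"]["desert"].start + 1_000
        pair = simulate_rearranged_pair(
            cfg, script=[("translocation", "chr1", p1, "chr2", p2)]
        )
        a1 = pair.a.genome["chr1"].sequence
        a2 = pair.a.genome["chr2"].sequence
        b1 = pair.genome_b["chr1"].sequence
        b2 = pair.genome_b["chr2"].sequence
        assert b1 == a1[:p1] + a2[p2:]
        assert b2 == a2[:p2] + a1[p1:]
        for g in pair.genes_b:
            seq = pair.genome_b[g.chromosome].sequence[g.start : g.end]
            orig = next(x for x in pair.a.genes if x.gene_id == g.gene_id)
            assert seq == pair.a.genome[orig.chromosome].sequence[
                orig.start : orig.end
            ]

    def test_cut_inside_gene_rejected(self):
        cfg = SimConfig(seed=2)
        base = simulate_genome(cfg)
        gene = base.genes[10]
        mid = (gene.start + gene.end) // 2
        with pytest.raises(ValueError, match="inside gene"):
            simulate_rearranged_pair(
                cfg, script=[("inversion", gene.chromosome, mid, mid + 50_000)]
            )

    def test_overlapping_script_segments_rejected(self):
        cfg = SimConfig(seed=2)
        base = simulate_genome(cfg)
        d = base.truth.centromeres["chr1"]["desert"]
        with pytest.raises(ValueError, match="overlapping"):
            simulate_rearranged_pair(
                cfg,
                script=[
                    ("inversion", "chr1", d.start + 100, d.start + 5_000),
                    ("inversion", "chr1", d.start + 2_000, d.start + 9_000),
                ],
            )
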