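"""LD statistics, pruning, EM haplotype frequencies, D' CIs and blocks."""

import numpy as np
import pandas as pd
import pytest

from keelgen.dataio import GenotypeMatrix
from keelgen.ldblocks import (
    HaplotypeBlock,
    assign_hits_to_blocks,
    dprime_ci,
    em_haplotype_freqs,
    find_blocks,
    genotype_r2,
    ld_prune,
)
from tests.conftest import random_genotype_matrix


def haplo_genotypes(rng, freqs, n):
    """Genotypes for 2 SNPs from known haplotype freqs (AB, Ab, aB, ab)."""
    haps = rng.choice(4, size=(n, 2), p=freqs)
    carries_A = np.isin(haps, (0, 1)).sum(axis=1).astype(float)
    carries_B = np.isin(haps, (0, 2)).sum(axis=1).astype(float)
    return carries_A, carries_B


def geno_with_positions(dosages, positions, chrom="1"):
    n, m = dosages.shape
    return GenotypeMatrix(
        dosages=dosages.astype(float),
        snp_info=pd.DataFrame(
            {"snp_id": [f"s{j}" for j in range(m)], "chrom": [chrom] * m,
             "pos": positions, "allele1": ["A"] * m, "allele2": ["B"] * m}
        ),
        sample_ids=[f"i{k}" for k in range(n)],
    )


class TestGenotypeR2:
    def test_identical_vectors(self):
        g = np.array([0, 1, 2, 1, 0, 2, 1, 0, 2, 1], dtype=float)
        assert genotype_r2(g, g) == pytest.approx(1.0)

    def test_allele_flip_invariance(self):
        g = np.array([0, 1, 2, 1, 0, 2, 1, 0, 2, 1], dtype=float)
        assert genotype_r2(g, 2 - g) == pytest.approx(1.0)
        rng = np.random.default_rng(0)
        h = rng.integers(0, 3, 50).astype(float)
        g2 = rng.integers(0, 3, 50).astype(float)
        assert genotype_r2(g2, h) == pytest.approx(genotype_r2(h, g2))
        assert genotype_r2(2 - g2, h) == pytest.approx(genotype_r2(g2, h))

    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.binomial(2, 0.4, 10_000).astype(float)
        b = rng.binomial(2, 0.6, 10_000).astype(float)
        assert genotype_r2(a, b) < 0.01

    def test_monomorphic_returns_nan(self):
        a = np.ones(20)
        b = np.arange(20) % 3.0
        assert np.isnan(genotype_r2(a, b))


class TestLdPrune:
    def test_perfect_ld_pair_keeps_one(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.5, 100).astype(float)
        geno = geno_with_positions(np.column_stack([g, g]), [1000, 2000])
        assert len(ld_prune(geno)) == 1

    def test_distant_pair_outside_window_kept(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.5, 100).astype(float)
        geno = geno_with_positions(np.column_stack([g, g]), [1000, 601_000])
        assert len(ld_prune(geno, window_kb=500)) == 2

    def test_retained_set_passes_brute_force_audit(self):
        rng = np.random.default_rng(4)
        base = rng.binomial(2, 0.5, size=(200, 12)).astype(float)
        # overlay heavy correlation among neighbours
        for j in range(1, 12):
            copy_from = rng.random(200) < 0.8
            base[copy_from, j] = base[copy_from, j - 1]
        pos = np.arange(12) * 40_000 + 1
        geno = geno_with_positions(base, pos)
        kept = set(ld_prune(geno, window_kb=500, step_snps=3, r2_max=0.2))
        idx = [j for j in range(12) if f"s{j}" in kept]
        for a_i, i in enumerate(idx):
            for j in idx[a_i + 1:]:
                if pos[j] - pos[i] <= 500_000:
                    r2 = genotype_r2(geno.dosages[:, i], geno.dosages[:, j])
                    assert not (np.isfinite(r2) and r2 > 0.2)

    def test_deterministic(self, small_cohort):
        geno = small_cohort[0]
        assert ld_prune(geno) == ld_prune(geno)


class TestEmHaplotypeFreqs:
    def test_no_double_hets_equals_direct_count(self):
        # genotypes chosen so no individual is het at both SNPs
        a = np.array([0, 0, 2, 2, 1, 1, 0, 2, 0, 2], dtype=float)
        b = np.array([0, 2, 0, 2, 0, 2, 1, 1, 0, 2], dtype=float)
        h, conv = em_haplotype_freqs(a, b)
        assert conv
        # direct haplotype count: each individual's phase is determined
        counts = np.zeros(4)
        for ga, gb in zip(a.astype(int), b.astype(int)):
            aa = [1] * ga + [0] * (2 - ga)
            bb = [1] * gb + [0] * (2 - gb)
            for x, y in zip(aa, bb):
                counts[{(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(x, y)]] += 1
        np.testing.assert_allclose(h, counts / counts.sum(), atol=1e-10)

    def test_complete_coupling(self):
        a = np.array([0.0] * 25 + [2.0] * 25)
        h, _ = em_haplotype_freqs(a, a)
        assert h[0] + h[3] == pytest.approx(1.0, abs=1e-9)
        lp = dprime_ci(a, a)
        assert lp.dprime == pytest.approx(1.0, abs=1e-9)

    def test_recovers_known_frequencies(self):
        rng = np.random.default_rng(5)
        truth = np.array([0.4, 0.3, 0.2, 0.1])
        a, b = haplo_genotypes(rng, truth, 5000)
        h, conv = em_haplotype_freqs(a, b)
        assert conv
        np.testing.assert_allclose(h, truth, atol=0.02)


class TestDprimeCi:
    def test_point_estimate_matches_em_formula(self):
        rng = np.random.default_rng(6)
        a, b = haplo_genotypes(rng, [0.35, 0.25, 0.15, 0.25], 400)
        lp = dprime_ci(a, b)
        h, _ = em_haplotype_freqs(a, b)
        pA, pB = h[0] + h[1], h[0] + h[2]
        D = h[0] - pA * pB
        dmax = min(pA * (1 - pB), (1 - pA) * pB) if D >= 0 else min(pA * pB, (1 - pA) * (1 - pB))
        assert lp.dprime == pytest.approx(abs(D) / dmax, abs=1e-8)

    def test_complete_ld_finite_sample_uncertainty(self):
        rng = np.random.default_rng(7)
        a, b = haplo_genotypes(rng, [0.5, 0.0, 0.0, 0.5], 50)
        lp = dprime_ci(a, b)
        assert lp.dprime == pytest.approx(1.0, abs=1e-9)
        assert lp.dprime_ci_low < 1.0

    def test_ci_tightens_with_sample_size(self):
        rng = np.random.default_rng(8)
        lows = []
        for n in (50, 500, 5000):
            a, b = haplo_genotypes(rng, [0.5, 0.0, 0.0, 0.5], n)
            lows.append(dprime_ci(a, b).dprime_ci_low)
        assert lows[0] < lows[1] <= lows[2] <= 1.0

    def test_bounds_ordered(self):
        rng = np.random.default_rng(9)
        a, b = haplo_genotypes(rng, [0.3, 0.3, 0.2, 0.2], 300)
        lp = dprime_ci(a, b)
        assert 0.0 <= lp.dprime_ci_low <= lp.dprime_ci_high <= 1.0


def three_block_chromosome(rng, n=250, snps_per_block=4, block_gap_bp=400_000):
    """Blocks of perfectly coupled SNPs; independent latents between blocks."""
    cols, pos = [], []
    base = 1
    for b in range(3):
        hap1 = (rng.random(n) < 0.5).astype(float)
        hap2 = (rng.random(n) < 0.5).astype(float)
        g = hap1 + hap2
        for s in range(snps_per_block):
            cols.append(g)
            pos.append(base + s * 10_000)
        base += block_gap_bp
    return geno_with_positions(np.column_stack(cols), pos)


class TestFindBlocks:
    def test_adjacent_pair_in_near_complete_ld(self):
        rng = np.random.default_rng(10)
        hap = (rng.random((1000, 2)) < 0.5).astype(float)
        g = hap.sum(axis=1)
        geno = geno_with_positions(np.column_stack([g, g]), [1000, 5000])
        blocks = find_blocks(geno)
        assert len(blocks) == 1 and blocks[0].n_snps == 2

    def test_max_span_rule(self):
        rng = np.random.default_rng(11)
        hap = (rng.random((1000, 2)) < 0.5).astype(float)
        g = hap.sum(axis=1)
        geno = geno_with_positions(np.column_stack([g, g]), [1000, 6_001_000])
        assert find_blocks(geno, max_kb=5000) == []

    def test_three_block_chromosome_recovered(self):
        rng = np.random.default_rng(12)
        geno = three_block_chromosome(rng)
        blocks = find_blocks(geno)
        assert len(blocks) == 3
        members = [tuple(b.snp_ids) for b in blocks]
        expect = [tuple(f"s{j}" for j in range(k * 4, k * 4 + 4)) for k in range(3)]
        assert members == expect
        assert [b.label for b in blocks] == ["1_1", "1_2", "1_3"]


class TestAssignHits:
    @staticmethod
    def blocks():
        return [
            HaplotypeBlock(chrom="20", start=1000, stop=5000,
                           snp_ids=["a1", "a2", "a3"], label="20_1"),
            HaplotypeBlock(chrom="20", start=9000, stop=12_000,
                           snp_ids=["b1", "b2"], label="20_2"),
        ]

    def test_hit_inside_block_gets_label(self):
        hits = pd.DataFrame({"snp_id": ["a2"], "chrom": ["20"], "pos": [3000]})
        table, union = assign_hits_to_blocks(hits, self.blocks())
        assert list(table["block"]) == ["20_1"]
        assert union == 3

    def test_hit_between_blocks_becomes_singleton(self):
        hits = pd.DataFrame({"snp_id": ["lone"], "chrom": ["20"], "pos": [7000]})
        table, union = assign_hits_to_blocks(hits, self.blocks())
        assert len(table) == 1
        assert table["start"].iloc[0] == table["stop"].iloc[0] == 7000
        assert union == 1

    def test_many_hits_few_blocks_union_count(self):
        rng = np.random.default_rng(13)
        blocks = [
            HaplotypeBlock(chrom="2", start=k * 10_000, stop=k * 10_000 + 5000,
                           snp_ids=[f"c{k}_{i}" for i in range(k + 2)], label=f"2_{k+1}")
            for k in range(4)
        ]
        positions = [k * 10_000 + int(rng.integers(0, 5000)) for k in range(4) for _ in range(3)]
        hits = pd.DataFrame({
            "snp_id": [f"h{i}" for i in range(11)],
            "chrom": ["2"] * 11,
            "pos": positions[:11],
        })
        table, union = assign_hits_to_blocks(hits, blocks)
        assert len(table) == 4
        assert union == sum(len(b.snp_ids) for b in blocks)
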