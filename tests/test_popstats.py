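"""Allele frequencies, diversity, WC84 F_ST, BY-FDR and PCA."""

import numpy as np
import pytest

from beemix.popstats import (allele_frequencies, by_fdr, diversity,
                             pairwise_fst, pca_embed, per_site_fst)
from beemix.simulate import apply_missingness

from conftest import make_geno, two_pool_geno, wc84_oracle


class TestAlleleFrequencies:
    def test_diploid_trio(self):
        geno = make_geno([[0, 1, 2]])
        t = allele_frequencies(geno, {s: "A" for s in geno.samples})
        assert t.freq[0, 0] == pytest.approx(0.5)
        assert t.n_alleles[0, 0] == 6

    def test_mixed_ploidy_counts_alleles(self):
        geno = make_geno([[2, 2, 1]], ploidy=[2, 2, 1])
        t = allele_frequencies(geno, {s: "A" for s in geno.samples})
        assert t.freq[0, 0] == pytest.approx(1.0)
        assert t.n_alleles[0, 0] == 5

    def test_missing_cells_excluded(self):
        missing = np.array([[False, False, True, False]])
        geno = make_geno([[0, 1, 2, 2]], missing=missing)
        t = allele_frequencies(geno, {s: "A" for s in geno.samples})
        assert t.freq[0, 0] == pytest.approx(3 / 6)
        assert t.n_alleles[0, 0] == 6

    def test_single_sample_group_valid(self):
        geno = make_geno([[1, 2]], ploidy=[1, 2])
        t = allele_frequencies(geno, {"s0": "hap", "s1": "dip"})
        i, j = t.column("hap"), t.column("dip")
        assert t.n_alleles[0, i] == 1 and t.freq[0, i] == 1.0
        assert t.n_alleles[0, j] == 2 and t.freq[0, j] == 1.0


class TestDiversity:
    def test_all_het_at_half_frequency(self):
        # every individual heterozygous, overall p = 0.5 -> Ho=1, He=0.5, F_IS=-1
        geno = make_geno(np.ones((10, 4), dtype=np.int8))
        d = diversity(geno, {s: "A" for s in geno.samples})
        assert d.loc[0, "Ho"] == pytest.approx(1.0)
        assert d.loc[0, "He"] == pytest.approx(0.5)
        assert d.loc[0, "F_IS"] == pytest.approx(-1.0)

    def test_haploids_excluded_and_flagged(self):
        geno = make_geno([[1, 1, 1]], ploidy=[2, 2, 1])
        d = diversity(geno, {s: "A" for s in geno.samples})
        assert d.loc[0, "N"] == 2
        assert d.attrs["haploids_excluded"] == ["s2"]

    def test_hardy_weinberg_population_has_null_fis(self):
        # 20 diploids x 2000 sites drawn at HW equilibrium -> mean F_IS ~ 0
        rng = np.random.default_rng(8)
        p = rng.uniform(0.1, 0.9, size=2000)
        dosage = rng.binomial(2, p[:, None], size=(2000, 20)).astype(np.int8)
        geno = make_geno(dosage)
        d = diversity(geno, {s: "A" for s in geno.samples})
        assert abs(d.loc[0, "F_IS"]) < 0.05


class TestPairwiseFst:
    def test_fixed_differences_give_one(self):
        dosage = np.tile([0] * 5 + [2] * 5, (20, 1)).astype(np.int8)
        geno = make_geno(dosage)
        groups = {f"s{j}": ("A" if j < 5 else "B") for j in range(10)}
        t, p = pairwise_fst(geno, groups, "A", "B", n_perm=99, seed=0)
        assert t == pytest.approx(1.0)
        assert p <= 0.05

    def test_matches_brute_force_oracle_exactly(self):
        # 3 sites, 2+2 individuals, including a missing call
        ga = [[0, 1], [2, None], [1, 1]]
        gb = [[2, 2], [0, 1], [1, 0]]
        dosage = np.array([[0, 1, 2, 2], [2, 0, 0, 1], [1, 1, 1, 0]],
                          dtype=np.int8)
        missing = np.zeros((3, 4), dtype=bool)
        missing[1, 1] = True
        geno = make_geno(dosage, missing=missing)
        groups = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        t, _ = pairwise_fst(geno, groups, "A", "B", n_perm=0)
        assert t == pytest.approx(wc84_oracle(ga, gb), abs=1e-12)

    def test_random_tables_match_oracle(self, rng):
        for _ in range(20):
            n1, n2, L = rng.integers(2, 6), rng.integers(2, 6), rng.integers(2, 10)
            dosage = rng.integers(0, 3, size=(L, n1 + n2)).astype(np.int8)
            missing = rng.random((L, n1 + n2)) < 0.15
            geno = make_geno(dosage, missing=missing)
            groups = {f"s{j}": ("A" if j < n1 else "B") for j in range(n1 + n2)}
            ga = [[None if missing[i, j] else int(dosage[i, j])
                   for j in range(n1)] for i in range(L)]
            gb = [[None if missing[i, j] else int(dosage[i, j])
                   for j in range(n1, n1 + n2)] for i in range(L)]
            expected = wc84_oracle(ga, gb)
            if not np.isfinite(expected):
                continue
            t, _ = pairwise_fst(geno, groups, "A", "B", n_perm=0)
            assert t == pytest.approx(expected, abs=1e-12)

    def test_symmetric_in_group_order(self):
        geno, _, labels = two_pool_geno(300, 6, 0.1, seed=3)
        tab, _ = pairwise_fst(geno, labels, "P1", "P2", n_perm=0)
        tba, _ = pairwise_fst(geno, labels, "P2", "P1", n_perm=0)
        assert tab == pytest.approx(tba, abs=1e-12)

    def test_null_split_of_one_population(self):
        # two groups drawn from one pool: F_ST ~ 0 and usually insignificant
        hits = 0
        for seed in range(10):
            geno, _, _ = two_pool_geno(2000, 10, 1e-4, seed=100 + seed)
            groups = {s: ("A" if i < 10 else "B")
                      for i, s in enumerate(geno.samples)}
            t, p = pairwise_fst(geno, groups, "A", "B", n_perm=99,
                                seed=seed)
            assert abs(t) < 0.02
            hits += p > 0.05
        assert hits >= 9

    def test_balding_nichols_recovery(self):
        # parameter recovery: F = 0.045 -> WC estimate in [0.03, 0.06]
        inside = 0
        for seed in range(20):
            geno, _, labels = two_pool_geno(2000, 20, 0.045, seed=200 + seed)
            t, _ = pairwise_fst(geno, labels, "P1", "P2", n_perm=0)
            inside += 0.03 <= t <= 0.06
        assert inside >= 18


class TestByFdr:
    @staticmethod
    def oracle(p):
        """Brute-force BY step-up with c(m) = sum_{i<=m} 1/i."""
        p = list(p)
        m = len(p)
        c = sum(1.0 / i for i in range(1, m + 1))
        order = sorted(range(m), key=lambda i: p[i])
        adj = [0.0] * m
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            val = min(prev, p[i] * m * c / rank)
            adj[i] = val
            prev = val
        return adj

    def test_single_p_unchanged(self):
        adj, tiers = by_fdr([0.01])
        assert adj[0] == pytest.approx(0.01)
        assert tiers[0] == "*"

    def test_two_values_hand_computed(self):
        # m=2, c(2)=1.5: adj = (0.01*2*1.5/1 -> capped by step-up, 0.04*2*1.5/2)
        adj, _ = by_fdr([0.01, 0.04])
        assert adj[1] == pytest.approx(0.04 * 2 * 1.5 / 2)
        assert adj[0] == pytest.approx(min(0.01 * 2 * 1.5 / 1, adj[1]))

    def test_matches_oracle_for_random_vectors(self, rng):
        for _ in range(30):
            m = int(rng.integers(1, 56))
            p = rng.uniform(1e-6, 1.0, size=m)
            adj, _ = by_fdr(p)
            assert np.allclose(adj, self.oracle(p), atol=1e-12)

    def test_monotone_in_rank(self, rng):
        p = rng.uniform(0, 1, size=25) + 1e-9
        adj, _ = by_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestPca:
    def test_duplicated_individual_has_identical_coordinates(self):
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(50, 5)).astype(np.int8)
        dosage[:, 4] = dosage[:, 0]
        geno = make_geno(dosage)
        coords, _ = pca_embed(geno, 3)
        assert np.allclose(coords[0], coords[4], atol=1e-9)

    def test_fully_missing_individual_at_origin(self):
        rng = np.random.default_rng(1)
        dosage = rng.integers(0, 3, size=(40, 5)).astype(np.int8)
        missing = np.zeros_like(dosage, dtype=bool)
        missing[:, 2] = True
        geno = make_geno(dosage, missing=missing)
        coords, _ = pca_embed(geno, 3)
        assert np.allclose(coords[2], 0.0, atol=1e-9)

    def test_pools_separate_on_pc1(self):
        # two pools at F_ST 0.05: PC1 splits them with no overlap
        ok = 0
        for seed in range(10):
            geno, _, _ = two_pool_geno(2000, 10, 0.05, seed=300 + seed)
            coords, _ = pca_embed(geno, 2)
            a, b = coords[:10, 0], coords[10:, 0]
            ok += (a.max() < b.min()) or (b.max() < a.min())
        assert ok >= 9

    def test_high_missingness_shrinks_toward_origin(self):
        # same individual at increasing missingness moves monotonically inward
        geno, _, _ = two_pool_geno(2000, 8, 0.05, seed=55)
        norms = []
        for rate in (0.0, 0.3, 0.6, 0.9):
            g = apply_missingness(geno, rate, seed=9) if rate else geno
            # mask only the probe individual, keep the rest clean
            mask = geno.missing.copy()
            mask[:, 0] = g.missing[:, 0] if rate else False
            probe = make_geno(geno.dosage, missing=mask)
            coords, _ = pca_embed(probe, 2)
            norms.append(float(np.linalg.norm(coords[0])))
        assert norms == sorted(norms, reverse=True)
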