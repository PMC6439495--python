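"""Genotype-frequency class model, top-F_ST panel, posterior classification."""

import math

import numpy as np
import pytest

from beemix.hybrid_classes import (CATEGORIES, class_genotype_prob, classify,
                                   top_fst_panel)
from beemix.hybrid_index import ParentalPanel
from beemix.simulate import simulate_individual, simulate_parental_freqs

from conftest import make_geno, two_pool_geno


class TestClassGenotypeProb:
    def test_f1_at_diagnostic_site_always_het(self):
        p0, p1, p2 = class_genotype_prob("F1", 1.0, 0.0)
        assert (p0, p1, p2) == (0.0, 1.0, 0.0)

    def test_f2_mixing_vector_at_diagnostic_site(self):
        p0, p1, p2 = class_genotype_prob("F2", 1.0, 0.0)
        assert (p0, p1, p2) == (0.25, 0.5, 0.25)

    def test_equal_frequencies_degenerate_to_hardy_weinberg(self):
        p = 0.37
        hw = ((1 - p) ** 2, 2 * p * (1 - p), p**2)
        for z in CATEGORIES:
            probs = class_genotype_prob(z, p, p)
            assert np.allclose(probs, hw, atol=1e-12)

    def test_probabilities_sum_to_one(self, rng):
        for _ in range(50):
            pa, pb = rng.uniform(0, 1, 2)
            z = CATEGORIES[int(rng.integers(len(CATEGORIES)))]
            assert math.isclose(sum(class_genotype_prob(z, pa, pb)), 1.0,
                                abs_tol=1e-12)

    def test_matches_explicit_gamete_simulation(self):
        # 10,000 draws per category at a partially diagnostic site
        pools = simulate_parental_freqs(1, 0.4, seed=1)
        p1, p2 = float(pools.native[0]), float(pools.commercial[0])
        rng = np.random.default_rng(2)
        for z, cat in [("Pure1", "pure_native"), ("Pure2", "pure_commercial"),
                       ("F1", "F1"), ("F2", "F2"), ("BC1", "BC1"), ("BC2", "BC2")]:
            draws = np.array([simulate_individual(cat, pools, rng=rng)[0]
                              for _ in range(10000)])
            emp = np.bincount(draws, minlength=3) / draws.size
            model = np.array(class_genotype_prob(z, p1, p2))
            assert np.max(np.abs(emp - model)) < 0.02


class TestTopFstPanel:
    def test_single_top_site_selected(self):
        geno, _, labels = two_pool_geno(100, 8, 0.3, seed=30)
        panel = top_fst_panel(geno, labels, "P1", "P2", quantile=0.01)
        assert panel.n_sites == 1
        from beemix.popstats import per_site_fst
        theta = per_site_fst(geno, labels, "P1", "P2")
        assert panel.fst[0] == pytest.approx(np.nanmax(theta))

    def test_tie_broken_by_coordinate_order(self):
        # all sites identical -> first site by (chrom, pos) wins
        dosage = np.tile([0, 0, 2, 2], (50, 1)).astype(np.int8)
        chrom = np.array(["c2"] * 25 + ["c1"] * 25, dtype=object)
        pos = np.concatenate([np.arange(1, 26), np.arange(1, 26)])
        geno = make_geno(dosage, chrom=chrom, pos=pos.astype(np.int64))
        labels = {f"s{j}": ("P1" if j < 2 else "P2") for j in range(4)}
        panel = top_fst_panel(geno, labels, "P1", "P2", quantile=0.01)
        assert geno.chrom[panel.site_idx[0]] == "c1"
        assert geno.pos[panel.site_idx[0]] == 1

    def test_panel_size_uses_ceiling(self):
        geno, _, labels = two_pool_geno(250, 6, 0.3, seed=31)
        panel = top_fst_panel(geno, labels, "P1", "P2", quantile=0.01)
        assert panel.n_sites == math.ceil(0.01 * 250)

    def test_threshold_reported(self):
        geno, _, labels = two_pool_geno(300, 6, 0.3, seed=32)
        panel = top_fst_panel(geno, labels, "P1", "P2", quantile=0.05)
        assert panel.threshold == pytest.approx(np.nanmin(panel.fst))
        assert np.all(np.diff(panel.fst) <= 1e-12)


def _simulated_cohort(category, pools, n, seed):
    rng = np.random.default_rng(seed)
    cols = [simulate_individual(category, pools, rng=rng) for _ in range(n)]
    return np.column_stack(cols)


class TestClassify:
    def _diagnostic_setup(self, n_sites=30):
        geno_sites = np.zeros((n_sites, 1), dtype=np.int8)
        panel_idx = np.arange(n_sites)
        from beemix.hybrid_classes import DifferentiatedPanel
        panel = DifferentiatedPanel(site_idx=panel_idx,
                                    fst=np.ones(n_sites), quantile=1.0,
                                    threshold=1.0)
        p1 = np.full(n_sites, 1 / 41)   # pool1 ~ fixed ref (shrunk)
        p2 = np.full(n_sites, 40 / 41)  # pool2 ~ fixed alt
        return panel, p1, p2

    def test_all_het_individual_is_f1(self):
        panel, p1, p2 = self._diagnostic_setup()
        geno = make_geno(np.ones((30, 1), dtype=np.int8))
        cp = classify(geno, "s0", panel, p1, p2)
        assert cp.map_category == "F1"
        assert cp.posterior["F1"] > 0.99

    def test_all_alt_homozygote_is_pure2(self):
        panel, p1, p2 = self._diagnostic_setup()
        geno = make_geno(np.full((30, 1), 2, dtype=np.int8))
        cp = classify(geno, "s0", panel, p1, p2)
        assert cp.map_category == "Pure2"

    def test_posterior_normalized(self):
        geno, _, labels = two_pool_geno(300, 10, 0.4, seed=33,
                                        categories=[("f2_", "F2", 2)])
        panel = top_fst_panel(geno, labels, "P1", "P2", quantile=0.2)
        from beemix.hybrid_index import parental_panel
        pool1 = [s for s in geno.samples if s.startswith("nat")]
        pool2 = [s for s in geno.samples if s.startswith("com")]
        pp = parental_panel(geno.take_sites(panel.site_idx), pool1, pool2)
        p1 = np.full(panel.n_sites, np.nan)
        p2 = np.full(panel.n_sites, np.nan)
        p1[pp.site_mask] = pp.p1
        p2[pp.site_mask] = pp.p2
        for s in geno.samples:
            cp = classify(geno, s, panel, p1, p2)
            assert sum(cp.posterior.values()) == pytest.approx(1.0, abs=1e-8)

    def test_pool_swap_maps_categories(self):
        geno, _, labels = two_pool_geno(400, 10, 0.4, seed=34,
                                        categories=[("bc_", "BC1", 1)])
        panel = top_fst_panel(geno, labels, "P1", "P2", quantile=0.3)
        sub = geno.take_sites(panel.site_idx)
        from beemix.hybrid_index import parental_panel
        pool1 = [s for s in geno.samples if s.startswith("nat")]
        pool2 = [s for s in geno.samples if s.startswith("com")]
        pp12 = parental_panel(sub, pool1, pool2)
        pp21 = parental_panel(sub, pool2, pool1)

        def _exp(pp):
            a = np.full(panel.n_sites, np.nan)
            b = np.full(panel.n_sites, np.nan)
            a[pp.site_mask] = pp.p1
            b[pp.site_mask] = pp.p2
            return a, b

        a12, b12 = _exp(pp12)
        a21, b21 = _exp(pp21)
        cp12 = classify(geno, "bc_0", panel, a12, b12)
        cp21 = classify(geno, "bc_0", panel, a21, b21)
        swap = {"Pure1": "Pure2", "Pure2": "Pure1", "BC1": "BC2",
                "BC2": "BC1", "F1": "F1", "F2": "F2"}
        for z in CATEGORIES:
            assert cp12.posterior[z] == pytest.approx(
                cp21.posterior[swap[z]], abs=1e-9)

    def test_map_accuracy_on_177_site_panel(self):
        # n=30 per category on a 177-site strongly differentiated panel:
        # parentals and F1 recovered >= 90%; F2/backcross confusion tolerated
        pools = simulate_parental_freqs(177, 0.4, seed=40)
        p1 = np.clip(pools.native, 1 / 81, 80 / 81)
        p2 = np.clip(pools.commercial, 1 / 81, 80 / 81)
        from beemix.hybrid_classes import DifferentiatedPanel
        panel = DifferentiatedPanel(site_idx=np.arange(177),
                                    fst=np.ones(177), quantile=0.01,
                                    threshold=0.39)
        truth_to_cat = {"Pure1": "pure_native", "Pure2": "pure_commercial",
                        "F1": "F1"}
        for z, cat in truth_to_cat.items():
            dosage = _simulated_cohort(cat, pools, 30, seed=hash(z) % 2**31)
            geno = make_geno(dosage)
            correct = sum(
                classify(geno, s, panel, p1, p2).map_category == z
                for s in geno.samples
            )
            assert correct >= 27, f"{z}: {correct}/30"
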