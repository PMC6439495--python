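"""Site/individual filters: rule-by-rule oracle, quantile cut, dataset builds."""

import numpy as np
import pandas as pd
import pytest

from beemix.filtering import (DATASET_SPECS, FilterConfig, build_dataset,
                              drop_low_yield_individuals, filter_sites,
                              select_one_snp_per_locus)
from beemix.simulate import SimulationConfig, simulate_study

from conftest import make_geno


def brute_force_keep(geno, groups, cfg):
    """Hand application of the site rules (presence, MAF, missingness,
    coverage, duplicate positions), scalar loops only."""
    labels = [groups[s] for s in geno.samples]
    names = sorted(set(labels))
    keep = []
    for i in range(geno.n_sites):
        present = 0
        for g in names:
            idx = [j for j, l in enumerate(labels) if l == g]
            called = sum(0 if geno.missing[i, j] else 1 for j in idx)
            if called >= 1 and called / len(idx) >= cfg.min_ind_frac_per_pop:
                present += 1
        if present < cfg.min_pops:
            keep.append(False)
            continue
        alt = tot = 0
        for j in range(geno.n_samples):
            if not geno.missing[i, j]:
                alt += int(geno.dosage[i, j])
                tot += int(geno.ploidy[j])
        if tot == 0:
            keep.append(False)
            continue
        p = alt / tot
        if min(p, 1 - p) < cfg.min_maf:
            keep.append(False)
            continue
        miss = sum(bool(m) for m in geno.missing[i]) / geno.n_samples
        if miss > cfg.max_missing_frac:
            keep.append(False)
            continue
        if geno.coverage is not None and geno.coverage[i] > cfg.max_mean_coverage:
            keep.append(False)
            continue
        keep.append(True)
    # duplicate (chrom, pos) among survivors
    coords = [(geno.chrom[i], geno.pos[i]) for i in range(geno.n_sites)]
    surv = [c for i, c in enumerate(coords) if keep[i]]
    for i in range(geno.n_sites):
        if keep[i] and surv.count(coords[i]) > 1:
            keep[i] = False
    return keep


def _toy_with_planted_violations(seed=0):
    """20 sites x 8 diploids in 2 groups, violations of each rule planted."""
    rng = np.random.default_rng(seed)
    n_sites, n = 20, 8
    dosage = rng.integers(0, 3, size=(n_sites, n)).astype(np.int8)
    missing = np.zeros((n_sites, n), dtype=bool)
    coverage = np.full(n_sites, 50.0)
    dosage[0] = 0            # monomorphic -> MAF 0
    dosage[1] = [0, 0, 0, 0, 0, 0, 0, 1]   # MAF 1/16 = 0.0625 (kept at 0.05)
    dosage[2] = [0, 0, 0, 0, 0, 0, 1, 0]   # same MAF, then masked below
    missing[3] = [True, True, True, False, False, False, False, False]  # 37.5% missing
    missing[4, :4] = True    # group A fully missing -> presence fails
    coverage[5] = 250.0      # coverage cap
    dosage[6] = [0, 1, 2, 0, 1, 2, 0, 1]
    pos = np.arange(1, n_sites + 1, dtype=np.int64)
    pos[8] = pos[7]          # duplicated position
    geno = make_geno(dosage, missing=missing, coverage=coverage, pos=pos)
    groups = {f"s{j}": ("A" if j < 4 else "B") for j in range(n)}
    return geno, groups


class TestFilterSites:
    def test_low_maf_site_removed(self):
        dosage = np.tile([0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1], (2, 1)).astype(np.int8)
        dosage[1, :3] = 1  # MAF 4/24
        geno = make_geno(dosage)
        groups = {s: "A" for s in geno.samples}
        out, report = filter_sites(geno, groups, FilterConfig(min_maf=0.05))
        assert out.n_sites == 1  # 1/24 = 0.042 < 0.05 removed
        assert dict(report.rules)["min_maf"] == 1

    def test_clean_site_retained(self):
        geno = make_geno([[0, 1, 2, 1]], coverage=np.array([50.0]))
        out, report = filter_sites(geno, {s: "A" for s in geno.samples},
                                   FilterConfig())
        assert out.n_sites == 1
        assert report.total_removed() == 0

    def test_matches_brute_force_on_planted_violations(self):
        geno, groups = _toy_with_planted_violations()
        cfg = FilterConfig(min_pops=2)
        out, report = filter_sites(geno, groups, cfg)
        expected = brute_force_keep(geno, groups, cfg)
        got = set(zip(out.chrom, out.pos))
        want = {(geno.chrom[i], geno.pos[i]) for i in range(geno.n_sites)
                if expected[i]}
        assert got == want
        assert report.total_removed() == geno.n_sites - out.n_sites

    def test_idempotent(self):
        geno, groups = _toy_with_planted_violations(seed=3)
        cfg = FilterConfig(min_pops=2)
        once, _ = filter_sites(geno, groups, cfg)
        twice, rep2 = filter_sites(once, groups, cfg)
        assert twice.n_sites == once.n_sites
        assert rep2.total_removed() == 0

    def test_removal_counts_sum_to_difference(self, rng):
        for seed in range(5):
            geno, groups = _toy_with_planted_violations(seed=seed)
            out, report = filter_sites(geno, groups, FilterConfig(min_pops=2))
            assert report.total_removed() == geno.n_sites - out.n_sites


class TestOneSnpPerLocus:
    def test_one_site_per_locus_kept(self):
        geno = make_geno(np.ones((3, 2), dtype=np.int8),
                         locus=np.array(["L1"] * 3, dtype=object))
        out = select_one_snp_per_locus(geno, seed=0)
        assert out.n_sites == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        geno = make_geno(rng.integers(0, 3, (30, 4)).astype(np.int8),
                         locus=np.array([f"L{i // 3}" for i in range(30)],
                                        dtype=object))
        a = select_one_snp_per_locus(geno, seed=42)
        b = select_one_snp_per_locus(geno, seed=42)
        assert np.array_equal(a.pos, b.pos)

    def test_site_count_equals_locus_count(self):
        rng = np.random.default_rng(1)
        sizes = rng.integers(1, 6, size=1000)
        loci = np.concatenate([[f"L{k}"] * s for k, s in enumerate(sizes)])
        n = loci.size
        geno = make_geno(rng.integers(0, 3, (n, 2)).astype(np.int8),
                         locus=np.asarray(loci, dtype=object))
        out = select_one_snp_per_locus(geno, seed=5)
        assert out.n_sites == 1000

    def test_invariant_to_site_order_permutation(self):
        rng = np.random.default_rng(2)
        geno = make_geno(rng.integers(0, 3, (30, 4)).astype(np.int8),
                         locus=np.array([f"L{i // 3}" for i in range(30)],
                                        dtype=object))
        perm = rng.permutation(30)
        shuffled = geno.take_sites(perm)
        a = select_one_snp_per_locus(geno, seed=7)
        b = select_one_snp_per_locus(shuffled, seed=7)
        assert sorted(zip(a.chrom, a.pos)) == sorted(zip(b.chrom, b.pos))


class TestDropLowYield:
    def test_counts_one_to_twenty(self):
        meta = pd.DataFrame({"sample_id": [f"s{i}" for i in range(1, 21)],
                             "read_count": np.arange(1, 21)})
        # linear-interpolation 15% quantile of 1..20 = 1 + 0.15*19 = 3.85
        kept, dropped = drop_low_yield_individuals(meta)
        assert dropped == ["s1", "s2", "s3"]
        assert len(kept) == 17

    def test_all_equal_counts_drop_nobody(self):
        meta = pd.DataFrame({"sample_id": ["a", "b", "c"], "read_count": [5, 5, 5]})
        kept, dropped = drop_low_yield_individuals(meta)
        assert dropped == []

    def test_study_scale_66_to_57(self):
        bundle = simulate_study(SimulationConfig(n_sites=50, seed=11))
        kept, dropped = drop_low_yield_individuals(
            bundle.metadata, protect=bundle.metadata.attrs["protect"])
        assert len(bundle.metadata) == 66
        assert len(dropped) == 9
        assert len(kept) == 57


@pytest.fixture(scope="module")
def bundle():
    return simulate_study(SimulationConfig(n_sites=800, seed=21))


class TestBuildDataset:

    def test_females_has_no_male_columns(self, bundle):
        females, _ = build_dataset(bundle.geno, bundle.metadata,
                                   DATASET_SPECS["FEMALES"])
        males = set(bundle.metadata.loc[bundle.metadata.sex == "male",
                                        "sample_id"])
        assert not males & set(females.samples)
        assert (females.ploidy == 2).all()

    def test_no_outgroup_additionally_drops_outgroup(self, bundle):
        noout, _ = build_dataset(bundle.geno, bundle.metadata,
                                 DATASET_SPECS["NO_OUTGROUP"])
        og = set(bundle.metadata.loc[bundle.metadata.group == "outgroup",
                                     "sample_id"])
        assert not og & set(noout.samples)

    def test_refiltering_changes_site_set(self, bundle):
        # MAF recomputed per dataset: removing samples shifts frequencies,
        # so the named datasets retain different SNP sets
        from beemix.filtering import DatasetSpec
        cfg = FilterConfig(min_pops=2, one_snp_per_locus=False)
        total, rep_t = build_dataset(
            bundle.geno, bundle.metadata,
            DatasetSpec("custom_total", True, True, cfg))
        noout, rep_n = build_dataset(
            bundle.geno, bundle.metadata,
            DatasetSpec("custom_noout", False, False, cfg))
        assert set(zip(total.chrom, total.pos)) != set(zip(noout.chrom, noout.pos))
        maf_t = dict(rep_t.rules)["min_maf"]
        maf_n = dict(rep_n.rules)["min_maf"]
        assert maf_t != maf_n  # the MAF rule fired differently after subsetting

    def test_unknown_dataset_name_errors(self):
        from beemix.filtering import named_dataset_spec
        with pytest.raises(ValueError, match="unknown dataset"):
            named_dataset_spec("WHATEVER")
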