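import numpy as np
import pytest

from beemix.io import GenotypeMatrix
from beemix.simulate import simulate_individual, simulate_parental_freqs


def make_geno(dosage, ploidy=None, missing=None, chrom=None, pos=None,
              locus=None, samples=None, coverage=None):
    """Small-matrix constructor with sensible defaults for tests."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    if ploidy is None:
        ploidy = np.full(n_samples, 2, dtype=np.int8)
    if missing is None:
        missing = np.zeros_like(dosage, dtype=bool)
    if chrom is None:
        chrom = np.array(["chr1"] * n_sites, dtype=object)
    if pos is None:
        pos = np.arange(1, n_sites + 1, dtype=np.int64)
    if locus is None:
        locus = np.array([f"loc{i}" for i in range(n_sites)], dtype=object)
    if samples is None:
        samples = [f"s{j}" for j in range(n_samples)]
    return GenotypeMatrix(chrom=chrom, pos=pos, locus=locus, dosage=dosage,
                          missing=missing, samples=samples,
                          ploidy=np.asarray(ploidy, dtype=np.int8),
                          coverage=coverage)


def random_geno(rng, n_sites=None, n_samples=None, haploid_frac=0.2,
                missing_rate=0.1):
    """Random mixed-ploidy matrix for round-trip / property tests."""
    if n_sites is None:
        n_sites = int(rng.integers(1, 40))
    if n_samples is None:
        n_samples = int(rng.integers(1, 12))
    ploidy = np.where(rng.random(n_samples) < haploid_frac, 1, 2).astype(np.int8)
    dosage = np.zeros((n_sites, n_samples), dtype=np.int8)
    for j in range(n_samples):
        dosage[:, j] = rng.integers(0, ploidy[j] + 1, size=n_sites)
    missing = rng.random((n_sites, n_samples)) < missing_rate
    chroms = np.array([f"scf{int(c)}" for c in rng.integers(1, 4, size=n_sites)],
                      dtype=object)
    pos = np.zeros(n_sites, dtype=np.int64)
    seen = {}
    for i, c in enumerate(chroms):
        seen[c] = seen.get(c, 0) + int(rng.integers(1, 50))
        pos[i] = seen[c]
    return make_geno(dosage, ploidy=ploidy, missing=missing, chrom=chroms,
                     pos=pos)


def two_pool_geno(n_sites, n_per_pool, fst, seed, categories=None):
    """Two diploid pools (native / commercial) plus optional extra categories.

    categories: list of (name_prefix, category, n) appended after the pools.
    Returns (geno, pools, labels) where labels maps sample -> 'P1'/'P2'/prefix.
    """
    pools = simulate_parental_freqs(n_sites, fst, seed=seed)
    rng = np.random.default_rng(seed + 7919)
    cols, names, labels = [], [], {}
    for i in range(n_per_pool):
        cols.append(simulate_individual("pure_native", pools, rng=rng))
        names.append(f"nat{i}")
        labels[f"nat{i}"] = "P1"
    for i in range(n_per_pool):
        cols.append(simulate_individual("pure_commercial", pools, rng=rng))
        names.append(f"com{i}")
        labels[f"com{i}"] = "P2"
    for prefix, category, n in categories or ():
        for i in range(n):
            cols.append(simulate_individual(category, pools, rng=rng))
            names.append(f"{prefix}{i}")
            labels[f"{prefix}{i}"] = prefix
    geno = make_geno(np.column_stack(cols), samples=names)
    return geno, pools, labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# Independent Weir & Cockerham (1984) oracle: scalar loops straight from the
# published variance-component definitions, no shared code with the package.
# ---------------------------------------------------------------------------


def wc84_oracle(genotypes_a, genotypes_b):
    """Multi-locus WC84 theta from per-individual diploid dosage lists.

    genotypes_x: list over loci of lists of dosages (None = missing).
    Returns sum(a) / sum(a + b + c).
    """
    num = den = 0.0
    for ga, gb in zip(genotypes_a, genotypes_b):
        ga = [g for g in ga if g is not None]
        gb = [g for g in gb if g is not None]
        n1, n2 = len(ga), len(gb)
        if n1 == 0 or n2 == 0 or n1 + n2 <= 2:
            continue
        r = 2
        nbar = (n1 + n2) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        p1 = sum(ga) / (2 * n1)
        p2 = sum(gb) / (2 * n2)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        h1 = sum(1 for g in ga if g == 1) / n1
        h2 = sum(1 for g in gb if g == 1) / n2
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den
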