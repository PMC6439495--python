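"""Study-shaped synthetic data with known truth.

Two source gene pools (native and commercial) are simulated under the
Balding-Nichols model: per site, an ancestral frequency p ~ Uniform(0.05, 0.95)
and pool frequencies p' ~ Beta(p (1-F)/F, (1-p) (1-F)/F), which gives direct
control of the expected differentiation F between the pools (default 0.045, the
scale observed between commercial and wild bumblebee groups). An outgroup pool
diverges at F = 0.5. Individuals are built by explicit gamete simulation:
pure parentals, F1, F2, backcrosses and "escapees" (pure commercial genotypes
collected in wild groups), with haploid males as single gametes. The bundle
also carries per-sample read counts (with planted low-yield individuals), a
COX1-like mitochondrial alignment with a fixed haplotype structure (four
ingroup haplotypes 1-4 substitutions apart, an outgroup 45-47 away), and a
truth table for every sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, SequenceAlignment

__all__ = [
    "SimulationConfig",
    "PoolFrequencies",
    "simulate_parental_freqs",
    "simulate_individual",
    "apply_missingness",
    "MtdnaSpec",
    "simulate_mtdna",
    "simulate_study",
    "StudyBundle",
    "TRUE_HYBRID_INDEX",
]

# pedigree expectation of the commercial-ancestry fraction per category
TRUE_HYBRID_INDEX = {
    "pure_native": 0.0,
    "BC1": 0.25,      # backcross with native
    "F1": 0.5,
    "F2": 0.5,
    "BC2": 0.75,      # backcross with commercial
    "pure_commercial": 1.0,
    "escapee": 1.0,
    "outgroup": np.nan,
}

_CATEGORY_ALIASES = {
    "Pure1": "pure_native",
    "Pure2": "pure_commercial",
    "native": "pure_native",
    "commercial": "pure_commercial",
}


@dataclass
class PoolFrequencies:
    """Per-site alt-allele frequencies of the simulated pools."""

    ancestral: np.ndarray
    native: np.ndarray
    commercial: np.ndarray
    outgroup: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.ancestral.size


def simulate_parental_freqs(n_sites: int, fst: float = 0.045, seed: int = 0,
                            outgroup_fst: float = 0.5) -> PoolFrequencies:
    """Balding-Nichols pool frequencies at a target differentiation level."""
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=n_sites)

    def _draw(f):
        a = p * (1.0 - f) / f
        b = (1.0 - p) * (1.0 - f) / f
        return rng.beta(a, b)

    return PoolFrequencies(
        ancestral=p,
        native=_draw(fst),
        commercial=_draw(fst),
        outgroup=_draw(outgroup_fst),
    )


def _gamete(kind: str, pools: PoolFrequencies, rng) -> np.ndarray:
    """One haploid gamete (per-site 0/1 alt alleles) from a parent of the given kind.

    'native'/'commercial'/'outgroup' parents transmit a Bernoulli(pool frequency)
    allele. An F1 parent carries one native- and one commercial-derived allele
    per site and transmits one of the two uniformly (unlinked sites).
    """
    if kind in ("native", "commercial", "outgroup"):
        p = getattr(pools, kind)
        return (rng.random(p.size) < p).astype(np.int8)
    if kind == "F1":
        a_nat = (rng.random(pools.n_sites) < pools.native).astype(np.int8)
        a_com = (rng.random(pools.n_sites) < pools.commercial).astype(np.int8)
        pick_com = rng.random(pools.n_sites) < 0.5
        return np.where(pick_com, a_com, a_nat).astype(np.int8)
    raise ValueError(f"unknown gamete kind {kind!r}")


_PARENTS = {
    "pure_native": ("native", "native"),
    "pure_commercial": ("commercial", "commercial"),
    "escapee": ("commercial", "commercial"),
    "outgroup": ("outgroup", "outgroup"),
    "F1": ("native", "commercial"),
    "F2": ("F1", "F1"),
    "BC1": ("F1", "native"),
    "BC2": ("F1", "commercial"),
}


def simulate_individual(category: str, pools: PoolFrequencies, seed=None,
                        ploidy: int = 2, rng=None) -> np.ndarray:
    """Per-site dosages for one individual of a pedigree category.

    Diploids are the sum of two explicit gametes (no frequency shortcuts for
    hybrid classes); haploids are a single maternal gamete. Unknown categories
    raise.
    """
    category = _CATEGORY_ALIASES.get(category, category)
    if category not in _PARENTS:
        raise ValueError(f"unknown category {category!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    mother, father = _PARENTS[category]
    if ploidy == 1:
        return _gamete(mother, pools, rng)
    return _gamete(mother, pools, rng) + _gamete(father, pools, rng)


def apply_missingness(geno: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Mask each cell independently with probability ``rate`` (seeded)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return geno
    rng = np.random.default_rng(seed)
    mask = rng.random(geno.dosage.shape) < rate
    return replace(geno, missing=geno.missing | mask)


def simulate_dstat_replicate(seed: int, kind: str = "null", n_sites: int = 2000,
                             fst: float = 0.045, n_p1: int = 13, n_p3: int = 8,
                             n_out: int = 2):
    """One replicate of the individual-level D-statistic study design.

    Genotyped samples: ``n_p1`` native diploids (P1), ``n_p3`` commercial
    diploids (P3) and ``n_out`` outgroup diploids, whose sample allele
    frequencies condition the test. The target individual (P2) is

    - ``"null"``: a pure native individual (no gene flow);
    - ``"F1"``: a native x commercial hybrid whose commercial gamete comes
      from one of the genotyped commercial individuals — escapee descendants
      stem from the very stock that was sampled;
    - ``"escapee"``: a pure commercial individual with both gametes from
      genotyped commercial parents.

    Returns (freqs, geno) where ``freqs`` holds the P1/P3/O sample
    frequencies and ``geno`` contains the single target individual "target".
    """
    from .popstats import SiteFrequencyTable

    pools = simulate_parental_freqs(n_sites, fst, seed=seed)
    rng = np.random.default_rng((seed * 2654435761 + 97) % (2**31 - 1))
    nat = rng.binomial(2, pools.native[:, None], size=(n_sites, n_p1))
    com = rng.binomial(2, pools.commercial[:, None], size=(n_sites, n_p3))
    out = rng.binomial(2, pools.outgroup[:, None], size=(n_sites, n_out))
    gam_native = (rng.random(n_sites) < pools.native).astype(np.int8)
    if kind == "null":
        target = gam_native + (rng.random(n_sites) < pools.native).astype(np.int8)
    elif kind == "F1":
        target = rng.binomial(1, com[:, 0] / 2.0).astype(np.int8) + gam_native
    elif kind == "escapee":
        target = (rng.binomial(1, com[:, 0] / 2.0)
                  + rng.binomial(1, com[:, 1 % n_p3] / 2.0)).astype(np.int8)
    else:
        raise ValueError(f"unknown replicate kind {kind!r}")
    geno = GenotypeMatrix(
        chrom=np.array(["c1"] * n_sites, dtype=object),
        pos=np.arange(1, n_sites + 1, dtype=np.int64),
        locus=np.array([f"l{i}" for i in range(n_sites)], dtype=object),
        dosage=target[:, None], missing=np.zeros((n_sites, 1), dtype=bool),
        samples=["target"], ploidy=np.array([2], dtype=np.int8),
    )
    freq = np.column_stack([nat.sum(axis=1) / (2 * n_p1),
                            com.sum(axis=1) / (2 * n_p3),
                            out.sum(axis=1) / (2 * n_out)])
    counts = np.column_stack([np.full(n_sites, 2 * n_p1),
                              np.full(n_sites, 2 * n_p3),
                              np.full(n_sites, 2 * n_out)])
    freqs = SiteFrequencyTable(
        chrom=geno.chrom.copy(), pos=geno.pos.copy(), groups=["P1", "P3", "O"],
        freq=freq, n_alleles=counts.astype(np.int64),
    )
    return freqs, geno


# ---------------------------------------------------------------------------
# mtDNA
# ---------------------------------------------------------------------------


@dataclass
class MtdnaSpec:
    """Haplotype templates as a tree of (parent index, substitutions) edges.

    Template 0 is drawn at random; template i (> 0) mutates ``edges[i-1] =
    (parent, k)`` at k fresh positions, so pairwise distances are additive along
    tree paths. The default reproduces the observed structure: four ingroup
    haplotypes with pairwise distances in 1..4 plus two outgroup haplotypes 45
    and 47 substitutions from H1.
    """

    length: int = 620
    # H1; H2 = H1+1; H3 = H1+2; H4 = H3+1; O1 = H1+45; O2 = O1+2
    edges: tuple = ((0, 1), (0, 2), (2, 1), (0, 45), (4, 2))
    names: tuple = ("hap1", "hap2", "hap3", "hap4", "out1", "out2")

    def n_templates(self) -> int:
        return len(self.edges) + 1


def simulate_mtdna(spec: MtdnaSpec, assignments, seed: int = 0) -> SequenceAlignment:
    """Build template haplotypes and assign them to samples.

    ``assignments`` maps sample_id -> template name. Substitutions are planted
    at random distinct positions never reused along the tree, so realized
    distances match the requested ones exactly; an infeasible request (more
    substitutions than positions) raises.
    """
    rng = np.random.default_rng(seed)
    total_subs = sum(k for _, k in spec.edges)
    if total_subs > spec.length:
        raise ValueError("requested distances exceed sequence length")
    bases = np.array(list("ACGT"))
    root = rng.choice(bases, size=spec.length)
    free = list(rng.permutation(spec.length))
    templates = [root.copy()]
    for parent, k in spec.edges:
        if parent >= len(templates):
            raise ValueError("template tree edges must reference earlier templates")
        t = templates[parent].copy()
        for _ in range(k):
            pos = free.pop()
            old = t[pos]
            t[pos] = rng.choice([b for b in "ACGT" if b != old])
        templates.append(t)
    by_name = {n: "".join(t) for n, t in zip(spec.names, templates)}
    ids, seqs = [], []
    for sid, hap in assignments.items():
        if hap not in by_name:
            raise ValueError(f"unknown haplotype template {hap!r} for {sid}")
        ids.append(sid)
        seqs.append(by_name[hap])
    return SequenceAlignment(ids=ids, seqs=seqs)


# ---------------------------------------------------------------------------
# Full study bundle
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study-shaped sampling design.

    The default reproduces the field design: 66 sampled individuals — 11 from
    commercial hives (3 of them low-yield), 53 wild (including 4 escapee
    females and 3 escapee males in NNear, one planted hybrid each in NNear (F2),
    NFar (BC1) and SFar (BC1), 6 native males, and 6 low-yield individuals) and
    2 outgroup specimens (one low-yield but protected from the read-count cut
    because the outgroup sample is already minimal). After the 15%-quantile
    read-count cut this leaves 57 genotyped individuals.
    """

    n_sites: int = 5000
    fst: float = 0.045
    missing_rate: float = 0.10
    seed: int = 0
    n_scaffolds: int = 12
    mean_coverage: float = 56.6
    high_coverage_frac: float = 0.005
    # (group, sex, category, n, low_yield?)
    design: tuple = (
        ("CH", "female", "pure_commercial", 8, False),
        ("CH", "female", "pure_commercial", 3, True),
        ("NNear", "female", "pure_native", 8, False),
        ("NNear", "female", "escapee", 4, False),
        ("NNear", "female", "F2", 1, False),
        ("NNear", "male", "pure_native", 2, False),
        ("NNear", "male", "escapee", 3, False),
        ("NNear", "female", "pure_native", 3, True),
        ("NFar", "female", "pure_native", 13, False),
        ("NFar", "female", "BC1", 1, False),
        ("NFar", "male", "pure_native", 4, False),
        ("NFar", "female", "pure_native", 2, True),
        ("SNear", "female", "pure_native", 5, False),
        ("SNear", "female", "pure_native", 1, True),
        ("SFar", "female", "pure_native", 5, False),
        ("SFar", "female", "BC1", 1, False),
        ("outgroup", "female", "outgroup", 1, False),
        ("outgroup", "female", "outgroup", 1, "protected"),
    )
    mtdna: MtdnaSpec = field(default_factory=MtdnaSpec)

    def __post_init__(self):
        if not 0 < self.fst < 1:
            raise ValueError("fst must be in (0,1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0,1)")
        if any(n < 0 for *_, n, _flag in self.design):
            raise ValueError("negative group size in design")


@dataclass
class StudyBundle:
    geno: GenotypeMatrix
    metadata: pd.DataFrame
    mtdna: SequenceAlignment
    truth: pd.DataFrame
    pools: PoolFrequencies


def _mt_haplotype(group: str, category: str, rng) -> str:
    """Haplotype assignment probabilities echoing the observed pattern: hap1
    common everywhere, hap3 frequent in commercial stock (and escapees),
    hap2/hap4 at low frequency in the wild."""
    if group == "outgroup":
        return "out1" if rng.random() < 0.5 else "out2"
    if category in ("pure_commercial", "escapee"):
        return "hap3" if rng.random() < 0.4 else "hap1"
    u = rng.random()
    if u < 0.70:
        return "hap1"
    if u < 0.85:
        return "hap2"
    return "hap4"


def simulate_study(config: SimulationConfig | None = None) -> StudyBundle:
    """Generate the full genotype + metadata + mtDNA + truth bundle.

    Deterministic given ``config.seed``. Sites are laid out round-robin on
    ``n_scaffolds`` synthetic scaffolds (so jackknife blocks are nontrivial),
    per-site coverage is Normal(mean_coverage, 15) with a small planted
    fraction above the 200x filter cap, and per-cell missingness is applied at
    ``missing_rate``.
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)
    pools = simulate_parental_freqs(config.n_sites, config.fst,
                                    seed=int(rng.integers(2**31 - 1)))

    samples, ploidy, dosage_cols = [], [], []
    meta_rows, truth_rows = [], []
    protect = []
    counter = 0
    for group, sex, category, n, low in config.design:
        for _ in range(n):
            counter += 1
            sid = f"BT_{counter:03d}"
            pl = 1 if sex == "male" else 2
            dosage_cols.append(
                simulate_individual(category, pools, ploidy=pl, rng=rng)
            )
            samples.append(sid)
            ploidy.append(pl)
            if low is True:
                reads = int(rng.uniform(1.0e6, 2.5e6))
            elif low == "protected":
                reads = int(rng.uniform(1.0e6, 2.0e6))
                protect.append(sid)
            else:
                reads = int(rng.normal(7.6e6, 1.2e6))
            region = group[0] if group[0] in "NS" else ""
            dist = ("near" if "Near" in group else
                    "far" if "Far" in group else "")
            meta_rows.append((sid, group, sex, region or "-", dist or "-", max(reads, 3.0e6) if not low else reads))
            truth_rows.append((
                sid, group, sex, category,
                TRUE_HYBRID_INDEX[category],
                _mt_haplotype(group, category, rng),
                bool(low),
            ))

    n_samples = len(samples)
    ploidy = np.asarray(ploidy, dtype=np.int8)
    dosage = np.zeros((config.n_sites, n_samples), dtype=np.int8)
    for j, col in enumerate(dosage_cols):
        dosage[:, j] = col

    scaffolds = np.array(
        [f"scaffold_{(i % config.n_scaffolds) + 1:02d}" for i in range(config.n_sites)],
        dtype=object,
    )
    pos = np.zeros(config.n_sites, dtype=np.int64)
    per = {}
    loci = np.empty(config.n_sites, dtype=object)
    for i in range(config.n_sites):
        k = per.get(scaffolds[i], 0) + 1
        per[scaffolds[i]] = k
        pos[i] = 1000 * k + int(rng.integers(0, 900))
        # ~3 SNPs per RAD tag, tags local to a scaffold
        loci[i] = f"{scaffolds[i]}_tag{(k - 1) // 3 + 1:05d}"

    coverage = rng.normal(config.mean_coverage, 15.0, size=config.n_sites)
    coverage = np.clip(coverage, 5.0, 199.0)
    hi = rng.random(config.n_sites) < config.high_coverage_frac
    coverage[hi] = rng.uniform(201.0, 400.0, size=int(hi.sum()))

    geno = GenotypeMatrix(
        chrom=scaffolds, pos=pos, locus=loci, dosage=dosage,
        missing=np.zeros_like(dosage, dtype=bool), samples=samples,
        ploidy=ploidy, coverage=coverage,
    ).sort_sites()
    geno = apply_missingness(geno, config.missing_rate,
                             seed=int(rng.integers(2**31 - 1)))

    metadata = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "group", "sex", "region", "distance_class", "read_count"],
    )
    metadata["read_count"] = metadata["read_count"].astype(np.int64)
    metadata.attrs["protect"] = protect

    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "group", "sex", "category", "true_hybrid_index",
                 "mt_haplotype", "low_yield"],
    )
    assignments = dict(zip(truth["sample_id"], truth["mt_haplotype"]))
    mt = simulate_mtdna(config.mtdna, assignments,
                        seed=int(rng.integers(2**31 - 1)))
    return StudyBundle(geno=geno, metadata=metadata, mtdna=mt, truth=truth,
                       pools=pools)
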