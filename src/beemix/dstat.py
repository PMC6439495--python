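"""Frequency-based ABBA/BABA D-statistics with block-jackknife significance.

For a four-taxon topology (((P1, P2), P3), O), incomplete lineage sorting alone
makes the ABBA and BABA site patterns equally frequent; gene flow between P3
and P2 (or P1) skews the balance. With derived-allele frequencies p1..p4 the
per-site pattern weights are abba = (1-p1) p2 p3 (1-p4) and
baba = p1 (1-p2) p3 (1-p4), and D = sum(abba - baba) / sum(abba + baba).
Significance comes from a block jackknife over contiguous genomic blocks, which
is robust to linkage between nearby sites. P2 may be a whole population or a
single individual (dosage/ploidy as its allele frequency), which localizes the
introgression signal to individual lineages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import GenotypeMatrix
from .popstats import SiteFrequencyTable, allele_frequencies, individual_frequencies

__all__ = [
    "DStatResult",
    "BlockPartition",
    "site_pattern_terms",
    "make_blocks",
    "d_statistic",
    "d_statistic_individual",
    "all_population_combinations",
    "all_individual_dstats",
]


@dataclass
class DStatResult:
    p1_label: str
    p2_label: str
    p3_label: str
    o_label: str
    D: float
    abba: float
    baba: float
    n_sites: int
    se: float
    z: float
    p: float
    n_blocks: int

    def row(self):
        return (self.p1_label, self.p2_label, self.p3_label, self.o_label,
                self.n_sites, self.D, self.se, self.z, self.p)


@dataclass
class BlockPartition:
    """Contiguous equal-sized blocks over sites in (chrom, pos) order."""

    block_of_site: np.ndarray  # per used site, block index
    n_blocks: int


def make_blocks(n_sites: int, n_blocks: int = 50) -> BlockPartition:
    """Split n_sites (already coordinate-ordered) into contiguous blocks whose
    sizes differ by at most one site."""
    n_blocks = min(n_blocks, n_sites) if n_sites else 0
    assign = np.zeros(n_sites, dtype=int)
    if n_blocks:
        bounds = np.linspace(0, n_sites, n_blocks + 1).round().astype(int)
        for b in range(n_blocks):
            assign[bounds[b]:bounds[b + 1]] = b
    return BlockPartition(block_of_site=assign, n_blocks=n_blocks)


def site_pattern_terms(p1, p2, p3, p4):
    """Per-site ABBA and BABA weights from derived-allele frequencies."""
    p1, p2, p3, p4 = (np.asarray(x, dtype=float) for x in (p1, p2, p3, p4))
    abba = (1.0 - p1) * p2 * p3 * (1.0 - p4)
    baba = p1 * (1.0 - p2) * p3 * (1.0 - p4)
    return abba, baba


def _polarize(p1, p2, p3, p4):
    """Orient alleles so the outgroup's major allele is ancestral.

    Sites where the outgroup frequency exceeds 0.5 have all four frequencies
    flipped (p -> 1-p); outgroup frequency exactly 0.5 is used as-is (the
    (1-p4) weight already discounts outgroup polymorphism).
    """
    flip = p4 > 0.5
    out = []
    for p in (p1, p2, p3, p4):
        q = p.copy()
        q[flip] = 1.0 - q[flip]
        out.append(q)
    return out


def _jackknife(abba, baba, blocks: BlockPartition):
    """Block-jackknife SE/Z/p for D = sum(abba - baba) / sum(abba + baba)."""
    num_tot = float(np.sum(abba - baba))
    den_tot = float(np.sum(abba + baba))
    if den_tot == 0:
        return np.nan, np.nan, np.nan, np.nan
    D = num_tot / den_tot
    n = blocks.n_blocks
    if n < 2:
        return D, np.nan, np.nan, np.nan
    num_b = np.bincount(blocks.block_of_site, weights=abba - baba, minlength=n)
    den_b = np.bincount(blocks.block_of_site, weights=abba + baba, minlength=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_loo = (num_tot - num_b) / (den_tot - den_b)
    if np.any(~np.isfinite(d_loo)):
        warnings.warn("leave-one-block-out D undefined for some block", stacklevel=3)
        d_loo = d_loo[np.isfinite(d_loo)]
        n = d_loo.size
        if n < 2:
            return D, np.nan, np.nan, np.nan
    se = float(np.sqrt((n - 1) / n * np.sum((d_loo - d_loo.mean()) ** 2)))
    if se == 0:
        warnings.warn("jackknife SE is zero; Z reported as infinite", stacklevel=3)
        z = np.inf if D != 0 else np.nan
    else:
        z = D / se
    p = 2.0 * norm.sf(abs(z)) if np.isfinite(z) else (0.0 if z == np.inf else np.nan)
    return D, se, z, p


def _freq_columns(freqs: SiteFrequencyTable, labels):
    cols = []
    for lab in labels:
        cols.append(freqs.freq[:, freqs.column(lab)])
    return cols


def _dstat_from_freqs(f1, f2, f3, f4, labels, n_blocks):
    use = np.isfinite(f1) & np.isfinite(f2) & np.isfinite(f3) & np.isfinite(f4)
    f1, f2, f3, f4 = (f[use] for f in (f1, f2, f3, f4))
    f1, f2, f3, f4 = _polarize(f1, f2, f3, f4)
    abba, baba = site_pattern_terms(f1, f2, f3, f4)
    # monomorphic-across-all sites contribute zero to both sums; keep them out
    # of the block partition so blocks carry informative sites
    inf = (abba + baba) > 0
    abba, baba = abba[inf], baba[inf]
    blocks = make_blocks(abba.size, n_blocks)
    if abba.size == 0:
        return DStatResult(*labels, D=np.nan, abba=0.0, baba=0.0, n_sites=0,
                           se=np.nan, z=np.nan, p=np.nan, n_blocks=0)
    D, se, z, p = _jackknife(abba, baba, blocks)
    return DStatResult(
        *labels, D=D, abba=float(abba.sum()), baba=float(baba.sum()),
        n_sites=int(use.sum()), se=se, z=z, p=p, n_blocks=blocks.n_blocks,
    )


def d_statistic(freqs: SiteFrequencyTable, p1: str, p2: str, p3: str, o: str,
                n_blocks: int = 50) -> DStatResult:
    """Population-level D(P1, P2; P3, O) with block-jackknife significance.

    Sites must have at least one called allele in each of the four populations;
    others are skipped (missing-data-aware frequencies are assumed to be in
    ``freqs``). ``freqs`` rows must be in (chrom, pos) order for blocks to be
    genomically contiguous.
    """
    f1, f2, f3, f4 = _freq_columns(freqs, (p1, p2, p3, o))
    return _dstat_from_freqs(f1, f2, f3, f4, (p1, p2, p3, o), n_blocks)


def d_statistic_individual(freqs: SiteFrequencyTable, geno: GenotypeMatrix,
                           p1: str, individual: str, p3: str, o: str,
                           n_blocks: int = 50) -> DStatResult:
    """Individual-level D with the target individual as P2.

    The individual's per-site frequency is dosage/ploidy (0, 0.5, 1 for
    diploids; 0, 1 for haploids); its missing sites are skipped. A significant
    positive D flags gene flow between P3 and the individual's lineage.
    """
    f2 = individual_frequencies(geno, individual)
    f1, f3, f4 = _freq_columns(freqs, (p1, p3, o))
    if freqs.n_sites != f2.size:
        raise ValueError("frequency table and genotype matrix disagree on sites")
    return _dstat_from_freqs(f1, f2, f3, f4, (p1, individual, p3, o), n_blocks)


def all_population_combinations(freqs: SiteFrequencyTable, native_groups,
                                p3: str, o: str, n_blocks: int = 50):
    """D for every ordered (P1, P2) pair among the native groups, P3 and O fixed."""
    native_groups = list(native_groups)
    if p3 in native_groups or o in native_groups:
        raise ValueError("native groups must not include P3 or the outgroup")
    if len(native_groups) < 2:
        raise ValueError("need >= 2 candidate groups besides P3 and O")
    results = []
    for g1 in native_groups:
        for g2 in native_groups:
            if g1 == g2:
                continue
            results.append(d_statistic(freqs, g1, g2, p3, o, n_blocks=n_blocks))
    return results


def all_individual_dstats(freqs: SiteFrequencyTable, geno: GenotypeMatrix,
                          groups: dict, native_groups, p3: str, o: str,
                          n_blocks: int = 50):
    """Individual-level D for every member of every target group against every
    alternative P1 group."""
    native_groups = list(native_groups)
    results = []
    for target in native_groups:
        members = [s for s in geno.samples if groups[s] == target]
        for p1 in native_groups:
            if p1 == target:
                continue
            for ind in members:
                results.append(
                    d_statistic_individual(freqs, geno, p1, ind, p3, o,
                                           n_blocks=n_blocks)
                )
    return results


def results_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [r.row() for r in results],
        columns=["P1", "P2", "P3", "O", "n_sites", "D", "SE", "Z", "p"],
    )
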