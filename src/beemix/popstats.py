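"""Population-level statistics: allele frequencies, diversity, F_ST, FDR, PCA.

Allele frequencies are ploidy-aware and account for missing data (only called
alleles enter numerator and denominator). Pairwise differentiation uses the
Weir & Cockerham (1984) variance-components estimator, combined across loci as
a ratio of sums, with permutation significance and Benjamini-Yekutieli FDR
control. PCA follows the usual genotype-dosage convention (per-site centering,
mean imputation of missing calls).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import GenotypeMatrix

__all__ = [
    "SiteFrequencyTable",
    "allele_frequencies",
    "individual_frequencies",
    "diversity",
    "pairwise_fst",
    "per_site_fst",
    "fst_matrix",
    "by_fdr",
    "pca_embed",
]


@dataclass
class SiteFrequencyTable:
    """Per-site, per-group alternate-allele frequencies with called-allele counts."""

    chrom: np.ndarray
    pos: np.ndarray
    groups: list
    freq: np.ndarray  # (n_sites, n_groups); NaN where no called alleles
    n_alleles: np.ndarray  # (n_sites, n_groups) int

    @property
    def n_sites(self) -> int:
        return self.freq.shape[0]

    def column(self, group: str) -> int:
        return self.groups.index(group)


def allele_frequencies(geno: GenotypeMatrix, groups: dict) -> SiteFrequencyTable:
    """p-hat per group = sum(dosage over called samples) / sum(ploidy over called)."""
    labels = np.asarray([groups[s] for s in geno.samples], dtype=object)
    names = list(dict.fromkeys(labels))
    if not names:
        raise ValueError("no groups")
    dos = np.where(geno.missing, 0, geno.dosage).astype(float)
    alleles = (~geno.missing) * geno.ploidy[None, :].astype(float)
    freq = np.full((geno.n_sites, len(names)), np.nan)
    counts = np.zeros((geno.n_sites, len(names)), dtype=np.int64)
    for k, g in enumerate(names):
        cols = labels == g
        tot = alleles[:, cols].sum(axis=1)
        alt = dos[:, cols].sum(axis=1)
        counts[:, k] = tot.astype(np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[:, k] = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    return SiteFrequencyTable(
        chrom=geno.chrom.copy(), pos=geno.pos.copy(), groups=names,
        freq=freq, n_alleles=counts,
    )


def individual_frequencies(geno: GenotypeMatrix, sample: str):
    """Per-site allele 'frequency' of one individual: dosage / ploidy, NaN if missing."""
    j = geno.sample_index(sample)
    p = geno.dosage[:, j].astype(float) / float(geno.ploidy[j])
    p[geno.missing[:, j]] = np.nan
    return p


# ---------------------------------------------------------------------------
# Diversity (Ho / He / F_IS)
# ---------------------------------------------------------------------------


def diversity(geno: GenotypeMatrix, groups: dict) -> pd.DataFrame:
    """Per-group means of individual Ho, He and F_IS (diploids only).

    Individual Ho is the fraction of called sites that are heterozygous. He is
    the expected heterozygosity 2p(1-p) averaged over the individual's called
    sites, with p the whole-dataset allele frequency — so He is nearly constant
    across groups, and F_IS = 1 - Ho/He measures each individual's
    heterozygote deficit against the pooled gene pool. Haploid samples are
    excluded and flagged (heterozygosity is undefined for them).
    """
    labels = {s: groups[s] for s in geno.samples}
    overall = allele_frequencies(geno, {s: "all" for s in geno.samples}).freq[:, 0]
    he_site = 2.0 * overall * (1.0 - overall)
    rows = []
    for j, s in enumerate(geno.samples):
        if geno.ploidy[j] != 2:
            continue
        called = ~geno.missing[:, j]
        n_called = int(called.sum())
        if n_called == 0:
            continue
        ho = float((geno.dosage[called, j] == 1).mean())
        he = float(np.nanmean(he_site[called]))
        fis = 1.0 - ho / he if he > 0 else np.nan
        rows.append((s, labels[s], ho, he, fis))
    per_ind = pd.DataFrame(rows, columns=["sample_id", "group", "Ho", "He", "F_IS"])
    out = (
        per_ind.groupby("group", sort=False)
        .agg(N=("sample_id", "size"), Ho=("Ho", "mean"), He=("He", "mean"),
             F_IS=("F_IS", "mean"))
        .reset_index()
    )
    skipped = [s for j, s in enumerate(geno.samples) if geno.ploidy[j] != 2]
    out.attrs["haploids_excluded"] = skipped
    out.attrs["per_individual"] = per_ind
    return out


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) F_ST
# ---------------------------------------------------------------------------


def _wc_components(nA, pA, hA, nB, pB, hB, haploid: bool):
    """Per-site WC84 variance components (a, b, c) for two populations.

    nA/nB: called individuals per site; pA/pB: alt frequencies; hA/hB observed
    heterozygote frequencies (0 for haploids). Sites with a population absent
    or with mean sample size <= 1 yield NaN components (excluded from sums).
    """
    r = 2.0
    nA = nA.astype(float)
    nB = nB.astype(float)
    valid = (nA > 0) & (nB > 0)
    nbar = (nA + nB) / r
    valid &= nbar > 1
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (nA**2 + nB**2) / (r * nbar)) / (r - 1.0)
        pbar = (nA * pA + nB * pB) / (r * nbar)
        s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1.0) * nbar)
        if haploid:
            # no within-individual level: a = between-pop, b = within-pop
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r)
            c = np.zeros_like(a)
        else:
            hbar = (nA * hA + nB * hB) / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
            )
            c = hbar / 2.0
    for arr in (a, b, c):
        arr[~valid] = np.nan
    return a, b, c


def _pop_site_stats(geno: GenotypeMatrix, cols):
    """Called-individual counts, alt frequency and het frequency per site."""
    sub_d = geno.dosage[:, cols]
    sub_m = geno.missing[:, cols]
    called = (~sub_m).sum(axis=1)
    pl = geno.ploidy[cols]
    alleles = ((~sub_m) * pl[None, :]).sum(axis=1).astype(float)
    alt = np.where(sub_m, 0, sub_d).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(alleles > 0, alt / np.maximum(alleles, 1), np.nan)
    het = np.where(sub_m, False, sub_d == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(called > 0, het / np.maximum(called, 1), 0.0)
    return called, p, h


def _wc_theta(geno, colsA, colsB, haploid):
    nA, pA, hA = _pop_site_stats(geno, colsA)
    nB, pB, hB = _pop_site_stats(geno, colsB)
    a, b, c = _wc_components(nA, pA, hA, nB, pB, hB, haploid)
    num = np.nansum(a)
    den = np.nansum(a + b + c)
    if den == 0 or not np.isfinite(den):
        return np.nan, a, b, c
    return num / den, a, b, c


def pairwise_fst(geno: GenotypeMatrix, groups: dict, group_a: str, group_b: str,
                 n_perm: int = 10000, seed: int = 0):
    """Multi-locus WC84 theta between two groups with a permutation p-value.

    Theta is the ratio of summed among-population components to summed total
    components over sites (ratio of sums). Negative estimates are reported as
    computed. The permutation test randomly reassigns the pooled individuals to
    the two groups (sizes preserved) and reports p = (#{theta_perm >= theta} + 1)
    / (n_perm + 1). Both groups must be all-diploid or all-haploid; mixing
    ploidy in one comparison is refused.
    """
    labels = np.asarray([groups[s] for s in geno.samples], dtype=object)
    colsA = np.flatnonzero(labels == group_a)
    colsB = np.flatnonzero(labels == group_b)
    if len(colsA) < 2 or len(colsB) < 2:
        raise ValueError("each group needs >= 2 samples")
    pl = set(geno.ploidy[np.concatenate([colsA, colsB])].tolist())
    if len(pl) != 1:
        raise ValueError("mixed ploidy between/within compared groups; "
                         "compare haploid and diploid groups separately")
    haploid = pl == {1}
    theta, a, b, c = _wc_theta(geno, colsA, colsB, haploid)
    if not np.isfinite(theta):
        warnings.warn("F_ST undefined (no polymorphic overlap)", stacklevel=2)
        return np.nan, np.nan
    if n_perm <= 0:
        return theta, np.nan
    rng = np.random.default_rng(seed)
    pool = np.concatenate([colsA, colsB])
    nA = len(colsA)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        t, *_ = _wc_theta(geno, perm[:nA], perm[nA:], haploid)
        if np.isfinite(t) and t >= theta:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return theta, p


def per_site_fst(geno: GenotypeMatrix, groups: dict, group_a: str, group_b: str):
    """Per-site WC84 theta_l = a_l / (a_l + b_l + c_l); NaN where undefined."""
    labels = np.asarray([groups[s] for s in geno.samples], dtype=object)
    colsA = np.flatnonzero(labels == group_a)
    colsB = np.flatnonzero(labels == group_b)
    pl = set(geno.ploidy[np.concatenate([colsA, colsB])].tolist())
    if len(pl) != 1:
        raise ValueError("mixed ploidy in per-site F_ST comparison")
    _, a, b, c = _wc_theta(geno, colsA, colsB, pl == {1})
    den = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(np.abs(den) > 0, a / den, np.nan)
    return theta


def fst_matrix(geno: GenotypeMatrix, groups: dict, group_names=None,
               n_perm: int = 10000, seed: int = 0, alpha: float = 0.05):
    """All pairwise F_ST among the named groups, with BY-FDR significance tiers.

    Groups are compared only when their ploidy matches; mixed-ploidy pairs are
    left NaN (haploid and diploid differentiation are not comparable).
    Returns a DataFrame with columns group_a, group_b, fst, p, p_adj, tier.
    """
    labels = np.asarray([groups[s] for s in geno.samples], dtype=object)
    if group_names is None:
        group_names = [g for g in dict.fromkeys(labels)]
    rows = []
    rng = np.random.default_rng(seed)
    for i, ga in enumerate(group_names):
        for gb in group_names[i + 1:]:
            na = int((labels == ga).sum())
            nb = int((labels == gb).sum())
            pla = set(geno.ploidy[labels == ga].tolist())
            plb = set(geno.ploidy[labels == gb].tolist())
            if na < 2 or nb < 2 or len(pla | plb) != 1:
                rows.append((ga, gb, np.nan, np.nan))
                continue
            t, p = pairwise_fst(geno, groups, ga, gb, n_perm=n_perm,
                                seed=int(rng.integers(2**31 - 1)))
            rows.append((ga, gb, t, p))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "fst", "p"])
    ok = df["p"].notna()
    df["p_adj"] = np.nan
    df["tier"] = ""
    if ok.any():
        adj, tiers = by_fdr(df.loc[ok, "p"].to_numpy(), alpha=alpha)
        df.loc[ok, "p_adj"] = adj
        df.loc[ok, "tier"] = tiers
    return df


def by_fdr(pvalues, alpha: float = 0.05):
    """Benjamini-Yekutieli step-up adjustment with significance tiers.

    Returns (adjusted p-values, tier labels) where tiers are '***' for
    adjusted p < 0.001, '**' < 0.01, '*' < 0.05, '' otherwise.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=object)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in (0, 1]")
    _, adj, _, _ = multipletests(p, alpha=alpha, method="fdr_by")
    tiers = np.array(
        ["***" if a < 0.001 else "**" if a < 0.01 else "*" if a < 0.05 else ""
         for a in adj],
        dtype=object,
    )
    return adj, tiers


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca_embed(geno: GenotypeMatrix, n_components: int | None = None):
    """PCA of samples on centered, mean-imputed dosages.

    Missing cells are imputed with the site mean (i.e. 0 after centering), so a
    fully missing individual sits at the origin and high-missingness samples
    shrink toward it. All-missing sites are dropped with a warning. Component
    signs are fixed by making each component's largest-|loading| site positive.
    Returns (coords (n_samples, k), explained_variance_ratio (k,)).
    """
    if geno.n_samples < 2:
        raise ValueError("need >= 2 samples for PCA")
    X = np.where(geno.missing, np.nan, geno.dosage).astype(float)
    site_mean = np.nanmean(X, axis=1)
    dead = ~np.isfinite(site_mean)
    if dead.any():
        warnings.warn(f"dropping {int(dead.sum())} all-missing site(s)", stacklevel=2)
        X = X[~dead]
        site_mean = site_mean[~dead]
    Xc = X - site_mean[:, None]
    Xc[~np.isfinite(Xc)] = 0.0  # mean imputation
    # samples are observations: SVD of (n_samples x n_sites)
    U, S, Vt = np.linalg.svd(Xc.T, full_matrices=False)
    k_max = min(geno.n_samples, Xc.shape[0])
    k = k_max if n_components is None else min(n_components, k_max)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # sign convention: largest-|loading| element of each component positive
    for comp in range(k):
        j = int(np.argmax(np.abs(Vt[comp])))
        if Vt[comp, j] < 0:
            Vt[comp] *= -1.0
            U[:, comp] *= -1.0
    coords = U * S[None, :]
    var = S**2
    total = (Xc**2).sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    return coords, ratio
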