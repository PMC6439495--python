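"""Maximum-likelihood genome-wide hybrid index with parental resampling.

The hybrid index h of an individual is the proportion of its genome derived
from parental pool 2 (here: the commercial stock), estimated by maximizing the
binomial genotype likelihood in which each allele copy is the alternate allele
with probability q_l(h) = h * p2_l + (1 - h) * p1_l. The log-likelihood is
concave in h on [0, 1], so a golden-section search finds the global maximum.
Uncertainty from the finite parental panels is quantified by re-estimating h
from repeated subsamples of the parental individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .io import GenotypeMatrix
from .popstats import individual_frequencies

__all__ = [
    "ParentalPanel",
    "HybridIndexResult",
    "parental_panel",
    "ml_hybrid_index",
    "resampled_hybrid_index",
]

_GOLD = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class ParentalPanel:
    """Per-site parental alt-allele frequencies with sampled-allele counts.

    Frequencies of exactly 0 or 1 are shrunk to 1/(c+1) and c/(c+1), where c is
    the number of sampled alleles at the site, so no genotype has zero
    likelihood under either pure ancestry (finite-sample frequency estimation,
    as in standard hybrid-index practice). Sites undefined in both pools are
    excluded by construction.
    """

    p1: np.ndarray
    p2: np.ndarray
    n1: np.ndarray  # sampled alleles per site, pool 1
    n2: np.ndarray

    def __post_init__(self):
        keep = np.isfinite(self.p1) & np.isfinite(self.p2)
        self.p1 = self.p1[keep].astype(float)
        self.p2 = self.p2[keep].astype(float)
        self.n1 = self.n1[keep].astype(int)
        self.n2 = self.n2[keep].astype(int)
        self.site_mask = keep
        self.p1 = _shrink(self.p1, self.n1)
        self.p2 = _shrink(self.p2, self.n2)

    @property
    def n_sites(self) -> int:
        return self.p1.size


def _shrink(p, c):
    c = np.maximum(c, 1).astype(float)
    lo = 1.0 / (c + 1.0)
    hi = c / (c + 1.0)
    return np.clip(p, lo, hi)


def parental_panel(geno: GenotypeMatrix, pool1, pool2) -> ParentalPanel:
    """Build a panel from the alt-allele frequencies of two sample pools."""
    def _freq(names):
        cols = [geno.sample_index(s) for s in names]
        sub_d = geno.dosage[:, cols]
        sub_m = geno.missing[:, cols]
        pl = geno.ploidy[cols]
        alleles = ((~sub_m) * pl[None, :]).sum(axis=1).astype(float)
        alt = np.where(sub_m, 0, sub_d).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(alleles > 0, alt / np.maximum(alleles, 1), np.nan)
        return p, alleles.astype(int)

    p1, n1 = _freq(pool1)
    p2, n2 = _freq(pool2)
    return ParentalPanel(p1=p1, p2=p2, n1=n1, n2=n2)


@dataclass
class HybridIndexResult:
    sample_id: str
    h: float            # mean over resamples (or the single ML estimate)
    h_reps: np.ndarray  # per-resample estimates
    n_sites_used: int

    @property
    def h_min(self) -> float:
        return float(np.min(self.h_reps))

    @property
    def h_max(self) -> float:
        return float(np.max(self.h_reps))


def _hi_loglik(h, g, m, p1, p2):
    q = np.clip(h * p2 + (1.0 - h) * p1, 1e-12, 1 - 1e-12)
    ll = g * np.log(q) + (m - g) * np.log1p(-q)
    # binomial coefficient for diploid hets (constant in h; kept for a proper loglik)
    ll = ll + gammaln(m + 1) - gammaln(g + 1) - gammaln(m - g + 1)
    return float(ll.sum())


def _golden_max(f, lo=0.0, hi=1.0, tol=1e-8):
    a, b = lo, hi
    c = b - _GOLD * (b - a)
    d = a + _GOLD * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _GOLD * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLD * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def ml_hybrid_index(geno: GenotypeMatrix, sample: str, panel: ParentalPanel) -> float:
    """ML hybrid index of one individual against a parental panel.

    h in [0, 1] is the proportion of ancestry from pool 2. Genotype likelihood
    is Binomial(ploidy, q_l(h)) per site; missing sites are skipped. Raises if
    no called site overlaps the panel.
    """
    j = geno.sample_index(sample)
    g = geno.dosage[:, j].astype(float)[panel.site_mask]
    miss = geno.missing[:, j][panel.site_mask]
    m = np.full(g.shape, float(geno.ploidy[j]))
    use = ~miss
    if not use.any():
        raise ValueError(f"no called sites overlap the parental panel for {sample}")
    g, m = g[use], m[use]
    p1, p2 = panel.p1[use], panel.p2[use]
    return _golden_max(lambda h: _hi_loglik(h, g, m, p1, p2))


def resampled_hybrid_index(geno: GenotypeMatrix, sample: str, pool1, pool2,
                           k: int = 5, reps: int = 10, seed: int = 0) -> HybridIndexResult:
    """Hybrid index averaged over parental-panel resamples.

    For each repetition, k individuals are drawn without replacement from each
    parental pool, panel frequencies are recomputed from them, and h is
    re-estimated; the mean over repetitions and the per-repetition values are
    returned. Deterministic given ``seed``.
    """
    pool1, pool2 = list(pool1), list(pool2)
    if k > len(pool1) or k > len(pool2):
        raise ValueError(f"k={k} exceeds a parental pool size "
                         f"({len(pool1)}, {len(pool2)})")
    rng = np.random.default_rng(seed)
    hs = []
    n_used = 0
    for _ in range(reps):
        sub1 = [pool1[i] for i in rng.choice(len(pool1), size=k, replace=False)]
        sub2 = [pool2[i] for i in rng.choice(len(pool2), size=k, replace=False)]
        panel = parental_panel(geno, sub1, sub2)
        hs.append(ml_hybrid_index(geno, sample, panel))
        j = geno.sample_index(sample)
        n_used = max(n_used, int((~geno.missing[:, j][panel.site_mask]).sum()))
    hs = np.asarray(hs)
    return HybridIndexResult(sample_id=sample, h=float(hs.mean()), h_reps=hs,
                             n_sites_used=n_used)
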