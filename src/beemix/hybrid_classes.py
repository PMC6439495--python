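"""Six-category hybrid classification from genotype-frequency classes.

Each first-/second-generation category z is characterized by its expected
proportions of locus-level ancestry pairs phi(z) = (phi11, phi12, phi22): the
probabilities that a random locus carries two pool-1 alleles, one allele from
each pool, or two pool-2 alleles. With parental allele frequencies plugged in,
each category implies a genotype distribution per site, and an individual's
posterior over categories follows from the product of per-site likelihoods
under a uniform prior (no individual is assigned a category a priori).
The classifier runs on the most-differentiated SNP panel (top F_ST percentile
between the parental pools).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .io import GenotypeMatrix
from .popstats import per_site_fst

__all__ = [
    "CATEGORIES",
    "PHI",
    "DifferentiatedPanel",
    "ClassPosterior",
    "top_fst_panel",
    "class_genotype_prob",
    "classify",
]

CATEGORIES = ["Pure1", "Pure2", "F1", "F2", "BC1", "BC2"]

# ancestry-pair mixing vectors (phi11, phi12, phi22)
PHI = {
    "Pure1": (1.0, 0.0, 0.0),
    "Pure2": (0.0, 0.0, 1.0),
    "F1": (0.0, 1.0, 0.0),
    "F2": (0.25, 0.5, 0.25),
    "BC1": (0.5, 0.5, 0.0),   # backcross with pool 1
    "BC2": (0.0, 0.5, 0.5),   # backcross with pool 2
}


@dataclass
class DifferentiatedPanel:
    """Top-differentiation SNP panel between two parental pools."""

    site_idx: np.ndarray      # indices into the source matrix, selection order
    fst: np.ndarray           # per-site F_ST of the selected sites (descending)
    quantile: float
    threshold: float          # smallest F_ST admitted

    @property
    def n_sites(self) -> int:
        return self.site_idx.size


def top_fst_panel(geno: GenotypeMatrix, groups: dict, pool1: str, pool2: str,
                  quantile: float = 0.01) -> DifferentiatedPanel:
    """Select the top `quantile` fraction of sites by per-site WC F_ST.

    The panel size is ceil(quantile * n_sites). Sites are ranked by descending
    F_ST with ties at the cutoff broken by (chrom, pos) order; undefined
    (NaN) F_ST ranks last. Warns when fewer than 10 sites are available.
    """
    theta = per_site_fst(geno, groups, pool1, pool2)
    n_panel = max(1, math.ceil(quantile * geno.n_sites))
    if geno.n_sites < 10:
        warnings.warn("fewer than 10 sites available for the panel", stacklevel=2)
    rank_fst = np.where(np.isfinite(theta), theta, -np.inf)
    # stable sort on (chrom, pos), then stable descending sort on F_ST:
    # equal-F_ST ties resolve by coordinate order
    coord = np.lexsort((geno.pos, geno.chrom.astype(str)))
    by_fst = coord[np.argsort(-rank_fst[coord], kind="stable")]
    sel = by_fst[:n_panel]
    return DifferentiatedPanel(
        site_idx=sel,
        fst=theta[sel],
        quantile=quantile,
        threshold=float(np.nanmin(theta[sel])),
    )


def class_genotype_prob(category: str, p1, p2):
    """Diploid genotype probabilities (P(dosage 0), P(1), P(2)) for a category.

    p1, p2 are the alt-allele frequencies in the two parental pools. With
    phi = (phi11, phi12, phi22):
      P(2) = phi11 p1^2 + phi12 p1 p2 + phi22 p2^2
      P(1) = phi11 2 p1 (1-p1) + phi12 [p1 (1-p2) + p2 (1-p1)] + phi22 2 p2 (1-p2)
      P(0) = 1 - P(1) - P(2)
    When p1 == p2 every category reduces to Hardy-Weinberg at that frequency.
    """
    f11, f12, f22 = PHI[category]
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p_2 = f11 * p1**2 + f12 * p1 * p2 + f22 * p2**2
    p_1 = (f11 * 2 * p1 * (1 - p1)
           + f12 * (p1 * (1 - p2) + p2 * (1 - p1))
           + f22 * 2 * p2 * (1 - p2))
    p_0 = 1.0 - p_1 - p_2
    return np.clip(p_0, 0.0, 1.0), np.clip(p_1, 0.0, 1.0), np.clip(p_2, 0.0, 1.0)


@dataclass
class ClassPosterior:
    sample_id: str
    posterior: dict  # category -> probability
    map_category: str
    n_panel_sites_used: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.posterior, name=self.sample_id)


def classify(geno: GenotypeMatrix, sample: str, panel: DifferentiatedPanel,
             p1: np.ndarray, p2: np.ndarray, prior: dict | None = None) -> ClassPosterior:
    """Posterior over the six categories for one diploid individual.

    ``p1``/``p2`` are parental alt-allele frequencies at the panel sites (same
    order as ``panel.site_idx``), already shrunk away from 0/1 by the caller
    (see :mod:`beemix.hybrid_index`). Missing panel sites are skipped; no
    called panel site is an error. The prior defaults to uniform.
    """
    j = geno.sample_index(sample)
    if geno.ploidy[j] != 2:
        raise ValueError("hybrid-class posterior is defined for diploids only")
    g = geno.dosage[panel.site_idx, j]
    miss = geno.missing[panel.site_idx, j]
    use = (~miss & np.isfinite(np.asarray(p1, dtype=float))
           & np.isfinite(np.asarray(p2, dtype=float)))
    if not use.any():
        raise ValueError(f"no called panel sites for {sample}")
    g = g[use].astype(int)
    pp1 = np.asarray(p1, dtype=float)[use]
    pp2 = np.asarray(p2, dtype=float)[use]
    if prior is None:
        prior = {z: 1.0 / len(CATEGORIES) for z in CATEGORIES}
    logpost = np.empty(len(CATEGORIES))
    for zi, z in enumerate(CATEGORIES):
        probs = np.stack(class_genotype_prob(z, pp1, pp2))  # (3, n_sites)
        site_p = np.clip(probs[g, np.arange(g.size)], 1e-300, None)
        logpost[zi] = math.log(prior[z]) + float(np.log(site_p).sum())
    logpost -= logsumexp(logpost)
    post = np.exp(logpost)
    post /= post.sum()
    posterior = {z: float(p) for z, p in zip(CATEGORIES, post)}
    map_cat = CATEGORIES[int(np.argmax(post))]
    return ClassPosterior(sample_id=sample, posterior=posterior,
                          map_category=map_cat, n_panel_sites_used=int(use.sum()))
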