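"""Maximum-likelihood admixture ancestry (EM), replicate alignment and Evanno delta-K.

The model is the standard admixture likelihood: each of an individual's allele
copies is drawn from cluster k with probability Q[i, k] and is the alternate
allele with probability F[l, k], so dosages are Binomial(ploidy, (QF')_{il}).
Q and F are estimated by EM (monotone in log-likelihood). Replicate runs are
label-aligned by exact search over column permutations, and the number of
clusters is chosen by the Evanno second-difference statistic delta-K.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

__all__ = [
    "AncestryResult",
    "KSelection",
    "em_admixture",
    "align_replicates",
    "evanno_delta_k",
    "run_k_scan",
]

_EPS = 1e-9


@dataclass
class AncestryResult:
    Q: np.ndarray  # (n_samples, K) ancestry proportions
    F: np.ndarray  # (n_sites, K) cluster alt-allele frequencies
    loglik: float
    K: int
    seed: int
    n_iter: int
    samples: list


def _loglik(G, M, Q, F):
    P = np.clip(Q @ F.T, _EPS, 1 - _EPS)  # (N, L) alt-copy probability
    return float(np.sum(G * np.log(P) + (M - G) * np.log1p(-P)))


def em_admixture(geno: GenotypeMatrix, K: int, seed: int = 0, tol: float = 1e-6,
                 max_iter: int = 2000) -> AncestryResult:
    """Fit the K-cluster admixture model by EM.

    Haploids contribute single allele copies; missing calls contribute nothing.
    Initialization: Q rows ~ Dirichlet(1,...,1); F = overall allele frequency
    plus uniform jitter of +-0.05, clipped to [0.01, 0.99]. Converged when the
    log-likelihood gain drops below ``tol``. K=1 reduces to the closed form
    (Q = 1, F = overall frequencies) in a single step.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > geno.n_samples:
        raise ValueError(f"K={K} exceeds the number of samples ({geno.n_samples})")
    rng = np.random.default_rng(seed)
    N, L = geno.n_samples, geno.n_sites
    G = np.where(geno.missing, 0, geno.dosage).astype(float).T  # (N, L) alt copies
    M = ((~geno.missing) * geno.ploidy[None, :]).astype(float).T  # (N, L) called copies

    with np.errstate(invalid="ignore", divide="ignore"):
        overall = G.sum(axis=0) / np.maximum(M.sum(axis=0), 1)
    overall[~np.isfinite(overall)] = 0.5
    Q = rng.dirichlet(np.ones(K), size=N)
    F = np.clip(overall[:, None] + rng.uniform(-0.05, 0.05, size=(L, K)), 0.01, 0.99)

    total_copies = M.sum(axis=1)  # per-sample called allele copies
    ll = _loglik(G, M, Q, F)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        P = np.clip(Q @ F.T, _EPS, 1 - _EPS)  # (N, L)
        Galt = G / P          # expected-count scaling for alt copies
        Gref = (M - G) / (1 - P)
        Q_new = np.empty_like(Q)
        F_num = np.empty_like(F)
        F_den = np.empty_like(F)
        for k in range(K):
            # responsibilities folded into expected copy counts for cluster k
            alt_k = Galt * (Q[:, k][:, None] * F[:, k][None, :])   # (N, L)
            ref_k = Gref * (Q[:, k][:, None] * (1 - F[:, k])[None, :])
            Q_new[:, k] = alt_k.sum(axis=1) + ref_k.sum(axis=1)
            F_num[:, k] = alt_k.sum(axis=0)
            F_den[:, k] = alt_k.sum(axis=0) + ref_k.sum(axis=0)
        Q = Q_new / np.maximum(total_copies, 1)[:, None]
        Q = np.clip(Q, _EPS, None)
        Q /= Q.sum(axis=1, keepdims=True)
        F = np.clip(F_num / np.maximum(F_den, _EPS), _EPS, 1 - _EPS)
        ll_new = _loglik(G, M, Q, F)
        gain = ll_new - ll
        ll = ll_new
        if gain < tol and n_iter > 1:
            break
    return AncestryResult(Q=Q, F=F, loglik=ll, K=K, seed=seed, n_iter=n_iter,
                          samples=list(geno.samples))


def align_replicates(results):
    """Align cluster labels across replicate runs of equal K.

    The best-log-likelihood replicate is the reference; every other replicate's
    columns are permuted to maximize the summed columnwise dot product with the
    reference Q, searching all K! permutations exactly (K <= 8). Returns a new
    list of AncestryResult with permuted Q and F.
    """
    ks = {r.K for r in results}
    if len(ks) != 1:
        raise ValueError(f"replicates have mixed K: {sorted(ks)}")
    K = ks.pop()
    if K > 8:
        raise ValueError("exact permutation search limited to K <= 8")
    ref = max(results, key=lambda r: r.loglik)
    aligned = []
    for r in results:
        best, best_score = None, -np.inf
        for perm in itertools.permutations(range(K)):
            score = sum(float(ref.Q[:, k] @ r.Q[:, perm[k]]) for k in range(K))
            if score > best_score:
                best_score, best = score, perm
        perm = list(best)
        aligned.append(
            AncestryResult(Q=r.Q[:, perm], F=r.F[:, perm], loglik=r.loglik,
                           K=r.K, seed=r.seed, n_iter=r.n_iter, samples=r.samples)
        )
    return aligned


@dataclass
class KSelection:
    """Replicate log-likelihoods per K and the Evanno delta-K table."""

    k_values: list
    logliks: dict  # K -> list of replicate logliks
    results: dict  # K -> list of AncestryResult

    def table(self) -> pd.DataFrame:
        rows = []
        dk = evanno_delta_k(self)
        for K in self.k_values:
            ll = np.asarray(self.logliks[K], dtype=float)
            rows.append((K, len(ll), ll.mean(), ll.std(ddof=1) if len(ll) > 1 else 0.0,
                         dk.get(K, np.nan)))
        return pd.DataFrame(rows, columns=["K", "replicates", "mean_loglik",
                                           "sd_loglik", "delta_k"])

    def best_k(self) -> int:
        dk = evanno_delta_k(self)
        return max(dk, key=lambda k: dk[k])


def evanno_delta_k(selection: KSelection) -> dict:
    """delta-K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)).

    Defined for interior K only; needs >= 3 consecutive K values with >= 2
    replicates each. A zero replicate sd yields an infinite delta-K with a
    warning.
    """
    ks = sorted(selection.k_values)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    mean = {K: float(np.mean(selection.logliks[K])) for K in ks}
    sd = {K: float(np.std(selection.logliks[K], ddof=1)) for K in ks}
    out = {}
    for K in ks[1:-1]:
        if len(selection.logliks[K]) < 2:
            raise ValueError(f"K={K} has fewer than 2 replicates")
        num = abs(mean[K + 1] - 2 * mean[K] + mean[K - 1])
        if sd[K] == 0:
            warnings.warn(f"sd of L(K={K}) is zero; delta-K infinite", stacklevel=2)
            out[K] = np.inf if num > 0 else np.nan
        else:
            out[K] = num / sd[K]
    return out


def run_k_scan(geno: GenotypeMatrix, k_min: int = 1, k_max: int = 6,
               n_replicates: int = 10, n_restarts: int = 2, seed: int = 0,
               site_fraction: float = 0.8, tol: float = 1e-4,
               max_iter: int = 500) -> KSelection:
    """Replicated EM fits over a K range for Evanno model choice.

    Each replicate slot subsamples ``site_fraction`` of the sites without
    replacement (this is what gives the replicate log-likelihoods their spread)
    and keeps the best of ``n_restarts`` random EM starts. Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_sub = max(1, int(round(site_fraction * geno.n_sites)))
    k_values = list(range(k_min, k_max + 1))
    logliks = {K: [] for K in k_values}
    results = {K: [] for K in k_values}
    for rep in range(n_replicates):
        sites = np.sort(rng.choice(geno.n_sites, size=n_sub, replace=False))
        sub = geno.take_sites(sites)
        for K in k_values:
            best = None
            for _ in range(n_restarts):
                r = em_admixture(sub, K, seed=int(rng.integers(2**31 - 1)),
                                 tol=tol, max_iter=max_iter)
                if best is None or r.loglik > best.loglik:
                    best = r
            logliks[K].append(best.loglik)
            results[K].append(best)
    return KSelection(k_values=k_values, logliks=logliks, results=results)
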