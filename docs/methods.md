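# Methods

This note documents the models, estimators and design choices behind
`beemix`, and what the synthetic-data tests do and do not demonstrate about
real data.

## Data model

Genotypes live in a sites × samples matrix of alternate-allele dosages with a
boolean missingness mask and per-sample ploidy (2 for females, 1 for haploid
males). Missingness is never encoded as a sentinel dosage. Sites are ordered
by (scaffold, position); that order is load-bearing — jackknife blocks and
tie-breaking in panel selection depend on it. VCF positions are kept 1-based
verbatim. Haploid genotypes are written as single-allele GT fields; a
diploid-style call for a sample previously seen as haploid is an error, not a
silent cast, because ploidy mix-ups silently corrupt every downstream
frequency.

## Filtering

Site rules run in a fixed order: presence-per-population (a site counts a
group as "present" when ≥ 1 member is called **and** the called fraction in
that group reaches `min_ind_frac_per_pop`, default 0.5; the site needs
`min_pops` such groups) → minor-allele frequency (≥ 0.05 over all called
alleles, ploidy-aware) → per-site missingness (≤ 25% of individuals) → mean
coverage (≤ 200×) → duplicate-position removal → one-SNP-per-locus thinning
(uniform choice per RAD tag, seeded; invariant to input site order because
the choice is made along the coordinate sort). This staging mirrors the
upstream tools the rules come from: the first two run inside the SNP caller,
the next three belong to VCF post-processing, and thinning comes last so that
the retained SNP is itself a survivor of every other rule.

The individual-level cut removes samples whose read count falls strictly
below the 15% quantile of all sampled individuals, with the quantile computed
by linear interpolation between order statistics (the convention must be
stated: with 66 samples the quantile sits between the 10th and 11th order
statistics, so "how many fall below" depends on it). A `protect` list exempts
samples that cannot be spared — in the default study design, one of the two
outgroup specimens is low-yield but retained, because two individuals are
already the minimum for outgroup allele frequencies. Named datasets
(TOTAL / FEMALES / NO_OUTGROUP) re-apply all site filters after subsetting
samples; MAF and presence change with the sample set, so each dataset has its
own SNP count, which is why the three datasets genuinely differ and must not
share one site list.

## Allele frequencies, diversity, F_ST

Frequencies are computed per group and site as Σ dosage / Σ ploidy over
called samples only, so groups with different genotyping rates remain
comparable. Observed heterozygosity per diploid individual is the fraction of
its called sites that are heterozygous; expected heterozygosity per
individual is Σ 2p(1−p)/n over its called sites with p taken from the **whole
dataset**, not the group. That convention makes He nearly identical across
groups and turns F_IS = 1 − Ho/He into a per-individual heterozygote deficit
against the pooled gene pool; group values are means over members. Haploid
males are excluded from Ho/F_IS and flagged — heterozygosity is undefined at
ploidy 1, and the ~0.96 "F_IS" haploid males show when forced through a
diploid pipeline is an encoding artefact, so male F_IS is reported as
undefined instead.

Pairwise F_ST is the Weir & Cockerham (1984) variance-components estimator
with per-site components a (among populations), b (among individuals within
populations) and c (within individuals), combined across loci as
Σa / Σ(a+b+c) (ratio of sums, the standard multi-locus form). Negative
estimates are reported as computed. For haploid groups the within-individual
level vanishes and the two-level form is used; haploid and diploid groups are
never mixed in one comparison, since ploidy itself inflates differentiation.
Significance comes from permutations of individuals between the two groups
(sizes preserved), with p = (b+1)/(n+1) smoothing; the family of pairwise
tests is adjusted by Benjamini–Yekutieli (statsmodels' step-up with
c(m) = Σ 1/i), tiered at 0.05/0.01/0.001. PCA centers dosages per site,
imputes missing cells with the site mean (equivalently zero after centering,
which is what pulls high-missingness samples toward the origin), and fixes
component signs by making each component's largest-|loading| site positive.

## Admixture EM

The ancestry stage replaces MCMC Bayesian clustering with maximum-likelihood
EM on the same admixture model: sample i's dosage at site l is
Binomial(ploidy, (QFᵀ)il). The EM updates are the classic expected
allele-assignment counts; the log-likelihood is monotone non-decreasing (the
test suite asserts this per iteration). Q rows initialize from Dirichlet(1),
F from the overall frequency ± 0.05 uniform jitter clipped to [0.01, 0.99];
probabilities are floored at 1e-9 during iteration. The correlated-allele-
frequency prior of the MCMC original is not implemented; consequences: the
EM surrogate gives point estimates (no credible intervals) and can be less
sensitive to very recent shared drift, but retains the identical Q
parameterization. K = 1 reduces to a closed form in one step.

Replicate alignment resolves label switching by permuting each replicate's
columns to maximize the summed columnwise dot product with the
best-likelihood replicate, searched exactly over K! permutations (K ≤ 8).
Model choice uses the Evanno statistic
ΔK = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd(L(K)), means and sd over
replicates. Replicate spread comes from fitting each replicate on an 80%
site subsample; each replicate slot keeps the best of `n_restarts` (default
2) random starts. (Running 10 independent restarts inside each of 10
replicate slots would cost ~100 EM fits per K for no extra statistical
content; the subsample already supplies the spread ΔK needs.)

## Hybrid index

For an individual with dosage g_l and ploidy m_l at panel site l, the
log-likelihood of commercial ancestry fraction h is
Σ log Binomial(g_l; m_l, q_l(h)) with q_l(h) = h·p2_l + (1−h)·p1_l. This is
concave in h, and a golden-section search on [0, 1] (tolerance 1e-8) finds
the maximum; the tight tolerance keeps the symmetry h(pool1,pool2) =
1 − h(pool2,pool1) good to 1e-6. Parental frequencies of exactly 0 or 1 are
shrunk to 1/(c+1) and c/(c+1) (c = sampled alleles at the site) so a single
discordant genotype cannot drive the likelihood to −∞. Uncertainty from
finite parental panels is quantified by re-estimating h from 10 draws of 5
individuals per parental pool (without replacement) and averaging. Samples
suspected of being hybrids are excluded from the parental pools via a
configuration list, never inferred implicitly. At real-data differentiation
(F_ST ≈ 0.045) the estimate is strongly compressed toward the interior —
pure individuals score 0.7–0.9 rather than 1.0 — which reproduces the
behaviour of frequency-based hybrid indices on weakly differentiated pools;
category *ordering* is reliable, absolute values are not.

## Genotype-frequency classes

Each first-/second-generation category z has a fixed ancestry-pair mixing
vector φ(z) = (φ11, φ12, φ22): Pure1 (1,0,0), Pure2 (0,0,1), F1 (0,1,0),
F2 (¼,½,¼), BC1 (½,½,0), BC2 (0,½,½). With parental frequencies p1, p2 the
genotype distribution is P(2) = φ11 p1² + φ12 p1p2 + φ22 p2², P(1) = φ11·2p1(1−p1)
+ φ12·[p1(1−p2) + p2(1−p1)] + φ22·2p2(1−p2), P(0) the complement; when
p1 = p2 every category collapses to Hardy–Weinberg, which is why the
classifier runs on the most-differentiated panel (top ceil(1%) of sites by
per-site WC F_ST between the parental pools, ties at the cutoff broken by
coordinate order). Posteriors use a uniform prior and log-domain
accumulation, with the same frequency shrinkage as the hybrid index. This is
a plug-in simplification of the full Bayesian treatment that samples allele
frequencies jointly: deterministic and adequate at panel-level
differentiation, but it understates uncertainty when parental pools are tiny.
Only the six first-/second-generation categories are modelled; an individual
from a later generation will be absorbed into whichever of the six fits best.
F2-vs-backcross confusion at moderate panels is real and reported, not
hidden.

## D-statistics

With derived-allele frequencies p1, p2, p3, p4 in (((P1,P2),P3),O), per-site
weights are abba = (1−p1)p2p3(1−p4) and baba = p1(1−p2)p3(1−p4), and
D = Σ(abba−baba)/Σ(abba+baba). Alleles are oriented per site so the
outgroup's major allele is ancestral; an outgroup frequency of exactly 0.5
is used as-is (the (1−p4) weight already discounts outgroup polymorphism).
Only sites with ≥ 1 called allele in all four populations enter; sites
contributing zero to both sums are skipped. Significance uses a block
jackknife: sites in coordinate order are cut into 50 contiguous blocks of
near-equal size, D is recomputed leaving out each block,
SE² = ((n−1)/n)·Σ(D₋ᵢ − mean)², Z = D/SE, p two-tailed normal. With
single-site blocks this reduces exactly to the classic leave-one-out
jackknife (tested). For the individual-level test, P2's per-site frequency is
dosage/ploidy; a significant positive D flags gene flow between P3 (the
commercial pool) and that individual's lineage. Swapping P1 and P2 negates D
exactly.

Power at desk scale deserves a caveat: for a first-generation hybrid as P2
with parental pools at F_ST 0.045 and 2,000 unlinked sites, the test detects
the hybrid in roughly 85% of replicates when the hybrid's commercial parent
is one of the genotyped commercial individuals (the realistic sampling
situation for escapee descendants), and far less often when the commercial
ancestry comes from the broad pool. Pure escapees are detected essentially
always. At the site counts typical of real reduced-representation datasets
(≳ 16,000 usable sites) F1 power reaches ~100%. The known weakness of D for
recent admixture between weakly differentiated populations is a property of
the statistic, not of this implementation.

## Synthetic data

The generator draws an ancestral frequency p ~ Uniform(0.05, 0.95) per site
and pool frequencies from Beta(p(1−F)/F, (1−p)(1−F)/F) (Balding–Nichols),
with F = 0.045 between commercial and native pools — the differentiation
scale the method targets — and F = 0.5 for the outgroup. Balding–Nichols was
chosen over coalescent simulation because it gives direct control of F_ST
and all analyses here are unlinked-site methods; block-jackknife machinery
is still exercised by laying sites round-robin across 12 synthetic scaffolds
(~3 SNPs per RAD tag). Individuals are built by explicit gamete simulation —
an F1 carries one allele from each pool per site, an F1 gamete picks either
of those uniformly, F2 = two independent F1 gametes, backcross = F1 gamete +
pure gamete — never by frequency shortcuts, so the genotype-class model can
be validated against the generator (they agree to < 1% at 10,000 draws).
Haploid males are single gametes. The default design reproduces the field
sampling: 66 individuals (11 commercial, 53 wild including 4 escapee females,
3 escapee males, one F2 and two backcross-native hybrids, 9 haploid males,
and 9 low-yield samples; 2 outgroup specimens, one low-yield but protected),
which the 15%-quantile read cut reduces to 57. Default per-cell missingness
is 0.10 (the filter cap is 0.25); per-site coverage is Normal(56.6, 15) with
0.5% of sites planted above the 200× cap so the coverage filter has work to
do. The mtDNA module plants substitutions on a template tree: four ingroup
haplotypes with pairwise distances 1–4 and two outgroup haplotypes 45 and 47
substitutions from the modal haplotype, on 620 bp sequences; haplotype
assignment probabilities echo the observed pattern (one haplotype common
everywhere, one enriched in commercial stock and its escapees).

What the generator does **not** emulate: linkage disequilibrium (sites are
exchangeable, so the block jackknife is conservative machinery here rather
than a necessity), selection, sequencing error, batch effects between
library preparations, and population structure within pools (real commercial
stock is a mix of source subspecies; real wild samples carry isolation by
distance). Passing tests therefore demonstrate estimator correctness and
calibration under the stated model, not robustness to those features.

## mtDNA

Sequences identical at every position where both are unambiguous collapse
into one haplotype; a sequence with N/gap characters joins the compatible
haplotype with the highest count (earliest on ties) and is flagged, so
partial reads cannot inflate the haplotype count; an ambiguous sequence
compatible with nothing founds its own haplotype. Distances count positions
where both bases are in ACGT and differ. The network is a minimum spanning
network — every edge that belongs to at least one minimum spanning tree of
the complete distance graph (an edge of weight w is included iff its
endpoints are not connected using edges of weight < w). For hand-countable
haplotype sets (≤ ~5 ingroup haplotypes) this coincides with the
median-joining topology while being exactly testable; true median-joining
with median vectors and the ε parameter is intentionally not implemented.

## Orchestration and reproducibility

`run_all` chains the stages (input → yield filter → named datasets →
diversity/F_ST → PCA → EM/ΔK → hybrid index → classification → D-statistics
→ mtDNA) and writes TSV outputs plus a JSON manifest with seeds and input
SHA-256 hashes. All randomness derives from one run seed through per-stage
substreams (seed × 1000003 + crc32(stage name)), so stages are independently
reproducible and a rerun with the same seed is byte-identical (tested). For
the Table-1-style statistics, haploid males are split into their own "-M"
groups so male and female differentiation are never pooled.

## Problem sizes in tests and the acceptance script

The suite uses 800–2,000 sites, 10–20 diploids per pool, 100–200 replicates
per calibration, 3 ΔK replicates × 1 restart over K = 1..4 for 20 seeds, and
a 177-site classification panel at parental F_ST 0.4 — sizes chosen so the
whole battery expresses each property clearly while completing in about a
minute per component on one core. The acceptance script reports every
quantity together with the problem size (`n`) it used.
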