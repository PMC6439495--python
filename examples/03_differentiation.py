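"""Diversity (Ho / He / F_IS) and pairwise Weir-Cockerham F_ST between groups.

He is computed against whole-dataset allele frequencies, so it is nearly equal
across groups and F_IS measures each group's heterozygote deficit. F_ST
significance comes from permutation tests with Benjamini-Yekutieli FDR tiers.
Haploid males are split into their own "-M" groups: ploidy inflates
differentiation, so male and female comparisons are never pooled.
"""

from beemix import SimulationConfig, simulate_study
from beemix.popstats import diversity, fst_matrix

bundle = simulate_study(SimulationConfig(n_sites=3000, seed=42))
geno, meta = bundle.geno, bundle.metadata
sex = dict(zip(meta.sample_id, meta.sex))
groups = {s: g + ("-M" if sex[s] == "male" else "")
          for s, g in zip(meta.sample_id, meta.group)}

print(diversity(geno, groups).round(3).to_string(index=False))

fst = fst_matrix(geno, groups, n_perm=499, seed=1)
fst = fst.dropna(subset=["fst"])
print("\npairwise F_ST (commercial vs native expected ~0.045, wild pairs ~0):")
print(fst.round(4).to_string(index=False))
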