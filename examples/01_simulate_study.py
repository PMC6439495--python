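"""Generate a study-shaped synthetic bundle and inspect its design.

Two gene pools (native and commercial) at differentiation F_ST ~ 0.045, with
escapees and pedigree hybrids planted among the wild groups, haploid males,
per-cell missingness, read counts with low-yield individuals, and a COX1-like
mitochondrial alignment. The truth table records every sample's category.
"""

from beemix import SimulationConfig, simulate_study
from beemix.filtering import drop_low_yield_individuals

bundle = simulate_study(SimulationConfig(n_sites=5000, seed=42))

print(f"{bundle.geno.n_samples} sampled individuals x {bundle.geno.n_sites} SNPs")
print(bundle.metadata.group.value_counts().to_string())

kept, dropped = drop_low_yield_individuals(
    bundle.metadata, protect=bundle.metadata.attrs["protect"])
print(f"\nread-count 15% quantile cut: {len(dropped)} dropped -> "
      f"{len(kept)} genotyped individuals")

planted = bundle.truth[bundle.truth.category.isin(
    ["escapee", "F1", "F2", "BC1", "BC2"])]
print("\nplanted non-pure individuals (the ground truth later stages must recover):")
print(planted[["sample_id", "group", "sex", "category",
               "true_hybrid_index"]].to_string(index=False))
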