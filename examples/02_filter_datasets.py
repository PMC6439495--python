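"""Build the named SNP datasets (TOTAL / FEMALES / NO_OUTGROUP).

Filters are re-applied after each sample subset, so every dataset has its own
SNP count: minor-allele frequency, presence per population, missingness and
coverage caps all shift when samples change.
"""

from beemix import SimulationConfig, simulate_study
from beemix.filtering import DATASET_SPECS, build_dataset

bundle = simulate_study(SimulationConfig(n_sites=5000, seed=42))

for name in ("TOTAL", "FEMALES", "NO_OUTGROUP"):
    ds, report = build_dataset(bundle.geno, bundle.metadata, DATASET_SPECS[name])
    print(f"\n{name}: {ds.n_samples} individuals, {ds.n_sites} SNPs")
    print(report.to_frame().to_string(index=False))
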