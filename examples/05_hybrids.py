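"""Hybrid index and six-category genotype-class posteriors.

The hybrid index h (commercial ancestry fraction) is the ML estimate under a
binomial genotype likelihood, averaged over 10 resamples of 5 parental
individuals per pool. Classification runs on the top-1% F_ST panel between the
parental pools: each category (pure x2, F1, F2, both backcrosses) has a fixed
ancestry-pair mixing vector and therefore a closed-form genotype distribution.
"""

from beemix import SimulationConfig, simulate_study
from beemix.filtering import DATASET_SPECS, build_dataset
from beemix.hybrid_classes import classify, top_fst_panel
from beemix.hybrid_index import parental_panel, resampled_hybrid_index
import numpy as np

bundle = simulate_study(SimulationConfig(n_sites=5000, seed=42))
noout, _ = build_dataset(bundle.geno, bundle.metadata,
                         DATASET_SPECS["NO_OUTGROUP"])
truth = bundle.truth.set_index("sample_id")
groups = dict(zip(bundle.metadata.sample_id, bundle.metadata.group))

pool_native = [s for s in noout.samples
               if groups[s] == "NFar" and truth.loc[s, "category"] == "pure_native"]
pool_comm = [s for s in noout.samples if groups[s] == "CH"]

panel = top_fst_panel(noout, {s: groups[s] for s in noout.samples},
                      "NFar", "CH", quantile=0.01)
print(f"most-differentiated panel: {panel.n_sites} SNPs, "
      f"F_ST threshold {panel.threshold:.2f}")

pp = parental_panel(noout.take_sites(panel.site_idx), pool_native, pool_comm)
p1 = np.full(panel.n_sites, np.nan)
p2 = np.full(panel.n_sites, np.nan)
p1[pp.site_mask] = pp.p1
p2[pp.site_mask] = pp.p2

print(f"\n{'sample':8s} {'truth':16s} {'h':>6s}  MAP class (posterior)")
interesting = truth[truth.category != "pure_native"].index
for s in noout.samples:
    if s not in interesting and truth.loc[s, "category"] == "pure_native":
        continue
    r = resampled_hybrid_index(noout, s, pool_native, pool_comm, seed=3)
    cp = classify(noout, s, panel, p1, p2)
    best = max(cp.posterior, key=cp.posterior.get)
    print(f"{s:8s} {truth.loc[s, 'category']:16s} {r.h:6.2f}  "
          f"{best} ({cp.posterior[best]:.2f})")
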