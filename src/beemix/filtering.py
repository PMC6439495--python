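"""Site- and individual-level filters and named dataset construction.

Reproduces a RAD-seq SNP curation stage: presence-per-population and minor-allele
frequency thresholds, per-site missingness and mean-coverage caps, removal of
duplicated positions, one-SNP-per-locus thinning, and a read-count quantile cut
on individuals. Named datasets (TOTAL / FEMALES / NO_OUTGROUP) re-apply the site
filters after subsetting samples, so each dataset has its own SNP count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

__all__ = [
    "FilterConfig",
    "FilterReport",
    "DatasetSpec",
    "filter_sites",
    "select_one_snp_per_locus",
    "drop_low_yield_individuals",
    "build_dataset",
    "DATASET_SPECS",
]


@dataclass
class FilterConfig:
    """Thresholds for the site filters, applied in the fixed order
    presence-per-population -> MAF -> missingness -> coverage -> duplicates ->
    one SNP per locus."""

    min_maf: float = 0.05
    min_pops: int = 1
    min_ind_frac_per_pop: float = 0.5
    max_missing_frac: float = 0.25
    max_mean_coverage: float = 200.0
    one_snp_per_locus: bool = False
    drop_duplicate_positions: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("min_maf", "min_ind_frac_per_pop", "max_missing_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.min_pops < 1:
            raise ValueError("min_pops must be >= 1")


@dataclass
class FilterReport:
    """Per-rule removal counts, in application order."""

    rules: list = field(default_factory=list)  # (rule name, sites removed)
    n_input: int = 0
    n_output: int = 0
    flags: dict = field(default_factory=dict)

    def add(self, rule: str, removed: int) -> None:
        self.rules.append((rule, int(removed)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rules, columns=["rule", "sites_removed"])

    def total_removed(self) -> int:
        return sum(r for _, r in self.rules)


@dataclass
class DatasetSpec:
    name: str
    include_males: bool = True
    include_outgroup: bool = True
    config: FilterConfig = field(default_factory=FilterConfig)


def _named_spec(name, males, outgroup, min_pops):
    return DatasetSpec(
        name=name,
        include_males=males,
        include_outgroup=outgroup,
        config=FilterConfig(min_pops=min_pops, one_snp_per_locus=True),
    )


# TOTAL keeps everything (-p 6 with the outgroup as the sixth population);
# FEMALES drops haploid males; NO_OUTGROUP further drops the outgroup (-p 5).
DATASET_SPECS = {
    "TOTAL": _named_spec("TOTAL", True, True, 6),
    "FEMALES": _named_spec("FEMALES", False, True, 6),
    "NO_OUTGROUP": _named_spec("NO_OUTGROUP", False, False, 5),
}


def _group_arrays(geno: GenotypeMatrix, groups: dict):
    labels = []
    for s in geno.samples:
        if s not in groups:
            raise ValueError(f"sample {s} has no group assignment")
        labels.append(groups[s])
    labels = np.asarray(labels, dtype=object)
    names = list(dict.fromkeys(labels))
    for g in names:
        if np.sum(labels == g) == 0:  # pragma: no cover - defensive
            raise ValueError(f"group {g} has zero samples")
    return labels, names


def _maf(geno: GenotypeMatrix, rows=None) -> np.ndarray:
    """Ploidy-aware minor-allele frequency over all called alleles per site."""
    dos = np.where(geno.missing, 0, geno.dosage).astype(float)
    called_alleles = (~geno.missing) * geno.ploidy[None, :]
    alt = dos.sum(axis=1)
    tot = called_alleles.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    return np.minimum(p, 1.0 - p)


def filter_sites(geno: GenotypeMatrix, groups: dict, config: FilterConfig):
    """Apply the ordered site filters; returns (filtered matrix, report).

    A site passes the presence rule when at least ``min_pops`` groups have >= 1
    call AND a called fraction >= ``min_ind_frac_per_pop`` of their members.
    MAF is computed over all called alleles, ploidy-aware. An empty result is a
    warning, not an error.
    """
    labels, names = _group_arrays(geno, groups)
    report = FilterReport(n_input=geno.n_sites)
    keep = np.ones(geno.n_sites, dtype=bool)

    # presence per population
    present_groups = np.zeros(geno.n_sites, dtype=int)
    for g in names:
        cols = labels == g
        called = (~geno.missing[:, cols]).sum(axis=1)
        frac = called / cols.sum()
        present_groups += ((called >= 1) & (frac >= config.min_ind_frac_per_pop)).astype(int)
    bad = keep & (present_groups < config.min_pops)
    report.add("presence_per_population", bad.sum())
    keep &= ~bad

    # minor allele frequency
    maf = _maf(geno)
    bad = keep & (~np.isfinite(maf) | (maf < config.min_maf))
    report.add("min_maf", bad.sum())
    keep &= ~bad

    # missingness (fraction of individuals without a call)
    miss_frac = geno.missing.mean(axis=1)
    bad = keep & (miss_frac > config.max_missing_frac)
    report.add("max_missing", bad.sum())
    keep &= ~bad

    # mean coverage cap
    if geno.coverage is not None:
        bad = keep & np.isfinite(geno.coverage) & (geno.coverage > config.max_mean_coverage)
    else:
        bad = np.zeros_like(keep)
    report.add("max_coverage", bad.sum())
    keep &= ~bad

    # repeated positions (overlapping read artefacts): drop every site sharing
    # an exact (chrom, pos) with another retained site
    if config.drop_duplicate_positions:
        key = pd.MultiIndex.from_arrays([geno.chrom[keep].astype(str), geno.pos[keep]])
        dup = key.duplicated(keep=False)
        bad = np.zeros_like(keep)
        bad[np.flatnonzero(keep)[dup]] = True
        report.add("duplicate_position", bad.sum())
        report.flags["duplicate_positions"] = int(bad.sum())
        keep &= ~bad
    else:
        report.add("duplicate_position", 0)

    out = geno.take_sites(np.flatnonzero(keep))

    if config.one_snp_per_locus:
        before = out.n_sites
        out = select_one_snp_per_locus(out, seed=config.rng_seed)
        report.add("one_snp_per_locus", before - out.n_sites)
    else:
        report.add("one_snp_per_locus", 0)

    report.n_output = out.n_sites
    if out.n_sites == 0:
        warnings.warn("all sites removed by filters", stacklevel=2)
    return out, report


def select_one_snp_per_locus(geno: GenotypeMatrix, locus_map=None, seed: int = 0):
    """Keep exactly one uniformly chosen SNP per locus, deterministically per seed.

    ``locus_map`` maps (chrom, pos, locus-tag) site index -> locus id; by default
    the matrix's own locus tags are used. Sites without a tag are singleton loci
    (kept, flagged). The choice is made on sites sorted by (chrom, pos), so it is
    invariant to the input site order.
    """
    order = geno.site_order()
    if locus_map is None:
        tags = geno.locus[order]
    else:
        tags = np.asarray([locus_map.get(i) for i in order], dtype=object)
    rng = np.random.default_rng(seed)
    chosen = []
    by_locus: dict = {}
    untagged = 0
    for rank, i in enumerate(order):
        tag = tags[rank]
        if tag is None or tag == "":
            untagged += 1
            chosen.append(i)  # singleton locus
            continue
        by_locus.setdefault(tag, []).append(i)
    # iterate loci in first-occurrence order along the coordinate sort
    for tag, members in by_locus.items():
        chosen.append(members[int(rng.integers(len(members)))])
    if untagged:
        warnings.warn(f"{untagged} site(s) without locus tag kept as singleton loci",
                      stacklevel=2)
    chosen = np.sort(np.asarray(chosen, dtype=int))
    return geno.take_sites(chosen)


def drop_low_yield_individuals(metadata: pd.DataFrame, quantile: float = 0.15,
                               protect=()):
    """Drop samples with read_count strictly below the empirical quantile.

    The quantile uses linear interpolation between order statistics (numpy's
    default). Samples named in ``protect`` are never dropped (e.g. an outgroup
    too small to thin). With all-equal counts nothing is strictly below the
    quantile, so nobody is dropped. Returns (kept_ids, dropped_ids).
    """
    counts = metadata["read_count"].to_numpy(dtype=float)
    if np.isnan(counts).any():
        raise ValueError("read_count missing for some samples")
    cut = np.quantile(counts, quantile, method="linear")
    protected = set(protect)
    dropped = [
        s for s, c in zip(metadata["sample_id"], counts)
        if c < cut and s not in protected
    ]
    kept = [s for s in metadata["sample_id"] if s not in set(dropped)]
    return kept, dropped


def build_dataset(geno: GenotypeMatrix, metadata: pd.DataFrame, spec: DatasetSpec,
                  outgroup_label: str = "outgroup"):
    """Subset samples per the dataset spec and re-apply the site filters.

    Site filters are recomputed on the subset, so SNP counts differ between
    named datasets (MAF and presence change when samples change). Returns
    (GenotypeMatrix, FilterReport).
    """
    meta = metadata[metadata["sample_id"].isin(geno.samples)]
    keep = pd.Series(True, index=meta.index)
    if not spec.include_males:
        keep &= meta["sex"].str.lower() != "male"
    if not spec.include_outgroup:
        keep &= meta["group"] != outgroup_label
    names = meta.loc[keep, "sample_id"].tolist()
    sub = geno.take_samples([s for s in geno.samples if s in set(names)])
    groups = dict(zip(meta["sample_id"], meta["group"]))
    cfg = spec.config
    if cfg.min_pops > len(set(groups[s] for s in sub.samples)):
        cfg = replace(cfg, min_pops=len(set(groups[s] for s in sub.samples)))
    return filter_sites(sub, {s: groups[s] for s in sub.samples}, cfg)


def named_dataset_spec(name: str) -> DatasetSpec:
    try:
        return DATASET_SPECS[name]
    except KeyError:
        raise ValueError(
            f"unknown dataset name {name!r}; provide a custom DatasetSpec"
        ) from None
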