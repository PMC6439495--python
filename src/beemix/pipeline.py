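"""End-to-end orchestration: simulate/load -> filter -> stats -> ancestry ->
hybrid index -> classification -> D-statistics -> mtDNA, with a run manifest.

Each stage draws its randomness from a substream derived from the run seed and
the stage name, so stages are individually reproducible and a rerun with the
same seed is byte-identical. Outputs are plain TSV (plus GraphML for the
haplotype network) under the chosen output directory.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .ancestry import align_replicates, run_k_scan
from .dstat import all_individual_dstats, all_population_combinations, results_frame
from .filtering import DATASET_SPECS, build_dataset, drop_low_yield_individuals
from .hybrid_classes import classify, top_fst_panel
from .hybrid_index import parental_panel, resampled_hybrid_index
from .io import (GenotypeMatrix, group_map, read_fasta_alignment, read_metadata,
                 read_vcf, write_fasta, write_metadata, write_vcf)
from .mtdna import build_network, collapse_haplotypes, network_edges_frame
from .popstats import allele_frequencies, diversity, fst_matrix, pca_embed
from .simulate import SimulationConfig, simulate_study

__all__ = ["RunConfig", "run_all", "stage_seed", "write_bundle"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the run seed."""
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Inputs, role assignments and per-stage knobs for a full run."""

    vcf: str | None = None
    metadata: str | None = None
    fasta: str | None = None
    simulation: SimulationConfig | None = None
    outdir: str = "beemix_run"
    seed: int = 0
    # role assignments (native parental pool, commercial pool, D-stat roles)
    pool_native: str = "NFar"
    pool_commercial: str = "CH"
    dstat_p3: str = "CH"
    outgroup: str = "outgroup"
    exclude_from_parentals: tuple = ()   # suspected hybrids kept out of pools
    n_perm: int = 10000
    n_blocks: int = 50
    panel_quantile: float = 0.01
    k_min: int = 1
    k_max: int = 6
    n_replicates: int = 10
    hybrid_resample_k: int = 5
    hybrid_resample_reps: int = 10
    datasets: tuple = ("TOTAL", "FEMALES", "NO_OUTGROUP")


def write_bundle(bundle, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(bundle.geno, outdir / "genotypes.vcf")
    write_metadata(bundle.metadata, outdir / "metadata.tsv")
    write_fasta(bundle.mtdna, outdir / "cox1.fasta")
    bundle.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return {
        "genotypes": str(outdir / "genotypes.vcf"),
        "metadata": str(outdir / "metadata.tsv"),
        "fasta": str(outdir / "cox1.fasta"),
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run the full analysis; returns a manifest dict (also written as JSON).

    Produces: filter reports per dataset, a diversity/F_ST table, PCA
    coordinates per dataset, aligned ancestry Q matrices and the Evanno
    delta-K table, hybrid-index and class-posterior tables, population- and
    individual-level D-statistic tables, and the haplotype table/network.
    A stage failure aborts with the stage name; earlier outputs are kept.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed, "stages": {},
                "inputs": {}}

    def _stage(name):
        manifest["stages"][name] = {"seed": stage_seed(config.seed, name)}
        return manifest["stages"][name]

    try:
        # ---------------- input ------------------------------------------
        stage = _stage("input")
        if config.simulation is not None or config.vcf is None:
            sim = config.simulation or SimulationConfig(
                seed=stage_seed(config.seed, "simulate"))
            bundle = simulate_study(sim)
            paths = write_bundle(bundle, outdir / "simulated_input")
            geno, metadata, mt = bundle.geno, bundle.metadata, bundle.mtdna
            protect = metadata.attrs.get("protect", [])
            stage["simulated"] = True
        else:
            geno = read_vcf(config.vcf)
            metadata = read_metadata(config.metadata)
            mt = read_fasta_alignment(config.fasta) if config.fasta else None
            paths = {"genotypes": config.vcf, "metadata": config.metadata,
                     "fasta": config.fasta}
            protect = []
            stage["simulated"] = False
        manifest["inputs"] = {
            k: {"path": v, "sha256": _sha256(Path(v))}
            for k, v in paths.items() if v
        }

        # ---------------- individual yield filter -------------------------
        stage = _stage("filter")
        kept, dropped = drop_low_yield_individuals(metadata, protect=protect)
        stage["individuals_dropped"] = dropped
        metadata = metadata[metadata["sample_id"].isin(kept)].reset_index(drop=True)
        geno = geno.take_samples([s for s in geno.samples if s in set(kept)])

        # ---------------- named datasets ----------------------------------
        datasets = {}
        for name in config.datasets:
            spec = DATASET_SPECS[name]
            spec.config.rng_seed = stage_seed(config.seed, f"filter:{name}")
            sub, report = build_dataset(geno, metadata, spec,
                                        outgroup_label=config.outgroup)
            datasets[name] = sub
            report.to_frame().to_csv(outdir / f"filter_report_{name}.tsv",
                                     sep="\t", index=False)
            write_vcf(sub, outdir / f"dataset_{name}.vcf")
            stage[name] = {"n_sites": sub.n_sites, "n_samples": sub.n_samples}

        groups = group_map(metadata)
        total = datasets.get("TOTAL", geno)
        females = datasets.get("FEMALES", total)
        noout = datasets.get("NO_OUTGROUP", females)

        # ---------------- diversity + F_ST (Table-1 style) ----------------
        # haploid males get their own "-M" groups: ploidy inflates F_ST, so
        # male and female differentiation are never pooled in one comparison
        stage = _stage("stats")
        sex = dict(zip(metadata["sample_id"], metadata["sex"]))
        t1_groups = {s: g + ("-M" if sex.get(s, "female") == "male" else "")
                     for s, g in groups.items()}
        div = diversity(total, {s: t1_groups[s] for s in total.samples})
        fst = fst_matrix(total, {s: t1_groups[s] for s in total.samples},
                         n_perm=config.n_perm, seed=stage["seed"])
        div.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
        fst.to_csv(outdir / "fst_matrix.tsv", sep="\t", index=False)

        # ---------------- PCA ---------------------------------------------
        _stage("pca")
        for name, ds in datasets.items():
            coords, evr = pca_embed(ds, n_components=10)
            k = coords.shape[1]
            df = pd.DataFrame(coords, columns=[f"PC{i+1}" for i in range(k)])
            df.insert(0, "sample_id", ds.samples)
            df.to_csv(outdir / f"pca_{name}.tsv", sep="\t", index=False)

        # ---------------- ancestry (EM + Evanno) --------------------------
        stage = _stage("ancestry")
        scan = run_k_scan(females, k_min=config.k_min, k_max=config.k_max,
                          n_replicates=config.n_replicates, seed=stage["seed"])
        table = scan.table()
        table.to_csv(outdir / "delta_k.tsv", sep="\t", index=False)
        best_k = scan.best_k()
        stage["best_k"] = int(best_k)
        aligned = align_replicates(scan.results[best_k])
        q_mean = np.mean([r.Q for r in aligned], axis=0)
        qdf = pd.DataFrame(q_mean, columns=[f"k{i+1}" for i in range(best_k)])
        qdf.insert(0, "sample_id", females.samples)
        qdf.to_csv(outdir / "ancestry_q.tsv", sep="\t", index=False)

        # ---------------- parental pools ----------------------------------
        excluded = set(config.exclude_from_parentals)
        pool1 = [s for s in noout.samples
                 if groups[s] == config.pool_native and s not in excluded]
        pool2 = [s for s in noout.samples
                 if groups[s] == config.pool_commercial and s not in excluded]

        # ---------------- hybrid index -------------------------------------
        stage = _stage("hybrid_index")
        rows = []
        for s in noout.samples:
            r = resampled_hybrid_index(
                noout, s, pool1, pool2, k=config.hybrid_resample_k,
                reps=config.hybrid_resample_reps,
                seed=stage_seed(config.seed, f"hybrid_index:{s}"))
            rows.append((s, r.h, r.h_min, r.h_max, r.n_sites_used))
        hi = pd.DataFrame(rows, columns=["sample_id", "h_mean", "h_min",
                                         "h_max", "n_sites_used"])
        hi.to_csv(outdir / "hybrid_index.tsv", sep="\t", index=False)

        # ---------------- hybrid classes -----------------------------------
        stage = _stage("classify")
        noout_groups = {s: groups[s] for s in noout.samples}
        panel_groups = dict(noout_groups)
        for s in excluded:  # suspects leave the pool, not the analysis
            if s in panel_groups and panel_groups[s] in (config.pool_native,
                                                         config.pool_commercial):
                panel_groups[s] = f"{panel_groups[s]}_suspect"
        panel = top_fst_panel(noout, panel_groups, config.pool_native,
                              config.pool_commercial,
                              quantile=config.panel_quantile)
        stage["panel_sites"] = int(panel.n_sites)
        stage["panel_threshold"] = float(panel.threshold)
        ppanel = parental_panel(noout.take_sites(panel.site_idx), pool1, pool2)
        rows = []
        for s in noout.samples:
            if noout.ploidy[noout.sample_index(s)] != 2:
                continue
            cp = classify(noout, s, panel,
                          _expand(ppanel.p1, ppanel.site_mask),
                          _expand(ppanel.p2, ppanel.site_mask))
            rows.append({"sample_id": s, **cp.posterior,
                         "MAP": cp.map_category,
                         "n_panel_sites_used": cp.n_panel_sites_used})
        pd.DataFrame(rows).to_csv(outdir / "class_posteriors.tsv", sep="\t",
                                  index=False)

        # ---------------- D-statistics --------------------------------------
        stage = _stage("dstat")
        dstat_groups = {s: groups[s] for s in females.samples}
        freqs = allele_frequencies(females, dstat_groups)
        natives = [g for g in dict.fromkeys(dstat_groups.values())
                   if g not in (config.dstat_p3, config.outgroup)]
        pop = all_population_combinations(freqs, natives, config.dstat_p3,
                                          config.outgroup,
                                          n_blocks=config.n_blocks)
        results_frame(pop).to_csv(outdir / "dstat_populations.tsv", sep="\t",
                                  index=False)
        ind = all_individual_dstats(freqs, females, dstat_groups, natives,
                                    config.dstat_p3, config.outgroup,
                                    n_blocks=config.n_blocks)
        results_frame(ind).to_csv(outdir / "dstat_individuals.tsv", sep="\t",
                                  index=False)

        # ---------------- mtDNA ---------------------------------------------
        if mt is not None:
            _stage("mtdna")
            table = collapse_haplotypes(mt, groups={s: groups.get(s, "dropped")
                                                    for s in mt.ids})
            hap = pd.DataFrame({
                "haplotype": table.names,
                "sequence": table.sequences,
                "count": table.counts,
            })
            if table.group_counts is not None:
                hap = pd.concat([hap, table.group_counts.reset_index(drop=True)],
                                axis=1)
            hap.to_csv(outdir / "haplotypes.tsv", sep="\t", index=False)
            net = build_network(table)
            network_edges_frame(net).to_csv(outdir / "network_edges.tsv",
                                            sep="\t", index=False)
            nx.write_graphml(net, outdir / "network.graphml")
    except Exception as exc:
        failed = [k for k in manifest["stages"]][-1] if manifest["stages"] else "input"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _expand(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Scatter panel values back onto the full site axis (NaN where dropped)."""
    out = np.full(mask.shape, np.nan)
    out[mask] = values
    return out
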