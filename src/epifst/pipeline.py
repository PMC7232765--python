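"""End-to-end orchestration of the divergence analysis.

One :class:`RunConfig` (built in code or loaded from a YAML file) drives
the stages in order: salinity profiling, locus filtering + F_ST,
methylation tiling, pairwise and meta-population DMR calling, feature
annotation with random-tile nulls, and the joint P_ST–F_ST divergence
summary.  Every stage writes TSV intermediates into the run directory so
the analysis can be re-entered at any point, and a plain-text report plus
a JSON summary close the run.  All thresholds default to the package's
standard values (10-read CpG filter, 100-bp non-overlapping tiles, 8
individuals per group, 15-point difference, q <= 0.05, 65% presence, MAF
0.05).
"""

from __future__ import annotations

import glob
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import annotation, divergence, fst, salinity, tiles
from .config import SimConfig

__all__ = ["RunConfig", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """Raised with a stage-qualified message when a stage cannot run."""


@dataclass
class RunConfig:
    """Paths, thresholds and grouping mode of one pipeline run."""

    outdir: str = "epifst_run"
    genotypes: Optional[str] = None        # VCF or genotype TSV
    popmap: Optional[str] = None
    coverage_dir: Optional[str] = None     # directory of *.cov files
    coverage_dialect: str = "zero_based"
    gff: Optional[str] = None
    salinity_csv: Optional[str] = None
    collection_date: Optional[str] = None
    simulate: bool = False
    sim: Dict = field(default_factory=dict)  # SimConfig overrides

    min_reads: int = 10
    tile: int = 100
    step: int = 100
    min_individuals: int = 8
    diff_threshold: float = 15.0
    q_threshold: float = 0.05
    min_presence: float = 0.65
    min_maf: float = 0.05
    grouping: str = "site"                 # "site" or "meta"
    n_random: int = 39053
    random_sets: int = 6
    seed: int = 0


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML key: value file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = RunConfig.__dataclass_fields__
    unknown = set(data) - set(known)
    if unknown:
        raise PipelineError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _read_popmap(path) -> pd.DataFrame:
    pm = pd.read_csv(path, sep="\t")
    need = {"individual", "site"}
    if not need.issubset(pm.columns):
        raise PipelineError(
            f"population map {path} needs columns {sorted(need)}")
    if "meta_population" not in pm.columns:
        pm["meta_population"] = pm["site"]
    return pm


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the run directory.

    Raises :class:`PipelineError` (after writing nothing beyond the logs
    of completed stages) when an input is missing or inconsistent.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: List[str] = ["epifst pipeline report", "=" * 40]
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(asdict(config), sort_keys=False))

    if config.simulate:
        sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})
        from . import simulate as sim_mod
        inputs = out / "inputs"
        sim_mod.simulate_genotypes(sim_cfg, outdir=inputs)
        sim_mod.simulate_methylomes(sim_cfg, outdir=inputs)
        sim_mod.simulate_genome_annotation(sim_cfg, path=inputs / "genes.gff3")
        pm = sim_mod.population_map(sim_cfg)
        sites = list(pd.unique(pm["site"]))
        means = dict(zip(sites, np.linspace(22, 4, len(sites))))
        sal = sim_mod.simulate_salinity_series(
            means, noise_sd=4.0, n_days=365, seed=config.seed)
        sal.to_csv(inputs / "salinity.csv", index=False)
        config.genotypes = str(inputs / "genotypes.vcf")
        config.popmap = str(inputs / "popmap.tsv")
        config.coverage_dir = str(inputs)
        config.gff = str(inputs / "genes.gff3")
        config.salinity_csv = str(inputs / "salinity.csv")
        if config.collection_date is None:
            config.collection_date = "2015-12-31"
        report.append(f"[simulate] inputs generated under {inputs}")

    required = ("genotypes", "popmap", "coverage_dir", "gff")
    missing = [k for k in required if getattr(config, k) is None]
    if missing:
        raise PipelineError(f"missing required config key(s): {missing}")
    for key in required:
        val = getattr(config, key)
        if not Path(val).exists():
            raise PipelineError(f"{key} path does not exist: {val}")

    popmap = _read_popmap(config.popmap)
    group_col = "meta_population" if config.grouping == "meta" else "site"
    groups = dict(zip(popmap["individual"], popmap[group_col]))
    site_of = dict(zip(popmap["individual"], popmap["site"]))
    meta_of = dict(zip(popmap["individual"], popmap["meta_population"]))

    # ---- salinity ---------------------------------------------------------
    if config.salinity_csv:
        sal = salinity.read_salinity_csv(config.salinity_csv)
        rows = []
        for site, sub in sal.groupby("site", sort=False):
            prof = salinity.bin_salinity_fractions(sub, site=site)
            row = {"site": site, "n_days": prof.n_days,
                   **prof.fractions.to_dict()}
            if config.collection_date:
                try:
                    wm, miss = salinity.window_mean(sub,
                                                    config.collection_date)
                    row["window_mean_psu"] = wm
                    row["window_missing_days"] = miss
                except ValueError:
                    row["window_mean_psu"] = np.nan
            rows.append(row)
        sal_out = pd.DataFrame(rows)
        sal_out.to_csv(out / "salinity_profiles.tsv", sep="\t", index=False)
        report.append(f"[salinity] {len(rows)} site profiles written")
    else:
        report.append("[salinity] no input; skipped")

    # ---- F_ST -------------------------------------------------------------
    pm_for_fst = popmap.rename(columns={group_col: "population"})[
        ["individual", "population"]]
    if str(config.genotypes).endswith((".vcf", ".vcf.gz")):
        gmat = fst.read_vcf(config.genotypes, pm_for_fst)
    else:
        gmat = fst.read_genotype_tsv(config.genotypes, pm_for_fst)
    filtered = fst.filter_loci(gmat, min_presence=config.min_presence,
                               min_maf=config.min_maf)
    fst_tab = fst.fst_per_locus(filtered)
    fst_tab.to_csv(out / "fst_loci.tsv", sep="\t", index=False)
    mean_theta, ratio = fst.mean_fst(fst_tab)
    report.append(f"[fst] {filtered.n_loci}/{gmat.n_loci} loci pass filters; "
                  f"mean theta {mean_theta:.4f}; ratio-of-sums {ratio:.4f}")

    # ---- feature model ----------------------------------------------------
    model = annotation.build_feature_model(config.gff)
    gene_fst = fst.gene_weighted_fst(fst_tab, model)
    gene_fst.to_csv(out / "fst_genes.tsv", sep="\t", index=False)
    report.append(f"[annotate] {len(model.genes)} genes; "
                  f"{len(gene_fst)} with loci in their bodies")

    # ---- coverage / tiles -------------------------------------------------
    cov_paths = sorted(glob.glob(str(Path(config.coverage_dir) / "*.cov")))
    if not cov_paths:
        raise PipelineError(f"no *.cov files in {config.coverage_dir}")
    covs = {}
    for p in cov_paths:
        cov = tiles.read_coverage(p, dialect=config.coverage_dialect)
        covs[cov.individual] = tiles.filter_by_coverage(
            cov, min_reads=config.min_reads)
    unmapped = [i for i in covs if i not in groups]
    if unmapped:
        raise PipelineError(
            f"coverage individuals absent from population map: {unmapped[:5]}")

    tm_all = tiles.make_tiles(covs, groups, tile=config.tile,
                              step=config.step,
                              min_individuals_per_group=config.min_individuals)
    report.append(f"[tiles] {tm_all.n_tiles} tiles covered by >= "
                  f"{config.min_individuals} individuals per group")

    # ---- DMR calling: all pairwise + K=2 meta comparison ------------------
    dmr_tiles_sig: Dict[str, set] = {}
    comparisons = []
    group_names = sorted(set(groups.values()))
    for i, g1 in enumerate(group_names):
        for g2 in group_names[i + 1:]:
            comparisons.append((g1, g2, groups))
    if config.grouping != "meta" and len(set(meta_of.values())) == 2:
        m1, m2 = sorted(set(meta_of.values()))
        comparisons.append((m1, m2, meta_of))
    n_dmrs_total = 0
    for g1, g2, gmap in comparisons:
        pair = {i: g for i, g in gmap.items() if g in (g1, g2) and i in covs}
        tm = tiles.make_tiles({i: covs[i] for i in pair}, pair,
                              tile=config.tile, step=config.step,
                              min_individuals_per_group=config.min_individuals)
        if tm.n_tiles == 0:
            report.append(f"[dmr] {g1} vs {g2}: no tile passes occupancy")
            continue
        res = tiles.dmr_test(tm, g1, g2,
                             diff_threshold=config.diff_threshold,
                             q_threshold=config.q_threshold)
        res.to_csv(out / f"dmr_{g1}_vs_{g2}.tsv", sep="\t", index=False)
        sig = res[res["call"] != "ns"]
        dmr_tiles_sig[f"{g1}_vs_{g2}"] = set(sig["tile"])
        n_dmrs_total += len(sig)
        report.append(f"[dmr] {g1} vs {g2}: {len(res)} tiles tested, "
                      f"{len(sig)} DMRs")

    # ---- annotation of tiles + random nulls -------------------------------
    classified = annotation.classify_regions(tm_all.keys, model)
    classified.to_csv(out / "tile_annotation.tsv", sep="\t", index=False)
    obs_dist = annotation.feature_distribution(classified["category"])
    rng_sets = annotation.generate_random_tiles(
        model, n_per_set=config.n_random, n_sets=config.random_sets,
        seed=config.seed)
    rand_fracs = []
    for s in rng_sets:
        lab = annotation.classify_regions(s, model)
        rand_fracs.append(
            annotation.feature_distribution(lab["category"]).fractions)
    rand_mean = pd.concat(rand_fracs, axis=1).mean(axis=1)
    rand_dist = annotation.FeatureDistribution(
        rand_mean, config.n_random * config.random_sets)
    D, p = annotation.compare_feature_distributions(obs_dist, rand_dist)
    dist_tab = pd.DataFrame({"observed": obs_dist.fractions,
                             "random_mean": rand_mean})
    for si, fr in enumerate(rand_fracs):
        dist_tab[f"random_set{si + 1}"] = fr
    dist_tab.to_csv(out / "feature_distributions.tsv", sep="\t")
    report.append(f"[annotate] covered-tile vs random feature distribution: "
                  f"KS D={D:.3f}, p={p:.3g}")

    # ---- P_ST and joint divergence ----------------------------------------
    site_groups = {i: site_of[i] for i in tm_all.individuals}
    tile_pst = divergence.pst_tiles(tm_all, site_groups)
    tile_pst.to_csv(out / "pst_tiles.tsv", sep="\t", index=False)
    mean_pst = float(tile_pst["pst"].mean())
    n_undef = int(tile_pst["pst"].isna().sum())

    all_sig_tiles = set().union(*dmr_tiles_sig.values()) if dmr_tiles_sig \
        else set()
    dmr_keys = tm_all.tile_ids().isin(all_sig_tiles)
    dmr_genes = set(classified.loc[dmr_keys.values &
                                   (classified["category"] != "intergenic"),
                                   "nearest_gene"].dropna())

    joint, meth_only = divergence.aggregate_by_gene(
        tile_pst, model, gene_fst, dmr_genes=dmr_genes)
    joint.to_csv(out / "gene_join.tsv", sep="\t", index=False)
    meth_only.to_csv(out / "gene_methylation_only.tsv", sep="\t", index=False)

    summary = {
        "mean_fst_loci": mean_theta,
        "fst_ratio_of_sums": ratio,
        "mean_pst_tiles": mean_pst,
        "n_tiles": tm_all.n_tiles,
        "n_pst_undefined": n_undef,
        "pst_fst_ratio": mean_pst / mean_theta if mean_theta else float("nan"),
        "n_dmrs_total": n_dmrs_total,
        "feature_ks": {"D": D, "p": p},
    }
    if len(joint) >= 2:
        summary["gene_level"] = divergence.divergence_summary(joint)
    summary_json = json.dumps(summary, indent=2, default=float)
    (out / "summary.json").write_text(summary_json)
    report.append(f"[divergence] mean tile P_ST {mean_pst:.4f} "
                  f"({n_undef} undefined); mean locus F_ST {mean_theta:.4f}; "
                  f"ratio {summary['pst_fst_ratio']:.2f}")
    (out / "report.txt").write_text("\n".join(report) + "\n")
    return out
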