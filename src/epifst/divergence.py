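"""P_ST — the methylation analogue of F_ST — and the joint divergence summary.

For a region (tile or gene) with per-individual methylation fractions and
population labels,

    P_ST = (Var_Total - Var_Sub) / Var_Total

where ``Var_Total`` is the sample variance (denominator n−1) over all
individuals pooled and ``Var_Sub`` the unweighted mean of the
per-population sample variances.  P_ST is undefined when Var_Total = 0,
equals 1 exactly when all within-population variance vanishes, and may be
slightly negative by sampling noise (it is deliberately not clipped so
region means stay unbiased).  Per-focal-population values
(Var_Total − Var_pop)/Var_Total are also emitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from .tiles import TileMatrix

__all__ = [
    "PstRecord",
    "pst_region",
    "pst_tiles",
    "aggregate_by_gene",
    "divergence_summary",
]


@dataclass
class PstRecord:
    """Variance decomposition of one region's methylation fractions."""

    region: str
    var_total: float
    var_sub: float
    pst: float                      # NaN when var_total == 0
    per_pop_var: Dict[str, float]
    per_pop_pst: Dict[str, float]


def pst_region(fractions: Sequence[float], populations: Sequence[str],
               region: str = "region") -> PstRecord:
    """P_ST of one region from per-individual fractions and labels.

    NaN fractions (individuals without coverage) are dropped; at least two
    populations with two defined fractions each are required.
    """
    x = np.asarray(fractions, dtype=float)
    pops = np.asarray(populations, dtype=object)
    ok = ~np.isnan(x)
    x, pops = x[ok], pops[ok]
    names = pd.unique(pops)
    per_pop = {p: x[pops == p] for p in names}
    informative = [p for p in names if len(per_pop[p]) >= 2]
    if len(informative) < 2:
        raise ValueError(
            "pst_region needs >= 2 populations with >= 2 defined fractions")
    var_total = float(np.var(x, ddof=1))
    pop_vars = {p: float(np.var(per_pop[p], ddof=1)) for p in informative}
    var_sub = float(np.mean(list(pop_vars.values())))
    if var_total > 0:
        pst = (var_total - var_sub) / var_total
        per_pop_pst = {p: (var_total - v) / var_total
                       for p, v in pop_vars.items()}
    else:
        pst = float("nan")
        per_pop_pst = {p: float("nan") for p in pop_vars}
    return PstRecord(region, var_total, var_sub, pst, pop_vars, per_pop_pst)


def pst_fractions(frac: np.ndarray, populations: Sequence[str]
                  ) -> pd.DataFrame:
    """Vectorised P_ST over many regions.

    ``frac`` is (n_regions, n_individuals) with NaN for missing; returns a
    DataFrame with var_total, var_sub, pst per region (NaN pst where
    var_total = 0 or fewer than two populations have two defined values).
    """
    frac = np.asarray(frac, dtype=float)
    pops = np.asarray(populations, dtype=object)
    names = pd.unique(pops)
    defined = ~np.isnan(frac)

    n_all = defined.sum(axis=1)
    mean_all = np.nanmean(np.where(defined, frac, np.nan), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ss_all = np.nansum((frac - mean_all[:, None]) ** 2, axis=1)
        var_total = np.where(n_all > 1, ss_all / (n_all - 1), np.nan)

    pop_vars = []
    pop_ok = []
    for p in names:
        cols = pops == p
        sub = frac[:, cols]
        n_p = (~np.isnan(sub)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            m_p = np.nanmean(sub, axis=1)
            ss_p = np.nansum((sub - m_p[:, None]) ** 2, axis=1)
            v_p = np.where(n_p > 1, ss_p / (n_p - 1), np.nan)
        pop_vars.append(v_p)
        pop_ok.append(n_p >= 2)
    pop_vars = np.vstack(pop_vars)
    pop_ok = np.vstack(pop_ok)
    n_pops_ok = pop_ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        var_sub = np.nansum(np.where(pop_ok, pop_vars, 0.0), axis=0)
        var_sub = np.where(n_pops_ok > 0, var_sub / n_pops_ok, np.nan)
        pst = np.where((n_pops_ok >= 2) & (var_total > 0),
                       (var_total - var_sub) / var_total, np.nan)
    out = pd.DataFrame({"var_total": var_total, "var_sub": var_sub,
                        "pst": pst})
    for i, p in enumerate(names):
        out[f"var_{p}"] = pop_vars[i]
    return out


def pst_tiles(tiles: TileMatrix,
              populations: Optional[Dict[str, str]] = None) -> pd.DataFrame:
    """Per-tile P_ST from a :class:`~epifst.tiles.TileMatrix`.

    Fractions are the per-individual pooled tile fractions (NaN where an
    individual has no reads in the tile).  ``populations`` maps individual
    to population; defaults to the tile matrix's own grouping.
    """
    groups = populations or tiles.groups
    labels = [groups[i] for i in tiles.individuals]
    res = pst_fractions(tiles.fractions(), labels)
    keys = tiles.keys.reset_index(drop=True)
    res.insert(0, "tile", keys["chrom"].astype(str) + ":"
               + keys["start"].astype(str) + "-" + keys["end"].astype(str))
    res.insert(1, "chrom", keys["chrom"].values)
    res.insert(2, "start", keys["start"].values)
    res.insert(3, "end", keys["end"].values)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = tiles.meth.sum(axis=1) / tiles.total.sum(axis=1)
    res["pooled_pct"] = 100.0 * pooled
    return res


def aggregate_by_gene(tile_pst: pd.DataFrame, genes: pd.DataFrame,
                      gene_fst: Optional[pd.DataFrame] = None,
                      dmr_genes: Optional[Set[str]] = None,
                      flank: int = 2000):
    """Gene-level reduction of tile methylation and join with gene F_ST.

    Per gene body (``flank`` bp upstream through downstream of the gene
    span): mean of tile pooled percentages, mean of defined tile P_ST.
    Returns ``(joint, meth_only)``: genes present in both the methylation
    and F_ST tables, and genes with tiles but no F_ST (or no F_ST table).
    ``dmr_genes`` flags genes containing at least one DMR tile.
    """
    genes = getattr(genes, "genes", genes)
    rows = []
    for chrom, gsub in genes.groupby("chrom", sort=False):
        tsub = tile_pst[tile_pst["chrom"] == chrom]
        if tsub.empty:
            continue
        starts = tsub["start"].to_numpy()
        ends = tsub["end"].to_numpy()
        for g in gsub.itertuples():
            lo, hi = max(0, g.start - flank), g.end + flank
            sel = (ends > lo) & (starts < hi)
            if not sel.any():
                continue
            sub = tsub.loc[sel]
            rows.append({
                "gene_id": g.gene_id,
                "chrom": chrom,
                "n_tiles": int(sel.sum()),
                "mean_methylation_pct": float(sub["pooled_pct"].mean()),
                "mean_pst": float(sub["pst"].mean())
                if sub["pst"].notna().any() else np.nan,
                "is_dmr": bool(g.gene_id in dmr_genes) if dmr_genes is not None
                else False,
            })
    meth = pd.DataFrame(rows, columns=["gene_id", "chrom", "n_tiles",
                                       "mean_methylation_pct", "mean_pst",
                                       "is_dmr"])
    if gene_fst is None or gene_fst.empty:
        return meth.iloc[0:0].assign(fst=pd.Series(dtype=float)), meth
    joint = meth.merge(gene_fst[["gene_id", "fst"]], on="gene_id",
                       how="inner")
    meth_only = meth[~meth["gene_id"].isin(joint["gene_id"])]
    return joint, meth_only


def divergence_summary(join: pd.DataFrame,
                       dmr_genes: Optional[Set[str]] = None) -> dict:
    """Joint P_ST–F_ST summary over the gene join table.

    Returns mean P_ST, mean F_ST, their ratio, Pearson and Spearman
    correlations between per-gene P_ST and F_ST (NaN and flagged when a
    column is constant), and a two-sample KS test of the F_ST of
    DMR-flagged genes against all genes (skipped with a note when the DMR
    set is empty).
    """
    if len(join) < 2:
        raise ValueError("divergence summary needs >= 2 gene rows")
    pst = join["mean_pst"].astype(float)
    fst = join["fst"].astype(float)
    out = {
        "mean_pst": float(pst.mean()),
        "mean_fst": float(fst.mean()),
        "n_genes": int(len(join)),
        "notes": [],
    }
    out["pst_fst_ratio"] = (out["mean_pst"] / out["mean_fst"]
                            if out["mean_fst"] != 0 else float("nan"))
    ok = pst.notna() & fst.notna()
    if ok.sum() >= 2 and pst[ok].nunique() > 1 and fst[ok].nunique() > 1:
        out["pearson_r"] = float(stats.pearsonr(pst[ok], fst[ok])[0])
        out["spearman_rho"] = float(stats.spearmanr(pst[ok], fst[ok])[0])
    else:
        out["pearson_r"] = out["spearman_rho"] = float("nan")
        out["notes"].append("correlations undefined (constant column)")
    if dmr_genes is None:
        dmr_mask = join.get("is_dmr", pd.Series(False, index=join.index))
    else:
        dmr_mask = join["gene_id"].isin(dmr_genes)
    dmr_fst = fst[dmr_mask & fst.notna()]
    all_fst = fst[fst.notna()]
    if len(dmr_fst) == 0:
        out["ks_dmr_vs_all"] = None
        out["notes"].append("no DMR-flagged gene; KS comparison skipped")
    else:
        res = stats.ks_2samp(dmr_fst, all_fst)
        out["ks_dmr_vs_all"] = {"D": float(res.statistic),
                                "p": float(res.pvalue),
                                "n_dmr": int(len(dmr_fst)),
                                "n_all": int(len(all_fst))}
    return out
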